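"""Shared in-memory containers.

The screen works on plain nucleotide strings grouped into a
:class:`ScaffoldSet` (an assembly under screen, a database, or a simulated
genome), plus a :class:`TruthSet` describing what a simulated genome really
contains.  Coordinates everywhere in this package are 0-based half-open;
1-based inclusive coordinates appear only inside files that demand them
(BLAST-style tabular hits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import ConsistencyError, InputError


class ScaffoldSet:
    """An ordered collection of named nucleotide sequences.

    Sequences keep their case: lowercase marks soft-masked positions
    (excluded from seeding, allowed in alignment extension).  An optional
    taxon label per sequence identifies the donor organism for database
    sequences.

    Parameters
    ----------
    sequences
        Mapping of scaffold name to sequence string (insertion order kept).
    taxa
        Optional mapping of scaffold name to taxon label.
    """

    def __init__(self, sequences: dict[str, str] | None = None,
                 taxa: dict[str, str] | None = None):
        self._seqs: dict[str, str] = dict(sequences or {})
        self.taxa: dict[str, str] = dict(taxa or {})

    def add(self, name: str, seq: str, taxon: str | None = None) -> None:
        if name in self._seqs:
            raise InputError(f"duplicate scaffold name {name!r}")
        self._seqs[name] = seq
        if taxon is not None:
            self.taxa[name] = taxon

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def taxon_of(self, name: str) -> str:
        return self.taxa.get(name, name)

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise ConsistencyError(f"unknown scaffold {name!r}") from None

    def __setitem__(self, name: str, seq: str) -> None:
        self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScaffoldSet({len(self)} sequences, {self.total_length} bp)"


@dataclass(frozen=True)
class ImplantTruth:
    """One implanted bacterial segment: where it landed and what it was."""

    scaffold: str
    start: int          # 0-based, post-insertion coordinates
    end: int            # half-open
    taxon: str
    divergence: float   # realized per-site substitution fraction
    source: str = ""    # donor substring before decay (kept for oracles)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ContaminantTruth:
    """One whole bacterial scaffold co-assembled into the genome."""

    scaffold: str
    taxon: str


@dataclass
class TruthSet:
    """Simulator ground truth: implanted intervals plus contaminant scaffolds."""

    implants: list[ImplantTruth] = field(default_factory=list)
    contaminants: list[ContaminantTruth] = field(default_factory=list)

    def implants_on(self, scaffold: str) -> list[ImplantTruth]:
        return [t for t in self.implants if t.scaffold == scaffold]

    def validate(self, genome: ScaffoldSet) -> None:
        """Check implant intervals are in-bounds and pairwise disjoint per scaffold."""
        by_scaffold: dict[str, list[ImplantTruth]] = {}
        for t in self.implants:
            if not (0 <= t.start < t.end <= len(genome[t.scaffold])):
                raise ConsistencyError(
                    f"implant {t.scaffold}:{t.start}-{t.end} out of bounds")
            by_scaffold.setdefault(t.scaffold, []).append(t)
        for items in by_scaffold.values():
            items.sort(key=lambda t: t.start)
            for a, b in zip(items, items[1:]):
                if b.start < a.end:
                    raise ConsistencyError(
                        f"implants overlap on {a.scaffold}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")


PAIR_COLUMNS = ["pair_id", "scaffold", "m1_start", "m1_end",
                "m2_start", "m2_end", "orientation"]
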