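"""Per-scaffold triage: whole bacterial scaffolds vs host scaffolds.

Co-assembled endosymbiont or contaminant scaffolds look bacterial end to
end; host scaffolds carrying an LGT insertion show only a short bacterial
region and usually stronger animal evidence.  Each scaffold gets exactly one
call:

* ``bacterial``  — best bacterial bit score beats the best animal bit score
  AND bacterial hits cover at least ``min_cov`` of the scaffold;
* ``host``       — no bacterial hit, or animal evidence at least as strong;
* ``ambiguous``  — bacterial-best but low coverage: the LGT-bearing host
  scaffold case, routed to the windowed scan.

"Score" here is always the bit score, comparable across databases of
different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import ScaffoldSet
from .errors import ConsistencyError
from .homology import HomologyHit


@dataclass
class ScaffoldCall:
    scaffold: str
    length: int
    call: str                               # bacterial | host | ambiguous
    best_bacterial: tuple | None            # (bit, e_value, taxon)
    best_animal: tuple | None               # (bit, e_value)
    n_bacterial_hits: int
    bacterial_covered_fraction: float
    has_rrna_like_hit: bool = False


def _best(hits: list[HomologyHit]) -> HomologyHit | None:
    """Best hit by bit score; ties broken by lower E then subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject))


def _covered_fraction(hits: list[HomologyHit], length: int) -> float:
    ivs = sorted((h.q_start, h.q_end) for h in hits)
    covered = 0
    cur_a = cur_b = None
    for a, b in ivs:
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        covered += cur_b - cur_a
    return covered / length if length else 0.0


def classify_scaffolds(scaffolds: ScaffoldSet,
                       bacterial_hits: list[HomologyHit],
                       animal_hits: list[HomologyHit],
                       min_cov: float = 0.5,
                       rrna_subjects: frozenset[str] = frozenset(),
                       ) -> list[ScaffoldCall]:
    """One call per scaffold (scaffolds with no hits default to host)."""
    by_scaffold_b: dict[str, list[HomologyHit]] = {}
    by_scaffold_a: dict[str, list[HomologyHit]] = {}
    for h in bacterial_hits:
        if h.query not in scaffolds:
            raise ConsistencyError(f"bacterial hit on unknown scaffold {h.query!r}")
        by_scaffold_b.setdefault(h.query, []).append(h)
    for h in animal_hits:
        if h.query not in scaffolds:
            raise ConsistencyError(f"animal hit on unknown scaffold {h.query!r}")
        by_scaffold_a.setdefault(h.query, []).append(h)

    calls = []
    for name, seq in scaffolds:
        bhits = by_scaffold_b.get(name, [])
        ahits = by_scaffold_a.get(name, [])
        best_b = _best(bhits)
        best_a = _best(ahits)
        cov = _covered_fraction(bhits, len(seq))
        if best_b is None:
            call = "host"
        elif best_a is not None and best_a.bit_score >= best_b.bit_score:
            call = "host"
        elif cov >= min_cov:
            call = "bacterial"
        else:
            call = "ambiguous"
        calls.append(ScaffoldCall(
            scaffold=name, length=len(seq), call=call,
            best_bacterial=((best_b.bit_score, best_b.e_value, best_b.taxon)
                            if best_b else None),
            best_animal=((best_a.bit_score, best_a.e_value)
                         if best_a else None),
            n_bacterial_hits=len(bhits),
            bacterial_covered_fraction=cov,
            has_rrna_like_hit=any(h.subject in rrna_subjects for h in bhits)))
    return calls


def summarize_bacterial_bins(calls: list[ScaffoldCall]) -> pd.DataFrame:
    """Group scaffolds called bacterial by best-hit taxon.

    Returns a frame with one row per taxon: scaffold count and summed
    length, descending by count then taxon name.
    """
    rows: dict[str, list] = {}
    for c in calls:
        if c.call != "bacterial":
            continue
        taxon = c.best_bacterial[2] if c.best_bacterial else ""
        rows.setdefault(taxon, [0, 0])
        rows[taxon][0] += 1
        rows[taxon][1] += c.length
    data = [(t, n, ln) for t, (n, ln) in rows.items()]
    data.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(data, columns=["taxon", "n_scaffolds", "total_length"])


def calls_to_frame(calls: list[ScaffoldCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scaffold": c.scaffold, "length": c.length, "call": c.call,
        "best_bacterial_bit": c.best_bacterial[0] if c.best_bacterial else 0.0,
        "best_bacterial_evalue": c.best_bacterial[1] if c.best_bacterial else "",
        "best_bacterial_taxon": c.best_bacterial[2] if c.best_bacterial else "",
        "best_animal_bit": c.best_animal[0] if c.best_animal else 0.0,
        "n_bacterial_hits": c.n_bacterial_hits,
        "bacterial_covered_fraction": round(c.bacterial_covered_fraction, 4),
        "has_rrna_like_hit": c.has_rrna_like_hit,
    } for c in calls])
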