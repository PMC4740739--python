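"""Truth-tracked genome simulator.

Generates the inputs the screen assumes: random host scaffolds, bacterial
donor genomes with a GC offset (so detection is driven by implanted
identity, not base composition), implanted LGT segments decayed by i.i.d.
substitutions, whole contaminant scaffolds emulating co-assembled
endosymbionts, junction-neighbourhood mate pairs, and per-condition
expression coverage tracks with a male-specific pattern.

The decay model is substitution-only: implant coordinates in the truth set
stay exact, which keeps recovery statistics crisp.  Indel decay and read
error models are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (PAIR_COLUMNS, ContaminantTruth, ImplantTruth,
                         ScaffoldSet, TruthSet)
from .errors import ConfigurationError, PlacementError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default donor taxon labels; genera reported as common LGT donors in the
#: bed-bug screen, recycled here so simulated outputs read naturally
DEFAULT_TAXA = ["Arsenophonus", "Wolbachia", "Sodalis",
                "Hamiltoniella", "Peptoclostridium"]


@dataclass(frozen=True)
class SimulationConfig:
    """All simulator knobs; defaults are the package's reference conditions.

    seed                    : PRNG seed; identical configs give byte-identical outputs.
    n_host_scaffolds        : host scaffolds in the assembly.
    host_scaffold_length    : bp per host scaffold.
    host_gc                 : host GC fraction (insect-like AT-rich default).
    n_donor_taxa            : bacterial donor genomes.
    donor_length            : bp per donor.
    donor_gc_offset         : donor GC = host GC + offset, capped at 0.8.
    n_implants              : LGT segments implanted across the host.
    implant_length_min/max  : implant length drawn uniformly in [min, max].
    divergence              : per-site substitution probability d (post-insertion decay).
    min_implant_spacing     : minimum bp between implants on a scaffold.
    n_contaminant_scaffolds : whole bacterial scaffolds appended to the assembly.
    contaminant_divergence  : decay applied to contaminant scaffolds.
    pair_insert_mean/sd     : mate-pair insert size (bp).
    read_length             : bp per mate.
    pair_depth              : physical (insert) coverage over junction neighbourhoods.
    expressed_fraction      : fraction of implants transcribed in condition A only.
    expression_depth        : fold coverage given to expressed implants.
    """

    seed: int = 0
    n_host_scaffolds: int = 10
    host_scaffold_length: int = 100_000
    host_gc: float = 0.36
    n_donor_taxa: int = 3
    donor_length: int = 50_000
    donor_gc_offset: float = 0.10
    n_implants: int = 20
    implant_length_min: int = 150
    implant_length_max: int = 2_000
    divergence: float = 0.05
    min_implant_spacing: int = 2_000
    n_contaminant_scaffolds: int = 2
    contaminant_divergence: float = 0.02
    pair_insert_mean: float = 500.0
    pair_insert_sd: float = 50.0
    read_length: int = 100
    pair_depth: float = 30.0
    expressed_fraction: float = 0.1
    expression_depth: float = 50.0

    def __post_init__(self):
        def bad(name, why=""):
            raise ConfigurationError(f"invalid {name}{': ' + why if why else ''}")

        for name in ("n_host_scaffolds", "host_scaffold_length",
                     "n_donor_taxa", "donor_length", "read_length"):
            if getattr(self, name) <= 0:
                bad(name, "must be positive")
        for name in ("n_implants", "n_contaminant_scaffolds",
                     "min_implant_spacing"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if not (0.0 <= self.host_gc <= 1.0):
            bad("host_gc", "must be in [0, 1]")
        for name in ("divergence", "contaminant_divergence",
                     "expressed_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                bad(name, "must be in [0, 1]")
        if self.implant_length_min < 1:
            bad("implant_length_min", "must be >= 1")
        if self.implant_length_max < self.implant_length_min:
            bad("implant_length_max", "must be >= implant_length_min")
        if self.implant_length_max > self.donor_length:
            bad("implant_length_max", "exceeds donor_length")
        if self.pair_insert_mean <= 2 * self.read_length:
            bad("pair_insert_mean", "must exceed 2 * read_length")
        if self.pair_depth < 0:
            bad("pair_depth", "must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per simulator stage."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, d: float) -> tuple[str, float]:
    """i.i.d. substitutions at rate d; returns (sequence, realized divergence)."""
    if d == 0.0 or not seq:
        return seq, 0.0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < d
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq, 0.0
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    cur = lut[arr[idx]]
    # pick uniformly among the three other bases
    offs = rng.integers(1, 4, size=len(idx))
    arr[idx] = _BASES[(cur + offs) % 4]
    return arr.tobytes().decode("ascii"), len(idx) / len(arr)


def simulate_host(config: SimulationConfig) -> ScaffoldSet:
    """Random host scaffolds at the configured GC; deterministic given seed."""
    rng = _rng(config, 1)
    out = ScaffoldSet()
    for i in range(config.n_host_scaffolds):
        out.add(f"scaffold_{i + 1}",
                _random_seq(rng, config.host_scaffold_length, config.host_gc))
    return out


def simulate_donors(config: SimulationConfig) -> ScaffoldSet:
    """Bacterial donor genomes, one per taxon, GC-offset from the host."""
    rng = _rng(config, 2)
    gc = min(config.host_gc + config.donor_gc_offset, 0.8)
    out = ScaffoldSet()
    for i in range(config.n_donor_taxa):
        taxon = (DEFAULT_TAXA[i] if i < len(DEFAULT_TAXA)
                 else f"Taxon{i + 1}")
        out.add(f"donor_{taxon}", _random_seq(rng, config.donor_length, gc),
                taxon=taxon)
    return out


def implant_lgts(host: ScaffoldSet, donors: ScaffoldSet,
                 config: SimulationConfig) -> tuple[ScaffoldSet, TruthSet]:
    """Insert decayed donor substrings at spaced random host positions.

    Host length grows by the implant lengths; the truth set records exact
    post-insertion coordinates, the donor taxon, the realized divergence and
    the pre-decay source substring.
    """
    rng = _rng(config, 3)
    names = host.names
    donor_names = donors.names
    # choose insertion points in original host coordinates, spaced per scaffold
    placements: dict[str, list[tuple[int, int, str]]] = {n: [] for n in names}
    tries = 0
    placed = 0
    while placed < config.n_implants:
        tries += 1
        if tries > 200 * max(1, config.n_implants):
            raise PlacementError(
                f"could not place {config.n_implants} implants with "
                f"{config.min_implant_spacing}-bp spacing")
        sc = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(len(host[sc]) + 1))
        if any(abs(pos - p) < config.min_implant_spacing
               for p, _, _ in placements[sc]):
            continue
        length = int(rng.integers(config.implant_length_min,
                                  config.implant_length_max + 1))
        dn = donor_names[int(rng.integers(len(donor_names)))]
        placements[sc].append((pos, length, dn))
        placed += 1

    genome = ScaffoldSet(taxa=dict(host.taxa))
    truth = TruthSet()
    for name in names:
        seq = host[name]
        parts = []
        cursor = 0
        offset = 0
        for pos, length, dn in sorted(placements[name]):
            donor_seq = donors[dn]
            start = int(rng.integers(len(donor_seq) - length + 1))
            source = donor_seq[start:start + length]
            decayed, realized = _mutate(rng, source, config.divergence)
            parts.append(seq[cursor:pos])
            parts.append(decayed)
            truth.implants.append(ImplantTruth(
                scaffold=name, start=pos + offset,
                end=pos + offset + length, taxon=donors.taxon_of(dn),
                divergence=realized, source=source))
            offset += length
            cursor = pos
        parts.append(seq[cursor:])
        genome.add(name, "".join(parts))
    return genome, truth


def add_contaminants(genome: ScaffoldSet, donors: ScaffoldSet,
                     config: SimulationConfig,
                     truth: TruthSet | None = None) -> tuple[ScaffoldSet, TruthSet]:
    """Append whole donor-derived scaffolds (co-assembled endosymbionts)."""
    if config.n_contaminant_scaffolds > len(donors):
        raise ConfigurationError(
            "n_contaminant_scaffolds exceeds available donor taxa")
    rng = _rng(config, 4)
    truth = truth if truth is not None else TruthSet()
    out = ScaffoldSet(taxa=dict(genome.taxa))
    for name, seq in genome:
        out.add(name, seq)
    donor_names = donors.names
    for i in range(config.n_contaminant_scaffolds):
        dn = donor_names[i % len(donor_names)]
        decayed, _ = _mutate(rng, donors[dn], config.contaminant_divergence)
        sc_name = f"contaminant_{i + 1}"
        out.add(sc_name, decayed)
        truth.contaminants.append(
            ContaminantTruth(scaffold=sc_name, taxon=donors.taxon_of(dn)))
    return out, truth


def simulate_pairs(genome: ScaffoldSet, truth: TruthSet,
                   config: SimulationConfig) -> pd.DataFrame:
    """Mate placements over each implant's junction neighbourhood.

    Pair starts arrive at rate ``pair_depth / insert_mean`` per bp (physical
    coverage ``pair_depth``), so the expected number of pairs bridging a
    junction is ``pair_depth * (insert - 2*read_length) / insert`` — the
    Lander-Waterman expectation.
    """
    rng = _rng(config, 5)
    rows = []
    pair_id = 0
    rl = config.read_length
    mean, sd = config.pair_insert_mean, config.pair_insert_sd
    for t in truth.implants:
        sc_len = len(genome[t.scaffold])
        if sc_len < mean + 4 * sd:
            raise PlacementError(
                f"scaffold {t.scaffold} shorter than insert size")
        margin = int(mean + 4 * sd)
        lo = max(0, t.start - margin)
        hi = min(sc_len, t.end + margin)
        if config.pair_depth == 0:
            continue
        n_pairs = rng.poisson(config.pair_depth * (hi - lo) / mean)
        for _ in range(n_pairs):
            insert = max(2 * rl + 1, int(round(rng.normal(mean, sd))))
            start = int(rng.integers(lo, hi))
            end = start + insert
            if end > sc_len:
                continue
            rows.append((f"pair_{pair_id}", t.scaffold,
                         start, start + rl, end - rl, end, "FR"))
            pair_id += 1
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def simulate_expression(genome: ScaffoldSet, truth: TruthSet,
                        config: SimulationConfig,
                        conditions: tuple[str, str] = ("male", "female"),
                        ) -> dict[str, dict[str, list[tuple[int, int, float]]]]:
    """Coverage tracks per condition: an expressed_fraction of implants get
    uniform ``expression_depth`` coverage in the first condition and zero in
    the second; everything else is zero everywhere."""
    rng = _rng(config, 6)
    tracks: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        c: {} for c in conditions}
    for t in truth.implants:
        if rng.random() < config.expressed_fraction:
            tracks[conditions[0]].setdefault(t.scaffold, []).append(
                (t.start, t.end, config.expression_depth))
    for cond in conditions:
        for runs in tracks[cond].values():
            runs.sort()
    return tracks


@dataclass
class Simulation:
    """Everything one simulated study provides, bundled."""

    config: SimulationConfig
    genome: ScaffoldSet
    donors: ScaffoldSet
    host_reference: ScaffoldSet   # pre-insertion host copies (animal database)
    truth: TruthSet
    pairs: pd.DataFrame
    expression: dict = field(default_factory=dict)


def simulate(config: SimulationConfig) -> Simulation:
    """Run the full generator: host, donors, implants, contaminants, pairs,
    expression.  The pre-insertion host doubles as the animal database."""
    host = simulate_host(config)
    donors = simulate_donors(config)
    genome, truth = implant_lgts(host, donors, config)
    genome, truth = add_contaminants(genome, donors, config, truth)
    truth.validate(genome)
    pairs = simulate_pairs(genome, truth, config)
    expression = simulate_expression(genome, truth, config)
    animal = ScaffoldSet({f"animal_{n}": s for n, s in host})
    return Simulation(config=config, genome=genome, donors=donors,
                      host_reference=animal, truth=truth, pairs=pairs,
                      expression=expression)
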