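"""The windowed LGT scan.

Scaffolds are tiled into abutting 1,000-bp windows; each window is searched
against the (masked) bacterial database, hit regions are lifted back to
scaffold coordinates, counter-screened against the animal database, joined
when less than 50 bp apart (strict), and length-filtered at >= 100 bp
(inclusive).  The join gap, window size, length threshold and E-value cutoff
are all parameters; the defaults are the screen's published operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .classify import ScaffoldCall
from .containers import ScaffoldSet
from .errors import ConfigurationError, ConsistencyError
from .homology import HomologyHit, ScoringParams, SeedIndex, search


@dataclass(frozen=True)
class ScanParams:
    """Windowed-scan tuning.

    window   : tile width W in bp.
    join_gap : two bacterial-similar intervals merge when their gap is
               strictly less than this (bp).
    min_len  : candidates shorter than this are dropped (inclusive keep).
    e_cutoff : maximum E-value for bacterial and animal hits.
    counter_rule : 'bacterial_gt_animal' keeps an interval unless an
               overlapping animal hit scores at least as high (bit score);
               'absent_animal' keeps only intervals with no animal hit at all.
    """

    window: int = 1_000
    join_gap: int = 50
    min_len: int = 100
    e_cutoff: float = 1e-5
    counter_rule: str = "bacterial_gt_animal"

    def __post_init__(self):
        if self.window < self.min_len:
            raise ConfigurationError("window must be >= min_len")
        if self.join_gap < 0:
            raise ConfigurationError("join_gap must be >= 0")
        if self.counter_rule not in ("bacterial_gt_animal", "absent_animal"):
            raise ConfigurationError(
                f"unknown counter_rule {self.counter_rule!r}")


@dataclass
class BacterialInterval:
    """A bacterial-similar region in scaffold coordinates."""

    scaffold: str
    start: int
    end: int
    best_hit: HomologyHit           # query coordinates already lifted
    n_windows: int = 1
    best_animal_bit: float | None = None


@dataclass
class LgtCandidate:
    """A merged, length-filtered putative LGT."""

    scaffold: str
    start: int
    end: int
    taxon: str
    bact_bit: float
    bact_evalue: float
    animal_bit: float | None = None
    n_windows: int = 1
    junction: object = None         # JunctionSupport, filled downstream
    expression: object = None       # ExpressionCall, filled downstream

    @property
    def id(self) -> str:
        return f"{self.scaffold}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def window_scaffolds(scaffolds: ScaffoldSet, window: int = 1_000,
                     min_tail: int = 1) -> list[tuple[str, int, int]]:
    """Abutting half-open tiles [0,W), [W,2W), ... per scaffold.

    A final partial tile is emitted only when at least ``min_tail`` bp long
    (the scan passes the seed word size, below which a tile cannot hit).
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    tiles = []
    for name, seq in scaffolds:
        n = len(seq)
        pos = 0
        while pos + window <= n:
            tiles.append((name, pos, pos + window))
            pos += window
        if n - pos >= min_tail and n - pos > 0:
            tiles.append((name, pos, n))
    return tiles


def scan_bacterial(tiles: list[tuple[str, int, int]], scaffolds: ScaffoldSet,
                   index: SeedIndex, scoring: ScoringParams,
                   params: ScanParams) -> list[BacterialInterval]:
    """Search each tile against the bacterial database; lift hits to
    scaffold coordinates.  Each interval keeps its best hit."""
    scoring = replace(scoring, e_cutoff=params.e_cutoff)
    out: list[BacterialInterval] = []
    for name, start, end in tiles:
        if name not in scaffolds or end > len(scaffolds[name]):
            raise ConsistencyError(f"tile {name}:{start}-{end} out of bounds")
        seq = scaffolds[name][start:end]
        hits = search(seq, index, scoring, query_name=name)
        for h in hits:
            lifted = h.shifted(start)
            out.append(BacterialInterval(
                scaffold=name, start=lifted.q_start, end=lifted.q_end,
                best_hit=lifted))
    out.sort(key=lambda iv: (iv.scaffold, iv.start, iv.end))
    return out


def counter_screen(intervals: list[BacterialInterval],
                   scaffolds: ScaffoldSet, animal_index: SeedIndex,
                   scoring: ScoringParams,
                   params: ScanParams) -> list[BacterialInterval]:
    """Search each bacterial-similar subregion against the animal database.

    Under ``bacterial_gt_animal`` an interval survives unless some animal
    hit overlapping it reaches a bit score at least equal to its bacterial
    bit score; under ``absent_animal`` any animal hit at E <= cutoff kills
    it.  Surviving intervals are unchanged in coordinates.
    """
    scoring = replace(scoring, e_cutoff=params.e_cutoff)
    kept: list[BacterialInterval] = []
    for iv in intervals:
        seq = scaffolds[iv.scaffold][iv.start:iv.end]
        ahits = search(seq, animal_index, scoring, query_name=iv.scaffold)
        best_a = max((h.bit_score for h in ahits), default=None)
        iv.best_animal_bit = best_a
        if params.counter_rule == "absent_animal":
            if not ahits:
                kept.append(iv)
        else:
            if best_a is None or best_a < iv.best_hit.bit_score:
                kept.append(iv)
    return kept


def join_intervals(intervals: list[BacterialInterval],
                   join_gap: int = 50) -> list[BacterialInterval]:
    """Merge same-scaffold intervals whose gap is strictly below ``join_gap``.

    Applied transitively to a fixpoint; the merged interval keeps the
    higher-bit bacterial hit of its parts and sums window counts.
    """
    by_scaffold: dict[str, list[BacterialInterval]] = {}
    for iv in intervals:
        by_scaffold.setdefault(iv.scaffold, []).append(iv)
    out: list[BacterialInterval] = []
    for name in sorted(by_scaffold):
        ivs = sorted(by_scaffold[name], key=lambda iv: (iv.start, iv.end))
        cur = None
        for iv in ivs:
            if cur is None:
                cur = replace_interval(iv)
            elif iv.start - cur.end < join_gap:
                cur.end = max(cur.end, iv.end)
                cur.n_windows += iv.n_windows
                if iv.best_hit.bit_score > cur.best_hit.bit_score:
                    cur.best_hit = iv.best_hit
                if iv.best_animal_bit is not None:
                    cur.best_animal_bit = max(cur.best_animal_bit or 0.0,
                                              iv.best_animal_bit)
            else:
                out.append(cur)
                cur = replace_interval(iv)
        if cur is not None:
            out.append(cur)
    return out


def replace_interval(iv: BacterialInterval) -> BacterialInterval:
    return BacterialInterval(scaffold=iv.scaffold, start=iv.start, end=iv.end,
                             best_hit=iv.best_hit, n_windows=iv.n_windows,
                             best_animal_bit=iv.best_animal_bit)


def length_filter(intervals: list[BacterialInterval],
                  min_len: int = 100) -> list[LgtCandidate]:
    """Keep intervals with length >= min_len (inclusive); emit candidates."""
    out = []
    for iv in intervals:
        if iv.end - iv.start >= min_len:
            out.append(LgtCandidate(
                scaffold=iv.scaffold, start=iv.start, end=iv.end,
                taxon=iv.best_hit.taxon, bact_bit=iv.best_hit.bit_score,
                bact_evalue=iv.best_hit.e_value,
                animal_bit=iv.best_animal_bit, n_windows=iv.n_windows))
    out.sort(key=lambda c: (c.scaffold, c.start))
    return out


def run_scan(calls: list[ScaffoldCall], scaffolds: ScaffoldSet,
             bacterial_index: SeedIndex, animal_index: SeedIndex | None,
             scoring: ScoringParams | None = None,
             params: ScanParams | None = None) -> list[LgtCandidate]:
    """Tile -> bacterial scan -> counter-screen -> join -> length filter.

    Scaffolds already called bacterial are excluded from candidate emission
    (they are whole bacterial replicons, reported separately by the
    classifier)."""
    scoring = scoring or ScoringParams()
    params = params or ScanParams()
    excluded = {c.scaffold for c in calls if c.call == "bacterial"}
    subset = ScaffoldSet({n: s for n, s in scaffolds if n not in excluded})
    if len(subset) == 0:
        return []
    tiles = window_scaffolds(subset, params.window, min_tail=scoring.k)
    intervals = scan_bacterial(tiles, subset, bacterial_index, scoring, params)
    if animal_index is not None:
        intervals = counter_screen(intervals, subset, animal_index, scoring,
                                   params)
    merged = join_intervals(intervals, params.join_gap)
    return length_filter(merged, params.min_len)


def candidates_to_frame(candidates: list[LgtCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "candidate_id": c.id, "scaffold": c.scaffold, "start": c.start,
        "end": c.end, "length": c.length, "taxon": c.taxon,
        "bacterial_bit": round(c.bact_bit, 2),
        "bacterial_evalue": f"{c.bact_evalue:.3e}",
        "animal_bit": round(c.animal_bit, 2) if c.animal_bit is not None else "",
        "n_windows": c.n_windows,
    } for c in candidates])


def candidates_to_bed(candidates: list[LgtCandidate]) -> list[tuple]:
    """BED6 rows: name = taxon, score = bit capped at 1000."""
    return [(c.scaffold, c.start, c.end, c.taxon,
             min(1000, int(round(c.bact_bit))), "+") for c in candidates]


def candidates_to_gff3(candidates: list[LgtCandidate]) -> list[str]:
    lines = ["##gff-version 3"]
    for c in candidates:
        lines.append("\t".join([
            c.scaffold, "lgtscreen", "lgt_candidate", str(c.start + 1),
            str(c.end), f"{c.bact_bit:.2f}", "+", ".",
            f"ID={c.id};taxon={c.taxon};n_windows={c.n_windows}"]))
    return lines
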