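"""Mate-pair junction validation.

A genuine insertion, unlike an assembly chimera, is crossed by read pairs:
reads spanning the prokaryote-eukaryote junction with overhang on both
sides, and pairs with one mate inside the insert and the other in flanking
host sequence.  This module does only the junction arithmetic over a table
of aligned mate placements; read mapping is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .scan import LgtCandidate


@dataclass
class JunctionSupport:
    candidate_id: str
    left_spanning_reads: int
    right_spanning_reads: int
    bridging_pairs: int
    status: str          # supported | unsupported | not_assessable
    supported: bool


def validate_junctions(candidates: list[LgtCandidate],
                       placements: pd.DataFrame,
                       min_overhang: int = 20,
                       s: int = 1, p: int = 1,
                       scaffold_lengths: dict[str, int] | None = None,
                       ) -> list[JunctionSupport]:
    """Count junction-spanning reads and bridging pairs per candidate.

    A mate interval spans a junction at x when it covers [x - min_overhang,
    x + min_overhang].  A pair bridges when one mate lies wholly inside the
    candidate and the other wholly in same-scaffold flanking sequence.
    ``supported`` requires spanning reads on both junctions (>= s each) or
    >= p bridging pairs.  A candidate covering its whole scaffold has no
    junctions and is ``not_assessable``.
    """
    if len(placements) and (
            (placements[["m1_start", "m1_end", "m2_start", "m2_end"]] < 0)
            .any().any()):
        raise InputError("negative coordinates in pair placements")

    by_scaffold = {}
    if len(placements):
        for sc, group in placements.groupby("scaffold"):
            by_scaffold[sc] = (
                group[["m1_start", "m1_end"]].to_numpy(),
                group[["m2_start", "m2_end"]].to_numpy())

    out = []
    for c in candidates:
        if scaffold_lengths is not None:
            sc_len = scaffold_lengths.get(c.scaffold)
            if sc_len is not None and c.start == 0 and c.end == sc_len:
                out.append(JunctionSupport(c.id, 0, 0, 0,
                                           "not_assessable", False))
                continue
        m1, m2 = by_scaffold.get(c.scaffold, (np.empty((0, 2), int),) * 2)
        reads = np.vstack([m1, m2]) if len(m1) else np.empty((0, 2), int)
        left = int(np.sum((reads[:, 0] <= c.start - min_overhang)
                          & (reads[:, 1] >= c.start + min_overhang)))
        right = int(np.sum((reads[:, 0] <= c.end - min_overhang)
                           & (reads[:, 1] >= c.end + min_overhang)))
        inside1 = (m1[:, 0] >= c.start) & (m1[:, 1] <= c.end)
        inside2 = (m2[:, 0] >= c.start) & (m2[:, 1] <= c.end)
        outside1 = (m1[:, 1] <= c.start) | (m1[:, 0] >= c.end)
        outside2 = (m2[:, 1] <= c.start) | (m2[:, 0] >= c.end)
        bridging = int(np.sum((inside1 & outside2) | (inside2 & outside1)))
        supported = (left >= s and right >= s) or bridging >= p
        out.append(JunctionSupport(
            c.id, left, right, bridging,
            "supported" if supported else "unsupported", supported))
    return out


def read_sam_placements(path: str) -> pd.DataFrame:
    """Thin reader turning a coordinate-sorted SAM/BAM of proper pairs into
    the placement table (first-mate records only; both mates same reference)."""
    import pysam  # optional input path; imported lazily

    from .containers import PAIR_COLUMNS
    rows = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if (rec.is_unmapped or rec.mate_is_unmapped or rec.is_secondary
                    or rec.is_supplementary or not rec.is_read1):
                continue
            if rec.reference_id != rec.next_reference_id:
                continue
            m1 = (rec.reference_start, rec.reference_end)
            m2_start = rec.next_reference_start
            m2 = (m2_start, m2_start + rec.query_length)
            rows.append((rec.query_name, rec.reference_name,
                         m1[0], m1[1], m2[0], m2[1], "FR"))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def support_to_frame(supports: list[JunctionSupport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "candidate_id": s.candidate_id,
        "left_spanning_reads": s.left_spanning_reads,
        "right_spanning_reads": s.right_spanning_reads,
        "bridging_pairs": s.bridging_pairs,
        "status": s.status,
    } for s in supports])
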