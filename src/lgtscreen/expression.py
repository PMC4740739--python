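"""Expression triage of LGT candidates from coverage tracks.

Most genuine bacterial insertions decay into non-genes, so the expected
pattern is no or only trace transcription; an insertion expressed in one
sex but silent in the other (the male-specific pattern) is flagged as
differential.  Classes per condition from mean per-base coverage x:

    none       x <= t0
    trace      t0 < x <= t1
    expressed  x > t1
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, InputError
from .scan import LgtCandidate

Track = dict[str, list[tuple[int, int, float]]]


@dataclass
class ExpressionCall:
    candidate_id: str
    means: dict[str, float]       # condition -> mean fold coverage
    classes: dict[str, str]       # condition -> none | trace | expressed
    differential: bool            # expressed in exactly one condition, none elsewhere


def _check_track(track: Track) -> None:
    for scaffold, runs in track.items():
        prev = None
        for start, end, value in sorted(runs):
            if start >= end:
                raise InputError(
                    f"empty bedGraph interval on {scaffold}: [{start},{end})")
            if prev is not None and start < prev[1] and value != prev[2]:
                raise InputError(
                    f"conflicting overlapping bedGraph records on {scaffold} "
                    f"near {start}")
            prev = (start, end, value)


def mean_coverage(track: Track, scaffold: str, start: int, end: int) -> float:
    """Mean per-base coverage over [start, end); absent regions count as 0."""
    total = 0.0
    for a, b, v in track.get(scaffold, []):
        lo, hi = max(a, start), min(b, end)
        if lo < hi:
            total += (hi - lo) * v
    return total / (end - start) if end > start else 0.0


def classify_expression(candidates: list[LgtCandidate],
                        tracks: dict[str, Track],
                        t0: float = 0.0, t1: float = 1.0,
                        ) -> list[ExpressionCall]:
    """Classify each candidate per condition and set the differential flag."""
    if not t0 < t1:
        raise ConfigurationError("thresholds must satisfy t0 < t1")
    for track in tracks.values():
        _check_track(track)
    out = []
    for c in candidates:
        means = {cond: mean_coverage(track, c.scaffold, c.start, c.end)
                 for cond, track in tracks.items()}
        classes = {}
        for cond, x in means.items():
            if x <= t0:
                classes[cond] = "none"
            elif x <= t1:
                classes[cond] = "trace"
            else:
                classes[cond] = "expressed"
        values = list(classes.values())
        differential = (values.count("expressed") == 1
                        and values.count("none") == len(values) - 1
                        and len(values) > 1)
        out.append(ExpressionCall(c.id, means, classes, differential))
    return out


def expression_to_frame(calls: list[ExpressionCall]):
    import pandas as pd
    conds = sorted({c for call in calls for c in call.means}) if calls else []
    rows = []
    for call in calls:
        row = {"candidate_id": call.candidate_id}
        for cond in conds:
            row[f"mean_{cond}"] = round(call.means.get(cond, 0.0), 3)
            row[f"class_{cond}"] = call.classes.get(cond, "none")
        row["differential"] = call.differential
        rows.append(row)
    return pd.DataFrame(rows)
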