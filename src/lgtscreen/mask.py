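"""Low-complexity masking with a DUST-style triplet score.

Database sequences are masked before indexing so that homopolymer runs and
simple repeats do not seed spurious cross-kingdom hits.  The masker scores
every window of length at most ``window`` by its triplet composition: for a
window holding k overlapping triplets with per-triplet counts c_t the score
is ``sum_t c_t (c_t - 1) / 2  /  (k - 1)``, and a window is low-complexity
when the score strictly exceeds ``level / 10``.  The masked region of a
sequence is the union of all low-complexity windows; maximal runs of masked
positions are reported as intervals.  ``N`` (or any non-ACGT base) breaks
triplets: segments between them are scored independently.

The implementation below is an incremental sweep (each window start extends
rightwards updating counts in O(1)); the test suite holds an independent
exhaustive enumerator that recomputes every window from scratch, and the two
must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, InputError

_VALID = set("ACGTacgt")
_BREAK = set("Nn")
_TRIPLET_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class MaskParams:
    """Masker tuning.

    window : largest interval length scored (bp).
    level  : score threshold times 10 (a window masks when score > level/10).
    linker : two masked runs closer than this many bp merge into one.
    """

    window: int = 64
    level: int = 20
    linker: int = 1

    def __post_init__(self):
        if self.window < 3:
            raise ConfigurationError("window must be >= 3")
        if self.level <= 0:
            raise ConfigurationError("level must be > 0")
        if self.linker < 0:
            raise ConfigurationError("linker must be >= 0")


@dataclass(frozen=True)
class MaskedInterval:
    """A masked run on a named scaffold, 0-based half-open."""

    scaffold: str
    start: int
    end: int


def _segments(seq: str) -> list[tuple[int, str]]:
    """Split on triplet-breaking characters; return (offset, ACGT-only chunk)."""
    out = []
    start = None
    for i, ch in enumerate(seq):
        if ch in _VALID:
            if start is None:
                start = i
        else:
            if ch not in _BREAK:
                raise InputError(f"invalid character {ch!r} at position {i}")
            if start is not None:
                out.append((start, seq[start:i]))
                start = None
    if start is not None:
        out.append((start, seq[start:]))
    return out


def _mask_segment(seq: str, params: MaskParams) -> list[tuple[int, int]]:
    """Masked runs within one ACGT-only segment (segment-local coordinates)."""
    import numpy as np

    from ._kernels import dust_sweep

    n = len(seq)
    if n < 4:
        return []
    trip = np.array(
        [
            (_TRIPLET_INDEX[seq[i].upper()] << 4)
            | (_TRIPLET_INDEX[seq[i + 1].upper()] << 2)
            | _TRIPLET_INDEX[seq[i + 2].upper()]
            for i in range(n - 2)
        ],
        dtype=np.int64,
    )
    end = dust_sweep(trip, params.window, params.level / 10.0)
    runs: list[tuple[int, int]] = []
    cur_start, cur_end = -1, -1
    for i in range(len(end)):
        if end[i] == 0:
            continue
        if cur_start < 0:
            cur_start, cur_end = i, int(end[i])
        elif i <= cur_end:
            cur_end = max(cur_end, int(end[i]))
        else:
            runs.append((cur_start, cur_end))
            cur_start, cur_end = i, int(end[i])
    if cur_start >= 0:
        runs.append((cur_start, cur_end))
    return runs


def dust_mask(seq: str, params: MaskParams | None = None) -> list[tuple[int, int]]:
    """Return sorted, disjoint masked intervals of ``seq`` (0-based half-open)."""
    params = params or MaskParams()
    if not seq:
        return []
    intervals: list[tuple[int, int]] = []
    for offset, segment in _segments(seq):
        for a, b in _mask_segment(segment, params):
            intervals.append((offset + a, offset + b))
    # merge runs separated by less than `linker`
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a - merged[-1][1] < params.linker:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def mask_scaffold_set(scaffolds, params: MaskParams | None = None,
                      mode: str = "soft"):
    """Mask every sequence of a ScaffoldSet; returns (masked set, intervals).

    ``intervals`` is a flat list of :class:`MaskedInterval` across scaffolds.
    """
    from .containers import ScaffoldSet

    params = params or MaskParams()
    out = ScaffoldSet(taxa=dict(scaffolds.taxa))
    all_intervals: list[MaskedInterval] = []
    for name, seq in scaffolds:
        ivs = dust_mask(seq, params)
        out.add(name, apply_mask(seq, ivs, mode))
        all_intervals.extend(MaskedInterval(name, a, b) for a, b in ivs)
    return out, all_intervals


def apply_mask(seq: str, intervals: list[tuple[int, int]],
               mode: str = "soft") -> str:
    """Lowercase (soft) or N-out (hard) the given intervals; length preserved."""
    if mode not in ("soft", "hard"):
        raise ConfigurationError(f"mode must be 'soft' or 'hard', got {mode!r}")
    if not intervals:
        return seq
    chars = list(seq)
    for a, b in intervals:
        if not (0 <= a < b <= len(seq)):
            raise InputError(f"mask interval [{a},{b}) out of bounds")
        for i in range(a, b):
            chars[i] = chars[i].lower() if mode == "soft" else "N"
    return "".join(chars)
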