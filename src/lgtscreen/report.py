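"""Summaries: per-genus counts/percentages and the 10-bp length histogram."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .scan import LgtCandidate


@dataclass
class GenusSummary:
    """Per-genus candidate counts with percentages of the total.

    Rows are (genus, count, percentage rounded to 1 decimal), in descending
    count order with lexicographic tie-breaks.
    """

    rows: list[tuple[str, int, float]]
    total: int

    def top_genus_percent_int(self) -> int:
        """The headline number: the top genus share to the nearest integer."""
        if not self.rows:
            return 0
        return int(round(100.0 * self.rows[0][1] / self.total))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["genus", "count", "percent"])


def summarize_genera(candidates) -> GenusSummary:
    """Summarize candidates (or a genus -> count mapping) per genus."""
    if isinstance(candidates, dict):
        counts = dict(candidates)
    else:
        counts = {}
        for c in candidates:
            counts[c.taxon] = counts.get(c.taxon, 0) + 1
    total = sum(counts.values())
    rows = [(g, n, round(100.0 * n / total, 1) if total else 0.0)
            for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return GenusSummary(rows=rows, total=total)


@dataclass
class LengthHistogram:
    """Candidate lengths binned into half-open [lo, lo+bin) bins."""

    edges: list[int]          # left edge per bin
    counts: list[int]
    bin: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.edges,
            "bin_end": [e + self.bin for e in self.edges],
            "count": self.counts})

    def plot(self, path: str) -> None:  # pragma: no cover - cosmetic output
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.bar(self.edges, self.counts, width=self.bin, align="edge",
               edgecolor="black", linewidth=0.3)
        ax.set_xlabel("candidate length (bp)")
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def length_histogram(candidates: list[LgtCandidate],
                     bin: int = 10) -> LengthHistogram:
    """Histogram of candidate lengths in ``bin``-bp half-open bins."""
    lengths = [c.length for c in candidates]
    if not lengths:
        return LengthHistogram(edges=[], counts=[], bin=bin)
    lo = (min(lengths) // bin) * bin
    hi = (max(lengths) // bin) * bin
    edges = list(range(lo, hi + bin, bin))
    counts = [0] * len(edges)
    for ln in lengths:
        counts[(ln - lo) // bin] += 1
    return LengthHistogram(edges=edges, counts=counts, bin=bin)


def load_published_genus_counts() -> dict[str, int]:
    """The per-genus candidate counts printed for the bed-bug assembly
    screen (the two named genera; the remainder aggregated as 'other')."""
    with resources.files("lgtscreen.data").joinpath(
            "bedbug_genus_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["genus"], df["count"]))
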