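"""Per-genus candidate summary: the published worked example.

Loads the per-genus candidate counts printed for the bed-bug assembly
screen (805 candidates; the remainder below the two named genera is
aggregated) and reproduces the headline share of the top genus.
"""

from lgtscreen import load_published_genus_counts, summarize_genera

counts = load_published_genus_counts()
summary = summarize_genera(counts)

print(f"total candidates: {summary.total}")
for genus, n, pct in summary.rows:
    print(f"  {genus:<14} n={n:>4}  {pct:>5.1f}%")
print(f"\ntop genus to the nearest integer: "
      f"{summary.top_genus_percent_int()}%")

# Expected output: Arsenophonus n=459 is 57.0% of 805 candidates (57% to
# the nearest integer); Wolbachia n=87 is 10.8%.
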