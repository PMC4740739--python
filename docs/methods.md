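# Methods

## The screening model

The screen assumes two evidence sources: a **bacterial database** (donor
genomes) and an **animal database** (transcripts or genomic sequence from
the host's kingdom). A region of an assembly is a candidate LGT when it
resembles the bacterial database significantly (E ≤ 1e−5) and that evidence
beats any overlapping animal evidence. Two granularities are screened:

* **Whole scaffolds.** Endosymbionts and surface bacteria co-assemble with
  their host; their scaffolds are bacterial end to end. A scaffold is
  called `bacterial` when its best bacterial bit score exceeds its best
  animal bit score *and* bacterial hits cover ≥ `min_cov` (default 0.5) of
  its length. The coverage criterion is this package's own addition: a
  bit-score comparison alone cannot distinguish a bacterial replicon from
  a host scaffold whose only strong hit is a large insertion when no
  animal evidence exists for that scaffold; such scaffolds are `ambiguous`
  and proceed to the windowed scan rather than being excluded.
* **Sub-scaffold insertions.** Scaffolds are tiled into abutting 1,000-bp
  windows. Window regions with a bacterial hit are lifted to scaffold
  coordinates, counter-screened, joined when < 50 bp apart (strictly:
  a gap of exactly 50 bp does not merge), and kept at ≥ 100 bp
  (inclusive: a 100-bp region survives). The join rule exists because an
  insertion split across a tile boundary produces two abutting or
  near-abutting regions; windows do not overlap, so joining is what
  rescues boundary-split hits.

**Counter-screen rule.** What to do with a bacterial-similar region that
also hits the animal database is genuinely open; the default
(`bacterial_gt_animal`) retains a region unless an overlapping animal hit
reaches at least the region's bacterial bit score, mirroring the
scaffold-level higher-bacterial-than-animal logic. A stricter
`absent_animal` rule (any animal hit kills the region) is selectable. Only
the bacterial-similar subregion, not its whole 1,000-bp window, is
counter-screened; screening the full window would let unrelated flanking
host sequence veto a genuine insertion.

## Alignment engine and statistics

The internal aligner is BLAST-shaped: exact k-mer seeds (k = 11) over both
strands of the (masked) database; seeds on one diagonal are collapsed —
extension from the first seed covers the rest; X-drop ungapped extension
(drop-off 20); then affine-gap Smith–Waterman refinement with traceback,
banded to ±16 diagonals around the seed for large regions and run as the
full matrix when the region is ≤ 250,000 cells. Scoring defaults are
match +1, mismatch −2, and a gap of length L costs −5 − 2L (opening
surcharge convention). On pairs small enough for the full matrix, emitted
raw scores equal the exhaustive dynamic-programming optimum; the test
suite enforces this against an independent naive implementation.

Heuristic gaps, stated plainly: an alignment whose every seed is destroyed
by mutation cannot be found (with k = 11 this matters only beyond ~25%
divergence), a banded refinement cannot recover alignments whose true path
drifts more than the band width off the seed diagonal, and the gapped
stage only runs when the ungapped score reaches half the E-cutoff score.
The simulator's substitution-only decay keeps true alignments on one
diagonal, so none of these limits bind in the packaged studies.

Statistics use the ungapped Karlin–Altschul model with λ = 1.28 and
K = 0.46 for the +1/−2 scheme, fixed rather than estimated — desk-scale
databases are far too small for stable empirical fitting. E-values use the
total database length n summed over sequences (the convention external
search tools calibrate their cutoffs against), and m is the query length —
for the windowed scan that is the window, not the scaffold. E-values below
double-precision underflow report as 0.

## DUST masking

The normative definition in this package: a position is masked when it
lies inside *any* interval of length ≤ `window` (64) whose triplet score
`sum_t c_t(c_t−1)/2 / (k−1)` strictly exceeds `level/10` (level 20), where
the k triplets are the overlapping 3-mers of the interval and N breaks
triplets. The production implementation is an incremental O(L·W) sweep;
the test suite recomputes every window from a prefix-count matrix and the
two must agree exactly on every sequence. Masked database positions are
lowercased (soft) before indexing: they never seed, but extension may run
through them; hard-masked positions (N) additionally score as mismatches,
which is what keeps alignments from penetrating more than
`xdrop/match` = 20 bp into a hard-masked run.

## The simulator

The generator's defaults are the package's reference study conditions:
10 host scaffolds × 100 kb at GC 0.36 (insect-like), 3 donor genomes of
50 kb at GC 0.46, 20 implants of 150–2,000 bp decayed at d = 0.05, 2
contaminant scaffolds decayed at 0.02, mate pairs with 500 ± 50 bp inserts
and 100-bp reads at 30× physical coverage over junction neighbourhoods,
and 10% of implants expressed at 50× in the male condition only.

Choices worth recording:

* **Decay = i.i.d. substitutions only.** Real post-insertion degradation
  also includes indels and rearrangements; substitutions-only keeps truth
  coordinates exact, so recovery statistics are crisp. Consequence:
  passing recovery tests says nothing about indel robustness.
* **Donor GC offset +0.10 (capped at 0.8).** The screen is homology-based;
  composition must not be the detection signal. The offset makes donor
  sequence realistically distinct without making k-mer matches more likely
  (random 50-kb donor vs 100-kb host sequences produce zero hits at the
  cutoff, verified over seeds).
* **Implant spacing ≥ 2 kb** between insertion points on a scaffold, so
  the < 50-bp join rule can never merge two distinct truths and
  sensitivity/precision are well defined.
* **pair_depth is physical (insert) coverage**: pair starts arrive at
  `depth/insert` per bp, making the expected number of junction-bridging
  pairs exactly `depth·(insert − 2·read)/insert` (18 at the defaults) —
  the Lander–Waterman expectation the tests check against a Poisson band.
* **The animal database is the pre-insertion host.** Implanted segments
  are absent from it, host windows are present in it; this emulates
  conspecific/related-animal transcripts with a perfectly known answer.
  Real animal databases are partial, so the counter-screen is gentler here
  than in the field.
* Mate placements are emitted directly as aligned intervals; no read
  mapping is simulated, because the logic under test is the junction
  arithmetic. FASTQ emission, read errors and quality strings are out of
  scope.

What passing these tests does **not** show: robustness to indel decay,
repeat-rich host genomes (the host is i.i.d. random sequence), partial
databases, or mapping artefacts.

## Junction validation and expression

A read spans a junction at x when its interval covers
[x − min_overhang, x + min_overhang] (default overhang 20 bp). A pair
bridges when one mate lies wholly inside the candidate and the other
wholly in same-scaffold flanking sequence. Support requires spanning reads
at both junctions (≥ s = 1 each) or ≥ p = 1 bridging pairs; the thresholds
are deliberately minimal and config-exposed, since the original screen's
evidence requirement was qualitative. A candidate spanning its entire
scaffold has no junctions and reports `not_assessable` — never supported.

Expression classes come from mean per-base coverage per condition:
none (≤ t0 = 0), trace (≤ t1 = 1), expressed (> 1). The tier boundaries
are verbal in origin and exposed in config; coverage is plain fold
coverage, not normalized units, because the packaged tracks are synthetic.
`differential` means expressed in exactly one condition with none in the
others.

## Reporting

Genus percentages are 100·count/total rounded to one decimal, headline
genus additionally to the nearest integer; ordering is count-descending
with lexicographic ties. The length histogram uses half-open 10-bp bins
anchored at the smallest candidate length rounded down to a multiple of
10. Both are pure functions of the candidate table.

## Problem sizes and determinism

The acceptance checks run the reference conditions over 20 simulated
genomes; the divergence curve uses a smaller genome (5 × 50 kb, 12
implants, 5 seeds per d ∈ {0, 0.05, 0.10, 0.20}), a size at which the
seed-averaged recovery estimate is already stable. All randomness flows
from one integer seed through per-stage `numpy` `SeedSequence` streams, so
identical configs give byte-identical outputs; the pipeline manifest
records parameters, versions and per-stage record counts, and a rerun
differs only in its timestamp.

## Known limitations

* No translated (protein-space) search: anciently diverged LGTs that are
  only detectable as protein similarity are invisible, as are LGTs more
  diverged than the seed length tolerates.
* No composition-based statistics or low-complexity query filtering
  beyond database masking.
* Taxon attribution is the single best hit's label; no phylogenetic
  placement or gene-tree/species-tree reconciliation.
* Coverage-depth evidence for contamination (read-depth ratios) is not
  modelled; triage is homology-only.
* The per-scaffold classifier reports an rRNA-like-hit flag when database
  metadata marks a subject as ribosomal, but takes no decision from it.
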