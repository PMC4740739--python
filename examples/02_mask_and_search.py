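"""DUST-mask a database and run the seed-and-extend search.

Masks a donor database (low-complexity runs would otherwise seed spurious
cross-kingdom hits), then searches a diverged copy of a donor fragment and
prints the alignment statistics.
"""

import random

from lgtscreen import (ScoringParams, build_index, mask_scaffold_set, search,
                       simulate_donors, SimulationConfig)

config = SimulationConfig(seed=3, n_donor_taxa=2, donor_length=20_000)
donors = simulate_donors(config)

masked, intervals = mask_scaffold_set(donors)
print(f"masked {len(intervals)} low-complexity intervals across "
      f"{len(donors)} donor genomes")

scoring = ScoringParams()          # +1/-2, E <= 1e-5, word size 11
index = build_index(masked, scoring, db_class="bacterial")

# a 600-bp donor fragment decayed at 5% of sites
rng = random.Random(0)
donor_name = donors.names[0]
fragment = "".join(
    rng.choice([b for b in "ACGT" if b != ch]) if rng.random() < 0.05 else ch
    for ch in donors[donor_name][5000:5600])

for h in search(fragment, index, scoring):
    print(f"hit {h.subject} ({h.taxon}) q[{h.q_start}:{h.q_end}) "
          f"s[{h.s_start}:{h.s_end}) strand={h.strand}")
    print(f"  raw score {h.raw_score}, bit {h.bit_score:.1f}, "
          f"E {h.e_value:.2e}, identity {100 * h.identity:.1f}%")

# The E-value is K*m*n*exp(-lambda*S) with m the query length and n the
# total database length; only hits at E <= 1e-5 are reported.
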