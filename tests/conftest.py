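import random

import pytest

from lgtscreen import ScaffoldSet, ScoringParams, build_index


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def mutate(rng: random.Random, seq: str, d: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < d:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture(scope="session")
def scoring():
    return ScoringParams()


@pytest.fixture(scope="session")
def small_db_index(scoring):
    """A 10-kb single-sequence database and its seed index."""
    rng = random.Random(42)
    db = ScaffoldSet({"subject_1": random_seq(rng, 10_000)},
                     taxa={"subject_1": "Wolbachia"})
    return db, build_index(db, scoring, db_class="bacterial")
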