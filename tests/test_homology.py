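"""Homology engine: Smith-Waterman oracle equivalence, statistics, I/O."""

import math
import random

import pytest

from lgtscreen import (HomologyHit, ScaffoldSet, ScoringParams, apply_mask,
                       build_index, read_tabular, search, write_tabular)
from lgtscreen.errors import ConfigurationError, InputError, ParseError
from lgtscreen.homology import revcomp

from .conftest import mutate, random_seq
from .oracles import sw_oracle


def planted_pair(rng, max_len=60):
    """Random (query, subject) pair with an embedded similar core."""
    a = random_seq(rng, rng.randint(25, max_len))
    b = random_seq(rng, rng.randint(25, max_len))
    if rng.random() < 0.75:
        core_len = rng.randint(15, min(len(a), len(b)) - 2)
        i = rng.randint(0, len(a) - core_len)
        j = rng.randint(0, len(b) - core_len)
        core = mutate(rng, a[i:i + core_len], rng.choice([0.0, 0.0, 0.05]))
        b = b[:j] + core + b[j + core_len:]
    return a, b


class TestScoringParams:
    def test_invariants(self):
        with pytest.raises(ConfigurationError):
            ScoringParams(match=-1)
        with pytest.raises(ConfigurationError):
            ScoringParams(k=3)
        with pytest.raises(ConfigurationError):
            ScoringParams(e_cutoff=0)

    def test_bit_and_evalue_formulas(self, scoring):
        # bit = (lambda*S - ln K)/ln 2 ; E = K*m*n*exp(-lambda*S)
        s = 100
        bit = scoring.bit_score(s)
        assert bit == pytest.approx(
            (scoring.lam * s - math.log(scoring.kappa)) / math.log(2))
        e = scoring.e_value(s, 1000, 1_000_000)
        assert e == pytest.approx(
            scoring.kappa * 1000 * 1_000_000 * math.exp(-scoring.lam * s))

    def test_evalue_monotone_in_score(self, scoring):
        assert scoring.e_value(50, 100, 1000) > scoring.e_value(60, 100, 1000)


class TestSeedIndex:
    def test_forward_seed_count(self, scoring):
        db = ScaffoldSet({"s": "ACGTACGTACGTACGTACGT"})  # 20-mer, k=11
        idx = build_index(db, scoring)
        assert idx.n_seeds("+") == 10

    def test_masked_positions_do_not_seed(self, scoring):
        seq = random_seq(random.Random(0), 100)
        db = ScaffoldSet({"s": apply_mask(seq, [(0, 100)], "soft")})
        idx = build_index(db, scoring)
        assert idx.n_seeds("+") == 0 and idx.n_seeds("-") == 0

    def test_empty_db_rejected(self, scoring):
        with pytest.raises(InputError):
            build_index(ScaffoldSet(), scoring)

    def test_rebuild_deterministic(self, scoring, small_db_index):
        db, idx = small_db_index
        idx2 = build_index(db, scoring, db_class="bacterial")
        assert (idx.kmers == idx2.kmers).all()
        assert (idx.pos == idx2.pos).all()


class TestSearch:
    def test_exact_substring_hit(self, scoring, small_db_index):
        db, idx = small_db_index
        q = db["subject_1"][3000:3200]
        hits = search(q, idx, scoring)
        assert len(hits) == 1
        h = hits[0]
        assert (h.q_start, h.q_end) == (0, 200)
        assert (h.s_start, h.s_end) == (3000, 3200)
        assert h.identity == 1.0 and h.strand == "+"
        assert h.raw_score == 200 * scoring.match

    def test_query_shorter_than_word_size(self, scoring, small_db_index):
        _, idx = small_db_index
        assert search("ACGTACGT", idx, scoring) == []

    def test_no_hit_between_unrelated_sequences(self, scoring, small_db_index):
        _, idx = small_db_index
        rng = random.Random(123)
        assert search(random_seq(rng, 500), idx, scoring) == []

    @pytest.mark.parametrize("batch", range(5))
    def test_sw_oracle_equivalence(self, scoring, batch):
        """Every reported raw score equals the full-DP local alignment
        optimum, over 500 random (query, subject) pairs <= 60 bp."""
        rng = random.Random(batch)
        checked = 0
        for _ in range(100):
            a, b = planted_pair(rng)
            db = ScaffoldSet({"s": b})
            # permissive cutoff so short alignments are emitted at all
            params = ScoringParams(e_cutoff=1e6)
            hits = search(a, build_index(db, params), params)
            for h in hits:
                oriented = a if h.strand == "+" else revcomp(a)
                assert h.raw_score == sw_oracle(oriented, b)
                checked += 1
        assert checked > 30  # the planted cores must actually produce hits

    def test_reverse_complement_symmetry(self, scoring, small_db_index):
        db, idx = small_db_index
        q = db["subject_1"][4000:4300]
        fwd = search(q, idx, scoring)
        rev = search(revcomp(q), idx, scoring)
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert f.raw_score == r.raw_score
        assert (f.s_start, f.s_end) == (r.s_start, r.s_end)
        assert {f.strand, r.strand} == {"+", "-"}
        # query coordinates mirror
        assert (r.q_start, r.q_end) == (300 - f.q_end, 300 - f.q_start)

    def test_hits_sorted_and_pass_cutoff(self, scoring):
        rng = random.Random(5)
        donor = random_seq(rng, 5000)
        db = ScaffoldSet({"d1": donor, "d2": random_seq(rng, 5000)})
        idx = build_index(db, scoring)
        q = (random_seq(rng, 100) + donor[100:400] + random_seq(rng, 100)
             + donor[2000:2250] + random_seq(rng, 50))
        hits = search(q, idx, scoring)
        assert len(hits) >= 2
        evs = [h.e_value for h in hits]
        assert evs == sorted(evs)
        assert all(e <= scoring.e_cutoff for e in evs)

    def test_bit_evalue_consistency_on_emitted_hits(self, scoring,
                                                    small_db_index):
        """Emitted statistics reproduce the Karlin-Altschul formulas to
        1e-9 relative."""
        db, idx = small_db_index
        q = db["subject_1"][1000:1500]
        n = idx.total_length
        for h in search(q, idx, scoring):
            assert h.bit_score == pytest.approx(
                scoring.bit_score(h.raw_score), rel=1e-9)
            assert h.e_value == pytest.approx(
                scoring.e_value(h.raw_score, len(q), n), rel=1e-9)

    def test_divergent_copy_found(self, scoring, small_db_index):
        db, idx = small_db_index
        rng = random.Random(77)
        q = mutate(rng, db["subject_1"][6000:6800], 0.05)
        hits = search(q, idx, scoring)
        assert hits and hits[0].s_start < 6100 and hits[0].s_end > 6700
        assert hits[0].identity > 0.9

    def test_hard_masked_region_not_hit(self, scoring):
        """No hit extends far into a hard-masked database interval."""
        rng = random.Random(9)
        raw = random_seq(rng, 3000)
        masked = apply_mask(raw, [(1000, 2000)], "hard")
        db = ScaffoldSet({"s": masked})
        idx = build_index(db, scoring)
        q = raw[800:2200]
        slack = scoring.xdrop // scoring.match
        for h in search(q, idx, scoring):
            assert h.s_start >= 1000 - (1000 - 800) or h.s_end <= 1000 + slack
            assert not (h.s_start >= 1000 + slack and h.s_end <= 2000 - slack)


class TestTabularIO:
    def _random_hits(self, rng, n=100):
        hits = []
        for i in range(n):
            qs = rng.randint(0, 900)
            qlen = rng.randint(30, 100)
            ss = rng.randint(0, 9000)
            raw = rng.randint(30, 200)
            params = ScoringParams()
            hits.append(HomologyHit(
                query=f"q{i % 7}", subject=f"s{i % 5}",
                q_start=qs, q_end=qs + qlen,
                s_start=ss, s_end=ss + qlen,
                strand=rng.choice("+-"), raw_score=raw,
                bit_score=round(params.bit_score(raw), 2),
                e_value=float(f"{params.e_value(raw, 1000, 100000):.3e}"),
                identity=round(rng.randint(80, 100) / 100, 2),
                aln_length=qlen, mismatches=rng.randint(0, 5),
                gap_opens=rng.randint(0, 2)))
        return hits

    def test_round_trip_identity(self, tmp_path):
        rng = random.Random(3)
        hits = self._random_hits(rng)
        path = tmp_path / "hits.tsv"
        write_tabular(hits, path)
        back = read_tabular(path)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            for f in ("query", "subject", "q_start", "q_end", "s_start",
                      "s_end", "strand", "aln_length", "mismatches",
                      "gap_opens", "identity", "bit_score", "e_value"):
                assert getattr(a, f) == getattr(b, f), f

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_tabular(p) == []

    def test_coordinate_convention(self, tmp_path):
        """1-based inclusive 101..200 in-file becomes [100, 200) internally."""
        p = tmp_path / "one.tsv"
        p.write_text("q\ts\t100.00\t100\t0\t0\t101\t200\t101\t200\t"
                     "1e-20\t50.0\n")
        h = read_tabular(p)[0]
        assert (h.q_start, h.q_end) == (100, 200)
        assert (h.s_start, h.s_end) == (100, 200)
        assert h.strand == "+"

    def test_reverse_strand_convention(self, tmp_path):
        p = tmp_path / "rev.tsv"
        p.write_text("q\ts\t100.00\t100\t0\t0\t1\t100\t200\t101\t"
                     "1e-20\t50.0\n")
        h = read_tabular(p)[0]
        assert h.strand == "-"
        assert (h.s_start, h.s_end) == (100, 200)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q\ts\tnot_all_columns\n")
        with pytest.raises(ParseError, match=":1"):
            read_tabular(p)
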