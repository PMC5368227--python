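import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from primerscope import (
    Primer,
    ReferenceRecord,
    ScoringConfig,
    align_primer,
    reverse_complement,
    score_primer_against_set,
    tp_score,
    weighted_score,
)
from primerscope.iupac import IUPAC_BASES

from _oracle import oracle_best
from conftest import make_primer


class TestWeightedScore:
    @pytest.mark.parametrize("counts,last,expected", [
        ((0, 0, 0, 0), False, 0.0),
        ((1, 0, 0, 0), False, 0.40),
        ((0, 1, 0, 0), False, 1.00),
        ((0, 0, 1, 0), False, 1.00),
        ((0, 0, 0, 1), False, 3.00),
        ((0, 1, 0, 0), True, 4.00),
        ((2, 1, 0, 1), False, 4.80),
        ((0, 0, 0, 0), True, 3.00),
    ])
    def test_formula(self, counts, last, expected):
        assert weighted_score(*counts, last) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            weighted_score(-1, 0, 0, 0, False)

    def test_custom_weights(self):
        cfg = ScoringConfig(w_non3p_mm=0.5, terminal_penalty=10.0)
        assert weighted_score(2, 0, 0, 0, True, cfg) == pytest.approx(11.0)


class TestTpScore:
    def test_unit_weights(self):
        assert tp_score(0, 0) == 0.0
        assert tp_score(3, 0) == 3.0
        assert tp_score(2, 2) == 4.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tp_score(-1, 0)

    def test_terminal_mismatch_scores_lower_than_weighted(self, toy_primer, toy_config):
        # one terminal 3' mismatch: tp counts 1.0 while weighted adds the
        # 3.00 terminal penalty on top of the 1.00 3' mismatch
        hit = align_primer(toy_primer, "GGGGGACGCGGGGG", toy_config)
        assert hit.last_base_mismatch
        assert hit.weighted_score == pytest.approx(4.0)
        assert hit.tp_score == pytest.approx(1.0)


class TestAlignPrimer:
    def test_perfect_planted_site(self, toy_primer, toy_config):
        hit = align_primer(toy_primer, "TTACGTTT", toy_config)
        assert (hit.weighted_score, hit.start, hit.end) == (0.0, 3, 6)
        assert hit.tp_score == 0.0 and not hit.last_base_mismatch

    def test_best_site_is_lexicographic_minimum(self, toy_primer, toy_config):
        # TTACGATT: the single-defect alignments are ACGA with a terminal
        # mismatch (weighted 4.0) and ACG[+A]T with one 3' insertion
        # (weighted 3.0); fewest-defects-first then lowest weighted picks
        # the insertion, and the enumeration oracle agrees
        hit = align_primer(toy_primer, "TTACGATT", toy_config)
        assert (hit.tp_score, hit.weighted_score) == \
            oracle_best("ACGT", "TTACGATT", toy_config)
        assert hit.weighted_score == pytest.approx(3.0)
        assert hit.tp_score == pytest.approx(1.0)
        assert not hit.last_base_mismatch

    def test_terminal_mismatch_site(self, toy_primer, toy_config):
        hit = align_primer(toy_primer, "GGGGGACGCGGGGG", toy_config)
        assert hit.weighted_score == pytest.approx(4.0)
        assert hit.last_base_mismatch

    def test_fully_degenerate_primer_matches_anything(self, toy_config):
        p = make_primer("NNNN")
        hit = align_primer(p, "GATTACAG", toy_config)
        assert hit.weighted_score == 0.0

    def test_template_shorter_than_primer_is_truncated_non_hit(self, toy_primer, toy_config):
        hit = align_primer(toy_primer, "AC", toy_config)
        assert hit.truncated
        assert math.isinf(hit.weighted_score)

    def test_gap_in_template_found(self):
        # template carries the primer site with one internal base deleted;
        # the gapped search should report a single non-3' gap (1.0), not
        # the pile of mismatches an ungapped scan would see
        p = make_primer("ACGTACGTAC")
        cfg = ScoringConfig(three_prime_len=3)
        site = "ACGTCGTAC"  # A deleted at primer position 5
        hit = align_primer(p, "GGGTTGGG" + site + "GGGTTGGG", cfg)
        assert hit.non3p_gaps == 1
        assert hit.weighted_score == pytest.approx(1.0)
        assert hit.tp_score == pytest.approx(1.0)

    def test_reverse_primer_coordinates_map_to_plus_strand(self):
        rev = make_primer("TTGACA", name="r", orientation="reverse")
        site = reverse_complement("TTGACA")
        template = "CCCCCCCC" + site + "CCCC"
        hit = align_primer(rev, template)
        assert hit.weighted_score == 0.0
        assert (hit.start, hit.end) == (9, 14)

    def test_invalid_template_raises(self, toy_primer):
        with pytest.raises(ValueError):
            align_primer(toy_primer, "ACGT!ACGT")


SEEDED_CASES = list(range(200))


class TestOracleEquivalence:
    """The production search equals brute-force alignment enumeration."""

    @pytest.mark.parametrize("seed", SEEDED_CASES)
    def test_random_pair_matches_oracle(self, seed):
        rng = random.Random(seed)
        m = rng.randint(4, 12)
        n = rng.randint(m, 60)
        # mostly concrete primers with occasional degenerate positions
        codes = sorted(IUPAC_BASES)
        primer = "".join(
            rng.choice(codes) if rng.random() < 0.15 else rng.choice("ACGT")
            for _ in range(m)
        )
        template = "".join(rng.choice("ACGT") for _ in range(n))
        cfg = ScoringConfig(three_prime_len=min(5, m), max_gaps=2)
        hit = align_primer(make_primer(primer), template, cfg)
        assert (hit.tp_score, hit.weighted_score) == oracle_best(primer, template, cfg)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_oracle_with_nonstandard_weights(self, seed):
        rng = random.Random(10_000 + seed)
        m = rng.randint(4, 9)
        primer = "".join(rng.choice("ACGT") for _ in range(m))
        template = "".join(rng.choice("ACGT") for _ in range(rng.randint(m, 40)))
        cfg = ScoringConfig(three_prime_len=3, max_gaps=1,
                            w_non3p_mm=0.7, w_3p_mm=2.0, w_non3p_gap=1.5,
                            w_3p_gap=2.5, terminal_penalty=1.25)
        hit = align_primer(make_primer(primer), template, cfg)
        assert (hit.tp_score, hit.weighted_score) == oracle_best(primer, template, cfg)


class TestSearchProperties:
    def test_score_zero_iff_perfect_window(self):
        rng = random.Random(7)
        cfg = ScoringConfig(three_prime_len=3)
        for _ in range(50):
            m = rng.randint(4, 8)
            primer = "".join(rng.choice("ACGT") for _ in range(m))
            template = "".join(rng.choice("ACGT") for _ in range(rng.randint(m, 50)))
            hit = align_primer(make_primer(primer), template, cfg)
            has_perfect = any(
                all(IUPAC_BASES[template[k + j]] <= IUPAC_BASES[primer[j]]
                    for j in range(m))
                for k in range(len(template) - m + 1)
            )
            assert (hit.weighted_score == 0.0) == has_perfect

    def test_extra_mismatch_never_decreases_best_score(self):
        rng = random.Random(11)
        cfg = ScoringConfig(three_prime_len=3)
        for _ in range(30):
            m = rng.randint(5, 10)
            primer = "".join(rng.choice("ACGT") for _ in range(m))
            template = (
                "".join(rng.choice("ACGT") for _ in range(12))
                + primer
                + "".join(rng.choice("ACGT") for _ in range(12))
            )
            p = make_primer(primer)
            base = align_primer(p, template, cfg)
            assert base.weighted_score == 0.0
            # corrupt one matching position of the best site
            j = rng.randrange(m)
            pos = base.start - 1 + j
            bad = next(b for b in "ACGT" if b != primer[j])
            mutated = template[:pos] + bad + template[pos + 1 :]
            worse = align_primer(p, mutated, cfg)
            assert worse.weighted_score >= base.weighted_score

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_strand_symmetry(self, seed):
        # a reverse primer on the template scores exactly like the same
        # oligo scanned as forward against the reverse complement
        rng = random.Random(seed)
        m = rng.randint(4, 10)
        seq = "".join(rng.choice("ACGT") for _ in range(m))
        template = "".join(rng.choice("ACGT") for _ in range(rng.randint(m, 80)))
        cfg = ScoringConfig(three_prime_len=3)
        fwd_on_rc = align_primer(make_primer(seq), reverse_complement(template), cfg)
        rev_on_plus = align_primer(
            make_primer(seq, orientation="reverse"), template, cfg
        )
        assert rev_on_plus.weighted_score == fwd_on_rc.weighted_score
        n = len(template)
        if not fwd_on_rc.truncated and fwd_on_rc.weighted_score == 0.0:
            assert rev_on_plus.start == n - fwd_on_rc.end + 1
            assert rev_on_plus.end == n - fwd_on_rc.start + 1


class TestEdlibCrossCheck:
    """Unit-weight configuration agrees with edlib's infix edit distance."""

    @pytest.mark.parametrize("seed", range(40))
    def test_unit_weight_score_equals_edit_distance(self, seed):
        edlib = pytest.importorskip("edlib")
        rng = random.Random(seed)
        m = rng.randint(5, 15)
        codes = sorted(IUPAC_BASES)
        primer = "".join(
            rng.choice(codes) if rng.random() < 0.2 else rng.choice("ACGT")
            for _ in range(m)
        )
        template = "".join(rng.choice("ACGT") for _ in range(rng.randint(m, 120)))
        cfg = ScoringConfig(
            three_prime_len=0, w_non3p_mm=1.0, w_3p_mm=1.0, w_non3p_gap=1.0,
            w_3p_gap=1.0, terminal_penalty=0.0, max_gaps=m,
        )
        hit = align_primer(make_primer(primer), template, cfg)
        equalities = [
            (code, base) for code, bases in IUPAC_BASES.items() for base in bases
            if code != base
        ]
        res = edlib.align(primer, template, mode="HW", task="distance",
                          additionalEqualities=equalities)
        assert hit.weighted_score == res["editDistance"]


class TestBatchScoring:
    def test_stream_preserves_order_and_scores(self, toy_primer, toy_config):
        records = [
            ReferenceRecord(id=f"r{i}", sequence="GGGG" + "ACGT" + "GGGG")
            for i in range(3)
        ]
        hits = list(score_primer_against_set(toy_primer, records, toy_config))
        assert [h.record_id for h in hits] == ["r0", "r1", "r2"]
        assert all(h.weighted_score == 0.0 for h in hits)

    def test_planted_mean_score(self, toy_config):
        # 10 perfect + 10 one-non-3'-mismatch records -> mean 0.20
        p = make_primer("ACGTGA", name="p6")
        cfg = ScoringConfig(three_prime_len=2)
        perfect = "TTTTT" + "ACGTGA" + "TTTTT"
        onemm = "TTTTT" + "CCGTGA" + "TTTTT"  # A->C at primer position 1
        records = [
            ReferenceRecord(id=f"r{i}", sequence=perfect if i < 10 else onemm)
            for i in range(20)
        ]
        hits = list(score_primer_against_set(p, records, cfg))
        mean = sum(h.weighted_score for h in hits) / len(hits)
        assert mean == pytest.approx(0.20)

    def test_empty_set_warns(self, toy_primer, toy_config, caplog):
        with caplog.at_level("WARNING"):
            hits = list(score_primer_against_set(toy_primer, [], toy_config))
        assert hits == []
        assert any("empty record set" in r.message for r in caplog.records)
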