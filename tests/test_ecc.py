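import itertools

import numpy as np
import pytest

from molbit import ecc
from molbit.ecc import (
    CodeSpec,
    CountVector,
    GeneratorMatrix,
    ScalingVector,
    bits_to_text,
    classify_by_length,
    decode_nearest,
    decode_tag,
    encode_message,
    estimate_error_probability,
    fit_scaling_vector,
    gf2_rank,
    load_counts_tsv,
    load_generator_matrix,
    make_generator_matrix,
    min_weight_search,
    save_counts_tsv,
    save_generator_matrix,
    shipped_generator_matrix,
    text_to_bits,
)

SPEC_12_4 = CodeSpec(n=12, k=4, t=2, required_min_distance=5)


@pytest.fixture(scope="module")
def code_12_4():
    return make_generator_matrix(SPEC_12_4, seed=3, search_iters=300)


@pytest.fixture(scope="module")
def shipped():
    return shipped_generator_matrix()


class TestAsciiCodec:
    def test_misl_is_32_bits(self):
        assert len(text_to_bits("MISL")) == 32

    def test_roundtrip(self):
        for text in ("MISL", "A", "Hello!", "1234"):
            assert bits_to_text(text_to_bits(text)) == text

    def test_m_is_ascii_77(self):
        assert "".join(map(str, text_to_bits("M"))) == "01001101"

    def test_non_ascii_rejected(self):
        with pytest.raises(UnicodeEncodeError):
            text_to_bits("café")


class TestCodeSpec:
    def test_inconsistent_radius_rejected(self):
        with pytest.raises(ValueError):
            CodeSpec(n=96, k=32, t=8, required_min_distance=19)

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            CodeSpec(n=8, k=8, t=1, required_min_distance=3)


class TestEncode:
    def test_zero_message_gives_zero_codeword(self, shipped):
        cw = encode_message(np.zeros(32, dtype=np.uint8), shipped)
        assert cw.sum() == 0

    def test_linearity(self, shipped, rng):
        m1 = rng.integers(0, 2, 32).astype(np.uint8)
        m2 = rng.integers(0, 2, 32).astype(np.uint8)
        np.testing.assert_array_equal(
            encode_message(m1 ^ m2, shipped),
            encode_message(m1, shipped) ^ encode_message(m2, shipped),
        )

    def test_32_bits_to_96_bits(self, shipped):
        assert len(encode_message(text_to_bits("MISL"), shipped)) == 96

    def test_length_mismatch_rejected(self, shipped):
        with pytest.raises(ValueError):
            encode_message(np.zeros(31, dtype=np.uint8), shipped)


class TestMinWeight:
    def test_repetition_code(self):
        G = GeneratorMatrix(bits=np.array([[1, 1, 1]], dtype=np.uint8))
        assert min_weight_search(G) == 3

    def test_search_matches_exhaustive_on_random_16_5_codes(self, rng):
        from molbit.ecc import _min_weight_kernel, _pack_rows

        for trial in range(10):
            while True:
                bits = rng.integers(0, 2, size=(5, 16), dtype=np.uint8)
                if gf2_rank(bits) == 5:
                    break
            G = GeneratorMatrix(bits=bits)
            exhaustive = min_weight_search(G)  # k <= 20: full enumeration
            searched = int(
                _min_weight_kernel(_pack_rows(bits, 1), 16, 5, 1, 300, trial)
            )
            assert searched == exhaustive

    def test_more_iterations_never_raise_the_minimum(self, shipped):
        w_small = min_weight_search(shipped, iters=500, seed=5)
        w_big = min_weight_search(shipped, iters=5000, seed=5)
        assert w_big <= w_small


class TestMakeGenerator:
    def test_deterministic_for_seed(self):
        a = make_generator_matrix(SPEC_12_4, seed=3, search_iters=300)
        b = make_generator_matrix(SPEC_12_4, seed=3, search_iters=300)
        np.testing.assert_array_equal(a.bits, b.bits)

    def test_accepted_code_has_required_distance(self, code_12_4):
        assert min_weight_search(code_12_4) >= SPEC_12_4.required_min_distance

    def test_full_rank_guaranteed(self, code_12_4):
        assert gf2_rank(code_12_4.bits) == 4

    def test_impossible_distance_errors(self):
        spec = CodeSpec(n=10, k=6, t=2, required_min_distance=5)
        with pytest.raises(RuntimeError, match="lower required_min_distance"):
            make_generator_matrix(spec, seed=0, search_iters=200, max_matrices=5)


class TestDecodeNearest:
    def test_exact_codeword_decodes_to_itself(self, code_12_4, rng):
        m = rng.integers(0, 2, 4).astype(np.uint8)
        res = decode_nearest(encode_message(m, code_12_4), code_12_4, SPEC_12_4)
        assert res.status == "unique" and res.distance == 0
        np.testing.assert_array_equal(res.message, m)

    def test_repetition_code_example(self):
        G = GeneratorMatrix(bits=np.array([[1, 1, 1]], dtype=np.uint8))
        spec = CodeSpec(n=3, k=1, t=1, required_min_distance=3)
        res = decode_nearest(np.array([1, 1, 0], dtype=np.uint8), G, spec)
        assert res.status == "unique"
        assert res.distance == 1 and res.message.tolist() == [1]

    def test_full_correction_guarantee_12_4(self, code_12_4):
        # every message x every error pattern of weight <= t decodes exactly
        for m_bits in itertools.product([0, 1], repeat=4):
            m = np.array(m_bits, dtype=np.uint8)
            cw = encode_message(m, code_12_4)
            for weight in range(SPEC_12_4.t + 1):
                for pos in itertools.combinations(range(12), weight):
                    e = np.zeros(12, dtype=np.uint8)
                    e[list(pos)] = 1
                    res = decode_nearest(cw ^ e, code_12_4, SPEC_12_4)
                    assert res.status == "unique"
                    np.testing.assert_array_equal(res.message, m)

    def test_isd_matches_exhaustive_on_20_8_code(self, rng):
        while True:
            bits = rng.integers(0, 2, size=(8, 20), dtype=np.uint8)
            if gf2_rank(bits) == 8:
                G = GeneratorMatrix(bits=bits)
                d = min_weight_search(G)  # exhaustive truth for k=8
                if d >= 3:
                    break
        t = (d - 1) // 2
        spec = CodeSpec(n=20, k=8, t=t, required_min_distance=2 * t + 1)
        for trial in range(200):
            word = rng.integers(0, 2, 20).astype(np.uint8)
            ex = decode_nearest(word, G, spec, strategy="exhaustive")
            isd = decode_nearest(
                word, G, spec, strategy="isd", iters=2000, seed=trial
            )
            if ex.status == "unique":
                assert isd.status == "unique"
                assert isd.distance == ex.distance
                np.testing.assert_array_equal(isd.message, ex.message)
            else:
                assert isd.status == "failure"

    def test_length_mismatch_rejected(self, code_12_4):
        with pytest.raises(ValueError):
            decode_nearest(np.zeros(11, dtype=np.uint8), code_12_4, SPEC_12_4)


class TestScaling:
    def test_uniform_calibration_gives_unit_factors(self):
        runs = [CountVector(counts=np.full(8, 100.0), run_id="a")]
        sv = fit_scaling_vector(runs, [np.ones(8, dtype=bool)])
        np.testing.assert_allclose(sv.factors, 1.0)

    def test_double_abundance_halves_the_factor(self):
        counts = np.full(96, 100.0)
        counts[7] = 200.0
        sv = fit_scaling_vector(
            [CountVector(counts=counts)], [np.ones(96, dtype=bool)]
        )
        assert sv.factors[7] == pytest.approx(0.5, rel=0.02)

    def test_rescaling_reduces_dispersion(self, rng):
        true_bias = rng.lognormal(0, 0.7, size=96)
        runs, presence = [], []
        for _ in range(3):
            lam = 500 * true_bias
            runs.append(CountVector(counts=rng.poisson(lam).astype(float)))
            presence.append(np.ones(96, dtype=bool))
        sv = fit_scaling_vector(runs, presence)
        raw_cv = np.std(runs[0].counts) / np.mean(runs[0].counts)
        scaled = runs[0].counts * sv.factors
        assert np.std(scaled) / np.mean(scaled) <= raw_cv

    def test_never_present_molbit_gets_unit_factor(self):
        counts = np.array([100.0, 100.0, 0.0])
        presence = np.array([True, True, False])
        with pytest.warns(UserWarning, match="absent"):
            sv = fit_scaling_vector([CountVector(counts=counts)], [presence])
        assert sv.factors[2] == 1.0


class TestDecodeTag:
    def test_clean_counts_decode_exactly(self, shipped):
        msg = text_to_bits("MISL")
        cw = encode_message(msg, shipped)
        res = decode_tag(CountVector(counts=cw * 100.0), None, shipped)
        assert res.status == "unique" and res.distance == 0
        assert bits_to_text(res.message) == "MISL"

    def test_scale_invariance(self, shipped, rng):
        msg = rng.integers(0, 2, 32).astype(np.uint8)
        cw = encode_message(msg, shipped)
        counts = cw * 50.0 + rng.integers(0, 5, 96)
        r1 = decode_tag(CountVector(counts=counts), None, shipped, seed=1)
        r2 = decode_tag(CountVector(counts=counts * 37.5), None, shipped, seed=1)
        assert r1.status == r2.status == "unique"
        np.testing.assert_array_equal(r1.message, r2.message)

    def test_nine_corrupted_bits_still_decode(self, shipped, rng):
        msg = text_to_bits("MISL")
        cw = encode_message(msg, shipped)
        for trial in range(10):
            flip = rng.choice(96, 9, replace=False)
            corrupted = cw.copy()
            corrupted[flip] ^= 1
            res = decode_tag(
                CountVector(counts=corrupted * 80.0), None, shipped, seed=trial
            )
            assert res.status == "unique" and res.distance == 9
            np.testing.assert_array_equal(res.message, msg)

    def test_all_zero_counts_fail(self, shipped):
        res = decode_tag(CountVector(counts=np.zeros(96)), None, shipped)
        assert res.status == "failure"


class TestLengthChannel:
    @pytest.mark.parametrize(
        "length,expected",
        [(5768, "short"), (16968, "long"), (9800, "short"), (9801, "long")],
    )
    def test_cutoff_binning(self, length, expected):
        assert classify_by_length(length) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_by_length(0)


class TestErrorProbability:
    def test_zero_rate_is_zero_both_methods(self, code_12_4):
        spec = SPEC_12_4
        assert estimate_error_probability(0.0, spec).value == 0.0
        mc = estimate_error_probability(
            0.0, spec, "monte_carlo", G=code_12_4, trials=50, seed=0
        )
        assert mc.value == 0.0

    def test_binomial_tail_monotone_in_p(self):
        spec = CodeSpec()
        vals = [
            estimate_error_probability(p, spec).value
            for p in (0.0, 0.02, 0.05, 0.1, 0.3)
        ]
        assert vals == sorted(vals)

    def test_monte_carlo_matches_exhaustive_enumeration(self, code_12_4):
        # exact failure probability from the coset structure: decoding is
        # wrong exactly when the error vector is not decoded back to zero
        from scipy import stats

        p_bit = 0.15
        p_exact = 0.0
        for weight in range(13):
            for pos in itertools.combinations(range(12), weight):
                e = np.zeros(12, dtype=np.uint8)
                e[list(pos)] = 1
                res = decode_nearest(e, code_12_4, SPEC_12_4)
                bad = res.status != "unique" or res.message.any()
                if bad:
                    p_exact += p_bit**weight * (1 - p_bit) ** (12 - weight)
        mc = estimate_error_probability(
            p_bit, SPEC_12_4, "monte_carlo", G=code_12_4, trials=400, seed=7
        )
        assert mc.ci_low <= p_exact <= mc.ci_high

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            estimate_error_probability(1.5, CodeSpec())


class TestShippedMatrix:
    def test_structure(self, shipped):
        assert shipped.bits.shape == (32, 96)
        assert gf2_rank(shipped.bits) == 32
        assert shipped.verified_weight_floor == 19

    def test_quick_correction_sample(self, shipped, rng):
        spec = CodeSpec()
        for trial in range(25):
            m = rng.integers(0, 2, 32).astype(np.uint8)
            cw = encode_message(m, shipped)
            e = np.zeros(96, dtype=np.uint8)
            e[rng.choice(96, 9, replace=False)] = 1
            res = decode_nearest(cw ^ e, shipped, spec, seed=trial)
            assert res.status == "unique"
            np.testing.assert_array_equal(res.message, m)


class TestIO:
    def test_matrix_json_roundtrip(self, tmp_path, code_12_4):
        path = tmp_path / "G.json"
        save_generator_matrix(code_12_4, path)
        loaded = load_generator_matrix(path)
        np.testing.assert_array_equal(loaded.bits, code_12_4.bits)
        assert loaded.seed == code_12_4.seed

    def test_counts_tsv_roundtrip(self, tmp_path, rng):
        cv = CountVector(counts=rng.integers(0, 100, 96).astype(float))
        path = tmp_path / "counts.tsv"
        save_counts_tsv(cv, path)
        loaded = load_counts_tsv(path, n=96)
        np.testing.assert_array_equal(loaded.counts, cv.counts)
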