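"""Nonlinear measures against independent oracles (literal-equation
transcriptions, brute-force parsers, generators with known exponents)."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfractal import (
    DEFAULT_BANDS,
    EEGSegment,
    FeatureError,
    HurstConfig,
    LZConfig,
    decompose,
    extract_features,
    feature_names,
    generate_fgn,
    higuchi_fd,
    hurst_exponent,
    katz_fd,
    lz_complexity,
)
from eegfractal.features import binarize, lz76_component_count

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive transcriptions)


def higuchi_fd_naive(x, p_max):
    """Literal nested-loop transcription of the length-curve definition."""
    y = len(x)
    log_a, log_inv_p = [], []
    for p in range(1, p_max + 1):
        lengths = []
        for f in range(1, p + 1):
            j_max = (y - f) // p
            total = sum(
                abs(x[f + j * p - 1] - x[f + (j - 1) * p - 1]) for j in range(1, j_max + 1)
            )
            lengths.append(total * (y - 1) / (j_max * p) / p)
        log_a.append(math.log(sum(lengths) / p))
        log_inv_p.append(math.log(1.0 / p))
    return np.polyfit(log_inv_p, log_a, 1)[0]


def katz_fd_literal(y):
    """K = log10(U/m) / log10(b/m) with m the mean step length."""
    pts = [(float(j), float(v)) for j, v in enumerate(y)]
    u = sum(
        math.hypot(pts[j + 1][0] - pts[j][0], pts[j + 1][1] - pts[j][1])
        for j in range(len(pts) - 1)
    )
    b = max(math.hypot(p[0] - pts[0][0], p[1] - pts[0][1]) for p in pts)
    m = u / (len(pts) - 1)
    return math.log10(u / m) / math.log10(b / m)


def lz76_brute(bits):
    """Quadratic exhaustive-history parser: each component is the shortest
    prefix of the remainder not contained in history + component[:-1]."""
    s = "".join(str(int(b)) for b in bits)
    c, i, n = 0, 0, len(s)
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


# ---------------------------------------------------------------------------
# Higuchi


class TestHiguchi:
    def test_linear_ramp_dimension_one(self):
        """A(p) = (Y-1)/p exactly for a ramp, so the slope is exactly 1."""
        assert higuchi_fd(np.arange(1000, dtype=float), 30) == pytest.approx(1.0, abs=0.01)

    def test_white_noise_dimension_two(self):
        ests = [
            higuchi_fd(np.random.default_rng(s).standard_normal(4096), 30)
            for s in range(20)
        ]
        assert np.mean(ests) == pytest.approx(2.0, abs=0.1)

    def test_matches_naive_transcription(self):
        """Production implementation equals the nested-loop transcription."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.standard_normal(512)
            assert higuchi_fd(x, 12) == pytest.approx(
                higuchi_fd_naive(x, 12), abs=1e-10
            )

    def test_constant_signal_raises(self):
        with pytest.raises(FeatureError):
            higuchi_fd(np.full(1000, 3.7), 30)

    def test_too_short_raises(self):
        with pytest.raises(FeatureError):
            higuchi_fd(np.arange(100, dtype=float), 30)

    def test_fgn_cumsum_roughness_decreases_with_hurst(self):
        """Fractional Brownian motion gets smoother as H grows."""
        lo, hi = [], []
        for s in range(20):
            lo.append(higuchi_fd(np.cumsum(generate_fgn(0.2, 4096, seed=s).samples), 30))
            hi.append(higuchi_fd(np.cumsum(generate_fgn(0.8, 4096, seed=s).samples), 30))
        assert np.mean(lo) > np.mean(hi)


# ---------------------------------------------------------------------------
# Katz


class TestKatz:
    def test_straight_line_is_exactly_one(self):
        assert katz_fd([0.0, 1.0, 2.0, 3.0]) == pytest.approx(1.0, abs=1e-12)

    def test_zigzag_hand_value(self):
        """[0,1,0,1]: U = 3 sqrt 2, b = sqrt 10, n = 3."""
        u, b, n = 3 * math.sqrt(2), math.sqrt(10), 3
        expected = math.log10(n) / (math.log10(b / u) + math.log10(n))
        assert katz_fd([0.0, 1.0, 0.0, 1.0]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.365, abs=0.005)

    def test_matches_literal_equations(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = rng.standard_normal(rng.integers(5, 21))
            assert katz_fd(y) == pytest.approx(katz_fd_literal(y), abs=1e-10)

    def test_not_amplitude_invariant(self):
        assert katz_fd([0, 1, 0, 1]) != pytest.approx(katz_fd([0, 2, 0, 2]), abs=1e-6)

    def test_too_short_raises(self):
        with pytest.raises(FeatureError):
            katz_fd([1.0, 2.0])


# ---------------------------------------------------------------------------
# Hurst


class TestHurst:
    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.7, 0.9])
    def test_fgn_recovery(self, hurst):
        ests = [
            hurst_exponent(generate_fgn(hurst, 4096, seed=s).samples)
            for s in range(20)
        ]
        assert np.mean(ests) == pytest.approx(hurst, abs=0.1)

    def test_recovery_mean_absolute_error(self):
        """MAE of the R/S estimator over the standard H grid stays below 0.1."""
        errs = []
        for hurst in (0.3, 0.5, 0.7, 0.9):
            ests = [
                hurst_exponent(generate_fgn(hurst, 4096, seed=200 + s).samples)
                for s in range(20)
            ]
            errs.append(abs(np.mean(ests) - hurst))
        assert np.mean(errs) < 0.1

    def test_white_noise_is_half(self):
        ests = [
            hurst_exponent(np.random.default_rng(s).standard_normal(4096))
            for s in range(20)
        ]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_constant_signal_raises(self):
        with pytest.raises(FeatureError):
            hurst_exponent(np.full(1024, 2.0))

    def test_min_block_config(self):
        with pytest.raises(ValueError):
            HurstConfig(min_block=4)


# ---------------------------------------------------------------------------
# Lempel-Ziv


class TestLempelZiv:
    def test_constant_signal(self):
        """All-zero binary string '0000' parses as 0|000 -> c=2, C=1."""
        assert lz_complexity([5.0, 5.0, 5.0, 5.0]) == pytest.approx(1.0)

    def test_alternating_signal(self):
        """'010101' parses as 0|1|0101 -> c=3."""
        expected = 3 * math.log2(6) / 6
        assert lz_complexity([1, 2, 1, 2, 1, 2], LZConfig("mean")) == pytest.approx(expected)

    def test_random_sequence_near_one(self):
        vals = []
        for s in range(20):
            x = np.random.default_rng(s).choice([-1.0, 1.0], size=4096)
            vals.append(lz_complexity(x, LZConfig("mean")))
        assert all(0.8 <= v <= 1.2 for v in vals)

    def test_parser_matches_brute_force_exhaustive(self):
        """Production parser equals the quadratic parser on all strings <= 12."""
        for length in range(1, 13):
            for code in range(2**length):
                bits = np.array(
                    [(code >> i) & 1 for i in range(length)], dtype=np.uint8
                )
                assert lz76_component_count(bits) == lz76_brute(bits), bits

    def test_parser_matches_brute_force_random_long(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            bits = rng.integers(0, 2, size=500).astype(np.uint8)
            assert lz76_component_count(bits) == lz76_brute(bits)

    def test_tie_maps_to_zero(self):
        """Samples equal to the margin binarize to 0."""
        x = np.array([1.0, 2.0, 3.0])  # mean = 2
        np.testing.assert_array_equal(binarize(x, "mean"), [0, 0, 1])

    def test_skewed_signal_mean_margin(self):
        """On a skewed signal only the outlier sits above the mean margin."""
        x = np.array([0.0, 0.0, 0.0, 10.0, 0.0, 0.0, 0.0, 0.0])
        assert binarize(x, "mean").sum() == 1
        assert binarize(x, "median").sum() == 1  # ties at the median map to 0


# ---------------------------------------------------------------------------
# feature vector assembly


class TestExtractFeatures:
    def test_thirty_named_features(self, small_corpus):
        bank = decompose(small_corpus[0], DEFAULT_BANDS)
        vec = extract_features(bank)
        assert len(vec.values) == 30
        assert vec.is_complete

    def test_expected_names_present(self):
        names = feature_names()
        assert "KFD(Beta)" in names
        assert "HFD_kmax=45(Beta)" in names
        assert "Hurst(Original Signal)" in names
        assert len(names) == 30

    def test_constant_segment_flags_hurst_missing(self):
        seg = EEGSegment(np.zeros(4097), label="A", source_id="const")
        bank = decompose(seg, DEFAULT_BANDS)
        vec = extract_features(bank)
        assert not vec.is_complete
        hurst_names = [n for n in vec.values if n.startswith("Hurst")]
        assert all(n in vec.missing for n in hurst_names)
        # LZC stays defined for constant signals
        assert np.isfinite(vec.values["LZC_mean(Original Signal)"])

    def test_hurst_clipped_to_unit_interval(self, small_corpus):
        for seg in small_corpus[:5]:
            vec = extract_features(decompose(seg))
            for name, val in vec.values.items():
                if name.startswith("Hurst"):
                    assert 0.0 <= val <= 1.0


# ---------------------------------------------------------------------------
# property tests


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_lz_parser_property_random_strings(seed):
    bits = np.random.default_rng(seed).integers(0, 2, size=200).astype(np.uint8)
    assert lz76_component_count(bits) == lz76_brute(bits)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_katz_property_matches_literal(seed):
    y = np.random.default_rng(seed).standard_normal(15)
    assert katz_fd(y) == pytest.approx(katz_fd_literal(y), abs=1e-10)
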