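import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps
from scipy import stats

from eegdep.features import (
    FEATURE_ORDER,
    ComplexityFeatures,
    DegenerateSignalError,
    FeatureParams,
    UndefinedEntropyError,
    dfa_exponent,
    extract_features,
    higuchi_fd,
    perm_entropy,
    sample_entropy,
    spectral_entropy,
    svd_entropy,
)
from eegdep.preprocess import WindowVector
from oracles import (
    dfa_naive,
    higuchi_naive,
    perm_entropy_naive,
    sample_entropy_naive,
    spectral_entropy_naive,
    svd_entropy_naive,
)

from eegdep.features import _dfa_box_sizes


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------

def test_perm_entropy_matches_hand_count():
    # (4,7,9,10,6,11,3): four ascending and two descending pairs
    x = np.array([4, 7, 9, 10, 6, 11, 3], float)
    expected = -(4 / 6) * np.log2(4 / 6) - (2 / 6) * np.log2(2 / 6)
    assert perm_entropy(x, order=2, normalized=False) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_all_estimators_match_naive_oracles(seed):
    """Vectorized estimators agree with literal-definition loop oracles."""
    rng = np.random.default_rng(seed)
    for trial in range(25):
        n = int(rng.integers(50, 130))
        x = rng.standard_normal(n)
        assert perm_entropy(x, 3, 1) == pytest.approx(
            perm_entropy_naive(x, 3, 1), abs=1e-10
        )
        assert svd_entropy(x, 3, 1) == pytest.approx(
            svd_entropy_naive(x, 3, 1), abs=1e-10
        )
        assert higuchi_fd(x, kmax=8) == pytest.approx(
            higuchi_naive(x, kmax=8), abs=1e-10
        )
        expected = sample_entropy_naive(x)
        if expected is None:
            with pytest.raises(UndefinedEntropyError):
                sample_entropy(x)
        else:
            assert sample_entropy(x) == pytest.approx(expected, abs=1e-12)


def test_perm_entropy_tie_handling_matches_oracle(rng):
    for _ in range(20):
        x = rng.integers(0, 4, size=80).astype(float)  # many ties
        assert perm_entropy(x, 3, 1) == pytest.approx(
            perm_entropy_naive(x, 3, 1), abs=1e-10
        )


def test_dfa_matches_naive_oracle(rng):
    for _ in range(10):
        x = rng.standard_normal(200)
        sizes = _dfa_box_sizes(200)
        assert dfa_exponent(x) == pytest.approx(dfa_naive(x, sizes), abs=1e-10)


def test_spectral_entropy_matches_naive_formula(rng):
    x = rng.standard_normal(400)
    _, psd = sps.welch(x, fs=200.0, nperseg=256)
    assert spectral_entropy(x, 200.0) == pytest.approx(
        spectral_entropy_naive(psd), abs=1e-10
    )


def test_sample_entropy_alternating_signal_matches_oracle():
    x = np.tile([0.0, 1.0], 50)
    got = sample_entropy(x)
    assert got == pytest.approx(sample_entropy_naive(x), abs=1e-12)
    assert got < 0.05  # perfectly predictable sequence


# ---------------------------------------------------------------------------
# analytic limits
# ---------------------------------------------------------------------------

def test_perm_entropy_monotone_is_zero():
    assert perm_entropy(np.arange(500.0), order=3) == 0.0
    assert perm_entropy(np.arange(500.0), order=4) == 0.0


def test_perm_entropy_iid_noise_saturates(rng):
    x = rng.uniform(size=100_000)
    assert perm_entropy(x, order=3, normalized=True) == pytest.approx(1.0, abs=0.01)


def test_spectral_entropy_limits(rng):
    t = np.arange(4000) / 200.0
    sine = np.sin(2 * np.pi * 12.5 * t)
    assert spectral_entropy(sine, 200.0) <= 0.2
    assert spectral_entropy(rng.standard_normal(100_000), 200.0) == pytest.approx(
        1.0, abs=0.02
    )


def test_spectral_entropy_two_tone_one_bit():
    # two equal-power tones on exact bins of a rectangular one-segment PSD
    n = 256
    t = np.arange(n)
    x = np.sin(2 * np.pi * 32 * t / n) + np.sin(2 * np.pi * 96 * t / n)
    _, psd = sps.periodogram(x, fs=1.0, window="boxcar")
    assert spectral_entropy_naive(psd, normalized=False) == pytest.approx(1.0, abs=1e-6)


def test_svd_entropy_limits(rng):
    assert svd_entropy(np.full(100, 3.0)) == pytest.approx(0.0, abs=1e-9)
    assert svd_entropy(rng.standard_normal(10_000), order=3) >= 0.95


def test_dfa_white_and_brownian_limits(rng):
    white = np.mean([dfa_exponent(rng.standard_normal(10_000)) for _ in range(5)])
    assert white == pytest.approx(0.5, abs=0.05)
    brown = np.mean(
        [dfa_exponent(np.cumsum(rng.standard_normal(10_000))) for _ in range(5)]
    )
    assert brown == pytest.approx(1.5, abs=0.1)


def test_dfa_linear_ramp_trend_dominated():
    assert dfa_exponent(np.arange(1000.0)) >= 1.8


def test_higuchi_limits(rng):
    assert higuchi_fd(np.arange(1000.0)) == pytest.approx(1.0, abs=0.02)
    white = np.mean([higuchi_fd(rng.standard_normal(10_000)) for _ in range(5)])
    assert white == pytest.approx(2.0, abs=0.1)


def test_monotonicity_in_spectral_exponent(rng):
    """Steeper 1/f^beta: SpectEnt falls, DFA rises (Spearman rho = +/-1)."""
    betas = np.linspace(0.0, 2.0, 9)
    spect, dfa = [], []
    for beta in betas:
        se, da = [], []
        for _ in range(4):
            white = rng.standard_normal(4096)
            spec = np.fft.rfft(white)
            f = np.fft.rfftfreq(4096, 1 / 200.0)
            shape = np.zeros_like(f)
            shape[1:] = f[1:] ** (-beta / 2)
            x = np.fft.irfft(spec * shape, 4096)
            se.append(spectral_entropy(x, 200.0))
            da.append(dfa_exponent(x))
        spect.append(np.mean(se))
        dfa.append(np.mean(da))
    assert stats.spearmanr(betas, spect).statistic == -1.0
    assert stats.spearmanr(betas, dfa).statistic == 1.0


# ---------------------------------------------------------------------------
# error handling and invariants
# ---------------------------------------------------------------------------

def test_degenerate_inputs_raise():
    const = np.full(300, 5.0)
    with pytest.raises(DegenerateSignalError):
        sample_entropy(const)
    with pytest.raises(DegenerateSignalError):
        spectral_entropy(np.zeros(300), 200.0)
    with pytest.raises(DegenerateSignalError):
        dfa_exponent(const)
    with pytest.raises(ValueError, match="too short"):
        perm_entropy(np.arange(3.0), order=4)
    with pytest.raises(ValueError, match="too short"):
        dfa_exponent(np.arange(10.0))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(128, 400))
def test_normalized_entropies_bounded_and_finite(seed, n):
    x = np.random.default_rng(seed).standard_normal(n)
    for value in (
        perm_entropy(x),
        svd_entropy(x),
        spectral_entropy(x, 200.0),
    ):
        assert 0.0 <= value <= 1.0
    assert np.isfinite(dfa_exponent(x))
    assert 0.9 <= higuchi_fd(x) <= 2.1


def test_features_run_on_200_sample_windows(rng):
    """All six must work at the pipeline's 1-s window length."""
    x = rng.standard_normal(200)
    params = FeatureParams()
    w = WindowVector(
        x=x[None, :] / np.linalg.norm(x), y=1, channel_names=["FC2"]
    )
    fv = extract_features(w, ["FC2"], params)
    assert set(fv.values) == set(FEATURE_ORDER)
    assert all(np.isfinite(v) for v in fv.values.values())


# ---------------------------------------------------------------------------
# electrode averaging
# ---------------------------------------------------------------------------

def _window(rows, names, y=1):
    rows = np.asarray(rows, float)
    rows = rows / np.linalg.norm(rows, axis=1, keepdims=True)
    return WindowVector(x=rows, y=y, channel_names=names)


def test_extract_features_mean_identity(rng):
    sig = rng.standard_normal(200)
    w = _window([sig, sig, sig], ["FC2", "AFz", "F2"])
    multi = extract_features(w, ["FC2", "AFz", "F2"])
    single = extract_features(w, ["FC2"])
    for name in FEATURE_ORDER:
        assert multi.values[name] == pytest.approx(single.values[name], abs=1e-12)


def test_extract_features_permutation_symmetry(rng):
    w = _window(rng.standard_normal((3, 200)), ["FC2", "AFz", "F2"])
    a = extract_features(w, ["FC2", "AFz", "F2"])
    b = extract_features(w, ["F2", "FC2", "AFz"])
    for name in FEATURE_ORDER:
        assert a.values[name] == pytest.approx(b.values[name], abs=1e-12)


def test_extract_features_is_arithmetic_mean(rng):
    w = _window(rng.standard_normal((2, 200)), ["FC2", "AFz"])
    both = extract_features(w, ["FC2", "AFz"])
    first = extract_features(w, ["FC2"])
    second = extract_features(w, ["AFz"])
    for name in FEATURE_ORDER:
        assert both.values[name] == pytest.approx(
            (first.values[name] + second.values[name]) / 2, abs=1e-12
        )


def test_extract_features_error_names_channel(rng):
    rows = rng.standard_normal((2, 200))
    rows[1] = 2.0  # constant channel: SampEnt degenerate
    w = WindowVector(x=rows, y=0, channel_names=["FC2", "AFz"])
    with pytest.raises(DegenerateSignalError, match="AFz"):
        extract_features(w, ["FC2", "AFz"])
    with pytest.raises(KeyError, match="Oz"):
        extract_features(w, ["Oz"])


def test_complexity_transformer_shape_and_order(rng):
    X = rng.standard_normal((4, 2, 200))
    tf = ComplexityFeatures()
    out = tf.fit_transform(X)
    assert out.shape == (4, 6)
    # column j equals the channel-mean of the j-th named feature
    w = _window(X[0], ["a", "b"])
    # transformer does not normalize rows; compare against raw rows
    from eegdep.features import compute_feature

    manual = np.mean([compute_feature("PermEnt", ch, 200.0) for ch in X[0]])
    assert out[0, 0] == pytest.approx(manual, abs=1e-12)
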