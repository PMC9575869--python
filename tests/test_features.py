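import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phm.features import (
    TemplateBank,
    dtw,
    gmrf_stats,
    hmrf_em,
    hmrf_features,
    kinematic_features,
    msst,
    renyi_entropy,
    static_features,
    tf_features,
)
from phm.fusion import Window


def brute_force_dtw(p, r):
    """Exhaustive enumeration of monotone warping paths (m, n ≤ 8)."""
    m, n = len(p), len(r)
    best = [np.inf]

    def rec(i, j, acc):
        acc = acc + (p[i] - r[j]) ** 2
        if (i, j) == (m - 1, n - 1):
            best[0] = min(best[0], acc)
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < m and j + dj < n:
                rec(i + di, j + dj, acc)

    rec(0, 0, 0.0)
    return np.sqrt(best[0])


class TestDtw:
    def test_identity_alignment(self):
        p = np.array([1.0, 2.0, 3.0])
        res = dtw(p, p)
        assert res.cost == 0.0
        assert res.path == [(0, 0), (1, 1), (2, 2)]
        assert res.k == 3

    def test_path_length_bound_small_case(self):
        res = dtw(np.array([1.0, 2, 3]), np.array([1.0, 3]))
        assert res.k == 3  # max(3,2) ≤ k < 3+2−1 forces k = 3
        assert abs(res.cost - brute_force_dtw([1.0, 2, 3], [1.0, 3])) < 1e-12

    def test_oracle_equivalence_random_pairs(self):
        r = np.random.default_rng(0)
        for _ in range(100):
            m, n = r.integers(2, 9, 2)
            p = r.integers(0, 10, m).astype(float)
            q = r.integers(0, 10, n).astype(float)
            res = dtw(p, q)
            assert abs(res.cost - brute_force_dtw(p, q)) < 1e-12
            assert max(m, n) <= res.k < m + n - 1
            assert res.path[0] == (0, 0) and res.path[-1] == (m - 1, n - 1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        st.lists(st.floats(-5, 5), min_size=2, max_size=8),
    )
    def test_symmetry_and_nonnegativity(self, p, r):
        a, b = np.array(p), np.array(r)
        assert dtw(a, b).cost >= 0.0
        assert np.isclose(dtw(a, b).cost, dtw(b, a).cost)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw(np.array([]), np.array([1.0]))


class TestGmrf:
    def test_white_noise_offdiagonals_vanish(self, rng):
        X = rng.normal(size=(10_000, 4))
        _, sigma = gmrf_stats(X)
        off = sigma[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3.0 / np.sqrt(10_000))

    def test_linear_dependence_gives_rank_one(self):
        x = np.linspace(0, 1, 100)
        data = np.column_stack([x, 2 * x])
        mu, sigma = gmrf_stats(data)
        corr = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert np.isclose(corr, 1.0)
        assert np.linalg.matrix_rank(sigma, tol=1e-10) == 1

    def test_covariance_psd(self, rng):
        for _ in range(10):
            _, sigma = gmrf_stats(rng.normal(size=(50, 6)))
            assert np.linalg.eigvalsh(sigma).min() >= -1e-9


class TestMsst:
    def test_pure_tone_concentration(self):
        rate = 100.0
        t = np.arange(200) / rate
        tf = msst(np.sin(2 * np.pi * 5 * t), rate, iterations=2)
        df = tf.freqs[1] - tf.freqs[0]
        near = np.abs(tf.freqs - 5.0) <= df + 1e-9
        assert tf.matrix[near].sum() / tf.matrix.sum() >= 0.90

    def test_energy_conserved_and_nonnegative(self, rng):
        rate = 100.0
        x = rng.normal(size=300)
        tf = msst(x, rate, iterations=3)
        assert np.all(tf.matrix >= 0)
        # squeezing permutes STFT mass along frequency: reference energy is
        # the 1-iteration transform's total (identical scatter base)
        tf1 = msst(x, rate, iterations=1)
        assert abs(tf.matrix.sum() - tf1.matrix.sum()) <= 0.05 * tf1.matrix.sum()

    def test_chirp_ridge_monotone(self):
        from scipy.signal import chirp

        rate = 100.0
        t = np.arange(300) / rate
        tf = msst(chirp(t, 2.0, t[-1], 8.0), rate, iterations=3)
        ridge = tf.freqs[np.argmax(tf.matrix, axis=0)]
        assert np.all(np.diff(ridge) >= 0)

    def test_entropy_nonincreasing_in_iterations(self):
        rate = 100.0
        t = np.arange(400) / rate
        x = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 15 * t)
        ents = [renyi_entropy(msst(x, rate, m)) for m in (1, 2, 3, 4)]
        assert np.all(np.diff(ents) <= 1e-9)

    def test_zero_signal_returns_zero_matrix(self):
        tf = msst(np.zeros(200), 100.0, 2)
        assert np.all(tf.matrix == 0)
        vals, _ = tf_features(tf)
        assert np.all(np.isfinite(vals))


class TestHmrf:
    def test_two_state_segmentation_accuracy(self):
        r = np.random.default_rng(5)
        truth = np.repeat([0, 1, 0, 1], 50)
        y = np.where(truth == 1, 5.0, 0.0) + r.normal(0, 0.5, 200)
        res = hmrf_em(y, n_states=2)
        acc = max(np.mean(res.states == truth), np.mean(res.states == 1 - truth))
        assert acc >= 0.95

    def test_constant_signal_single_state(self):
        res = hmrf_em(np.ones(60), n_states=2)
        assert len(np.unique(res.states)) == 1
        assert res.energies[-1] == 0.0

    def test_energy_trace_nonincreasing(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.concatenate([r.normal(0, 1, 80), r.normal(3, 1, 80)])
            res = hmrf_em(y, n_states=2)
            assert np.all(np.diff(res.energies) <= 1e-9)

    def test_state_permutation_invariant_features(self):
        r = np.random.default_rng(3)
        y = np.concatenate([r.normal(0, 0.3, 60), r.normal(4, 0.3, 60)])
        res = hmrf_em(y, n_states=2)
        v1, _ = hmrf_features(res, len(y))
        flipped = hmrf_em(-y, n_states=2)
        v2, _ = hmrf_features(flipped, len(y))
        # occupancies mirror; sorted means negate and swap
        assert np.allclose(sorted(v1[3:5]), sorted(v2[3:5]), atol=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hmrf_em(np.zeros(5), n_states=2)


def _make_window(x3, phy, meta_kinds=("acc", "gyro")):
    n = len(x3)
    cols, meta = [], []
    for kind in meta_kinds:
        for a in "xyz":
            cols.append(x3 if kind == "acc" else 0.1 * x3)
            meta.append((f"{kind}_{a}", kind, "u"))
    cols.append(phy)
    meta.append(("emg", "emg", "mV"))
    cols.append(np.cos(np.arange(n) / 10.0))
    meta.append(("ecg", "ecg", "mV"))
    return Window(0.0, 2.0, np.column_stack(cols), meta, label="act")


class TestWindowFeatures:
    def test_window_identical_to_template_scores_zero(self):
        t = np.linspace(0, 2, 200)
        w = _make_window(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        w.pattern = "kinematic"
        bank = TemplateBank.fit([w])
        fv = kinematic_features(w, bank)
        dtw_vals = [v for v, n in zip(fv.values, fv.names) if n.startswith("dtw_")]
        assert np.allclose(dtw_vals, 0.0, atol=1e-12)

    def test_untrained_bank_channel_rejected(self):
        t = np.linspace(0, 2, 200)
        w = _make_window(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        bank = TemplateBank.fit([w])
        w2 = _make_window(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        w2.label = "other"
        bank.activities = ("other",)  # bank no longer matches its templates
        with pytest.raises(KeyError):
            kinematic_features(w2, bank)

    def test_static_features_deterministic_and_fixed_length(self):
        r = np.random.default_rng(2)
        x = r.normal(0, 0.05, 200) + 9.8
        phy = r.normal(0, 0.1, 200)
        w1 = _make_window(x, phy)
        w2 = _make_window(x.copy(), phy.copy())
        f1 = static_features(w1, rate=100.0)
        f2 = static_features(w2, rate=100.0)
        assert np.array_equal(f1.values, f2.values)
        # 3 MSST groups × (8 bands + 2 ridge + 1 energy) + 2 HMRF groups × 9
        assert len(f1.values) == 3 * 11 + 2 * 9
        assert f1.provenance == "msst+hmrf"

    def test_static_classes_separate_in_feature_space(self):
        """Typing-like tremor windows sit apart from resting-like windows."""
        r = np.random.default_rng(0)
        t = np.arange(200) / 100.0
        feats, labels = [], []
        for k in range(8):
            resting = 0.03 * np.sin(2 * np.pi * 9 * t) + r.normal(0, 0.05, 200) + 9.8
            typing = 0.12 * np.sin(2 * np.pi * 6 * t) + r.normal(0, 0.05, 200) + 9.8
            for x, emg_amp, lab in ((resting, 0.05, 0), (typing, 0.2, 1)):
                w = _make_window(x, emg_amp * r.normal(size=200))
                feats.append(static_features(w, 100.0).values)
                labels.append(lab)
        F = np.asarray(feats)
        F = (F - F.mean(0)) / np.where(F.std(0) > 0, F.std(0), 1.0)
        y = np.asarray(labels)
        d = np.linalg.norm(F[:, None] - F[None, :], axis=2)
        same = d[y[:, None] == y[None, :]]
        diff = d[y[:, None] != y[None, :]]
        assert diff.mean() > same[same > 0].mean()
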