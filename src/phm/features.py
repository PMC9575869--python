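"""Pattern-specific feature extraction.

Kinematic windows (complex, high-motion) are described by

* **DTW costs** against a per-(channel-group, activity) template bank —
  dynamic time warping under the local distance d(p, r) = √((p − r)²) with
  step set {(1,0), (0,1), (1,1)}; the cost is the square root of the
  DP-optimal sum of squared local distances along the warping path; and
* **Gaussian-random-field moments** — the per-channel mean vector μ̃ and
  the across-channel covariance Σ̃ (upper triangle), i.e. the first two
  moments that determine a Gaussian field over the window's channels.

Static windows (low-motion, pause/delay structure) are described by

* **MSST** — a multisynchrosqueezing transform: STFT energy reassigned
  along frequency to the instantaneous-frequency estimate, with the
  reassignment map composed M times, summarized as band energies, ridge
  statistics and log total energy; and
* **HMRF** — a two-state hidden Markov random field over time with Potts
  pairwise potentials, fitted by EM with ICM label updates; features are the
  final prior energy U(x), its decrease, and per-state occupancy/Gaussian
  parameters (states sorted by mean for permutation invariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal as sps

from .fusion import Window

# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------


@dataclass
class WarpResult:
    """Optimal warping path between two series.

    ``path`` holds 0-based grid cells from (0, 0) to (m−1, n−1); ``k`` is
    the path length.  For non-degenerate series (m, n ≥ 2) the length obeys
    max(m, n) ≤ k < m + n − 1 because ties are broken toward the diagonal.
    """

    cost: float
    path: list[tuple[int, int]]

    @property
    def k(self) -> int:
        return len(self.path)


@njit(cache=True)
def _dtw_dp(p, r):  # pragma: no cover - jit
    m, n = len(p), len(r)
    D = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            d2 = (p[i] - r[j]) ** 2
            if i == 0 and j == 0:
                D[i, j] = d2
            elif i == 0:
                D[i, j] = d2 + D[i, j - 1]
            elif j == 0:
                D[i, j] = d2 + D[i - 1, j]
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = d2 + best
    return D


def dtw(p: np.ndarray, r: np.ndarray) -> WarpResult:
    """Dynamic-programming optimal alignment of two 1-D series.

    Cost is √(Σ d²) accumulated along the optimal monotone path; identical
    inputs give cost 0 with the diagonal path.
    """
    p = np.ascontiguousarray(p, float).ravel()
    r = np.ascontiguousarray(r, float).ravel()
    if len(p) == 0 or len(r) == 0:
        raise ValueError("dtw requires non-empty series")
    D = _dtw_dp(p, r)
    # backtrack, preferring the diagonal on ties
    i, j = len(p) - 1, len(r) - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            best = min(candidates)
            if D[i - 1, j - 1] == best:
                i, j = i - 1, j - 1
            elif D[i - 1, j] == best:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return WarpResult(float(np.sqrt(D[-1, -1])), path)


# ---------------------------------------------------------------------------
# Template bank for DTW features
# ---------------------------------------------------------------------------

#: Channel groups aligned against templates (magnitudes for the tri-axial
#: sensors keep the features orientation-invariant).
DTW_GROUPS = ("acc", "gyro", "emg", "ecg")


def _group_series(win: Window, group: str, downsample: int) -> np.ndarray:
    """Window-level z-scored magnitude series, decimated for DTW."""
    x = win.magnitude(group)[::downsample]
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


@dataclass
class TemplateBank:
    """Per-(channel-group, activity) reference series for DTW features.

    The template is the medoid (minimum summed DTW cost) among the labeled
    training windows of that activity.
    """

    templates: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    activities: tuple[str, ...] = ()
    groups: tuple[str, ...] = DTW_GROUPS
    downsample: int = 4

    @classmethod
    def fit(
        cls,
        windows: list[Window],
        groups: tuple[str, ...] = DTW_GROUPS,
        downsample: int = 4,
        max_candidates: int = 20,
    ) -> "TemplateBank":
        """Choose medoid templates from labeled windows (all activities
        present in the labels; at most ``max_candidates`` windows per
        activity enter the medoid search, in corpus order)."""
        labeled = [w for w in windows if w.label is not None]
        if not labeled:
            raise ValueError("template bank needs labeled windows")
        activities = tuple(dict.fromkeys(w.label for w in labeled))
        bank = cls(activities=activities, groups=groups, downsample=downsample)
        for act in activities:
            cand = [w for w in labeled if w.label == act][:max_candidates]
            for g in groups:
                series = [_group_series(w, g, downsample) for w in cand]
                if len(series) == 1:
                    bank.templates[(g, act)] = series[0]
                    continue
                costs = np.zeros((len(series), len(series)))
                for i in range(len(series)):
                    for j in range(i + 1, len(series)):
                        c = dtw(series[i], series[j]).cost
                        costs[i, j] = costs[j, i] = c
                bank.templates[(g, act)] = series[int(costs.sum(axis=1).argmin())]
        return bank

    def feature_names(self) -> list[str]:
        return [f"dtw_{g}_{a}" for g in self.groups for a in self.activities]


# ---------------------------------------------------------------------------
# Gaussian-field moments
# ---------------------------------------------------------------------------

def gmrf_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and across-channel covariance of a window's channels."""
    data = np.asarray(data, float)
    mu = data.mean(axis=0)
    sigma = np.cov(data, rowvar=False, bias=True)
    return mu, np.atleast_2d(sigma)


@dataclass
class FeatureVector:
    """Fixed-length descriptor of one window plus extractor provenance."""

    values: np.ndarray
    names: list[str]
    provenance: str


def kinematic_features(win: Window, bank: TemplateBank) -> FeatureVector:
    """DTW costs to every activity template + Gaussian-field moments."""
    vals, names = [], []
    for g in bank.groups:
        series = _group_series(win, g, bank.downsample)
        for act in bank.activities:
            key = (g, act)
            if key not in bank.templates:
                raise KeyError(f"template bank has no entry for {key}")
            vals.append(dtw(series, bank.templates[key]).cost)
            names.append(f"dtw_{g}_{act}")
    mu, sigma = gmrf_stats(win.data)
    ch = [m[0] for m in win.channel_meta]
    vals.extend(mu)
    names.extend(f"gmrf_mean_{c}" for c in ch)
    iu = np.triu_indices(len(ch))
    vals.extend(sigma[iu])
    names.extend(f"gmrf_cov_{ch[i]}_{ch[j]}" for i, j in zip(*iu))
    return FeatureVector(np.asarray(vals, float), names, "dtw+gmrf")


# ---------------------------------------------------------------------------
# Multisynchrosqueezing transform
# ---------------------------------------------------------------------------

@dataclass
class TFRepresentation:
    """Squeezed time–frequency energy (freq bins × frames), all entries ≥ 0;
    total energy equals the underlying STFT energy (reassignment only moves
    mass along frequency)."""

    matrix: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    iterations: int


def msst(
    x: np.ndarray,
    rate: float,
    iterations: int = 3,
    win_seconds: float = 0.5,
    hop_fraction: float = 0.25,
) -> TFRepresentation:
    """Multisynchrosqueezing: iterated frequency reassignment of the STFT.

    The instantaneous-frequency estimate ω̂(t, ω) comes from the phase
    derivative (ratio of the derivative-window STFT to the window STFT);
    squeezing assigns each bin's energy |S|² to the nearest bin of ω̂, and
    the reassignment map is composed ``iterations`` times (each composition
    is one further squeeze of the previous result).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    x = np.asarray(x, float).ravel()
    nwin = int(round(win_seconds * rate))
    if len(x) < nwin:
        raise ValueError("signal shorter than the STFT window")
    hop = max(1, int(round(nwin * hop_fraction)))
    win = sps.windows.hann(nwin, sym=False)
    dwin = np.gradient(win) * rate

    sft = sps.ShortTimeFFT(win, hop, fs=rate, fft_mode="onesided")
    sft_d = sps.ShortTimeFFT(dwin, hop, fs=rate, fft_mode="onesided")
    # force one frame range on both transforms (the derivative window has a
    # different nonzero support, which would shift its default range)
    p0, p1 = 0, sft.p_max(len(x))
    S = sft.stft(x, p0=p0, p1=p1)
    Sd = sft_d.stft(x, p0=p0, p1=p1)
    freqs = sft.f
    times = np.arange(p0, p1) * sft.delta_t
    df = freqs[1] - freqs[0]

    # keep only frames whose window lies fully inside the signal (border
    # frames mix zero padding into the phase estimate)
    half = win_seconds / 2.0
    keep = (times >= half - 1e-9) & (times <= (len(x) - 1) / rate - half + 1e-9)
    if keep.any():
        S, Sd, times = S[:, keep], Sd[:, keep], times[keep]

    E = np.abs(S) ** 2
    if E.sum() == 0:
        return TFRepresentation(np.zeros_like(E), freqs, times, iterations)

    with np.errstate(divide="ignore", invalid="ignore"):
        omega = freqs[:, None] - np.imag(Sd / S) / (2 * np.pi)
    # bins with negligible energy keep their own frequency
    weak = E < 1e-12 * E.max()
    omega = np.where(weak | ~np.isfinite(omega), freqs[:, None], omega)

    map1 = np.clip(np.rint(omega / df).astype(np.int64), 0, len(freqs) - 1)
    map_m = map1
    for _ in range(iterations - 1):
        map_m = np.take_along_axis(map1, map_m, axis=0)

    T = np.zeros_like(E)
    frames = np.broadcast_to(np.arange(E.shape[1]), E.shape)
    np.add.at(T, (map_m.ravel(), frames.ravel()), E.ravel())
    return TFRepresentation(T, freqs, times, iterations)


def tf_features(tf: TFRepresentation, n_bands: int = 8) -> tuple[np.ndarray, list[str]]:
    """Band energy fractions + ridge-frequency statistics + log energy."""
    total = tf.matrix.sum()
    edges = np.linspace(0, tf.matrix.shape[0], n_bands + 1).astype(int)
    if total > 0:
        bands = np.array(
            [tf.matrix[edges[i] : edges[i + 1]].sum() for i in range(n_bands)]
        ) / total
        ridge = tf.freqs[np.argmax(tf.matrix, axis=0)]
        stats = [float(ridge.mean()), float(ridge.std())]
    else:
        bands = np.zeros(n_bands)
        stats = [0.0, 0.0]
    vals = np.concatenate([bands, stats, [np.log(total + 1e-12)]])
    names = [f"band{i}" for i in range(n_bands)] + ["ridge_mean", "ridge_sd", "log_energy"]
    return vals, names


def renyi_entropy(tf: TFRepresentation, order: float = 3.0) -> float:
    """Rényi entropy of the normalized TF energy (concentration measure)."""
    p = tf.matrix / tf.matrix.sum()
    p = p[p > 0]
    return float(np.log(np.sum(p**order)) / (1.0 - order))


# ---------------------------------------------------------------------------
# Hidden Markov random field over time (chain graph, Potts potential)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _icm_sweep(y, x, means, sds, beta):  # pragma: no cover - jit
    n = len(y)
    changed = 0
    k = len(means)
    for i in range(n):
        best_s = x[i]
        best_e = 1e300
        for s in range(k):
            e = 0.5 * ((y[i] - means[s]) / sds[s]) ** 2 + np.log(sds[s])
            if i > 0 and x[i - 1] != s:
                e += beta
            if i < n - 1 and x[i + 1] != s:
                e += beta
            if e < best_e - 1e-12:
                best_e = e
                best_s = s
        if best_s != x[i]:
            x[i] = best_s
            changed += 1
    return changed


@dataclass
class HmrfResult:
    """EM fit of the chain hidden Markov random field."""

    states: np.ndarray  # per-sample state index
    means: np.ndarray
    sds: np.ndarray
    energies: list[float]  # prior energy U(x) after each EM iteration
    converged: bool

    def prior_energy(self, beta: float = 1.0) -> float:
        return float(beta * np.sum(self.states[1:] != self.states[:-1]))


def hmrf_em(
    y: np.ndarray,
    n_states: int = 2,
    beta: float = 1.0,
    max_iter: int = 20,
    icm_sweeps: int = 10,
    seed: int = 0,
) -> HmrfResult:
    """EM segmentation of a 1-D series under a chain MRF prior.

    Cliques are adjacent time pairs with Potts potential β·1[x_i ≠ x_{i+1}];
    emissions are per-state Gaussians.  The E-step runs ICM (each flip
    accepted only when it lowers the posterior energy), the M-step
    re-estimates the Gaussian parameters; the prior energy U(x) is recorded
    after every iteration.
    """
    y = np.ascontiguousarray(y, float).ravel()
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if len(y) < 10 * n_states:
        raise ValueError(f"series too short: need >= {10 * n_states} samples")
    rng = np.random.default_rng(seed)

    scale = y.std() if y.std() > 0 else 1.0
    # initialize states from sorted-quantile chunks
    order = np.argsort(y)
    chunks = np.array_split(order, n_states)
    means = np.array([y[c].mean() for c in chunks])
    sds = np.array([max(y[c].std(), 1e-3 * scale) for c in chunks])
    # likelihood-only initial labeling
    ll = ((y[:, None] - means[None, :]) / sds[None, :]) ** 2 / 2 + np.log(sds)[None, :]
    x = np.ascontiguousarray(ll.argmin(axis=1).astype(np.int64))

    energies: list[float] = []
    converged = False
    for _ in range(max_iter):
        for _ in range(icm_sweeps):
            if _icm_sweep(y, x, means, sds, beta) == 0:
                break
        energies.append(beta * float(np.sum(x[1:] != x[:-1])))
        new_means, new_sds = means.copy(), sds.copy()
        for s in range(n_states):
            sel = x == s
            if sel.sum() == 0:
                # degenerate state: reseed at a random data quantile
                new_means[s] = float(np.quantile(y, rng.uniform(0.05, 0.95)))
                new_sds[s] = scale
                continue
            new_means[s] = y[sel].mean()
            new_sds[s] = max(y[sel].std(), 1e-3 * scale)
        if np.allclose(new_means, means) and np.allclose(new_sds, sds):
            converged = True
            break
        means, sds = new_means, new_sds
    return HmrfResult(x, means, sds, energies, converged)


def hmrf_features(res: HmrfResult, n: int) -> tuple[np.ndarray, list[str]]:
    """Fixed-length HMRF summary (states sorted by mean)."""
    order = np.argsort(res.means)
    occ = np.array([(res.states == s).mean() for s in order])
    u_final = res.energies[-1] / n
    du = (res.energies[0] - res.energies[-1]) / n
    vals = np.concatenate(
        [[u_final, du, len(res.energies)], occ, res.means[order], res.sds[order]]
    )
    k = len(order)
    names = (
        ["hmrf_u_final", "hmrf_du", "hmrf_iters"]
        + [f"hmrf_occ{i}" for i in range(k)]
        + [f"hmrf_mean{i}" for i in range(k)]
        + [f"hmrf_sd{i}" for i in range(k)]
    )
    return vals, names


# ---------------------------------------------------------------------------
# Static-window feature vector
# ---------------------------------------------------------------------------

#: Channel groups fed to the static extractors.
STATIC_MSST_GROUPS = ("acc", "emg", "ecg")
STATIC_HMRF_GROUPS = ("acc", "emg")


def static_features(
    win: Window,
    rate: float,
    msst_iterations: int = 3,
    n_bands: int = 8,
    n_states: int = 2,
    beta: float = 1.0,
) -> FeatureVector:
    """MSST band/ridge/energy features + HMRF segmentation features."""
    vals: list[float] = []
    names: list[str] = []
    for g in STATIC_MSST_GROUPS:
        tf = msst(win.magnitude(g) - win.magnitude(g).mean(), rate, msst_iterations)
        v, nm = tf_features(tf, n_bands)
        vals.extend(v)
        names.extend(f"msst_{g}_{s}" for s in nm)
    for g in STATIC_HMRF_GROUPS:
        y = win.magnitude(g)
        res = hmrf_em(y, n_states=n_states, beta=beta, seed=0)
        v, nm = hmrf_features(res, len(y))
        vals.extend(v)
        names.extend(f"{s}_{g}" for s in nm)
    return FeatureVector(np.asarray(vals, float), names, "msst+hmrf")
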