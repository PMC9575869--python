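"""Kinematic-vs-static pattern decision via polynomial probability densities.

Each window's accelerometer- and gyroscope-magnitude samples (standardized
with *recording-level* statistics) are summarized by a polynomial
probability density P(a) = w0 + w1·a + … + wM·a^M fitted over the observed
value interval.  Low-motion ("static") windows concentrate their mass in a
narrow sliver of the standardized range and yield a narrow density;
high-motion ("kinematic") windows spread over a wide range and yield a
broad, often multi-modal density.  The decision statistic is the standard
deviation of the fitted density treated as a distribution over its support,
averaged over the two channel groups; a window is called kinematic when the
score exceeds a frozen threshold τ.

Recording-level standardization makes the call scale-equivariant: rescaling
all channels of a recording by a constant leaves every score unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fusion import FusedSignal, Window

#: Decision threshold on the density-spread score, calibrated once on a
#: held-out synthetic recording (seed 0) by maximizing Youden's J and then
#: frozen.  Static windows score well below, kinematic well above.
DEFAULT_TAU = 0.3615

#: Channel groups whose magnitude densities enter the score.
DECISION_GROUPS = ("acc", "gyro")

_GRID = 512  # evaluation grid for normalization/moments


@dataclass
class PolyDensity:
    """Polynomial density fit on a real interval [x, y].

    ``weights`` are the polynomial coefficients (ascending powers) after
    normalization; the density is clipped at zero before renormalization if
    the raw least-squares fit dips negative. ``gof`` is the chi-square
    statistic of fitted vs. empirical bin masses and ``gof_p`` its p-value.
    """

    degree: int
    weights: np.ndarray
    support: tuple[float, float]
    gof: float
    gof_p: float
    degenerate: bool = False  # all samples identical → point mass

    def grid(self, n: int = _GRID) -> np.ndarray:
        return np.linspace(self.support[0], self.support[1], n)

    def pdf(self, a: np.ndarray) -> np.ndarray:
        """Evaluate the (clipped, normalized) density."""
        if self.degenerate:
            raise ValueError("degenerate density has no continuous pdf")
        raw = np.polynomial.polynomial.polyval(np.asarray(a, float), self.weights)
        return np.clip(raw, 0.0, None)

    def integral(self) -> float:
        if self.degenerate:
            return 1.0
        g = self.grid()
        return float(np.trapezoid(self.pdf(g), g))

    def spread(self) -> float:
        """Standard deviation of the density as a distribution over [x, y]."""
        if self.degenerate:
            return 0.0
        g = self.grid()
        p = self.pdf(g)
        z = np.trapezoid(p, g)
        mean = np.trapezoid(g * p, g) / z
        var = np.trapezoid((g - mean) ** 2 * p, g) / z
        return float(np.sqrt(max(var, 0.0)))


def _sturges(n: int) -> int:
    return int(np.ceil(np.log2(n))) + 1


def fit_poly_density(
    values: np.ndarray,
    degree: int | None = None,
    support: tuple[float, float] | None = None,
    max_degree: int = 6,
    alpha: float = 0.05,
) -> PolyDensity:
    """Fit a polynomial density to samples by least squares on a histogram.

    The histogram uses equal-width bins (Sturges' rule).  With
    ``degree=None`` the degree is the smallest M ≤ ``max_degree`` whose
    chi-square goodness-of-fit p-value exceeds ``alpha``, else
    ``max_degree``.  The fitted polynomial is clipped at zero and
    renormalized so it integrates to one over the support.
    """
    values = np.asarray(values, float).ravel()
    if degree is not None and degree < 0:
        raise ValueError("degree must be >= 0")
    if len(values) < 20:
        raise ValueError("need at least 20 samples for a density fit")

    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return PolyDensity(0, np.array([np.inf]), (lo, hi), 0.0, 1.0, degenerate=True)
    if support is None:
        pad = 0.05 * (hi - lo)
        support = (lo - pad, hi + pad)
    x, y = support
    if not (x < y):
        raise ValueError("support must satisfy x < y")

    nbins = _sturges(len(values))
    counts, edges = np.histogram(values, bins=nbins, range=(x, y))
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (len(values) * np.diff(edges))

    def _fit(m: int) -> PolyDensity:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            w = np.polynomial.polynomial.polyfit(centers, dens, min(m, nbins - 1))
        w = np.pad(w, (0, m + 1 - len(w)))
        grid = np.linspace(x, y, _GRID)
        raw = np.clip(np.polynomial.polynomial.polyval(grid, w), 0.0, None)
        z = np.trapezoid(raw, grid)
        if z <= 0:
            # fit collapsed; fall back to the uniform density
            w = np.zeros(m + 1)
            w[0] = 1.0 / (y - x)
        else:
            w = w / z
        fit = PolyDensity(m, w, (x, y), 0.0, 1.0)
        # chi-square of fitted vs. empirical bin masses
        exp_mass = np.empty(nbins)
        for i in range(nbins):
            seg = np.linspace(edges[i], edges[i + 1], 16)
            exp_mass[i] = np.trapezoid(fit.pdf(seg), seg)
        exp_mass = np.clip(exp_mass, 1e-12, None)
        exp_mass = exp_mass / exp_mass.sum()
        obs = counts / counts.sum()
        chi2 = float(len(values) * np.sum((obs - exp_mass) ** 2 / exp_mass))
        dof = max(nbins - 1 - (m + 1), 1)
        fit.gof = chi2
        fit.gof_p = float(stats.chi2.sf(chi2, dof))
        return fit

    if degree is not None:
        return _fit(degree)
    best = None
    for m in range(max_degree + 1):
        best = _fit(m)
        if best.gof_p > alpha:
            return best
    return best


@dataclass
class PatternCall:
    """Outcome of the kinematic/static decision for one window."""

    pattern: str  # kinematic | static
    score: float
    threshold: float
    degrees: dict = field(default_factory=dict)
    gof: dict = field(default_factory=dict)


@dataclass
class RecordingStats:
    """Recording-level mean/SD of each decision group's magnitude series."""

    mean: dict[str, float]
    sd: dict[str, float]


def _group_magnitude(matrix: np.ndarray, cols: list[int]) -> np.ndarray:
    block = matrix[:, cols]
    return np.linalg.norm(block, axis=1) if block.shape[1] > 1 else block[:, 0]


def recording_stats(fus: FusedSignal, groups=DECISION_GROUPS) -> RecordingStats:
    """Whole-recording magnitude statistics used to standardize windows."""
    mean, sd = {}, {}
    for g in groups:
        mag = _group_magnitude(fus.matrix, fus.kind_columns(g))
        mean[g] = float(mag.mean())
        sd[g] = float(mag.std())
    return RecordingStats(mean, sd)


def decide_pattern(
    window: Window,
    stats_: RecordingStats,
    tau: float = DEFAULT_TAU,
    max_degree: int = 6,
    groups=DECISION_GROUPS,
) -> PatternCall:
    """Classify one window as kinematic or static.

    Per group the window's magnitude series is standardized with the
    recording-level mean/SD, a polynomial density is fitted on its observed
    range, and the density spread (SD over the support) is recorded.  The
    score is the mean spread over groups; ``score > tau`` ⇒ kinematic.
    """
    spreads, degrees, gofs = [], {}, {}
    for g in groups:
        if g not in stats_.mean:
            raise KeyError(f"missing recording stats for group {g!r}")
        mag = window.magnitude(g)
        sd = stats_.sd[g] if stats_.sd[g] > 0 else 1.0
        z = (mag - stats_.mean[g]) / sd
        if np.ptp(z) < 1e-12:
            spreads.append(0.0)
            degrees[g], gofs[g] = 0, 0.0
            continue
        fit = fit_poly_density(z, max_degree=max_degree)
        spreads.append(fit.spread())
        degrees[g], gofs[g] = fit.degree, fit.gof
    score = float(np.mean(spreads))
    pattern = "kinematic" if score > tau else "static"
    call = PatternCall(pattern, score, tau, degrees, gofs)
    window.pattern = pattern
    return call


def calibrate_tau(scores: np.ndarray, is_kinematic: np.ndarray) -> float:
    """Threshold maximizing Youden's J over candidate cuts between scores."""
    scores = np.asarray(scores, float)
    is_kin = np.asarray(is_kinematic, bool)
    order = np.argsort(scores)
    s = scores[order]
    cuts = (s[:-1] + s[1:]) / 2.0
    best_tau, best_j = float(np.median(s)), -np.inf
    for c in cuts:
        tpr = np.mean(scores[is_kin] > c) if is_kin.any() else 0.0
        fpr = np.mean(scores[~is_kin] > c) if (~is_kin).any() else 0.0
        j = tpr - fpr
        if j > best_j:
            best_j, best_tau = j, float(c)
    return best_tau
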