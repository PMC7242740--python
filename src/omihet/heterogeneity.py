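"""Cell-population heterogeneity statistics for a scalar endpoint.

A cell group's endpoint distribution (typically the OMI index of all cells in
one treatment group and timepoint) is modeled as a 1-D Gaussian mixture

    f(y) = sum_i  pi_i  phi(y; mu_i, V_i),        g in {1, 2, 3}

fit by EM; the number of subpopulations g is selected by the Akaike
information criterion AIC = 2k - 2 ln L with k = 3g - 1 free parameters
(g means, g variances, g - 1 proportions).  From the selected model the
weighted heterogeneity index — a modified Shannon diversity index — is

    wH = sum_i (1 - p_i ln(p_i + 1)) * (sigma_i + d_i)

where p_i is the mixing proportion, sigma_i = sqrt(V_i), and d_i is the
distance between the subpopulation median (= mu_i for Gaussian components)
and the median of the full mixture distribution.  Companion descriptors:
quadratic entropy (QE), the Kolmogorov-Smirnov distance from a fitted normal
(KS), outlier percentage by Tukey fences (OL), SD and CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "SubpopulationModel", "HeterogeneityProfile", "BootstrapSummary",
    "fit_gmm", "select_model", "wh_index", "mixture_median", "quadratic_entropy",
    "ks_normality", "outlier_pct", "bootstrap_wh", "density_curves", "profile",
]


@dataclass
class SubpopulationModel:
    """A fitted 1-D Gaussian mixture, components sorted by mean ascending."""

    g: int
    pi: np.ndarray
    mu: np.ndarray
    V: np.ndarray
    log_likelihood: float
    aic: float
    n_cells: int

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if not (len(self.pi) == len(self.mu) == len(self.V) == self.g):
            raise ValueError("pi, mu, V must each have length g")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.V <= 0):
            raise ValueError("component variances must be positive")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.V)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.pi[:, None] * norm.pdf(x[None, :], self.mu[:, None], self.sigma[:, None]),
            axis=0,
        )

    def cdf(self, x: float | np.ndarray) -> float | np.ndarray:
        return np.sum(self.pi * norm.cdf(np.asarray(x)[..., None], self.mu, self.sigma), axis=-1)


@dataclass
class HeterogeneityProfile:
    wh_index: float
    qe: float
    ks: float
    ol_pct: float
    sd: float
    cv: float
    model: SubpopulationModel


@dataclass
class BootstrapSummary:
    point: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_boot: int


def _variance_floor(values: np.ndarray) -> float:
    v = float(np.var(values))
    return max(1e-6 * v, 1e-12)


def _degenerate_model(values: np.ndarray) -> SubpopulationModel:
    floor = _variance_floor(values)
    mu = float(values[0])
    n = len(values)
    ll = float(np.sum(norm.logpdf(values, mu, np.sqrt(floor))))
    return SubpopulationModel(1, np.array([1.0]), np.array([mu]), np.array([floor]),
                              ll, 2 * 2 - 2 * ll, n)


def _log_density(x, pi, mu, var):
    return (np.log(pi)[None, :] - 0.5 * np.log(2.0 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :])


def _em(x: np.ndarray, g: int, floor: float, tol: float, max_iter: int):
    """1-D Gaussian-mixture EM from a deterministic quantile initialization.

    Component means start at the g sample quantiles (2i+1)/2g, weights start
    uniform, and every component starts with the overall sample variance —
    a deliberately broad start, as in standard mixture-fitting software.
    Component variances are floored at ``floor`` in every M step (a hard
    floor, not a ridge).  Convergence: relative log-likelihood change below
    ``tol`` (run to modest precision on purpose; chasing the last decimals of
    mixture likelihood rewards spurious splits of unimodal samples during
    AIC model selection).
    """
    n = len(x)
    qs = (2.0 * np.arange(g) + 1.0) / (2.0 * g)
    mu = np.quantile(x, qs)
    pi = np.full(g, 1.0 / g)
    var = np.full(g, max(float(np.var(x)), floor))
    ll_old = -np.inf
    for _ in range(max_iter):
        logp = _log_density(x, pi, mu, var)
        norm_c = logsumexp(logp, axis=1)
        ll = float(norm_c.sum())
        resp = np.exp(logp - norm_c[:, None])
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        pi = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = np.maximum((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk, floor)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    ll = float(logsumexp(_log_density(x, pi, mu, var), axis=1).sum())
    return pi, mu, var, ll


def fit_gmm(
    values: np.ndarray,
    g: int,
    seed: int | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> SubpopulationModel:
    """EM-fit a g-component 1-D Gaussian mixture.

    The fit is fully deterministic (quantile-based initialization); ``seed``
    is accepted for interface stability but unused.  Variances are floored at
    ``1e-6`` times the sample variance; components are reported sorted by
    mean.  A constant sample degenerates to g = 1 with the variance at its
    floor (with a warning).
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if g < 1:
        raise ValueError("g must be >= 1")
    if len(x) < 5 * g:
        raise ValueError(f"need at least {5 * g} cells to fit g={g}, got {len(x)}")
    if np.ptp(x) == 0.0:
        warnings.warn("constant sample: returning degenerate single-component model",
                      stacklevel=2)
        return _degenerate_model(x)
    pi, mu, var, ll = _em(x, g, _variance_floor(x), tol, max_iter)
    order = np.argsort(mu)
    pi = pi[order] / pi[order].sum()
    k = 3 * g - 1
    return SubpopulationModel(g, pi, mu[order], var[order], ll, 2 * k - 2 * ll, len(x))


def select_model(
    values: np.ndarray, seed: int | None = None, g_max: int = 3
) -> SubpopulationModel:
    """Fit g = 1..g_max mixtures and return the one with minimal AIC.

    Ties break toward smaller g.  Candidate g values whose sample size falls
    below 5g are not fit (so small groups are always modeled with fewer
    components).
    """
    x = np.asarray(values, dtype=float).ravel()
    best: SubpopulationModel | None = None
    for g in range(1, g_max + 1):
        if len(x) < 5 * g:
            break
        model = fit_gmm(x, g, seed=seed)
        if best is None or model.aic < best.aic - 1e-12:
            best = model
        if model.g == 1 and np.ptp(x) == 0.0:
            break  # degenerate path: no point fitting larger g
    if best is None:
        raise ValueError("too few values to fit any mixture model")
    return best


def mixture_median(model: SubpopulationModel) -> float:
    """Median of the full mixture distribution (root of CDF = 1/2 by bisection)."""
    sd_max = float(model.sigma.max())
    lo = float(model.mu.min()) - 12.0 * sd_max
    hi = float(model.mu.max()) + 12.0 * sd_max
    return brentq(lambda x: model.cdf(x) - 0.5, lo, hi, xtol=1e-12)


def wh_index(model: SubpopulationModel) -> float:
    """Weighted heterogeneity index of a fitted subpopulation model.

    ``wH = sum_i (1 - p_i ln(p_i + 1)) * (sigma_i + d_i)`` with d_i the
    distance from each subpopulation median (the component mean, by Gaussian
    symmetry) to the median of the entire mixture distribution.  For a single
    component this reduces to ``(1 - ln 2) * sigma``.
    """
    m = mixture_median(model)
    d = np.abs(model.mu - m)
    weights = 1.0 - model.pi * np.log(model.pi + 1.0)
    return float(np.sum(weights * (model.sigma + d)))


def quadratic_entropy(values: np.ndarray, n_bins: int = 20) -> float:
    """Quadratic entropy of a sample on ``n_bins`` equal-width bins.

    ``QE = sum_ij p_i p_j d_ij`` with p the bin occupancy fractions and
    ``d_ij`` the distance between bin centers normalized by the sample range;
    bounded in [0, 1].  Constant samples have QE = 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    rng = np.ptp(x)
    if rng == 0.0:
        return 0.0
    counts, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    d = np.abs(centers[:, None] - centers[None, :]) / rng
    return float(p @ d @ p)


def ks_normality(values: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance between the sample and a normal with the
    sample's mean and SD: ``sup |ECDF - Phi|`` over the sorted points (both
    one-sided sups).  A descriptive normality distance, not a test p-value.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        warnings.warn("constant sample: KS distance defined as 0", stacklevel=2)
        return 0.0
    cdf = norm.cdf(x, x.mean(), sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def outlier_pct(values: np.ndarray) -> float:
    """Percentage of values outside the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return float(100.0 * np.mean((x < lo) | (x > hi)))


def bootstrap_wh(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 0,
    g_max: int = 3,
    reselect_g: bool = False,
) -> BootstrapSummary:
    """Bootstrap the wH-index: ``n_boot`` resamples with replacement, each
    passed through a fresh mixture fit.

    By default the subpopulation count g is selected once on the full sample
    and held fixed while each resample re-fits the mixture parameters:
    resampling duplicates data points, and AIC read on such lumpy resamples
    systematically inflates g, which makes the wH distribution jump between
    model classes instead of reflecting sampling noise.  ``reselect_g=True``
    re-runs AIC selection inside every resample instead, propagating
    model-choice uncertainty (at the price of much wider intervals).
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 15:
        raise ValueError("need at least 15 cells to bootstrap")
    rng = np.random.default_rng(seed)
    point_model = select_model(x, g_max=g_max)
    point = wh_index(point_model)
    samples = np.empty(n_boot)
    for b in range(n_boot):
        resample = x[rng.integers(0, len(x), size=len(x))]
        if reselect_g:
            model = select_model(resample, g_max=g_max)
        elif np.ptp(resample) == 0.0:
            model = _degenerate_model(resample)
        else:
            model = fit_gmm(resample, point_model.g)
        samples[b] = wh_index(model)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return BootstrapSummary(point, float(samples.mean()), float(samples.std(ddof=1)),
                            float(lo), float(hi), n_boot)


def density_curves(
    model: SubpopulationModel, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mixture density on a grid: (total curve, per-component curves).

    Component curves are scaled by their mixing proportions, so they sum to
    the total pointwise; the total integrates to 1 once the grid spans the
    mixture support.
    """
    grid = np.asarray(grid, dtype=float)
    comps = model.pi[:, None] * norm.pdf(grid[None, :], model.mu[:, None], model.sigma[:, None])
    return comps.sum(axis=0), comps


def profile(
    values: np.ndarray, seed: int | None = None, n_bins: int = 20, g_max: int = 3,
) -> HeterogeneityProfile:
    """Full heterogeneity profile (wH, QE, KS, OL, SD, CV) of a cell group."""
    x = np.asarray(values, dtype=float).ravel()
    model = select_model(x, seed=seed, g_max=g_max)
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    mean = float(x.mean())
    if np.ptp(x) == 0.0:
        wh = qe = ks = ol = 0.0
    else:
        wh = wh_index(model)
        qe = quadratic_entropy(x, n_bins=n_bins)
        ks = ks_normality(x) if len(x) >= 8 else float("nan")
        ol = outlier_pct(x)
    cv = sd / abs(mean) if mean != 0 else float("inf") if sd > 0 else 0.0
    return HeterogeneityProfile(wh, qe, ks, ol, sd, cv, model)
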