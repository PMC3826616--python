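"""Variance-stabilizing normalization of the regions x samples count matrix.

Counts are modeled as overdispersed (negative-binomial-like): the variance
of normalized counts at mean q is w(q) = q * zeta + alpha(q) * q^2, where
zeta accounts for size-factor rescaling and alpha(q) is an empirical
dispersion-mean relationship shared by the whole analysis.  The pipeline is

1. median-of-ratios size factors,
2. a pooled local-regression fit of the variance-mean relationship across
   replicate classes (only the fitted values are used downstream),
3. the variance-stabilizing transformation tau(q) = integral_0^q dv/sqrt(w(v)),
   evaluated numerically, which maps counts to a scale with approximately
   mean-independent spread.  In the alpha -> 0 (Poisson) limit tau(q) -> 2*sqrt(q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over regions with all-positive counts.

    factor_s = median_r ( count_rs / geometric-mean_r ), the standard
    count-normalization convention for sequencing depth.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (regions x samples)")
    positive = (counts > 0).all(axis=1)
    if positive.sum() < 2:
        raise ValueError(
            "fewer than 2 regions with nonzero counts in every sample; "
            "consider adding a pseudocount"
        )
    sub = counts[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


@dataclass
class DispersionFit:
    """Fitted variance-mean relationship, queryable at any mean.

    Stores the local-regression fit of log variance vs log mean of
    normalized counts, plus the mean reciprocal size factor ``zeta`` used to
    subtract the counting (shot-noise) component when converting fitted
    variance to dispersion alpha(q) = (w(q) - zeta*q) / q^2.
    """

    log_mean_grid: np.ndarray
    log_var_fit: np.ndarray
    zeta: float
    alpha_floor: float = 1e-8
    scalar_alpha: float | None = None  # optional single-dispersion mode

    def fitted_variance(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.scalar_alpha is not None:
            return q * self.zeta + self.scalar_alpha * q * q
        logq = np.log(np.maximum(q, 1e-300))
        logw = np.interp(logq, self.log_mean_grid, self.log_var_fit)
        return np.exp(logw)

    def alpha(self, q) -> np.ndarray:
        """Fitted dispersion at mean q (floored at a small positive value).

        Outside the fitted mean range the *dispersion* is held constant at
        the boundary value (clamping the variance instead would inflate the
        shot-noise term at small means).
        """
        q = np.asarray(q, dtype=float)
        if self.scalar_alpha is not None:
            return np.full(q.shape, max(self.scalar_alpha, self.alpha_floor))
        q_eval = np.clip(
            q, np.exp(self.log_mean_grid[0]), np.exp(self.log_mean_grid[-1])
        )
        a = (self.fitted_variance(q_eval) - self.zeta * q_eval) / (q_eval * q_eval)
        return np.clip(a, self.alpha_floor, None)

    def variance(self, q) -> np.ndarray:
        """Variance function w(q) = zeta*q + alpha(q)*q^2 used by the VST."""
        q = np.asarray(q, dtype=float)
        return self.zeta * q + self.alpha(q) * q * q


def _lowess_fit(x: np.ndarray, y: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(y, x, frac=frac, it=2, return_sorted=True)
    # collapse duplicate x for interpolation
    xs, idx = np.unique(fitted[:, 0], return_index=True)
    return xs, fitted[idx, 1]


def fit_dispersion(
    counts: np.ndarray,
    factors: np.ndarray,
    class_ids: list[str],
    span: float = 0.3,
    scalar: bool = False,
) -> DispersionFit:
    """Pooled local fit of the dispersion-mean relationship.

    Per-region means and variances of factor-normalized counts are computed
    within each replicate class (>= 2 samples), pooled across classes into a
    single analysis-wide cloud, and the variance-mean relationship is
    smoothed by local linear regression on the log-log scale with fixed
    span.  Only the fitted values are exposed.  ``scalar=True`` instead
    reduces the pooled raw dispersions to their median, a single dispersion
    for the whole analysis.
    """
    counts = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    class_ids = list(class_ids)
    if counts.shape[1] != len(class_ids) or counts.shape[1] != factors.size:
        raise ValueError("counts columns, factors and class_ids must align")
    normalized = counts / factors[None, :]
    means, variances, zetas, weights = [], [], [], []
    for cid in sorted(set(class_ids)):
        cols = [j for j, c in enumerate(class_ids) if c == cid]
        if len(cols) < 2:
            continue
        sub = normalized[:, cols]
        q = sub.mean(axis=1)
        w = sub.var(axis=1, ddof=1)
        keep = (q > 0) & (w > 0)
        means.append(q[keep])
        variances.append(w[keep])
        zetas.append(np.mean(1.0 / factors[cols]))
        weights.append(keep.sum())
    if not means:
        raise ValueError("no replicate class with >= 2 samples: cannot estimate dispersion")
    q = np.concatenate(means)
    w = np.concatenate(variances)
    zeta = (
        float(np.average(zetas, weights=weights))
        if sum(weights) > 0
        else float(np.mean(zetas))
    )
    if q.size < 2:
        # no region shows positive within-class variance: no excess
        # dispersion to estimate, the data are noise-free replicates
        logger.info("no within-class variance observed; dispersion fixed at 0")
        return DispersionFit(
            log_mean_grid=np.array([-30.0, 30.0]),
            log_var_fit=np.array([-30.0, 30.0]) + np.log(max(zeta, 1e-12)),
            zeta=zeta,
            scalar_alpha=0.0,
        )
    logq, logw_fit = _lowess_fit(np.log(q), np.log(w), frac=span)
    fit = DispersionFit(log_mean_grid=logq, log_var_fit=logw_fit, zeta=zeta)
    if scalar:
        raw = (w - zeta * q) / (q * q)
        fit.scalar_alpha = float(max(np.median(raw), 0.0))
    return fit


@dataclass
class OccupancyMatrix:
    """Continuous variance-stabilized occupancy scores, same shape as the
    source count matrix."""

    values: np.ndarray
    sample_ids: list[str]
    region_ids: list[str]
    size_factors: np.ndarray
    dispersion_fit: DispersionFit | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.region_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "region"
        df.to_csv(path, sep="\t", float_format="%.6g")


def vst_function(fit: DispersionFit, q_max: float, n_grid: int = 4096):
    """Numeric variance-stabilizing transform tau on [0, q_max].

    tau(q) = integral_0^q dv / sqrt(w(v)).  The integrable 1/sqrt(v)
    singularity at zero is removed by the substitution v = u^2, giving
    integrand 2u/sqrt(w(u^2)), evaluated by the trapezoid rule on a uniform
    u grid.  Returns a callable strictly increasing on [0, q_max].
    """
    u = np.linspace(0.0, np.sqrt(max(q_max, 1.0)) * 1.001, n_grid)
    v = u * u
    w = fit.variance(v)
    if np.any(w[1:] <= 0):
        raise ValueError("fitted variance is not positive on the count range")
    integrand = np.empty_like(u)
    integrand[1:] = 2.0 * u[1:] / np.sqrt(w[1:])
    # w(v) ~ zeta*v near 0, so 2u/sqrt(w(u^2)) -> 2/sqrt(zeta)
    integrand[0] = 2.0 / np.sqrt(fit.zeta) if fit.zeta > 0 else integrand[1]
    tau_grid = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(u))])

    def tau(q):
        q = np.asarray(q, dtype=float)
        return np.interp(np.sqrt(np.maximum(q, 0.0)), u, tau_grid)

    return tau


def vst(
    counts: np.ndarray,
    factors: np.ndarray,
    fit: DispersionFit,
    sample_ids: list[str] | None = None,
    region_ids: list[str] | None = None,
) -> OccupancyMatrix:
    """Apply the variance-stabilizing transform to size-factor-normalized
    counts; tau(0) = 0 and tau is strictly increasing, so scores are
    monotone in counts within each sample."""
    counts = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    normalized = counts / factors[None, :]
    tau = vst_function(fit, float(normalized.max(initial=1.0)))
    values = tau(normalized)
    n_regions, n_samples = counts.shape
    return OccupancyMatrix(
        values=values,
        sample_ids=sample_ids or [f"s{j}" for j in range(n_samples)],
        region_ids=region_ids or [f"r{i}" for i in range(n_regions)],
        size_factors=factors,
        dispersion_fit=fit,
    )


def normalize_counts(count_matrix, span: float = 0.3, scalar: bool = False) -> OccupancyMatrix:
    """End-to-end normalization of a :class:`~unipeak.regions.CountMatrix`."""
    counts = count_matrix.matrix
    factors = size_factors(counts)
    class_ids = [s.class_id for s in count_matrix.samples]
    fit = fit_dispersion(counts, factors, class_ids, span=span, scalar=scalar)
    return vst(
        counts,
        factors,
        fit,
        sample_ids=[s.sample_id for s in count_matrix.samples],
        region_ids=[f"{r.chromosome}:{r.start}-{r.end}" for r in count_matrix.regions],
    )
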