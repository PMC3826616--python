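"""Downstream analyses of the occupancy matrix: co-occupancy clustering,
motif-conditioned occupancy tests, interaction-pair correlation comparison,
and the partial least-squares model of gene-regulation readouts.
"""

from __future__ import annotations

import io as _stdio
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pearson distances and trees


def pearson_distance(values: np.ndarray, sample_ids: list[str]) -> "DistanceMatrix":
    """Pairwise Pearson distance 1 - r between samples' occupancy vectors
    over all regions."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 regions")
    sd = values.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0.0:
            raise ValueError(f"zero-variance sample {sample_ids[j]}")
    r = np.corrcoef(values.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(sample_ids), matrix=d)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class Tree:
    """Phylogeny-style tree over sample ids, held as a newick string."""

    newick: str
    rooted: bool

    def _skbio(self):
        from skbio import TreeNode

        return TreeNode.read(_stdio.StringIO(self.newick))

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self._skbio().tips()}

    def tip_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        dm = self._skbio().tip_tip_distances()
        ids = list(dm.ids)
        return DistanceMatrix(ids=ids, matrix=np.asarray(dm.data, dtype=float))

    def root_to_leaf_depths(self) -> dict[str, float]:
        tree = self._skbio()
        return {t.name: tree.distance(t) for t in tree.tips()}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick.rstrip() + "\n")


def _quote(name: str) -> str:
    return name if name.replace("_", "").replace("-", "").isalnum() else f"'{name}'"


def upgma(d: DistanceMatrix) -> Tree:
    """Rooted ultrametric tree by average-linkage agglomeration.

    Merge height is half the average inter-cluster distance, so root-to-leaf
    path lengths are equal.  Ties in the minimal pair are broken toward the
    lexicographically smallest (label_a, label_b) pair, labels being each
    cluster's smallest leaf id.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 samples")
    # active clusters: label -> (newick, height, size)
    clusters: dict[str, tuple[str, float, int]] = {
        name: (_quote(name), 0.0, 1) for name in d.ids
    }
    dist: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[frozenset((d.ids[i], d.ids[j]))] = float(d.matrix[i, j])
    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for a, b in itertools.combinations(labels, 2):
            val = dist[frozenset((a, b))]
            if best is None or val < best[0] - 1e-15:
                best = (val, a, b)
        _, a, b = best
        na, nb = clusters[a][2], clusters[b][2]
        height = best[0] / 2.0
        nwk_a, h_a, _ = clusters[a]
        nwk_b, h_b, _ = clusters[b]
        merged_nwk = f"({nwk_a}:{height - h_a:.12g},{nwk_b}:{height - h_b:.12g})"
        label = min(a, b)
        for other in labels:
            if other in (a, b):
                continue
            val = (
                na * dist[frozenset((a, other))] + nb * dist[frozenset((b, other))]
            ) / (na + nb)
            dist[frozenset((label, other))] = val
        del clusters[a], clusters[b]
        clusters[label] = (merged_nwk, height, na + nb)
    (nwk, _, _), = clusters.values()
    return Tree(newick=nwk + ";", rooted=True)


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Unrooted tree by the Saitou-Nei neighbor-joining agglomeration."""
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    dm = SkbioDM(d.matrix, ids=d.ids)
    tree = nj(dm)
    buf = _stdio.StringIO()
    tree.write(buf)
    return Tree(newick=buf.getvalue().strip(), rooted=False)


# ---------------------------------------------------------------------------
# Motif-conditioned occupancy statistics


def pool_replicates(values: np.ndarray, sample_ids: list[str], targets: list[str]):
    """Per-TF occupancy = mean of that TF's variance-stabilized replicate
    columns.  Returns (pooled regions x TFs array, TF names)."""
    values = np.asarray(values, dtype=float)
    tf_names = sorted(set(targets))
    pooled = np.column_stack(
        [
            values[:, [j for j, t in enumerate(targets) if t == tf]].mean(axis=1)
            for tf in tf_names
        ]
    )
    return pooled, tf_names


@dataclass
class MotifTestResult:
    tf: str
    motif_set: str
    t_statistic: float
    p_value: float
    signed_log10_p: float
    n_with: int
    n_without: int


def welch_signed_log10_p(with_motif: np.ndarray, without_motif: np.ndarray):
    """Two-sided Welch t-test; returns (t, p, signed log10 p) where the sign
    is that of mean(with) - mean(without): positive = enrichment at
    motif-bearing promoters."""
    from scipy import stats

    t, p = stats.ttest_ind(with_motif, without_motif, equal_var=False)
    diff = float(np.mean(with_motif) - np.mean(without_motif))
    sign = 0.0 if diff == 0.0 else float(np.sign(diff))
    logp = 0.0 if p >= 1.0 else -float(np.log10(p))
    return float(t), float(p), sign * logp


def motif_occupancy_test(
    occupancy: np.ndarray, hits: np.ndarray, tf: str = "", motif_set: str = ""
) -> MotifTestResult | None:
    """Occupancy of one TF at consensus promoters with vs. without one motif
    set.  Returns None (with a log entry) when either group has < 2 members."""
    occupancy = np.asarray(occupancy, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    a = occupancy[hits]
    b = occupancy[~hits]
    if a.size < 2 or b.size < 2:
        logger.info("motif test %s x %s skipped: group of size < 2", tf, motif_set)
        return None
    t, p, slp = welch_signed_log10_p(a, b)
    return MotifTestResult(
        tf=tf,
        motif_set=motif_set,
        t_statistic=t,
        p_value=p,
        signed_log10_p=slp,
        n_with=int(a.size),
        n_without=int(b.size),
    )


def motif_test_table(values, sample_ids, targets, set_table):
    """All TF x motif-set Welch tests as a DataFrame of signed log10 p."""
    import pandas as pd

    pooled, tf_names = pool_replicates(values, sample_ids, targets)
    out = pd.DataFrame(np.nan, index=tf_names, columns=list(set_table.columns))
    for j, sid in enumerate(set_table.columns):
        hits = set_table[sid].to_numpy(dtype=bool)
        for i, tf in enumerate(tf_names):
            res = motif_occupancy_test(pooled[:, i], hits, tf, sid)
            if res is not None:
                out.loc[tf, sid] = res.signed_log10_p
    return out


def motif_summaries(set_table):
    """Row sums (distinct motif sets per region) and column sums (regions
    carrying each set) of the 0/1 set-collapsed hit table."""
    arr = set_table.to_numpy(dtype=bool)
    per_region = arr.sum(axis=1)
    per_set = arr.sum(axis=0)
    return per_region, per_set


# ---------------------------------------------------------------------------
# Interaction-pair correlation comparison


@dataclass
class CorrelationSplit:
    binding: np.ndarray
    non_binding: np.ndarray

    @property
    def mean_difference(self) -> float:
        return float(self.binding.mean() - self.non_binding.mean())


def interaction_correlation_split(
    values: np.ndarray,
    sample_ids: list[str],
    targets: list[str],
    interacting_pairs: set[frozenset],
) -> CorrelationSplit:
    """Partition pairwise sample correlations into those between interacting
    TF pairs and the rest; pairs of replicates of the same TF are excluded."""
    values = np.asarray(values, dtype=float)
    r = np.corrcoef(values.T)
    binding, non_binding = [], []
    n = len(sample_ids)
    for i, j in itertools.combinations(range(n), 2):
        ti, tj = targets[i], targets[j]
        if ti == tj:
            continue
        pair = frozenset((ti, tj))
        (binding if pair in interacting_pairs else non_binding).append(r[i, j])
    if not binding:
        raise ValueError("no correlations from interacting (binding) pairs")
    if not non_binding:
        raise ValueError("no correlations from non-binding pairs")
    return CorrelationSplit(
        binding=np.asarray(binding), non_binding=np.asarray(non_binding)
    )


# ---------------------------------------------------------------------------
# Partial least-squares model of gene regulation


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int, tol=1e-12, max_iter=2000):
    """Two-block NIPALS PLS with Y deflation.

    Returns weights W, X loadings P, Y loadings Q, each with
    ``n_components`` columns, for centered/scaled X and Y.
    """
    X = X.copy()
    Y = Y.copy()
    n, px = X.shape
    py = Y.shape[1]
    W = np.zeros((px, n_components))
    P = np.zeros((px, n_components))
    Q = np.zeros((py, n_components))
    extracted = 0
    x_norm0 = np.linalg.norm(X) or 1.0
    y_norm0 = np.linalg.norm(Y) or 1.0
    for a in range(n_components):
        # stop once either block is numerically exhausted
        if (
            np.linalg.norm(X) < 1e-10 * x_norm0
            or np.linalg.norm(Y) < 1e-10 * y_norm0
        ):
            break
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        w = np.zeros(px)
        for _ in range(max_iter):
            w_new = X.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            t = X @ w_new
            tt = t @ t
            if tt == 0:
                break
            q = Y.T @ t / tt
            qq = q @ q
            if qq == 0:
                u_new = u
            else:
                u_new = Y @ q / qq
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            u = u_new
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        p = X.T @ t / tt
        q = Y.T @ t / tt
        X -= np.outer(t, p)
        Y -= np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p, q
        extracted = a + 1
    return W, P, Q, extracted


@dataclass
class PLSModel:
    """Fitted latent-variable regression of regulation readouts on occupancy.

    ``variant`` tags the predictor block: 'full' (TF + control occupancy) or
    'null' (control/input occupancy only).  Coefficients are stored per
    component count so predictions can be made with any number of latent
    variables up to ``max_components``.
    """

    x_names: list[str]
    y_names: list[str]
    n_components: int
    max_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    coefs: np.ndarray            # (max_components, px, py) on the scaled scale
    rmsep: np.ndarray | None = None   # LOO RMSEP averaged over responses, per ncomp
    cv_r2: dict[str, float] = field(default_factory=dict)
    variant: str = "full"

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        a = (n_components or self.n_components) - 1
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        Ys = Xs @ self.coefs[a]
        return Ys * self.y_scale + self.y_mean


def _fit_coefs(Xs: np.ndarray, Ys: np.ndarray, max_components: int) -> np.ndarray:
    W, P, Q, extracted = _nipals_pls2(Xs, Ys, max_components)
    px, py = Xs.shape[1], Ys.shape[1]
    coefs = np.zeros((max_components, px, py))
    for a in range(1, max_components + 1):
        k = min(a, extracted)
        if k == 0:
            continue
        Wa, Pa, Qa = W[:, :k], P[:, :k], Q[:, :k]
        # B = W (P'W)^-1 Q'
        coefs[a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)
    return coefs


def _scale_blocks(X, Y, autoscale):
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    if autoscale:
        x_scale = X.std(axis=0, ddof=1)
        y_scale = Y.std(axis=0, ddof=1)
    else:
        x_scale = np.ones(X.shape[1])
        y_scale = np.ones(Y.shape[1])
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    y_scale = np.where(y_scale == 0, 1.0, y_scale)
    return x_mean, x_scale, y_mean, y_scale


def loo_rmsep(
    X: np.ndarray, Y: np.ndarray, max_components: int, autoscale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out prediction error per component count.

    Each region is predicted after re-fitting (including re-centering and
    re-scaling) on the remaining regions.  Returns (rmsep, press) where
    ``rmsep[a-1]`` is the root mean squared LOO error at ``a`` components,
    averaged over response columns on the autoscaled response scale, and
    ``press[a-1]`` is the per-column squared-error sum on the original scale.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 regions")
    py = Y.shape[1]
    sq_err = np.zeros((max_components, n, py))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Ytr = X[mask], Y[mask]
        x_mean, x_scale, y_mean, y_scale = _scale_blocks(Xtr, Ytr, autoscale)
        Xs = (Xtr - x_mean) / x_scale
        Ys = (Ytr - y_mean) / y_scale
        coefs = _fit_coefs(Xs, Ys, max_components)
        xs_i = (X[i] - x_mean) / x_scale
        for a in range(max_components):
            pred = xs_i @ coefs[a] * y_scale + y_mean
            sq_err[a, i] = (pred - Y[i]) ** 2
    press = sq_err.sum(axis=1)  # (max_components, py), original scale
    # RMSEP on the scaled response scale for comparability across responses
    y_sd = Y.std(axis=0, ddof=1)
    y_sd = np.where(y_sd == 0, 1.0, y_sd)
    rmsep = np.sqrt((sq_err / (y_sd**2)[None, None, :]).mean(axis=1)).mean(axis=1)
    return rmsep, press


def select_components(rmsep: np.ndarray, decrement: float = 0.01) -> int:
    """Latent-variable selection rule: the first LV plus every subsequent LV
    that lowers the average RMSEP by at least ``decrement``, applied greedily
    in component order."""
    n = 1
    for a in range(1, rmsep.size):
        if rmsep[a - 1] - rmsep[a] >= decrement:
            n = a + 1
        else:
            break
    return n


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
    variant: str = "full",
    autoscale: bool = True,
    max_components: int | None = None,
    rmsep_decrement: float = 0.01,
) -> PLSModel:
    """Fit the latent-variable regression of regulation readouts on occupancy.

    X and Y are column-centered (and unit-variance scaled when ``autoscale``)
    before two-block NIPALS PLS.  The component count follows the RMSEP-
    decrement rule under leave-one-out cross-validation; per-response LOO CV
    R^2 values are stored on the model.  Zero-variance columns are dropped
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of regions")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 complete regions")
    x_names = list(x_names) if x_names is not None else [f"x{j}" for j in range(X.shape[1])]
    y_names = list(y_names) if y_names is not None else [f"y{j}" for j in range(Y.shape[1])]
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [x_names[j] for j in np.flatnonzero(~keep)]
        logger.warning("dropping zero-variance predictors: %s", dropped)
        X = X[:, keep]
        x_names = [x_names[j] for j in np.flatnonzero(keep)]
    n, px = X.shape
    if max_components is None:
        max_components = int(min(px, n - 2, 20))
    max_components = max(1, max_components)

    rmsep, press = loo_rmsep(X, Y, max_components, autoscale)
    n_components = select_components(rmsep, rmsep_decrement)

    x_mean, x_scale, y_mean, y_scale = _scale_blocks(X, Y, autoscale)
    Xs = (X - x_mean) / x_scale
    Ys = (Y - y_mean) / y_scale
    coefs = _fit_coefs(Xs, Ys, max_components)

    # CV R^2 about the full-data column means (documented convention)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - press[n_components - 1] / tss
    r2 = np.where(tss == 0, 0.0, r2)  # constant response -> R^2 = 0
    cv_r2 = {name: float(v) for name, v in zip(y_names, r2)}

    return PLSModel(
        x_names=x_names,
        y_names=y_names,
        n_components=n_components,
        max_components=max_components,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        coefs=coefs,
        rmsep=rmsep,
        cv_r2=cv_r2,
        variant=variant,
    )


def loo_cv_r2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    y_names: list[str] | None = None,
    autoscale: bool = True,
) -> dict[str, float]:
    """Per-response leave-one-out CV R^2 at a fixed component count.

    R^2 = 1 - PRESS / TSS with TSS about the full-data column mean (a
    constant response is defined to have R^2 = 0).  Each held-out region is
    predicted from a literal re-fit on the remaining regions.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    _, press = loo_rmsep(X, Y, n_components, autoscale)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - press[n_components - 1] / tss
    r2 = np.where(tss == 0, 0.0, r2)  # constant response -> R^2 = 0
    names = list(y_names) if y_names is not None else [f"y{j}" for j in range(Y.shape[1])]
    return {name: float(v) for name, v in zip(names, r2)}
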