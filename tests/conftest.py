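import numpy as np
import pytest

from unipeak.io import GenomeLayout, HitTrack, SampleMeta


@pytest.fixture
def meta():
    return SampleMeta(sample_id="s1", target="TF1", cell_type="cellA", lab="lab1")


@pytest.fixture
def layout():
    return GenomeLayout(chrom_sizes={"chr1": 1_000_000, "chr2": 500_000})


def make_track(positions, strand="+", chrom="chr1", counts=None, meta=None):
    track = HitTrack(
        sample=meta or SampleMeta(sample_id="t", target="TF1")
    )
    track.add_hits(chrom, strand, np.asarray(positions), counts)
    return track


def brute_force_density(hit_pos, hit_cnt, h, length):
    """O(N*h) double-loop Epanechnikov KDE oracle with the fixed denominator."""
    from unipeak.density import epanechnikov_kernel

    dense = np.zeros(length)
    denom = sum(epanechnikov_kernel(k / h) for k in range(-h, h + 1))
    for p, c in zip(hit_pos, hit_cnt):
        for off in range(-h, h + 1):
            i = p + off
            if 0 <= i < length:
                dense[i] += epanechnikov_kernel(off / h) * c
    return dense / denom


def random_additive_tree(rng, n_leaves):
    """A random binary tree with positive branch lengths and the additive
    leaf-to-leaf distance matrix it implies.

    Returns (names, distance_matrix).  Distances are computed by brute-force
    path summation, independent of any tree-building code.
    """
    names = [f"L{i}" for i in range(n_leaves)]
    # each node: dict leaf -> distance to this node
    nodes = [{name: 0.0} for name in names]
    dist = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.5, 3.0), rng.uniform(0.5, 3.0)
        for x, dx in a.items():
            for y, dy in b.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = dist[frozenset((names[i], names[j]))]
    return names, D


def svd_pls_predict(X, Y, Xnew, n_components, autoscale=True):
    """Independent PLS2 oracle: per-component weight = dominant left singular
    vector of the cross-covariance of the deflated blocks (no power
    iteration).  Returns predictions for Xnew on the original Y scale."""
    X = np.asarray(X, float).copy()
    Y = np.asarray(Y, float).copy()
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    if autoscale:
        xs = X.std(axis=0, ddof=1)
        ys = Y.std(axis=0, ddof=1)
    else:
        xs = np.ones(X.shape[1])
        ys = np.ones(Y.shape[1])
    xs = np.where(xs == 0, 1.0, xs)
    ys = np.where(ys == 0, 1.0, ys)
    Xs, Ys = (X - xm) / xs, (Y - ym) / ys
    Xd, Yd = Xs.copy(), Ys.copy()
    W, P, Q = [], [], []
    for _ in range(n_components):
        U, S, Vt = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
        if S[0] < 1e-12:
            break
        w = U[:, 0]
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, q)
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q).T
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    Xn = (np.asarray(Xnew, float) - xm) / xs
    return Xn @ B * ys + ym
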