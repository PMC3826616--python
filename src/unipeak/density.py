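"""Kernel density estimation of strand-specific 5'-hit profiles.

The density at position i on one strand is the Epanechnikov-weighted average
of the hit counts C(j) within +/- h bases,

    H(i) = sum_{j=i-h..i+h} K((i-j)/h) C(j) / sum_{k=-h..h} K(k/h),

with the *fixed* position-independent denominator: there is no boundary
renormalization, so hits within h of a chromosome end lose the kernel mass
that falls off-chromosome.  Each interior hit contributes exactly unit mass,
so for hits at least h from both ends, sum_i H(i) equals the number of hits.

Profiles are sparse: H is materialized only within +/- h of some hit and is
zero (implicitly) elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HitTrack


def epanechnikov_kernel(x):
    """Epanechnikov (quadratic) kernel: (3/4)(1 - x^2) for |x| <= 1, else 0."""
    x = np.asarray(x, dtype=float)
    w = np.where(np.abs(x) <= 1.0, 0.75 * (1.0 - x * x), 0.0)
    return w if w.ndim else float(w)


@dataclass
class DensityProfile:
    """Sparse kernel-smoothed density for one chromosome.

    ``positions`` is strictly increasing; ``values`` holds H at those
    positions; H is zero everywhere else.  ``shift`` records the signed
    translation already applied (positive = 3'-ward on the forward strand).
    """

    chromosome: str
    strand: str  # '+', '-', or 'both'
    bandwidth: int
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    values: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    shift: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must align")

    @property
    def mass(self) -> float:
        return float(self.values.sum())

    def translate(self, s: int) -> "DensityProfile":
        """Return a copy shifted by ``s`` bases (positive = rightward)."""
        return DensityProfile(
            chromosome=self.chromosome,
            strand=self.strand,
            bandwidth=self.bandwidth,
            positions=self.positions + int(s),
            values=self.values.copy(),
            shift=self.shift + int(s),
        )

    def dense(self, start: int, end: int) -> np.ndarray:
        """Materialize H over [start, end) as a dense array."""
        out = np.zeros(end - start, dtype=float)
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="left")
        out[self.positions[lo:hi] - start] = self.values[lo:hi]
        return out

    def at(self, positions) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.positions, positions)
        out = np.zeros(positions.shape, dtype=float)
        ok = idx < self.positions.size
        ok[ok] &= self.positions[idx[ok]] == positions[ok]
        out[ok] = self.values[idx[ok]]
        return out


def _sum_sparse(
    pos_list: list[np.ndarray], val_list: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    pos = np.concatenate(pos_list)
    val = np.concatenate(val_list)
    upos, inv = np.unique(pos, return_inverse=True)
    uval = np.bincount(inv, weights=val, minlength=upos.size)
    keep = uval != 0.0
    return upos[keep] if not keep.all() else upos, uval[keep] if not keep.all() else uval


def smooth_profile(
    track: HitTrack,
    chrom: str,
    strand: str,
    h: int,
    chrom_length: int | None = None,
) -> DensityProfile:
    """Smooth one strand of one chromosome of a hit track with bandwidth h.

    An empty track yields an all-zero (empty-sparse) profile.  Positions
    outside [0, chrom_length) are clipped away after smoothing.
    """
    if int(h) != h or h < 1:
        raise ValueError("bandwidth h must be a positive integer")
    h = int(h)
    hit_pos, hit_cnt = track.strand(chrom, strand)
    prof = DensityProfile(chromosome=chrom, strand=strand, bandwidth=h)
    if hit_pos.size == 0:
        return prof
    offsets = np.arange(-h, h + 1)
    weights = epanechnikov_kernel(offsets / h)
    weights = weights / weights.sum()
    # scatter each hit's kernel onto its +/- h neighborhood
    all_pos = (hit_pos[:, None] + offsets[None, :]).ravel()
    all_val = (hit_cnt[:, None].astype(float) * weights[None, :]).ravel()
    pos, val = _sum_sparse([all_pos], [all_val])
    keep = pos >= 0
    if chrom_length is not None:
        keep &= pos < chrom_length
    prof.positions, prof.values = pos[keep], val[keep]
    return prof


def sum_profiles(profiles: list[DensityProfile]) -> DensityProfile:
    """Positionwise sum of profiles on the same chromosome and bandwidth."""
    if not profiles:
        raise ValueError("no profiles to sum")
    first = profiles[0]
    for p in profiles[1:]:
        if p.bandwidth != first.bandwidth:
            raise ValueError("mismatched bandwidths")
        if p.chromosome != first.chromosome:
            raise ValueError("mismatched chromosomes")
    strands = {p.strand for p in profiles}
    strand = strands.pop() if len(strands) == 1 else "both"
    pos, val = _sum_sparse(
        [p.positions for p in profiles], [p.values for p in profiles]
    )
    return DensityProfile(
        chromosome=first.chromosome,
        strand=strand,
        bandwidth=first.bandwidth,
        positions=pos,
        values=val,
    )


def combine_profiles(
    fwd: DensityProfile, rev: DensityProfile, s: int
) -> DensityProfile:
    """Unified strand-independent profile: forward translated +s (3'-ward),
    reverse translated -s, summed positionwise."""
    if fwd.bandwidth != rev.bandwidth:
        raise ValueError("mismatched bandwidths")
    if fwd.chromosome != rev.chromosome:
        raise ValueError("mismatched chromosomes")
    if s < 0:
        raise ValueError("shift must be >= 0")
    out = sum_profiles([fwd.translate(s), rev.translate(-s)])
    out.strand = "both"
    out.shift = int(s)
    return out


def pooled_profile(profiles: list[DensityProfile]) -> DensityProfile:
    """Positionwise sum of per-sample unified profiles (controls excluded
    by the caller)."""
    if not profiles:
        raise ValueError("cannot pool zero profiles")
    out = sum_profiles(profiles)
    out.strand = "both"
    return out


def profile_to_bedgraph(profile: DensityProfile, fh) -> None:
    """Write a sparse profile as single-base bedGraph records (inspection aid)."""
    for p, v in zip(profile.positions, profile.values):
        fh.write(f"{profile.chromosome}\t{p}\t{p + 1}\t{v:.6g}\n")
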