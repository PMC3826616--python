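"""Per-sample strand-shift estimation.

Reads come from the two ends of sheared fragments, so forward- and
reverse-strand 5'-start pileups flank each binding site at roughly half the
fragment length.  For each sample, preliminary enriched regions are called
from the unshifted sum of the two strand profiles; within each of the
strongest regions the Pearson correlation between the strand profiles is
scanned over a grid of candidate per-strand shifts, and the density of the
per-region correlation-maximizing shifts (Epanechnikov KDE on the shift
grid) is maximized to give the sample-wide shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .density import (
    DensityProfile,
    epanechnikov_kernel,
    smooth_profile,
    sum_profiles,
)
from .io import GenomeLayout, HitTrack, SampleMeta
from .regions import (
    EnrichedRegion,
    UniPeakParams,
    call_regions,
    hits_in_region,
    region_kurtosis,
)

logger = logging.getLogger(__name__)


@dataclass
class RegionShift:
    region: EnrichedRegion
    best_shift: int
    max_correlation: float


@dataclass
class ShiftEstimate:
    sample_id: str
    shift: int
    region_shifts: list[RegionShift] = field(default_factory=list)
    curve_shifts: np.ndarray | None = None  # shift grid
    curve_density: np.ndarray | None = None  # smoothed argmax density
    n_regions_used: int = 0


def preliminary_regions(
    pooled_unshifted: DensityProfile,
    hit_pos: np.ndarray,
    hit_cnt: np.ndarray,
    total_reads: int,
    layout: GenomeLayout,
    fold_threshold: float = 25.0,
    kurtosis_max: float = 50.0,
    top: int = 1000,
) -> list[tuple[EnrichedRegion, int]]:
    """Regions of the unshifted both-strand profile exceeding the fold
    threshold, leptokurtic regions removed, ranked by contained hit count
    (descending) and truncated to the strongest ``top``.

    Returns (region, hit_count) pairs; raises if nothing is enriched.
    """
    raw = call_regions(pooled_unshifted, total_reads, layout, fold_threshold)
    ranked: list[tuple[EnrichedRegion, int]] = []
    for region in raw:
        rp, rc = hits_in_region(hit_pos, hit_cnt, region.start, region.end)
        if rp.size == 0:
            continue
        if region_kurtosis(rp, rc) > kurtosis_max:
            continue
        ranked.append((region, int(rc.sum())))
    if not ranked:
        raise ValueError(
            "no preliminary enriched regions: insufficient enrichment for "
            "shift estimation"
        )
    ranked.sort(key=lambda t: (-t[1], t[0].chromosome, t[0].start))
    return ranked[:top]


def _region_shift_scan(
    fwd: DensityProfile,
    rev: DensityProfile,
    region: EnrichedRegion,
    min_shift: int,
    max_shift: int,
) -> tuple[int, float] | None:
    """Best per-strand shift for one region.

    The correlation window is the region span; the strand profiles are read
    from a window extended by ``max_shift`` on both sides so every shifted
    slice stays in bounds.  At shift s the forward profile is translated +s
    and the reverse profile -s, i.e. position i compares fwd H(i-s) with
    rev H(i+s).  Returns None when either strand has zero variance at every
    shift.
    """
    w0 = region.start - max_shift
    w1 = region.end + max_shift
    f = fwd.dense(w0, w1)
    r = rev.dense(w0, w1)
    span = region.end - region.start
    base = region.start - w0
    best: tuple[float, int] | None = None
    for s in range(min_shift, max_shift + 1):
        fs = f[base - s : base - s + span]
        rs = r[base + s : base + s + span]
        if fs.std() == 0.0 or rs.std() == 0.0:
            continue
        corr = float(np.corrcoef(fs, rs)[0, 1])
        # ties broken toward the smaller shift (strict improvement required)
        if best is None or corr > best[0]:
            best = (corr, s)
    if best is None:
        return None
    return best[1], best[0]


def smoothed_shift_mode(
    best_shifts: list[int],
    min_shift: int,
    max_shift: int,
    curve_bw: int = 5,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Epanechnikov KDE of the per-region argmax shifts over the integer
    shift grid; the grid point maximizing the density is the sample-wide
    shift, ties broken toward the smaller shift."""
    grid = np.arange(min_shift, max_shift + 1)
    shifts = np.asarray(best_shifts, dtype=float)
    weights = epanechnikov_kernel((grid[:, None] - shifts[None, :]) / curve_bw)
    density = weights.sum(axis=1)
    mode = int(grid[int(np.argmax(density))])  # argmax takes the first (smallest)
    return mode, grid, density


def estimate_shift(
    fwd: DensityProfile,
    rev: DensityProfile,
    regions: list[EnrichedRegion],
    sample_id: str = "",
    min_shift: int = 25,
    max_shift: int = 150,
    curve_bw: int = 5,
    min_correlation: float = 0.3,
) -> ShiftEstimate:
    """Sample-wide shift from per-region correlation scans.

    Regions whose best correlation falls below ``min_correlation`` are
    recorded but do not vote for the sample-wide shift.
    """
    if not regions:
        raise ValueError("no regions for shift estimation")
    if min_shift > max_shift:
        raise ValueError("min_shift must be <= max_shift")
    region_shifts: list[RegionShift] = []
    for region in regions:
        res = _region_shift_scan(fwd, rev, region, min_shift, max_shift)
        if res is None:
            logger.info(
                "%s: region %s:%d-%d skipped (zero strand variance)",
                sample_id,
                region.chromosome,
                region.start,
                region.end,
            )
            continue
        s, corr = res
        region_shifts.append(RegionShift(region, s, corr))
    voters = [rs.best_shift for rs in region_shifts if rs.max_correlation >= min_correlation]
    if not voters:
        raise ValueError(
            f"{sample_id}: no region passed the shift-estimation correlation "
            "threshold"
        )
    mode, grid, density = smoothed_shift_mode(voters, min_shift, max_shift, curve_bw)
    return ShiftEstimate(
        sample_id=sample_id,
        shift=mode,
        region_shifts=region_shifts,
        curve_shifts=grid,
        curve_density=density,
        n_regions_used=len(voters),
    )


def estimate_sample_shift(
    track: HitTrack,
    layout: GenomeLayout,
    params: UniPeakParams | None = None,
) -> ShiftEstimate:
    """Preliminary pass for a single ChIP sample across its chromosomes.

    Strand profiles are smoothed at the preliminary bandwidth, preliminary
    regions called per chromosome from their unshifted sum, ranked globally
    by contained hit count, and the strongest regions scanned for the
    correlation-maximizing shift.
    """
    params = params or UniPeakParams()
    total = track.total_hits
    if total == 0:
        raise ValueError(f"{track.sample.sample_id}: empty track")
    per_chrom: dict[str, tuple[DensityProfile, DensityProfile]] = {}
    candidates: list[tuple[EnrichedRegion, int]] = []
    for chrom in track.chromosomes():
        if layout.is_excluded(chrom):
            continue
        length = layout.chrom_sizes.get(chrom)
        f = smooth_profile(track, chrom, "+", params.prelim_bandwidth, length)
        r = smooth_profile(track, chrom, "-", params.prelim_bandwidth, length)
        per_chrom[chrom] = (f, r)
        fpos, fcnt = track.strand(chrom, "+")
        rpos, rcnt = track.strand(chrom, "-")
        pos = np.concatenate([fpos, rpos])
        cnt = np.concatenate([fcnt, rcnt])
        order = np.argsort(pos, kind="stable")
        pos, cnt = pos[order], cnt[order]
        try:
            ranked = preliminary_regions(
                sum_profiles([f, r]),
                pos,
                cnt,
                total,
                layout,
                params.prelim_fold_threshold,
                params.kurtosis_cutoff(),
                params.top_regions,
            )
        except ValueError:
            continue
        candidates.extend(ranked)
    if not candidates:
        raise ValueError(
            f"{track.sample.sample_id}: no preliminary enriched regions for "
            "shift estimation"
        )
    candidates.sort(key=lambda t: (-t[1], t[0].chromosome, t[0].start))
    candidates = candidates[: params.top_regions]
    # group scan by chromosome to reuse the dense strand profiles
    region_shifts: list[RegionShift] = []
    for region, _ in candidates:
        f, r = per_chrom[region.chromosome]
        res = _region_shift_scan(f, r, region, params.min_shift, params.max_shift)
        if res is None:
            continue
        s, corr = res
        region_shifts.append(RegionShift(region, s, corr))
    voters = [
        rs.best_shift
        for rs in region_shifts
        if rs.max_correlation >= params.min_strand_correlation
    ]
    if not voters:
        raise ValueError(
            f"{track.sample.sample_id}: no region passed the shift-estimation "
            "correlation threshold"
        )
    mode, grid, density = smoothed_shift_mode(
        voters, params.min_shift, params.max_shift, params.shift_curve_bandwidth
    )
    return ShiftEstimate(
        sample_id=track.sample.sample_id,
        shift=mode,
        region_shifts=region_shifts,
        curve_shifts=grid,
        curve_density=density,
        n_regions_used=len(voters),
    )


def assign_control_shift(
    controls: list[SampleMeta], chip_shifts: list[float]
) -> float:
    """Controls yield too few enriched regions for their own estimate; they
    inherit the median of the ChIP samples' shifts (midpoint for an even
    count)."""
    if not chip_shifts:
        raise ValueError("no ChIP shift estimates to infer a control shift from")
    return float(np.median(np.asarray(chip_shifts, dtype=float)))
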