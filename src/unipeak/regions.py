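"""Enriched-region calling, QC filters, per-sample counting, and the
end-to-end pipeline orchestrator.

A region is a maximal run of consecutive positions where the pooled smoothed
density exceeds ``fold_threshold`` times the uniform background rate
(total confident non-control reads / effective genome size).  Regions then
pass three QC filters: excess-kurtosis of the contained 5'-start positions
(leptokurtic single-base stacks are artifacts), Pearson correlation between
the shifted strand profiles, and structural filters (excluded chromosomes,
blacklist overlap, maximum length).  Finally every sample's shifted hits --
including negative controls and histone marks, which never shaped the
regions -- are counted within each region.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .density import DensityProfile, combine_profiles, pooled_profile, smooth_profile
from .io import GenomeLayout, HitTrack, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class EnrichedRegion:
    chromosome: str
    start: int
    end: int
    peak_pos: int  # leftmost argmax of the pooled density
    peak_height: float = 0.0
    kurtosis: float | None = None
    strand_correlation: float | None = None
    pass_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty region")
        if not self.start <= self.peak_pos < self.end:
            raise ValueError("peak outside region")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())


@dataclass
class CountMatrix:
    """Integer hit counts for every region (rows) and sample (columns)."""

    regions: list[EnrichedRegion]
    samples: list[SampleMeta]
    matrix: np.ndarray  # (n_regions, n_samples) int64

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(self.regions), len(self.samples)):
            raise ValueError("matrix shape does not match region/sample lists")

    def to_dataframe(self):
        import pandas as pd

        index = [
            f"{r.chromosome}:{r.start}-{r.end}" for r in self.regions
        ]
        return pd.DataFrame(
            self.matrix, index=index, columns=[s.sample_id for s in self.samples]
        )

    def write_tsv(self, path) -> None:
        """TSV with sample-metadata header rows above the count block."""
        with open(path, "w") as fh:
            for attr in ("target", "cell_type", "lab", "class_id"):
                vals = "\t".join(str(getattr(s, attr)) for s in self.samples)
                fh.write(f"#{attr}\t{vals}\n")
            flags = "\t".join(str(int(s.is_control)) for s in self.samples)
            fh.write(f"#is_control\t{flags}\n")
            ids = "\t".join(s.sample_id for s in self.samples)
            fh.write(f"region\t{ids}\n")
            for region, row in zip(self.regions, self.matrix):
                key = f"{region.chromosome}:{region.start}-{region.end}"
                fh.write(key + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def call_regions(
    pooled: DensityProfile,
    total_reads: int,
    layout: GenomeLayout,
    fold_threshold: float = 25.0,
) -> list[EnrichedRegion]:
    """Maximal runs of consecutive positions with pooled H(i) above
    fold_threshold times the uniform background."""
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    if total_reads <= 0:
        raise ValueError("no reads: background rate undefined")
    background = total_reads / layout.effective_genome_size
    threshold = fold_threshold * background
    pos, val = pooled.positions, pooled.values
    above = val > threshold
    if pooled.chromosome in layout.chrom_sizes:
        above &= (pos >= 0) & (pos < layout.chrom_sizes[pooled.chromosome])
    regions: list[EnrichedRegion] = []
    if not above.any():
        return regions
    idx = np.flatnonzero(above)
    # break runs where indices or genomic positions are non-consecutive
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) != 1)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [idx.size]])
    for a, b in zip(starts, ends):
        run = idx[a:b]
        peak_local = int(np.argmax(val[run]))  # leftmost tie
        regions.append(
            EnrichedRegion(
                chromosome=pooled.chromosome,
                start=int(pos[run[0]]),
                end=int(pos[run[-1]]) + 1,
                peak_pos=int(pos[run[peak_local]]),
                peak_height=float(val[run[peak_local]]),
            )
        )
    return regions


def region_kurtosis(positions, counts) -> float:
    """Excess (Fisher) kurtosis of the multiset of hit positions.

    Zero positional variance (all hits on one base) is defined as +inf so
    the region always fails the leptokurtosis filter.
    """
    positions = np.asarray(positions, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("kurtosis of an empty region")
    mu = (positions * counts).sum() / n
    d = positions - mu
    m2 = (counts * d**2).sum() / n
    if m2 == 0.0:
        return float("inf")
    m4 = (counts * d**4).sum() / n
    return float(m4 / m2**2 - 3.0)


def hits_in_region(
    track_pos: np.ndarray, track_cnt: np.ndarray, start: int, end: int
) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(track_pos, start, side="left")
    hi = np.searchsorted(track_pos, end, side="left")
    return track_pos[lo:hi], track_cnt[lo:hi]


def strand_correlation(
    region: EnrichedRegion,
    fwd: DensityProfile,
    rev: DensityProfile,
    min_corr: float = 0.3,
) -> tuple[bool, float]:
    """Pearson r between the (already shifted) strand profiles over the
    region span; fail when r < min_corr or either strand has zero variance."""
    f = fwd.dense(region.start, region.end)
    r = rev.dense(region.start, region.end)
    if f.std() == 0.0 or r.std() == 0.0:
        return False, float("nan")
    corr = float(np.corrcoef(f, r)[0, 1])
    return corr >= min_corr, corr


def apply_structural_filters(
    regions: list[EnrichedRegion],
    layout: GenomeLayout,
    max_length: int = 500,
) -> list[EnrichedRegion]:
    """Drop regions on excluded chromosomes, regions overlapping a blacklist
    interval by >= 1 bp, and regions longer than ``max_length`` bp."""
    out = []
    for region in regions:
        if layout.is_excluded(region.chromosome):
            continue
        if region.length > max_length:
            continue
        if any(
            bl.chrom == region.chromosome
            and region.start < bl.end
            and bl.start < region.end
            for bl in layout.blacklist
        ):
            continue
        out.append(region)
    return out


def shifted_strand_hits(
    track: HitTrack, chrom: str, shift: int
) -> tuple[np.ndarray, np.ndarray]:
    """All of one sample's hits on a chromosome after shifting the forward
    strand +s and the reverse strand -s, merged and sorted."""
    fpos, fcnt = track.strand(chrom, "+")
    rpos, rcnt = track.strand(chrom, "-")
    pos = np.concatenate([fpos + shift, rpos - shift])
    cnt = np.concatenate([fcnt, rcnt])
    order = np.argsort(pos, kind="stable")
    return pos[order], cnt[order]


def count_hits(
    regions: list[EnrichedRegion],
    tracks: list[HitTrack],
    shifts: dict[str, int],
) -> CountMatrix:
    """Count each sample's shifted 5' starts within each region.

    Controls and histone marks are counted even though they never shaped the
    regions.  Intervals are half-open: a shifted hit at ``end`` is excluded.
    """
    for track in tracks:
        if track.sample.sample_id not in shifts:
            raise ValueError(f"no shift assigned to {track.sample.sample_id}")
    matrix = np.zeros((len(regions), len(tracks)), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, EnrichedRegion]]] = {}
    for i, region in enumerate(regions):
        by_chrom.setdefault(region.chromosome, []).append((i, region))
    for j, track in enumerate(tracks):
        s = int(round(shifts[track.sample.sample_id]))
        for chrom, items in by_chrom.items():
            pos, cnt = shifted_strand_hits(track, chrom, s)
            if pos.size == 0:
                continue
            csum = np.concatenate([[0], np.cumsum(cnt)])
            for i, region in items:
                lo = np.searchsorted(pos, region.start, side="left")
                hi = np.searchsorted(pos, region.end, side="left")
                matrix[i, j] = csum[hi] - csum[lo]
    return CountMatrix(regions=regions, samples=[t.sample for t in tracks], matrix=matrix)


@dataclass
class UniPeakParams:
    """All tunable pipeline parameters with their standard defaults."""

    bandwidth: int = 100              # final-pass smoothing bandwidth (nt)
    prelim_bandwidth: int = 50        # shift-estimation smoothing bandwidth (nt)
    fold_threshold: float = 25.0      # fold enrichment over uniform background
    prelim_fold_threshold: float = 25.0
    kurtosis_max: float = 50.0        # leptokurtosis cutoff
    min_strand_correlation: float = 0.3
    min_shift: int = 25               # per-strand shift grid (nt)
    max_shift: int = 150
    shift_curve_bandwidth: int = 5    # smoothing of the argmax-shift density
    top_regions: int = 1000           # regions voting for the sample shift
    max_region_length: int = 500      # final size filter (bp)
    kurtosis_raw: bool = False        # report raw (Pearson) kurtosis instead

    def kurtosis_cutoff(self) -> float:
        return self.kurtosis_max

    def region_kurtosis(self, positions, counts) -> float:
        k = region_kurtosis(positions, counts)
        return k + 3.0 if self.kurtosis_raw else k


@dataclass
class UniPeakResult:
    regions: list[EnrichedRegion]
    counts: CountMatrix
    shifts: dict[str, float]
    qc: dict

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.write_bed(os.path.join(outdir, "regions.bed"))
        self.counts.write_tsv(os.path.join(outdir, "counts.tsv"))
        with open(os.path.join(outdir, "qc.json"), "w") as fh:
            json.dump(self.qc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_bed(self, path) -> None:
        peak_max = max((r.peak_height for r in self.regions), default=0.0)
        with open(path, "w") as fh:
            for i, r in enumerate(self.regions):
                score = 0 if peak_max == 0 else int(round(1000 * r.peak_height / peak_max))
                fh.write(
                    f"{r.chromosome}\t{r.start}\t{r.end}\tregion_{i + 1}\t{score}\t.\n"
                )


def run_unipeak(
    tracks: list[HitTrack],
    layout: GenomeLayout,
    params: UniPeakParams | None = None,
) -> UniPeakResult:
    """Full pipeline: per-sample shift estimation, unified smoothing, pooled
    region calling, QC filtering, and per-sample counting.

    Controls (and any sample flagged ``is_control``) are excluded from shift
    estimation, pooling and the background rate; their shift is the median
    of the ChIP samples' shifts and their hits are counted in the final
    matrix.
    """
    from .shift import assign_control_shift, estimate_sample_shift

    params = params or UniPeakParams()
    chip = [t for t in tracks if not t.sample.is_control]
    controls = [t for t in tracks if t.sample.is_control]
    if not chip:
        raise ValueError("need at least one non-control sample")
    total_reads = sum(t.total_hits for t in chip)

    shifts: dict[str, float] = {}
    shift_qc: dict[str, dict] = {}
    for track in chip:
        est = estimate_sample_shift(track, layout, params)
        shifts[track.sample.sample_id] = est.shift
        shift_qc[track.sample.sample_id] = {
            "shift": est.shift,
            "n_regions_used": est.n_regions_used,
        }
    control_shift = None
    if controls:
        control_shift = assign_control_shift(
            [t.sample for t in controls], list(shifts.values())
        )
        for track in controls:
            shifts[track.sample.sample_id] = control_shift

    chroms = sorted(
        {c for t in chip for c in t.chromosomes() if not layout.is_excluded(c)}
    )
    regions: list[EnrichedRegion] = []
    tallies = {"raw": 0, "kurtosis_fail": 0, "strand_corr_fail": 0, "structural_fail": 0}
    for chrom in chroms:
        length = layout.chrom_sizes.get(chrom)
        fwd_parts, rev_parts, unified = [], [], []
        for track in chip:
            s = int(round(shifts[track.sample.sample_id]))
            f = smooth_profile(track, chrom, "+", params.bandwidth, length)
            r = smooth_profile(track, chrom, "-", params.bandwidth, length)
            fwd_parts.append(f.translate(s))
            rev_parts.append(r.translate(-s))
            unified.append(combine_profiles(f, r, s))
        pooled = pooled_profile(unified)
        pooled_fwd = pooled_profile(fwd_parts)
        pooled_rev = pooled_profile(rev_parts)
        raw = call_regions(pooled, total_reads, layout, params.fold_threshold)
        tallies["raw"] += len(raw)
        pooled_hits = [
            shifted_strand_hits(t, chrom, int(round(shifts[t.sample.sample_id])))
            for t in chip
        ]
        all_pos = np.concatenate([p for p, _ in pooled_hits])
        all_cnt = np.concatenate([c for _, c in pooled_hits])
        order = np.argsort(all_pos, kind="stable")
        all_pos, all_cnt = all_pos[order], all_cnt[order]
        for region in raw:
            rp, rc = hits_in_region(all_pos, all_cnt, region.start, region.end)
            if rp.size == 0:
                tallies["kurtosis_fail"] += 1
                continue
            k = params.region_kurtosis(rp, rc)
            region.kurtosis = k
            if k > params.kurtosis_cutoff():
                region.pass_flags["kurtosis"] = False
                tallies["kurtosis_fail"] += 1
                continue
            region.pass_flags["kurtosis"] = True
            ok, corr = strand_correlation(
                region, pooled_fwd, pooled_rev, params.min_strand_correlation
            )
            region.strand_correlation = corr
            region.pass_flags["strand_correlation"] = ok
            if not ok:
                tallies["strand_corr_fail"] += 1
                continue
            regions.append(region)

    n_before = len(regions)
    regions = apply_structural_filters(regions, layout, params.max_region_length)
    tallies["structural_fail"] = n_before - len(regions)
    for region in regions:
        region.pass_flags["structural"] = True

    counts = count_hits(regions, tracks, {k: int(round(v)) for k, v in shifts.items()})
    qc = {
        "total_chip_reads": total_reads,
        "background_rate": total_reads / layout.effective_genome_size,
        "fold_threshold": params.fold_threshold,
        "shifts": shift_qc,
        "control_shift": control_shift,
        "n_regions": len(regions),
        "filter_tallies": tallies,
    }
    return UniPeakResult(regions=regions, counts=counts, shifts=shifts, qc=qc)
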