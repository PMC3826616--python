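"""Region annotation: nearest-feature promoter matching, consensus-promoter
labels, sequence composition, evolutionary constraint, and gene-body counts.

A region is matched to a feature (initiating Pol II peak, CAGE peak, RefSeq
TSS) when the feature lies within 500 bp of the region's density maximum;
the nearest such feature is taken.  A region whose peak matches all three
feature kinds is a *consensus promoter*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import HitTrack, ScoreTrack
from .motifs import collapse_motif_sets, load_mast_hits, scan_motifs  # noqa: F401

logger = logging.getLogger(__name__)

CONSENSUS_KINDS = ("polII_peak", "cage_peak", "tss")


@dataclass
class FeatureSet:
    """Point features of one kind on one genome, sorted per chromosome.

    ``positions[chrom]`` is a sorted int64 array; ``strands[chrom]`` (optional,
    same length) holds '+'/'-' for directional features such as CAGE peaks
    and TSSs.
    """

    kind: str
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            self.positions[chrom] = pos[order]
            if self.strands is not None and chrom in self.strands:
                self.strands[chrom] = np.asarray(self.strands[chrom])[order]

    @classmethod
    def from_intervals(cls, kind: str, intervals, point: str = "start") -> "FeatureSet":
        """Build from intervals, using the start (default), midpoint, or the
        strand-aware 5' end as the point coordinate."""
        positions: dict[str, list[int]] = {}
        strands: dict[str, list[str]] = {}
        has_strand = False
        for iv in intervals:
            if point == "midpoint":
                p = (iv.start + iv.end) // 2
            elif point == "five_prime":
                p = iv.start if iv.strand != "-" else iv.end - 1
            else:
                p = iv.start
            positions.setdefault(iv.chrom, []).append(p)
            strands.setdefault(iv.chrom, []).append(iv.strand or ".")
            has_strand = has_strand or iv.strand is not None
        pos_arr = {c: np.asarray(v, dtype=np.int64) for c, v in positions.items()}
        str_arr = (
            {c: np.asarray(v) for c, v in strands.items()} if has_strand else None
        )
        return cls(kind=kind, positions=pos_arr, strands=str_arr)


@dataclass
class FeatureMatch:
    feature_pos: int
    distance: int          # |feature - peak|
    signed_distance: int   # feature - peak, oriented by feature strand
    strand: str | None = None


def match_nearest(
    peaks: list[tuple[str, int]],
    features: FeatureSet,
    max_dist: int = 500,
) -> list[FeatureMatch | None]:
    """Nearest feature within ``max_dist`` of each peak, else None.

    Exact distance ties resolve to the smaller coordinate.  The signed
    distance is feature - peak on the feature's strand (negated for minus-
    strand features), so negative values mean the feature lies upstream of
    the peak; strand is ignored for the distance itself.
    """
    out: list[FeatureMatch | None] = []
    for chrom, peak in peaks:
        pos = features.positions.get(chrom)
        if pos is None or pos.size == 0:
            out.append(None)
            continue
        i = int(np.searchsorted(pos, peak))
        candidates = []
        if i > 0:
            candidates.append(int(pos[i - 1]))
        if i < pos.size:
            candidates.append(int(pos[i]))
        # ties -> smaller coordinate: candidates are ordered by coordinate
        best = min(candidates, key=lambda c: (abs(c - peak), c))
        if abs(best - peak) > max_dist:
            out.append(None)
            continue
        strand = None
        if features.strands is not None and chrom in features.strands:
            j = int(np.searchsorted(pos, best))
            strand = str(features.strands[chrom][j])
            if strand not in ("+", "-"):
                strand = None
        raw = best - peak
        signed = raw if strand != "-" else -raw
        out.append(
            FeatureMatch(
                feature_pos=best,
                distance=abs(raw),
                signed_distance=signed,
                strand=strand,
            )
        )
    return out


def consensus_labels(
    matches_by_kind: dict[str, list[FeatureMatch | None]],
) -> np.ndarray:
    """True where a region matched all three promoter-evidence kinds."""
    missing = [k for k in CONSENSUS_KINDS if k not in matches_by_kind]
    if missing:
        raise ValueError(f"missing feature kinds: {missing}")
    lists = [matches_by_kind[k] for k in CONSENSUS_KINDS]
    n = len(lists[0])
    if any(len(l) != n for l in lists):
        raise ValueError("feature-kind match lists differ in length")
    return np.array([all(l[i] is not None for l in lists) for i in range(n)])


def sequence_composition(seq: str) -> tuple[float, float]:
    """GC fraction and CpG dinucleotide rate of a region's sequence.

    GC fraction is (G+C) over called A/C/G/T bases; the CpG rate counts
    'CG' dinucleotides over adjacent fully-called pairs.  Soft-masked
    (lowercase) bases count; an all-N sequence yields (nan, nan).
    """
    s = seq.upper()
    valid = np.frombuffer(s.encode(), dtype=np.uint8)
    is_acgt = np.isin(valid, np.frombuffer(b"ACGT", dtype=np.uint8))
    n_valid = int(is_acgt.sum())
    if n_valid == 0:
        return float("nan"), float("nan")
    gc = sum(s.count(b) for b in "GC") / n_valid
    pair_valid = is_acgt[:-1] & is_acgt[1:]
    n_pairs = int(pair_valid.sum())
    if n_pairs == 0:
        return gc, float("nan")
    cg = sum(
        1
        for i in range(len(s) - 1)
        if pair_valid[i] and s[i] == "C" and s[i + 1] == "G"
    )
    return gc, cg / n_pairs


def constraint_fraction(
    chrom: str, start: int, end: int, track: ScoreTrack, rs_min: float = 2.0
) -> float:
    """Proportion of scored positions in [start, end) with constraint score
    strictly greater than ``rs_min``; positions without scores are excluded
    from the denominator; no scored positions -> nan."""
    scores = track.get(chrom, np.arange(start, end))
    scored = ~np.isnan(scores)
    if not scored.any():
        return float("nan")
    return float((scores[scored] > rs_min).sum() / scored.sum())


def gene_body_count(
    track: HitTrack,
    chrom: str,
    tss: int,
    tes: int,
    strand: str,
    pad: int = 100,
) -> int:
    """Unshifted 5' starts within the padded gene body.

    The window runs from ``pad`` bp upstream of the TSS to ``pad`` bp
    downstream of the TES of the longest isoform, inclusive at both ends;
    upstream/downstream flip for minus-strand genes.
    """
    if strand == "+":
        if tes < tss:
            raise ValueError("TES before TSS on the plus strand")
        lo, hi = tss - pad, tes + pad
    elif strand == "-":
        if tes > tss:
            raise ValueError("TES after TSS on the minus strand")
        lo, hi = tes - pad, tss + pad
    else:
        raise ValueError(f"bad strand {strand!r}")
    total = 0
    for s in ("+", "-"):
        pos, cnt = track.strand(chrom, s)
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, hi, side="right")
        total += int(cnt[a:b].sum())
    return total


def longest_isoform(isoforms: list[tuple[int, int]]) -> tuple[int, int]:
    """(TSS, TES) of the longest isoform from (tss, tes) pairs."""
    if not isoforms:
        raise ValueError("no isoforms")
    return max(isoforms, key=lambda t: abs(t[1] - t[0]))


def annotate_regions(
    peaks: list[tuple[str, int]],
    feature_sets: dict[str, FeatureSet],
    max_dist: int = 500,
):
    """Nearest-feature table for all kinds plus the consensus label, as a
    pandas DataFrame indexed like the peak list."""
    import pandas as pd

    matches = {
        kind: match_nearest(peaks, fs, max_dist) for kind, fs in feature_sets.items()
    }
    data = {}
    for kind, ms in matches.items():
        data[f"{kind}_distance"] = [
            m.signed_distance if m is not None else np.nan for m in ms
        ]
        data[f"{kind}_matched"] = [m is not None for m in ms]
    df = pd.DataFrame(data, index=[f"{c}:{p}" for c, p in peaks])
    if all(k in feature_sets for k in CONSENSUS_KINDS):
        df["consensus_promoter"] = consensus_labels(
            {k: matches[k] for k in CONSENSUS_KINDS}
        )
    return df
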