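"""Input of alignments and genomic tracks.

Every read alignment is reduced to a single *hit*: the 5'-most reference
coordinate of the alignment on its own strand.  Hits are the unit signal of
the density model; per-sample, per-strand sparse hit tracks are the input to
all smoothing and region calling.

Coordinates are 0-based half-open everywhere internally.  BED input/output
is passed through unchanged; 1-based annotation tables must be converted by
the caller on load.
"""

from __future__ import annotations

import fnmatch
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class SampleMeta:
    """Identity and grouping metadata for one ChIP-seq sample (one replicate).

    ``class_id`` groups replicates for dispersion estimation; replicates of
    the same target from different laboratories belong to separate classes.
    ``is_control`` marks input/IgG-type samples, which never contribute to
    region calling but are counted within called regions.
    """

    sample_id: str
    target: str
    cell_type: str = ""
    lab: str = ""
    replicate: int = 1
    is_control: bool = False
    class_id: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.class_id is None:
            object.__setattr__(
                self, "class_id", f"{self.target}|{self.cell_type}|{self.lab}"
            )


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeLayout:
    """Chromosome sizes, exclusion patterns and blacklist intervals.

    ``excluded_patterns`` are fnmatch-style patterns of chromosome names
    removed from final region lists (sex chromosomes and the mitochondrial
    genome by default).  ``effective_genome_size`` defaults to the summed
    length of non-excluded chromosomes and is the denominator of the uniform
    background rate.
    """

    chrom_sizes: dict[str, int]
    excluded_patterns: tuple[str, ...] = ("chrX", "chrY", "chrM")
    blacklist: list[Interval] = field(default_factory=list)
    effective_genome_size: int | None = None

    def __post_init__(self) -> None:
        for iv in self.blacklist:
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"blacklist interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(f"blacklist interval {iv} beyond chromosome end")
        if self.effective_genome_size is None:
            self.effective_genome_size = sum(
                n for c, n in self.chrom_sizes.items() if not self.is_excluded(c)
            )
        included = sum(
            n for c, n in self.chrom_sizes.items() if not self.is_excluded(c)
        )
        if self.effective_genome_size > included:
            raise ValueError("effective_genome_size exceeds included chromosome span")

    def is_excluded(self, chrom: str) -> bool:
        return any(fnmatch.fnmatch(chrom, p) for p in self.excluded_patterns)

    @classmethod
    def from_chrom_sizes(cls, path, **kwargs) -> "GenomeLayout":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                sizes[parts[0]] = int(parts[1])
        return cls(chrom_sizes=sizes, **kwargs)


def _as_sparse(positions: np.ndarray, counts: np.ndarray | None = None):
    """Collapse a position array (with optional per-position counts) into a
    sorted unique-position + count pair."""
    positions = np.asarray(positions, dtype=np.int64)
    if counts is None:
        pos, cnt = np.unique(positions, return_counts=True)
        return pos, cnt.astype(np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    positions, counts = positions[order], counts[order]
    pos, idx = np.unique(positions, return_index=True)
    cnt = np.add.reduceat(counts, idx)
    return pos, cnt


@dataclass
class HitTrack:
    """Per-chromosome, per-strand sparse counts of 5' read starts.

    ``data[chrom][strand]`` is a pair ``(positions, counts)`` of equal-length
    int64 arrays, positions strictly increasing, counts >= 1.
    """

    sample: SampleMeta
    data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict
    )

    @property
    def total_hits(self) -> int:
        return int(
            sum(
                int(cnt.sum())
                for strands in self.data.values()
                for (_, cnt) in strands.values()
            )
        )

    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    def strand(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return self.data.get(chrom, {}).get(strand, empty)

    def add_hits(self, chrom: str, strand: str, positions, counts=None) -> None:
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r}")
        pos, cnt = _as_sparse(positions, counts)
        old_pos, old_cnt = self.strand(chrom, strand)
        if old_pos.size:
            pos, cnt = _as_sparse(
                np.concatenate([old_pos, pos]), np.concatenate([old_cnt, cnt])
            )
        self.data.setdefault(chrom, {})[strand] = (pos, cnt)

    def merged(self, other: "HitTrack", sample: SampleMeta | None = None) -> "HitTrack":
        out = HitTrack(sample=sample or self.sample)
        for track in (self, other):
            for chrom, strands in track.data.items():
                for strand, (pos, cnt) in strands.items():
                    out.add_hits(chrom, strand, pos, cnt)
        return out

    def to_bed(self, path) -> None:
        """Dump hits as single-base BED6 intervals (one line per position,
        score = hit count)."""
        with open(path, "w") as fh:
            for chrom in self.chromosomes():
                rows = []
                for strand in STRANDS:
                    pos, cnt = self.strand(chrom, strand)
                    rows.extend(
                        (int(p), strand, int(c)) for p, c in zip(pos, cnt)
                    )
                rows.sort()
                for p, strand, c in rows:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\thit\t{c}\t{strand}\n")

    @classmethod
    def from_bed(cls, path, meta: SampleMeta) -> "HitTrack":
        """Load hits from a BED6 file of single-base intervals whose score
        column carries the hit count (the inverse of :meth:`to_bed`)."""
        track = cls(sample=meta)
        acc: dict[tuple[str, str], tuple[list, list]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                chrom, start, end = f[0], int(f[1]), int(f[2])
                if end != start + 1:
                    raise ValueError("hit BED must contain single-base intervals")
                count = int(float(f[4])) if len(f) > 4 else 1
                strand = f[5] if len(f) > 5 else "+"
                p, c = acc.setdefault((chrom, strand), ([], []))
                p.append(start)
                c.append(count)
        for (chrom, strand), (p, c) in acc.items():
            track.add_hits(chrom, strand, p, c)
        return track


def min_posterior_to_mapq(min_posterior: float) -> int:
    """Smallest MAPQ implying alignment posterior >= ``min_posterior``.

    MAPQ encodes -10*log10(P_error), so posterior >= 0.9 corresponds to
    MAPQ >= 10.
    """
    if not 0.0 < min_posterior <= 1.0:
        raise ValueError("min_posterior must be in (0, 1]")
    if min_posterior == 1.0:
        return 255
    return math.ceil(-10.0 * math.log10(1.0 - min_posterior) - 1e-9)


def load_alignments(
    path,
    meta: SampleMeta,
    layout: GenomeLayout | None = None,
    min_posterior: float = 0.9,
    collapse_duplicates: bool = False,
    keep_secondary: bool = False,
) -> HitTrack:
    """Read a BAM/SAM file into a strand-specific 5'-hit track.

    One hit is recorded at the 5'-most reference position of each retained
    alignment: ``reference_start`` on the forward strand, the rightmost
    aligned base (``reference_end - 1``) on the reverse strand.  Alignments
    with posterior below ``min_posterior`` (via the MAPQ bridge) are dropped;
    unmapped, secondary and supplementary records are skipped.  Read
    truncation to a fixed length is an upstream (aligner-side) concern when
    consuming already-aligned files.

    Duplicate hits are kept by default; ``collapse_duplicates`` caps each
    (position, strand) at one hit.
    """
    import pysam

    min_mapq = min_posterior_to_mapq(min_posterior)
    track = HitTrack(sample=meta)
    n_kept = n_dropped = n_unknown = 0
    acc: dict[tuple[str, str], list[int]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if rec.is_secondary and not keep_secondary:
                continue
            if rec.mapping_quality < min_mapq:
                n_dropped += 1
                continue
            chrom = rec.reference_name
            if layout is not None and chrom not in layout.chrom_sizes:
                n_unknown += 1
                continue
            if rec.is_reverse:
                pos, strand = rec.reference_end - 1, "-"
            else:
                pos, strand = rec.reference_start, "+"
            acc.setdefault((chrom, strand), []).append(pos)
            n_kept += 1
    for (chrom, strand), positions in acc.items():
        pos, cnt = _as_sparse(np.asarray(positions))
        if collapse_duplicates:
            cnt = np.minimum(cnt, 1)
        track.data.setdefault(chrom, {})[strand] = (pos, cnt)
    if n_unknown:
        logger.warning(
            "%s: rejected %d alignments on chromosomes absent from the layout",
            meta.sample_id,
            n_unknown,
        )
    logger.info(
        "%s: kept %d hits, dropped %d below MAPQ %d",
        meta.sample_id,
        n_kept,
        n_dropped,
        min_mapq,
    )
    return track


def load_hits(path, meta: SampleMeta, **kwargs) -> HitTrack:
    """Dispatch on file extension: BED of hits or BAM/SAM of alignments."""
    p = str(path)
    if p.endswith(".bed"):
        return HitTrack.from_bed(p, meta)
    return load_alignments(p, meta, **kwargs)


def load_intervals(path, layout: GenomeLayout | None = None) -> list[Interval]:
    """Load a BED-like file as sorted 0-based half-open intervals.

    Records with end <= start are rejected with a warning; strand is
    retained when the sixth column is present.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                logger.warning("%s:%d: skipped record with end <= start", path, ln)
                continue
            if layout is not None and chrom not in layout.chrom_sizes:
                logger.warning("%s:%d: unknown chromosome %s", path, ln, chrom)
                continue
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 and f[5] in STRANDS else None
            out.append(Interval(chrom, start, end, name, score, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


class ScoreTrack:
    """Per-base numeric scores held as non-overlapping scored intervals.

    Positions not covered by any record are *missing*, never zero.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), starts sorted, non-overlapping
        self._data = intervals

    @classmethod
    def from_records(cls, records: list[tuple[str, int, int, float]]) -> "ScoreTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            bad = starts[1:] < ends[:-1]
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"overlapping score records on {chrom} near position "
                    f"{int(starts[i + 1])}"
                )
            data[chrom] = (starts, ends, values)
        return cls(data)

    def get(self, chrom: str, positions) -> np.ndarray:
        """Scores at ``positions``; NaN where no record covers a position."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        ok[ok] &= positions[ok] < ends[idx[ok]]
        out[ok] = values[idx[ok]]
        return out


def load_score_track(path) -> ScoreTrack:
    """Load a bedGraph (or variableStep wig, span 1) per-base score track.

    Overlapping records are a fatal error; the track distinguishes missing
    positions from zero scores.
    """
    records: list[tuple[str, int, int, float]] = []
    wig_chrom = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            if s.startswith("variableStep"):
                wig_chrom = dict(
                    kv.split("=") for kv in s.split()[1:]
                ).get("chrom")
                continue
            if s.startswith("fixedStep"):
                raise ValueError("fixedStep wig is not supported; use bedGraph")
            f = s.split()
            if wig_chrom is not None and len(f) == 2:
                pos = int(f[0]) - 1  # wig is 1-based
                records.append((wig_chrom, pos, pos + 1, float(f[1])))
            else:
                records.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return ScoreTrack.from_records(records)


def reverse_track(track: HitTrack, chrom_sizes: dict[str, int]) -> HitTrack:
    """Mirror a track: flip strands and reflect coordinates through each
    chromosome (position p -> L-1-p).  Used by symmetry checks."""
    out = HitTrack(sample=replace(track.sample))
    for chrom, strands in track.data.items():
        length = chrom_sizes[chrom]
        for strand, (pos, cnt) in strands.items():
            flipped = "-" if strand == "+" else "+"
            new_pos = length - 1 - pos[::-1]
            out.data.setdefault(chrom, {})[flipped] = (new_pos, cnt[::-1].copy())
    return out
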