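"""PWM scanning of region windows with exact score p-values.

A built-in scanner for motif-set hit calling when pre-computed MAST tables
are unavailable.  Each position weight matrix is converted to an integerized
log2-odds score against a uniform 0.25 background; the null distribution of
the per-window score is computed exactly by dynamic programming over the
integerized columns, so the p-value of the best hit equals the fraction of
random background words scoring at least as high.  The motif's E-value is
that p-value times the number of window positions scanned in the run (both
strands of every region window).  This is a documented approximation of
MAST, which combines positional p-values per sequence differently;
ingesting a MAST tabular hit file is the fidelity route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PWM:
    """Position weight matrix: ``probs`` is (width, 4) over A, C, G, T with
    rows summing to 1.  ``set_id`` groups motifs annotated to the same TF."""

    name: str
    probs: np.ndarray
    set_id: str

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.probs.argmax(axis=1))


def parse_meme(path) -> list[PWM]:
    """Minimal MEME-format matrix reader (letter-probability blocks).

    The motif set is taken from the alternate name when present, else the
    motif name itself.
    """
    pwms: list[PWM] = []
    name = alt = None
    rows: list[list[float]] | None = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(name, np.array(rows), alt or name))
                parts = s.split()
                name = parts[1]
                alt = parts[2] if len(parts) > 2 else None
                rows = None
            elif s.startswith("letter-probability"):
                rows = []
            elif rows is not None and s and s[0] in "0123456789.":
                rows.append([float(x) for x in s.split()[:4]])
    if name is not None and rows:
        pwms.append(PWM(name, np.array(rows), alt or name))
    return pwms


class MotifScorer:
    """Integerized log-odds scorer with an exact DP null distribution.

    Scores are log2(p_base / 0.25) per column, multiplied by ``scale`` and
    rounded to integers; zero-probability cells get a large negative
    sentinel.  The null score distribution under the uniform background is
    the ``width``-fold convolution of the per-column score distributions,
    computed exactly on the integer grid.
    """

    NEG = -10_000  # integer score for a zero-probability base

    def __init__(self, pwm: PWM, scale: int = 1000, pseudo: float = 0.0):
        self.pwm = pwm
        self.scale = int(scale)
        probs = pwm.probs + pseudo
        probs = probs / probs.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            logodds = np.log2(probs / 0.25)
        iscores = np.where(
            np.isfinite(logodds), np.rint(logodds * self.scale), self.NEG
        ).astype(np.int64)
        self.int_scores = iscores  # (width, 4)
        self._pvalue_grid = self._null_distribution()

    def _null_distribution(self) -> tuple[int, np.ndarray]:
        lo = int(self.int_scores.min(axis=1).sum())
        # distribution over offset score = score - lo
        dist = np.zeros(1)
        dist[0] = 1.0
        offset = 0
        for col in self.int_scores:
            col_lo = int(col.min())
            col_dist = np.zeros(int(col.max()) - col_lo + 1)
            for s in col:
                col_dist[int(s) - col_lo] += 0.25
            dist = np.convolve(dist, col_dist)
            offset += col_lo
        assert offset == lo
        # survival function: P(score >= s)
        sf = np.cumsum(dist[::-1])[::-1]
        return lo, sf

    def score_int(self, window: str) -> np.ndarray:
        """Integerized score at every start position of ``window`` (one
        strand); positions containing non-ACGT bases score the sentinel."""
        w = self.pwm.width
        seq = window.upper()
        idx = np.array([_BASES.find(b) for b in seq], dtype=np.int64)
        n = len(seq) - w + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        out = np.zeros(n, dtype=np.int64)
        for j in range(w):
            col_idx = idx[j : j + n]
            col = np.where(
                col_idx >= 0, self.int_scores[j][np.clip(col_idx, 0, 3)], self.NEG
            )
            out += col
        return out

    def pvalue(self, score_int: int) -> float:
        """Exact P(null window score >= score_int) under the 0.25 background."""
        lo, sf = self._pvalue_grid
        k = score_int - lo
        if k < 0:
            return 1.0
        if k >= sf.size:
            return 0.0
        return float(sf[k])

    def best_hit(self, window: str) -> tuple[int, float]:
        """Best integer score over both strands of ``window`` and its exact
        p-value; also returns the number of scanned start positions."""
        fwd = self.score_int(window)
        rev = self.score_int(reverse_complement(window))
        scores = np.concatenate([fwd, rev])
        if scores.size == 0:
            return self.NEG * self.pwm.width, 1.0
        best = int(scores.max())
        return best, self.pvalue(best)


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def scan_motifs(
    peak_positions: list[tuple[str, int]],
    pwms: list[PWM],
    fetch_sequence,
    window: int = 201,
    e_max: float = 10.0,
    scale: int = 1000,
):
    """Scan a window centered on each region peak for every motif.

    ``fetch_sequence(chrom, start, end)`` must return the reference sequence
    for a 0-based half-open interval (windows past chromosome ends come back
    truncated, with a warning).  A motif's E-value within a region window is
    its best-hit p-value times the total number of window start positions
    scanned for that motif across the whole run.  Returns a pandas DataFrame
    of booleans (regions x motifs, E < e_max) -- collapse with
    :func:`collapse_motif_sets`.
    """
    import pandas as pd

    if window % 2 == 0:
        raise ValueError("window must be odd (centered on the peak)")
    half = window // 2
    scorers = [MotifScorer(p, scale=scale) for p in pwms]
    sequences = []
    for chrom, peak in peak_positions:
        start = max(0, peak - half)
        seq = fetch_sequence(chrom, start, peak + half + 1)
        if len(seq) < window:
            logger.warning(
                "window at %s:%d truncated to %d bp at a chromosome end",
                chrom,
                peak,
                len(seq),
            )
        sequences.append(seq)
    hits = np.zeros((len(sequences), len(pwms)), dtype=bool)
    evalues = np.full((len(sequences), len(pwms)), np.inf)
    for j, scorer in enumerate(scorers):
        w = scorer.pwm.width
        n_scanned = sum(2 * max(len(s) - w + 1, 0) for s in sequences)
        for i, seq in enumerate(sequences):
            _, p = scorer.best_hit(seq)
            e = p * n_scanned
            evalues[i, j] = e
            hits[i, j] = e < e_max
    region_ids = [f"{c}:{p}" for c, p in peak_positions]
    motif_ids = [p.name for p in pwms]
    table = pd.DataFrame(hits, index=region_ids, columns=motif_ids)
    table.attrs["evalues"] = pd.DataFrame(evalues, index=region_ids, columns=motif_ids)
    table.attrs["set_ids"] = {p.name: p.set_id for p in pwms}
    return table


def collapse_motif_sets(table, set_ids: dict[str, str] | None = None):
    """Region x motif-set table: a set hits a region if any member motif
    does (row-wise OR within each set)."""
    set_ids = set_ids or table.attrs.get("set_ids")
    if set_ids is None:
        raise ValueError("no motif-set mapping available")
    groups: dict[str, list[str]] = {}
    for motif in table.columns:
        groups.setdefault(set_ids[motif], []).append(motif)
    import pandas as pd

    out = pd.DataFrame(
        {sid: table[cols].any(axis=1) for sid, cols in sorted(groups.items())},
        index=table.index,
    )
    return out


def load_mast_hits(path, set_ids: dict[str, str], e_max: float = 10.0):
    """Ingest a pre-computed MAST tabular hit file (region, motif, E-value
    columns; comment lines ignored) and collapse to motif sets with the same
    any-member rule as the built-in scanner."""
    import pandas as pd

    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            rows.append((f[0], f[1], float(f[2])))
    df = pd.DataFrame(rows, columns=["region", "motif", "evalue"])
    hit = df[df.evalue < e_max]
    regions = sorted(df.region.unique())
    table = pd.DataFrame(
        False, index=regions, columns=sorted(df.motif.unique())
    )
    for _, r in hit.iterrows():
        table.loc[r.region, r.motif] = True
    return collapse_motif_sets(table, set_ids)
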