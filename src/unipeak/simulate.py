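"""Synthetic data with known truth for every stage of the pipeline.

Three generators, all pure functions of their parameters and a seed:

- :func:`simulate_chipseq` plants point binding sites on a synthetic
  chromosome and emits strand-asymmetric 5'-start pileups: forward-strand
  starts centered half a fragment length upstream of the site, reverse-strand
  starts half a fragment downstream, with rounded-normal jitter (sd = F/10, a
  fixture convention) and uniform background; negative controls are
  background-only.
- :func:`simulate_nb_counts` draws a regions x samples matrix of
  negative-binomial counts with planted region means, per-sample size
  factors and a common dispersion.
- :func:`simulate_regulation` builds TF occupancy from a low-rank latent
  factor model plus noise, regulation readouts as a linear map of the same
  latent factors, and input-control columns as independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomeLayout, HitTrack, SampleMeta

DEFAULT_CHROM = "chr1"


def default_layout(chrom_length: int = 1_000_000) -> GenomeLayout:
    return GenomeLayout(chrom_sizes={DEFAULT_CHROM: chrom_length})


@dataclass
class SimTruth:
    """Ground truth for a simulated ChIP-seq data set."""

    chromosome: str
    sites: np.ndarray                  # site positions, bp
    intensities: np.ndarray            # (n_sites, n_samples) relative strengths
    fragment_length: int
    background_rate: float             # reads per bp per sample
    seed: int
    sample_ids: list[str] = field(default_factory=list)

    @property
    def expected_shift(self) -> float:
        return self.fragment_length / 2.0


def simulate_chipseq(
    layout: GenomeLayout | None = None,
    n_sites: int = 30,
    fragment_length: int = 150,
    reads_per_site: int = 200,
    background_rate: float = 0.005,
    n_samples: int = 3,
    n_controls: int = 1,
    intensity_sd: float = 0.0,
    min_site_spacing: int = 2000,
    seed: int = 0,
) -> tuple[list[HitTrack], SimTruth]:
    """Simulate multi-sample ChIP-seq hit tracks around planted sites.

    Per site and sample, Poisson(reads_per_site * intensity) reads are drawn;
    each read picks a strand uniformly; forward 5' starts fall at
    site - F/2 + jitter, reverse at site + F/2 + jitter with jitter ~
    round(Normal(0, F/10)).  Uniform background reads (Poisson of
    background_rate per base) are added; control samples receive background
    only.  Intensities are 1 unless ``intensity_sd`` > 0, in which case they
    are lognormal with that log-sd.
    """
    if fragment_length < 2:
        raise ValueError("fragment_length must be >= 2")
    layout = layout or default_layout()
    chrom, length = next(iter(layout.chrom_sizes.items()))
    rng = np.random.default_rng(seed)
    margin = fragment_length + min_site_spacing // 2
    lo, hi = margin, length - margin
    if hi <= lo:
        raise ValueError("chromosome too short for the requested sites")
    # evenly spaced site slots with random offsets keep sites well separated
    slots = np.linspace(lo, hi, n_sites, dtype=np.int64)
    jitter_slots = rng.integers(-min_site_spacing // 4, min_site_spacing // 4 + 1, n_sites)
    sites = np.sort(slots + jitter_slots)
    if sites.min() < fragment_length or sites.max() >= length - fragment_length:
        raise ValueError("site within a fragment length of the chromosome end")
    if intensity_sd > 0:
        intensities = rng.lognormal(0.0, intensity_sd, size=(n_sites, n_samples))
    else:
        intensities = np.ones((n_sites, n_samples))

    half = fragment_length / 2.0
    jitter_sd = fragment_length / 10.0
    tracks: list[HitTrack] = []
    sample_ids: list[str] = []
    for s in range(n_samples + n_controls):
        is_control = s >= n_samples
        sid = f"{'control' if is_control else 'chip'}_{s - n_samples + 1 if is_control else s + 1}"
        meta = SampleMeta(
            sample_id=sid,
            target="input" if is_control else "TF1",
            cell_type="sim",
            lab="simlab",
            replicate=(s - n_samples + 1) if is_control else (s + 1),
            is_control=is_control,
        )
        fwd: list[np.ndarray] = []
        rev: list[np.ndarray] = []
        if not is_control:
            for i, site in enumerate(sites):
                n_reads = rng.poisson(reads_per_site * intensities[i, s])
                if n_reads == 0:
                    continue
                strands = rng.random(n_reads) < 0.5
                jit = np.rint(rng.normal(0.0, jitter_sd, n_reads)).astype(np.int64)
                pos = np.where(
                    strands,
                    np.rint(site - half).astype(np.int64) + jit,
                    np.rint(site + half).astype(np.int64) + jit,
                )
                fwd.append(pos[strands])
                rev.append(pos[~strands])
        n_bg = rng.poisson(background_rate * length)
        if n_bg:
            bg_pos = rng.integers(0, length, n_bg)
            bg_strand = rng.random(n_bg) < 0.5
            fwd.append(bg_pos[bg_strand])
            rev.append(bg_pos[~bg_strand])
        track = HitTrack(sample=meta)
        for strand, parts in (("+", fwd), ("-", rev)):
            if parts:
                pos = np.clip(np.concatenate(parts), 0, length - 1)
                track.add_hits(chrom, strand, pos)
        tracks.append(track)
        sample_ids.append(sid)
    truth = SimTruth(
        chromosome=chrom,
        sites=sites,
        intensities=intensities,
        fragment_length=fragment_length,
        background_rate=background_rate,
        seed=seed,
        sample_ids=sample_ids,
    )
    return tracks, truth


def simulate_nb_counts(
    n_regions: int = 500,
    n_samples: int = 6,
    mean_range: tuple[float, float] = (10.0, 10_000.0),
    dispersion: float = 0.1,
    size_factor_spread: float = 0.5,
    n_classes: int = 1,
    seed: int = 0,
):
    """Negative-binomial regions x samples count matrix with planted truth.

    Region means are log-uniform over ``mean_range``; per-sample size
    factors are lognormal with log-sd ``size_factor_spread`` (normalized to
    geometric mean 1); counts are NB with common dispersion alpha
    (Var = mu + alpha mu^2), reducing to Poisson at alpha = 0.  Samples are
    split round-robin into ``n_classes`` replicate classes.

    Returns (counts, sample_metas, truth) with truth = dict of mu, alpha,
    size_factors.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_regions))
    if size_factor_spread > 0:
        f = rng.lognormal(0.0, size_factor_spread, n_samples)
        f = f / np.exp(np.log(f).mean())
    else:
        f = np.ones(n_samples)
    mean = mu[:, None] * f[None, :]
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    metas = [
        SampleMeta(
            sample_id=f"s{j + 1}",
            target="TF1",
            cell_type="sim",
            lab=f"lab{j % n_classes + 1}",
            replicate=j // n_classes + 1,
        )
        for j in range(n_samples)
    ]
    truth = {"mu": mu, "alpha": dispersion, "size_factors": f}
    return counts.astype(np.int64), metas, truth


def simulate_regulation(
    n_regions: int = 200,
    n_tfs: int = 20,
    n_controls: int = 3,
    n_responses: int = 6,
    rank: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Latent-factor link between TF occupancy and regulation readouts.

    ``rank`` latent factors with distinct strong variances (sd 2^-j) drive
    both the TF occupancy block X_TF (through a random loading matrix, plus
    Gaussian noise) and the responses Y = L B + noise; the input-control
    block is independent noise.  Returns (X, Y, truth) where X stacks
    [X_TF | X_input] and truth records the loadings and rank.
    """
    if rank > n_tfs:
        raise ValueError("rank cannot exceed n_tfs")
    rng = np.random.default_rng(seed)
    factor_sd = 2.0 ** -np.arange(rank)
    L = rng.normal(0.0, 1.0, (n_regions, rank)) * factor_sd[None, :]
    A = rng.normal(0.0, 1.0, (rank, n_tfs))
    B = rng.normal(0.0, 1.0, (rank, n_responses))
    X_tf = L @ A + rng.normal(0.0, noise_sd, (n_regions, n_tfs))
    X_input = rng.normal(0.0, 1.0, (n_regions, n_controls))
    Y = L @ B + rng.normal(0.0, noise_sd, (n_regions, n_responses))
    X = np.column_stack([X_tf, X_input])
    x_names = [f"TF{j + 1}" for j in range(n_tfs)] + [
        f"input{j + 1}" for j in range(n_controls)
    ]
    y_names = [f"response{j + 1}" for j in range(n_responses)]
    truth = {
        "latent": L,
        "tf_loadings": A,
        "response_loadings": B,
        "rank": rank,
        "x_names": x_names,
        "y_names": y_names,
        "n_tfs": n_tfs,
    }
    return X, Y, truth
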