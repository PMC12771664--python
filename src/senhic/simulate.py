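"""Synthetic Hi-C generator with planted architecture.

Generates binned intra-chromosomal contact maps whose every structural
layer — distance decay, A/B checkerboard, TAD blocks, focal loops,
per-bin biases — is planted with known parameters, so that each analysis
stage downstream can be validated by parameter recovery.

Intensity model for a pixel (i, j) at bin distance ``s = |i-j|``::

    lambda_ij = B_i * B_j
              * (max(s, 1) * bin_size)^(-alpha)
              * exp(c_eff(s) * p_i * p_j)
              * (1 + e_T * [i, j in the same TAD])
              * (1 + f_L * K(i, j))

where ``p_i`` in [-1, 1] is the planted compartment profile, ``c_eff(s)
= c * (1 + s*bin/10 Mb)^(-gamma)`` lets compartmentalization weaken with
genomic distance (as observed in real maps), ``e_T`` is the intra-domain
enrichment of the TAD containing the pixel, and ``K`` is a truncated
Gaussian kernel centered on each planted loop anchor pair.  The total
intensity is scaled to the configured sequencing depth and counts are
drawn pixel-wise Poisson; replicates share the intensity and differ only
by the random stream.

A condition pair (baseline vs perturbed) is produced by applying a
:class:`Perturbation` — decay-exponent shift, compartment-amplitude
scaling, TAD-enrichment scaling, loop deletion/addition and regional
fold changes — to the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ContactMatrix


@dataclass(frozen=True)
class Loop:
    """Planted focal enrichment between two anchors (bin indices, a1 < a2)."""

    a1: int
    a2: int
    strength: float = 2.0  # f_L
    sigma: float = 2.0     # Gaussian kernel width in bins
    support: int = 5       # kernel truncated at +/- support bins


@dataclass(frozen=True)
class Tad:
    """Planted domain: half-open bin interval with intra-domain enrichment e_T."""

    start: int
    end: int
    enrichment: float = 1.0


@dataclass(frozen=True)
class DciRegion:
    """Regional interaction fold change: pixels with both ends inside
    [start, end) are multiplied by ``fold`` in the perturbed condition."""

    start: int
    end: int
    fold: float


@dataclass(frozen=True)
class Perturbation:
    """Condition-B overrides relative to the baseline configuration."""

    delta_alpha: float = 0.0
    amplitude_scale: float = 1.0
    tad_scale: float = 1.0
    tad_scale_overrides: tuple[tuple[int, float], ...] = ()  # (tad index, scale)
    drop_loops: tuple[int, ...] = ()     # indices into SimConfig.loops
    add_loops: tuple[Loop, ...] = ()
    dci_regions: tuple[DciRegion, ...] = ()


@dataclass
class SimConfig:
    """Full specification of a synthetic chromosome and its conditions.

    Defaults are chosen to resemble a down-sampled mammalian Hi-C map:
    power-law decay exponent ``alpha`` of 1.0, megabase-scale compartment
    blocks, and domains of a few hundred kb to a few Mb.
    """

    chrom_length: int = 60_000_000
    bin_size: int = 100_000
    chrom: str = "chrS"
    alpha: float = 1.0
    compartment_profile: np.ndarray | None = None  # p_i in [-1, 1]; None = no compartments
    compartment_amplitude: float = 0.0             # c
    amplitude_distance_decay: float = 0.3          # gamma; 0 = distance-independent
    tads: tuple[Tad, ...] = ()
    loops: tuple[Loop, ...] = ()
    bias_sigma: float = 0.0        # lognormal sd of planted per-bin biases
    bias_vector: np.ndarray | None = None
    depth: float = 2_000_000.0
    n_replicates: int = 2
    seed: int = 0
    perturbation: Perturbation | None = None

    @property
    def n_bins(self) -> int:
        return self.chrom_length // self.bin_size

    def validate(self) -> None:
        n = self.n_bins
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.compartment_profile is not None:
            p = np.asarray(self.compartment_profile)
            if p.shape != (n,):
                raise ValueError("compartment profile length must equal n_bins")
            if np.abs(p).max() > 1:
                raise ValueError("compartment profile must lie in [-1, 1]")
        prev_end = 0
        for t in sorted(self.tads, key=lambda t: t.start):
            if t.start < prev_end:
                raise ValueError("TADs overlap")
            if t.end > n or t.start < 0:
                raise ValueError("TAD outside genome")
            if t.enrichment < 0:
                raise ValueError("TAD enrichment must be >= 0")
            prev_end = t.end
        for lp in self.loops:
            if not (0 <= lp.a1 < lp.a2 < n):
                raise ValueError("loop anchor outside genome")
            if lp.a2 - lp.a1 < 2:
                raise ValueError("loop anchors must be >= 2 bins apart")
            if lp.strength < 0:
                raise ValueError("loop strength must be >= 0")
        if self.bias_vector is not None and np.min(self.bias_vector) <= 0:
            raise ValueError("biases must be positive")


@dataclass
class GroundTruth:
    """Planted features of one simulated condition."""

    boundaries: np.ndarray           # bin indices of TAD boundaries
    compartment_labels: np.ndarray   # +1 (A) / -1 (B) / 0 (none) per bin
    compartment_profile: np.ndarray  # planted p_i
    tads: tuple[Tad, ...]
    loops: tuple[Loop, ...]
    dci_regions: tuple[DciRegion, ...]
    alpha: float
    amplitude: float
    bias: np.ndarray


def _condition_params(config: SimConfig, condition: str):
    """Resolve (alpha, amplitude, tads, loops, dci_regions) for a condition."""
    if condition not in ("baseline", "perturbed"):
        raise ValueError("condition must be 'baseline' or 'perturbed'")
    pert = config.perturbation if condition == "perturbed" else None
    if pert is None:
        pert = Perturbation()
    alpha = config.alpha + pert.delta_alpha
    amp = config.compartment_amplitude * pert.amplitude_scale
    overrides = dict(pert.tad_scale_overrides)
    tads = tuple(
        replace(t, enrichment=t.enrichment * overrides.get(k, pert.tad_scale))
        for k, t in enumerate(config.tads)
    )
    loops = tuple(
        lp for k, lp in enumerate(config.loops) if k not in set(pert.drop_loops)
    ) + tuple(pert.add_loops)
    return alpha, amp, tads, loops, pert.dci_regions


def loop_kernel(n: int, loops: tuple[Loop, ...]) -> np.ndarray:
    """Summed truncated-Gaussian kernel K(i, j) over all planted loops
    (upper triangle; symmetrized by the caller)."""
    K = np.zeros((n, n))
    for lp in loops:
        r = lp.support
        i0, i1 = max(lp.a1 - r, 0), min(lp.a1 + r + 1, n)
        j0, j1 = max(lp.a2 - r, 0), min(lp.a2 + r + 1, n)
        di = np.arange(i0, i1) - lp.a1
        dj = np.arange(j0, j1) - lp.a2
        g = np.exp(-(di[:, None] ** 2 + dj[None, :] ** 2) / (2 * lp.sigma**2))
        K[i0:i1, j0:j1] += lp.strength * g
        K[j0:j1, i0:i1] += lp.strength * g.T
    return K


def intensity(config: SimConfig, condition: str = "baseline") -> np.ndarray:
    """Expected-count matrix lambda_ij scaled so the upper triangle
    (incl. diagonal) sums to the configured depth."""
    config.validate()
    n = config.n_bins
    alpha, amp, tads, loops, dci_regions = _condition_params(config, condition)

    idx = np.arange(n)
    s = np.abs(np.subtract.outer(idx, idx))
    sep_bp = np.maximum(s, 1) * config.bin_size  # diagonal capped at the 1-bin value
    lam = sep_bp.astype(float) ** (-alpha)

    if config.compartment_profile is not None and amp != 0:
        p = np.asarray(config.compartment_profile, dtype=float)
        gamma = config.amplitude_distance_decay
        c_eff = amp * (1.0 + (s * config.bin_size) / 1e7) ** (-gamma)
        lam *= np.exp(c_eff * np.outer(p, p))

    if tads:
        tad_id = np.full(n, -1)
        for k, t in enumerate(tads):
            tad_id[t.start : t.end] = k
        same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
        e = np.array([t.enrichment for t in tads])
        boost = np.ones((n, n))
        boost[same] = 1.0 + e[tad_id[np.where(same)[0]]]
        lam *= boost

    if loops:
        lam *= 1.0 + loop_kernel(n, loops)

    for reg in dci_regions:
        inside = np.zeros(n, dtype=bool)
        inside[reg.start : reg.end] = True
        lam[np.ix_(inside, inside)] *= reg.fold

    bias = _bias(config)
    lam *= np.outer(bias, bias)

    lam = (lam + lam.T) / 2.0
    scale = config.depth / np.triu(lam).sum()
    return lam * scale


def _bias(config: SimConfig) -> np.ndarray:
    if config.bias_vector is not None:
        return np.asarray(config.bias_vector, dtype=float)
    if config.bias_sigma > 0:
        rng = np.random.default_rng([config.seed, 977])
        b = rng.lognormal(0.0, config.bias_sigma, config.n_bins)
        return b / b.mean()
    return np.ones(config.n_bins)


def ground_truth(config: SimConfig, condition: str = "baseline") -> GroundTruth:
    alpha, amp, tads, loops, dci_regions = _condition_params(config, condition)
    bounds = sorted({t.start for t in tads} | {t.end for t in tads})
    p = (
        np.asarray(config.compartment_profile, dtype=float)
        if config.compartment_profile is not None
        else np.zeros(config.n_bins)
    )
    return GroundTruth(
        boundaries=np.array(bounds, dtype=int),
        compartment_labels=np.sign(p).astype(int),
        compartment_profile=p,
        tads=tads,
        loops=loops,
        dci_regions=dci_regions,
        alpha=alpha,
        amplitude=amp,
        bias=_bias(config),
    )


def simulate_matrix(
    config: SimConfig, condition: str = "baseline", replicate: int = 0
) -> tuple[ContactMatrix, GroundTruth]:
    """Draw one replicate contact map for one condition.

    Counts are Poisson with the shared intensity; the same
    (seed, condition, replicate) triple is bit-reproducible.
    """
    lam = intensity(config, condition)
    cond_code = 0 if condition == "baseline" else 1
    rng = np.random.default_rng([config.seed, cond_code, replicate])
    n = config.n_bins
    iu = np.triu_indices(n)
    draws = rng.poisson(lam[iu])
    M = np.zeros((n, n))
    M[iu] = draws
    M = M + np.triu(M, 1).T
    cm = ContactMatrix(M, resolution=config.bin_size, chrom=config.chrom)
    return cm, ground_truth(config, condition)


def simulate_replicates(
    config: SimConfig, condition: str = "baseline"
) -> list[ContactMatrix]:
    return [
        simulate_matrix(config, condition, rep)[0] for rep in range(config.n_replicates)
    ]


# ---------------------------------------------------------------------------
# Matched 1D tracks and annotations
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    """Synthetic 1D tracks and interval annotations matched to a SimConfig.

    accessibility : per-bin bedGraph-style signal, positively correlated
        with the active (p_i > 0) compartment.
    ctcf : per-bin signal peaked at TAD boundaries and loop anchors.
    peaks : BED intervals at every boundary and anchor bin.
    genes/promoters/enhancers : BED intervals; promoters at gene starts,
        enhancers restricted to planted-A bins.
    """

    accessibility: pd.DataFrame
    ctcf: pd.DataFrame
    peaks: pd.DataFrame
    genes: pd.DataFrame
    promoters: pd.DataFrame
    enhancers: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.accessibility.to_csv(
            outdir / "accessibility.bedgraph", sep="\t", header=False, index=False
        )
        self.ctcf.to_csv(outdir / "ctcf.bedgraph", sep="\t", header=False, index=False)
        for name in ("peaks", "genes", "promoters", "enhancers"):
            getattr(self, name).to_csv(
                outdir / f"{name}.bed", sep="\t", header=False, index=False
            )


def simulate_tracks(config: SimConfig, n_genes: int = 60) -> TrackSet:
    """Generate covariate tracks consistent with the planted architecture."""
    config.validate()
    n = config.n_bins
    res = config.bin_size
    rng = np.random.default_rng([config.seed, 555])
    p = (
        np.asarray(config.compartment_profile, dtype=float)
        if config.compartment_profile is not None
        else np.zeros(n)
    )
    truth = ground_truth(config, "baseline")

    acc = 0.5 + np.maximum(p, 0.0) + rng.normal(0.0, 0.1, n)
    acc = np.maximum(acc, 0.0)

    ctcf = rng.normal(0.2, 0.05, n).clip(min=0)
    anchor_bins = sorted(
        set(truth.boundaries.tolist())
        | {lp.a1 for lp in truth.loops}
        | {lp.a2 for lp in truth.loops}
    )
    for b in anchor_bins:
        lo, hi = max(b - 2, 0), min(b + 3, n)
        ctcf[lo:hi] += 1.5 * np.exp(-((np.arange(lo, hi) - b) ** 2) / 2.0)

    starts = np.arange(n) * res

    def track(values):
        return pd.DataFrame(
            {"chrom": config.chrom, "start": starts, "end": starts + res, "value": values}
        )

    peaks = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": [b * res for b in anchor_bins if b < n],
            "end": [(b + 1) * res for b in anchor_bins if b < n],
            "name": [f"peak_{k}" for k, b in enumerate(b for b in anchor_bins if b < n)],
        }
    )

    gene_bins = np.sort(rng.choice(n, size=min(n_genes, n), replace=False))
    gene_len = max(res // 2, 1)
    genes = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": gene_bins * res,
            "end": gene_bins * res + gene_len,
            "name": [f"gene_{k}" for k in range(len(gene_bins))],
        }
    )
    promoters = genes.copy()
    promoters["end"] = promoters["start"] + max(res // 10, 1)
    promoters["name"] = [f"prom_{k}" for k in range(len(genes))]

    a_bins = np.flatnonzero(p > 0)
    enh_bins = (
        np.sort(rng.choice(a_bins, size=min(n_genes, a_bins.size), replace=False))
        if a_bins.size
        else np.array([], dtype=int)
    )
    enhancers = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": enh_bins * res + res // 3,
            "end": enh_bins * res + res // 3 + max(res // 10, 1),
            "name": [f"enh_{k}" for k in range(len(enh_bins))],
        }
    )
    return TrackSet(
        accessibility=track(acc),
        ctcf=track(ctcf),
        peaks=peaks,
        genes=genes,
        promoters=promoters,
        enhancers=enhancers,
    )


def simulate_pair_labels(
    n_pairs: int, cis_probability: float, chroms: tuple[str, ...] = ("chr1", "chr2", "chr3"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair chromosome labels with a set cis probability, for
    cis-fraction accounting (the matrices themselves are cis-only)."""
    rng = np.random.default_rng([seed, 313])
    c1 = rng.choice(len(chroms), n_pairs)
    cis = rng.random(n_pairs) < cis_probability
    c2 = np.where(cis, c1, (c1 + 1 + rng.integers(0, len(chroms) - 1, n_pairs)) % len(chroms))
    arr = np.array(chroms)
    return pd.DataFrame({"chrom1": arr[c1], "chrom2": arr[c2]})


# ---------------------------------------------------------------------------
# Canonical study-condition factories
# ---------------------------------------------------------------------------

def checkerboard(n_bins: int, block_bins: int) -> np.ndarray:
    """Alternating +1/-1 compartment profile tiling the chromosome."""
    blocks = np.resize(np.repeat([1.0, -1.0], block_bins), n_bins)
    return blocks


def compartment_config(
    seed: int = 0,
    amplitude: float = 0.6,
    depth: float = 2_000_000.0,
    perturbation: Perturbation | None = None,
) -> SimConfig:
    """60 Mb @ 100 kb with 2 Mb checkerboard blocks: the compartment-level
    test genome (large enough that the >30 Mb distance stratum is populated)."""
    n = 60_000_000 // 100_000
    return SimConfig(
        chrom_length=60_000_000,
        bin_size=100_000,
        alpha=1.0,
        compartment_profile=checkerboard(n, 20),
        compartment_amplitude=amplitude,
        amplitude_distance_decay=0.3,
        bias_sigma=0.2,
        depth=depth,
        seed=seed,
        perturbation=perturbation,
    )


def domain_config(
    seed: int = 0,
    tad_enrichment: float = 1.0,
    loop_strength: float = 2.0,
    depth: float = 5_000_000.0,
    with_loops: bool = True,
    perturbation: Perturbation | None = None,
) -> SimConfig:
    """20 Mb @ 10 kb with 8 TADs and intra-TAD loops: the TAD/loop/DCI
    test genome.

    Boundaries are placed on a jittered 250-bin grid; loops join anchor
    pairs inside TADs at 300 kb - 1.5 Mb separations.
    """
    length, res = 20_000_000, 10_000
    n = length // res
    rng = np.random.default_rng([seed, 101])
    edges = [0]
    for k in range(1, 8):
        edges.append(k * 250 + int(rng.integers(-20, 21)))
    edges.append(n)
    tads = tuple(
        Tad(edges[k], edges[k + 1], enrichment=tad_enrichment) for k in range(8)
    )
    loops: list[Loop] = []
    if with_loops:
        for t in tads:
            span = t.end - t.start
            if span < 80:
                continue
            for _ in range(3):
                a1 = int(rng.integers(t.start + 5, t.end - 40))
                gap = int(rng.integers(30, min(150, t.end - 5 - a1)))
                loops.append(Loop(a1, a1 + gap, strength=loop_strength, sigma=1.5))
    # compartments at TAD granularity: alternate whole TADs between A and B
    prof = np.zeros(n)
    for k, t in enumerate(tads):
        prof[t.start : t.end] = 1.0 if k % 2 == 0 else -1.0
    return SimConfig(
        chrom_length=length,
        bin_size=res,
        alpha=1.0,
        compartment_profile=prof,
        compartment_amplitude=0.3,
        amplitude_distance_decay=0.0,
        tads=tads,
        loops=tuple(loops),
        bias_sigma=0.15,
        depth=depth,
        seed=seed,
        perturbation=perturbation,
    )


DCI_REGIONS = ((300, 316), (800, 816), (1300, 1316))


def dci_config(
    seed: int = 0,
    fold: float = 2.5,
    depth: float = 10_000_000.0,
    regions: tuple[tuple[int, int], ...] = DCI_REGIONS,
) -> SimConfig:
    """Domain genome with three planted 160 kb regional fold changes.

    Regions are kept small relative to the map so that depth matching
    dilutes the planted fold only marginally; replicate depth is doubled
    relative to the TAD genome because pixel-level differential testing
    is the most count-hungry analysis.
    """
    pert = Perturbation(
        dci_regions=tuple(DciRegion(a, b, fold) for a, b in regions)
    )
    return domain_config(seed=seed, depth=depth, perturbation=pert)


def loop_config(seed: int = 0, loop_strength: float = 2.0) -> SimConfig:
    """Domain genome at loop-calling depth (30M contacts): focal-dot
    detection at 10 kb needs the deepest maps of any analysis layer."""
    return domain_config(seed=seed, depth=30_000_000.0, loop_strength=loop_strength)


DIFFTAD_PERTURBED = (5, 15, 25, 35)


def difftad_config(
    seed: int = 0,
    scale: float = 0.5,
    perturbed_tads: tuple[int, ...] = DIFFTAD_PERTURBED,
    depth: float = 5_000_000.0,
) -> SimConfig:
    """20 Mb @ 10 kb tiled by forty 500 kb TADs, a minority of which have
    their intra-domain enrichment scaled in the perturbed condition —
    the differential-TAD test genome.  The perturbed fraction is kept
    small (10%) so the outlier-based detector sees a mostly-null cloud.
    """
    length, res = 20_000_000, 10_000
    tads = tuple(Tad(k * 50, (k + 1) * 50, enrichment=1.0) for k in range(40))
    pert = Perturbation(
        tad_scale_overrides=tuple((k, scale) for k in perturbed_tads)
    )
    return SimConfig(
        chrom_length=length, bin_size=res, alpha=1.0, tads=tads,
        bias_sigma=0.15, depth=depth, seed=seed, perturbation=pert,
    )
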