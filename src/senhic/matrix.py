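"""Contact-matrix container, I/O and primary matrix-level operations.

A :class:`ContactMatrix` holds one chromosome's binned intra-chromosomal
contact map as a dense symmetric array together with its normalization
state.  Dense storage is deliberate: the package targets desk-scale
regional / synthetic maps (hundreds to a few thousand bins per
chromosome), where dense linear algebra is both simpler and faster than
sparse bookkeeping.

Operations
----------
ice_balance
    Iterative correction (matrix balancing) with low-coverage masking.
observed_expected
    Per-distance expected profile E(s) and the observed/expected map.
contact_decay
    Contact probability P(s) versus genomic distance with a log-log
    slope fit.
downsample
    Exact multivariate-hypergeometric thinning to a target total.
effective_resolution
    Smallest bin size at which >= 80% of bins reach a coverage threshold.
cis_fraction
    Fraction of contact pairs with both ends on the same chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


class BalanceError(RuntimeError):
    """Raised when iterative correction cannot proceed (e.g. empty matrix)."""


@dataclass
class ContactMatrix:
    """Binned symmetric intra-chromosomal contact map.

    Parameters
    ----------
    counts : ndarray (n, n)
        Symmetric non-negative matrix. Raw integer counts or balanced
        floats depending on ``balanced``.
    resolution : int
        Bin size in bp.
    chrom : str
        Chromosome name.
    balanced : bool
        Whether ``counts`` has been ICE-normalized.
    bias : ndarray (n,) or None
        Per-bin multiplicative biases b_i such that
        raw_ij ~= bias_i * bias_j * counts_ij.  Defined only when
        ``balanced`` is True; NaN for masked bins.
    mask : ndarray (n,) bool or None
        True marks low-coverage bins excluded from normalization and
        downstream statistics.
    """

    counts: np.ndarray
    resolution: int
    chrom: str = "chrS"
    balanced: bool = False
    bias: np.ndarray | None = None
    mask: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
        if not self.balanced and np.nanmin(self.counts) < 0:
            raise ValueError("raw counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def length(self) -> int:
        """Chromosome length in bp covered by the binning."""
        return self.n_bins * self.resolution

    def total(self) -> float:
        """Total contact count: sum over the upper triangle incl. diagonal."""
        return float(np.triu(np.nan_to_num(self.counts)).sum())

    def bins(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins, dtype=int) * self.resolution
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.resolution,
                "bin": np.arange(self.n_bins, dtype=int),
            }
        )

    def coverage(self) -> np.ndarray:
        """Per-bin marginal (row sum, diagonal counted once)."""
        return np.nan_to_num(self.counts).sum(axis=1)

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            bias=None if self.bias is None else self.bias.copy(),
            mask=self.mask.copy(),
        )


# ---------------------------------------------------------------------------
# I/O: HiC-Pro style bins BED + upper-triangular triplet TSV
# ---------------------------------------------------------------------------

def write_hicpro(cm: ContactMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write *prefix*_abs.bed (bins) and *prefix*.matrix (triplets).

    Coordinates are 0-based half-open; triplets cover the upper triangle
    including the diagonal and store only nonzero pixels.
    """
    prefix = Path(prefix)
    bed = prefix.with_name(prefix.name + "_abs.bed")
    mat = prefix.with_name(prefix.name + ".matrix")
    cm.bins().to_csv(bed, sep="\t", header=False, index=False)
    iu = np.triu_indices(cm.n_bins)
    vals = np.nan_to_num(cm.counts)[iu]
    keep = vals != 0
    pd.DataFrame(
        {"bin_i": iu[0][keep], "bin_j": iu[1][keep], "count": vals[keep]}
    ).to_csv(mat, sep="\t", header=False, index=False)
    return bed, mat


def read_hicpro(bed_path: str | Path, matrix_path: str | Path) -> dict[str, ContactMatrix]:
    """Read a HiC-Pro-style bins BED + triplet TSV into per-chromosome maps.

    Trans (inter-chromosomal) triplets are ignored with a warning.
    """
    bins = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "bin"]
    )
    trip = pd.read_csv(
        matrix_path, sep="\t", header=None, names=["bin_i", "bin_j", "count"]
    )
    chrom_of = bins.set_index("bin")["chrom"]
    ci = trip["bin_i"].map(chrom_of)
    cj = trip["bin_j"].map(chrom_of)
    if (ci != cj).any():
        warnings.warn("trans triplets present; ignored (intra-chromosomal container)")
        trip = trip[ci == cj]
    out: dict[str, ContactMatrix] = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        res = int((sub["end"] - sub["start"]).iloc[0])
        offset = int(sub["bin"].min())
        n = len(sub)
        m = np.zeros((n, n))
        t = trip[trip["bin_i"].map(chrom_of) == chrom]
        i = (t["bin_i"] - offset).to_numpy(dtype=int)
        j = (t["bin_j"] - offset).to_numpy(dtype=int)
        m[i, j] = t["count"].to_numpy()
        m[j, i] = m[i, j]
        out[str(chrom)] = ContactMatrix(m, resolution=res, chrom=str(chrom))
    return out


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_balance(
    cm: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_fraction: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: equalize marginals via per-bin biases.

    Bins with zero coverage plus the lowest ``mask_fraction`` of
    nonzero-coverage bins are masked and excluded from the marginals;
    their bias is NaN and their rows/columns NaN in the output.

    Convergence: coefficient of variation of unmasked marginals < ``tol``.
    The returned bias vector is scaled so its unmasked mean is 1, and the
    balanced matrix is counts / (b_i * b_j).
    """
    if not 0 <= mask_fraction < 1:
        raise ValueError("mask_fraction must be in [0, 1)")
    C = np.nan_to_num(np.asarray(cm.counts, dtype=float))
    n = C.shape[0]
    cov = C.sum(axis=1)
    if cov.sum() == 0:
        raise BalanceError("all-zero matrix cannot be balanced")
    mask = cov == 0
    nz = cov[~mask]
    if mask_fraction > 0 and nz.size:
        cut = np.quantile(nz, mask_fraction)
        mask |= cov <= cut
    if mask.all():
        raise BalanceError("every bin masked; nothing to balance")

    W = C.copy()
    W[mask, :] = 0.0
    W[:, mask] = 0.0
    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=1)
        sm = s[~mask]
        mean = sm.mean()
        cv = sm.std() / mean if mean > 0 else np.inf
        if cv < tol:
            converged = True
            break
        adj = np.ones(n)
        adj[~mask] = s[~mask] / mean
        adj[adj == 0] = 1.0
        bias *= adj
        W /= np.outer(adj, adj)
    else:
        s = W.sum(axis=1)
        sm = s[~mask]
        cv = sm.std() / sm.mean()
        warnings.warn(f"ICE did not converge after {max_iter} iterations (CV={cv:.2e})")

    # normalize bias to unmasked mean 1 and rescale the matrix accordingly
    scale = bias[~mask].mean()
    bias /= scale
    W = C / np.outer(bias, bias)
    W[mask, :] = np.nan
    W[:, mask] = np.nan
    bias_out = bias.copy()
    bias_out[mask] = np.nan
    return ContactMatrix(
        W,
        resolution=cm.resolution,
        chrom=cm.chrom,
        balanced=True,
        bias=bias_out,
        mask=mask,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Expected profile and observed/expected
# ---------------------------------------------------------------------------

def expected_profile(cm: ContactMatrix) -> np.ndarray:
    """E(s): mean balanced value over unmasked pairs at each bin distance.

    Returns an array of length n_bins (index = distance in bins); NaN for
    distances with no unmasked pair.
    """
    n = cm.n_bins
    out = np.full(n, np.nan)
    M = cm.counts
    for s in range(n):
        d = np.diagonal(M, offset=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[s] = np.nanmean(d) if d.size else np.nan
    return out


def observed_expected(cm: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Expected profile and the O/E matrix of a balanced map.

    O/E_ij = N_ij / E(|i-j|); undefined (NaN) where E is missing or the
    bin is masked.
    """
    if not cm.balanced:
        raise ValueError("observed_expected requires a balanced matrix")
    exp = expected_profile(cm)
    n = cm.n_bins
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = cm.counts / exp[idx]
    return exp, oe


# ---------------------------------------------------------------------------
# Contact decay P(s)
# ---------------------------------------------------------------------------

@dataclass
class ContactDecay:
    """P(s) table plus the fitted log-log slope of per-pair contact frequency."""

    table: pd.DataFrame  # distance_lo, distance_hi, n_pairs, count_sum, prob, mean_per_pair
    slope: float
    fit_range: tuple[float, float]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def contact_decay(
    cm: ContactMatrix,
    log_bins: bool = True,
    bin_ratio: float = 1.12,
    fit_range: tuple[float, float] = (1e6, 1e7),
    n_linear_bins: int = 50,
) -> ContactDecay:
    """Contact probability versus genomic distance on raw counts.

    P(s) per distance bin is the summed count divided by the total count
    (so the probabilities sum to 1).  The slope is fit by least squares on
    log10(mean count per pair) vs log10(distance) restricted to
    ``fit_range``, which estimates the decay exponent without the
    pair-multiplicity artifact of binned totals.
    """
    n = cm.n_bins
    if n < 3:
        raise ValueError("need at least 3 bins for a decay curve")
    res = cm.resolution
    dists = np.arange(1, n)  # exclude the diagonal
    sums = np.array([np.nan_to_num(np.diagonal(cm.counts, k)).sum() for k in dists])
    npairs = np.array([n - k for k in dists], dtype=float)
    bp = dists * res

    if log_bins:
        edges = [float(res)]
        while edges[-1] <= bp[-1]:
            edges.append(max(edges[-1] * bin_ratio, edges[-1] + res))
        edges = np.array(edges)
    else:
        edges = np.linspace(res, bp[-1] + res, n_linear_bins + 1)
    which = np.digitize(bp, edges) - 1

    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "distance_lo": edges[b],
                "distance_hi": edges[b + 1],
                "n_pairs": npairs[sel].sum(),
                "count_sum": sums[sel].sum(),
            }
        )
    tab = pd.DataFrame(rows)
    total = tab["count_sum"].sum()
    if total == 0:
        raise ValueError("empty matrix: no contacts to profile")
    tab["prob"] = tab["count_sum"] / total
    tab["mean_per_pair"] = tab["count_sum"] / tab["n_pairs"]
    mid = np.sqrt(tab["distance_lo"] * tab["distance_hi"])
    sel = (mid >= fit_range[0]) & (mid <= fit_range[1]) & (tab["mean_per_pair"] > 0)
    if sel.sum() < 2:
        slope = np.nan
    else:
        slope = float(
            np.polyfit(np.log10(mid[sel]), np.log10(tab["mean_per_pair"][sel]), 1)[0]
        )
    return ContactDecay(table=tab, slope=slope, fit_range=fit_range)


# ---------------------------------------------------------------------------
# Down-sampling
# ---------------------------------------------------------------------------

def downsample(cm: ContactMatrix, target_total: int, seed: int | np.random.Generator = 0) -> ContactMatrix:
    """Thin raw counts to exactly ``target_total`` via multivariate
    hypergeometric sampling over pixels (sampling reads without replacement)."""
    if cm.balanced:
        raise ValueError("downsample operates on raw counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu = np.triu_indices(cm.n_bins)
    vals = np.nan_to_num(cm.counts)[iu].astype(np.int64)
    total = int(vals.sum())
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds current total {total}")
    if target_total == total:
        return cm.copy()
    new = rng.multivariate_hypergeometric(vals, target_total, method="marginals")
    M = np.zeros_like(cm.counts)
    M[iu] = new
    M = M + np.triu(M, 1).T
    return ContactMatrix(M, resolution=cm.resolution, chrom=cm.chrom)


# ---------------------------------------------------------------------------
# Effective resolution & cis fraction
# ---------------------------------------------------------------------------

def effective_resolution(
    coverage_by_binsize: dict[int, np.ndarray],
    thresholds: tuple[int, ...] = (500, 1000),
    min_fraction: float = 0.8,
) -> dict[int, int | None]:
    """Smallest bin size at which >= ``min_fraction`` of bins have at least
    ``threshold`` contacts, per threshold.  None when no size qualifies."""
    if not coverage_by_binsize:
        raise ValueError("no candidate bin sizes supplied")
    out: dict[int, int | None] = {}
    for thr in thresholds:
        best: int | None = None
        for size in sorted(coverage_by_binsize):
            cov = np.asarray(coverage_by_binsize[size])
            if cov.size and (cov >= thr).mean() >= min_fraction:
                best = size
                break
        out[thr] = best
    return out


def cis_fraction(chrom_a, chrom_b) -> float:
    """Fraction of pairs whose two ends fall on the same chromosome."""
    a = np.asarray(chrom_a)
    b = np.asarray(chrom_b)
    if a.size == 0:
        raise ValueError("no pairs")
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float((a == b).mean())
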