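"""A/B compartment calling and compartmentalization strength.

The genome partitions into two megabase-scale compartments: A (active,
gene-rich, accessible) and B (repressive).  The partition is read off
the leading eigenvector (PC1) of the Pearson-correlation matrix of the
observed/expected map, computed per chromosome; PC1 sign is arbitrary
and is oriented against an external activity track (GC content or
accessibility) so that positive PC1 = A.

Compartmentalization strength is quantified two ways:

* saddle plots — bins ranked by PC1 into quantile groups; the corner
  ratio mean(AA, BB) / mean(AB, BA) of the group-pair mean O/E matrix;
* distance-stratified interval-pair strength — every pair of contiguous
  A/B intervals contributes a rescaled O/E submatrix, accumulated by
  category (intra-A / intra-B / inter) x range (short = self-pair on
  the diagonal, long = distinct pair) x separation stratum
  (<10 Mb, 10-30 Mb, >30 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .matrix import ContactMatrix, observed_expected

STRATA = ((0, 10_000_000), (10_000_000, 30_000_000), (30_000_000, None))
STRATUM_NAMES = ("<10Mb", "10-30Mb", ">30Mb")


class OrientationError(ValueError):
    """PC1 cannot be oriented (zero correlation with the orientation track)."""


@dataclass
class CompartmentProfile:
    """Per-bin PC1 with A/B labels and contiguous intervals."""

    pc1: np.ndarray            # NaN for masked bins
    labels: np.ndarray         # 'A' / 'B' / '' per bin
    resolution: int
    chrom: str = "chrS"
    degenerate: bool = False   # flagged when O/E was (near-)constant

    @property
    def n_bins(self) -> int:
        return self.pc1.size

    def intervals(self) -> pd.DataFrame:
        """Contiguous same-label runs as (chrom, start, end, label, n_bins)."""
        rows = []
        lab = self.labels
        i = 0
        while i < lab.size:
            if lab[i] == "":
                i += 1
                continue
            j = i
            while j + 1 < lab.size and lab[j + 1] == lab[i]:
                j += 1
            rows.append(
                {
                    "chrom": self.chrom,
                    "start": i * self.resolution,
                    "end": (j + 1) * self.resolution,
                    "label": lab[i],
                    "start_bin": i,
                    "end_bin": j + 1,
                }
            )
            i = j + 1
        return pd.DataFrame(rows)

    def to_bedgraph(self, path) -> None:
        starts = np.arange(self.n_bins) * self.resolution
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.resolution,
                "value": self.pc1,
            }
        ).dropna().to_csv(path, sep="\t", header=False, index=False)


def call_pc1(
    cm: ContactMatrix, orientation_track: np.ndarray
) -> CompartmentProfile:
    """PC1 of the O/E Pearson-correlation matrix, sign-oriented.

    The eigenvector is scaled by sqrt(eigenvalue) and the sign flipped so
    its Pearson correlation with ``orientation_track`` over unmasked bins
    is positive.  Bins with PC1 > 0 are labeled A, < 0 labeled B.
    """
    _, oe = observed_expected(cm)
    n = cm.n_bins
    track = np.asarray(orientation_track, dtype=float)
    if track.shape != (n,):
        raise ValueError("orientation track must cover every bin")
    good = ~cm.mask & np.isfinite(oe).any(axis=1)
    sub = oe[np.ix_(good, good)]
    sub = np.nan_to_num(sub, nan=1.0)

    pc1 = np.full(n, np.nan)
    degenerate = False
    if np.allclose(sub.std(axis=0), 0):
        degenerate = True
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        vals, vecs = np.linalg.eigh(corr)
        lead = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        if np.allclose(lead, 0):
            degenerate = True
        else:
            pc1[good] = lead

    if not degenerate:
        t = track[good]
        v = pc1[good]
        if np.std(t) == 0 or np.std(v) == 0:
            raise OrientationError("orientation track is constant")
        r = np.corrcoef(t, v)[0, 1]
        if r == 0 or not np.isfinite(r):
            raise OrientationError("orientation correlation is exactly zero")
        if r < 0:
            pc1 = -pc1

    labels = np.full(n, "", dtype=object)
    labels[np.nan_to_num(pc1) > 0] = "A"
    labels[np.nan_to_num(pc1) < 0] = "B"
    labels[~np.isfinite(pc1)] = ""
    return CompartmentProfile(
        pc1=pc1,
        labels=labels,
        resolution=cm.resolution,
        chrom=cm.chrom,
        degenerate=degenerate,
    )


def classify_switches(
    profile_1: CompartmentProfile, profile_2: CompartmentProfile
) -> pd.DataFrame:
    """Joint A/B classification of two conditions per bin.

    Returns per-bin classes from {A-A, B-B, A-B, B-A} (condition-1 label
    first) over doubly-labeled bins, with summary fractions available via
    :func:`switch_fractions`.
    """
    if profile_1.n_bins != profile_2.n_bins or profile_1.resolution != profile_2.resolution:
        raise ValueError("profiles use different binnings")
    l1, l2 = profile_1.labels, profile_2.labels
    both = (l1 != "") & (l2 != "")
    cls = np.full(profile_1.n_bins, "", dtype=object)
    cls[both] = [f"{a}-{b}" for a, b in zip(l1[both], l2[both])]
    starts = np.arange(profile_1.n_bins) * profile_1.resolution
    return pd.DataFrame(
        {
            "chrom": profile_1.chrom,
            "start": starts,
            "end": starts + profile_1.resolution,
            "class": cls,
        }
    )


def switch_fractions(classes: pd.DataFrame) -> dict[str, float]:
    """Class fractions over doubly-labeled bins, plus the switch fraction."""
    lab = classes["class"]
    lab = lab[lab != ""]
    frac = (lab.value_counts() / len(lab)).to_dict() if len(lab) else {}
    for k in ("A-A", "B-B", "A-B", "B-A"):
        frac.setdefault(k, 0.0)
    frac["switch"] = frac["A-B"] + frac["B-A"]
    return frac


@dataclass
class SaddleResult:
    matrix: np.ndarray        # n_deciles x n_deciles mean O/E, B-most first
    strength: float
    n_deciles: int
    corner_fraction: float


def saddle_strength(
    cm: ContactMatrix,
    profile: CompartmentProfile,
    n_deciles: int = 50,
    corner_fraction: float = 0.2,
) -> SaddleResult:
    """Saddle plot and corner-ratio compartment strength.

    Unmasked bins are ranked by PC1 into ``n_deciles`` equal-occupancy
    groups (row/col 0 = most negative PC1).  Entry (g, h) is the mean
    O/E over off-diagonal bin pairs in groups g and h.  Strength =
    mean over the intra corners (BB top-left, AA bottom-right blocks of
    side ``corner_fraction * n_deciles``) divided by the mean over the
    two inter corners.
    """
    _, oe = observed_expected(cm)
    good = np.isfinite(profile.pc1) & ~cm.mask
    if good.sum() < n_deciles:
        raise ValueError("fewer unmasked bins than quantile groups")
    vals = profile.pc1[good]
    order = np.empty(good.sum(), dtype=int)
    ranks = stats.rankdata(vals, method="ordinal") - 1
    group = (ranks * n_deciles // good.sum()).astype(int)

    sub = oe[np.ix_(good, good)].copy()
    np.fill_diagonal(sub, np.nan)
    S = np.full((n_deciles, n_deciles), np.nan)
    cnt = np.zeros((n_deciles, n_deciles))
    finite = np.isfinite(sub)
    gi = group[:, None].repeat(group.size, 1)
    gj = group[None, :].repeat(group.size, 0)
    flat_g = gi[finite] * n_deciles + gj[finite]
    sums = np.bincount(flat_g, weights=sub[finite], minlength=n_deciles**2)
    counts = np.bincount(flat_g, minlength=n_deciles**2)
    with np.errstate(invalid="ignore"):
        S = (sums / counts).reshape(n_deciles, n_deciles)

    k = max(int(round(corner_fraction * n_deciles)), 1)
    bb = S[:k, :k]
    aa = S[-k:, -k:]
    ab = np.concatenate([S[:k, -k:].ravel(), S[-k:, :k].ravel()])
    strength = float(
        np.nanmean(np.concatenate([aa.ravel(), bb.ravel()])) / np.nanmean(ab)
    )
    return SaddleResult(matrix=S, strength=strength, n_deciles=n_deciles, corner_fraction=corner_fraction)


@dataclass
class PentadResult:
    """Distance-stratified interval-pair compartment strength.

    ``pileups`` maps (category, range, stratum) -> rescaled mean O/E
    matrix; ``strengths`` is a long table with one strength per intra-type
    interval pair (columns: pair, category, range, stratum, strength).
    """

    pileups: dict[tuple[str, str, str], np.ndarray]
    strengths: pd.DataFrame

    def strength_by(self, category: str | None = None, stratum: str | None = None,
                    range_: str | None = None) -> np.ndarray:
        t = self.strengths
        if category:
            t = t[t["category"] == category]
        if stratum:
            t = t[t["stratum"] == stratum]
        if range_:
            t = t[t["range"] == range_]
        return t["strength"].to_numpy()


def _rescale(mat: np.ndarray, size: int) -> np.ndarray:
    filled = np.nan_to_num(mat, nan=np.nanmean(mat) if np.isfinite(mat).any() else 1.0)
    zoom = (size / filled.shape[0], size / filled.shape[1])
    return ndimage.zoom(filled, zoom, order=1, grid_mode=True, mode="nearest")


def pentad_strength(
    cm: ContactMatrix,
    profile: CompartmentProfile,
    min_interval_bins: int = 3,
    rescale_size: int = 33,
) -> PentadResult:
    """Interval-pair compartment strength stratified by genomic distance.

    Every ordered pair of A/B intervals (>= ``min_interval_bins`` long)
    contributes its O/E submatrix, rescaled to ``rescale_size`` squared.
    Self-pairs are "short" range (on-diagonal), distinct pairs "long".
    Distance stratum follows the interval-midpoint separation.  The
    strength of an intra-type pair is the mean of its submatrix divided
    by the pooled mean of inter-type submatrices in the same range and
    stratum; empty cells are reported missing.
    """
    _, oe = observed_expected(cm)
    ivals = profile.intervals()
    ivals = ivals[(ivals["end_bin"] - ivals["start_bin"]) >= min_interval_bins].reset_index(drop=True)
    res = cm.resolution

    records = []  # (category, range, stratum, mean, pair_id, submatrix)
    for a in range(len(ivals)):
        for b in range(a, len(ivals)):
            ia, ib = ivals.iloc[a], ivals.iloc[b]
            rng_class = "short" if a == b else "long"
            if ia["label"] == ib["label"]:
                cat = "intra-A" if ia["label"] == "A" else "intra-B"
            else:
                cat = "inter-AB"
            mid_a = (ia["start_bin"] + ia["end_bin"]) / 2 * res
            mid_b = (ib["start_bin"] + ib["end_bin"]) / 2 * res
            sep = abs(mid_b - mid_a)
            stratum = None
            for (lo, hi), name in zip(STRATA, STRATUM_NAMES):
                if sep >= lo and (hi is None or sep < hi):
                    stratum = name
                    break
            sub = oe[ia["start_bin"]:ia["end_bin"], ib["start_bin"]:ib["end_bin"]]
            if not np.isfinite(sub).any():
                continue
            records.append(
                (cat, rng_class, stratum, float(np.nanmean(sub)), f"{a}:{b}", sub)
            )

    pileups: dict[tuple[str, str, str], list[np.ndarray]] = {}
    for cat, rng_class, stratum, _, _, sub in records:
        pileups.setdefault((cat, rng_class, stratum), []).append(
            _rescale(sub, rescale_size)
        )
    pileup_means = {k: np.mean(v, axis=0) for k, v in pileups.items()}

    # pooled inter-type mean per (range, stratum)
    inter_mean: dict[tuple[str, str], float] = {}
    for rng_class in ("short", "long"):
        for name in STRATUM_NAMES:
            vals = [m for c, r, s, m, _, _ in records if c == "inter-AB" and r == rng_class and s == name]
            if vals:
                inter_mean[(rng_class, name)] = float(np.mean(vals))

    # self-pairs have no same-stratum inter reference on the diagonal;
    # fall back to the nearest-stratum long-range inter mean
    def inter_ref(rng_class: str, stratum: str) -> float | None:
        if (rng_class, stratum) in inter_mean:
            return inter_mean[(rng_class, stratum)]
        for s in STRATUM_NAMES:
            if ("long", s) in inter_mean:
                return inter_mean[("long", s)]
        return None

    rows = []
    for cat, rng_class, stratum, mean, pair, _ in records:
        if cat == "inter-AB":
            continue
        ref = inter_ref(rng_class, stratum)
        if ref is None or ref <= 0:
            continue
        rows.append(
            {
                "pair": pair,
                "category": cat,
                "range": rng_class,
                "stratum": stratum,
                "strength": mean / ref,
            }
        )
    return PentadResult(pileups=pileup_means, strengths=pd.DataFrame(rows))
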