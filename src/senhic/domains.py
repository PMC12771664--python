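"""Insulation, TAD calling, aggregate TAD analysis, stability metrics,
differential TADs and rearrangement classification.

TADs (topologically associating domains) are contiguous regions of
preferential self-interaction delimited by insulation minima.  Beyond
calling them, this module quantifies their architectural integrity:

* consolidation score (CS) — long-span (>= 400 kb) intra-TAD signal over
  distance-matched local background outside TADs; 1 means no
  consolidation;
* intra-TAD connectivity (iTC) — intra-TAD contact mass over all contact
  mass with at least one end in the TAD (inter-TAD mass capped at a 2 Mb
  span); always in (0, 1];
* degree of disorder (DoD) — mean pairwise distance (in bin units)
  between the TAD's strongest (top-decile O/E) pixels, normalized by TAD
  length; dispersed strong pixels = high disorder.

Differential TADs follow a two-pass Mahalanobis / chi-square procedure
on paired per-TAD scores; rearrangement events between two TAD sets are
classified deterministically into unchanged / split / merge / shift /
complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .matrix import ContactMatrix, observed_expected


@dataclass
class InsulationTrack:
    """Per-bin insulation score with boundary calls.

    score_i = log2( mean of the window-square upstream x downstream of
    bin i / chromosome-wide mean of such squares ); NaN within one
    window of the chromosome edges.  Boundaries are local minima whose
    prominence (mean of flanking maxima minus the minimum) exceeds the
    delta threshold.
    """

    score: np.ndarray
    window_bins: int
    resolution: int
    chrom: str = "chrS"
    boundaries: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    boundary_strength: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_bedgraph(self, path) -> None:
        starts = np.arange(self.score.size) * self.resolution
        pd.DataFrame(
            {"chrom": self.chrom, "start": starts, "end": starts + self.resolution,
             "value": self.score}
        ).dropna().to_csv(path, sep="\t", header=False, index=False)


def insulation(
    cm: ContactMatrix, window_bp: int, delta_threshold: float = 0.1
) -> InsulationTrack:
    """Sliding-square insulation score and boundary calls on a balanced map."""
    if not cm.balanced:
        raise ValueError("insulation requires a balanced matrix")
    w = max(int(round(window_bp / cm.resolution)), 1)
    if w < 3:
        raise ValueError("window must span at least 3 bins")
    n = cm.n_bins
    if n < 2 * w + 1:
        raise ValueError("chromosome shorter than 2*window + 1 bins")
    M = cm.counts
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        sq = M[i - w : i, i : i + w]
        if np.isfinite(sq).any():
            raw[i] = np.nanmean(sq)
    mean = np.nanmean(raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.log2(raw / mean)
    score[~np.isfinite(score)] = np.nan

    # modest Gaussian smoothing suppresses single-bin noise dips before
    # minima detection; the reported per-bin score stays unsmoothed
    finite = np.isfinite(score)
    smooth = score.copy()
    if finite.any():
        filled = np.where(finite, score, np.nanmean(score))
        sm = ndimage.gaussian_filter1d(filled, sigma=max(w / 10.0, 1.0))
        smooth = np.where(finite, sm, np.nan)
    boundaries, strengths = _call_boundaries(smooth, w, delta_threshold)
    # snap each smoothed minimum back to the raw-score minimum nearby
    refine = max(int(round(w / 10.0)), 1)
    refined = []
    for b in boundaries:
        lo, hi = max(b - refine, 0), min(b + refine + 1, n)
        seg = score[lo:hi]
        if np.isfinite(seg).any():
            refined.append(lo + int(np.nanargmin(seg)))
        else:
            refined.append(int(b))
    boundaries = np.array(refined, dtype=int)
    return InsulationTrack(
        score=score, window_bins=w, resolution=cm.resolution, chrom=cm.chrom,
        boundaries=boundaries, boundary_strength=strengths,
    )


def _call_boundaries(score: np.ndarray, w: int, delta: float):
    n = score.size
    mins = []
    for i in range(1, n - 1):
        s = score[i]
        if not np.isfinite(s):
            continue
        left = score[i - 1] if np.isfinite(score[i - 1]) else np.inf
        right = score[i + 1] if np.isfinite(score[i + 1]) else np.inf
        if s <= left and s < right:
            mins.append(i)
    out, strength = [], []
    for i in mins:
        lo = max(i - w, 0)
        hi = min(i + w + 1, n)
        lmax = np.nanmax(score[lo:i]) if i > lo and np.isfinite(score[lo:i]).any() else np.nan
        rmax = np.nanmax(score[i + 1 : hi]) if hi > i + 1 and np.isfinite(score[i + 1 : hi]).any() else np.nan
        flank = np.nanmean([lmax, rmax])
        d = flank - score[i]
        if np.isfinite(d) and d >= delta:
            out.append(i)
            strength.append(d)
    return np.array(out, dtype=int), np.array(strength)


@dataclass
class TadSet:
    """Sorted non-overlapping domains with optional per-TAD metrics."""

    table: pd.DataFrame  # chrom, start_bin, end_bin, start, end [+ metric columns]
    resolution: int
    chrom: str = "chrS"
    flagged: bool = False  # True when no boundary was found (whole-chromosome TAD)

    def __len__(self) -> int:
        return len(self.table)

    def bounds(self) -> list[tuple[int, int]]:
        return list(zip(self.table["start_bin"], self.table["end_bin"]))

    def to_bed(self, path) -> None:
        cols = ["chrom", "start", "end"] + [
            c for c in self.table.columns if c not in ("chrom", "start", "end", "start_bin", "end_bin")
        ]
        self.table[cols].to_csv(path, sep="\t", index=False)


def call_tads(track: InsulationTrack, min_tad_bins: int = 5) -> TadSet:
    """Segment the chromosome at insulation boundaries.

    Consecutive boundaries (plus the chromosome ends) delimit TADs; any
    TAD shorter than ``min_tad_bins`` is merged into a neighbor by
    removing its weaker flanking boundary.
    """
    n = track.score.size
    bounds = list(track.boundaries)
    strengths = {b: s for b, s in zip(track.boundaries, track.boundary_strength)}
    flagged = len(bounds) == 0

    edges = [0] + bounds + [n]
    # iteratively drop the weaker boundary of any under-length TAD
    changed = True
    while changed:
        changed = False
        for k in range(len(edges) - 1):
            if edges[k + 1] - edges[k] < min_tad_bins and len(edges) > 2:
                left = edges[k] if edges[k] != 0 else None
                right = edges[k + 1] if edges[k + 1] != n else None
                cand = [b for b in (left, right) if b is not None]
                if not cand:
                    continue
                drop = min(cand, key=lambda b: strengths.get(b, np.inf))
                edges.remove(drop)
                changed = True
                break
    if len(edges) == 2:
        flagged = True

    rows = []
    for k in range(len(edges) - 1):
        s, e = edges[k], edges[k + 1]
        rows.append(
            {
                "chrom": track.chrom,
                "start_bin": s,
                "end_bin": e,
                "start": s * track.resolution,
                "end": e * track.resolution,
            }
        )
    return TadSet(table=pd.DataFrame(rows), resolution=track.resolution,
                  chrom=track.chrom, flagged=flagged)


def tadset_from_bounds(bounds, resolution: int, chrom: str = "chrS") -> TadSet:
    rows = [
        {"chrom": chrom, "start_bin": s, "end_bin": e,
         "start": s * resolution, "end": e * resolution}
        for s, e in bounds
    ]
    return TadSet(table=pd.DataFrame(rows), resolution=resolution, chrom=chrom)


# ---------------------------------------------------------------------------
# Aggregate TAD analysis
# ---------------------------------------------------------------------------

@dataclass
class AtaResult:
    pileup: np.ndarray
    score: float
    n_tads: int


def ata_pileup(
    cm: ContactMatrix,
    tads: TadSet,
    rescale_size: int = 45,
    flank_fraction: float = 0.5,
    exclude_diagonals: int = 2,
) -> AtaResult:
    """Rescaled mean O/E pileup over TAD windows.

    Each window spans the TAD extended by ``flank_fraction`` of its
    length on both sides; the first ``exclude_diagonals`` diagonals are
    dropped before rescaling.  The aggregate score is the mean of the
    central TAD area of the averaged pileup.
    """
    if len(tads) == 0:
        raise ValueError("empty TAD list")
    _, oe = observed_expected(cm)
    n = cm.n_bins
    mats = []
    for s, e in tads.bounds():
        L = e - s
        if L < 3:
            continue
        f = int(round(flank_fraction * L))
        lo, hi = s - f, e + f
        if lo < 0 or hi > n:
            continue
        sub = oe[lo:hi, lo:hi].copy()
        m = hi - lo
        idx = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        sub[idx < exclude_diagonals] = np.nan
        filled = np.where(np.isfinite(sub), sub, np.nanmean(sub))
        z = rescale_size / m
        mats.append(ndimage.zoom(filled, (z, z), order=1, grid_mode=True, mode="nearest"))
    if not mats:
        raise ValueError("no TAD window fits inside the matrix")
    pileup = np.mean(mats, axis=0)
    frac = 1.0 / (1.0 + 2.0 * flank_fraction)
    lo = int(round(rescale_size * flank_fraction * frac))
    hi = int(round(rescale_size * (flank_fraction + 1.0) * frac))
    score = float(np.nanmean(pileup[lo:hi, lo:hi]))
    return AtaResult(pileup=pileup, score=score, n_tads=len(mats))


# ---------------------------------------------------------------------------
# Stability metrics: CS, iTC, DoD
# ---------------------------------------------------------------------------

def tad_stability(
    cm: ContactMatrix,
    tads: TadSet,
    cs_min_span_bp: int = 400_000,
    itc_max_span_bp: int = 2_000_000,
    dod_top_quantile: float = 0.9,
    metrics: tuple[str, ...] = ("CS", "iTC", "DoD"),
) -> pd.DataFrame:
    """Per-TAD consolidation (CS), connectivity (iTC) and disorder (DoD).

    CS compares intra-TAD signal to flanking non-TAD background at
    matched distances (spans >= ``cs_min_span_bp``); undefined for TADs
    shorter than the span floor.  iTC uses contact mass with inter-TAD
    pairs capped at ``itc_max_span_bp`` span.  DoD is the normalized mean
    pairwise pixel distance among top-decile O/E pixels of the TAD.
    """
    M = np.nan_to_num(cm.counts)
    _, oe = observed_expected(cm) if cm.balanced else (None, None)
    n = cm.n_bins
    res = cm.resolution
    smin = int(np.ceil(cs_min_span_bp / res))
    smax_itc = int(itc_max_span_bp // res)

    in_tad = np.full(n, -1)
    for k, (s, e) in enumerate(tads.bounds()):
        in_tad[s:e] = k

    rows = []
    for k, (s, e) in enumerate(tads.bounds()):
        L = e - s
        # --- CS ---
        cs = np.nan
        if "CS" in metrics and L > smin:
            intra_by_s, bg_by_s = [], []
            flank_lo, flank_hi = max(s - L, 0), min(e + L, n)
            for span in range(smin, L):
                d = np.diagonal(M, span)
                intra = d[s : e - span]
                # background: pairs inside the flanking window, not both ends in one TAD
                i_idx = np.arange(flank_lo, flank_hi - span)
                j_idx = i_idx + span
                ok = ~((in_tad[i_idx] >= 0) & (in_tad[i_idx] == in_tad[j_idx]))
                bg = M[i_idx[ok], j_idx[ok]]
                if intra.size and bg.size:
                    intra_by_s.append(intra.mean())
                    bg_by_s.append(bg.mean())
            if intra_by_s and np.mean(bg_by_s) > 0:
                cs = float(np.mean(intra_by_s) / np.mean(bg_by_s))
        # --- iTC ---
        itc = np.nan
        intra_mass = np.triu(M[s:e, s:e]).sum()
        lo = max(s - smax_itc, 0)
        hi = min(e + smax_itc, n)
        inter_mass = 0.0
        left = M[lo:s, s:e]
        if left.size:
            ii, jj = np.meshgrid(np.arange(lo, s), np.arange(s, e), indexing="ij")
            inter_mass += left[(jj - ii) <= smax_itc].sum()
        right = M[s:e, e:hi]
        if right.size:
            ii, jj = np.meshgrid(np.arange(s, e), np.arange(e, hi), indexing="ij")
            inter_mass += right[(jj - ii) <= smax_itc].sum()
        itc = intra_mass / (intra_mass + inter_mass) if intra_mass > 0 else np.nan
        # --- DoD ---
        dod = np.nan
        src = oe if oe is not None else M
        sub = src[s:e, s:e]
        iu = np.triu_indices(L, k=1)
        vals = sub[iu]
        fin = np.isfinite(vals)
        if "DoD" in metrics and fin.sum() >= 2:
            thr = np.quantile(vals[fin], dod_top_quantile)
            top = fin & (vals >= thr)
            pts = np.column_stack([iu[0][top], iu[1][top]]).astype(float)
            if len(pts) >= 2:
                d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
                tri = d[np.triu_indices(len(pts), k=1)]
                dod = float(tri.mean() / L)
        rows.append({"tad": k, "start_bin": s, "end_bin": e, "CS": cs, "iTC": itc, "DoD": dod})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential TADs (two-pass Mahalanobis + chi-square)
# ---------------------------------------------------------------------------

@dataclass
class DiffTadResult:
    table: pd.DataFrame  # x, y, mahalanobis_sq, p, direction

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]


def diff_tads(
    scores_1,
    scores_2,
    outlier_pass_quantile: float = 0.95,
    alpha: float = 0.05,
) -> DiffTadResult:
    """Differential TADs from paired per-TAD scores.

    Pass 1 fits mean/covariance of (x, y) over all TADs and removes
    points with squared Mahalanobis distance above the chi-square(2)
    ``outlier_pass_quantile``; pass 2 refits on the remainder with the
    standard truncation consistency correction so that null data stay
    chi-square(2) distributed.  p is the upper chi-square(2) tail of the
    pass-2 distance; direction (up / down by sign of y - x) is assigned
    where p < ``alpha``.
    """
    x = np.asarray(scores_1, dtype=float)
    y = np.asarray(scores_2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("need at least 10 TADs with finite scores")
    X = np.column_stack([x[ok], y[ok]])

    def mahal_sq(Z, mu, cov):
        # pseudo-inverse: perfectly colinear score pairs (a degenerate
        # but legitimate null) measure deviation only off the fitted axis
        if np.allclose(cov, 0):
            raise ValueError("singular covariance (constant scores?)")
        vals, vecs = np.linalg.eigh(cov)
        good = vals > 1e-10 * vals.max()
        d = (Z - mu) @ vecs[:, good] / np.sqrt(vals[good])
        if not good.all():
            # deviation along the degenerate direction: nonzero => infinite
            # distance, but colinear points have exactly zero there
            resid = (Z - mu) @ vecs[:, ~good]
            off_axis = (np.abs(resid) > 1e-8 * np.sqrt(vals.max())).any(axis=1)
            d2 = np.zeros(Z.shape[0])
            d2[off_axis] = np.inf
            return d2
        return (d**2).sum(axis=1)

    mu1 = X.mean(axis=0)
    cov1 = np.cov(X, rowvar=False)
    d2 = mahal_sq(X, mu1, cov1)
    cut = stats.chi2.ppf(outlier_pass_quantile, df=2)
    keep = d2 <= cut
    Z = X[keep] if keep.sum() >= 10 else X
    mu = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False)
    # consistency factor for trimming a bivariate normal at quantile h
    h = outlier_pass_quantile
    cov = cov * (h / stats.chi2.cdf(cut, df=4)) if keep.sum() >= 10 else cov
    d2_final = mahal_sq(X, mu, cov)
    p = stats.chi2.sf(d2_final, df=2)

    direction = np.full(ok.sum(), "ns", dtype=object)
    sig = p < alpha
    delta = X[:, 1] - X[:, 0]
    direction[sig & (delta > 0)] = "up"
    direction[sig & (delta < 0)] = "down"

    full = pd.DataFrame({"x": x, "y": y})
    full["mahalanobis_sq"] = np.nan
    full["p"] = np.nan
    full["direction"] = "ns"
    full.loc[np.flatnonzero(ok), "mahalanobis_sq"] = d2_final
    full.loc[np.flatnonzero(ok), "p"] = p
    full.loc[np.flatnonzero(ok), "direction"] = direction
    return DiffTadResult(table=full)


# ---------------------------------------------------------------------------
# Rearrangement classification
# ---------------------------------------------------------------------------

REARRANGEMENT_LABELS = ("unchanged", "split", "merge", "shift", "complex")


def classify_rearrangements(
    reference: TadSet, target: TadSet, tol_bins: int = 1
) -> pd.DataFrame:
    """Label every target TAD by its relation to the reference TAD set.

    Precedence: unchanged > split > merge > shift > complex.

    unchanged — both target boundaries match one reference TAD within tol;
    split — the target is one of >= 2 target TADs whose union matches one
    reference TAD at the outer boundaries, with new interior boundaries;
    merge — the target outer boundaries match those of >= 2 consecutive
    reference TADs; shift — reciprocal overlap >= 50% with exactly one
    reference TAD but a displaced boundary; complex — anything else.
    """
    ref = _check_sorted(reference)
    tgt = _check_sorted(target)
    ref_bounds = ref.bounds()
    tgt_bounds = tgt.bounds()

    def close(a, b):
        return abs(a - b) <= tol_bins

    labels = []
    ref_ids_col = []
    for ti, (ts, te) in enumerate(tgt_bounds):
        label, ref_ids = None, []
        # unchanged
        for ri, (rs, re) in enumerate(ref_bounds):
            if close(ts, rs) and close(te, re):
                label, ref_ids = "unchanged", [ri]
                break
        # split: some reference TAD contains this target, and the union of
        # all targets inside it matches its outer boundaries
        if label is None:
            for ri, (rs, re) in enumerate(ref_bounds):
                members = [
                    (s, e) for s, e in tgt_bounds
                    if s >= rs - tol_bins and e <= re + tol_bins
                ]
                if (
                    len(members) >= 2
                    and (ts, te) in members
                    and close(min(m[0] for m in members), rs)
                    and close(max(m[1] for m in members), re)
                    and _contiguous(members, tol_bins)
                ):
                    label, ref_ids = "split", [ri]
                    break
        # merge: target outer boundaries match >= 2 consecutive reference TADs
        if label is None:
            inside = [
                ri for ri, (rs, re) in enumerate(ref_bounds)
                if rs >= ts - tol_bins and re <= te + tol_bins
            ]
            if (
                len(inside) >= 2
                and close(ref_bounds[inside[0]][0], ts)
                and close(ref_bounds[inside[-1]][1], te)
                and inside == list(range(inside[0], inside[-1] + 1))
            ):
                label, ref_ids = "merge", inside
        # shift: reciprocal overlap >= 50% with exactly one reference TAD
        if label is None:
            cands = []
            for ri, (rs, re) in enumerate(ref_bounds):
                ov = max(0, min(te, re) - max(ts, rs))
                if ov >= 0.5 * (te - ts) and ov >= 0.5 * (re - rs):
                    cands.append(ri)
            if len(cands) == 1:
                label, ref_ids = "shift", cands
        if label is None:
            label = "complex"
        labels.append(label)
        ref_ids_col.append(",".join(map(str, ref_ids)))
    return pd.DataFrame(
        {
            "target_id": np.arange(len(tgt_bounds)),
            "start_bin": [b[0] for b in tgt_bounds],
            "end_bin": [b[1] for b in tgt_bounds],
            "ref_ids": ref_ids_col,
            "label": labels,
        }
    )


def _contiguous(members, tol):
    ms = sorted(members)
    return all(abs(ms[k + 1][0] - ms[k][1]) <= tol for k in range(len(ms) - 1))


def _check_sorted(ts: TadSet) -> TadSet:
    b = ts.bounds()
    for k in range(len(b) - 1):
        if b[k][1] > b[k + 1][0]:
            raise ValueError("TADs must be sorted and non-overlapping")
    return ts


# ---------------------------------------------------------------------------
# Compartment assignment
# ---------------------------------------------------------------------------

def assign_tad_compartment(tads: TadSet, profile) -> pd.DataFrame:
    """Proportional A/B assignment of each TAD from overlapped interval
    lengths; the majority label ('A', 'B', or '' when unlabeled)."""
    labels = profile.labels
    rows = []
    for k, (s, e) in enumerate(tads.bounds()):
        lab = labels[s:e]
        n_a = int((lab == "A").sum())
        n_b = int((lab == "B").sum())
        tot = n_a + n_b
        if tot == 0:
            rows.append({"tad": k, "frac_A": np.nan, "frac_B": np.nan, "label": ""})
            continue
        fa, fb = n_a / tot, n_b / tot
        rows.append(
            {"tad": k, "frac_A": fa, "frac_B": fb, "label": "A" if fa >= 0.5 else "B"}
        )
    return pd.DataFrame(rows)
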