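"""Chromatin-loop calling, aggregate peak analysis, annotation and
differential loops.

Loops are focal contact enrichments between two anchors.  The caller
follows the donut-background idea: for every pixel in a distance band,
a local expected count is computed from four neighborhoods — donut,
lower-left quadrant, horizontal and vertical stripes (inner radius 2,
outer radius 5 bins) — each scaled through the global distance-decay
expectation so that the test is insensitive to P(s) and to per-bin
biases.  A pixel is a loop pixel when its raw count clears a Poisson
upper-tail test against all four expectations after per-neighborhood
Benjamini-Hochberg correction, and its enrichment over the donut
expectation exceeds a floor.  Significant pixels are clustered by
8-connectivity; each cluster reports its strongest pixel as the loop.

APA averages O/E windows centered on loops.  Annotation assigns length,
compartment, switch-region, TAD, CTCF and enhancer/promoter classes.
Differential loops quantify a union loop list in both conditions and
classify common / lost / gained with a count floor (cacut) and a
fold-change floor (cmcut).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .matrix import ContactMatrix, observed_expected, expected_profile


@dataclass
class LoopSet:
    """Anchor-pair records; one row per loop.

    Core columns: chrom, bin1, bin2, start1, end1, start2, end2,
    resolution, observed, expected_donut, q_donut (max q over the four
    neighborhoods).  Annotation columns are added by
    :func:`annotate_loops`.
    """

    table: pd.DataFrame
    resolution: int
    chrom: str = "chrS"

    def __len__(self) -> int:
        return len(self.table)

    def anchors(self) -> np.ndarray:
        return self.table[["bin1", "bin2"]].to_numpy(dtype=int)

    def to_bedpe(self, path) -> None:
        t = self.table
        out = pd.DataFrame(
            {
                "chrom1": self.chrom, "start1": t["start1"], "end1": t["end1"],
                "chrom2": self.chrom, "start2": t["start2"], "end2": t["end2"],
                "name": [f"loop_{k}" for k in range(len(t))],
                "score": t.get("q_max", pd.Series(np.nan, index=t.index)),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def loopset_from_anchors(anchors, resolution: int, chrom: str = "chrS") -> LoopSet:
    a = np.asarray(anchors, dtype=int)
    t = pd.DataFrame({"bin1": a[:, 0], "bin2": a[:, 1]})
    t["start1"] = t["bin1"] * resolution
    t["end1"] = t["start1"] + resolution
    t["start2"] = t["bin2"] * resolution
    t["end2"] = t["start2"] + resolution
    return LoopSet(table=t, resolution=resolution, chrom=chrom)


# ---------------------------------------------------------------------------
# Donut-background loop calling
# ---------------------------------------------------------------------------

def _footprints(inner: int, outer: int):
    """Boolean footprints (donut, lower-left, horizontal, vertical) on a
    (2*outer+1)^2 stencil centered at the pixel."""
    size = 2 * outer + 1
    ii, jj = np.meshgrid(np.arange(size) - outer, np.arange(size) - outer, indexing="ij")
    ring = (np.maximum(np.abs(ii), np.abs(jj)) > inner) & (
        np.maximum(np.abs(ii), np.abs(jj)) <= outer
    )
    donut = ring.copy()
    # exclude the cross through the center from the donut (classic shape)
    donut &= ~((ii == 0) | (jj == 0))
    lowerleft = ring & (ii > inner) & (jj < -inner)
    horizontal = (np.abs(jj) > inner) & (np.abs(jj) <= outer) & (np.abs(ii) <= 1)
    vertical = (np.abs(ii) > inner) & (np.abs(ii) <= outer) & (np.abs(jj) <= 1)
    return {"donut": donut, "lowerleft": lowerleft, "horizontal": horizontal, "vertical": vertical}


def _neighborhood_expected(raw: np.ndarray, expected_raw: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """mu_ij = E_raw_ij * (sum of raw over footprint / sum of E_raw over
    footprint): local enrichment of the neighborhood transferred to the
    center pixel's global expectation."""
    k = fp.astype(float)
    # correlate, not convolve: the footprint is oriented (lower-left)
    num = ndimage.correlate(raw, k, mode="constant", cval=0.0)
    den = ndimage.correlate(expected_raw, k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = num / den
    return expected_raw * ratio


def call_loops(
    raw: ContactMatrix,
    balanced: ContactMatrix,
    fdr: float = 0.1,
    max_span_bp: int = 2_000_000,
    min_span_bins: int = 3,
    inner_radius: int = 2,
    outer_radius: int = 5,
    min_enrichment: float = 1.5,
    peak_window: int = 1,
    singleton_q_factor: float = 20.0,
) -> LoopSet:
    """Call loops on one resolution from matched raw + balanced matrices.

    ``peak_window`` (odd, in bins) is the square over which observed and
    expected counts are summed before the Poisson test; the default 1
    tests single pixels, 3 suits wider dots.  Because true loops cluster
    into one call while stray significant pixels each become their own
    call, single-pixel clusters are kept only when their worst q-value
    clears ``fdr / singleton_q_factor``.
    """
    n = raw.n_bins
    res = raw.resolution
    C = np.nan_to_num(raw.counts)
    bias = balanced.bias if balanced.bias is not None else np.ones(n)
    b = np.where(np.isfinite(bias), bias, np.nan)
    exp_bal = expected_profile(balanced)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore"):
        E_raw = np.outer(b, b) * exp_bal[idx]
    E_raw = np.nan_to_num(E_raw)

    max_span = max_span_bp // res
    band = (idx >= min_span_bins) & (idx <= max_span) & (E_raw > 0)
    band &= np.triu(np.ones((n, n), dtype=bool))

    fps = _footprints(inner_radius, outer_radius)
    bi, bj = np.where(band)
    if peak_window % 2 != 1 or peak_window < 1:
        raise ValueError("peak_window must be odd and >= 1")
    box = np.ones((peak_window, peak_window))
    obs_w_full = ndimage.correlate(C, box, mode="constant", cval=0.0)
    E_w_full = ndimage.correlate(E_raw, box, mode="constant", cval=0.0)
    obs = obs_w_full[bi, bj]
    with np.errstate(invalid="ignore", divide="ignore"):
        win_scale = (E_w_full / np.where(E_raw > 0, E_raw, np.nan))[bi, bj]
    qs = {}
    mus = {}
    for name, fp in fps.items():
        mu = _neighborhood_expected(C, E_raw, fp)[bi, bj] * win_scale
        mu = np.where(np.isfinite(mu) & (mu > 0), mu, np.inf)
        p = stats.poisson.sf(obs - 1, mu)
        qs[name] = _bh(p)
        mus[name] = mu
    q_max = np.max(np.column_stack(list(qs.values())), axis=1)
    mu_donut = mus["donut"]
    mu_ll = mus["lowerleft"]
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(mu_donut > 0, obs / mu_donut, 0.0)
        enr_ll = np.where(mu_ll > 0, obs / mu_ll, 0.0)
    sig = (q_max <= fdr) & (enr >= min_enrichment) & (enr_ll >= min_enrichment)

    sig_mask = np.zeros((n, n), dtype=bool)
    sig_mask[bi[sig], bj[sig]] = True
    labels, n_lab = ndimage.label(sig_mask, structure=np.ones((3, 3), dtype=int))
    rows = []
    for lab in range(1, n_lab + 1):
        pi, pj = np.where(labels == lab)
        best = np.argmax(C[pi, pj])
        i, j = int(pi[best]), int(pj[best])
        flat = np.flatnonzero((bi == i) & (bj == j))[0]
        if len(pi) == 1 and q_max[flat] > fdr / singleton_q_factor:
            continue
        rows.append(
            {
                "bin1": i, "bin2": j,
                "start1": i * res, "end1": (i + 1) * res,
                "start2": j * res, "end2": (j + 1) * res,
                "observed": C[i, j],
                "expected_donut": mu_donut[flat] if np.isfinite(mu_donut[flat]) else np.nan,
                "enrichment": enr[flat],
                "q_max": q_max[flat],
                "n_pixels": len(pi),
                "resolution": res,
            }
        )
    table = pd.DataFrame(rows, columns=[
        "bin1", "bin2", "start1", "end1", "start2", "end2", "observed",
        "expected_donut", "enrichment", "q_max", "n_pixels", "resolution",
    ])
    return LoopSet(table=table, resolution=res, chrom=raw.chrom)


def merge_resolutions(loopsets: list[LoopSet], merge_bp: int = 20_000) -> LoopSet:
    """Union across resolutions; where calls at different resolutions fall
    within ``merge_bp`` of each other (both anchors), keep the
    finest-resolution call."""
    if not loopsets:
        raise ValueError("no loop sets to merge")
    ordered = sorted(loopsets, key=lambda ls: ls.resolution)
    kept = []
    for ls in ordered:
        for _, row in ls.table.iterrows():
            m1 = (row["start1"] + row["end1"]) / 2
            m2 = (row["start2"] + row["end2"]) / 2
            dup = any(
                abs(m1 - k["mid1"]) <= merge_bp and abs(m2 - k["mid2"]) <= merge_bp
                for k in kept
            )
            if not dup:
                rec = row.to_dict()
                rec["mid1"], rec["mid2"] = m1, m2
                kept.append(rec)
    table = pd.DataFrame(kept).drop(columns=["mid1", "mid2"], errors="ignore")
    res = ordered[0].resolution
    return LoopSet(table=table.reset_index(drop=True), resolution=res, chrom=ordered[0].chrom)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Aggregate peak analysis
# ---------------------------------------------------------------------------

@dataclass
class ApaResult:
    pileup: np.ndarray
    center_enrichment: float
    n_loops: int


def apa(
    balanced: ContactMatrix,
    loops: LoopSet,
    window_bp: int = 100_000,
    exclude_diagonals: int = 2,
) -> ApaResult:
    """Mean O/E pileup over +/- ``window_bp`` windows at the loop pixels.

    Windows that cross the matrix edge or the excluded diagonals at the
    center are dropped; center enrichment is the center pixel of the
    averaged pileup.
    """
    _, oe = observed_expected(balanced)
    n = balanced.n_bins
    w = window_bp // balanced.resolution
    mats = []
    for i, j in loops.anchors():
        if i - w < 0 or j + w >= n or i + w >= n or j - w < 0:
            continue
        if abs(j - i) <= 2 * w + exclude_diagonals:
            # window would touch the excluded diagonals
            if abs(j - i) <= w + exclude_diagonals:
                continue
        sub = oe[i - w : i + w + 1, j - w : j + w + 1].copy()
        ii = np.arange(i - w, i + w + 1)[:, None]
        jj = np.arange(j - w, j + w + 1)[None, :]
        sub[np.abs(jj - ii) < exclude_diagonals] = np.nan
        mats.append(sub)
    if not mats:
        raise ValueError("no usable loop windows")
    with np.errstate(invalid="ignore"):
        pileup = np.nanmean(np.stack(mats), axis=0)
    center = float(pileup[w, w])
    return ApaResult(pileup=pileup, center_enrichment=center, n_loops=len(mats))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

LENGTH_EDGES = (200_000, 500_000, 1_000_000)
LENGTH_CLASSES = ("<200kb", "200-500kb", "500kb-1Mb", ">1Mb")


def _length_class(sep: float) -> str:
    for edge, name in zip(LENGTH_EDGES, LENGTH_CLASSES):
        if sep < edge:
            return name
    return LENGTH_CLASSES[-1]


def _overlaps(start: float, end: float, intervals: pd.DataFrame) -> bool:
    if intervals is None or len(intervals) == 0:
        return False
    return bool(((intervals["start"] < end) & (intervals["end"] > start)).any())


def annotate_loops(
    loops: LoopSet,
    profile=None,
    switch_classes: pd.DataFrame | None = None,
    tads=None,
    ctcf_peaks: pd.DataFrame | None = None,
    enhancers: pd.DataFrame | None = None,
    promoters: pd.DataFrame | None = None,
) -> LoopSet:
    """Attach length / compartment / switch / TAD / CTCF / regulatory
    classes; annotation sets with missing inputs are left absent."""
    t = loops.table.copy()
    res = loops.resolution
    mid1 = (t["start1"] + t["end1"]) / 2
    mid2 = (t["start2"] + t["end2"]) / 2
    t["length_class"] = [(lambda s: _length_class(s))(s) for s in (mid2 - mid1).abs()]

    if profile is not None:
        lab = profile.labels
        pres = profile.resolution

        def bin_label(start, end):
            b0, b1 = int(start // pres), max(int(np.ceil(end / pres)), int(start // pres) + 1)
            seg = lab[b0:b1]
            n_a, n_b = (seg == "A").sum(), (seg == "B").sum()
            if n_a == n_b == 0:
                return ""
            return "A" if n_a >= n_b else "B"

        l1 = [bin_label(s, e) for s, e in zip(t["start1"], t["end1"])]
        l2 = [bin_label(s, e) for s, e in zip(t["start2"], t["end2"])]
        t["compartment_class"] = [
            (a + b) if a and b else "" for a, b in zip(l1, l2)
        ]

    if switch_classes is not None:
        sres = int(switch_classes["end"].iloc[0] - switch_classes["start"].iloc[0]) if len(switch_classes) else res
        cls = switch_classes["class"].to_numpy()

        def sw_label(start, end):
            b0 = int(start // sres)
            b1 = max(int(np.ceil(end / sres)), b0 + 1)
            seg = [c for c in cls[b0:b1] if c != ""]
            if not seg:
                return ""
            u = set(seg)
            if len(u) > 1:
                return "mixed"
            return {
                "A-A": "Stable-A", "B-B": "Stable-B", "A-B": "A->B", "B-A": "B->A"
            }[seg[0]]

        s1 = [sw_label(s, e) for s, e in zip(t["start1"], t["end1"])]
        s2 = [sw_label(s, e) for s, e in zip(t["start2"], t["end2"])]
        t["switch_class"] = [
            a if (a == b and a) else ("mixed" if a and b else "")
            for a, b in zip(s1, s2)
        ]

    if tads is not None:
        bounds = [(s * tads.resolution, e * tads.resolution) for s, e in tads.bounds()]

        def tad_of(pos):
            for k, (s, e) in enumerate(bounds):
                if s <= pos < e:
                    return k
            return -1

        t1 = [tad_of(m) for m in mid1]
        t2 = [tad_of(m) for m in mid2]
        t["within_tad"] = [(a == b and a >= 0) for a, b in zip(t1, t2)]

    if ctcf_peaks is not None:
        n1 = [_overlaps(s, e, ctcf_peaks) for s, e in zip(t["start1"], t["end1"])]
        n2 = [_overlaps(s, e, ctcf_peaks) for s, e in zip(t["start2"], t["end2"])]
        t["ctcf_class"] = [
            "both" if a and b else ("single" if a or b else "none")
            for a, b in zip(n1, n2)
        ]

    if enhancers is not None or promoters is not None:
        def reg(start, end):
            if promoters is not None and _overlaps(start, end, promoters):
                return "P"
            if enhancers is not None and _overlaps(start, end, enhancers):
                return "E"
            return "N"

        r1 = [reg(s, e) for s, e in zip(t["start1"], t["end1"])]
        r2 = [reg(s, e) for s, e in zip(t["start2"], t["end2"])]
        order = {"E": 0, "P": 1, "N": 2}
        t["regulatory_class"] = [
            "-".join(sorted((a, b), key=order.get)) for a, b in zip(r1, r2)
        ]

    return LoopSet(table=t, resolution=res, chrom=loops.chrom)


# ---------------------------------------------------------------------------
# Differential loops
# ---------------------------------------------------------------------------

@dataclass
class DiffLoopResult:
    table: pd.DataFrame  # union loops + mean_1, mean_2, log2fc, padj, class

    def counts(self) -> dict[str, int]:
        return self.table["class"].value_counts().to_dict()


def diff_loops(
    loops_1: LoopSet,
    loops_2: LoopSet,
    raw_1: ContactMatrix,
    raw_2: ContactMatrix,
    cacut: float = 5.0,
    cmcut: float = 0.5,
    q_max: float = 0.05,
    merge_bins: int = 2,
) -> DiffLoopResult:
    """Quantify the union loop list in both conditions and classify.

    Per union loop: mean raw count over the loop pixel +/- 1 bin per
    condition (CPM-scaled to condition 1's total when totals differ);
    loops with max mean < ``cacut`` are dropped; |log2FC| >= ``cmcut``
    with BH-adjusted two-sided conditional-binomial p <= ``q_max``
    classifies lost (down in condition 2) or gained; remainder common.
    """
    import warnings

    t1, t2 = raw_1.total(), raw_2.total()
    scale2 = 1.0 if t2 == 0 else t1 / t2
    if abs(scale2 - 1.0) > 0.05:
        warnings.warn("condition totals differ by >5%; applying CPM scaling")

    union: list[tuple[int, int]] = []
    for ls in (loops_1, loops_2):
        for i, j in ls.anchors():
            if not any(abs(i - a) <= merge_bins and abs(j - b) <= merge_bins for a, b in union):
                union.append((int(i), int(j)))

    n = raw_1.n_bins
    C1 = np.nan_to_num(raw_1.counts)
    C2 = np.nan_to_num(raw_2.counts)
    rows = []
    for i, j in union:
        lo_i, hi_i = max(i - 1, 0), min(i + 2, n)
        lo_j, hi_j = max(j - 1, 0), min(j + 2, n)
        m1 = C1[lo_i:hi_i, lo_j:hi_j].mean()
        m2 = C2[lo_i:hi_i, lo_j:hi_j].mean() * scale2
        s1 = C1[lo_i:hi_i, lo_j:hi_j].sum()
        s2 = C2[lo_i:hi_i, lo_j:hi_j].sum()
        rows.append({"bin1": i, "bin2": j, "mean_1": m1, "mean_2": m2,
                     "sum_1": s1, "sum_2": s2})
    t = pd.DataFrame(rows, columns=["bin1", "bin2", "mean_1", "mean_2", "sum_1", "sum_2"])
    if len(t) == 0:
        t["log2fc"] = []
        t["p"] = []
        t["padj"] = []
        t["class"] = []
        return DiffLoopResult(table=t)
    t["kept"] = np.maximum(t["mean_1"], t["mean_2"]) >= cacut
    t["log2fc"] = np.log2((t["mean_2"] + 1) / (t["mean_1"] + 1))

    # two-sided conditional binomial on summed anchor counts
    pvals = []
    p_null = t2 / (t1 + t2) if (t1 + t2) > 0 else 0.5
    for _, r in t.iterrows():
        x2 = int(round(r["sum_2"]))
        tot = int(round(r["sum_1"] + r["sum_2"]))
        if tot == 0:
            pvals.append(1.0)
            continue
        pvals.append(stats.binomtest(x2, tot, p_null).pvalue)
    t["p"] = pvals
    t["padj"] = 1.0
    kept_idx = t.index[t["kept"]]
    if len(kept_idx):
        t.loc[kept_idx, "padj"] = _bh(t.loc[kept_idx, "p"].to_numpy())

    cls = np.full(len(t), "dropped", dtype=object)
    kept = t["kept"].to_numpy()
    sig = kept & (t["padj"].to_numpy() <= q_max) & (np.abs(t["log2fc"].to_numpy()) >= cmcut)
    cls[kept] = "common"
    cls[sig & (t["log2fc"].to_numpy() < 0)] = "lost"
    cls[sig & (t["log2fc"].to_numpy() > 0)] = "gained"
    t["class"] = cls
    t["start1"] = t["bin1"] * raw_1.resolution
    t["end1"] = t["start1"] + raw_1.resolution
    t["start2"] = t["bin2"] * raw_1.resolution
    t["end2"] = t["start2"] + raw_1.resolution
    return DiffLoopResult(table=t.drop(columns=["kept"]))
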