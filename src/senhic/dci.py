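"""Differential chromatin interactions (DCIs) between two conditions.

Works on per-sample pixel tables (bin_i, bin_j, count) at a fixed
resolution with at least two replicates per condition.  The analysis
follows the joint-normalization + exact-test design used for replicated
Hi-C comparisons:

1. ``joint_normalize`` — within log-spaced distance strata, cyclic
   pairwise loess of M (log2 ratio) on A (mean log2) removes
   sample-specific distance-dependent trends.
2. ``dci_test`` — per pixel, an exact conditional binomial test of the
   condition-2 total against the condition-1 total given the pixel
   total, BH-corrected genome-wide.  A pixel is directional (up/down)
   only when log2CPM, |log2FC| and adjusted p all pass their filters.
3. ``tad_dci_summary`` — per TAD (+ flank), counts of up/down DCIs, the
   down fraction, covariate means and Spearman correlations.
4. ``dci_enrichment`` — Fisher's exact test of compartment x down-group
   and logistic regression of the high-down group on rearrangement type.

The default filters (log2CPM > 2, |log2FC| > 1.2, adjusted p < 0.05,
span <= 2 Mb, >= 10 directional DCIs per TAD) match common practice for
senescence Hi-C comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .matrix import ContactMatrix


def pixel_table(cm: ContactMatrix, max_span_bp: int | None = None) -> pd.DataFrame:
    """Upper-triangle (distance > 0) pixel table of a raw matrix."""
    n = cm.n_bins
    iu = np.triu_indices(n, k=1)
    t = pd.DataFrame(
        {"bin_i": iu[0], "bin_j": iu[1], "count": np.nan_to_num(cm.counts)[iu]}
    )
    t["distance"] = (t["bin_j"] - t["bin_i"]) * cm.resolution
    if max_span_bp is not None:
        t = t[t["distance"] <= max_span_bp].reset_index(drop=True)
    return t


def _distance_strata(dist: np.ndarray, ratio: float = 1.3) -> np.ndarray:
    """Log-spaced stratum index per pixel."""
    lo = dist.min()
    edges = [lo]
    while edges[-1] <= dist.max():
        edges.append(edges[-1] * ratio)
    return np.digitize(dist, edges) - 1


def joint_normalize(
    tables: list[pd.DataFrame],
    ratio: float = 1.3,
    min_stratum: int = 30,
    n_cycles: int = 3,
    loess_frac: float = 0.4,
) -> list[pd.DataFrame]:
    """Cyclic pairwise loess normalization within distance strata.

    Every table must share (bin_i, bin_j, distance).  Counts become
    floats; strata with fewer than ``min_stratum`` pixels are passed
    through unchanged (flagged via the ``skipped_strata`` attribute on
    the returned tables).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(tables) < 2:
        raise ValueError("need at least two samples")
    base = tables[0][["bin_i", "bin_j", "distance"]]
    for t in tables[1:]:
        if not base.equals(t[["bin_i", "bin_j", "distance"]].reset_index(drop=True)):
            raise ValueError("samples must share the same pixel set")
    counts = [t["count"].to_numpy(dtype=float).copy() for t in tables]
    dist = base["distance"].to_numpy(dtype=float)
    strata = _distance_strata(dist, ratio)
    skipped = []
    for s in np.unique(strata):
        sel = strata == s
        if sel.sum() < min_stratum:
            skipped.append(int(s))
            continue
        for _ in range(n_cycles):
            for a in range(len(counts)):
                for b in range(a + 1, len(counts)):
                    xa = counts[a][sel]
                    xb = counts[b][sel]
                    la = np.log2(xa + 0.5)
                    lb = np.log2(xb + 0.5)
                    M = la - lb
                    A = 0.5 * (la + lb)
                    if np.ptp(A) < 1e-9:
                        fit = np.full(M.size, M.mean())
                    else:
                        # focal differential signal must not bend the trend:
                        # fit on |M - median| <= 3 MAD pixels, then evaluate
                        # everywhere by interpolation in A
                        med = np.median(M)
                        mad = np.median(np.abs(M - med)) + 1e-12
                        fit_sel = np.abs(M - med) <= 3.0 * 1.4826 * mad
                        if fit_sel.sum() < min_stratum or np.ptp(A[fit_sel]) < 1e-9:
                            fit_sel = np.ones(M.size, dtype=bool)
                        # delta collapses near-duplicate abscissae: O(n) not O(n^2)
                        curve = lowess(
                            M[fit_sel], A[fit_sel], frac=loess_frac,
                            delta=0.01 * np.ptp(A[fit_sel]),
                        )
                        fit = np.interp(A, curve[:, 0], curve[:, 1])
                    counts[a][sel] = np.maximum(
                        2.0 ** (la - fit / 2.0) - 0.5, 0.0
                    )
                    counts[b][sel] = np.maximum(
                        2.0 ** (lb + fit / 2.0) - 0.5, 0.0
                    )
    out = []
    for t, c in zip(tables, counts):
        t2 = t.copy()
        t2["count"] = c
        t2.attrs["skipped_strata"] = skipped
        out.append(t2)
    return out


@dataclass
class DciTable:
    """Per-pixel two-condition test results."""

    table: pd.DataFrame  # bin_i, bin_j, distance, log2cpm, log2fc, p, padj, direction
    resolution: int
    chrom: str = "chrS"

    def directional(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    def write(self, path) -> None:
        t = self.table.copy()
        t.insert(0, "chrom", self.chrom)
        t.to_csv(path, sep="\t", index=False)


def dci_test(
    tables_1: list[pd.DataFrame],
    tables_2: list[pd.DataFrame],
    resolution: int,
    cpm_min: float = 2.0,
    lfc_min: float = 1.2,
    q_max: float = 0.05,
    max_span_bp: int = 2_000_000,
    chrom: str = "chrS",
) -> DciTable:
    """Exact conditional test per pixel with edgeR-style filters.

    ``tables_*`` are normalized pixel tables (>= 2 replicates each).
    The test conditions the condition-2 pixel total on the pixel grand
    total with success probability given by the library-size ratio;
    direction is set only when all three filters pass.
    """
    if len(tables_1) < 2 or len(tables_2) < 2:
        raise ValueError("need at least two replicates per condition")
    base = tables_1[0][["bin_i", "bin_j", "distance"]].reset_index(drop=True)
    t1 = np.sum([t["count"].to_numpy(dtype=float) for t in tables_1], axis=0)
    t2 = np.sum([t["count"].to_numpy(dtype=float) for t in tables_2], axis=0)
    lib1, lib2 = t1.sum(), t2.sum()
    p_null = lib2 / (lib1 + lib2)

    n_samples = len(tables_1) + len(tables_2)
    mean_lib = (lib1 + lib2) / n_samples
    cpm = ((t1 + t2) / n_samples + 0.5) / (mean_lib + 1.0) * 1e6
    log2cpm = np.log2(cpm)
    # library-size-adjusted fold change
    log2fc = np.log2((t2 / lib2 + 0.5 / lib2) / (t1 / lib1 + 0.5 / lib1))

    x2 = np.round(t2).astype(int)
    tot = np.round(t1 + t2).astype(int)
    span_ok = base["distance"].to_numpy() <= max_span_bp
    test_idx = np.flatnonzero(span_ok & (tot > 0))
    pvals = np.ones(len(base))
    # vectorized two-sided binomial via minimum-likelihood summation is
    # expensive; use the central-p doubling approximation refined by
    # scipy for moderate totals
    from scipy.stats import binom

    k = x2[test_idx]
    nn = tot[test_idx]
    cdf = binom.cdf(k, nn, p_null)
    sf = binom.sf(k - 1, nn, p_null)
    pvals[test_idx] = np.minimum(2 * np.minimum(cdf, sf), 1.0)

    padj = np.ones(len(base))
    padj[test_idx] = _bh(pvals[test_idx])

    direction = np.full(len(base), "ns", dtype=object)
    passing = (
        span_ok
        & (log2cpm > cpm_min)
        & (np.abs(log2fc) > lfc_min)
        & (padj < q_max)
    )
    direction[passing & (log2fc > 0)] = "up"
    direction[passing & (log2fc < 0)] = "down"

    out = base.copy()
    out["log2cpm"] = log2cpm
    out["log2fc"] = log2fc
    out["p"] = pvals
    out["padj"] = np.maximum(padj, pvals)
    out["direction"] = direction
    return DciTable(table=out, resolution=resolution, chrom=chrom)


def _bh(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Per-TAD summaries
# ---------------------------------------------------------------------------

def tad_dci_summary(
    dcis: DciTable,
    tads,
    covariates: pd.DataFrame | None = None,
    rearrangement: pd.DataFrame | None = None,
    compartment: pd.DataFrame | None = None,
    flank_bp: int = 80_000,
    min_dci: int = 10,
    min_dci_rule: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TAD up/down DCI counts, down fraction and covariate means.

    A directional DCI is counted for a TAD when both pixel ends fall
    inside the TAD extended by ``flank_bp`` (clipped at the chromosome
    edge).  TADs are retained when n_up + n_down >= ``min_dci``
    (``min_dci_rule='sum'``) or when either class alone reaches it
    (``'either'``).  ``covariates`` is a per-bin DataFrame (one column
    per covariate) averaged over the TAD body.

    Returns (summary table, Spearman correlation table).
    """
    d = dcis.directional()
    res = dcis.resolution
    fl = int(round(flank_bp / res))
    rows = []
    for k, (s, e) in enumerate(tads.bounds()):
        lo, hi = max(s - fl, 0), e + fl
        sel = (d["bin_i"] >= lo) & (d["bin_i"] < hi) & (d["bin_j"] >= lo) & (d["bin_j"] < hi)
        sub = d[sel]
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        keep = (
            (n_up + n_down) >= min_dci
            if min_dci_rule == "sum"
            else max(n_up, n_down) >= min_dci
        )
        if not keep:
            continue
        row = {
            "tad": k, "start_bin": s, "end_bin": e,
            "n_up": n_up, "n_down": n_down,
            "downFrac": n_down / (n_up + n_down),
        }
        if covariates is not None:
            for col in covariates.columns:
                row[col] = float(np.nanmean(covariates[col].to_numpy()[s:e]))
        if rearrangement is not None:
            lab = rearrangement.loc[rearrangement["target_id"] == k, "label"]
            row["rearrangement"] = lab.iloc[0] if len(lab) else ""
        if compartment is not None:
            lab = compartment.loc[compartment["tad"] == k, "label"]
            row["compartment"] = lab.iloc[0] if len(lab) else ""
        rows.append(row)
    summary = pd.DataFrame(rows)
    if len(summary):
        summary["group"] = np.where(summary["downFrac"] >= 0.5, "high", "low")

    corr_rows = []
    if covariates is not None and len(summary) >= 3:
        for col in covariates.columns:
            rho, p = stats.spearmanr(summary["downFrac"], summary[col])
            corr_rows.append({"covariate": col, "subset": "all", "rho": rho, "p": p, "n": len(summary)})
        if "rearrangement" in summary.columns:
            for lab, grp in summary.groupby("rearrangement"):
                if len(grp) < 3:
                    continue
                for col in covariates.columns:
                    rho, p = stats.spearmanr(grp["downFrac"], grp[col])
                    corr_rows.append({"covariate": col, "subset": lab, "rho": rho, "p": p, "n": len(grp)})
    return summary, pd.DataFrame(corr_rows)


@dataclass
class EnrichmentResult:
    odds_ratio: float
    fisher_p: float
    fisher_table: np.ndarray
    logit: pd.DataFrame | None  # per rearrangement type vs unchanged
    separation_flagged: bool = False
    odds_ratio_haldane: float = np.nan  # +0.5 continuity-corrected


def dci_enrichment(summary: pd.DataFrame) -> EnrichmentResult:
    """Compartment/down-group Fisher test and rearrangement logistic model.

    Fisher: 2x2 of compartment (A/B) x group (high/low), cross-product
    odds ratio.  Logistic: high-group indicator ~ rearrangement type with
    'unchanged' as the reference; per-type log odds ratio, Wald p, 95% CI.
    """
    logit_table = None
    separation = False
    or_, fisher_p, tab = np.nan, np.nan, np.zeros((2, 2))
    or_hald = np.nan
    if "compartment" in summary.columns and \
            summary["compartment"].isin(["A", "B"]).any():
        sub = summary[summary["compartment"].isin(["A", "B"])]
        if sub["compartment"].nunique() < 2:
            sub = sub.iloc[0:0]  # one factor level: 2x2 test undefined
        a_hi = ((sub["compartment"] == "A") & (sub["group"] == "high")).sum()
        a_lo = ((sub["compartment"] == "A") & (sub["group"] == "low")).sum()
        b_hi = ((sub["compartment"] == "B") & (sub["group"] == "high")).sum()
        b_lo = ((sub["compartment"] == "B") & (sub["group"] == "low")).sum()
        tab = np.array([[a_hi, a_lo], [b_hi, b_lo]], dtype=float)
        if tab.sum() > 0:
            or_, fisher_p = stats.fisher_exact(tab)
            or_hald = ((tab[0, 0] + 0.5) * (tab[1, 1] + 0.5)
                       / ((tab[0, 1] + 0.5) * (tab[1, 0] + 0.5)))
            if 0 in tab:
                warnings.warn(
                    "zero cell in the 2x2 table; cross-product odds ratio "
                    "is degenerate, see odds_ratio_haldane"
                )

    if "rearrangement" in summary.columns:
        sub = summary[summary["rearrangement"] != ""]
        levels = [l for l in sub["rearrangement"].unique() if l != "unchanged"]
        if "unchanged" in sub["rearrangement"].values and levels:
            y = (sub["group"] == "high").astype(int).to_numpy()
            X = pd.DataFrame({"const": 1.0}, index=sub.index)
            for l in levels:
                X[l] = (sub["rearrangement"] == l).astype(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=False)
                ci = fit.conf_int()
                logit_table = pd.DataFrame(
                    {
                        "type": levels,
                        "logOR": [fit.params[l] for l in levels],
                        "wald_p": [fit.pvalues[l] for l in levels],
                        "ci_lo": [ci.loc[l, 0] for l in levels],
                        "ci_hi": [ci.loc[l, 1] for l in levels],
                    }
                )
                if np.abs(fit.params).max() > 15:
                    separation = True
            except Exception:
                separation = True
    return EnrichmentResult(
        odds_ratio=float(or_), fisher_p=float(fisher_p), fisher_table=tab,
        logit=logit_table, separation_flagged=separation,
        odds_ratio_haldane=float(or_hald),
    )
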