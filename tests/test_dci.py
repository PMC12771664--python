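"""Differential-interaction normalization, testing, per-TAD summaries
and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senhic import dci
from senhic.domains import tadset_from_bounds
from senhic.matrix import ContactMatrix


@pytest.fixture(scope="module")
def small_tables(rng_mod=None):
    rng = np.random.default_rng(7)
    n, res = 200, 10_000
    iu = np.triu_indices(n, 1)
    lam = 2000.0 / (iu[1] - iu[0])
    m = np.zeros((n, n))
    m[iu] = rng.poisson(lam)
    m += np.triu(m, 1).T
    cm = ContactMatrix(m, res)
    return dci.pixel_table(cm)


class TestJointNormalize:
    def test_identical_samples_unchanged(self, small_tables):
        t = small_tables
        a, b = dci.joint_normalize([t, t.copy()])
        assert np.max(np.abs(a["count"] - t["count"]) / (t["count"] + 1)) < 1e-8

    def test_global_scaling_removed(self, small_tables):
        t = small_tables
        t2 = t.copy()
        t2["count"] = t["count"] * 2.0
        a, b = dci.joint_normalize([t, t2])
        strata = dci._distance_strata(t["distance"].to_numpy(dtype=float))
        for s in np.unique(strata):
            sel = strata == s
            if sel.sum() < 30:
                continue
            med = np.median(np.log2(a["count"][sel] + 0.5)
                            - np.log2(b["count"][sel] + 0.5))
            assert abs(med) <= 0.05

    def test_distance_dependent_trend_removed(self, small_tables):
        t = small_tables
        t2 = t.copy()
        t2["count"] = t["count"] * (1.0 + t["distance"] / 2e7)
        a, b = dci.joint_normalize([t, t2])
        strata = dci._distance_strata(t["distance"].to_numpy(dtype=float))
        for s in np.unique(strata):
            sel = strata == s
            if sel.sum() < 30:
                continue
            med = np.median(np.log2(a["count"][sel] + 0.5)
                            - np.log2(b["count"][sel] + 0.5))
            assert abs(med) < 0.1

    def test_mismatched_pixel_sets_rejected(self, small_tables):
        t2 = small_tables.iloc[:-5].reset_index(drop=True)
        with pytest.raises(ValueError):
            dci.joint_normalize([small_tables, t2])


def make_tables(counts_by_sample, distance_bp=500_000):
    """Pixel tables with one row per pixel from explicit count vectors."""
    n_pix = len(counts_by_sample[0])
    base = pd.DataFrame(
        {"bin_i": np.arange(n_pix), "bin_j": np.arange(n_pix) + 50,
         "distance": distance_bp}
    )
    out = []
    for c in counts_by_sample:
        t = base.copy()
        t["count"] = np.asarray(c, dtype=float)
        out.append(t)
    return out


class TestDciTest:
    def test_strong_fold_with_low_cpm_stays_ns(self):
        """A pixel below the log2CPM floor is never directional no matter
        the fold change."""
        rng = np.random.default_rng(1)
        base = rng.poisson(200, 20_000).astype(float)
        t1a, t1b = base.copy(), rng.poisson(200, 20_000).astype(float)
        t2a, t2b = base.copy(), rng.poisson(200, 20_000).astype(float)
        # pixel 0: tiny counts but 20x fold
        for t in (t1a, t1b):
            t[0] = 1
        for t in (t2a, t2b):
            t[0] = 20
        tabs = make_tables([t1a, t1b, t2a, t2b])
        res = dci.dci_test(tabs[:2], tabs[2:], 10_000)
        row = res.table.iloc[0]
        assert row["log2cpm"] <= 2.0
        assert row["direction"] == "ns"

    def test_direction_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(2)
        a = [rng.poisson(80, 2000).astype(float) for _ in range(2)]
        b = [rng.poisson(80, 2000).astype(float) for _ in range(2)]
        for t in b:
            t[:50] *= 6  # strong planted change
        tabs = make_tables(a + b)
        fwd = dci.dci_test(tabs[:2], tabs[2:], 10_000)
        rev = dci.dci_test(tabs[2:], tabs[:2], 10_000)
        f = fwd.table["direction"].to_numpy()
        r = rev.table["direction"].to_numpy()
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert all(r[i] == swap[f[i]] for i in range(len(f)))
        assert (f[:50] == "up").mean() > 0.9

    def test_single_replicate_condition_rejected(self):
        tabs = make_tables([[1.0], [1.0], [1.0]])
        with pytest.raises(ValueError):
            dci.dci_test(tabs[:1], tabs[1:], 10_000)

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(3)
        tabs = make_tables([rng.poisson(30, 500).astype(float) for _ in range(4)])
        res = dci.dci_test(tabs[:2], tabs[2:], 10_000)
        assert (res.table["padj"] >= res.table["p"] - 1e-12).all()


def make_dci_table(pixels, res=10_000):
    """pixels: list of (bin_i, bin_j, direction)."""
    t = pd.DataFrame(pixels, columns=["bin_i", "bin_j", "direction"])
    t["distance"] = (t["bin_j"] - t["bin_i"]) * res
    t["log2cpm"] = 5.0
    t["log2fc"] = np.where(t["direction"] == "up", 2.0,
                           np.where(t["direction"] == "down", -2.0, 0.0))
    t["p"] = 0.001
    t["padj"] = 0.001
    return dci.DciTable(table=t, resolution=res)


class TestTadSummary:
    def test_all_down_tad_retained_with_unit_downfrac(self):
        pix = [(10, 20, "down")] * 12
        d = make_dci_table(pix)
        tads = tadset_from_bounds([(0, 50)], 10_000)
        summary, _ = dci.tad_dci_summary(d, tads)
        assert len(summary) == 1
        assert summary.loc[0, "downFrac"] == 1.0
        assert summary.loc[0, "group"] == "high"

    def test_nine_directional_dcis_excluded_under_sum_rule(self):
        pix = [(10, 20, "up")] * 4 + [(12, 22, "down")] * 5
        d = make_dci_table(pix)
        tads = tadset_from_bounds([(0, 50)], 10_000)
        summary, _ = dci.tad_dci_summary(d, tads, min_dci=10)
        assert len(summary) == 0
        # either-class reading keeps it only if one class alone reaches 10
        summary2, _ = dci.tad_dci_summary(d, tads, min_dci=5,
                                          min_dci_rule="either")
        assert len(summary2) == 1

    def test_flank_captures_pixels_just_outside_tad(self):
        pix = [(52, 60, "down")] * 10  # TAD is [0, 55); flank 80 kb = 8 bins
        d = make_dci_table(pix)
        tads = tadset_from_bounds([(0, 55)], 10_000)
        with_flank, _ = dci.tad_dci_summary(d, tads, flank_bp=80_000)
        without, _ = dci.tad_dci_summary(d, tads, flank_bp=0)
        assert len(with_flank) == 1
        assert len(without) == 0

    def test_spearman_matches_bruteforce_ranks(self):
        """Constructed 8-TAD summary: rho equals the exhaustive rank
        computation."""
        downfrac = np.array([0.9, 0.8, 0.75, 0.6, 0.4, 0.3, 0.2, 0.1])
        covariate = np.array([2.0, 1.5, 1.9, 1.0, 0.7, 0.9, 0.2, 0.1])
        pix = []
        tad_bounds = [(k * 10, k * 10 + 10) for k in range(8)]
        for k, f in enumerate(downfrac):
            nd = int(round(20 * f))
            s = tad_bounds[k][0]
            pix += [(s + 1, s + 5, "down")] * nd + [(s + 2, s + 6, "up")] * (20 - nd)
        d = make_dci_table(pix)
        tads = tadset_from_bounds(tad_bounds, 10_000)
        cov = pd.DataFrame({"x": np.repeat(covariate, 10)})
        summary, corr = dci.tad_dci_summary(d, tads, covariates=cov, flank_bp=0)
        # brute-force Spearman: Pearson on ranks
        rx = pd.Series(summary["downFrac"]).rank()
        ry = pd.Series(summary["x"]).rank()
        brute = np.corrcoef(rx, ry)[0, 1]
        got = corr.loc[(corr["covariate"] == "x") & (corr["subset"] == "all"),
                       "rho"].iloc[0]
        assert got == pytest.approx(brute)


class TestEnrichment:
    def summary_from_table(self, a_hi, a_lo, b_hi, b_lo):
        rows = []
        for comp_lab, grp, cnt in [("A", "high", a_hi), ("A", "low", a_lo),
                                   ("B", "high", b_hi), ("B", "low", b_lo)]:
            rows += [{"compartment": comp_lab, "group": grp}] * cnt
        df = pd.DataFrame(rows)
        df["downFrac"] = np.where(df["group"] == "high", 0.8, 0.2)
        return df

    def test_balanced_table_gives_unit_odds_ratio(self):
        res = dci.dci_enrichment(self.summary_from_table(25, 25, 25, 25))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_cross_product_odds_ratio_and_exact_p(self):
        res = dci.dci_enrichment(self.summary_from_table(30, 10, 10, 30))
        assert res.odds_ratio == pytest.approx(9.0)
        # oracle: exhaustive hypergeometric two-sided p
        p_oracle = stats.fisher_exact([[30, 10], [10, 30]])[1]
        table_p = stats.hypergeom(80, 40, 40)
        probs = [table_p.pmf(k) for k in range(41)]
        p_brute = sum(p for k, p in enumerate(probs)
                      if p <= table_p.pmf(30) + 1e-12)
        assert res.fisher_p == pytest.approx(p_oracle)
        assert res.fisher_p == pytest.approx(p_brute, rel=1e-6)

    def test_logistic_recovers_planted_log_odds(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 20
        true_logor = np.log((0.3 / 0.7) / (0.6 / 0.4))
        for _ in range(reps):
            n = 400
            types = rng.choice(["unchanged", "shift"], n)
            p = np.where(types == "shift", 0.3, 0.6)
            high = rng.random(n) < p
            df = pd.DataFrame({
                "compartment": "A", "group": np.where(high, "high", "low"),
                "rearrangement": types,
                "downFrac": np.where(high, 0.8, 0.2),
            })
            res = dci.dci_enrichment(df)
            row = res.logit.set_index("type").loc["shift"]
            if row["ci_lo"] <= true_logor <= row["ci_hi"]:
                hits += 1
        assert hits >= 0.9 * reps
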