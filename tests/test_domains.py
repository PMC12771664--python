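"""Insulation/TAD calling, ATA, stability metrics, differential TADs,
rearrangement classification and compartment assignment."""

import numpy as np
import pandas as pd
import pytest

from senhic import domains as dom
from senhic import matrix as mx
from senhic import simulate as sim


def toeplitz_balanced(n=80, res=10_000):
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return mx.ContactMatrix(20.0 / (idx + 1.0), res, balanced=True)


class TestInsulation:
    def test_toeplitz_matrix_has_flat_score_and_no_boundaries(self):
        cm = toeplitz_balanced()
        tr = dom.insulation(cm, window_bp=50_000)
        finite = tr.score[np.isfinite(tr.score)]
        assert np.allclose(finite, finite[0], atol=1e-9)
        assert tr.boundaries.size == 0

    def test_two_block_matrix_boundary_at_junction(self):
        """Two abutting 25-bin enriched blocks: the unique boundary sits
        at the junction within one bin (brute-force verifiable score)."""
        n, k = 50, 25
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 10.0 / (idx + 1.0)
        block = np.zeros((n, n), dtype=bool)
        block[:k, :k] = True
        block[k:, k:] = True
        m[block] *= 3.0
        cm = mx.ContactMatrix(m, 10_000, balanced=True)
        tr = dom.insulation(cm, window_bp=50_000)
        assert tr.boundaries.size == 1
        assert abs(int(tr.boundaries[0]) - k) <= 1

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            dom.insulation(toeplitz_balanced(n=8), window_bp=50_000)

    def test_planted_boundary_recovery_f1(self, domain_sim):
        tr = dom.insulation(domain_sim["bal"], window_bp=500_000)
        planted = [b for b in domain_sim["truth"].boundaries
                   if 0 < b < domain_sim["bal"].n_bins]
        called = list(tr.boundaries)
        tp = sum(any(abs(c - p) <= 1 for c in called) for p in planted)
        prec = sum(any(abs(c - p) <= 1 for p in planted) for c in called) / max(len(called), 1)
        rec = tp / len(planted)
        f1 = 2 * prec * rec / (prec + rec)
        assert f1 >= 0.9


class TestCallTads:
    def track(self, boundaries, n=60, strengths=None):
        tr = dom.InsulationTrack(
            score=np.zeros(n), window_bins=5, resolution=10_000,
            boundaries=np.array(boundaries, dtype=int),
            boundary_strength=np.array(strengths if strengths is not None
                                       else [1.0] * len(boundaries)),
        )
        return tr

    def test_two_boundaries_delimit_two_tads(self):
        ts = dom.call_tads(self.track([25]), min_tad_bins=5)
        assert ts.bounds() == [(0, 25), (25, 60)]

    def test_short_tad_merged_into_neighbor_by_weaker_boundary(self):
        ts = dom.call_tads(self.track([20, 23, 40], strengths=[1.0, 0.1, 1.0]),
                           min_tad_bins=5)
        assert ts.bounds() == [(0, 20), (20, 40), (40, 60)]

    def test_no_boundaries_gives_flagged_whole_chromosome_tad(self):
        ts = dom.call_tads(self.track([]), min_tad_bins=5)
        assert ts.bounds() == [(0, 60)]
        assert ts.flagged

    def test_oversized_min_tad_collapses_to_single_flagged_tad(self):
        ts = dom.call_tads(self.track([20, 40]), min_tad_bins=30)
        assert len(ts) == 1
        assert ts.flagged

    def test_planted_tad_count_recovered(self, domain_sim):
        tr = dom.insulation(domain_sim["bal"], window_bp=500_000)
        ts = dom.call_tads(tr, min_tad_bins=20)
        assert abs(len(ts) - 8) <= 1


class TestAta:
    def test_uniform_oe_pileup_is_flat_with_unit_score(self):
        cm = mx.ContactMatrix(np.ones((120, 120)), 10_000, balanced=True)
        ts = dom.tadset_from_bounds([(20, 50), (60, 100)], 10_000)
        res = dom.ata_pileup(cm, ts, rescale_size=21)
        assert res.score == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(res.pileup, 1.0, atol=1e-6)

    def test_single_tad_pileup_equals_its_own_window(self, domain_sim):
        bal = domain_sim["bal"]
        s, e = domain_sim["truth"].tads[2].start, domain_sim["truth"].tads[2].end
        one = dom.ata_pileup(bal, dom.tadset_from_bounds([(s, e)], bal.resolution),
                             rescale_size=33)
        assert one.n_tads == 1
        assert one.pileup.shape == (33, 33)

    def test_empty_tad_list_rejected(self, domain_sim):
        with pytest.raises(ValueError):
            dom.ata_pileup(domain_sim["bal"],
                           dom.tadset_from_bounds([], 10_000))


class TestStability:
    def test_isolated_tad_has_unit_connectivity(self):
        n = 60
        m = np.zeros((n, n))
        m[10:30, 10:30] = 5.0  # contacts only inside the TAD
        cm = mx.ContactMatrix(m, 10_000)
        ts = dom.tadset_from_bounds([(10, 30)], 10_000)
        out = dom.tad_stability(cm, ts, metrics=("iTC",))
        assert out["iTC"].iloc[0] == pytest.approx(1.0)

    def test_itc_bounded_in_unit_interval(self, domain_sim):
        ts = dom.tadset_from_bounds(
            [(t.start, t.end) for t in domain_sim["truth"].tads],
            domain_sim["bal"].resolution,
        )
        out = dom.tad_stability(domain_sim["raw"], ts, metrics=("iTC",))
        assert ((out["iTC"] > 0) & (out["iTC"] <= 1)).all()

    def test_toeplitz_background_gives_unit_consolidation(self):
        cm = toeplitz_balanced(n=300)
        ts = dom.tadset_from_bounds([(100, 200)], 10_000)
        out = dom.tad_stability(cm, ts, metrics=("CS",))
        assert out["CS"].iloc[0] == pytest.approx(1.0)

    def test_sub_threshold_tad_has_undefined_consolidation(self):
        cm = toeplitz_balanced(n=100)
        ts = dom.tadset_from_bounds([(10, 40)], 10_000)  # 300 kb < 400 kb
        out = dom.tad_stability(cm, ts)
        assert np.isnan(out["CS"].iloc[0])

    def test_dod_matches_bruteforce_on_five_bin_fixture(self):
        """A 5-bin TAD with 3 designated top pixels: DoD equals the mean
        pairwise pixel distance over those pixels divided by 5."""
        n = 5
        m = np.ones((n, n))
        tops = [(0, 2), (1, 4), (2, 3)]
        for i, j in tops:
            m[i, j] = m[j, i] = 10.0
        cm = mx.ContactMatrix(m, 10_000)  # raw: top pixels picked by value
        ts = dom.tadset_from_bounds([(0, 5)], 10_000)
        out = dom.tad_stability(cm, ts, metrics=("DoD",), dod_top_quantile=0.8)
        pts = np.array(tops, dtype=float)
        dists = [np.linalg.norm(pts[a] - pts[b])
                 for a in range(3) for b in range(a + 1, 3)]
        assert out["DoD"].iloc[0] == pytest.approx(np.mean(dists) / n)


class TestDiffTads:
    def test_identical_colinear_scores_yield_no_differentials(self):
        x = np.linspace(0.4, 0.8, 15)
        r = dom.diff_tads(x, x.copy())
        assert (r.table["p"] >= 0.05).all()
        assert (r.table["direction"] == "ns").all()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            dom.diff_tads(np.ones(12), np.ones(12))

    def test_too_few_tads_rejected(self):
        with pytest.raises(ValueError):
            dom.diff_tads(np.arange(5.0), np.arange(5.0) + 0.1)

    def test_null_calibration_on_bivariate_normal(self, rng):
        fracs = []
        for _ in range(10):
            Z = rng.multivariate_normal([0.7, 0.7],
                                        [[0.02, 0.018], [0.018, 0.02]], 500)
            r = dom.diff_tads(Z[:, 0], Z[:, 1])
            fracs.append((r.table["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_direction_follows_score_shift(self, rng):
        x = rng.normal(0.7, 0.1, 100)
        y = x + rng.normal(0, 0.005, 100)
        y[:5] -= 0.2
        r = dom.diff_tads(x, y)
        assert (r.table.loc[:4, "direction"] == "down").all()


class TestRearrangements:
    def ts(self, bounds):
        return dom.tadset_from_bounds(bounds, 40_000)

    def test_identical_sets_are_unchanged(self):
        ref = self.ts([(0, 20), (20, 40), (40, 60)])
        out = dom.classify_rearrangements(ref, self.ts([(0, 20), (20, 40), (40, 60)]))
        assert (out["label"] == "unchanged").all()

    def test_split_event(self):
        ref = self.ts([(0, 40), (40, 60)])
        out = dom.classify_rearrangements(ref, self.ts([(0, 22), (22, 40), (40, 60)]))
        assert list(out["label"]) == ["split", "split", "unchanged"]

    def test_merge_event(self):
        ref = self.ts([(0, 20), (20, 40), (40, 60)])
        out = dom.classify_rearrangements(ref, self.ts([(0, 40), (40, 60)]))
        assert list(out["label"]) == ["merge", "unchanged"]
        assert out.loc[0, "ref_ids"] == "0,1"

    def test_shift_event(self):
        ref = self.ts([(0, 20), (20, 60)])
        out = dom.classify_rearrangements(ref, self.ts([(3, 20), (20, 60)]))
        assert list(out["label"]) == ["shift", "unchanged"]

    def test_complex_event(self):
        ref = self.ts([(0, 20), (20, 40), (40, 60)])
        out = dom.classify_rearrangements(ref, self.ts([(10, 55)]))
        assert list(out["label"]) == ["complex"]

    def test_tolerance_absorbs_one_bin_jitter(self):
        ref = self.ts([(0, 20), (20, 40)])
        out = dom.classify_rearrangements(ref, self.ts([(0, 21), (21, 40)]))
        assert (out["label"] == "unchanged").all()

    def test_every_target_gets_exactly_one_label(self, domain_sim):
        tr = dom.insulation(domain_sim["bal"], window_bp=500_000)
        called = dom.call_tads(tr, min_tad_bins=20)
        planted = dom.tadset_from_bounds(
            [(t.start, t.end) for t in domain_sim["truth"].tads],
            domain_sim["bal"].resolution,
        )
        out = dom.classify_rearrangements(planted, called)
        assert len(out) == len(called)
        assert out["label"].isin(dom.REARRANGEMENT_LABELS).all()

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            dom.classify_rearrangements(self.ts([(0, 30), (20, 50)]),
                                        self.ts([(0, 30)]))


class TestAssignCompartment:
    def profile(self, labels):
        lab = np.array(labels, dtype=object)
        from senhic.compartments import CompartmentProfile

        return CompartmentProfile(
            pc1=np.where(lab == "A", 1.0, np.where(lab == "B", -1.0, np.nan)),
            labels=lab, resolution=10_000,
        )

    def test_pure_a_tad(self):
        out = dom.assign_tad_compartment(
            dom.tadset_from_bounds([(0, 4)], 10_000), self.profile(["A"] * 6)
        )
        assert (out.loc[0, "frac_A"], out.loc[0, "frac_B"]) == (1.0, 0.0)

    def test_even_split(self):
        out = dom.assign_tad_compartment(
            dom.tadset_from_bounds([(0, 4)], 10_000),
            self.profile(["A", "A", "B", "B"]),
        )
        assert out.loc[0, "frac_A"] == pytest.approx(0.5)

    def test_thirty_seventy(self):
        labels = ["A"] * 3 + ["B"] * 7
        out = dom.assign_tad_compartment(
            dom.tadset_from_bounds([(0, 10)], 10_000), self.profile(labels)
        )
        assert out.loc[0, "frac_A"] == pytest.approx(0.3)
        assert out.loc[0, "frac_B"] == pytest.approx(0.7)
        assert out.loc[0, "label"] == "B"

    def test_unlabeled_tad_is_missing(self):
        out = dom.assign_tad_compartment(
            dom.tadset_from_bounds([(0, 3)], 10_000),
            self.profile(["", "", "", "A"]),
        )
        assert np.isnan(out.loc[0, "frac_A"])
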