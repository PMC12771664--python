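"""Matrix operations: ICE, O/E, P(s), down-sampling, coverage stats."""

import numpy as np
import pandas as pd
import pytest

from senhic import matrix as mx
from senhic import simulate as sim


def toeplitz_matrix(n=30, res=100_000, base=10.0):
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return mx.ContactMatrix(base / (idx + 1.0), res)


class TestIceBalance:
    def test_all_ones_matrix_balances_to_uniform(self):
        cm = mx.ContactMatrix(np.ones((4, 4)), 100_000)
        bal = mx.ice_balance(cm, mask_fraction=0.0)
        assert np.allclose(bal.bias, bal.bias[0])
        assert np.allclose(bal.counts, bal.counts[0, 0])

    def test_construct_and_invert_recovers_matrix(self, rng):
        """Inflating a balanced matrix with known biases and rebalancing
        recovers it up to a global scale, to 1e-6 relative."""
        n = 40
        raw = np.abs(rng.normal(5, 1, (n, n)))
        raw = (raw + raw.T) / 2
        ref = mx.ice_balance(mx.ContactMatrix(raw, 100_000),
                             tol=1e-10, max_iter=1000, mask_fraction=0.0)
        b = rng.lognormal(0, 0.3, n)
        inflated = ref.counts * np.outer(b, b)
        out = mx.ice_balance(mx.ContactMatrix(inflated, 100_000),
                             tol=1e-10, max_iter=1000, mask_fraction=0.0)
        ratio = out.counts / ref.counts
        assert np.nanmax(np.abs(ratio / np.nanmean(ratio) - 1)) < 1e-6

    def test_zero_coverage_bin_is_masked_not_fatal(self):
        m = np.ones((6, 6))
        m[2, :] = 0.0
        m[:, 2] = 0.0
        bal = mx.ice_balance(mx.ContactMatrix(m, 100_000), mask_fraction=0.0)
        assert bal.mask[2]
        assert np.isnan(bal.bias[2])
        assert np.isfinite(bal.bias[~bal.mask]).all()
        assert bal.converged

    def test_balancing_is_idempotent(self, domain_sim):
        bal = domain_sim["bal"]
        again = mx.ice_balance(
            mx.ContactMatrix(np.nan_to_num(bal.counts), bal.resolution),
            mask_fraction=0.0,
        )
        b = again.bias[~again.mask]
        assert np.nanmax(np.abs(b / b.mean() - 1)) < 1e-4

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(mx.BalanceError):
            mx.ice_balance(mx.ContactMatrix(np.zeros((5, 5)), 100_000))


class TestObservedExpected:
    def test_toeplitz_gives_unit_oe(self):
        cm = toeplitz_matrix()
        cm.balanced = True
        _, oe = mx.observed_expected(cm)
        assert np.allclose(oe, 1.0)

    def test_doubled_pixel_matches_bruteforce_per_distance_mean(self):
        n = 20
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 10.0 / (idx + 1.0)
        m[3, 8] *= 2
        m[8, 3] = m[3, 8]
        cm = mx.ContactMatrix(m, 100_000, balanced=True)
        _, oe = mx.observed_expected(cm)
        s = 5
        brute_mean = np.diagonal(m, s).mean()
        assert oe[3, 8] == pytest.approx(m[3, 8] / brute_mean)

    def test_oe_times_expected_reconstructs_matrix(self, domain_sim):
        bal = domain_sim["bal"]
        exp, oe = mx.observed_expected(bal)
        n = bal.n_bins
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        recon = oe * exp[idx]
        good = np.isfinite(bal.counts) & np.isfinite(recon)
        assert np.allclose(recon[good], bal.counts[good])

    def test_fully_masked_input_gives_all_missing_profile(self):
        cm = mx.ContactMatrix(np.full((5, 5), np.nan), 100_000, balanced=True,
                              mask=np.ones(5, dtype=bool))
        exp, oe = mx.observed_expected(cm)
        assert np.isnan(exp).all()
        assert np.isnan(oe).all()


class TestContactDecay:
    def test_probabilities_sum_to_one(self, domain_sim):
        dec = mx.contact_decay(domain_sim["raw"])
        assert dec.table["prob"].sum() == pytest.approx(1.0)

    def test_analytic_intensity_recovers_planted_exponent(self):
        cfg = sim.SimConfig(chrom_length=60_000_000, bin_size=100_000,
                            alpha=1.0, depth=5e6)
        lam = sim.intensity(cfg)
        cm = mx.ContactMatrix(lam, 100_000)
        dec = mx.contact_decay(cm)
        assert dec.slope == pytest.approx(-1.0, abs=0.02)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            mx.contact_decay(mx.ContactMatrix(np.ones((2, 2)), 100_000))


class TestDownsample:
    def test_target_equal_to_total_is_identity(self):
        cm = toeplitz_matrix()
        cm.counts = np.round(cm.counts * 10)
        out = mx.downsample(cm, int(cm.total()), seed=1)
        assert np.array_equal(out.counts, cm.counts)

    def test_half_target_halves_each_pixel_in_expectation(self, rng):
        n = 12
        m = np.round(np.abs(rng.normal(40, 5, (n, n))))
        m = np.triu(m) + np.triu(m, 1).T
        cm = mx.ContactMatrix(m, 100_000)
        target = int(cm.total() // 2)
        acc = np.zeros_like(m)
        n_seeds = 20
        for s in range(n_seeds):
            acc += mx.downsample(cm, target, seed=s).counts
        mean = acc / n_seeds
        # expectation m/2 (up to the integer-total rounding)
        resid = mean - m * (target / cm.total())
        se = np.sqrt(m / 2 / n_seeds) + 1e-9
        assert (np.abs(resid) < 5 * se).all()

    def test_zero_target_gives_empty_valid_matrix(self):
        cm = toeplitz_matrix()
        cm.counts = np.round(cm.counts)
        out = mx.downsample(cm, 0, seed=0)
        assert out.total() == 0
        assert out.n_bins == cm.n_bins

    def test_exact_total_and_symmetry(self, rng):
        cm = toeplitz_matrix()
        cm.counts = np.round(cm.counts * 7)
        out = mx.downsample(cm, 100, seed=2)
        assert out.total() == 100
        assert np.array_equal(out.counts, out.counts.T)
        assert out.counts.min() >= 0

    def test_overdrawn_target_rejected(self):
        cm = toeplitz_matrix()
        with pytest.raises(ValueError, match="exceeds"):
            mx.downsample(cm, 10**9)


class TestEffectiveResolution:
    def test_all_bins_qualify_at_finest_size(self):
        cov = {10_000: np.full(100, 600), 20_000: np.full(50, 1200)}
        out = mx.effective_resolution(cov, thresholds=(500,))
        assert out[500] == 10_000

    def test_first_qualifying_size_is_selected(self):
        cov10 = np.r_[np.full(79, 600), np.full(21, 10)]   # 79% >= 500
        cov20 = np.r_[np.full(95, 900), np.full(5, 10)]    # 95% >= 500
        out = mx.effective_resolution({10_000: cov10, 20_000: cov20},
                                      thresholds=(500,))
        assert out[500] == 20_000

    def test_unmet_threshold_returns_sentinel(self):
        out = mx.effective_resolution({10_000: np.full(10, 100)},
                                      thresholds=(1000,))
        assert out[1000] is None

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            mx.effective_resolution({})


class TestCisFraction:
    def test_all_cis(self):
        assert mx.cis_fraction(["chr1"] * 5, ["chr1"] * 5) == 1.0

    def test_nine_of_ten(self):
        a = ["chr1"] * 10
        b = ["chr1"] * 9 + ["chr2"]
        assert mx.cis_fraction(a, b) == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.cis_fraction([], [])


def test_hicpro_roundtrip(tmp_path, domain_sim):
    cm = domain_sim["raw"]
    bed, mat = mx.write_hicpro(cm, tmp_path / "m")
    back = mx.read_hicpro(bed, mat)
    assert list(back) == [cm.chrom]
    assert np.array_equal(back[cm.chrom].counts, cm.counts)
    assert back[cm.chrom].resolution == cm.resolution


from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    counts=hnp.arrays(np.int64, (8, 8), elements=st.integers(0, 50)),
    frac=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**16),
)
def test_downsample_invariants_hold_for_arbitrary_matrices(counts, frac, seed):
    """Thinning any symmetric count matrix preserves symmetry and
    non-negativity, hits the target total exactly, and never increases a
    pixel."""
    m = np.triu(counts) + np.triu(counts, 1).T
    cm = mx.ContactMatrix(m.astype(float), 10_000)
    total = int(cm.total())
    target = int(round(frac * total))
    out = mx.downsample(cm, target, seed=seed)
    assert out.total() == target
    assert np.array_equal(out.counts, out.counts.T)
    assert (out.counts >= 0).all()
    assert (out.counts <= cm.counts + 1e-9).all()
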