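"""Monte Carlo sampling, PMF estimation and decorrelation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from twochain.errors import SamplingShortfallError, StitchingError
from twochain.model import HPSequence, ModelParameters, pair_energy
from twochain.sampler import (
    PMFProfile,
    SampleEnsemble,
    UmbrellaWindow,
    draw_well_configurations,
    estimate_pmf,
    integrated_autocorrelation_time,
    mc_sample_single_chain,
    mc_sample_two_chain_window,
    sample_two_chain_pmf,
    well_bounds_from_profile,
)

PARAMS = ModelParameters(epsilon=1.0)


class TestSingleChain:
    def test_frozen_sampler_returns_identical_snapshots(self):
        seq = HPSequence("s", "HPHP")
        ens = mc_sample_single_chain(
            seq, PARAMS, n_sweeps=50, seed=1, max_displacement=0.0, max_rotation=0.0
        )
        assert ens.n > 1
        # pivot proposals with zero angle round-trip through (x - xp) + xp,
        # so "identical" means identical to 1 ulp
        np.testing.assert_allclose(ens.states[0], ens.states[-1], atol=1e-12)

    def test_reproducible_given_seed(self):
        seq = HPSequence("s", "HPHP")
        a = mc_sample_single_chain(seq, PARAMS, 200, seed=5)
        b = mc_sample_single_chain(seq, PARAMS, 200, seed=5)
        c = mc_sample_single_chain(seq, PARAMS, 200, seed=6)
        np.testing.assert_array_equal(a.states, b.states)
        assert not np.array_equal(a.states, c.states)

    def test_excluded_volume_rg_grows_with_length(self):
        # all-P chains are self-avoiding; mean Rg^2 must grow with N
        rgs = []
        for n in (5, 10, 20):
            seq = HPSequence(f"p{n}", "P" * n)
            ens = mc_sample_single_chain(seq, PARAMS, 3000, seed=2)
            delta = ens.states - ens.states.mean(axis=1, keepdims=True)
            rgs.append((delta**2).sum(axis=2).mean())
        assert rgs[0] < rgs[1] < rgs[2]

    def test_bond_length_distribution_matches_boltzmann_quadrature(self):
        """3-bead all-P chain: sampled bond lengths vs direct 1-D quadrature
        of the bond potential with the r^2 Jacobian."""
        from twochain.model import bond_energy

        seq = HPSequence("b3", "PPP")
        ens = mc_sample_single_chain(seq, PARAMS, 20_000, seed=3)
        bonds = np.linalg.norm(np.diff(ens.states, axis=1), axis=2).ravel()
        edges = np.linspace(0.8, 1.15, 8)
        counts, _ = np.histogram(bonds, bins=edges)
        r_fine = np.linspace(0.5, 1.4999, 4000)
        u = np.array([bond_energy(r, PARAMS) for r in r_fine])
        w = np.exp(-u) * r_fine**2
        probs = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (r_fine >= lo) & (r_fine < hi)
            probs.append(np.trapezoid(w[m], r_fine[m]))
        probs = np.array(probs) / np.trapezoid(w, r_fine)
        n_tot = counts.sum()
        tau = integrated_autocorrelation_time(bonds[::2]).tau
        n_eff = n_tot / max(tau, 1.0)
        for c, p in zip(counts, probs):
            se = np.sqrt(p * (1 - p) / n_eff)
            assert abs(c / n_tot - p) < 3 * se + 1e-3


class TestTwoChainWindow:
    def test_hard_bounds_enforced(self):
        seq = HPSequence("s", "HH")
        w = UmbrellaWindow(r_lo=2.0, r_hi=3.0)
        filled = mc_sample_two_chain_window(seq, PARAMS, w, 500, seed=4)
        assert filled.n_samples > 0
        assert filled.r_samples.min() >= 2.0
        assert filled.r_samples.max() < 3.0

    def test_ideal_chains_record_isolated_energy(self):
        # epsilon=0 all-P chains beyond contact range: energy has no
        # interchain part, so it fluctuates around the bonded-only value
        seq = HPSequence("s", "PP")
        params = PARAMS.with_epsilon(0.0)
        w = UmbrellaWindow(r_lo=6.0, r_hi=7.0)
        filled = mc_sample_two_chain_window(seq, params, w, 500, seed=4)
        from twochain.model import bond_energy

        # interchain distance >= 6 - chain extent >> WCA range: recorded
        # energies are exactly the two bonded terms
        for state, e in zip(filled.states[:50], filled.energies[:50]):
            bonds = np.linalg.norm(np.diff(state, axis=1), axis=2).ravel()
            e_bonds = sum(bond_energy(b, params) for b in bonds)
            assert e == pytest.approx(e_bonds, abs=1e-9)

    def test_single_bead_window_histogram_matches_boltzmann(self):
        """Two single H beads in a hard window: the r histogram reweighted by
        4*pi*r^2 must reproduce exp(-u(r))."""
        seq = HPSequence("b", "H")
        w = UmbrellaWindow(r_lo=0.8, r_hi=1.8)
        filled = mc_sample_two_chain_window(seq, PARAMS, w, 30_000, seed=5)
        edges = np.linspace(0.8, 1.8, 11)
        counts, _ = np.histogram(filled.r_samples, bins=edges)
        H = PARAMS.monomer_types["H"]
        r_fine = np.linspace(0.8, 1.8, 4000)
        wgt = np.exp(-pair_energy(r_fine, H, H, PARAMS)) * r_fine**2
        probs = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (r_fine >= lo) & (r_fine < hi)
            probs.append(np.trapezoid(wgt[m], r_fine[m]))
        probs = np.array(probs) / np.trapezoid(wgt, r_fine)
        n_tot = counts.sum()
        tau = integrated_autocorrelation_time(filled.r_samples).tau
        n_eff = n_tot / max(tau, 1.0)
        for c, p in zip(counts, probs):
            se = np.sqrt(p * (1 - p) / n_eff)
            assert abs(c / n_tot - p) < 3 * se + 2e-3

    def test_detailed_balance_two_bead_chi_square(self):
        """Long-run distance distribution of a 2-bead toy vs Boltzmann
        quadrature: chi-square not rejected at alpha=0.01 in >= 9/10 seeds."""
        seq = HPSequence("b", "H")
        H = PARAMS.monomer_types["H"]
        edges = np.linspace(0.9, 1.9, 6)
        r_fine = np.linspace(0.9, 1.9, 3000)
        wgt = np.exp(-pair_energy(r_fine, H, H, PARAMS)) * r_fine**2
        probs = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (r_fine >= lo) & (r_fine < hi)
            probs.append(np.trapezoid(wgt[m], r_fine[m]))
        probs = np.array(probs)
        probs /= probs.sum()
        passes = 0
        for seed in range(10):
            w = UmbrellaWindow(r_lo=0.9, r_hi=1.9)
            filled = mc_sample_two_chain_window(seq, PARAMS, w, 6000, seed=seed)
            tau = integrated_autocorrelation_time(filled.r_samples).tau
            thin = filled.r_samples[:: max(1, int(np.ceil(tau)))]
            counts, _ = np.histogram(thin, bins=edges)
            stat, pval = chisquare(counts, probs * counts.sum())
            passes += pval > 0.01
        assert passes >= 9


class TestEstimatePMF:
    def test_noninteracting_pmf_is_flat_zero(self):
        seq = HPSequence("b", "P")
        params = PARAMS.with_epsilon(0.0)
        _, pmf = sample_two_chain_pmf(seq, params, n_sweeps=8000, seed=6, r_max=4.0)
        m = (pmf.r_grid > 1.5) & np.isfinite(pmf.u_over_kBT)
        z = pmf.u_over_kBT[m] / pmf.statistical_error[m]
        assert np.abs(z).max() < 4.0

    def test_two_bead_pmf_recovers_pair_potential(self, single_bead_pmf, hp_params):
        seq, windows, pmf = single_bead_pmf
        H = hp_params.monomer_types["H"]
        bw = pmf.bin_width
        for r0, u, se in zip(pmf.r_grid, pmf.u_over_kBT, pmf.statistical_error):
            if not np.isfinite(u):
                continue
            rr = np.linspace(max(r0 - bw / 2, 1e-6), r0 + bw / 2, 101)
            uu = pair_energy(rr, H, H, hp_params)
            ref = -np.log(
                np.trapezoid(np.exp(-uu) * rr**2, rr) / np.trapezoid(rr**2, rr)
            )
            assert abs(u - ref) < 3 * se + 1e-3

    def test_synthetic_gaussian_well_windows_recover_generator(self):
        """Windows drawn directly from a known Gaussian-well density."""
        rng = np.random.default_rng(8)
        depth, r0, width = 1.5, 2.0, 0.4

        def u_true(r):
            return -depth * np.exp(-((r - r0) ** 2) / (2 * width**2))

        windows = []
        for lo in np.arange(0.5, 4.5, 0.5):
            hi = lo + 1.0
            r_prop = rng.uniform(lo, hi, 120_000)
            keep = rng.random(len(r_prop)) < np.exp(-u_true(r_prop)) * (
                r_prop**2 / hi**2
            ) / np.exp(depth)
            r_acc = r_prop[keep][:6000]
            w = UmbrellaWindow(r_lo=lo, r_hi=hi)
            w.r_samples = r_acc
            w.states = np.zeros((len(r_acc), 2, 1, 3))
            w.energies = np.zeros(len(r_acc))
            windows.append(w)
        pmf = estimate_pmf(windows, bin_width=0.1, anchor_width=0.5)
        m = np.isfinite(pmf.u_over_kBT) & (pmf.r_grid < 4.0)
        resid = pmf.u_over_kBT[m] - u_true(pmf.r_grid[m])
        # generator anchor differs from the estimated anchor by a constant
        resid -= resid.mean()
        assert np.all(np.abs(resid) < 3 * pmf.statistical_error[m] + 1e-3)

    def test_well_bounds_one_kbt_rule(self):
        r = np.linspace(0.5, 5.0, 451)
        u = np.where(r < 1.0, np.inf, np.where(r < 2.0, -2.0, 0.0))
        (lo, hi), u_min = well_bounds_from_profile(r, u)
        assert u_min == -2.0
        assert lo == pytest.approx(1.0, abs=0.02)
        assert hi == pytest.approx(2.0, abs=0.02)

    def test_non_overlapping_windows_raise(self):
        rng = np.random.default_rng(0)
        w1 = UmbrellaWindow(r_lo=0.5, r_hi=1.0)
        w1.r_samples = rng.uniform(0.5, 1.0, 500)
        w1.states = np.zeros((500, 2, 1, 3))
        w2 = UmbrellaWindow(r_lo=2.0, r_hi=2.5)
        w2.r_samples = rng.uniform(2.0, 2.5, 500)
        w2.states = np.zeros((500, 2, 1, 3))
        with pytest.raises(StitchingError):
            estimate_pmf([w1, w2], bin_width=0.1)

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            estimate_pmf([UmbrellaWindow(r_lo=0.0, r_hi=1.0)])

    def test_window_doubling_leaves_pmf_invariant(self, hp_params):
        seq = HPSequence("b", "H")
        _, coarse = sample_two_chain_pmf(
            seq, hp_params, n_sweeps=8000, seed=9, r_max=4.0,
            window_width=1.0, window_step=0.5,
        )
        _, fine = sample_two_chain_pmf(
            seq, hp_params, n_sweeps=8000, seed=10, r_max=4.0,
            window_width=1.0, window_step=0.25,
        )
        # window sets cover slightly different ranges; compare shared bins
        rc = np.round(coarse.r_grid, 6)
        rf = np.round(fine.r_grid, 6)
        shared, ic, i_f = np.intersect1d(rc, rf, return_indices=True)
        keep = (
            (shared > 0.9)
            & np.isfinite(coarse.u_over_kBT[ic])
            & np.isfinite(fine.u_over_kBT[i_f])
        )
        diff = coarse.u_over_kBT[ic][keep] - fine.u_over_kBT[i_f][keep]
        se = np.sqrt(
            coarse.statistical_error[ic][keep] ** 2
            + fine.statistical_error[i_f][keep] ** 2
        )
        assert np.abs(diff / se).max() < 3.5


class TestAutocorrelation:
    def test_white_noise_tau_near_one(self):
        taus = [
            integrated_autocorrelation_time(
                np.random.default_rng(s).normal(size=20_000)
            ).tau
            for s in range(5)
        ]
        assert abs(np.mean(taus) - 1.0) < 0.15

    def test_alternating_series_flagged(self):
        res = integrated_autocorrelation_time(np.tile([1.0, -1.0], 200))
        assert res.tau >= 1.0
        assert res.truncated_at == 1

    def test_constant_series_degenerate(self):
        res = integrated_autocorrelation_time(np.ones(100))
        assert res.tau == 1.0
        assert res.degenerate

    def test_ar1_matches_closed_form(self):
        phi = 0.8
        rng = np.random.default_rng(12)
        n = 100_000
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + noise[t]
        tau = integrated_autocorrelation_time(x).tau
        expected = (1 + phi) / (1 - phi)  # = 9
        assert abs(tau - expected) / expected < 0.2


class TestWellConfigurations:
    def _windows_with_states(self, r_values, n_beads=1):
        w = UmbrellaWindow(r_lo=0.0, r_hi=10.0)
        m = len(r_values)
        states = np.zeros((m, 2, n_beads, 3))
        states[:, 1, :, 2] = np.asarray(r_values)[:, None]
        w.states = states
        w.r_samples = np.asarray(r_values, dtype=float)
        w.energies = np.zeros(m)
        return [w]

    def _pmf_with_well(self, lo, hi):
        r = np.linspace(0.05, 9.95, 100)
        u = np.where((r >= lo) & (r <= hi), -2.0, 0.0)
        return PMFProfile(
            r_grid=r,
            u_over_kBT=u,
            statistical_error=np.zeros_like(u),
            well_bounds=(lo, hi),
            u_min=-2.0,
        )

    def test_all_snapshots_outside_well_shortfall_zero(self):
        windows = self._windows_with_states(np.linspace(5.0, 9.0, 50))
        pmf = self._pmf_with_well(1.0, 2.0)
        with pytest.raises(SamplingShortfallError) as err:
            draw_well_configurations(windows, pmf, 10, seed=0)
        assert err.value.achievable == 0

    def test_iid_snapshots_returned_in_full(self):
        rng = np.random.default_rng(1)
        windows = self._windows_with_states(rng.uniform(1.0, 2.0, 300))
        pmf = self._pmf_with_well(1.0, 2.0)
        ens = draw_well_configurations(windows, pmf, 50, seed=0)
        assert ens.n == 50
        assert np.all(pmf.in_well(ens.com_distances()))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        windows = self._windows_with_states(rng.uniform(0.5, 3.0, 400))
        pmf = self._pmf_with_well(1.0, 2.5)
        a = draw_well_configurations(windows, pmf, 30, seed=3)
        b = draw_well_configurations(windows, pmf, 30, seed=3)
        np.testing.assert_array_equal(a.states, b.states)

    def test_stride_respects_autocorrelation_of_contact_count(self):
        """Synthetic AR(1) contact-count stream: the chosen stride must be at
        least the closed-form correlation time."""
        phi = 0.6
        expected_tau = (1 + phi) / (1 - phi)  # = 4
        rng = np.random.default_rng(4)
        n = 4000
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal()
        # encode the AR(1) signal as the interchain distance so that the
        # contact count (0 or 1 for single beads) inherits its correlation
        r_vals = np.where(x > 0, 1.5, 5.0)
        w = UmbrellaWindow(r_lo=0.0, r_hi=10.0)
        states = np.zeros((n, 2, 1, 3))
        states[:, 1, 0, 2] = r_vals
        w.states = states
        w.r_samples = np.full(n, 1.5)  # keep everything "in the well"
        w.energies = np.zeros(n)
        pmf = self._pmf_with_well(1.0, 2.0)
        ens = draw_well_configurations([w], pmf, 10, seed=0, rc=3.0)
        assert ens.stride >= 2
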