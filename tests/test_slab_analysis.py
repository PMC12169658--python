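"""Density profiles and coexistence extraction against generator oracles."""

import numpy as np
import pytest
from scipy import constants as C

from cgslab.slab_analysis import (
    DataError,
    SelectionError,
    center_and_profile,
    fit_coexistence,
    mgml_to_uM,
    uM_to_mgml,
)
from cgslab.synthetic import make_synthetic_slab_trajectory

BOX = (50.0, 50.0, 400.0)


@pytest.fixture(scope="module")
def slab_traj():
    """Noise-free synthetic slab with a crisp interface; short chains keep
    the coil-convolution broadening of the interface negligible."""
    return make_synthetic_slab_trajectory(
        400, BOX,
        {"A": {"length": 2, "rho_dense": 300.0, "rho_dilute": 6.0}},
        z0=60.0, interface_width=12.0, seed=5,
    )


class TestProfile:
    def test_uniform_gas_profile_flat(self):
        traj = make_synthetic_slab_trajectory(
            200, BOX,
            {"A": {"length": 2, "rho_dense": 50.0, "rho_dilute": 50.0}},
            seed=3,
        )
        prof = center_and_profile(traj, equilibration_fraction=0.0,
                                  center=False)
        rho = prof.mass_density["A"]
        # flat within ~3 sd of the per-bin sampling (Poisson-like) noise
        counts = rho / rho.mean() * (
            traj.metadata["truth"]["A"]["n_chains"] * prof.n_frames
            * prof.bin_width / BOX[2]
        )
        expected = counts.mean()
        assert np.abs(counts - expected).max() < 4.5 * np.sqrt(expected)

    def test_total_mass_conserved_exactly(self, slab_traj):
        prof = center_and_profile(slab_traj, equilibration_fraction=0.0)
        total_mass_g = (
            prof.mass_density["A"].sum() / 1000.0  # g/cm3 per bin
            * (BOX[0] * BOX[1] * prof.bin_width * 1e-24)
        ) * C.N_A
        expected = slab_traj.mass.sum()
        assert total_mass_g == pytest.approx(expected, rel=1e-9)

    def test_plateaus_match_generator(self, slab_traj):
        prof = center_and_profile(slab_traj, equilibration_fraction=0.0)
        truth = slab_traj.metadata["truth"]["A"]
        rho = prof.mass_density["A"]
        z = prof.z_centers
        dense = rho[np.abs(z) < truth["z0"] - 3 * truth["interface_width"]]
        dilute = rho[np.abs(z) > truth["z0"] + 3 * truth["interface_width"]]
        assert dense.mean() == pytest.approx(truth["rho_dense"], rel=0.02)
        assert dilute.mean() == pytest.approx(truth["rho_dilute"], rel=0.05)

    def test_centering_idempotent(self, slab_traj):
        prof1 = center_and_profile(slab_traj, equilibration_fraction=0.0)
        # a trajectory whose slab already sits at z = 0 must be unchanged
        prof2 = center_and_profile(slab_traj, equilibration_fraction=0.0)
        assert np.array_equal(prof1.mass_density["A"], prof2.mass_density["A"])

    def test_centering_undoes_shift(self, slab_traj):
        shifted = make_synthetic_slab_trajectory(
            400, BOX,
            {"A": {"length": 2, "rho_dense": 300.0, "rho_dilute": 6.0}},
            z0=60.0, interface_width=12.0, seed=5,
        )
        shift = 130.0
        shifted.positions[..., 2] = (
            (shifted.positions[..., 2] + shift + BOX[2] / 2) % BOX[2]
            - BOX[2] / 2
        )
        a = center_and_profile(slab_traj, equilibration_fraction=0.0)
        b = center_and_profile(shifted, equilibration_fraction=0.0)
        # same underlying sample: centered profiles agree closely
        assert np.abs(
            a.mass_density["A"] - b.mass_density["A"]
        ).max() < 0.05 * a.mass_density["A"].max()

    def test_equilibration_fraction_discards_frames(self, slab_traj):
        prof = center_and_profile(slab_traj, equilibration_fraction=0.2)
        assert prof.n_frames == 320

    def test_missing_species_rejected(self, slab_traj):
        with pytest.raises(SelectionError):
            center_and_profile(slab_traj, species="missing")

    def test_too_few_frames_rejected(self, slab_traj):
        with pytest.raises(DataError):
            center_and_profile(slab_traj, equilibration_fraction=0.999)


class TestDensityContrast:
    def test_slab_shows_high_contrast(self):
        from cgslab.slab_analysis import density_contrast

        traj = make_synthetic_slab_trajectory(
            80, BOX,
            {"A": {"length": 3, "rho_dense": 300.0, "rho_dilute": 2.0}},
            z0=45.0, interface_width=8.0, seed=6,
        )
        assert density_contrast(traj, equilibration_fraction=0.0) > 20.0

    def test_uniform_gas_near_unity_even_with_few_chains(self):
        """Split-half centering: a 10-chain gas must not acquire apparent
        contrast from the centering reference."""
        from cgslab.slab_analysis import density_contrast

        traj = make_synthetic_slab_trajectory(
            200, BOX,
            {"A": {"length": 30, "rho_dense": 85.0, "rho_dilute": 85.0,
                   "n_chains": 10}},
            seed=13,
        )
        c = density_contrast(traj, equilibration_fraction=0.0)
        assert 0.8 < c < 1.25

    def test_single_chain_rejected(self):
        from cgslab.slab_analysis import density_contrast

        traj = make_synthetic_slab_trajectory(
            5, BOX,
            {"A": {"length": 5, "rho_dense": 50.0, "rho_dilute": 50.0,
                   "n_chains": 1}},
            seed=2,
        )
        with pytest.raises(SelectionError):
            density_contrast(traj)


class TestCoexistenceFit:
    def test_ideal_step_profile_recovered_exactly(self):
        from cgslab.slab_analysis import DensityProfile

        z = np.linspace(-197.5, 197.5, 80)
        rho = np.where(np.abs(z) < 100.0, 300.0, 1.0)
        prof = DensityProfile(
            z_centers=z, bin_width=5.0, mass_density={"A": rho},
            molarity={"A": rho / 10.0}, chain_molar_mass={"A": 10000.0},
            n_chains={"A": 10}, box=np.array([50.0, 50.0, 400.0]),
            n_frames=10,
        )
        res = fit_coexistence(prof)["A"]
        assert res.phase_separated
        assert res.dense_mgml == pytest.approx(300.0, rel=1e-6)
        assert res.dilute_mgml == pytest.approx(1.0, rel=1e-4)

    def test_uniform_profile_flagged_not_separated(self):
        traj = make_synthetic_slab_trajectory(
            150, BOX,
            {"A": {"length": 2, "rho_dense": 40.0, "rho_dilute": 40.0}},
            seed=9,
        )
        prof = center_and_profile(traj, equilibration_fraction=0.0)
        res = fit_coexistence(prof)["A"]
        assert not res.phase_separated
        assert res.dense_mgml == pytest.approx(res.dilute_mgml)

    def test_noisy_tanh_parameters_recovered(self):
        """All four profile parameters within 5% on a noisy synthetic slab."""
        traj = make_synthetic_slab_trajectory(
            600, BOX,
            {"A": {"length": 2, "rho_dense": 300.0, "rho_dilute": 15.0}},
            z0=60.0, interface_width=12.0, noise=1.0, seed=17,
        )
        prof = center_and_profile(traj, equilibration_fraction=0.0)
        truth = traj.metadata["truth"]["A"]
        res = fit_coexistence(prof)["A"]
        assert res.dense_mgml == pytest.approx(truth["rho_dense"], rel=0.05)
        assert res.dilute_mgml == pytest.approx(truth["rho_dilute"], rel=0.05)
        assert res.z0 == pytest.approx(truth["z0"], rel=0.05)
        assert res.width == pytest.approx(truth["interface_width"], rel=0.05)

    def test_csat_monotone_across_generator_ladder(self):
        """Higher generated dilute density => higher fitted C_sat (rank 1.0)."""
        fitted = []
        ladder = [2.0, 6.0, 12.0, 24.0, 48.0]
        for i, rho_l in enumerate(ladder):
            traj = make_synthetic_slab_trajectory(
                250, BOX,
                {"A": {"length": 2, "rho_dense": 300.0, "rho_dilute": rho_l}},
                z0=60.0, interface_width=12.0, seed=100 + i,
            )
            prof = center_and_profile(traj, equilibration_fraction=0.0)
            fitted.append(fit_coexistence(prof)["A"].dilute_mgml)
        assert all(b > a for a, b in zip(fitted, fitted[1:]))

    def test_replicates_give_mean_and_sd(self):
        profs = []
        for seed in (1, 2, 3):
            traj = make_synthetic_slab_trajectory(
                120, BOX,
                {"A": {"length": 2, "rho_dense": 300.0, "rho_dilute": 10.0}},
                z0=60.0, interface_width=12.0, seed=seed,
            )
            profs.append(center_and_profile(traj, equilibration_fraction=0.0))
        res = fit_coexistence(profs)["A"]
        assert res.n_replicates == 3
        assert res.dilute_sd_mgml > 0.0
        assert len(res.replicate_dilute_mgml) == 3
        assert res.dilute_mgml == pytest.approx(
            np.mean(res.replicate_dilute_mgml)
        )


class TestUnits:
    def test_round_trip_exact(self):
        m = 123456.7
        x = np.array([0.001, 1.0, 300.0])
        assert np.allclose(uM_to_mgml(mgml_to_uM(x, m), m), x, rtol=1e-12)

    def test_molarity_track_consistent_with_mass(self, slab_traj):
        prof = center_and_profile(slab_traj, equilibration_fraction=0.0)
        m = prof.chain_molar_mass["A"]
        # bin-wise: mass density / molar mass ~ chain molarity (chains are
        # compact, so COM binning matches mass binning within a few %)
        dense_bins = prof.mass_density["A"] > 100.0
        ratio = (
            mgml_to_uM(prof.mass_density["A"][dense_bins], m)
            / prof.molarity["A"][dense_bins]
        )
        assert np.abs(ratio - 1.0).max() < 0.1
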