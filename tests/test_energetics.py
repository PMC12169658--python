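"""Pair potentials, Debye screening, force/energy consistency, neighbor lists.

The all-pairs oracle used here is an independent pure-numpy evaluation of
the model energetics (vectorized closed forms), not the package's compiled
kernel.
"""

import numpy as np
import pytest
from scipy import constants as C

from cgslab.energetics import (
    COULOMB,
    InteractionConfig,
    NumericError,
    ah_pair_energy,
    build_exclusions,
    candidate_pairs,
    compute_energy_forces,
    debye_length,
    dh_pair_energy,
)
from cgslab.params import default_table
from cgslab.synthetic import make_polyampholyte
from cgslab.topology import build_protein_chain
from tests.conftest import random_spaced_positions


def numpy_oracle_energy(topo, config):
    """Independent all-pairs energy: plain numpy, no shared kernel code."""
    pos = topo.positions
    n = len(pos)
    box = np.asarray(topo.box, float) if topo.box is not None else None
    ii, jj = np.triu_indices(n, k=1)
    d = pos[ii] - pos[jj]
    if box is not None:
        d -= box * np.rint(d / box)
    r = np.linalg.norm(d, axis=1)
    excl_keys = set(build_exclusions(topo).tolist())
    keep = np.array(
        [i * n + j not in excl_keys for i, j in zip(ii, jj)], dtype=bool
    )
    ii, jj, r = ii[keep], jj[keep], r[keep]
    sij = 0.5 * (topo.sigma[ii] + topo.sigma[jj])
    lij = 0.5 * (topo.lam[ii] + topo.lam[jj])
    sr6 = (sij / r) ** 6
    lj = 4.0 * config.epsilon * (sr6 ** 2 - sr6)
    rmin = 2 ** (1 / 6) * sij
    ah = np.where(r <= rmin, lj + (1 - lij) * config.epsilon, lij * lj)
    ah = np.where(r > config.ah_cutoff, 0.0, ah)
    kappa = config.kappa
    qq = topo.charge[ii] * topo.charge[jj]
    dh = COULOMB * qq / (config.dielectric * r) * np.exp(-kappa * r)
    dh = np.where(r > config.dh_cutoff, 0.0, dh)
    # bonds
    bd = pos[topo.bonds[:, 0]] - pos[topo.bonds[:, 1]]
    if box is not None:
        bd -= box * np.rint(bd / box)
    br = np.linalg.norm(bd, axis=1)
    bond = 0.5 * topo.bond_k * (br - topo.bond_r0) ** 2
    return float(ah.sum() + dh.sum() + bond.sum())


@pytest.fixture
def random_system(rng):
    """50 randomly placed charged beads in a periodic box (no bonds: random
    positions would stretch bonds absurdly and swamp the energy scale)."""
    frag = build_protein_chain(make_polyampholyte(50, 0.3, 0.3, 0.5, 3), seed=2)
    frag.box = np.array([60.0, 60.0, 120.0])
    frag.positions = random_spaced_positions(rng, 50, 55.0, 4.0)
    frag.bonds = np.empty((0, 2), dtype=np.int64)
    frag.bond_r0 = np.empty(0)
    frag.bond_k = np.empty(0)
    return frag


class TestDebyeLength:
    def test_closed_form_oracle(self):
        # independent evaluation of the closed form via scipy.constants
        got = debye_length(298.15, 0.1, 80.0)
        expected = np.sqrt(
            C.epsilon_0 * 80.0 * C.k * 298.15
            / (2 * (1000 * 0.1 * C.N_A) * C.e ** 2)
        ) * 1e10
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(9.7113, rel=1e-4)  # ~9.7 A at 100 mM

    def test_quadrupling_ionic_strength_halves(self):
        assert debye_length(320.0, 0.4, 80.0) == pytest.approx(
            debye_length(320.0, 0.1, 80.0) / 2.0, rel=1e-12
        )

    def test_temperature_scaling(self):
        ratio = debye_length(320.0, 0.1, 80.0) / debye_length(298.15, 0.1, 80.0)
        assert ratio == pytest.approx(np.sqrt(320.0 / 298.15), rel=1e-12)

    def test_zero_salt_unscreened(self):
        assert np.isinf(debye_length(320.0, 0.0, 80.0))


class TestAhPair:
    def test_minimum_depth_is_lambda_epsilon(self, rng):
        for _ in range(20):
            s = rng.uniform(4.5, 7.0)
            l = rng.uniform(0.0, 1.0)
            u = ah_pair_energy(2 ** (1 / 6) * s, s, l, 0.2)
            assert u == pytest.approx(-l * 0.2, abs=1e-12)

    def test_value_at_sigma(self):
        assert ah_pair_energy(6.0, 6.0, 0.7, 0.2) == pytest.approx(0.06)

    def test_continuity_at_crossover(self, rng):
        for _ in range(20):
            s = rng.uniform(4.5, 7.0)
            l = rng.uniform(0.0, 1.0)
            rmin = 2 ** (1 / 6) * s
            # both branches share the LJ minimum value there, and dLJ/dr = 0,
            # so the mismatch vanishes quadratically in delta
            for delta in (1e-4, 1e-6):
                jump = abs(
                    ah_pair_energy(rmin - delta, s, l, 0.2)
                    - ah_pair_energy(rmin + delta, s, l, 0.2)
                )
                assert jump < 1e-6 * delta / 1e-6

    def test_continuity_for_all_default_residue_pairs(self, table):
        res = list("ARNDCQEGHILKMFPSTWYV")
        for a in res:
            for b in res:
                s = 0.5 * (table.sigma(a) + table.sigma(b))
                l = 0.5 * (table.lam(a) + table.lam(b))
                rmin = 2 ** (1 / 6) * s
                jump = abs(
                    ah_pair_energy(rmin - 1e-9, s, l, 0.2)
                    - ah_pair_energy(rmin + 1e-9, s, l, 0.2)
                )
                assert jump < 1e-8

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            ah_pair_energy(-1.0, 6.0, 0.5)


class TestDhPair:
    def test_opposite_charges_attract_everywhere(self):
        cfg = InteractionConfig()
        r = np.linspace(1.0, cfg.dh_cutoff - 1e-9, 200)
        assert (dh_pair_energy(r, 1.0, -1.0, cfg) < 0).all()

    def test_unscreened_limit_recovers_coulomb(self):
        cfg = InteractionConfig(ionic_strength=0.0)
        r = 12.0
        u = dh_pair_energy(r, 1.0, -1.0, cfg)
        assert u * cfg.dielectric * r / (1.0 * -1.0) == pytest.approx(
            COULOMB, rel=1e-12
        )

    def test_closed_form_oracle(self):
        cfg = InteractionConfig(temperature=320.0, ionic_strength=0.1,
                                dielectric=80.0)
        r = 10.0
        coulomb = C.e ** 2 * C.N_A / (4 * np.pi * C.epsilon_0) / 4184.0 * 1e10
        kappa_inv = np.sqrt(
            C.epsilon_0 * 80.0 * C.k * 320.0
            / (2 * (1000 * 0.1 * C.N_A) * C.e ** 2)
        ) * 1e10
        expected = coulomb * (1.0 * -1.0) / (80.0 * r) * np.exp(-r / kappa_inv)
        assert dh_pair_energy(r, 1.0, -1.0, cfg) == pytest.approx(
            expected, rel=1e-12
        )

    def test_truncation_beyond_cutoff(self):
        cfg = InteractionConfig()
        assert dh_pair_energy(cfg.dh_cutoff + 1.0, 1.0, 1.0, cfg) == 0.0


class TestEnergyForces:
    def test_isolated_neutral_pair_beyond_cutoff(self):
        from tests.conftest import free_bead_system

        topo = free_bead_system(2, box_side=500.0)
        topo.positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 100.0]])
        energies, forces = compute_energy_forces(topo)
        assert energies["total"] == 0.0
        assert np.all(forces == 0.0)

    def test_forces_match_central_differences(self, random_system):
        """Analytic forces equal -grad U to 1e-6 relative.

        Components are compared where the force is large enough that the
        central difference is not dominated by floating-point cancellation
        of the total energy; the full sampled vector is also compared in
        norm.
        """
        cfg = InteractionConfig()
        _, forces = compute_energy_forces(random_system, config=cfg,
                                          brute_force=True)
        gen = np.random.default_rng(1)
        h = 2e-5
        sampled_f, sampled_fd = [], []
        for _ in range(40):
            i = int(gen.integers(random_system.n_beads))
            d = int(gen.integers(3))
            p = random_system.positions.copy()
            p[i, d] += h
            ep, _ = compute_energy_forces(random_system, p, cfg,
                                          brute_force=True)
            p[i, d] -= 2 * h
            em, _ = compute_energy_forces(random_system, p, cfg,
                                          brute_force=True)
            fd = -(ep["total"] - em["total"]) / (2 * h)
            sampled_f.append(forces[i, d])
            sampled_fd.append(fd)
            if abs(forces[i, d]) > 1e-2:
                assert abs(fd - forces[i, d]) / abs(forces[i, d]) < 1e-6
        sampled_f = np.asarray(sampled_f)
        sampled_fd = np.asarray(sampled_fd)
        rel_norm = (
            np.linalg.norm(sampled_fd - sampled_f)
            / np.linalg.norm(sampled_f)
        )
        assert rel_norm < 1e-6

    def test_bond_force_matches_central_differences(self):
        from tests.conftest import free_bead_system

        topo = free_bead_system(2, box_side=500.0)
        topo.bonds = np.array([[0, 1]], dtype=np.int64)
        topo.bond_r0 = np.array([3.8])
        topo.bond_k = np.array([2.39])
        topo.positions = np.array([[0.0, 0.0, 0.0], [2.0, 2.5, 3.0]])
        _, f = compute_energy_forces(topo)
        h = 1e-6
        for d in range(3):
            p = topo.positions.copy()
            p[1, d] += h
            ep, _ = compute_energy_forces(topo, p)
            p[1, d] -= 2 * h
            em, _ = compute_energy_forces(topo, p)
            fd = -(ep["total"] - em["total"]) / (2 * h)
            assert fd == pytest.approx(f[1, d], rel=1e-6)

    def test_net_force_vanishes(self, random_system):
        _, forces = compute_energy_forces(random_system, brute_force=True)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9

    def test_newtons_third_law_pairwise(self):
        # two isolated charged beads: forces exactly opposite
        from tests.conftest import free_bead_system

        topo = free_bead_system(2, box_side=500.0)
        topo.charge = np.array([1.0, -1.0])
        topo.positions = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 5.0]])
        _, f = compute_energy_forces(topo)
        assert np.allclose(f[0], -f[1], atol=1e-15)

    def test_energy_translation_invariant(self, random_system):
        cfg = InteractionConfig()
        e0, _ = compute_energy_forces(random_system, config=cfg,
                                      brute_force=True)
        shifted = random_system.positions + np.array([3.1, -7.2, 11.4])
        e1, _ = compute_energy_forces(random_system, shifted, cfg,
                                      brute_force=True)
        assert e1["total"] == pytest.approx(e0["total"], rel=1e-12)

    def test_matches_numpy_oracle(self, random_system):
        cfg = InteractionConfig()
        e, _ = compute_energy_forces(random_system, config=cfg,
                                     brute_force=True)
        assert e["total"] == pytest.approx(
            numpy_oracle_energy(random_system, cfg), rel=1e-12
        )

    def test_nan_position_reported_with_index(self, random_system):
        p = random_system.positions.copy()
        p[17, 1] = np.nan
        with pytest.raises(NumericError, match="17"):
            compute_energy_forces(random_system, p)

    def test_exclusions_cover_bonds_and_rigid(self):
        from cgslab.topology import DomainAnnotation
        from cgslab.synthetic import make_rigid_fixture
        from cgslab.sequences import SequenceRecord

        ann = DomainAnnotation("d", 2, 5, template=make_rigid_fixture(4))
        frag = build_protein_chain(
            SequenceRecord("p", "protein", "A" * 8), [ann]
        )
        n = frag.n_beads
        keys = set(build_exclusions(frag).tolist())
        assert 0 * n + 1 in keys  # bond 0-1
        assert 1 * n + 4 in keys  # rigid pair (beads 1..4 rigid)
        assert 5 * n + 7 not in keys


class TestNeighborList:
    @pytest.mark.parametrize("n_beads", [60, 200])
    def test_neighbor_equals_brute_force(self, rng, n_beads):
        """Cell-listed evaluation agrees with all pairs to 1e-12."""
        frag = build_protein_chain(
            make_polyampholyte(n_beads, 0.3, 0.3, 0.5, 5), seed=4
        )
        frag.box = np.array([90.0, 90.0, 140.0])
        frag.positions = random_spaced_positions(rng, n_beads, 85.0, 3.5)
        cfg = InteractionConfig()
        excl = build_exclusions(frag)
        listed = candidate_pairs(frag.positions, frag.box, cfg.max_cutoff,
                                 exclusions=excl)
        e_list, f_list = compute_energy_forces(frag, config=cfg, pairs=listed)
        e_brut, f_brut = compute_energy_forces(frag, config=cfg,
                                               brute_force=True)
        assert e_list["total"] == pytest.approx(e_brut["total"], abs=1e-12)
        assert np.abs(f_list - f_brut).max() < 1e-12
        assert e_brut["total"] == pytest.approx(
            numpy_oracle_energy(frag, cfg), rel=1e-10
        )
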