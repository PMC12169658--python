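"""Pairwise energetics: hydropathy-scaled Lennard-Jones + screened electrostatics.

Nonbonded interactions combine two terms, evaluated with Lorentz-Berthelot
style combining rules sigma_ij = (sigma_i + sigma_j)/2 and
lambda_ij = (lambda_i + lambda_j)/2:

* Ashbaugh-Hatch (AH): a Lennard-Jones potential whose attractive well is
  scaled by the pair hydropathy lambda_ij while the repulsive core is kept,

      U(r) = LJ(r) + (1 - lambda) * eps     for r <= 2^(1/6) sigma
      U(r) = lambda * LJ(r)                 for 2^(1/6) sigma < r <= cutoff

  with LJ(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]; continuous at the LJ
  minimum, plainly truncated (no shift) at the cutoff.

* Debye-Hueckel (DH): screened Coulomb,
  U(r) = C q_i q_j exp(-r / kappa^-1) / (eps_r r), with kappa^-1 the Debye
  length set by temperature and ionic strength.

Units: Angstrom, kcal/mol, elementary charges, g/mol, ps.

Bonded beads and bead pairs inside the same rigid group are excluded from the
nonbonded sums.  Harmonic bonds use U = k (r - r0)^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import constants as _const
from scipy.spatial import cKDTree

KB = _const.k * _const.N_A / 4184.0                      # kcal/(mol K)
#: Coulomb constant e^2 N_A / (4 pi eps0), kcal A / (mol e^2)
COULOMB = (
    _const.e ** 2 * _const.N_A / (4.0 * np.pi * _const.epsilon_0) / 4184.0 * 1e10
)
#: 1 kcal/mol expressed in g A^2 ps^-2 / mol (energy -> mass*velocity^2)
ENERGY_TO_ACC = 4184.0 * 1e-1


class NumericError(RuntimeError):
    """Non-finite coordinates encountered during evaluation."""


@dataclass
class InteractionConfig:
    """Nonbonded interaction settings.

    epsilon is the AH well-depth scale in kcal/mol; cutoffs in Angstrom;
    ionic_strength in mol/L; temperature in K (used for the Debye length).
    """

    epsilon: float = 0.2
    ah_cutoff: float = 25.0
    dh_cutoff: float = 35.0
    dielectric: float = 80.0
    temperature: float = 320.0
    ionic_strength: float = 0.1
    skin: float = 3.0

    def __post_init__(self) -> None:
        if self.ah_cutoff <= 0 or self.dh_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be nonnegative")

    @property
    def kappa(self) -> float:
        """Inverse Debye length in 1/Angstrom (0 for unscreened)."""
        lam = debye_length(self.temperature, self.ionic_strength, self.dielectric)
        return 0.0 if np.isinf(lam) else 1.0 / lam

    @property
    def max_cutoff(self) -> float:
        return max(self.ah_cutoff, self.dh_cutoff)


def debye_length(temperature: float, ionic_strength: float, dielectric: float = 80.0) -> float:
    """Debye screening length kappa^-1 in Angstrom.

    kappa^-1 = sqrt(eps0 eps_r kB T / (2 NA e^2 I)) with I the ionic strength
    of a 1:1 salt in mol/L.  I = 0 returns +inf (unscreened Coulomb limit).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be nonnegative")
    if ionic_strength == 0.0:
        return np.inf
    number_density = 1000.0 * ionic_strength * _const.N_A  # ions / m^3 per species
    length_m = np.sqrt(
        _const.epsilon_0 * dielectric * _const.k * temperature
        / (2.0 * number_density * _const.e ** 2)
    )
    return length_m * 1e10


def ah_pair_energy(r, sigma_ij, lambda_ij, epsilon: float = 0.2, cutoff: float = 25.0):
    """Ashbaugh-Hatch pair energy in kcal/mol (vectorized over r)."""
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("pair distance must be positive")
    sr6 = (sigma_ij / r) ** 6
    lj = 4.0 * epsilon * (sr6 * sr6 - sr6)
    rmin = 2.0 ** (1.0 / 6.0) * sigma_ij
    u = np.where(r <= rmin, lj + (1.0 - lambda_ij) * epsilon, lambda_ij * lj)
    u = np.where(r > cutoff, 0.0, u)
    return u if u.shape else float(u)


def dh_pair_energy(r, qi, qj, config: InteractionConfig | None = None):
    """Debye-Hueckel pair energy in kcal/mol (vectorized over r)."""
    config = config or InteractionConfig()
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("pair distance must be positive")
    u = COULOMB * qi * qj / (config.dielectric * r) * np.exp(-config.kappa * r)
    u = np.where(r > config.dh_cutoff, 0.0, u)
    return u if u.shape else float(u)


@njit(cache=True)
def _pair_kernel(pos, pairs, sigma, lam, charge, box, use_pbc,
                 eps, ah_cut, dh_cut, kappa, coul_over_eps, forces):
    # positions are expected pre-wrapped into the box (minimum image is a
    # single branch per axis, much cheaper than rint for these tight loops)
    e_ah = 0.0
    e_dh = 0.0
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    gmax2 = max(ah_cut, dh_cut) ** 2
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if use_pbc:
            if dx > hx:
                dx -= box[0]
            elif dx < -hx:
                dx += box[0]
            if dy > hy:
                dy -= box[1]
            elif dy < -hy:
                dy += box[1]
            if dz > hz:
                dz -= box[2]
            elif dz < -hz:
                dz += box[2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > gmax2 or r2 <= 0.0:
            continue
        r = np.sqrt(r2)
        fmag = 0.0  # -dU/dr
        if r < ah_cut:
            sij = 0.5 * (sigma[i] + sigma[j])
            lij = 0.5 * (lam[i] + lam[j])
            sr6 = (sij / r) ** 6
            lj = 4.0 * eps * (sr6 * sr6 - sr6)
            dlj = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r  # dU_LJ/dr
            rmin = 1.122462048309373 * sij
            if r <= rmin:
                e_ah += lj + (1.0 - lij) * eps
                fmag -= dlj
            else:
                e_ah += lij * lj
                fmag -= lij * dlj
        qq = charge[i] * charge[j]
        if qq != 0.0 and r < dh_cut:
            u = coul_over_eps * qq * np.exp(-kappa * r) / r
            e_dh += u
            fmag += u * (kappa + 1.0 / r)
        if fmag != 0.0:
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e_ah, e_dh


@njit(cache=True)
def _bond_kernel(pos, bonds, r0, k, box, use_pbc, forces):
    e = 0.0
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if use_pbc:
            if dx > hx:
                dx -= box[0]
            elif dx < -hx:
                dx += box[0]
            if dy > hy:
                dy -= box[1]
            elif dy < -hy:
                dy += box[1]
            if dz > hz:
                dz -= box[2]
            elif dz < -hz:
                dz += box[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[b]
        e += 0.5 * k[b] * dr * dr
        if r > 0.0:
            fmag = -k[b] * dr
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e


def build_exclusions(topology) -> np.ndarray:
    """Sorted int64 pair keys (i * N + j, i < j) excluded from nonbonded sums.

    Excluded are directly bonded pairs and every pair inside one rigid group.
    """
    n = topology.n_beads
    keys = set()
    for i, j in np.asarray(topology.bonds, dtype=np.int64):
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        keys.add(a * n + b)
    for group in topology.rigid_groups:
        g = np.asarray(group, dtype=np.int64)
        for ii in range(len(g)):
            for jj in range(ii + 1, len(g)):
                a, b = int(g[ii]), int(g[jj])
                if a > b:
                    a, b = b, a
                keys.add(a * n + b)
    return np.array(sorted(keys), dtype=np.int64)


def candidate_pairs(positions, box, cutoff, exclusions=None, brute_force=False):
    """Pair candidates (i < j) within cutoff, minus exclusions.

    Uses a periodic k-d tree grid search when the cutoff fits the minimum
    image convention, otherwise falls back to all pairs.
    """
    n = len(positions)
    if box is not None:
        box = np.asarray(box, dtype=float)
    small_box = box is not None and cutoff >= np.min(box) / 2.0
    if brute_force or small_box or box is None and n <= 2000:
        ii, jj = np.triu_indices(n, k=1)
        pairs = np.column_stack([ii, jj]).astype(np.int64)
    else:
        if box is not None:
            wrapped = (positions + box / 2.0) % box
            tree = cKDTree(wrapped, boxsize=box)
        else:
            tree = cKDTree(positions)
        raw = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(raw) == 0:
            pairs = np.empty((0, 2), dtype=np.int64)
        else:
            pairs = np.sort(raw.astype(np.int64), axis=1)
            # lexicographic order: summation order matches the all-pairs
            # route bit for bit (pairs beyond cutoff add exactly zero)
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs = pairs[order]
    if exclusions is not None and len(exclusions) and len(pairs):
        keys = pairs[:, 0] * n + pairs[:, 1]
        idx = np.searchsorted(exclusions, keys)
        idx = np.clip(idx, 0, len(exclusions) - 1)
        excluded = exclusions[idx] == keys
        pairs = pairs[~excluded]
    return pairs


class NeighborList:
    """Verlet-style pair list with a skin, rebuilt on large displacements."""

    def __init__(self, config: InteractionConfig, exclusions=None):
        self.config = config
        self.exclusions = exclusions
        self.pairs = None
        self._ref = None

    def update(self, positions, box, force_rebuild=False):
        if (
            force_rebuild
            or self.pairs is None
            or self._ref is None
            or len(self._ref) != len(positions)
            or np.max(np.linalg.norm(positions - self._ref, axis=1))
            > self.config.skin / 2.0
        ):
            self.pairs = candidate_pairs(
                positions, box, self.config.max_cutoff + self.config.skin,
                exclusions=self.exclusions,
            )
            self._ref = positions.copy()
        return self.pairs


def compute_energy_forces(
    topology,
    positions=None,
    config: InteractionConfig | None = None,
    pairs=None,
    brute_force=False,
):
    """Total energy (bond + AH + DH) and per-bead forces.

    Forces are -grad U under minimum-image periodicity (when the topology has
    a box) and obey Newton's third law pairwise.  ``pairs`` may carry a
    prebuilt candidate list; otherwise one is built from scratch
    (``brute_force=True`` forces the all-pairs route).

    Returns ``(energies, forces)`` with ``energies`` a dict holding the
    ``ah``, ``dh``, ``bond`` and ``total`` terms in kcal/mol.
    """
    config = config or InteractionConfig()
    pos = np.asarray(
        positions if positions is not None else topology.positions, dtype=float
    )
    bad = ~np.isfinite(pos).all(axis=1)
    if bad.any():
        raise NumericError(
            f"non-finite position for bead index {int(np.nonzero(bad)[0][0])}"
        )
    box = topology.box
    use_pbc = box is not None
    box_arr = np.asarray(box, dtype=float) if use_pbc else np.ones(3)
    if use_pbc:
        # kernels assume pre-wrapped coordinates (single-branch min image)
        pos = (pos + box_arr / 2.0) % box_arr - box_arr / 2.0
    if pairs is None:
        pairs = candidate_pairs(
            pos, box, config.max_cutoff, exclusions=build_exclusions(topology),
            brute_force=brute_force,
        )
    forces = np.zeros_like(pos)
    e_ah, e_dh = _pair_kernel(
        pos, np.asarray(pairs, dtype=np.int64), topology.sigma, topology.lam,
        topology.charge, box_arr, use_pbc, config.epsilon, config.ah_cutoff,
        config.dh_cutoff, config.kappa, COULOMB / config.dielectric, forces,
    )
    e_bond = _bond_kernel(
        pos, np.asarray(topology.bonds, dtype=np.int64), topology.bond_r0,
        topology.bond_k, box_arr, use_pbc, forces,
    )
    energies = {
        "ah": e_ah,
        "dh": e_dh,
        "bond": e_bond,
        "total": e_ah + e_dh + e_bond,
    }
    return energies, forces
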