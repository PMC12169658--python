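"""Langevin NVT dynamics with rigid-body support.

The integrator is a BAOAB splitting of underdamped Langevin dynamics: half
kick (B), half drift (A), Ornstein-Uhlenbeck velocity refresh (O), half
drift, force evaluation, half kick.  Each flexible bead feels a drag
gamma_i = m_i / tau and the matched fluctuation-dissipation random kick, so
the damping time tau (default 1000 ps) is the single friction parameter.

Rigid groups (folded domains) move as rigid bodies: the net force translates
the center of mass (total drag M / tau) and the net torque rotates the body
about its principal axes via a quaternion update, with an independent
Ornstein-Uhlenbeck refresh on each rotational degree of freedom (relaxation
time tau, noise satisfying fluctuation-dissipation on all six dof).
Principal axes with near-zero inertia (collinear groups) are frozen and do
not count as degrees of freedom.

Systems without rigid groups run in a numba-compiled loop with an internal
Verlet pair list; rigid systems use a Python-level driver over the same
compiled force kernels.  Both are deterministic for a given seed.

Units: Angstrom, ps, g/mol, kcal/mol; velocities in Angstrom/ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from cgslab.energetics import (
    COULOMB,
    ENERGY_TO_ACC,
    KB,
    InteractionConfig,
    NeighborList,
    _bond_kernel,
    _pair_kernel,
    build_exclusions,
)
from cgslab.trajectory import Trajectory


class InstabilityError(RuntimeError):
    """A bead moved more than half a bead diameter in one step."""


@dataclass
class SimulationConfig:
    """Integration settings.

    timestep is in fs, friction_tau in ps (gamma_i = m_i / tau); ``nve``
    disables friction and noise (microcanonical test hook);
    ``save_velocities`` keeps per-frame velocities for temperature checks.
    """

    n_steps: int = 1000
    temperature: float = 320.0
    timestep_fs: float = 10.0
    friction_tau_ps: float = 1000.0
    seed: int = 0
    save_interval: int = 1000
    nve: bool = False
    save_velocities: bool = False

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.friction_tau_ps <= 0:
            raise ValueError("friction tau must be positive")


def _thermal_velocities(rng, mass, temperature):
    scale = np.sqrt(KB * temperature * ENERGY_TO_ACC / mass)
    return rng.normal(size=(len(mass), 3)) * scale[:, None]


@njit(cache=True)
def _build_pairs_nb(pos, box, use_pbc, cutoff, excl, pairs_out):
    # positions must be pre-wrapped (single-branch minimum image)
    n = pos.shape[0]
    count = 0
    cut2 = cutoff * cutoff
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    for i in range(n):
        for j in range(i + 1, n):
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
            if dx * dx + dy * dy + dz * dz < cut2:
                key = i * n + j
                lo = np.searchsorted(excl, key)
                if lo < len(excl) and excl[lo] == key:
                    continue
                pairs_out[count, 0] = i
                pairs_out[count, 1] = j
                count += 1
    return count


@njit(cache=True)
def _integrate_flexible(
    pos, vel, mass, sigma, lam, charge, box, use_pbc,
    bonds, bond_r0, bond_k, excl,
    eps, ah_cut, dh_cut, kappa, coul_over_eps,
    dt, c1, noise_scale, kT_acc,
    n_steps, save_interval, seed, skin, list_cutoff, max_disp,
    out_pos, out_vel, out_times, save_vel,
):
    """Compiled BAOAB loop for fully flexible systems.

    Returns (status, step): status 0 = ok, 1 = instability at ``step``.
    Frames are written into out_pos/out_times (frame 0 is the initial state).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    if use_pbc:
        for i in range(n):
            for d in range(3):
                pos[i, d] = (pos[i, d] + 0.5 * box[d]) % box[d] - 0.5 * box[d]
    max_pairs = n * (n - 1) // 2
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    n_pairs = _build_pairs_nb(pos, box, use_pbc, list_cutoff, excl, pairs)
    ref = pos.copy()
    forces = np.zeros((n, 3))
    _pair_kernel(pos, pairs[:n_pairs], sigma, lam, charge, box, use_pbc,
                 eps, ah_cut, dh_cut, kappa, coul_over_eps, forces)
    _bond_kernel(pos, bonds, bond_r0, bond_k, box, use_pbc, forces)
    frame = 0
    out_pos[frame] = pos
    out_times[frame] = 0.0
    if save_vel:
        out_vel[frame] = vel
    frame += 1
    half = 0.5 * dt
    for step in range(n_steps):
        for i in range(n):
            acc = ENERGY_TO_ACC / mass[i]
            for d in range(3):
                vel[i, d] += half * forces[i, d] * acc
        old = pos.copy()
        for i in range(n):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
        if c1 != 1.0 or noise_scale != 0.0:
            for i in range(n):
                sc = np.sqrt(kT_acc / mass[i]) * noise_scale
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + sc * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
        # displacement/instability check and neighbor bookkeeping
        max_d2 = 0.0
        max_ref2 = 0.0
        for i in range(n):
            d2 = 0.0
            r2 = 0.0
            for d in range(3):
                dd = pos[i, d] - old[i, d]
                d2 += dd * dd
                rr = pos[i, d] - ref[i, d]
                r2 += rr * rr
            if d2 > max_d2:
                max_d2 = d2
            if r2 > max_ref2:
                max_ref2 = r2
        if max_d2 > max_disp * max_disp:
            return 1, step
        if max_ref2 > (skin * 0.5) ** 2:
            if use_pbc:
                for i in range(n):
                    for d in range(3):
                        pos[i, d] = (
                            (pos[i, d] + 0.5 * box[d]) % box[d] - 0.5 * box[d]
                        )
            n_pairs = _build_pairs_nb(pos, box, use_pbc, list_cutoff, excl, pairs)
            ref = pos.copy()
        for i in range(n):
            for d in range(3):
                forces[i, d] = 0.0
        _pair_kernel(pos, pairs[:n_pairs], sigma, lam, charge, box, use_pbc,
                     eps, ah_cut, dh_cut, kappa, coul_over_eps, forces)
        _bond_kernel(pos, bonds, bond_r0, bond_k, box, use_pbc, forces)
        for i in range(n):
            acc = ENERGY_TO_ACC / mass[i]
            for d in range(3):
                vel[i, d] += half * forces[i, d] * acc
        if (step + 1) % save_interval == 0:
            out_pos[frame] = pos
            out_times[frame] = (step + 1) * dt
            if save_vel:
                out_vel[frame] = vel
            frame += 1
    return 0, n_steps


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention)

def _quat_multiply(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_to_matrix(q):
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class _RigidGroup:
    """Rigid-body state: principal-frame geometry plus COM/orientation."""

    __slots__ = (
        "indices", "masses", "total_mass", "body_coords", "inertia",
        "free_axes", "quat", "com", "vel", "omega",
    )

    def __init__(self, indices, masses, positions):
        self.indices = np.asarray(indices, dtype=np.int64)
        self.masses = masses[self.indices]
        self.total_mass = float(self.masses.sum())
        com = (self.masses[:, None] * positions[self.indices]).sum(0) / self.total_mass
        rel = positions[self.indices] - com
        inertia_tensor = np.zeros((3, 3))
        for m, r in zip(self.masses, rel):
            inertia_tensor += m * ((r @ r) * np.eye(3) - np.outer(r, r))
        evals, evecs = np.linalg.eigh(inertia_tensor)
        if np.linalg.det(evecs) < 0:
            evecs[:, -1] *= -1
        self.inertia = evals  # principal moments, g/mol A^2
        self.free_axes = evals > 1e-9 * max(evals.max(), 1.0)
        self.body_coords = rel @ evecs  # coordinates in principal frame
        # orientation: lab = R(quat) . body; initialise from evecs
        self.quat = _matrix_to_quat(evecs)
        self.com = com.astype(float)
        self.vel = np.zeros(3)
        self.omega = np.zeros(3)  # body-frame angular velocity, rad/ps

    @property
    def n_dof(self) -> int:
        return 3 + int(self.free_axes.sum())

    def rotation(self):
        return _quat_to_matrix(self.quat)

    def bead_positions(self):
        return self.com + self.body_coords @ self.rotation().T

    def bead_velocities(self):
        rot = self.rotation()
        omega_lab = rot @ self.omega
        rel = self.body_coords @ rot.T
        return self.vel + np.cross(omega_lab, rel)

    def kick(self, forces_lab, half_dt):
        f_net = forces_lab.sum(axis=0)
        rot = self.rotation()
        rel = self.body_coords @ rot.T
        torque_lab = np.cross(rel, forces_lab).sum(axis=0)
        torque_body = rot.T @ torque_lab
        self.vel += half_dt * f_net * ENERGY_TO_ACC / self.total_mass
        gyro = np.cross(self.omega, self.inertia * self.omega)
        omega_dot = np.where(
            self.free_axes,
            (torque_body * ENERGY_TO_ACC - gyro) / np.where(self.free_axes, self.inertia, 1.0),
            0.0,
        )
        self.omega = np.where(self.free_axes, self.omega + half_dt * omega_dot, 0.0)

    def drift(self, half_dt):
        self.com = self.com + half_dt * self.vel
        w = np.linalg.norm(self.omega)
        if w > 0:
            angle = w * half_dt
            axis = self.omega / w
            dq = np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])
            self.quat = _quat_multiply(self.quat, dq)
            self.quat /= np.linalg.norm(self.quat)

    def thermostat(self, c1, noise, kT_acc, rng):
        if noise == 0.0 and c1 == 1.0:
            return
        self.vel = (
            c1 * self.vel
            + noise * np.sqrt(kT_acc / self.total_mass) * rng.normal(size=3)
        )
        scale = np.sqrt(kT_acc / np.where(self.free_axes, self.inertia, 1.0))
        self.omega = np.where(
            self.free_axes,
            c1 * self.omega + noise * scale * rng.normal(size=3),
            0.0,
        )


def _matrix_to_quat(m):
    w = np.sqrt(max(0.0, 1.0 + m[0, 0] + m[1, 1] + m[2, 2])) / 2.0
    if w > 1e-8:
        x = (m[2, 1] - m[1, 2]) / (4 * w)
        y = (m[0, 2] - m[2, 0]) / (4 * w)
        z = (m[1, 0] - m[0, 1]) / (4 * w)
    else:  # w ~ 0: 180 degree rotation
        x = np.sqrt(max(0.0, 1.0 + m[0, 0] - m[1, 1] - m[2, 2])) / 2.0
        if x > 1e-8:
            y = (m[0, 1] + m[1, 0]) / (4 * x)
            z = (m[0, 2] + m[2, 0]) / (4 * x)
        else:
            y = np.sqrt(max(0.0, 1.0 - m[0, 0] + m[1, 1] - m[2, 2])) / 2.0
            z = (m[1, 2] + m[2, 1]) / (4 * y)
        w = (m[2, 1] - m[1, 2]) / (4 * x) if x > 1e-8 else w
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def run_langevin(
    topology,
    config: SimulationConfig,
    interactions: InteractionConfig | None = None,
) -> Trajectory:
    """Integrate Langevin NVT dynamics and return the sampled trajectory.

    Frame 0 is the initial configuration; subsequent frames are saved every
    ``config.save_interval`` steps.  Deterministic for a given seed (each
    execution path has its own random stream).  Raises InstabilityError when
    any bead moves farther than half the smallest bead diameter in one step.
    """
    interactions = interactions or InteractionConfig()
    dt = config.timestep_fs * 1e-3  # ps
    tau = config.friction_tau_ps
    if config.nve:
        c1, noise = 1.0, 0.0
    else:
        c1 = float(np.exp(-dt / tau))
        noise = float(np.sqrt(1.0 - c1 * c1))
    kT_acc = KB * config.temperature * ENERGY_TO_ACC
    rng = np.random.default_rng(config.seed)
    pos = topology.positions.astype(float).copy()
    vel = _thermal_velocities(rng, topology.mass, config.temperature)
    use_pbc = topology.box is not None
    box = np.asarray(topology.box, float) if use_pbc else np.ones(3)
    excl = build_exclusions(topology)
    n_frames = 1 + (config.n_steps // config.save_interval
                    if config.n_steps else 0)
    max_disp = 0.5 * float(topology.sigma.min())
    bonds = np.asarray(topology.bonds, dtype=np.int64).reshape(-1, 2)

    if not topology.rigid_groups:
        out_pos = np.zeros((n_frames, topology.n_beads, 3))
        out_vel = np.zeros((n_frames, topology.n_beads, 3) if config.save_velocities else (1, 1, 3))
        out_times = np.zeros(n_frames)
        status, step = _integrate_flexible(
            pos, vel, topology.mass, topology.sigma, topology.lam,
            topology.charge, box, use_pbc, bonds, topology.bond_r0,
            topology.bond_k, excl,
            interactions.epsilon, interactions.ah_cutoff,
            interactions.dh_cutoff, interactions.kappa,
            COULOMB / interactions.dielectric,
            dt, c1, noise, kT_acc,
            config.n_steps, config.save_interval, config.seed % (2 ** 31),
            interactions.skin, interactions.max_cutoff + interactions.skin,
            max_disp, out_pos, out_vel, out_times, config.save_velocities,
        )
        if status != 0:
            raise InstabilityError(
                f"bead displacement exceeded {max_disp:.2f} A at step {step}; "
                "reduce the timestep"
            )
        return Trajectory.from_topology(
            topology, out_pos, out_times,
            velocities=out_vel if config.save_velocities else None,
        )

    return _run_rigid(
        topology, config, interactions, pos, vel, box, use_pbc, excl,
        dt, c1, noise, kT_acc, rng, n_frames, max_disp, bonds,
    )


def _run_rigid(topology, config, interactions, pos, vel, box, use_pbc, excl,
               dt, c1, noise, kT_acc, rng, n_frames, max_disp, bonds):
    groups = [
        _RigidGroup(g, topology.mass, pos) for g in topology.rigid_groups
    ]
    rigid_mask = np.zeros(topology.n_beads, dtype=bool)
    for g in groups:
        rigid_mask[g.indices] = True
    flex = np.nonzero(~rigid_mask)[0]
    # rigid-body velocities start thermal on their 6 dof
    for g in groups:
        g.vel = rng.normal(size=3) * np.sqrt(kT_acc / g.total_mass)
        scale = np.sqrt(kT_acc / np.where(g.free_axes, g.inertia, 1.0))
        g.omega = np.where(g.free_axes, rng.normal(size=3) * scale, 0.0)
        vel[g.indices] = g.bead_velocities()

    nlist = NeighborList(interactions, exclusions=excl)
    half = 0.5 * dt

    def forces_at(p):
        pairs = nlist.update(p, topology.box if use_pbc else None)
        f = np.zeros_like(p)
        pw = (p + box / 2.0) % box - box / 2.0 if use_pbc else p
        _pair_kernel(
            pw, pairs, topology.sigma, topology.lam, topology.charge, box,
            use_pbc, interactions.epsilon, interactions.ah_cutoff,
            interactions.dh_cutoff, interactions.kappa,
            COULOMB / interactions.dielectric, f,
        )
        _bond_kernel(pw, bonds, topology.bond_r0, topology.bond_k, box,
                     use_pbc, f)
        return f

    forces = forces_at(pos)
    frames = [pos.copy()]
    times = [0.0]
    vels = [vel.copy()] if config.save_velocities else None
    acc_flex = ENERGY_TO_ACC / topology.mass[flex, None]
    for step in range(config.n_steps):
        old = pos.copy()
        vel[flex] += half * forces[flex] * acc_flex
        for g in groups:
            g.kick(forces[g.indices], half)
        pos[flex] += half * vel[flex]
        for g in groups:
            g.drift(half)
        if not config.nve:
            sc = np.sqrt(kT_acc / topology.mass[flex]) * noise
            vel[flex] = c1 * vel[flex] + sc[:, None] * rng.normal(
                size=(len(flex), 3)
            )
            for g in groups:
                g.thermostat(c1, noise, kT_acc, rng)
        pos[flex] += half * vel[flex]
        for g in groups:
            g.drift(half)
            pos[g.indices] = g.bead_positions()
            vel[g.indices] = g.bead_velocities()
        disp = np.linalg.norm(pos - old, axis=1).max()
        if disp > max_disp:
            raise InstabilityError(
                f"bead displacement {disp:.2f} A exceeded {max_disp:.2f} A at "
                f"step {step}; reduce the timestep"
            )
        forces = forces_at(pos)
        vel[flex] += half * forces[flex] * acc_flex
        for g in groups:
            g.kick(forces[g.indices], half)
            vel[g.indices] = g.bead_velocities()
        if (step + 1) % config.save_interval == 0:
            frames.append(pos.copy())
            times.append((step + 1) * dt)
            if vels is not None:
                vels.append(vel.copy())
    return Trajectory.from_topology(
        topology, np.asarray(frames), np.asarray(times),
        velocities=np.asarray(vels) if vels is not None else None,
    )


def minimize(topology, interactions: InteractionConfig | None = None,
             n_steps: int = 200, max_step: float = 0.2) -> np.ndarray:
    """Displacement-capped steepest descent to relax packed initial states.

    Moves every flexible bead along the force direction by at most
    ``max_step`` Angstrom per iteration (rigid groups translate as a unit);
    returns the relaxed positions and stores them on the topology.  This is
    a pre-dynamics regularizer, not an optimizer: it only removes the steep
    overlaps a random packing leaves behind.
    """
    from cgslab.energetics import compute_energy_forces

    interactions = interactions or InteractionConfig()
    pos = topology.positions.astype(float).copy()
    rigid_mask = np.zeros(topology.n_beads, dtype=bool)
    for g in topology.rigid_groups:
        rigid_mask[np.asarray(g, dtype=np.int64)] = True
    for _ in range(n_steps):
        _, forces = compute_energy_forces(topology, pos, interactions)
        for g in topology.rigid_groups:
            idx = np.asarray(g, dtype=np.int64)
            forces[idx] = forces[idx].mean(axis=0)
        norms = np.linalg.norm(forces, axis=1)
        fmax = norms.max()
        if fmax < 1e-3:
            break
        step = forces * (max_step / max(fmax, 1e-12))
        pos += step
        if topology.box is not None:
            box = np.asarray(topology.box)
            pos = (pos + box / 2.0) % box - box / 2.0
    topology.positions = pos
    return pos


def count_dof(topology) -> int:
    """Degrees of freedom: 3 per flexible bead, up to 6 per rigid group."""
    rigid_mask = np.zeros(topology.n_beads, dtype=bool)
    dof = 0
    for g in topology.rigid_groups:
        grp = _RigidGroup(g, topology.mass, topology.positions)
        rigid_mask[grp.indices] = True
        dof += grp.n_dof
    dof += 3 * int((~rigid_mask).sum())
    return dof


def kinetic_temperature(velocities, topology) -> float:
    """Instantaneous temperature T = 2 KE / (kB N_dof) from bead velocities.

    Rigid groups contribute six degrees of freedom (three translational,
    three rotational; collinear groups lose their degenerate axis).  Bead
    velocities of a rigid group are assumed consistent with rigid motion, so
    the group kinetic energy is simply the sum over its beads.
    """
    dof = count_dof(topology)
    if dof == 0:
        raise ValueError("system has no degrees of freedom")
    v2 = (np.asarray(velocities) ** 2).sum(axis=1)
    ke = 0.5 * float((topology.mass * v2).sum()) / ENERGY_TO_ACC  # kcal/mol
    return 2.0 * ke / (KB * dof)
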