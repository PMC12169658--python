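"""Seeded generators for pipeline inputs with known ground truth.

Three generator families cover everything the simulation and analysis layers
consume, without any external downloads:

* charge-patterned polyampholyte sequences (K/E with G filler) spanning
  strict alternation to fully blocky architectures -- the sequence feature
  that controls electrostatics-driven phase separation;
* rigid-domain bead fixtures (ideal helix or jammed compact cluster)
  standing in for folded-domain template coordinates;
* slab trajectories whose z-density follows a prescribed tanh coexistence
  profile, with the realized parameters recorded in the trajectory metadata
  so analysis code can be tested against a known answer.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _const

from cgslab.params import default_table
from cgslab.sequences import SequenceRecord
from cgslab.trajectory import Trajectory

#: mg/mL above which a requested dense phase exceeds plausible close packing
CLOSE_PACKING_MGML = 1400.0


class GeneratorSpecError(ValueError):
    """Infeasible generator parameters."""


def make_polyampholyte(
    length: int,
    fraction_positive: float,
    fraction_negative: float,
    blockiness: float,
    seed: int = 0,
    record_id: str | None = None,
) -> SequenceRecord:
    """Generate a K/E polyampholyte (G filler) with controlled patterning.

    Exact charge counts are floor(length * fraction).  ``blockiness`` 0
    yields strict K/E alternation, 1 yields a leading K block and trailing E
    block; intermediate values place that fraction of the charges in the end
    blocks and alternate the rest in the middle.  Positions of G fillers are
    interleaved with a seeded tie-break.
    """
    if length < 2:
        raise GeneratorSpecError("length must be >= 2")
    if fraction_positive < 0 or fraction_negative < 0:
        raise GeneratorSpecError("fractions must be nonnegative")
    if fraction_positive + fraction_negative > 1.0 + 1e-12:
        raise GeneratorSpecError("charge fractions must sum to <= 1")
    if not 0.0 <= blockiness <= 1.0:
        raise GeneratorSpecError("blockiness must be in [0, 1]")
    n_pos = int(np.floor(length * fraction_positive))
    n_neg = int(np.floor(length * fraction_negative))
    n_fill = length - n_pos - n_neg
    rng = np.random.default_rng(seed)

    block_pos = int(round(blockiness * n_pos))
    block_neg = int(round(blockiness * n_neg))
    mid_pos = n_pos - block_pos
    mid_neg = n_neg - block_neg

    # middle: alternate remaining charges as evenly as possible (K first),
    # then interleave the G fillers with a seeded phase
    charges = []
    placed_p = placed_n = 0
    for _ in range(mid_pos + mid_neg):
        if placed_p * max(mid_neg, 1) <= placed_n * max(mid_pos, 1) and placed_p < mid_pos:
            charges.append("K")
            placed_p += 1
        elif placed_n < mid_neg:
            charges.append("E")
            placed_n += 1
        else:
            charges.append("K")
            placed_p += 1
    middle = charges
    if n_fill > 0:
        # charges keep their relative (alternating) order; the G fillers are
        # scattered among them at seeded positions
        total_mid = len(middle) + n_fill
        slots = np.sort(
            rng.choice(total_mid, size=len(middle), replace=False)
        )
        out = ["G"] * total_mid
        for ch, slot in zip(middle, slots):
            out[slot] = ch
        middle = out
    letters = "K" * block_pos + "".join(middle) + "E" * block_neg
    assert len(letters) == length
    return SequenceRecord(
        id=record_id or f"polyampholyte_b{blockiness:g}_s{seed}",
        kind="protein",
        letters=letters,
    )


def make_rigid_fixture(
    n_beads: int, geometry: str = "helix", seed: int = 0
) -> np.ndarray:
    """Template coordinates for a rigid folded-domain stand-in.

    ``helix``: ideal backbone helix with exactly 3.8 A consecutive-bead
    spacing (1.5 A rise, 100 deg turn).  ``compact``: jammed random cluster
    with minimum pair distance >= 3.8 A.  Deterministic for a given seed.
    """
    if n_beads < 3:
        raise GeneratorSpecError("rigid fixtures need >= 3 beads")
    if geometry == "helix":
        rise = 1.5
        turn = np.deg2rad(100.0)
        chord = np.sqrt(3.8 ** 2 - rise ** 2)
        radius = chord / (2.0 * np.sin(turn / 2.0))
        k = np.arange(n_beads)
        return np.column_stack(
            [radius * np.cos(k * turn), radius * np.sin(k * turn), rise * k]
        )
    if geometry == "compact":
        rng = np.random.default_rng(seed)
        min_dist = 3.8
        # sphere radius for ~25% packing of 1.9 A-radius beads
        radius = (n_beads * min_dist ** 3 / 0.25) ** (1.0 / 3.0) / 2.0
        coords = []
        while len(coords) < n_beads:
            for _ in range(20000):
                cand = rng.uniform(-radius, radius, size=3)
                if np.linalg.norm(cand) > radius:
                    continue
                if not coords or np.min(
                    np.linalg.norm(np.asarray(coords) - cand, axis=1)
                ) >= min_dist:
                    coords.append(cand)
                    break
            else:
                radius *= 1.1  # dilate and keep going
        return np.asarray(coords)
    raise GeneratorSpecError(f"unknown geometry {geometry!r}")


def _tanh_density(z, rho_d, rho_l, z0, w):
    return 0.5 * (rho_d + rho_l) - 0.5 * (rho_d - rho_l) * np.tanh(
        (np.abs(z) - z0) / w
    )


def _coils(n_chains, length, rng):
    """(n_chains, length, 3) random coils: 3.8 A freely jointed steps,
    each recentered on its center of geometry."""
    if length == 1:
        return np.zeros((n_chains, 1, 3))
    steps = rng.normal(size=(n_chains, length - 1, 3))
    steps *= 3.8 / np.linalg.norm(steps, axis=2, keepdims=True)
    rel = np.concatenate(
        [np.zeros((n_chains, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return rel - rel.mean(axis=1, keepdims=True)


def make_synthetic_slab_trajectory(
    n_frames: int,
    box,
    species_specs: dict,
    z0: float | None = None,
    interface_width: float = 10.0,
    noise: float = 0.0,
    seed: int = 0,
    frame_spacing_ps: float = 10.0,
) -> Trajectory:
    """Slab trajectory with a prescribed tanh coexistence profile.

    ``species_specs`` maps species name to a dict with keys ``length``
    (residues per chain, poly-G beads by default or an explicit ``letters``
    string), ``rho_dense`` and ``rho_dilute`` (mg/mL), and optionally
    ``n_chains`` (otherwise derived from the densities).  Chain centers are
    sampled independently each frame from the normalized tanh profile, chain
    conformations are compact random coils, and ``noise`` adds Gaussian
    positional jitter.  The realized profile parameters (after integer
    chain-count rounding) are recorded in ``trajectory.metadata["truth"]``
    per species -- the oracle used by the analysis tests.
    """
    box = np.asarray(box, dtype=float)
    if box[2] < max(box[0], box[1]):
        raise GeneratorSpecError("slab box needs z as the long axis")
    if z0 is None:
        z0 = box[2] / 8.0
    rng = np.random.default_rng(seed)
    table = default_table()
    lx, ly, lz = box
    area = lx * ly

    zgrid = np.linspace(-lz / 2.0, lz / 2.0, 4001)
    truth = {}
    per_species = {}
    for name, spec in species_specs.items():
        length = int(spec["length"])
        letters = spec.get("letters", "G" * length)
        rho_d = float(spec["rho_dense"])
        rho_l = float(spec["rho_dilute"])
        if rho_d > CLOSE_PACKING_MGML:
            raise GeneratorSpecError(
                f"{name}: rho_dense {rho_d} mg/mL exceeds close packing"
            )
        if rho_d < rho_l:
            raise GeneratorSpecError(f"{name}: rho_dense < rho_dilute")
        arrs = table.arrays_for(list(letters))
        chain_mass = float(arrs["mass"].sum())  # g/mol
        dens = _tanh_density(zgrid, rho_d, rho_l, z0, interface_width)
        # expected chains: integral of rho * A dz / chain mass
        # rho in mg/mL = g/L = 1e-27 g/A^3
        total_mass_g = np.trapezoid(dens, zgrid) * area * 1e-27  # g per box
        exact_n = total_mass_g / chain_mass * _const.N_A
        n_chains = int(spec.get("n_chains", round(exact_n)))
        if n_chains < 1:
            raise GeneratorSpecError(
                f"{name}: requested densities yield {exact_n:.2f} chains"
            )
        scale = n_chains / exact_n
        cdf = np.cumsum(dens)
        cdf = cdf / cdf[-1]
        per_species[name] = {
            "letters": letters, "n_chains": n_chains, "cdf": cdf,
            "arrs": arrs,
        }
        truth[name] = {
            "rho_dense": rho_d * scale,
            "rho_dilute": rho_l * scale,
            "z0": z0,
            "interface_width": interface_width,
            "n_chains": n_chains,
            "chain_molar_mass": chain_mass,
        }

    types, mol_id, species_arr, chain_index = [], [], [], []
    mass, sigma, charge = [], [], []
    mol = 0
    for name, info in per_species.items():
        L = len(info["letters"])
        for _ in range(info["n_chains"]):
            types.extend(list(info["letters"]))
            mol_id.extend([mol] * L)
            species_arr.extend([name] * L)
            chain_index.extend(range(1, L + 1))
            mass.extend(info["arrs"]["mass"])
            sigma.extend(info["arrs"]["sigma"])
            charge.extend(info["arrs"]["charge"])
            mol += 1
    n_beads = len(types)

    positions = np.zeros((n_frames, n_beads, 3))
    for f in range(n_frames):
        offset = 0
        for name, info in per_species.items():
            L = len(info["letters"])
            nc = info["n_chains"]
            zc = np.interp(rng.random(nc), info["cdf"], zgrid)
            centers = np.column_stack(
                [rng.uniform(-lx / 2, lx / 2, nc),
                 rng.uniform(-ly / 2, ly / 2, nc), zc]
            )
            coils = _coils(nc, L, rng) + centers[:, None, :]
            if noise > 0:
                coils = coils + rng.normal(scale=noise, size=coils.shape)
            coils = (coils + box / 2.0) % box - box / 2.0
            positions[f, offset:offset + nc * L] = coils.reshape(-1, 3)
            offset += nc * L

    return Trajectory(
        positions=positions,
        times=np.arange(n_frames, dtype=float) * frame_spacing_ps,
        box=box,
        types=np.array(types, dtype=object),
        mol_id=np.array(mol_id, dtype=np.int64),
        species=np.array(species_arr, dtype=object),
        chain_index=np.array(chain_index, dtype=np.int64),
        mass=np.array(mass),
        sigma=np.array(sigma),
        charge=np.array(charge),
        metadata={"truth": truth, "seed": seed, "noise": noise},
    )
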