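"""Frame-averaged intermolecular contact maps.

Two beads on different molecules are "in contact" when their distance (under
minimum image) is below ``cutoff_factor`` times the arithmetic mean of their
van der Waals diameters, i.e. r < cutoff_factor * (sigma_i + sigma_j) / 2
with the model's per-bead sigma standing in for the vdW size (~9 A for a
typical residue pair at the default factor 1.5).  Counts are resolved by the
1-based intra-chain position of each partner, averaged per frame and per
contributing chain pair, and can be restricted to the condensed phase
(|z - z_slab| below the fitted interface position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from cgslab.slab_analysis import (
    SelectionError,
    _circular_mean_z,
    center_and_profile,
    fit_coexistence,
)

logger = logging.getLogger(__name__)


@dataclass
class ContactMap:
    """Mean intermolecular contacts per frame per chain pair.

    ``matrix[i, j]`` refers to position i+1 of species A and position j+1 of
    species B; ``marginal_a``/``marginal_b`` are its row/column sums.  For
    A == B the matrix is symmetric.
    """

    species_a: str
    species_b: str
    matrix: np.ndarray
    cutoff_factor: float
    n_frames: int
    dense_phase_only: bool

    @property
    def marginal_a(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def intermolecular_contact_map(
    traj,
    species_pair,
    cutoff_factor: float = 1.5,
    dense_phase_only: bool = True,
    z_interface: float | None = None,
) -> ContactMap:
    """Compute the 2D intermolecular contact map for a species pair.

    Equilibration frames are assumed excluded upstream.  When
    ``dense_phase_only`` is set, only bead pairs whose members both lie
    within the slab (|z - slab center| < z0, the interface position from the
    coexistence fit, or ``z_interface`` when given) are counted; if the
    trajectory is not phase-separated the restriction is dropped with a
    warning.
    """
    if cutoff_factor <= 0:
        raise ValueError("cutoff_factor must be positive")
    name_a, name_b = species_pair
    for name in (name_a, name_b):
        if not (traj.species == name).any():
            raise SelectionError(f"species {name!r} not in trajectory")
    box = np.asarray(traj.box, dtype=float)
    lz = box[2]
    mask_a = traj.species == name_a
    mask_b = traj.species == name_b
    idx_a = np.nonzero(mask_a)[0]
    idx_b = np.nonzero(mask_b)[0]
    len_a = int(traj.chain_index[idx_a].max())
    len_b = int(traj.chain_index[idx_b].max())
    n_chains_a = len(np.unique(traj.mol_id[idx_a]))
    n_chains_b = len(np.unique(traj.mol_id[idx_b]))
    same = name_a == name_b
    if same and n_chains_a < 2:
        # a single chain has no intermolecular partner: all-zero map
        return ContactMap(name_a, name_b, np.zeros((len_a, len_b)),
                          cutoff_factor, traj.n_frames, dense_phase_only)

    if dense_phase_only and z_interface is None:
        prof = center_and_profile(
            traj, species=sorted({name_a, name_b}),
            equilibration_fraction=0.0,
        )
        coex = fit_coexistence(prof)
        seps = [c for c in coex.values() if c.phase_separated]
        if seps:
            z_interface = float(np.mean([c.z0 for c in seps]))
        else:
            logger.warning(
                "no phase separation detected; contact map computed over the "
                "whole box"
            )
            dense_phase_only = False

    max_cut = cutoff_factor * float(traj.sigma.max())
    counts = np.zeros((len_a, len_b))
    sel_mass = np.isin(traj.species, sorted({name_a, name_b}))
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        if dense_phase_only:
            zc = _circular_mean_z(pos[sel_mass, 2], traj.mass[sel_mass], lz)
            dz = (pos[:, 2] - zc + lz / 2.0) % lz - lz / 2.0
            in_slab = np.abs(dz) < z_interface
            sub_a = idx_a[in_slab[idx_a]]
            sub_b = idx_b[in_slab[idx_b]]
        else:
            sub_a, sub_b = idx_a, idx_b
        if len(sub_a) == 0 or len(sub_b) == 0:
            continue
        wrapped = (pos + box / 2.0) % box
        tree_a = cKDTree(wrapped[sub_a], boxsize=box)
        tree_b = cKDTree(wrapped[sub_b], boxsize=box)
        neighbor_lists = tree_a.query_ball_tree(tree_b, r=max_cut)
        for ia_local, partners in enumerate(neighbor_lists):
            ga = sub_a[ia_local]
            for ib_local in partners:
                gb = sub_b[ib_local]
                if traj.mol_id[ga] == traj.mol_id[gb]:
                    continue
                if same and ga >= gb:
                    continue  # count unordered pairs once
                d = wrapped[ga] - wrapped[gb]
                d -= box * np.rint(d / box)
                r = np.sqrt((d * d).sum())
                cut = cutoff_factor * 0.5 * (traj.sigma[ga] + traj.sigma[gb])
                if r < cut:
                    ca = int(traj.chain_index[ga]) - 1
                    cb = int(traj.chain_index[gb]) - 1
                    counts[ca, cb] += 1.0
                    if same:
                        counts[cb, ca] += 1.0
    if same:
        n_pairs = n_chains_a * (n_chains_a - 1)
    else:
        n_pairs = n_chains_a * n_chains_b
    matrix = counts / max(traj.n_frames, 1) / max(n_pairs, 1)
    return ContactMap(
        species_a=name_a,
        species_b=name_b,
        matrix=matrix,
        cutoff_factor=cutoff_factor,
        n_frames=traj.n_frames,
        dense_phase_only=dense_phase_only,
    )
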