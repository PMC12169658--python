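"""z-density profiles and coexistence (saturation concentration) extraction.

A slab simulation samples both phases at once: the dense phase forms a slab
perpendicular to the long z axis and the dilute phase fills the rest of the
box.  The analysis (i) discards an equilibration fraction of frames,
(ii) recenters every frame so the slab's mass center (a circular mean over
the periodic z coordinate) sits at z = 0, (iii) accumulates species-resolved
histograms in both mass density (mg/mL) and chain molarity (uM), and
(iv) extracts coexistence concentrations by fitting the symmetrized profile

    rho(z) = (rho_d + rho_l)/2 - (rho_d - rho_l)/2 * tanh((|z| - z0)/w)

The fitted dilute-phase value rho_l is the saturation concentration C_sat;
region averages (dense: |z| < z0 - 2w, dilute: |z| > z0 + 2w) are reported
alongside as a fit-free fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: mg/mL threshold treated as numerically zero when judging phase separation
_RHO_FLOOR = 1e-9
#: minimum dense/dilute contrast to call a profile phase-separated
MIN_CONTRAST = 1.5


class SelectionError(ValueError):
    """Requested species not present in the trajectory."""


class DataError(ValueError):
    """Not enough post-equilibration frames."""


def mgml_to_uM(rho_mgml, molar_mass: float):
    """mg/mL (= g/L) to micromolar given the chain molar mass in g/mol."""
    return np.asarray(rho_mgml) / molar_mass * 1e6


def uM_to_mgml(c_uM, molar_mass: float):
    return np.asarray(c_uM) * molar_mass / 1e6


@dataclass
class DensityProfile:
    """Species-resolved density vs z, slab-centered.

    ``mass_density[s]`` is in mg/mL and ``molarity[s]`` in uM (chains, by
    center of mass), both shaped like ``z_centers``.
    """

    z_centers: np.ndarray
    bin_width: float
    mass_density: dict
    molarity: dict
    chain_molar_mass: dict
    n_chains: dict
    box: np.ndarray
    n_frames: int

    def species_names(self):
        return sorted(self.mass_density)


def _circular_mean_z(z, weights, lz):
    theta = 2.0 * np.pi * z / lz
    s = np.average(np.sin(theta), weights=weights)
    c = np.average(np.cos(theta), weights=weights)
    return lz * np.arctan2(s, c) / (2.0 * np.pi)


def _wrap(z, lz):
    return (z + lz / 2.0) % lz - lz / 2.0


def center_and_profile(
    traj,
    species=None,
    bin_width: float = 5.0,
    equilibration_fraction: float = 0.2,
    center: bool = True,
) -> DensityProfile:
    """Slab-centered z-density profile of a trajectory.

    The leading ``equilibration_fraction`` of frames is discarded.  Each
    remaining frame is shifted so the mass-weighted circular mean of the
    selected species' z coordinates is zero, then species-resolved mass and
    chain-count histograms are accumulated.

    Caveat: recentering a system that is *not* phase-separated aligns its
    density fluctuations and imprints a spurious central bump (amplitude
    ~ n_chains^-1/2); :func:`fit_coexistence` guards against mistaking it
    for coexistence, and :func:`density_contrast` measures dense/dilute
    contrast in a way that is immune to it.
    """
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    names = traj.species_names() if species is None else (
        [species] if isinstance(species, str) else list(species)
    )
    for name in names:
        if not (traj.species == name).any():
            raise SelectionError(f"species {name!r} not in trajectory")
    start = int(np.floor(traj.n_frames * equilibration_fraction))
    frames = range(start, traj.n_frames)
    if len(frames) < 2:
        raise DataError(
            f"only {len(frames)} post-equilibration frames (need >= 2)"
        )
    box = np.asarray(traj.box, dtype=float)
    lx, ly, lz = box
    n_bins = max(int(round(lz / bin_width)), 1)
    width = lz / n_bins
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    sel_mask = np.isin(traj.species, names)
    mass_hist = {name: np.zeros(n_bins) for name in names}
    chain_hist = {name: np.zeros(n_bins) for name in names}
    mol_masses = {}
    n_chains = {}
    species_masks = {name: traj.species == name for name in names}
    mol_info = {}
    for name in names:
        mols = np.unique(traj.mol_id[species_masks[name]])
        n_chains[name] = len(mols)
        idx_list = [np.nonzero(traj.mol_id == m)[0] for m in mols]
        if len({len(ix) for ix in idx_list}) != 1:
            raise ValueError(
                f"species {name!r}: chains of unequal length share a label"
            )
        # chains of one species share a length: index as a (n_mols, L) block
        mol_info[name] = np.vstack(idx_list)
        mol_masses[name] = float(traj.mass[idx_list[0]].sum())

    frame_centers = np.array(
        [
            _circular_mean_z(
                traj.positions[f, sel_mask, 2], traj.mass[sel_mask], lz
            )
            for f in frames
        ]
    )
    for fi, f in enumerate(frames):
        z = traj.positions[f, :, 2]
        zc = frame_centers[fi] if center else 0.0
        zs = _wrap(z - zc, lz)
        for name in names:
            mask = species_masks[name]
            mass_hist[name] += np.histogram(
                zs[mask], bins=edges, weights=traj.mass[mask]
            )[0]
            blk = mol_info[name]
            theta = 2.0 * np.pi * zs[blk] / lz
            w = traj.mass[blk]
            s = (w * np.sin(theta)).sum(1)
            c = (w * np.cos(theta)).sum(1)
            coms = lz * np.arctan2(s, c) / (2.0 * np.pi)
            chain_hist[name] += np.histogram(_wrap(coms, lz), bins=edges)[0]

    n_used = len(frames)
    bin_vol_cm3 = lx * ly * width * 1e-24
    bin_vol_L = bin_vol_cm3 * 1e-3
    mass_density = {}
    molarity = {}
    for name in names:
        grams_per_bin = mass_hist[name] / n_used / _const.N_A
        mass_density[name] = grams_per_bin / bin_vol_cm3 * 1000.0  # mg/mL
        mols_per_bin = chain_hist[name] / n_used / _const.N_A
        molarity[name] = mols_per_bin / bin_vol_L * 1e6  # uM
    return DensityProfile(
        z_centers=centers,
        bin_width=width,
        mass_density=mass_density,
        molarity=molarity,
        chain_molar_mass=mol_masses,
        n_chains=n_chains,
        box=box,
        n_frames=n_used,
    )


def density_contrast(
    traj,
    species=None,
    equilibration_fraction: float = 0.2,
    bin_width: float = 5.0,
) -> float:
    """Slab-center vs box-edge density ratio, robust to drift and to the
    recentering bias of homogeneous systems.

    Uses split-half centering: chains are divided into two groups by parity;
    each frame is centered on the circular mean of one group while only the
    *other* group's beads are histogrammed (both orientations accumulated).
    For a phase-separated slab the two halves are co-located, so this tracks
    the drifting slab like ordinary centering; for a dispersed system the
    groups are independent, so the reference shift cannot imprint structure
    and the expected profile is flat.  Returns the mean density in the
    central quarter of z divided by the mean density in the outer quarter.
    """
    names = traj.species_names() if species is None else (
        [species] if isinstance(species, str) else list(species)
    )
    sel = np.isin(traj.species, names)
    mols = np.unique(traj.mol_id[sel])
    if len(mols) < 2:
        raise SelectionError("split-half contrast needs at least two chains")
    group_a = np.isin(traj.mol_id, mols[::2]) & sel
    group_b = np.isin(traj.mol_id, mols[1::2]) & sel
    lz = float(traj.box[2])
    n_bins = max(int(round(lz / bin_width)), 1)
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    start = int(np.floor(traj.n_frames * equilibration_fraction))
    hist = np.zeros(n_bins)
    for f in range(start, traj.n_frames):
        z = traj.positions[f, :, 2]
        for ref, other in ((group_a, group_b), (group_b, group_a)):
            zc = _circular_mean_z(z[ref], traj.mass[ref], lz)
            zs = _wrap(z[other] - zc, lz)
            hist += np.histogram(zs, bins=edges, weights=traj.mass[other])[0]
    central = hist[np.abs(centers) < lz / 8.0].mean()
    outer = hist[np.abs(centers) > 3.0 * lz / 8.0].mean()
    return float(central / max(outer, 1e-12 * max(central, 1.0)))


@dataclass
class CoexistenceResult:
    """Coexisting dense/dilute concentrations for one species.

    ``dilute_mgml`` is the saturation concentration C_sat.  ``method`` is
    "fit" when the tanh fit converged, "region" when the region-average
    fallback was used.  Replicate statistics (mean +- sd over seeds) are
    populated by :func:`fit_coexistence` when several profiles are given.
    """

    species: str
    dense_mgml: float
    dilute_mgml: float
    dense_uM: float
    dilute_uM: float
    z0: float
    width: float
    phase_separated: bool
    method: str = "fit"
    dense_sd_mgml: float = 0.0
    dilute_sd_mgml: float = 0.0
    n_replicates: int = 1
    region_dense_mgml: float = np.nan
    region_dilute_mgml: float = np.nan
    replicate_dilute_mgml: list = field(default_factory=list)
    replicate_dense_mgml: list = field(default_factory=list)


def _tanh_profile(z, rho_d, rho_l, z0, w):
    return 0.5 * (rho_d + rho_l) - 0.5 * (rho_d - rho_l) * np.tanh(
        (np.abs(z) - z0) / w
    )


def _fit_single(z, rho, bin_width, lz):
    """Fit the symmetric tanh profile; returns (params, converged)."""
    rho_d0 = float(np.max(rho))
    n_edge = max(len(rho) // 10, 1)
    rho_l0 = float(np.mean(np.concatenate([rho[:n_edge], rho[-n_edge:]])))
    mid = 0.5 * (rho_d0 + rho_l0)
    above = np.abs(z)[rho > mid]
    z0_0 = float(above.max()) if len(above) else lz / 8.0
    best = None
    for w0 in (bin_width, 4.0 * bin_width, 0.25 * bin_width):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _tanh_profile, z, rho,
                    p0=[rho_d0, rho_l0, z0_0, w0],
                    bounds=([0.0, 0.0, 0.0, 1e-4],
                            [np.inf, np.inf, lz / 2.0, lz]),
                    maxfev=20000,
                )
        except RuntimeError:
            continue
        resid = float(np.sum((_tanh_profile(z, *popt) - rho) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return None, False
    return best[0], True


def _finite_mean(vals) -> float:
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("nan")


def _region_averages(z, rho, z0, w):
    dense = rho[np.abs(z) < max(z0 - 2.0 * w, 0.0)]
    dilute = rho[np.abs(z) > z0 + 2.0 * w]
    d = float(dense.mean()) if len(dense) else np.nan
    l = float(dilute.mean()) if len(dilute) else np.nan
    return d, l


def fit_coexistence(profiles, species=None) -> dict:
    """Extract coexistence concentrations per species.

    ``profiles`` is a DensityProfile or a list of replicate profiles sharing
    the same binning (independent seeds); replicate mean +- sd is reported.
    Returns ``{species: CoexistenceResult}``.
    """
    if isinstance(profiles, DensityProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    names = ref.species_names() if species is None else (
        [species] if isinstance(species, str) else list(species)
    )
    results = {}
    for name in names:
        per_rep = []
        for prof in profiles:
            z = prof.z_centers
            rho = prof.mass_density[name]
            lz = prof.box[2]
            popt, converged = _fit_single(z, rho, prof.bin_width, lz)
            if converged:
                rho_d, rho_l, z0, w = (float(v) for v in popt)
                method = "fit"
            else:
                logger.warning(
                    "tanh fit did not converge for %s; falling back to "
                    "region averages", name,
                )
                rho_d = float(np.max(rho))
                rho_l = float(np.min(rho))
                z0, w = lz / 8.0, prof.bin_width
                method = "region"
            reg_d, reg_l = _region_averages(z, rho, z0, w)
            if method == "region" and np.isfinite(reg_d) and np.isfinite(reg_l):
                rho_d, rho_l = reg_d, reg_l
            contrast = rho_d / max(rho_l, _RHO_FLOOR)
            # a genuine coexistence interface is sharp on the box scale and
            # leaves room for a dilute plateau; recentering noise on a
            # homogeneous system imprints a box-wide cosine bump instead
            separated = bool(
                contrast >= MIN_CONTRAST
                and w < lz / 8.0
                and z0 + 2.0 * w < lz / 2.0
            )
            if not separated:
                mean_rho = float(np.mean(rho))
                rho_d = rho_l = mean_rho
            per_rep.append((rho_d, rho_l, z0, w, method, separated, reg_d, reg_l))
        dense_vals = np.array([r[0] for r in per_rep])
        dilute_vals = np.array([r[1] for r in per_rep])
        m = ref.chain_molar_mass[name]
        results[name] = CoexistenceResult(
            species=name,
            dense_mgml=float(dense_vals.mean()),
            dilute_mgml=float(dilute_vals.mean()),
            dense_uM=float(mgml_to_uM(dense_vals.mean(), m)),
            dilute_uM=float(mgml_to_uM(dilute_vals.mean(), m)),
            z0=float(np.mean([r[2] for r in per_rep])),
            width=float(np.mean([r[3] for r in per_rep])),
            phase_separated=all(r[5] for r in per_rep),
            method=per_rep[0][4],
            dense_sd_mgml=float(dense_vals.std(ddof=1)) if len(per_rep) > 1 else 0.0,
            dilute_sd_mgml=float(dilute_vals.std(ddof=1)) if len(per_rep) > 1 else 0.0,
            n_replicates=len(per_rep),
            region_dense_mgml=_finite_mean([r[6] for r in per_rep]),
            region_dilute_mgml=_finite_mean([r[7] for r in per_rep]),
            replicate_dilute_mgml=[float(v) for v in dilute_vals],
            replicate_dense_mgml=[float(v) for v in dense_vals],
        )
    return results
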