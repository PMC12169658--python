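"""Two-component coexistence scans: mixture points, tie lines, dense arm.

A mixture scan varies the ratio of two species at (approximately) constant
total chain count, runs one slab coexistence simulation per ratio and seed
(or consumes pre-made trajectories), extracts per-species dense and dilute
concentrations, and assembles the two-component phase diagram: one mixture
point per ratio, a tie line connecting each point's dilute and dense
compositions, and the dense-arm boundary polyline.  A third fixed-
stoichiometry species (e.g. duplex DNA at a 5:1 protein-to-DNA mole ratio)
can ride along; its concentrations are recorded but it is not a diagram
axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from cgslab.dynamics import SimulationConfig, run_langevin
from cgslab.energetics import InteractionConfig
from cgslab.slab_analysis import center_and_profile, fit_coexistence
from cgslab.topology import assemble_slab_system

logger = logging.getLogger(__name__)

DEFAULT_RATIOS = ((4, 1), (2, 1), (1, 1), (1, 2), (1, 4))


@dataclass
class MixturePoint:
    """Coexistence data for one input ratio (replicate mean +- sd)."""

    ratio: tuple
    counts: dict
    dilute_uM: dict
    dense_uM: dict
    dilute_sd_uM: dict
    dense_sd_uM: dict
    phase_separated: bool
    n_replicates: int
    failed_seeds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ratio": list(self.ratio),
            "counts": self.counts,
            "dilute_uM": self.dilute_uM,
            "dense_uM": self.dense_uM,
            "dilute_sd_uM": self.dilute_sd_uM,
            "dense_sd_uM": self.dense_sd_uM,
            "phase_separated": self.phase_separated,
            "n_replicates": self.n_replicates,
            "failed_seeds": self.failed_seeds,
        }


@dataclass
class PhaseDiagram:
    """Ordered mixture points plus tie lines and the dense-arm boundary.

    Tie lines are ((dilute_A, dilute_B), (dense_A, dense_B)) in uM for each
    phase-separated point, in ratio order; the dense arm is the polyline of
    dense-phase compositions.
    """

    species_a: str
    species_b: str
    points: list
    tie_lines: list
    dense_arm: list

    def to_json(self, path=None) -> str:
        payload = {
            "species": [self.species_a, self.species_b],
            "points": [p.to_dict() for p in self.points],
            "tie_lines": self.tie_lines,
            "dense_arm": self.dense_arm,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path=None) -> str:
        lines = [
            "ratio_a\tratio_b\tdilute_a_uM\tdilute_b_uM\tdense_a_uM\t"
            "dense_b_uM\tphase_separated"
        ]
        for p in self.points:
            a, b = p.ratio
            lines.append(
                f"{a}\t{b}\t{p.dilute_uM[self.species_a]:.6g}\t"
                f"{p.dilute_uM[self.species_b]:.6g}\t"
                f"{p.dense_uM[self.species_a]:.6g}\t"
                f"{p.dense_uM[self.species_b]:.6g}\t{p.phase_separated}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _counts_for_ratio(ratio, total_chains):
    a, b = ratio
    if a < 0 or b < 0 or (a == 0 and b == 0):
        raise ValueError(f"invalid ratio {ratio}")
    n_a = int(round(total_chains * a / (a + b)))
    n_b = total_chains - n_a
    return n_a, n_b


def build_phase_diagram(
    fragments: dict,
    species_pair,
    ratios=DEFAULT_RATIOS,
    total_chains: int = 40,
    box=(80.0, 80.0, 480.0),
    seeds=(1, 2, 3),
    sim_config: SimulationConfig | None = None,
    interactions: InteractionConfig | None = None,
    dna_species: str | None = None,
    protein_per_dna: int = 5,
    equilibration_fraction: float = 0.2,
    bin_width: float = 5.0,
    workdir=None,
    trajectories: dict | None = None,
) -> PhaseDiagram:
    """Run (or consume) one slab simulation per ratio x seed and assemble
    the two-component phase diagram.

    ``fragments`` maps species name to a single-chain CGTopology fragment;
    ``species_pair`` = (A, B) names the diagram axes.  ``trajectories`` may
    supply pre-made trajectories keyed ``(ratio, seed)`` (then no dynamics
    is run).  With ``workdir`` set, per-cell results are written as JSON and
    completed cells are skipped on re-runs, making long scans resumable.
    A failed replicate flags the point but the diagram is still produced.
    """
    name_a, name_b = species_pair
    sim_config = sim_config or SimulationConfig()
    interactions = interactions or InteractionConfig()
    if workdir is not None:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)

    points = []
    for ratio in ratios:
        n_a, n_b = _counts_for_ratio(tuple(ratio), total_chains)
        counts = {}
        if n_a > 0:
            counts[name_a] = n_a
        if n_b > 0:
            counts[name_b] = n_b
        if dna_species is not None:
            n_dna = max(int(round((n_a + n_b) / protein_per_dna)), 1)
            counts[dna_species] = n_dna
        per_seed = {}
        failed = []
        for seed in seeds:
            cell = f"r{ratio[0]}-{ratio[1]}_s{seed}"
            cell_file = workdir / f"{cell}.json" if workdir else None
            if cell_file is not None and cell_file.exists():
                per_seed[seed] = json.loads(cell_file.read_text())
                continue
            try:
                if trajectories is not None:
                    traj = trajectories[(tuple(ratio), seed)]
                    equil = 0.0
                else:
                    topo = assemble_slab_system(
                        fragments, counts, box, seed=seed
                    )
                    traj = run_langevin(
                        topo, replace(sim_config, seed=seed), interactions
                    )
                    equil = equilibration_fraction
                prof = center_and_profile(
                    traj, bin_width=bin_width, equilibration_fraction=equil
                )
                coex = fit_coexistence(prof)
                result = {
                    name: {
                        "dilute_uM": coex[name].dilute_uM,
                        "dense_uM": coex[name].dense_uM,
                        "phase_separated": coex[name].phase_separated,
                    }
                    for name in coex
                }
                per_seed[seed] = result
                if cell_file is not None:
                    cell_file.write_text(json.dumps(result, sort_keys=True))
            except Exception as err:  # noqa: BLE001 - replicate-level fault wall
                logger.warning("ratio %s seed %s failed: %s", ratio, seed, err)
                failed.append(seed)
        if not per_seed:
            points.append(
                MixturePoint(
                    ratio=tuple(ratio), counts=counts,
                    dilute_uM={}, dense_uM={}, dilute_sd_uM={},
                    dense_sd_uM={}, phase_separated=False,
                    n_replicates=0, failed_seeds=failed,
                )
            )
            continue
        names_here = sorted(next(iter(per_seed.values())))
        dil, den, dil_sd, den_sd = {}, {}, {}, {}
        for name in names_here:
            dvals = np.array([per_seed[s][name]["dilute_uM"] for s in per_seed])
            Dvals = np.array([per_seed[s][name]["dense_uM"] for s in per_seed])
            dil[name] = float(dvals.mean())
            den[name] = float(Dvals.mean())
            dil_sd[name] = float(dvals.std(ddof=1)) if len(dvals) > 1 else 0.0
            den_sd[name] = float(Dvals.std(ddof=1)) if len(Dvals) > 1 else 0.0
        separated = all(
            per_seed[s][name]["phase_separated"]
            for s in per_seed for name in names_here
        )
        points.append(
            MixturePoint(
                ratio=tuple(ratio), counts=counts, dilute_uM=dil,
                dense_uM=den, dilute_sd_uM=dil_sd, dense_sd_uM=den_sd,
                phase_separated=separated, n_replicates=len(per_seed),
                failed_seeds=failed,
            )
        )

    tie_lines = []
    dense_arm = []
    for p in points:
        if not p.dilute_uM:
            continue
        da = p.dense_uM.get(name_a, 0.0)
        db = p.dense_uM.get(name_b, 0.0)
        la = p.dilute_uM.get(name_a, 0.0)
        lb = p.dilute_uM.get(name_b, 0.0)
        dense_arm.append([da, db])
        if p.phase_separated:
            tie_lines.append([[la, lb], [da, db]])
    return PhaseDiagram(
        species_a=name_a, species_b=name_b, points=points,
        tie_lines=tie_lines, dense_arm=dense_arm,
    )
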