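import numpy as np
import pytest

from cgslab.params import default_table
from cgslab.sequences import SequenceRecord
from cgslab.topology import CGTopology

# ---------------------------------------------------------------------------
# shared heavy simulation runs (session-scoped: computed once, asserted on
# both by the module tests and by the acceptance suite)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = "".join(rng.choice(list(alphabet), size=length))
    return SequenceRecord(id=f"rand{length}", kind="protein", letters=letters)


def free_bead_system(n, box_side=2000.0, mass=100.0, sigma=5.0, seed=0):
    """Noninteracting beads spread far apart in a huge box."""
    gen = np.random.default_rng(seed)
    return CGTopology(
        types=np.array(["G"] * n, dtype=object),
        mass=np.full(n, mass),
        charge=np.zeros(n),
        sigma=np.full(n, sigma),
        lam=np.zeros(n),
        mol_id=np.arange(n, dtype=np.int64),
        species=np.array(["X"] * n, dtype=object),
        chain_index=np.ones(n, dtype=np.int64),
        positions=gen.uniform(-box_side / 2, box_side / 2, (n, 3)),
        bonds=np.empty((0, 2), np.int64),
        bond_r0=np.empty(0),
        bond_k=np.empty(0),
        rigid_groups=[],
        box=np.array([box_side] * 3),
    )


def dimer_array_system(n_dimers, k=10.0, r0=3.8, mass=100.0, spacing=60.0):
    """Independent harmonic dimers far apart (bond interactions only)."""
    n = 2 * n_dimers
    side = spacing * int(np.ceil(n_dimers ** (1 / 3))) + spacing
    grid = []
    m = int(np.ceil(n_dimers ** (1 / 3)))
    for a in range(m):
        for b in range(m):
            for c in range(m):
                if len(grid) < n_dimers:
                    grid.append(
                        np.array([a, b, c]) * spacing - side / 2 + spacing / 2
                    )
    pos = np.zeros((n, 3))
    for d, g in enumerate(grid):
        pos[2 * d] = g
        pos[2 * d + 1] = g + np.array([r0, 0.0, 0.0])
    topo = free_bead_system(n, box_side=side, mass=mass)
    topo.positions = pos
    topo.mol_id = np.repeat(np.arange(n_dimers, dtype=np.int64), 2)
    topo.bonds = np.array(
        [[2 * d, 2 * d + 1] for d in range(n_dimers)], dtype=np.int64
    )
    topo.bond_r0 = np.full(n_dimers, r0)
    topo.bond_k = np.full(n_dimers, k)
    return topo


@pytest.fixture(scope="session")
def equipartition_run():
    """Thermostatted ensemble of noninteracting beads at 320 K, 10 fs,
    tau = 1000 ps; returns (topology, trajectory)."""
    from cgslab.dynamics import SimulationConfig, run_langevin
    from cgslab.energetics import InteractionConfig

    topo = free_bead_system(300, box_side=4000.0)
    cfg = SimulationConfig(
        n_steps=300_000, save_interval=6000, seed=41,
        save_velocities=True, temperature=320.0,
    )
    traj = run_langevin(
        topo, cfg, InteractionConfig(ah_cutoff=0.5, dh_cutoff=0.5)
    )
    return topo, traj


@pytest.fixture(scope="session")
def dimer_run():
    """Harmonic-dimer ensemble (k = 10 kcal/mol/A^2) at 320 K, 10 fs,
    tau = 1000 ps; returns (k, bond-length samples after thermalization)."""
    from cgslab.dynamics import SimulationConfig, run_langevin
    from cgslab.energetics import InteractionConfig

    k = 10.0
    topo = dimer_array_system(256, k=k)
    cfg = SimulationConfig(
        n_steps=800_000, save_interval=4000, seed=7, temperature=320.0,
    )
    # full cutoffs: dimers fly ballistically at this weak friction and do
    # meet; smooth elastic cores leave the equilibrium bond statistics alone
    traj = run_langevin(topo, cfg, InteractionConfig())
    start = traj.n_frames // 4
    d = traj.positions[start:, 0::2] - traj.positions[start:, 1::2]
    d -= traj.box * np.rint(d / traj.box)  # dimers may straddle the boundary
    r = np.linalg.norm(d, axis=2).ravel()
    return k, r


@pytest.fixture(scope="session")
def rigid_drift_run():
    """Rigid-domain chain integrated 1e4 steps; returns (group indices,
    reference positions, trajectory)."""
    from cgslab.dynamics import SimulationConfig, run_langevin
    from cgslab.energetics import InteractionConfig
    from cgslab.synthetic import make_rigid_fixture
    from cgslab.topology import DomainAnnotation, build_protein_chain

    template = make_rigid_fixture(12, geometry="compact", seed=3)
    ann = DomainAnnotation("fold", 5, 16, template=template)
    frag = build_protein_chain(
        SequenceRecord(
            "p", "protein", "A" * 4 + "K" * 6 + "E" * 6 + "A" * 4
        ),
        [ann], seed=2,
    )
    frag.box = np.array([150.0, 150.0, 160.0])
    from cgslab.dynamics import minimize

    minimize(frag, InteractionConfig(), n_steps=200)
    cfg = SimulationConfig(n_steps=10_000, save_interval=2000, seed=21)
    traj = run_langevin(frag, cfg, InteractionConfig())
    return frag, traj


@pytest.fixture(scope="session")
def charge_patterning_runs():
    """Scaled-down slab coexistence of blocky vs alternating 30-mer K/E
    polyampholytes (10 chains, 320 K, 100 mM salt); returns trajectories
    keyed by blockiness.  Density contrast on these is measured with
    split-half centering (see slab_analysis.density_contrast), which tracks
    a drifting slab without letting recentering bias inflate the apparent
    contrast of a dispersed system.
    """
    from cgslab.dynamics import SimulationConfig, minimize, run_langevin
    from cgslab.energetics import InteractionConfig
    from cgslab.synthetic import make_polyampholyte
    from cgslab.topology import assemble_slab_system, build_protein_chain

    box = (50.0, 50.0, 300.0)
    inter = InteractionConfig(
        ah_cutoff=15.0, dh_cutoff=25.0, skin=2.0,
        temperature=320.0, ionic_strength=0.1,
    )
    trajs = {}
    for blockiness, steps in ((1.0, 100_000), (0.0, 250_000)):
        seq = make_polyampholyte(30, 0.5, 0.5, blockiness, 0)
        frag = build_protein_chain(seq, seed=1)
        topo = assemble_slab_system(
            {"P": frag}, {"P": 10}, box, seed=2, min_dist=3.5
        )
        minimize(topo, inter, n_steps=100)
        cfg = SimulationConfig(
            n_steps=steps, save_interval=steps // 40, seed=5,
            temperature=320.0,
        )
        trajs[blockiness] = run_langevin(topo, cfg, inter)
    return trajs


def random_spaced_positions(rng, n, extent, min_dist):
    """Random points with a minimum pairwise spacing (rejection sampling)."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-extent / 2, extent / 2, 3)
        if not pts or np.min(
            np.linalg.norm(np.asarray(pts) - cand, axis=1)
        ) >= min_dist:
            pts.append(cand)
    return np.asarray(pts)
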