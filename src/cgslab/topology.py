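"""Coarse-grained topology builders.

Proteins are modeled with one bead per residue (bead type = residue letter),
double-stranded DNA with two beads per nucleotide: a charged sugar-phosphate
backbone bead (type ``DB``, -1 e) and a neutral base bead (type ``DN``).
Folded domains are registered as rigid groups whose reference geometry is the
template coordinates; the rest of a chain is flexible and initialized as a
self-avoiding walk.  Multi-chain slab systems are assembled inside an
orthorhombic periodic box centered at the origin with z as the long axis.

Residue indices are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from cgslab.params import ParameterTable, default_table
from cgslab.sequences import SequenceRecord, reverse_complement

BACKBONE_R0 = 3.8  # Angstrom, Calpha-Calpha virtual bond
BACKBONE_K = 2.39  # kcal/(mol A^2), harmonic bond constant of the HPS family
MIN_PLACEMENT_DIST = 2.0  # Angstrom, inter-bead clearance at assembly

# B-DNA-like duplex stand-in geometry
DNA_RISE = 3.4          # Angstrom per base pair
DNA_TWIST = np.deg2rad(36.0)
DNA_R_BACKBONE = 9.0    # Angstrom, backbone helix radius
DNA_R_BASE = 3.0        # Angstrom, base bead radius


class AnnotationError(ValueError):
    """Invalid or overlapping domain annotations."""


class GeometryError(ValueError):
    """Template geometry inconsistent with the annotated span."""


class PackingError(RuntimeError):
    """Could not place all requested chains; try a larger box."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A named span of a chain, optionally rigid with template coordinates.

    ``start``/``end`` are 1-based inclusive residue indices.  ``template``
    holds one (x, y, z) coordinate per residue of the span (e.g. Calpha
    positions extracted from a PDB file) and is required for rigid spans.
    """

    name: str
    start: int
    end: int
    rigid: bool = True
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"domain {self.name!r}: invalid span {self.start}..{self.end}"
            )
        if self.template is not None:
            object.__setattr__(
                self, "template", np.asarray(self.template, dtype=float)
            )
            if self.template.ndim != 2 or self.template.shape[1] != 3:
                raise GeometryError(
                    f"domain {self.name!r}: template must be (n, 3) coordinates"
                )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class CGTopology:
    """An assembled bead system (single fragment or multi-chain slab).

    Arrays are parallel over beads.  ``chain_index`` is the 1-based residue
    (or nucleotide) index within the parent molecule; ``rigid_groups`` are
    bead-index sets whose reference geometry is the stored positions.
    """

    types: np.ndarray            # (N,) str bead types
    mass: np.ndarray             # (N,) g/mol
    charge: np.ndarray          # (N,) e
    sigma: np.ndarray           # (N,) Angstrom
    lam: np.ndarray             # (N,) unitless hydropathy
    mol_id: np.ndarray          # (N,) int
    species: np.ndarray         # (N,) str labels
    chain_index: np.ndarray     # (N,) int, 1-based
    positions: np.ndarray       # (N, 3) Angstrom
    bonds: np.ndarray           # (M, 2) int bead indices
    bond_r0: np.ndarray         # (M,) Angstrom
    bond_k: np.ndarray          # (M,) kcal/(mol A^2)
    rigid_groups: list = field(default_factory=list)
    box: np.ndarray | None = None  # (3,) Angstrom, periodic, origin-centered

    @property
    def n_beads(self) -> int:
        return len(self.types)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.mol_id))

    def validate(self) -> None:
        n = self.n_beads
        assert self.positions.shape == (n, 3)
        if len(self.bonds):
            same_mol = self.mol_id[self.bonds[:, 0]] == self.mol_id[self.bonds[:, 1]]
            if not same_mol.all():
                raise ValueError("bond connects beads of different molecules")
        seen = np.zeros(n, dtype=bool)
        for group in self.rigid_groups:
            if seen[group].any():
                raise ValueError("bead assigned to two rigid groups")
            seen[group] = True
        if self.box is not None:
            half = np.asarray(self.box) / 2.0
            if (np.abs(self.positions) > half + 1e-9).any():
                raise ValueError("positions outside the periodic box")

    def species_names(self):
        return sorted(set(self.species.tolist()))

    def molecules_of(self, species: str) -> np.ndarray:
        return np.unique(self.mol_id[self.species == species])


def _walk_step(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _self_avoiding_extend(
    existing: list, start: np.ndarray, n: int, rng: np.random.Generator,
    step: float = BACKBONE_R0, min_dist: float = MIN_PLACEMENT_DIST,
    max_attempts: int = 200,
) -> list:
    """Grow n beads from ``start`` as a self-avoiding random walk."""
    new = []
    current = start
    for _ in range(n):
        placed = None
        best = None
        best_min = -np.inf
        for _ in range(max_attempts):
            cand = current + step * _walk_step(rng)
            pts = existing + new
            if pts:
                d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
                dmin = float(d.min())
            else:
                dmin = np.inf
            if dmin >= min_dist:
                placed = cand
                break
            if dmin > best_min:
                best_min, best = dmin, cand
        if placed is None:
            placed = best  # accept least-bad candidate; walk stays bonded
        new.append(placed)
        current = placed
    return new


def build_protein_chain(
    seq: SequenceRecord,
    annotations=(),
    table: ParameterTable | None = None,
    species: str | None = None,
    seed: int = 0,
) -> CGTopology:
    """Build a single protein chain fragment: one bead per residue.

    Consecutive residues are joined by harmonic bonds (r0 = 3.8 A).  Rigid
    annotated spans carry their template geometry verbatim (translated to
    splice into the walk); flexible residues follow a seeded self-avoiding
    walk with 2 A clearance.
    """
    if seq.kind != "protein":
        raise TypeError("build_protein_chain requires a protein sequence")
    table = table or default_table()
    L = len(seq)
    rigid_spans = []
    covered = np.zeros(L + 1, dtype=bool)
    for ann in annotations:
        if ann.end > L:
            raise AnnotationError(
                f"domain {ann.name!r}: span {ann.start}..{ann.end} exceeds "
                f"chain length {L}"
            )
        if not ann.rigid:
            continue
        if covered[ann.start:ann.end + 1].any():
            raise AnnotationError(f"domain {ann.name!r}: overlapping rigid spans")
        covered[ann.start:ann.end + 1] = True
        template = ann.template
        if template is None:
            from cgslab.synthetic import make_rigid_fixture
            template = make_rigid_fixture(len(ann), geometry="helix", seed=seed)
        if len(template) != len(ann):
            raise GeometryError(
                f"domain {ann.name!r}: template has {len(template)} coordinates "
                f"for a {len(ann)}-residue span"
            )
        rigid_spans.append((ann.start, ann.end, template))
    rigid_spans.sort()

    rng = np.random.default_rng(seed)
    coords: list = []
    i = 1
    spans = iter(rigid_spans)
    next_span = next(spans, None)
    while i <= L:
        if next_span is not None and next_span[0] == i:
            start, end, template = next_span
            anchor = (
                coords[-1] + BACKBONE_R0 * _walk_step(rng)
                if coords else np.zeros(3)
            )
            block = template - template[0] + anchor
            coords.extend(list(block))
            i = end + 1
            next_span = next(spans, None)
        else:
            stop = next_span[0] - 1 if next_span is not None else L
            n_flex = stop - i + 1
            start_pt = coords[-1] if coords else None
            if start_pt is None:
                coords.append(np.zeros(3))
                n_flex -= 1
                start_pt = coords[-1]
            coords.extend(
                _self_avoiding_extend(coords, np.asarray(start_pt), n_flex, rng)
            )
            i = stop + 1

    positions = np.asarray(coords, dtype=float)
    beads = list(seq.letters)
    arrs = table.arrays_for(beads)
    bonds = np.column_stack([np.arange(L - 1), np.arange(1, L)]).astype(np.int64)
    groups = [
        np.arange(start - 1, end, dtype=np.int64) for start, end, _ in rigid_spans
    ]
    return CGTopology(
        types=np.array(beads, dtype=object),
        mass=arrs["mass"],
        charge=arrs["charge"],
        sigma=arrs["sigma"],
        lam=arrs["lambda"],
        mol_id=np.zeros(L, dtype=np.int64),
        species=np.array([species or seq.id] * L, dtype=object),
        chain_index=np.arange(1, L + 1, dtype=np.int64),
        positions=positions,
        bonds=bonds,
        bond_r0=np.full(L - 1, BACKBONE_R0),
        bond_k=np.full(L - 1, BACKBONE_K),
        rigid_groups=groups,
    )


def build_dna_duplex(
    seq: SequenceRecord,
    table: ParameterTable | None = None,
    species: str | None = None,
    bond_k: float = BACKBONE_K,
) -> CGTopology:
    """Build a duplex DNA fragment: two beads per nucleotide, two strands.

    The sense strand is given; the antisense strand is its reverse
    complement.  Each nucleotide contributes one charged backbone bead (DB,
    -1 e) and one neutral base bead (DN) placed on a B-DNA-like helix (3.4 A
    rise, 36 deg twist).  Harmonic bonds along each backbone, backbone-base,
    and between paired bases hold the duplex together; this bonded scheme is
    a documented geometric stand-in rather than a published nucleic-acid
    force field, and the bead parameters can be replaced via ``table``.
    """
    if seq.kind != "dna":
        raise TypeError("build_dna_duplex requires a dna sequence")
    table = table or default_table()
    L = len(seq)
    anti = reverse_complement(seq)

    def helix(bp: int, radius: float, phase: float) -> np.ndarray:
        theta = bp * DNA_TWIST + phase
        return np.array(
            [radius * np.cos(theta), radius * np.sin(theta), bp * DNA_RISE]
        )

    positions = np.zeros((4 * L, 3))
    types = np.empty(4 * L, dtype=object)
    chain_index = np.zeros(4 * L, dtype=np.int64)
    # strand 1: nucleotide j (0-based) sits at base pair j
    # strand 2 (antisense, 5'->3'): nucleotide j pairs with bp L-1-j
    for j in range(L):
        b = 2 * j
        positions[b] = helix(j, DNA_R_BACKBONE, 0.0)
        positions[b + 1] = helix(j, DNA_R_BASE, 0.0)
        types[b], types[b + 1] = "DB", "DN"
        chain_index[b] = chain_index[b + 1] = j + 1
    for j in range(L):
        b = 2 * L + 2 * j
        bp = L - 1 - j
        positions[b] = helix(bp, DNA_R_BACKBONE, np.pi)
        positions[b + 1] = helix(bp, DNA_R_BASE, np.pi)
        types[b], types[b + 1] = "DB", "DN"
        chain_index[b] = chain_index[b + 1] = j + 1
    positions -= positions.mean(axis=0)

    bonds = []
    for s in range(2):
        off = 2 * L * s
        for j in range(L):
            bonds.append((off + 2 * j, off + 2 * j + 1))      # backbone-base
            if j + 1 < L:
                bonds.append((off + 2 * j, off + 2 * j + 2))  # backbone-backbone
    for j in range(L):  # base pairing: strand1 bp j <-> strand2 nt L-1-j
        bonds.append((2 * j + 1, 2 * L + 2 * (L - 1 - j) + 1))
    bonds = np.asarray(bonds, dtype=np.int64)
    dvec = positions[bonds[:, 0]] - positions[bonds[:, 1]]
    r0 = np.linalg.norm(dvec, axis=1)

    arrs = table.arrays_for(types.tolist())
    return CGTopology(
        types=types,
        mass=arrs["mass"],
        charge=arrs["charge"],
        sigma=arrs["sigma"],
        lam=arrs["lambda"],
        mol_id=np.zeros(4 * L, dtype=np.int64),
        species=np.array([species or seq.id] * (4 * L), dtype=object),
        chain_index=chain_index,
        positions=positions,
        bonds=bonds,
        bond_r0=r0,
        bond_k=np.full(len(bonds), bond_k),
        rigid_groups=[],
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _is_linear_chain(frag: CGTopology) -> bool:
    """True when bonds are exactly the consecutive path 0-1, 1-2, ..."""
    n = frag.n_beads
    if len(frag.bonds) != n - 1:
        return False
    expected = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return np.array_equal(np.sort(np.asarray(frag.bonds), axis=1), expected)


def _min_image_dist(points, cand, box):
    d = points - cand
    d -= box * np.rint(d / box)
    return np.sqrt((d * d).sum(axis=1))


def _grow_chain_in_situ(frag, rng, box, z_half, placed_pts, min_dist,
                        max_attempts):
    """Regrow a linear chain bead-by-bead amid already-placed beads.

    Flexible beads take 3.8 A self-avoiding steps; rigid spans are placed
    as randomly rotated template blocks.  This lets coils interpenetrate at
    condensed-slab density while honoring the bead-level clearance, which a
    whole-molecule placement cannot do.
    """
    n = frag.n_beads
    rigid_spans = []
    for grp in frag.rigid_groups:
        g = np.sort(np.asarray(grp))
        rigid_spans.append((int(g[0]), int(g[-1])))
    rigid_spans.sort()
    tree = cKDTree(placed_pts + box / 2.0, boxsize=box) if len(placed_pts) else None

    def clear(cand, own):
        if abs(cand[2]) > z_half:
            return False
        if tree is not None:
            d, _ = tree.query(((cand + box / 2.0) % box)[None, :], k=1)
            if d[0] < min_dist:
                return False
        if len(own) > 1:
            if _min_image_dist(np.asarray(own[:-1]), cand, box).min() < min_dist:
                return False
        return True

    for _restart in range(60):
        own: list = []
        i = 0
        spans = list(rigid_spans)
        failed = False
        while i < n and not failed:
            if spans and spans[0][0] == i:
                start, end = spans[0]
                template = frag.positions[start:end + 1]
                template = template - template[0]
                ok = False
                for _ in range(max_attempts):
                    rot = _random_rotation(rng)
                    anchor = (
                        own[-1] + BACKBONE_R0 * _walk_step(rng)
                        if own else np.array([
                            rng.uniform(-box[0] / 2, box[0] / 2),
                            rng.uniform(-box[1] / 2, box[1] / 2),
                            rng.uniform(-z_half, z_half),
                        ])
                    )
                    block = template @ rot.T + anchor
                    if all(clear(b, own + [b]) for b in block):
                        own.extend(list(block))
                        ok = True
                        break
                if not ok:
                    failed = True
                else:
                    spans.pop(0)
                    i = end + 1
            else:
                for _ in range(max_attempts):
                    cand = (
                        own[-1] + BACKBONE_R0 * _walk_step(rng)
                        if own else np.array([
                            rng.uniform(-box[0] / 2, box[0] / 2),
                            rng.uniform(-box[1] / 2, box[1] / 2),
                            rng.uniform(-z_half, z_half),
                        ])
                    )
                    own.append(cand)
                    if clear(cand, own):
                        break
                    own.pop()
                else:
                    failed = True
                i += 1
        if not failed:
            return np.asarray(own)
    raise PackingError(
        "could not grow chain at the requested density; use a larger box "
        "or fewer chains"
    )


def assemble_slab_system(
    fragments: dict,
    counts: dict,
    box,
    seed: int = 0,
    min_dist: float = MIN_PLACEMENT_DIST,
    slab_fraction: float = 0.25,
    max_attempts: int = 400,
) -> CGTopology:
    """Assemble a multi-chain system in a slab box (dense central start).

    Linear chains (proteins) are regrown in situ as self-avoiding walks so
    coils can interpenetrate at condensed density, with rigid spans placed
    as randomly rotated blocks; other fragments (e.g. DNA duplexes) are
    placed whole with random orientations.  Every bead starts within the
    central ``slab_fraction`` of the z axis (the dense-slab initialization
    that accelerates coexistence) and at least ``min_dist`` from beads of
    other molecules, under periodic boundaries.  Deterministic for a given
    seed.
    """
    box = np.asarray(box, dtype=float)
    if box[2] < max(box[0], box[1]):
        raise ValueError("slab box must have z as its longest dimension")
    z_half = slab_fraction * box[2] / 2.0
    rng = np.random.default_rng(seed)

    all_pos, all_types, all_mass, all_charge, all_sigma, all_lam = [], [], [], [], [], []
    all_mol, all_species, all_chain = [], [], []
    all_bonds, all_r0, all_k = [], [], []
    rigid_groups = []
    mol_counter = 0
    offset = 0
    placed_tree = None
    placed_pts = np.empty((0, 3))

    for name in counts:
        if name not in fragments:
            raise KeyError(f"no fragment named {name!r}")
    for name, n_copies in counts.items():
        frag = fragments[name]
        if n_copies < 1:
            raise ValueError(f"counts must be >= 1, got {n_copies} for {name!r}")
        base = frag.positions - frag.positions.mean(axis=0)
        linear = _is_linear_chain(frag)
        for _copy in range(n_copies):
            if linear:
                grown = _grow_chain_in_situ(
                    frag, rng, box, z_half, placed_pts, min_dist, max_attempts
                )
                wrapped = (grown + box / 2.0) % box - box / 2.0
            else:
                ok = False
                for _try in range(max_attempts):
                    rot = _random_rotation(rng)
                    pts = base @ rot.T
                    ext = np.abs(pts[:, 2]).max()
                    if ext > z_half:
                        # re-orient; elongated fragments may still fit
                        continue
                    com = np.array(
                        [
                            rng.uniform(-box[0] / 2, box[0] / 2),
                            rng.uniform(-box[1] / 2, box[1] / 2),
                            rng.uniform(-(z_half - ext), z_half - ext),
                        ]
                    )
                    cand = pts + com
                    wrapped = (cand + box / 2.0) % box - box / 2.0
                    if placed_tree is not None:
                        d, _ = placed_tree.query(wrapped + box / 2.0, k=1)
                        if d.min() < min_dist:
                            continue
                    ok = True
                    break
                if not ok:
                    raise PackingError(
                        f"could not place copy of {name!r} after "
                        f"{max_attempts} attempts; use a larger box or fewer "
                        "chains"
                    )
            all_pos.append(wrapped)
            all_types.append(frag.types)
            all_mass.append(frag.mass)
            all_charge.append(frag.charge)
            all_sigma.append(frag.sigma)
            all_lam.append(frag.lam)
            all_mol.append(np.full(frag.n_beads, mol_counter, dtype=np.int64))
            all_species.append(np.array([name] * frag.n_beads, dtype=object))
            all_chain.append(frag.chain_index)
            if len(frag.bonds):
                all_bonds.append(frag.bonds + offset)
                all_r0.append(frag.bond_r0)
                all_k.append(frag.bond_k)
            for grp in frag.rigid_groups:
                rigid_groups.append(np.asarray(grp) + offset)
            mol_counter += 1
            offset += frag.n_beads
            placed_pts = np.vstack([placed_pts, wrapped])
            placed_tree = cKDTree(placed_pts + box / 2.0, boxsize=box)

    topo = CGTopology(
        types=np.concatenate(all_types),
        mass=np.concatenate(all_mass),
        charge=np.concatenate(all_charge),
        sigma=np.concatenate(all_sigma),
        lam=np.concatenate(all_lam),
        mol_id=np.concatenate(all_mol),
        species=np.concatenate(all_species),
        chain_index=np.concatenate(all_chain),
        positions=np.vstack(all_pos),
        bonds=np.vstack(all_bonds) if all_bonds else np.empty((0, 2), np.int64),
        bond_r0=np.concatenate(all_r0) if all_r0 else np.empty(0),
        bond_k=np.concatenate(all_k) if all_k else np.empty(0),
        rigid_groups=rigid_groups,
        box=box,
    )
    topo.validate()
    return topo


def topology_to_json(topo: CGTopology, path=None) -> str:
    """Serialize a topology to a documented JSON schema (arrays as lists)."""
    import json

    payload = {
        "types": topo.types.tolist(),
        "mass": topo.mass.tolist(),
        "charge": topo.charge.tolist(),
        "sigma": topo.sigma.tolist(),
        "lambda": topo.lam.tolist(),
        "mol_id": topo.mol_id.tolist(),
        "species": topo.species.tolist(),
        "chain_index": topo.chain_index.tolist(),
        "positions": topo.positions.tolist(),
        "bonds": topo.bonds.tolist(),
        "bond_r0": topo.bond_r0.tolist(),
        "bond_k": topo.bond_k.tolist(),
        "rigid_groups": [np.asarray(g).tolist() for g in topo.rigid_groups],
        "box": None if topo.box is None else np.asarray(topo.box).tolist(),
    }
    text = json.dumps(payload)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def topology_from_json(source) -> CGTopology:
    """Inverse of :func:`topology_to_json` (path or JSON string)."""
    import json
    from pathlib import Path

    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        source = Path(source).read_text()
    d = json.loads(source)
    return CGTopology(
        types=np.array(d["types"], dtype=object),
        mass=np.array(d["mass"], dtype=float),
        charge=np.array(d["charge"], dtype=float),
        sigma=np.array(d["sigma"], dtype=float),
        lam=np.array(d["lambda"], dtype=float),
        mol_id=np.array(d["mol_id"], dtype=np.int64),
        species=np.array(d["species"], dtype=object),
        chain_index=np.array(d["chain_index"], dtype=np.int64),
        positions=np.array(d["positions"], dtype=float),
        bonds=np.array(d["bonds"], dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array(d["bond_r0"], dtype=float),
        bond_k=np.array(d["bond_k"], dtype=float),
        rigid_groups=[np.array(g, dtype=np.int64) for g in d["rigid_groups"]],
        box=None if d["box"] is None else np.array(d["box"], dtype=float),
    )


def write_ca_template(coords, path, residue_name: str = "ALA") -> None:
    """Write template coordinates as a Calpha-trace PDB file."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("template")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i, xyz in enumerate(np.asarray(coords, dtype=float), start=1):
        builder.init_residue(residue_name, " ", i, " ")
        builder.init_atom("CA", xyz, 0.0, 1.0, " ", "CA", element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_ca_template(path, chain: str | None = None) -> np.ndarray:
    """Extract one Calpha coordinate per residue from a PDB file."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("template", path)
    model = next(structure.get_models())
    coords = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            if "CA" in residue:
                coords.append(residue["CA"].coord)
    if not coords:
        raise GeometryError(f"no Calpha atoms found in {path}")
    return np.asarray(coords, dtype=float)
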