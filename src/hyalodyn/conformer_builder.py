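"""Cartesian conformer construction from internal coordinates.

Conformers are built atom-by-atom from a *build tree* of internal-coordinate
records (natural extension reference frame / NeRF placement): each atom is
placed from three previously placed reference atoms using a bond length, a
bond angle and a dihedral.  The dihedral slot is either a fixed value
(rigid geometry: ring interiors, anchors, hydrogens) or a named torsion whose
value is drawn from a :class:`~hyalodyn.dynamics_model.DynamicModel` — a
categorical draw over joint modes for codependent groups followed by a
wrapped-normal libration, or a single wrapped-normal draw for unimodal
torsions.

Seeding convention: the first tree atom is placed at the origin, the second
along +x, the third in the xy-plane (positive y side).  One seeded generator
per ensemble; draws are conformer-major, then groups in model order, then
unimodal torsions, then torsions within a group in group order.  This makes
ensembles bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from hyalodyn.dynamics_model import (
    CodependentGroup,
    DynamicModel,
    TorsionMode,
    iter_torsion_modes,
    model_hash,
    wrap_angle,
)

__all__ = [
    "Atom",
    "BuildError",
    "Conformer",
    "Ensemble",
    "MolecularTopology",
    "Placement",
    "TorsionRef",
    "build_cartesian",
    "generate_ensemble",
    "measure_torsion",
    "read_ensemble",
    "sample_torsion",
    "signed_volume",
    "write_ensemble",
]


class BuildError(ValueError):
    """Raised for unbuildable topologies or degenerate reference frames."""


@dataclass(frozen=True)
class Atom:
    """One atom of a topology.

    ``flags`` carries role annotations used downstream, e.g.
    ``carboxylate_O``, ``hbond_donor``, ``hbond_acceptor``, ``aromatic``,
    ``hydrophobic``.
    """

    name: str  # unique identifier, "<residue>:<atom>"
    element: str
    residue: str
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TorsionRef:
    """A dihedral slot bound to a named model torsion, plus a constant offset
    (degrees).  Offsets place substituents (e.g. geminal hydrogens) relative
    to the sampled heavy-atom dihedral."""

    name: str
    offset: float = 0.0


@dataclass(frozen=True)
class Placement:
    """Internal-coordinate record: place ``atom`` bonded to ``refs[0]`` with
    angle ``atom-refs[0]-refs[1]`` and dihedral ``atom-refs[0]-refs[1]-refs[2]``.
    The first three tree entries use the seeding convention and carry fewer
    references."""

    atom: str
    refs: tuple[str, ...]
    length: float = 0.0
    angle: float = 0.0
    dihedral: float | TorsionRef = 0.0


@dataclass
class MolecularTopology:
    """Atoms, bonds and build tree of one molecule.

    ``anchor_atoms`` lists the atoms of the nonreducing-terminal residues
    that are held in a fixed conformation across an ensemble (all their
    dihedral slots are fixed values, so their local geometry is bitwise
    identical in every conformer).  ``j_couplings`` lists vicinal proton
    pairs (H, C, C, H paths) for ³J back-calculation; ``stereocenters`` lists
    (center, neighbour triple) records used for chirality checks.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[str, str]]
    build_tree: list[Placement]
    anchor_atoms: list[str] = field(default_factory=list)
    j_couplings: list[tuple[str, str, str, str]] = field(default_factory=list)
    stereocenters: list[tuple[str, tuple[str, str, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise BuildError(f"topology {self.name!r}: duplicate atom names")
        placed = [p.atom for p in self.build_tree]
        if sorted(placed) != sorted(names):
            missing = set(names) - set(placed)
            extra = set(placed) - set(names)
            raise BuildError(
                f"topology {self.name!r}: build tree must place every atom "
                f"exactly once (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        self.index = {n: i for i, n in enumerate(names)}
        unknown = [a for a in self.anchor_atoms if a not in self.index]
        if unknown:
            raise BuildError(f"anchor atoms not in topology: {unknown}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def torsion_names(self) -> list[str]:
        """Named torsions referenced by the build tree, in tree order."""
        seen: list[str] = []
        for p in self.build_tree:
            if isinstance(p.dihedral, TorsionRef) and p.dihedral.name not in seen:
                seen.append(p.dihedral.name)
        return seen

    def torsion_quadruple(self, name: str) -> tuple[str, str, str, str]:
        """Atom quadruple (A, B, C, D) defining a named torsion, taken from
        the tree placement with offset 0 (the canonical definition)."""
        for p in self.build_tree:
            d = p.dihedral
            if isinstance(d, TorsionRef) and d.name == name and d.offset == 0.0:
                c, b, a = p.refs
                return (a, b, c, p.atom)
        raise KeyError(f"no zero-offset placement defines torsion {name!r}")

    def atoms_with_flag(self, flag: str) -> list[str]:
        return [a.name for a in self.atoms if flag in a.flags]

    def atom(self, name: str) -> Atom:
        return self.atoms[self.index[name]]

    def bonded_hydrogens(self, heavy: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == heavy and self.atom(b).element == "H":
                out.append(b)
            elif b == heavy and self.atom(a).element == "H":
                out.append(a)
        return out


@dataclass
class Conformer:
    """One Cartesian conformation: coordinates (Å), the torsion values it was
    built from, and the joint-mode index sampled per codependent group."""

    coordinates: np.ndarray  # (n_atoms, 3)
    torsion_values: dict[str, float]
    mode_labels: dict[str, int]

    def xyz(self, topology: MolecularTopology, name: str) -> np.ndarray:
        return self.coordinates[topology.index[name]]


@dataclass
class Ensemble:
    """A set of conformers sharing one topology, tagged with the generating
    seed and a digest of the dynamic model used."""

    topology: MolecularTopology
    conformers: list[Conformer]
    seed: int
    model_digest: str = ""

    def __post_init__(self) -> None:
        if not self.conformers:
            raise BuildError("ensemble must be non-empty")

    def __len__(self) -> int:
        return len(self.conformers)

    def coordinates(self) -> np.ndarray:
        """(n_conformers, n_atoms, 3) coordinate stack."""
        return np.stack([c.coordinates for c in self.conformers])


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-8


def _nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """Place atom D bonded to c with angle(D,c,b)=theta and signed dihedral
    (a,b,c,D)=phi (radians)."""
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _COLLINEAR_TOL:
        raise BuildError("coincident reference atoms in build frame")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise BuildError("collinear reference triple (degenerate frame)")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_torsion(
    coords: np.ndarray, quadruple: Sequence[int] | Sequence[str], topology=None
) -> float:
    """Signed dihedral (degrees, in (−180, 180]) over an atom quadruple.

    ``quadruple`` holds integer indices into ``coords`` or atom names (then
    ``topology`` must be given).  Raises :class:`BuildError` when the central
    bond atoms are collinear with a flanking atom.
    """
    if topology is not None and isinstance(quadruple[0], str):
        quadruple = [topology.index[q] for q in quadruple]
    p0, p1, p2, p3 = (coords[int(i)] for i in quadruple)
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise BuildError("collinear atoms: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(float(np.degrees(np.arctan2(y, x))))


def signed_volume(
    coords: np.ndarray, topology: MolecularTopology, center: str, neighbors: Sequence[str]
) -> float:
    """Signed volume of the tetrahedron (center; three neighbours): its sign
    is the configuration of a stereocenter and must be conserved across an
    ensemble built from a chirality-preserving tree."""
    c = coords[topology.index[center]]
    v = [coords[topology.index[n]] - c for n in neighbors]
    return float(np.dot(v[0], np.cross(v[1], v[2])))


# ---------------------------------------------------------------------------
# sampling and building
# ---------------------------------------------------------------------------


def sample_torsion(
    mode_set: CodependentGroup | TorsionMode, rng: np.random.Generator
) -> tuple[dict[str, float], int] | float:
    """Draw torsion value(s) from a model element.

    For a :class:`CodependentGroup`: one joint mode is drawn from the
    categorical distribution π, then each torsion of the group receives an
    independent wrapped-normal draw about that mode's (μ, σ).  Returns
    ``(angles_by_torsion, mode_index)``.

    For a :class:`TorsionMode`: a single wrapped-normal draw (float).
    All angles are wrapped to (−180, 180].
    """
    if isinstance(mode_set, CodependentGroup):
        idx = int(rng.choice(mode_set.n_modes, p=mode_set.populations))
        mode = mode_set.modes[idx]
        angles = {
            t: wrap_angle(mode[t].mu + mode[t].sigma * rng.standard_normal())
            for t in mode_set.torsions
        }
        return angles, idx
    return wrap_angle(mode_set.mu + mode_set.sigma * rng.standard_normal())


def build_cartesian(
    topology: MolecularTopology, torsion_values: dict[str, float]
) -> np.ndarray:
    """Build Cartesian coordinates (Å) from the topology's internal
    coordinates, resolving named dihedral slots from ``torsion_values``.

    Raises :class:`BuildError` when a named torsion is unresolved or a
    reference frame is degenerate.
    """
    coords = np.empty((topology.n_atoms, 3))
    placed: dict[str, int] = {}

    for k, p in enumerate(topology.build_tree):
        i = topology.index[p.atom]
        if k == 0:
            coords[i] = (0.0, 0.0, 0.0)
        elif k == 1:
            (c,) = p.refs
            coords[i] = coords[placed[c]] + (p.length, 0.0, 0.0)
        elif k == 2:
            c, b = p.refs
            pc, pb = coords[placed[c]], coords[placed[b]]
            u = pc - pb
            nu = np.linalg.norm(u)
            if nu < _COLLINEAR_TOL:
                raise BuildError("coincident seed atoms")
            u = u / nu
            theta = np.radians(p.angle)
            # v completes a right-handed frame in the xy-plane
            v = np.cross([0.0, 0.0, 1.0], u)
            nv = np.linalg.norm(v)
            if nv < _COLLINEAR_TOL:
                v = np.array([0.0, 1.0, 0.0])
            else:
                v = v / nv
            coords[i] = pc + p.length * (-np.cos(theta) * u + np.sin(theta) * v)
        else:
            c, b, a = p.refs
            for r in (c, b, a):
                if r not in placed:
                    raise BuildError(
                        f"placement of {p.atom!r} references unplaced atom {r!r}"
                    )
            d = p.dihedral
            if isinstance(d, TorsionRef):
                if d.name not in torsion_values:
                    raise BuildError(f"unresolved torsion {d.name!r}")
                phi = wrap_angle(torsion_values[d.name] + d.offset)
            else:
                phi = float(d)
            coords[i] = _nerf_place(
                coords[placed[a]],
                coords[placed[b]],
                coords[placed[c]],
                p.length,
                np.radians(p.angle),
                np.radians(phi),
            )
        placed[p.atom] = i

    return coords


def generate_ensemble(
    model: DynamicModel,
    topology: MolecularTopology,
    n: int,
    seed: int,
) -> Ensemble:
    """Generate ``n`` conformers by sampling the model's torsions with one
    seeded generator and building each conformer from internal coordinates.

    Anchor-residue coordinates are bitwise identical across conformers
    because every anchor dihedral slot is a fixed value and the build is
    deterministic for fixed slots.
    """
    if n < 1:
        raise BuildError("ensemble size must be >= 1")
    needed = set(topology.torsion_names())
    available = set(model.torsion_names)
    missing = needed - available
    if missing:
        raise BuildError(f"topology torsions absent from model: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    conformers: list[Conformer] = []
    for _ in range(n):
        torsion_values: dict[str, float] = {}
        mode_labels: dict[str, int] = {}
        for name, element in iter_torsion_modes(model):
            out = sample_torsion(element, rng)
            if isinstance(element, CodependentGroup):
                angles, idx = out
                torsion_values.update(angles)
                mode_labels[name] = idx
            else:
                torsion_values[name] = out
        coords = build_cartesian(topology, torsion_values)
        conformers.append(
            Conformer(
                coordinates=coords,
                torsion_values=torsion_values,
                mode_labels=mode_labels,
            )
        )
    return Ensemble(
        topology=topology,
        conformers=conformers,
        seed=seed,
        model_digest=model_hash(model),
    )


# ---------------------------------------------------------------------------
# multi-model PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_REMARK_SEED = re.compile(r"^REMARK 250 SEED (\-?\d+)\s*$")
_REMARK_MODES = re.compile(r"^REMARK 250 MODES (\d+) (.*?)\s*$")
_REMARK_DIGEST = re.compile(r"^REMARK 250 MODEL-DIGEST (\S+)\s*$")


def _remark_lines(ensemble: Ensemble) -> list[str]:
    lines = [f"REMARK 250 SEED {ensemble.seed}"]
    if ensemble.model_digest:
        lines.append(f"REMARK 250 MODEL-DIGEST {ensemble.model_digest}")
    for i, conf in enumerate(ensemble.conformers, start=1):
        if conf.mode_labels:
            tags = " ".join(f"{g}={m}" for g, m in sorted(conf.mode_labels.items()))
            lines.append(f"REMARK 250 MODES {i} {tags}")
    return lines


def write_ensemble(
    ensemble: Ensemble, path: str | Path, format: str = "pdb_multimodel"
) -> Path:
    """Write an ensemble as a standard multi-model PDB file (HETATM records,
    MODEL/ENDMDL per conformer).  REMARK 250 lines carry the seed, the model
    digest and the per-conformer joint-mode labels."""
    if format != "pdb_multimodel":
        raise ValueError(f"unsupported ensemble format {format!r}")
    if not str(path):
        raise ValueError("empty output path")
    path = Path(path)
    topo = ensemble.topology

    n = topo.n_atoms
    template = struc.AtomArray(n)
    template.coord = np.zeros((n, 3))
    template.atom_name = np.array([a.name.split(":", 1)[1] for a in topo.atoms])
    template.res_name = np.array([a.residue for a in topo.atoms])
    # residue ids follow first-appearance order of residue labels
    res_order: dict[str, int] = {}
    for a in topo.atoms:
        res_order.setdefault(a.residue, len(res_order) + 1)
    template.res_id = np.array([res_order[a.residue] for a in topo.atoms])
    template.element = np.array([a.element for a in topo.atoms])
    template.hetero = np.full(n, True)
    template.chain_id = np.full(n, "A")

    stack = struc.stack([template] * len(ensemble))
    stack.coord = ensemble.coordinates()

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.lines = _remark_lines(ensemble) + pdb.lines
    path.parent.mkdir(parents=True, exist_ok=True)
    pdb.write(str(path))
    return path


def read_ensemble(path: str | Path, topology: MolecularTopology) -> Ensemble:
    """Read a multi-model PDB written by :func:`write_ensemble`.

    Torsion values are re-measured from the coordinates for every named
    torsion of the topology; mode labels and seed are recovered from the
    REMARK 250 header."""
    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)

    seed = 0
    digest = ""
    modes_by_model: dict[int, dict[str, int]] = {}
    for line in pdb.lines:
        if m := _REMARK_SEED.match(line):
            seed = int(m.group(1))
        elif m := _REMARK_DIGEST.match(line):
            digest = m.group(1)
        elif m := _REMARK_MODES.match(line):
            idx = int(m.group(1))
            modes_by_model[idx] = {
                k: int(v) for k, v in (tag.split("=") for tag in m.group(2).split())
            }

    quadruples = {
        name: [topology.index[a] for a in topology.torsion_quadruple(name)]
        for name in topology.torsion_names()
    }
    conformers = []
    for i in range(stack.stack_depth()):
        coords = np.asarray(stack.coord[i], dtype=float)
        torsions = {
            name: measure_torsion(coords, quad) for name, quad in quadruples.items()
        }
        conformers.append(
            Conformer(
                coordinates=coords,
                torsion_values=torsions,
                mode_labels=modes_by_model.get(i + 1, {}),
            )
        )
    return Ensemble(
        topology=topology, conformers=conformers, seed=seed, model_digest=digest
    )
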