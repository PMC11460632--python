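"""Rigid-body placement into a binding-groove model and component scoring.

The protocol mirrors an ensemble-docking workflow for a conformationally
dynamic ligand: every conformer is superposed onto the groove via its rigid
anchor residues (least-squares proper rotation + translation, no internal
motion), then scored against pocket pseudo-atom sites with three components:

* **hbond** — a distance-and-angle-damped well per donor/acceptor pair
  (optimum 2.9 Å heavy-atom separation, depth −4.0, zero beyond 4.5 Å);
  cationic sites act as donors toward carboxylate/acceptor oxygens, so the
  salt bridge is scored through this term.
* **vdw** — a soft 4-8 potential against steric/hydrophobic/aromatic sites,
  with a clash penalty growing as overlap⁴, capped.
* **torsion_strain** — k·(1 − cos(θ − μ_nearest)) per sampled torsion,
  k = 0.5, against the nearest mode mean of the dynamic model.

Scores are arbitrary units; only orderings and groupings are meaningful.
The reported *favorability* is the negated energy, so higher is more
favorable.  A salt-bridge flag records whether any ligand carboxylate
oxygen lies within 4.0 Å of a cationic site.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from hyalodyn.conformer_builder import Conformer, Ensemble, MolecularTopology
from hyalodyn.dynamics_model import DynamicModel, wrap_angle

__all__ = [
    "ModeScoreSummary",
    "Pocket",
    "PoseRecord",
    "PoseScore",
    "ScoreParams",
    "Site",
    "detect_salt_bridge",
    "load_pocket",
    "rank_ensemble",
    "save_pocket",
    "score_pose",
    "strain_reference",
    "superpose_anchor",
]

SITE_ROLES = {"hbond_donor", "hbond_acceptor", "cation", "aromatic", "hydrophobic", "steric"}

#: Salt-bridge criterion: carboxylate O within this distance of a cation (Å).
SALT_BRIDGE_CUTOFF = 4.0


@dataclass(frozen=True)
class Site:
    """A pocket pseudo-atom: position, interaction role, contact radius."""

    label: str
    role: str
    xyz: tuple[float, float, float]
    radius: float = 1.8

    def __post_init__(self) -> None:
        if self.role not in SITE_ROLES:
            raise ValueError(f"unknown site role {self.role!r}")


@dataclass
class Pocket:
    """Binding-groove model: interaction sites plus the reference coordinates
    the ligand anchor residues are superposed onto."""

    sites: list[Site]
    anchor_reference: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            raise ValueError("site labels must be unique")
        if not any(s.role == "steric" for s in self.sites):
            raise ValueError("pocket requires at least one steric site")

    def sites_with_role(self, *roles: str) -> list[Site]:
        return [s for s in self.sites if s.role in roles]


@dataclass(frozen=True)
class ScoreParams:
    """Documented, configurable scoring parameters (arbitrary energy units)."""

    hbond_optimum: float = 2.9
    hbond_width: float = 1.6  # zero at optimum ± width (4.5 Å outer cutoff)
    hbond_depth: float = 4.0
    hbond_angle_min: float = 120.0
    vdw_eps_carbon: float = 0.2
    vdw_eps_polar: float = 0.05
    vdw_clash_k: float = 0.5
    vdw_clash_cap: float = 2.0
    vdw_cutoff: float = 8.0
    clash_overlap: float = 0.5
    strain_k: float = 0.5
    atom_radius: dict[str, float] = field(
        default_factory=lambda: {"C": 1.7, "N": 1.55, "O": 1.52}
    )


@dataclass
class PoseScore:
    """Component-decomposed score of one placed pose (energy convention:
    negative favorable; ``favorability = -total``)."""

    hbond: float
    vdw: float
    torsion_strain: float
    salt_bridge: bool
    min_no_dist: float
    clashes: int

    @property
    def total(self) -> float:
        return self.hbond + self.vdw + self.torsion_strain

    @property
    def favorability(self) -> float:
        return -self.total


@dataclass
class PoseRecord:
    """One ranked docking result."""

    conformer_id: int
    mode_label: int | None
    score: PoseScore
    anchor_rmsd: float


@dataclass
class ModeScoreSummary:
    """Per-mode favorability statistics (mean, interquartile range, min, max,
    count), as a tidy DataFrame in ``table``."""

    table: pd.DataFrame

    @property
    def n_total(self) -> int:
        return int(self.table["n"].sum())


# ---------------------------------------------------------------------------
# pocket JSON I/O
# ---------------------------------------------------------------------------


def save_pocket(pocket: Pocket, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "sites": [
            {"label": s.label, "role": s.role, "xyz": list(s.xyz), "radius": s.radius}
            for s in pocket.sites
        ],
        "anchor_reference": {k: list(v) for k, v in pocket.anchor_reference.items()},
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_pocket(path: str | Path) -> Pocket:
    payload = json.loads(Path(path).read_text())
    return Pocket(
        sites=[
            Site(
                label=s["label"],
                role=s["role"],
                xyz=tuple(s["xyz"]),
                radius=s.get("radius", 1.8),
            )
            for s in payload["sites"]
        ],
        anchor_reference={k: tuple(v) for k, v in payload["anchor_reference"].items()},
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def superpose_anchor(
    conformer: Conformer, pocket: Pocket, topology: MolecularTopology
) -> tuple[Conformer, float]:
    """Least-squares rigid superposition (proper rotation + translation, no
    scaling) of the conformer's anchor atoms onto the pocket's reference.

    Returns the transformed conformer and the anchor RMSD (Å).
    """
    names = [a for a in topology.anchor_atoms if a in pocket.anchor_reference]
    if len(names) < 3:
        raise ValueError("need at least 3 anchor correspondences")
    idx = [topology.index[a] for a in names]
    mov = conformer.coordinates[idx]
    ref = np.array([pocket.anchor_reference[a] for a in names])

    mov_c = mov.mean(axis=0)
    ref_c = ref.mean(axis=0)
    # Kabsch with proper-rotation guarantee
    rot, rssd = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    span = np.linalg.svd(mov - mov_c, compute_uv=False)
    if span[1] < 1e-8:
        raise ValueError("collinear anchor atoms: superposition ill-defined")
    new_coords = rot.apply(conformer.coordinates - mov_c) + ref_c
    rmsd = float(rssd / math.sqrt(len(names)))
    return replace(conformer, coordinates=new_coords), rmsd


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _hbond_well(d: float, params: ScoreParams) -> float:
    x = abs(d - params.hbond_optimum)
    if x >= params.hbond_width:
        return 0.0
    return math.cos(0.5 * math.pi * x / params.hbond_width) ** 2


def _donor_angle_factor(
    coords: np.ndarray,
    topology: MolecularTopology,
    donor: str,
    site_xyz: np.ndarray,
    params: ScoreParams,
) -> float:
    """Best donor-H...site angle factor over the donor's hydrogens (1 for
    linear, 0 below the angular cutoff); 1 when the donor carries no
    explicit hydrogen."""
    hs = topology.bonded_hydrogens(donor)
    if not hs:
        return 1.0
    d = coords[topology.index[donor]]
    best = 0.0
    cos_min = math.cos(math.radians(params.hbond_angle_min))
    for h in hs:
        hv = coords[topology.index[h]]
        v1 = d - hv
        v2 = site_xyz - hv
        c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        if c > cos_min:  # angle below the cutoff
            continue
        best = max(best, ((c - cos_min) / (-1.0 - cos_min)) ** 2)
    return best


def score_pose(
    conformer: Conformer,
    pocket: Pocket,
    topology: MolecularTopology,
    strain_ref: dict[str, list[float]] | None = None,
    params: ScoreParams = ScoreParams(),
) -> PoseScore:
    """Score a placed pose against the pocket sites (see module docstring
    for the three components)."""
    coords = conformer.coordinates

    # hydrogen bonding (includes cation...carboxylate salt-bridge contacts)
    hb = 0.0
    donor_sites = pocket.sites_with_role("hbond_donor", "cation")
    acceptor_sites = pocket.sites_with_role("hbond_acceptor")
    lig_donors = topology.atoms_with_flag("hbond_donor")
    lig_acceptors = topology.atoms_with_flag("hbond_acceptor")
    for site in donor_sites:
        sx = np.asarray(site.xyz)
        for atom in lig_acceptors:
            d = float(np.linalg.norm(coords[topology.index[atom]] - sx))
            hb -= params.hbond_depth * _hbond_well(d, params)
    for site in acceptor_sites:
        sx = np.asarray(site.xyz)
        for atom in lig_donors:
            d = float(np.linalg.norm(coords[topology.index[atom]] - sx))
            w = _hbond_well(d, params)
            if w > 0.0:
                hb -= params.hbond_depth * w * _donor_angle_factor(
                    coords, topology, atom, sx, params
                )

    # van der Waals: soft 4-8 well with capped overlap^4 clash penalty
    vdw = 0.0
    clashes = 0
    heavy = [a for a in topology.atoms if a.element != "H"]
    for site in pocket.sites_with_role("steric", "hydrophobic", "aromatic"):
        sx = np.asarray(site.xyz)
        for atom in heavy:
            r0 = site.radius + params.atom_radius.get(atom.element, 1.7)
            d = float(np.linalg.norm(coords[topology.index[atom.name]] - sx))
            if d > params.vdw_cutoff:
                continue
            if site.role == "steric":
                eps = params.vdw_eps_polar
            elif "hydrophobic" in atom.flags or "aromatic" in atom.flags:
                eps = params.vdw_eps_carbon
            else:
                eps = params.vdw_eps_polar
            if d >= r0:
                q = (r0 / d) ** 4
                vdw += eps * (q * q - 2.0 * q)
            else:
                overlap = r0 - d
                vdw += min(-eps + params.vdw_clash_k * overlap**4, params.vdw_clash_cap)
                if overlap > params.clash_overlap:
                    clashes += 1

    # ligand torsion strain against the nearest mode mean
    strain = 0.0
    if strain_ref:
        for name, theta in conformer.torsion_values.items():
            mus = strain_ref.get(name)
            if not mus:
                continue
            dev = min(abs(wrap_angle(theta - mu)) for mu in mus)
            strain += params.strain_k * (1.0 - math.cos(math.radians(dev)))

    if pocket.sites_with_role("cation"):
        flag, min_no = detect_salt_bridge(conformer, pocket, topology)
    else:
        flag, min_no = False, math.inf
    return PoseScore(
        hbond=hb,
        vdw=vdw,
        torsion_strain=strain,
        salt_bridge=flag,
        min_no_dist=min_no,
        clashes=clashes,
    )


def detect_salt_bridge(
    conformer: Conformer,
    pocket: Pocket,
    topology: MolecularTopology,
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> tuple[bool, float]:
    """True iff any flagged carboxylate oxygen is within ``cutoff`` (Å,
    inclusive) of any cationic site; also returns the minimum O...cation
    distance (inf when the ligand carries no carboxylate — a note, not an
    error)."""
    cations = pocket.sites_with_role("cation")
    if not cations:
        raise ValueError("pocket has no cation site")
    oxygens = topology.atoms_with_flag("carboxylate_O")
    if not oxygens:
        return False, math.inf
    coords = conformer.coordinates
    dmin = min(
        float(np.linalg.norm(coords[topology.index[o]] - np.asarray(s.xyz)))
        for o in oxygens
        for s in cations
    )
    return dmin <= cutoff, dmin


def strain_reference(model: DynamicModel) -> dict[str, list[float]]:
    """Candidate mode means per torsion, the reference set for the
    torsion-strain component."""
    ref: dict[str, list[float]] = {
        name: [mode.mu] for name, mode in model.unimodal.items()
    }
    for g in model.groups:
        for t in g.torsions:
            ref[t] = [mode[t].mu for mode in g.modes]
    return ref


def rank_ensemble(
    ensemble: Ensemble,
    pocket: Pocket,
    model: DynamicModel | None = None,
    params: ScoreParams = ScoreParams(),
) -> tuple[list[PoseRecord], ModeScoreSummary]:
    """Superpose, score and rank every conformer of an ensemble.

    Poses are ranked by favorability, descending; exact ties keep conformer
    order (stable sort by index).  The summary reports per joint-mode group
    (label = sampled mode index of the first codependent group) the mean,
    interquartile range, minimum and maximum favorability and the member
    count.
    """
    sref = strain_reference(model) if model is not None else None
    records: list[PoseRecord] = []
    for i, conf in enumerate(ensemble.conformers):
        placed, rmsd = superpose_anchor(conf, pocket, ensemble.topology)
        score = score_pose(placed, pocket, ensemble.topology, sref, params)
        mode = next(iter(conf.mode_labels.values())) if conf.mode_labels else None
        records.append(
            PoseRecord(conformer_id=i, mode_label=mode, score=score, anchor_rmsd=rmsd)
        )

    ranked = sorted(records, key=lambda r: (-r.score.favorability, r.conformer_id))

    rows = []
    df = pd.DataFrame(
        {
            "mode": [r.mode_label for r in records],
            "favorability": [r.score.favorability for r in records],
        }
    )
    for mode, grp in df.groupby("mode", dropna=False, sort=True):
        fav = grp["favorability"]
        rows.append(
            {
                "mode": mode,
                "n": len(fav),
                "mean": fav.mean(),
                "iqr": fav.quantile(0.75) - fav.quantile(0.25),
                "min": fav.min(),
                "max": fav.max(),
            }
        )
    return ranked, ModeScoreSummary(table=pd.DataFrame(rows))
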