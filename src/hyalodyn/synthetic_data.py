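"""Synthetic-data generators with known ground truth.

Every generator is a pure function of (truth, seed) and returns the dataset
together with a serializable :class:`TruthRecord`.  Defaults emulate the
study conditions:

* ITC — 18 × 2 μl injections of 0.29 mM ligand into 200 μl of 0.029 mM
  protein at 25 °C, Gaussian heat noise (default 1% of the maximum heat)
  plus a constant dilution offset drawn once per titration;
* MST — a 16-step 1:1 serial dilution from 5 mM ligand with 10 nM labelled
  receptor, ΔFnorm responses in per mil with Gaussian noise (default 2% of
  the amplitude);
* restraints — NOE/noNOE/³J/temperature-coefficient records forward-
  simulated from an ensemble (or exactly from a dynamic model via per-mode
  conditional averages, for population-recovery studies);
* pocket — a deterministic binding-groove fixture with one cationic site,
  one aromatic shelf, a three-sphere hydrophobic subpocket and a steric
  wall, built so the joint-mode-2 geometry of the 2AA terminus places the
  ligand carboxylate within salt-bridge distance of the cation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hyalodyn.binding_thermo import DoseResponse, TitrationData, wiseman_heats
from hyalodyn.conformer_builder import Conformer, Ensemble, build_cartesian
from hyalodyn.dynamics_model import DynamicModel
from hyalodyn.docking import Pocket, Site
from hyalodyn.nmr_observables import (
    KARPLUS_DEFAULT,
    MODE_ENSEMBLE_SEED,
    MODE_ENSEMBLE_SIZE,
    Restraint,
    RestraintSet,
    _coupling_path,
    _hbond_satisfied,
    ensemble_karplus,
    ensemble_noe_distance,
    mode_conditional_observables,
)
from hyalodyn.topologies import dynamic_model_for, get_topology

__all__ = [
    "ITC_SCHEDULE_DEFAULT",
    "TruthRecord",
    "centroid_conformer",
    "make_pocket_fixture",
    "simulate_itc",
    "simulate_mst",
    "simulate_restraints",
    "simulate_restraints_from_model",
]


@dataclass
class TruthRecord:
    """Generating parameters, seed and noise model of a synthetic dataset."""

    kind: str
    parameters: dict
    seed: int
    noise: str = ""
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, blob: str) -> "TruthRecord":
        return cls(**json.loads(blob))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------


def ITC_SCHEDULE_DEFAULT(temperature: float = 298.15) -> TitrationData:
    """The study's injection schedule: 18 × 2 μl of 0.29 mM ligand into
    ~200 μl of 0.029 mM protein (heats left empty)."""
    return TitrationData(
        cell_conc=0.029e-3,
        syringe_conc=0.29e-3,
        cell_volume=200e-6,
        injection_volumes=[2e-6] * 18,
        heats=[0.0] * 18,
        temperature=temperature,
    )


def simulate_itc(
    truth: tuple[float, float, float],
    schedule: TitrationData | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[TitrationData, TruthRecord]:
    """Simulate a one-site titration from (K_D, ΔH, N).

    Heats are the Wiseman forward model plus a constant dilution offset
    (drawn once, sd = 5% of the maximum |heat|) plus i.i.d. Gaussian noise
    (sd = ``noise_sd`` × maximum |heat|).
    """
    kd, dh, n = truth
    sched = schedule or ITC_SCHEDULE_DEFAULT()
    rng = np.random.default_rng(seed)
    q = wiseman_heats((kd, dh, n), sched)
    scale = float(np.max(np.abs(q)))
    offset = float(rng.normal(0.0, 0.05 * scale))
    noise = rng.normal(0.0, noise_sd * scale, size=len(q)) if noise_sd > 0 else 0.0
    data = TitrationData(
        cell_conc=sched.cell_conc,
        syringe_conc=sched.syringe_conc,
        cell_volume=sched.cell_volume,
        injection_volumes=list(sched.injection_volumes),
        heats=list(q + offset + noise),
        temperature=sched.temperature,
    )
    record = TruthRecord(
        kind="itc",
        parameters={"K_D": kd, "delta_H": dh, "N": n, "offset": offset},
        seed=seed,
        noise=f"gaussian sd={noise_sd} of max|heat| + constant offset",
    )
    return data, record


# ---------------------------------------------------------------------------
# MST
# ---------------------------------------------------------------------------


def simulate_mst(
    kd: float,
    n_steps: int = 16,
    top_conc: float = 5e-3,
    receptor_conc: float = 10e-9,
    baseline: float = 850.0,
    amplitude: float = 25.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[DoseResponse, TruthRecord]:
    """Simulate a ΔFnorm dose-response from a 1:1 binding truth.

    The ligand series is a 1:1 serial dilution: ``n_steps`` concentrations
    from ``top_conc`` down to ``top_conc / 2**(n_steps-1)``; responses are
    baseline + amplitude × fraction_bound with Gaussian noise
    (sd = ``noise_sd`` × |amplitude|).
    """
    from hyalodyn.binding_thermo import mst_fraction_bound

    rng = np.random.default_rng(seed)
    concs = top_conc / 2.0 ** np.arange(n_steps)
    fb = mst_fraction_bound(concs, receptor_conc, kd)
    noise = rng.normal(0.0, noise_sd * abs(amplitude), size=n_steps) if noise_sd > 0 else 0.0
    data = DoseResponse(
        ligand_concs=list(concs),
        receptor_conc=receptor_conc,
        responses=list(baseline + amplitude * fb + noise),
    )
    record = TruthRecord(
        kind="mst",
        parameters={
            "K_D": kd,
            "baseline": baseline,
            "amplitude": amplitude,
            "receptor_conc": receptor_conc,
        },
        seed=seed,
        noise=f"gaussian sd={noise_sd} of |amplitude|",
    )
    return data, record


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------


def _eligible_proton_pairs(topology) -> list[tuple[str, str]]:
    """Proton pairs on distinct heavy atoms, deterministic order."""
    hs = [a.name for a in topology.atoms if a.element == "H"]
    parent = {}
    for h in hs:
        for a, b in topology.bonds:
            if a == h:
                parent[h] = b
            elif b == h:
                parent[h] = a
    pairs = []
    for i in range(len(hs)):
        for j in range(i + 1, len(hs)):
            if parent.get(hs[i]) != parent.get(hs[j]):
                pairs.append((hs[i], hs[j]))
    return pairs


def simulate_restraints(
    ensemble: Ensemble,
    n_noe: int = 20,
    n_nonoe: int = 10,
    noe_slack: float = 0.0,
    noe_max: float = 4.5,
    nonoe_threshold: float = 5.0,
    j_tolerance: float = 0.5,
    noise_sd_j: float = 0.0,
    include_hbond: bool = True,
    include_tempcoeff: bool = True,
    seed: int = 0,
) -> tuple[RestraintSet, TruthRecord]:
    """Forward-simulate a restraint set from an ensemble.

    NOE upper bounds are r_eff·(1+slack) on proton pairs with
    r_eff ≤ ``noe_max``; noNOE lower bounds (``nonoe_threshold``) go on
    pairs with r_eff above that threshold; ³J targets are the ensemble
    Karplus values of the topology's registered vicinal pairs, with optional
    Gaussian noise.  A geometric hydrogen-bond record and the aniline
    temperature-coefficient annotation (−2.6 ppb/K) are appended when
    applicable.  At zero noise and zero slack the generating ensemble
    satisfies every record.
    """
    topo = ensemble.topology
    rng = np.random.default_rng(seed)
    pairs = _eligible_proton_pairs(topo)
    reffs = {p: ensemble_noe_distance(ensemble, p) for p in pairs}
    noe_pool = [p for p in pairs if reffs[p] <= noe_max]
    nonoe_pool = [p for p in pairs if reffs[p] >= nonoe_threshold]
    if len(noe_pool) < n_noe or len(nonoe_pool) < n_nonoe:
        raise ValueError(
            f"insufficient eligible pairs: {len(noe_pool)} NOE candidates, "
            f"{len(nonoe_pool)} noNOE candidates"
        )
    noe_sel = [noe_pool[i] for i in rng.choice(len(noe_pool), n_noe, replace=False)]
    nonoe_sel = [
        nonoe_pool[i] for i in rng.choice(len(nonoe_pool), n_nonoe, replace=False)
    ]

    restraints = [
        Restraint("NOE", p, bound=reffs[p] * (1.0 + noe_slack), note="simulated")
        for p in noe_sel
    ] + [
        Restraint("noNOE", p, bound=nonoe_threshold, note="simulated")
        for p in nonoe_sel
    ]
    true_j = {}
    for path in topo.j_couplings:
        j = ensemble_karplus(ensemble, path, KARPLUS_DEFAULT)
        true_j[(path[0], path[3])] = j
        target = j + (rng.normal(0.0, noise_sd_j) if noise_sd_j > 0 else 0.0)
        restraints.append(
            Restraint(
                "scalar3J",
                (path[0], path[3]),
                bound=float(target),
                tolerance=j_tolerance,
                note="simulated",
            )
        )
    if include_hbond:
        donors = topo.atoms_with_flag("hbond_donor")
        acceptors = topo.atoms_with_flag("carboxylate_O")
        for donor in donors:
            for acc in acceptors:
                frac = np.mean(
                    [
                        _hbond_satisfied(c, ensemble, donor, acc)
                        for c in ensemble.conformers
                    ]
                )
                if frac >= 0.5:
                    restraints.append(
                        Restraint(
                            "hbond",
                            (donor, acc),
                            bound=3.5,
                            note="internal hydrogen bond (simulated)",
                        )
                    )
                    break
            else:
                continue
            break
    if include_tempcoeff:
        aniline_h = [a.name for a in topo.atoms if a.name.endswith(":HN11")]
        if aniline_h:
            restraints.append(
                Restraint(
                    "tempCoeff",
                    (aniline_h[0],),
                    bound=-2.6,
                    note="aniline proton temperature coefficient, ppb/K (provenance)",
                )
            )

    record = TruthRecord(
        kind="restraints",
        parameters={
            "n_noe": n_noe,
            "n_nonoe": n_nonoe,
            "noe_slack": noe_slack,
            "j_tolerance": j_tolerance,
            "ensemble_seed": ensemble.seed,
            "true_j": {f"{a}|{b}": v for (a, b), v in true_j.items()},
        },
        seed=seed,
        noise=f"gaussian sd={noise_sd_j} Hz on 3J targets",
    )
    return RestraintSet(restraints), record


def simulate_restraints_from_model(
    model: DynamicModel,
    topology,
    noise_sd_j: float = 0.0,
    j_tolerance: float = 0.5,
    n_noe_pairs: int = 8,
    n_per_mode: int = MODE_ENSEMBLE_SIZE,
    seed: int = 0,
    mode_seed: int = MODE_ENSEMBLE_SEED,
) -> tuple[RestraintSet, TruthRecord]:
    """Forward-simulate population-sensitive restraints exactly from a
    dynamic model.

    ³J targets and r⁻⁶ NOE distances are per-mode conditional ensemble
    averages combined with the model's true occupancies π — the same
    forward machinery the population fitter uses, so at zero noise the true
    π reproduces every target exactly (up to the shared conditional-ensemble
    size).  The ``n_noe_pairs`` proton pairs with the largest inter-mode
    effective-distance contrast each yield an NOE upper bound and a noNOE
    lower bound at the true r_eff (the distance observable seen from both
    sides); J noise is Gaussian with sd ``noise_sd_j``.
    """
    pairs = [(p[0], p[3]) for p in topology.j_couplings]
    candidates = _eligible_proton_pairs(topology)
    inv6_all, jays = mode_conditional_observables(
        model, topology, candidates, pairs, n_per_mode=n_per_mode, seed=mode_seed
    )
    pi = np.asarray(model.groups[0].populations)
    rng = np.random.default_rng(seed)

    # distance observables: pick the pairs whose per-mode effective
    # distances differ the most (strongest population leverage) within the
    # observable NOE range
    r_modes = inv6_all ** (-1.0 / 6.0)  # (n_pairs, n_modes)
    contrast = r_modes.max(axis=1) - r_modes.min(axis=1)
    observable = r_modes.min(axis=1) <= 4.5
    order = np.argsort(-contrast)
    chosen = [i for i in order if observable[i]][:n_noe_pairs]

    restraints = []
    for i in chosen:
        r_true = float((inv6_all[i] @ pi) ** (-1.0 / 6.0))
        restraints.append(
            Restraint("NOE", candidates[i], bound=r_true, note="model-simulated")
        )
        restraints.append(
            Restraint("noNOE", candidates[i], bound=r_true, note="model-simulated")
        )
    for q, pair in enumerate(pairs):
        target = float(jays[q] @ pi)
        if noise_sd_j > 0:
            target += float(rng.normal(0.0, noise_sd_j))
        restraints.append(
            Restraint(
                "scalar3J", pair, bound=target, tolerance=j_tolerance, note="model-simulated"
            )
        )
    record = TruthRecord(
        kind="restraints_from_model",
        parameters={
            "populations": list(pi),
            "n_per_mode": n_per_mode,
            "mode_seed": mode_seed,
            "j_tolerance": j_tolerance,
            "n_noe_pairs": n_noe_pairs,
        },
        seed=seed,
        noise=f"gaussian sd={noise_sd_j} Hz on 3J targets",
    )
    return RestraintSet(restraints), record


# ---------------------------------------------------------------------------
# pocket fixture
# ---------------------------------------------------------------------------


def centroid_conformer(model: DynamicModel, topology, mode_index: int) -> Conformer:
    """The libration-free conformer of one joint mode: every torsion at its
    mean (group torsions at the mode's means, unimodal at μ)."""
    group = model.groups[0]
    torsions = {t: group.modes[mode_index][t].mu for t in group.torsions}
    torsions.update({name: m.mu for name, m in model.unimodal.items()})
    coords = build_cartesian(topology, torsions)
    return Conformer(
        coordinates=coords,
        torsion_values=torsions,
        mode_labels={group.group_id: mode_index},
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_pocket_fixture(
    spec: str = "link_tsg6_groove", topology_name: str = "ha6_2aa"
) -> tuple[Pocket, TruthRecord]:
    """Deterministic binding-groove fixture.

    The groove is laid out around the joint-mode-2 centroid geometry of the
    modified terminus: a cationic site (arginine surrogate) 3.0 Å from the
    carboxylate oxygen along the C→O direction, a second donor site at the
    other carboxylate oxygen, an aromatic shelf (tyrosine surrogate) against
    the opened-ring backbone, three hydrophobic spheres packing the 2AA
    ring, and a steric wall at the mode-4 carboxylate position penalizing
    the low-occupancy joint modes.  The anchor reference is the centroid's
    own anchor coordinates, so a perfectly matching anchor superposes with
    zero RMSD.
    """
    if spec != "link_tsg6_groove":
        raise KeyError(f"unknown pocket preset {spec!r}")
    topo = get_topology(topology_name)
    model = dynamic_model_for(topo)
    c2 = centroid_conformer(model, topo, mode_index=1)  # joint mode 2
    c4 = centroid_conformer(model, topo, mode_index=3)  # joint mode 4

    x_res = topo.atoms_with_flag("carboxylate_O")[0].split(":")[0]
    t_res = topo.torsion_quadruple("T4 C2-C3")[0].split(":")[0]
    heavy_idx = [topo.index[a.name] for a in topo.atoms if a.element != "H"]

    def at(conf: Conformer, atom: str) -> np.ndarray:
        return conf.xyz(topo, atom)

    # salt-bridge donors at the hydrogen-bond optimum from the mode-2
    # carboxylate oxygens, along the outward C->O directions
    o7a, o7b = at(c2, f"{x_res}:O7A"), at(c2, f"{x_res}:O7B")
    c7a = at(c2, f"{x_res}:C7A")
    cation = o7a + 2.9 * _unit(o7a - c7a)
    donor2 = o7b + 2.9 * _unit(o7b - c7a)

    # hydrophobic spheres packing the face of the 2AA ring that points away
    # from the body of the ligand
    mol_center = c2.coordinates[heavy_idx].mean(axis=0)
    ring = np.mean([at(c2, f"{x_res}:CA{i}") for i in range(1, 7)], axis=0)
    normal = _unit(
        np.cross(
            at(c2, f"{x_res}:CA3") - at(c2, f"{x_res}:CA1"),
            at(c2, f"{x_res}:CA5") - at(c2, f"{x_res}:CA1"),
        )
    )
    if float(np.dot(normal, ring - mol_center)) < 0:
        normal = -normal
    base = ring + 4.3 * normal
    hydros = [base, base + 1.5 * _unit(o7a - ring), base - 1.5 * _unit(o7a - ring)]

    # aromatic shelf against the opened-ring backbone, on the solvent side
    backbone = at(c2, f"{t_res}:C2")
    shelf = backbone + 4.3 * _unit(backbone - mol_center)

    # steric wall out along the mode-4 carboxylate direction: penalizes the
    # low-occupancy joint modes while staying clear of modes 1-3
    o7a4, c7a4 = at(c4, f"{x_res}:O7A"), at(c4, f"{x_res}:C7A")
    wall = o7a4 + 4.0 * _unit(o7a4 - c7a4)

    pocket = Pocket(
        sites=[
            Site("Arg81-NH1", "cation", tuple(cation), radius=1.6),
            Site("Arg81-NH2", "hbond_donor", tuple(donor2), radius=1.6),
            Site("Tyr78-ring", "aromatic", tuple(shelf), radius=2.0),
            Site("Val57", "hydrophobic", tuple(hydros[0]), radius=2.0),
            Site("Gly79", "hydrophobic", tuple(hydros[1]), radius=2.0),
            Site("Ile80", "hydrophobic", tuple(hydros[2]), radius=2.0),
            Site("groove-wall", "steric", tuple(wall), radius=1.8),
        ],
        anchor_reference={
            a: tuple(at(c2, a)) for a in topo.anchor_atoms
        },
    )
    record = TruthRecord(
        kind="pocket",
        parameters={"preset": spec, "topology": topology_name, "built_from_mode": 2},
        seed=0,
        noise="deterministic fixture",
    )
    return pocket, record
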