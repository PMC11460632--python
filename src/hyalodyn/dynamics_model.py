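"""Torsion dynamic models for flexible oligosaccharide termini.

A *dynamic model* describes the solution behaviour of the rotatable bonds of
a molecule as a set of torsions.  Each torsion either librates unimodally
about a single mean (``μ ± σ``, degrees) or belongs to a *codependent group*:
several torsions that switch together between a small number of joint modes,
each mode assigning one (μ, σ) per torsion and carrying an occupancy π.  The
mode occupancies of a group sum to one.  For the 2AA-modified reducing
terminus of HA the three backbone torsions of the opened GlcNAc ring
(C2-C3, C1-C2 and the C1-aniline bond) populate five such joint modes.

Angles are in degrees, IUPAC dihedral sign convention, wrapped to
(−180, 180].
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "POPULATION_INPUT_TOL",
    "CodependentGroup",
    "DynamicModel",
    "ModelError",
    "TorsionMode",
    "TorsionSpec",
    "ValidationReport",
    "load_dynamic_model",
    "mode_populations",
    "model_hash",
    "save_dynamic_model",
    "validate_model",
    "wrap_angle",
]

#: Tolerance on the population sum of a group at load time.  Sums within this
#: tolerance of 1 are renormalized silently (printed occupancies are usually
#: 2-decimal fractions); larger deviations are an input error.
POPULATION_INPUT_TOL = 1e-6

#: Tolerance on the population sum after validation/renormalization.
POPULATION_STRICT_TOL = 1e-9


class ModelError(ValueError):
    """Raised for malformed or inconsistent dynamic-model input."""


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into the half-open interval (−180, 180]."""
    wrapped = math.fmod(deg, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    # fmod(-180., 360.) is -180.; map to +180 per the convention
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


@dataclass(frozen=True)
class TorsionMode:
    """One librational state of a torsion: mean angle μ and width σ (degrees)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu) or not math.isfinite(self.sigma):
            raise ModelError("torsion mode requires finite mu and sigma")
        if self.sigma <= 0:
            raise ModelError(f"libration width must be > 0, got sigma={self.sigma}")
        object.__setattr__(self, "mu", wrap_angle(self.mu))


@dataclass(frozen=True)
class TorsionSpec:
    """Identity of a rotatable bond: label plus the defining atom quadruple."""

    name: str
    atoms: tuple[str, str, str, str]
    group_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise ModelError(
                f"torsion {self.name!r} needs four distinct atoms, got {self.atoms}"
            )


@dataclass
class CodependentGroup:
    """Joint modes of several torsions that move in tandem.

    ``modes[m][torsion_name]`` is the :class:`TorsionMode` of that torsion in
    joint mode ``m``; ``populations[m]`` is the occupancy π of the mode.
    """

    group_id: str
    torsions: list[str]
    modes: list[dict[str, TorsionMode]]
    populations: list[float]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ModelError(f"group {self.group_id!r} has no modes")
        if len(self.modes) != len(self.populations):
            raise ModelError(
                f"group {self.group_id!r}: {len(self.modes)} modes but "
                f"{len(self.populations)} populations"
            )
        total = math.fsum(self.populations)
        if abs(total - 1.0) > POPULATION_INPUT_TOL:
            raise ModelError(
                f"group {self.group_id!r}: populations sum to {total:.9f}, "
                f"not 1 within {POPULATION_INPUT_TOL}"
            )
        # silent renormalization below the input tolerance
        self.populations = [p / total for p in self.populations]
        for i, mode in enumerate(self.modes):
            if set(mode) != set(self.torsions):
                raise ModelError(
                    f"group {self.group_id!r} mode {i}: assignments "
                    f"{sorted(mode)} do not match torsions {sorted(self.torsions)}"
                )

    @property
    def n_modes(self) -> int:
        return len(self.modes)


@dataclass
class DynamicModel:
    """A complete torsion dynamic model: unimodal torsions plus groups."""

    specs: dict[str, TorsionSpec]
    unimodal: dict[str, TorsionMode]
    groups: list[CodependentGroup] = field(default_factory=list)
    metadata: str = ""

    def __post_init__(self) -> None:
        grouped = [t for g in self.groups for t in g.torsions]
        dup = set(self.unimodal) & set(grouped)
        if dup:
            raise ModelError(f"torsions in both unimodal and a group: {sorted(dup)}")
        if len(grouped) != len(set(grouped)):
            raise ModelError("a torsion appears in more than one group")

    def group(self, group_id: str) -> CodependentGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"unknown group id {group_id!r}")

    @property
    def torsion_names(self) -> list[str]:
        names = list(self.unimodal)
        for g in self.groups:
            names.extend(g.torsions)
        return names


@dataclass
class ValidationReport:
    """List of invariant violations; empty iff the model is valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == valid, mirrors `if report:` usage
        return self.ok


# ---------------------------------------------------------------------------
# serialization
#
# Canonical JSON schema:
#   {"torsions": [{"name", "atoms": [4], "group": id-or-null}],
#    "groups": [{"id", "torsions": [...],
#                "modes": [{"assignments": {name: {"mu", "sigma"}},
#                           "population": float}]}],
#    "unimodal": {name: {"mu", "sigma"}},
#    "metadata": str}
#
# CSV is accepted for flat unimodal lists only, with columns
#   name, atom1, atom2, atom3, atom4, mu, sigma
# ---------------------------------------------------------------------------


def _model_from_dict(payload: dict) -> DynamicModel:
    specs: dict[str, TorsionSpec] = {}
    for rec in payload.get("torsions", []):
        name = rec["name"]
        if name in specs:
            raise ModelError(f"duplicate torsion name {name!r}")
        specs[name] = TorsionSpec(
            name=name,
            atoms=tuple(rec["atoms"]),
            group_id=rec.get("group") or None,
        )
    unimodal = {
        name: TorsionMode(mu=m["mu"], sigma=m["sigma"])
        for name, m in payload.get("unimodal", {}).items()
    }
    groups = []
    for grec in payload.get("groups", []):
        modes = []
        populations = []
        for mrec in grec["modes"]:
            modes.append(
                {
                    t: TorsionMode(mu=a["mu"], sigma=a["sigma"])
                    for t, a in mrec["assignments"].items()
                }
            )
            populations.append(float(mrec["population"]))
        groups.append(
            CodependentGroup(
                group_id=grec["id"],
                torsions=list(grec["torsions"]),
                modes=modes,
                populations=populations,
            )
        )
    return DynamicModel(
        specs=specs,
        unimodal=unimodal,
        groups=groups,
        metadata=payload.get("metadata", ""),
    )


def _model_to_dict(model: DynamicModel) -> dict:
    return {
        "torsions": [
            {"name": s.name, "atoms": list(s.atoms), "group": s.group_id}
            for s in model.specs.values()
        ],
        "groups": [
            {
                "id": g.group_id,
                "torsions": list(g.torsions),
                "modes": [
                    {
                        "assignments": {
                            t: {"mu": m.mu, "sigma": m.sigma}
                            for t, m in g.modes[i].items()
                        },
                        "population": g.populations[i],
                    }
                    for i in range(g.n_modes)
                ],
            }
            for g in model.groups
        ],
        "unimodal": {
            name: {"mu": m.mu, "sigma": m.sigma} for name, m in model.unimodal.items()
        },
        "metadata": model.metadata,
    }


def load_dynamic_model(path: str | Path, format: str = "json") -> DynamicModel:
    """Load and validate a dynamic model from ``path``.

    ``format`` is ``"json"`` (canonical, supports codependent groups) or
    ``"csv"`` (flat unimodal lists only).  Group populations are renormalized
    silently when their sum is within ``1e-6`` of 1 and rejected otherwise.
    """
    path = Path(path)
    if format == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelError(f"cannot parse {path}: {exc}") from exc
        model = _model_from_dict(payload)
    elif format == "csv":
        specs: dict[str, TorsionSpec] = {}
        unimodal: dict[str, TorsionMode] = {}
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                name = row["name"]
                if name in specs:
                    raise ModelError(f"duplicate torsion name {name!r}")
                specs[name] = TorsionSpec(
                    name=name,
                    atoms=(row["atom1"], row["atom2"], row["atom3"], row["atom4"]),
                )
                unimodal[name] = TorsionMode(
                    mu=float(row["mu"]), sigma=float(row["sigma"])
                )
        model = DynamicModel(specs=specs, unimodal=unimodal)
    else:
        raise ModelError(f"unknown model format {format!r}")

    report = validate_model(model)
    if not report.ok:
        raise ModelError("; ".join(report.violations))
    return model


def save_dynamic_model(model: DynamicModel, path: str | Path) -> Path:
    """Write ``model`` to canonical JSON (stable key order, round-trippable)."""
    path = Path(path)
    path.write_text(json.dumps(_model_to_dict(model), indent=2, sort_keys=True))
    return path


def model_hash(model: DynamicModel) -> str:
    """Content digest of a model (sha256 of its canonical JSON form)."""
    blob = json.dumps(_model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# validation / queries
# ---------------------------------------------------------------------------


def validate_model(model: DynamicModel) -> ValidationReport:
    """Report every violated model invariant (empty report iff valid)."""
    violations: list[str] = []

    def _check_mode(owner: str, mode: TorsionMode) -> None:
        if mode.sigma <= 0:
            violations.append(f"{owner}: sigma must be > 0, got {mode.sigma}")
        if not (-180.0 < mode.mu <= 180.0):
            violations.append(f"{owner}: mu {mode.mu} outside (-180, 180]")

    for name, mode in model.unimodal.items():
        _check_mode(f"unimodal torsion {name!r}", mode)

    seen_groups: set[str] = set()
    for g in model.groups:
        if g.group_id in seen_groups:
            violations.append(f"duplicate group id {g.group_id!r}")
        seen_groups.add(g.group_id)
        total = math.fsum(g.populations)
        if abs(total - 1.0) > POPULATION_STRICT_TOL:
            violations.append(
                f"group {g.group_id!r}: populations sum to {total:.12f}"
            )
        if any(p < 0 for p in g.populations):
            violations.append(f"group {g.group_id!r}: negative population")
        for i, mode_assign in enumerate(g.modes):
            for t, mode in mode_assign.items():
                _check_mode(f"group {g.group_id!r} mode {i} torsion {t!r}", mode)

    for name, spec in model.specs.items():
        if name != spec.name:
            violations.append(f"spec key {name!r} != spec name {spec.name!r}")
        in_group = any(name in g.torsions for g in model.groups)
        if spec.group_id and not in_group:
            violations.append(
                f"torsion {name!r} declares group {spec.group_id!r} "
                "but no group lists it"
            )

    return ValidationReport(violations=violations)


def mode_populations(model: DynamicModel, group_id: str) -> list[float]:
    """Mode occupancies π of a codependent group, in mode order (sum to 1)."""
    return list(model.group(group_id).populations)


def iter_torsion_modes(
    model: DynamicModel,
) -> Iterable[tuple[str, TorsionMode | CodependentGroup]]:
    """Yield (name, element) pairs in the model's canonical draw order:
    codependent groups first (model order), then unimodal torsions."""
    for g in model.groups:
        yield g.group_id, g
    for name, mode in model.unimodal.items():
        yield name, mode
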