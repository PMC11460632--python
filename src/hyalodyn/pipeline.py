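"""End-to-end orchestration: structural runs (model → ensemble → dock →
report) and thermodynamic runs (titration CSVs → fits → summary tables),
with a reproducibility manifest.

Config files are flat ``key = value`` text; CLI flags override config
values.  Every output file is listed in ``manifest.json`` with a sha256
content hash, so reruns with an identical config can be verified
byte-for-byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hyalodyn import __version__
from hyalodyn.binding_thermo import (
    BindingResult,
    DoseResponse,
    TitrationData,
    fit_itc,
    fit_mst,
    free_energy_from_kd,
    entropy_term,
)
from hyalodyn.conformer_builder import generate_ensemble, write_ensemble
from hyalodyn.dynamics_model import load_dynamic_model, model_hash
from hyalodyn.docking import load_pocket, rank_ensemble
from hyalodyn.nmr_observables import check_restraints, load_restraints
from hyalodyn.synthetic_data import make_pocket_fixture
from hyalodyn.topologies import dynamic_model_for, get_topology

__all__ = [
    "RunConfig",
    "load_config",
    "load_itc_csv",
    "load_mst_csv",
    "run_structural",
    "run_thermo",
    "save_itc_csv",
    "save_mst_csv",
]

log = logging.getLogger("hyalodyn")


@dataclass
class RunConfig:
    """Inputs of an orchestrated run; paths may be None to use fixtures."""

    topology: str = "ha6_2aa"
    model_path: str | None = None
    pocket_path: str | None = None
    restraints_path: str | None = None
    thermo_dir: str | None = None
    n_conformers: int = 250
    seed: int = 0
    outdir: str = "runs/out"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        for key in ("model_path", "pocket_path", "restraints_path", "thermo_dir"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    kwargs: dict = {}
    for key in ("topology", "model_path", "pocket_path", "restraints_path", "thermo_dir", "outdir"):
        if key in values:
            kwargs[key] = values.pop(key)
    if "n_conformers" in values:
        kwargs["n_conformers"] = int(values.pop("n_conformers"))
    if "seed" in values:
        kwargs["seed"] = int(values.pop("seed"))
    return RunConfig(extras=values, **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, inputs: dict, outputs: list[Path]) -> Path:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in config.__dict__.items() if k != "extras"},
        "inputs": inputs,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_structural(config: RunConfig) -> Path:
    """Sample an ensemble, dock it into the pocket, and write the run
    directory (ensemble PDB, scores CSV, per-mode summary CSV, optional
    restraint report, manifest).  Stage failures abort with the stage name
    in the logged error."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    stage = "load-model"
    try:
        topology = get_topology(config.topology)
        if config.model_path:
            model = load_dynamic_model(config.model_path)
        else:
            model = dynamic_model_for(topology)

        stage = "generate-ensemble"
        log.info("generating %d conformers (seed %d)", config.n_conformers, config.seed)
        ensemble = generate_ensemble(model, topology, config.n_conformers, config.seed)
        outputs.append(write_ensemble(ensemble, outdir / "ensemble.pdb"))

        stage = "load-pocket"
        if config.pocket_path:
            pocket = load_pocket(config.pocket_path)
        else:
            pocket, _ = make_pocket_fixture(topology_name=config.topology)

        stage = "dock"
        ranked, summary = rank_ensemble(ensemble, pocket, model)
        scores = pd.DataFrame(
            [
                {
                    "conformer_id": r.conformer_id,
                    "mode": r.mode_label,
                    "hbond": r.score.hbond,
                    "vdw": r.score.vdw,
                    "strain": r.score.torsion_strain,
                    "total": r.score.total,
                    "favorability": r.score.favorability,
                    "salt_bridge": r.score.salt_bridge,
                    "min_NO_dist": r.score.min_no_dist,
                }
                for r in ranked
            ]
        )
        scores_path = outdir / "scores.csv"
        scores.to_csv(scores_path, index=False, float_format="%.6f")
        outputs.append(scores_path)
        summary_path = outdir / "mode_summary.csv"
        summary.table.to_csv(summary_path, index=False, float_format="%.6f")
        outputs.append(summary_path)

        if config.restraints_path:
            stage = "restraints"
            restraints = load_restraints(config.restraints_path)
            report = check_restraints(ensemble, restraints)
            rep_path = outdir / "restraint_report.csv"
            with rep_path.open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["kind", "atoms", "bound", "satisfied", "margin"])
                for r, ok, margin in report.statuses:
                    writer.writerow([r.kind, "|".join(r.atoms), r.bound, ok, f"{margin:.6f}"])
            outputs.append(rep_path)
    except Exception:
        log.exception("structural run failed at stage %r", stage)
        raise

    inputs = {
        "topology": config.topology,
        "model_digest": model_hash(model),
        "pocket": config.pocket_path or "link_tsg6_groove fixture",
    }
    _write_manifest(outdir, config, inputs, outputs)
    return outdir


# ---------------------------------------------------------------------------
# thermo CSV I/O
#
# ITC files (*_itc.csv): '#' header lines cell_mM / syringe_mM / cell_ul /
# temp_C, then columns injection_index, volume_ul, heat, unit (ucal|kcal).
# MST files (*_mst.csv): '#' header lines receptor_nM / temp_C, then columns
# conc_M, dFnorm.
# ---------------------------------------------------------------------------

_HEAT_UNIT = {"ucal": 1e-9, "kcal": 1.0}  # to kcal


def _read_meta(path: Path) -> tuple[dict[str, float], list[str]]:
    meta: dict[str, float] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = float(value.strip())
        elif line.strip():
            body.append(line)
    return meta, body


def save_itc_csv(data: TitrationData, path: str | Path, unit: str = "ucal") -> Path:
    path = Path(path)
    factor = _HEAT_UNIT[unit]
    with path.open("w", newline="") as fh:
        fh.write(f"# cell_mM={data.cell_conc * 1e3}\n")
        fh.write(f"# syringe_mM={data.syringe_conc * 1e3}\n")
        fh.write(f"# cell_ul={data.cell_volume * 1e6}\n")
        fh.write(f"# temp_C={data.temperature - 273.15}\n")
        writer = csv.writer(fh)
        writer.writerow(["injection_index", "volume_ul", "heat", "unit"])
        for i, (v, q) in enumerate(zip(data.injection_volumes, data.heats), start=1):
            writer.writerow([i, v * 1e6, repr(float(q) / factor), unit])
    return path


def load_itc_csv(path: str | Path) -> TitrationData:
    path = Path(path)
    meta, body = _read_meta(path)
    volumes, heats = [], []
    for row in csv.DictReader(body):
        if "unit" not in row or row["unit"] not in _HEAT_UNIT:
            raise ValueError(f"{path}: heat unit column is mandatory (ucal|kcal)")
        volumes.append(float(row["volume_ul"]) * 1e-6)
        heats.append(float(row["heat"]) * _HEAT_UNIT[row["unit"]])
    return TitrationData(
        cell_conc=meta["cell_mM"] * 1e-3,
        syringe_conc=meta["syringe_mM"] * 1e-3,
        cell_volume=meta["cell_ul"] * 1e-6,
        injection_volumes=volumes,
        heats=heats,
        temperature=meta.get("temp_C", 25.0) + 273.15,
    )


def save_mst_csv(data: DoseResponse, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# receptor_nM={data.receptor_conc * 1e9}\n")
        fh.write(f"# temp_C={data.temperature - 273.15}\n")
        writer = csv.writer(fh)
        writer.writerow(["conc_M", "dFnorm"])
        for c, r in zip(data.ligand_concs, data.responses):
            writer.writerow([repr(float(c)), repr(float(r))])
    return path


def load_mst_csv(path: str | Path) -> DoseResponse:
    meta, body = _read_meta(Path(path))
    concs, resp = [], []
    for row in csv.DictReader(body):
        concs.append(float(row["conc_M"]))
        resp.append(float(row["dFnorm"]))
    return DoseResponse(
        ligand_concs=concs,
        receptor_conc=meta["receptor_nM"] * 1e-9,
        responses=resp,
        temperature=meta.get("temp_C", 25.0) + 273.15,
    )


_REPLICATE = re.compile(r"_rep\d+$")


def run_thermo(config: RunConfig) -> tuple[Path, int]:
    """Fit every titration/dose-response CSV under ``config.thermo_dir``.

    Writes one BindingResult JSON per file and a replicate-grouped summary
    CSV (mean ± SEM per group).  Per-file failures are recorded and the run
    continues; the returned count is the number of failures.
    """
    if not config.thermo_dir:
        raise ValueError("thermo_dir is required for a thermo run")
    indir = Path(config.thermo_dir)
    files = sorted(indir.glob("*_itc.csv")) + sorted(indir.glob("*_mst.csv"))
    if not files:
        raise FileNotFoundError(f"no *_itc.csv or *_mst.csv files in {indir}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    outputs: list[Path] = []
    records: list[dict] = []
    failures = 0
    for f in files:
        kind = "itc" if f.stem.endswith("_itc") else "mst"
        group = _REPLICATE.sub("", f.stem[: -len("_itc")])
        try:
            if kind == "itc":
                data = load_itc_csv(f)
                res = fit_itc(data)
                payload = res.__dict__
            else:
                mdata = load_mst_csv(f)
                kd, baseline, amplitude, unc = fit_mst(mdata)
                dg = free_energy_from_kd(kd, mdata.temperature)
                payload = {
                    "K_D": kd,
                    "baseline": baseline,
                    "amplitude": amplitude,
                    "delta_G": dg,
                    "temperature": mdata.temperature,
                    "uncertainties": unc,
                }
            out = outdir / f"{f.stem}_result.json"
            out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
            outputs.append(out)
            records.append({"group": group, "kind": kind, "file": f.name, **{
                k: v for k, v in payload.items() if isinstance(v, (int, float))
            }})
        except Exception as exc:
            failures += 1
            log.error("fit failed for %s: %s", f.name, exc)
            records.append({"group": group, "kind": kind, "file": f.name, "error": str(exc)})

    df = pd.DataFrame(records)
    fitted = df[~df.get("error", pd.Series(dtype=object)).notna()] if "error" in df else df
    summary_rows = []
    for (group, kind), grp in fitted.groupby(["group", "kind"]):
        row = {"group": group, "kind": kind, "n": len(grp)}
        for col in ("K_D", "delta_H", "N", "delta_G", "minus_T_delta_S"):
            if col in grp and grp[col].notna().any():
                vals = grp[col].dropna().astype(float)
                row[f"{col}_mean"] = vals.mean()
                row[f"{col}_sem"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        summary_rows.append(row)
    summary_path = outdir / "thermo_summary.csv"
    pd.DataFrame(summary_rows).to_csv(summary_path, index=False, float_format="%.6g")
    outputs.append(summary_path)

    _write_manifest(outdir, config, {"thermo_dir": str(indir)}, outputs)
    return outdir, failures
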