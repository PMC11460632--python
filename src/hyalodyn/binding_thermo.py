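"""Binding thermodynamics: one-site ITC isotherms, 1:1 MST binding, and the
derived affinity/discrimination tables.

The ITC forward model is the single-site (Wiseman) isotherm with perfusion
cell bookkeeping: each injection dilutes the cell contents exponentially
(displaced volume leaves the cell at the pre-injection composition), the
bound-complex concentration follows from the exact quadratic root, and the
measured heat of injection *i* is ΔH times the moles of complex formed during
that injection.  The MST model is the exact 1:1 quadratic fraction bound of
the labelled receptor, mapped to a normalized fluorescence change
ΔFnorm = baseline + amplitude · fraction_bound (per mil).

Thermodynamic conventions: 1 M standard state, R = 1.98720425×10⁻³
kcal·mol⁻¹·K⁻¹, 25 °C = 298.15 K, so ΔG = RT·ln K_D and −TΔS = ΔG − ΔH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT_KCAL",
    "AffinityRecord",
    "BindingResult",
    "DoseResponse",
    "FitError",
    "TitrationData",
    "build_affinity_table",
    "discrimination_ratio",
    "entropy_term",
    "fit_itc",
    "fit_mst",
    "free_energy_from_kd",
    "mst_fraction_bound",
    "percent_binding",
    "wiseman_heats",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Default experimental temperature (25 °C).
T_STANDARD = 298.15


class FitError(RuntimeError):
    """Raised when a binding fit cannot converge or the data are degenerate."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TitrationData:
    """One ITC titration: injection schedule plus measured heats.

    Units: concentrations mol/L, volumes L, heats kcal (per injection),
    temperature K.  The default schedule mirrors a PEAQ-style experiment:
    18 × 2 μl of 0.29 mM ligand into 200 μl of 0.029 mM protein.
    """

    cell_conc: float
    syringe_conc: float
    cell_volume: float
    injection_volumes: list[float]
    heats: list[float]
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if len(self.injection_volumes) != len(self.heats):
            raise ValueError("injection_volumes and heats must have equal length")
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise ValueError("concentrations and cell volume must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.heats)


@dataclass
class BindingResult:
    """Fitted binding parameters with uncertainties.

    ``minus_T_delta_S = delta_G - delta_H`` and ``delta_G = RT ln K_D`` hold
    exactly (internal precision) for every instance produced by the fits.
    """

    K_D: float
    delta_H: float
    N: float
    delta_G: float
    minus_T_delta_S: float
    temperature: float
    uncertainties: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_fit(
        cls,
        kd: float,
        dh: float,
        n: float,
        temperature: float,
        uncertainties: dict[str, float] | None = None,
    ) -> "BindingResult":
        dg = free_energy_from_kd(kd, temperature)
        return cls(
            K_D=kd,
            delta_H=dh,
            N=n,
            delta_G=dg,
            minus_T_delta_S=entropy_term(dg, dh),
            temperature=temperature,
            uncertainties=uncertainties or {},
        )


@dataclass
class DoseResponse:
    """One MST dose-response series: titrated ligand concentrations (mol/L),
    fixed labelled-receptor concentration, and ΔFnorm responses (per mil)."""

    ligand_concs: list[float]
    receptor_conc: float
    responses: list[float]
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if len(self.ligand_concs) != len(self.responses):
            raise ValueError("ligand_concs and responses must have equal length")
        if any(c <= 0 for c in self.ligand_concs):
            raise ValueError("ligand concentrations must be strictly positive")


@dataclass
class AffinityRecord:
    """One row of the relative-affinity summary: %K_B per protein versus the
    unmodified oligomer of the same length, the TSG-6:CD44 discrimination
    ratio, and the heavy-chain-transfer substrate annotation."""

    oligo: str
    modification: str
    kd_tsg6: float | None
    kd_cd44: float | None
    percent_kb_tsg6: float | None
    percent_kb_cd44: float | None
    discrimination: float | None
    hc_substrate: str | None


# ---------------------------------------------------------------------------
# elementary thermodynamics
# ---------------------------------------------------------------------------


def free_energy_from_kd(kd: float, temperature: float = T_STANDARD) -> float:
    """ΔG (kcal/mol) from a dissociation constant, 1 M standard state."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("kd and temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def entropy_term(delta_G: float, delta_H: float) -> float:
    """−TΔS = ΔG − ΔH (kcal/mol)."""
    return delta_G - delta_H


def percent_binding(kd_modified: float, kd_reference: float) -> float:
    """%K_B: association-constant ratio versus the unmodified reference of the
    same length, ×100 (= 100·K_D(ref)/K_D(modified))."""
    if kd_modified <= 0 or kd_reference <= 0:
        raise ValueError("dissociation constants must be positive")
    return 100.0 * kd_reference / kd_modified


def discrimination_ratio(
    pct_tsg6: float | None, pct_cd44: float | None
) -> float | None:
    """Relative discrimination TSG-6 : CD44 from the two %K_B values; None
    (absent, not an error) when either side is missing."""
    if pct_tsg6 is None or pct_cd44 is None:
        return None
    if pct_tsg6 <= 0 or pct_cd44 <= 0:
        raise ValueError("percent binding values must be positive")
    return pct_tsg6 / pct_cd44


# ---------------------------------------------------------------------------
# ITC forward model and fit
# ---------------------------------------------------------------------------


def _complex_conc(m_tot: np.ndarray, x_tot: np.ndarray, kd: float, n: float) -> np.ndarray:
    """Exact single-site bound-complex concentration from the quadratic root.

    ``n·m_tot`` is the binding-site concentration; the stable root form
    avoids cancellation at high c."""
    sites = n * m_tot
    b = sites + x_tot + kd
    disc = np.sqrt(np.maximum(b * b - 4.0 * sites * x_tot, 0.0))
    return 2.0 * sites * x_tot / (b + disc)


def wiseman_heats(
    params: tuple[float, float, float],
    schedule: TitrationData,
) -> np.ndarray:
    """Predicted per-injection heats (kcal) for (K_D, ΔH, N) under the
    perfusion convention.

    After cumulative injected volume v, cell totals are
    M = M₀·exp(−v/V₀) and X = X_s·(1 − exp(−v/V₀)); the heat of injection i
    is ΔH × (moles of complex formed) =
    ΔH·(V₀·[RL]ᵢ − (V₀ − dVᵢ)·[RL]ᵢ₋₁), counting the complex carried out
    with the displaced volume at its pre-injection concentration.
    """
    kd, dh, n = params
    if kd <= 0 or n <= 0:
        raise ValueError("K_D and N must be positive")
    v0 = schedule.cell_volume
    dvs = np.asarray(schedule.injection_volumes)
    vcum = np.cumsum(dvs)
    dil = np.exp(-vcum / v0)
    m_tot = schedule.cell_conc * dil
    x_tot = schedule.syringe_conc * (1.0 - dil)
    rl = _complex_conc(m_tot, x_tot, kd, n)
    rl_prev = np.concatenate([[0.0], rl[:-1]])
    return dh * (v0 * rl - (v0 - dvs) * rl_prev)


def fit_itc(
    data: TitrationData,
    multistart_kd: Sequence[float] = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4),
    multistart_dh: Sequence[float] = (-20.0, -10.0, -5.0, -1.0),
) -> BindingResult:
    """Fit the one-site isotherm to a titration.

    The dilution offset (mean of the final three heats) is subtracted from
    every injection first, then (K_D, ΔH, N) plus a residual constant
    per-injection heat are fitted by nonlinear least squares over a
    deterministic multi-start grid; the residual-offset parameter absorbs
    the binding heat still present in the final injections.  ΔG and −TΔS
    are derived from the best fit; uncertainties come from the fit
    covariance.
    """
    if data.n_injections < 6:
        raise FitError("at least 6 injections are required")
    heats = np.asarray(data.heats, dtype=float)
    if not np.any(heats):
        raise FitError("all-zero heats: degenerate titration")
    offset = float(np.mean(heats[-3:]))
    y = heats - offset
    scale = np.max(np.abs(y))
    if scale == 0:
        raise FitError("no signal after dilution subtraction")

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, dh, n, q0 = theta
        pred = wiseman_heats((10.0**log_kd, dh, n), data) + q0
        # normalize so tolerances act on the isotherm shape, not on the
        # absolute heat scale (kcal-per-injection values are ~1e-9)
        return (pred - y) / scale

    best = None
    for kd0 in multistart_kd:
        for dh0 in multistart_dh:
            try:
                sol = least_squares(
                    residuals,
                    x0=[math.log10(kd0), dh0, 1.0, 0.0],
                    bounds=([-12, -100, 1e-3, -abs(scale)], [0, 100, 100, abs(scale)]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitError("ITC fit failed to converge from every start")

    log_kd, dh, n, _q0 = best.x
    kd = 10.0**log_kd
    unc = _covariance_uncertainties(best, ["log10_K_D", "delta_H", "N", "q0"])
    if "log10_K_D" in unc:
        unc["K_D"] = kd * math.log(10.0) * unc.pop("log10_K_D")
    return BindingResult.from_fit(kd, dh, n, data.temperature, unc)


def _covariance_uncertainties(sol, names: list[str]) -> dict[str, float]:
    """1σ parameter uncertainties from the Gauss-Newton covariance of a
    scipy least-squares solution (empty when the Jacobian is singular)."""
    m, p = sol.jac.shape
    dof = max(m - p, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * 2.0 * sol.cost / dof
    except np.linalg.LinAlgError:
        return {}
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return dict(zip(names, sd))


# ---------------------------------------------------------------------------
# MST forward model and fit
# ---------------------------------------------------------------------------


def mst_fraction_bound(
    ligand_total: float | np.ndarray, receptor_total: float, kd: float
) -> float | np.ndarray:
    """Fraction of receptor bound, exact 1:1 quadratic solution (no
    free-ligand approximation)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    lig = np.asarray(ligand_total, dtype=float)
    if np.any(lig < 0) or receptor_total < 0:
        raise ValueError("concentrations must be non-negative")
    if receptor_total == 0:
        out = lig / (lig + kd)
        return float(out) if out.ndim == 0 else out
    b = receptor_total + lig + kd
    rl = (b - np.sqrt(b * b - 4.0 * receptor_total * lig)) / 2.0
    out = rl / receptor_total
    return float(out) if out.ndim == 0 else out


def fit_mst(data: DoseResponse) -> tuple[float, float, float, dict[str, float]]:
    """Fit (K_D, baseline, amplitude) to a ΔFnorm dose-response.

    Returns ``(K_D, baseline, amplitude, uncertainties)``.  Raises
    :class:`FitError` when fewer than 8 points are given, when the response
    is flat (amplitude indistinguishable from zero), or on non-convergence.
    """
    if len(data.ligand_concs) < 8:
        raise FitError("at least 8 dose points are required")
    concs = np.asarray(data.ligand_concs, dtype=float)
    resp = np.asarray(data.responses, dtype=float)
    span = float(resp.max() - resp.min())
    if span < 1e-12:
        raise FitError("flat response: amplitude indistinguishable from zero")

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, baseline, amplitude = theta
        fb = mst_fraction_bound(concs, data.receptor_conc, 10.0**log_kd)
        return baseline + amplitude * fb - resp

    geo_mid = math.log10(math.sqrt(concs.min() * concs.max()))
    best = None
    for log_kd0 in (geo_mid - 2, geo_mid, geo_mid + 2):
        for amp0 in (span, -span):
            sol = least_squares(
                residuals,
                x0=[log_kd0, float(resp[np.argmin(concs)]), amp0],
                bounds=([-12, -1e4, -1e4], [1, 1e4, 1e4]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitError("MST fit failed to converge")
    log_kd, baseline, amplitude = best.x
    kd = 10.0**log_kd
    if abs(amplitude) < 1e-6 * span:
        raise FitError("fitted amplitude indistinguishable from zero")
    unc = _covariance_uncertainties(best, ["log10_K_D", "baseline", "amplitude"])
    if "log10_K_D" in unc:
        unc["K_D"] = kd * math.log(10.0) * unc.pop("log10_K_D")
    return kd, float(baseline), float(amplitude), unc


# ---------------------------------------------------------------------------
# derived affinity tables
# ---------------------------------------------------------------------------


def build_affinity_table(
    measurements: list[dict],
) -> pd.DataFrame:
    """Assemble the relative-affinity summary from per-oligosaccharide K_D
    measurements.

    Each measurement dict carries: ``oligo`` (length label, e.g. "HA6"),
    ``modification`` ("" for unmodified), ``protein`` ("TSG6" or "CD44"),
    ``kd`` (mol/L or None for not determined), optional ``hc_substrate``
    ("Yes"/"No").  The unmodified oligomer of each length/protein pair in
    use is the %K_B reference; the discrimination ratio is
    %K_B(TSG6)/%K_B(CD44) where both are defined.  Missing measurements
    propagate as absent (NaN), mirroring "n.d." entries.
    """
    refs: dict[tuple[str, str], float] = {}
    for m in measurements:
        if not m.get("modification") and m.get("kd"):
            refs[(m["oligo"], m["protein"])] = m["kd"]

    by_key: dict[tuple[str, str], dict] = {}
    for m in measurements:
        key = (m["oligo"], m.get("modification") or "")
        rec = by_key.setdefault(
            key, {"oligo": key[0], "modification": key[1], "hc_substrate": None}
        )
        rec[f"kd_{m['protein'].lower()}"] = m.get("kd")
        if m.get("hc_substrate") is not None:
            rec["hc_substrate"] = m["hc_substrate"]

    rows: list[AffinityRecord] = []
    for (oligo, mod), rec in by_key.items():
        pct: dict[str, float | None] = {}
        for protein in ("tsg6", "cd44"):
            kd = rec.get(f"kd_{protein}")
            ref = refs.get((oligo, protein.upper()))
            if kd is None or ref is None:
                pct[protein] = None
            else:
                if ref is None:
                    raise KeyError(f"missing unmodified reference for {oligo}/{protein}")
                pct[protein] = percent_binding(kd, ref)
        rows.append(
            AffinityRecord(
                oligo=oligo,
                modification=mod,
                kd_tsg6=rec.get("kd_tsg6"),
                kd_cd44=rec.get("kd_cd44"),
                percent_kb_tsg6=pct["tsg6"],
                percent_kb_cd44=pct["cd44"],
                discrimination=discrimination_ratio(pct["tsg6"], pct["cd44"]),
                hc_substrate=rec.get("hc_substrate"),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
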