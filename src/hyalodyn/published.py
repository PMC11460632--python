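"""Published binding measurements for modified HA oligosaccharides.

These are the printed experimental inputs of the study this package
models: dissociation constants (μM) with thermodynamic parameters
(kcal/mol) for Link_TSG6 by ITC, dissociation constants for the CD44
HA-binding domain by MST, and the heavy-chain-transfer substrate
annotations.  They serve as inputs to the derived-table layer
(:func:`hyalodyn.binding_thermo.build_affinity_table`) and as reference
truths for the synthetic generators.

Conventions: ``kd_um`` in 1e-6 M as printed; ``None`` marks values not
determined (too weak for ITC, or fluorescence interference in MST).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ITC_TSG6",
    "MST_CD44",
    "HC_SUBSTRATE",
    "affinity_measurements",
    "itc_frame",
    "mst_frame",
]

#: Link_TSG6 ITC results (25 °C, pH 6.0): oligo, modification ->
#: (N, K_D μM, ΔG, ΔH, −TΔS).  Unmodified rows are the %K_B references.
ITC_TSG6: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("HA6", ""): (1.04, 1.09, -8.13, -8.29, 0.162),
    ("HA6", "2AA"): (1.03, 0.57, -8.50, -7.84, -0.66),
    ("HA6", "3AA"): (1.05, 0.50, -8.61, -6.30, -2.21),
    ("HA6", "4AA"): (1.02, 0.70, -8.40, -7.57, -0.83),
    ("HA8", ""): (0.98, 0.31, -8.89, -7.26, -1.63),
    ("HA8", "2AA"): (1.06, 1.97, -7.83, -12.55, 4.69),
    ("HA8", "3AA"): (1.05, 0.29, -8.95, -8.53, -0.60),
    ("HA8", "4AA"): (0.86, 0.74, -8.37, -11.53, 3.17),
    ("HA6", "2A4MBA"): (1.00, 0.46, -8.64, -10.07, 1.44),
    ("HA6", "3APY"): (0.93, 2.24, -7.77, -7.82, 0.04),
    ("HA6", "4AI"): (0.97, 1.42, -7.98, -7.16, -0.82),
    ("HA6", "5AI"): (1.03, 0.68, -8.43, -7.46, -0.96),
    ("HA8", "2A4MBA"): (1.04, 1.46, -8.23, -8.06, -0.16),
    ("HA8", "3APY"): (1.19, 0.27, -8.97, -5.70, -3.28),
    ("HA8", "4AI"): (1.01, 0.22, -9.15, -7.02, -2.13),
    ("HA8", "5AI"): (0.97, 0.15, -9.34, -7.43, -1.91),
}

#: CD44 HABD MST dissociation constants (μM, 25 °C, pH 7.5); None = not
#: determined (6AQ oligosaccharides interfere with the fluorescence readout).
MST_CD44: dict[tuple[str, str], float | None] = {
    ("HA4", ""): 2200.0,
    ("HA4", "2AA"): 1200.0,
    ("HA4", "3AA"): 845.0,
    ("HA4", "4AA"): 488.0,
    ("HA6", ""): 103.0,
    ("HA6", "2AA"): 181.0,
    ("HA6", "3AA"): 896.0,
    ("HA6", "4AA"): 253.0,
    ("HA8", ""): 51.0,
    ("HA8", "2AA"): 108.0,
    ("HA8", "3AA"): 399.0,
    ("HA8", "4AA"): 478.0,
    ("HA6", "2A4MBA"): 198.0,
    ("HA6", "3APY"): 113.0,
    ("HA6", "4AI"): 369.0,
    ("HA6", "5AI"): 77.0,
    ("HA6", "6AQ"): None,
    ("HA8", "2A4MBA"): 36.0,
    ("HA8", "3APY"): 220.0,
    ("HA8", "4AI"): 139.0,
    ("HA8", "5AI"): 54.0,
    ("HA8", "6AQ"): None,
}

#: Heavy-chain transfer substrate annotation (categorical assay outcome).
HC_SUBSTRATE: dict[tuple[str, str], str] = {
    ("HA4", ""): "No",
    ("HA4", "2AA"): "No",
    ("HA4", "3AA"): "No",
    ("HA4", "4AA"): "Yes",
    ("HA4", "2A4MBA"): "Yes",
    ("HA6", ""): "No",
    ("HA6", "2AA"): "Yes",
    ("HA6", "3AA"): "No",
    ("HA6", "4AA"): "Yes",
    ("HA6", "2A4MBA"): "Yes",
    ("HA6", "3APY"): "Yes",
    ("HA6", "4AI"): "No",
    ("HA6", "5AI"): "No",
    ("HA6", "6AQ"): "No",
    ("HA8", ""): "Yes",
    ("HA8", "2AA"): "Yes",
    ("HA8", "3AA"): "Yes",
    ("HA8", "4AA"): "Yes",
    ("HA8", "2A4MBA"): "Yes",
    ("HA8", "3APY"): "Yes",
    ("HA8", "4AI"): "Yes",
    ("HA8", "5AI"): "Yes",
    ("HA8", "6AQ"): "Yes",
}


def itc_frame() -> pd.DataFrame:
    rows = [
        {
            "oligo": o,
            "modification": m,
            "N": v[0],
            "kd_um": v[1],
            "delta_G": v[2],
            "delta_H": v[3],
            "minus_T_delta_S": v[4],
        }
        for (o, m), v in ITC_TSG6.items()
    ]
    return pd.DataFrame(rows)


def mst_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [{"oligo": o, "modification": m, "kd_um": v} for (o, m), v in MST_CD44.items()]
    )


def affinity_measurements() -> list[dict]:
    """The published K_D values as the measurement list consumed by
    :func:`hyalodyn.binding_thermo.build_affinity_table` (kd in mol/L)."""
    out = []
    for (oligo, mod), (_, kd_um, *_rest) in ITC_TSG6.items():
        out.append(
            {
                "oligo": oligo,
                "modification": mod,
                "protein": "TSG6",
                "kd": kd_um * 1e-6,
                "hc_substrate": HC_SUBSTRATE.get((oligo, mod)),
            }
        )
    for (oligo, mod), kd_um in MST_CD44.items():
        out.append(
            {
                "oligo": oligo,
                "modification": mod,
                "protein": "CD44",
                "kd": None if kd_um is None else kd_um * 1e-6,
                "hc_substrate": HC_SUBSTRATE.get((oligo, mod)),
            }
        )
    return out
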