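"""Binding thermodynamics: identities, Wiseman isotherm, fits and derived
affinity tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyalodyn.binding_thermo import (
    FitError,
    TitrationData,
    build_affinity_table,
    discrimination_ratio,
    entropy_term,
    fit_itc,
    fit_mst,
    free_energy_from_kd,
    mst_fraction_bound,
    percent_binding,
    wiseman_heats,
)
from hyalodyn.published import affinity_measurements
from hyalodyn.synthetic_data import ITC_SCHEDULE_DEFAULT, simulate_itc, simulate_mst


class TestElementary:
    def test_free_energy_published_hexasaccharide(self):
        """K_D = 1.09 μM at 25 °C gives ΔG = −8.13 kcal/mol (2 dp)."""
        assert round(free_energy_from_kd(1.09e-6, 298.15), 2) == -8.13

    def test_free_energy_standard_state(self):
        assert free_energy_from_kd(1.0, 310.0) == 0.0

    def test_free_energy_micromolar(self):
        assert round(free_energy_from_kd(1.0e-6, 298.15), 2) == -8.19

    @pytest.mark.parametrize(
        "dg, dh, expected",
        [(-8.89, -7.26, -1.63), (-3.0, -3.0, 0.0), (-8.13, -8.29, 0.16)],
    )
    def test_entropy_term(self, dg, dh, expected):
        assert entropy_term(dg, dh) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "kd_mod, kd_ref, expected",
        [(0.50, 1.09, 218), (845.0, 2200.0, 260), (7.0, 7.0, 100)],
    )
    def test_percent_binding(self, kd_mod, kd_ref, expected):
        assert round(percent_binding(kd_mod, kd_ref)) == expected

    @pytest.mark.parametrize(
        "pct_t, pct_c, expected",
        [(156.0, 41.0, 3.80), (100.0, 100.0, 1.00), (21.0, 141.0, 0.15)],
    )
    def test_discrimination_ratio(self, pct_t, pct_c, expected):
        assert round(discrimination_ratio(pct_t, pct_c), 2) == expected

    def test_discrimination_absent_side(self):
        assert discrimination_ratio(None, 50.0) is None

    @given(
        a=st.floats(min_value=1.0, max_value=1e4),
        b=st.floats(min_value=1.0, max_value=1e4),
    )
    @settings(derandomize=True, max_examples=50)
    def test_discrimination_inverse(self, a, b):
        assert discrimination_ratio(a, b) == pytest.approx(
            1.0 / discrimination_ratio(b, a)
        )

    @given(
        kd1=st.floats(min_value=1e-9, max_value=1e-3),
        kd2=st.floats(min_value=1e-9, max_value=1e-3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_percent_binding_antitone(self, kd1, kd2):
        lo, hi = sorted((kd1, kd2))
        assert percent_binding(hi, 1e-6) <= percent_binding(lo, 1e-6)


class TestWisemanForward:
    def test_zero_enthalpy_zero_heats(self):
        q = wiseman_heats((1e-6, 0.0, 1.0), ITC_SCHEDULE_DEFAULT())
        assert np.allclose(q, 0.0)

    def test_saturating_regime_front_loaded(self):
        """With K_D far below the cell concentration the first injection
        carries nearly all the heat of its injected ligand and the final
        injections approach zero."""
        sched = ITC_SCHEDULE_DEFAULT()
        q = wiseman_heats((1e-10, -8.0, 1.0), sched)
        moles_1 = sched.syringe_conc * sched.injection_volumes[0]
        assert q[0] == pytest.approx(-8.0 * moles_1, rel=0.02)
        assert abs(q[-1]) < 0.02 * abs(q[0])

    def test_paper_schedule_c_value_and_sigmoid(self):
        """The study conditions give c ≈ 27.7 and an inflection near molar
        ratio N."""
        sched = ITC_SCHEDULE_DEFAULT()
        kd, dh, n = 1.09e-6, -8.29, 1.04
        c_value = n * sched.cell_conc / kd
        assert c_value == pytest.approx(27.7, abs=0.1)
        q = wiseman_heats((kd, dh, n), sched)
        vcum = np.cumsum(sched.injection_volumes)
        dil = np.exp(-vcum / sched.cell_volume)
        ratio = (sched.syringe_conc * (1 - dil)) / (sched.cell_conc * dil)
        # steepest heat change happens within +/-0.4 of molar ratio N
        steep = np.argmax(np.abs(np.diff(q)))
        assert abs(ratio[steep] - n) < 0.4

    def test_heat_conservation_at_saturation(self):
        """Total heat approaches N·ΔH·(cell protein moles) within 0.5% when
        the displaced volume is negligible and the titration saturates, for
        c across [5, 500]."""
        for c in (5.0, 50.0, 500.0):
            m0, v0, n = 0.029e-3, 1.4e-3, 1.0
            kd = n * m0 / c
            # tiny cumulative volume, enormous ligand excess
            syringe = max(1000.0 * kd * v0 / 10e-6, 100.0 * m0)
            sched = TitrationData(
                cell_conc=m0,
                syringe_conc=syringe,
                cell_volume=v0,
                injection_volumes=[0.4e-6] * 25,
                heats=[0.0] * 25,
            )
            q = wiseman_heats((kd, -8.0, n), sched)
            total = q.sum()
            expected = n * -8.0 * m0 * v0
            assert total == pytest.approx(expected, rel=5e-3)

    def test_total_heat_equals_complex_formed(self):
        """Exact bookkeeping identity: the summed heats equal ΔH times the
        total moles of complex formed (in-cell plus displaced)."""
        sched = ITC_SCHEDULE_DEFAULT()
        kd, dh, n = 1.09e-6, -8.29, 1.04
        q = wiseman_heats((kd, dh, n), sched)
        v0 = sched.cell_volume
        dvs = np.asarray(sched.injection_volumes)
        vcum = np.cumsum(dvs)
        dil = np.exp(-vcum / v0)
        m = sched.cell_conc * dil
        x = sched.syringe_conc * (1 - dil)
        b = n * m + x + kd
        rl = (b - np.sqrt(b * b - 4 * n * m * x)) / 2
        formed = v0 * rl[-1] + np.sum(dvs * np.concatenate([[0.0], rl[:-1]]))
        assert q.sum() == pytest.approx(dh * formed, rel=1e-9)


class TestItcFit:
    TRUTH = (1.09e-6, -8.29, 1.04)

    def test_zero_noise_recovery(self):
        """Fitting the forward model's own output returns the generating
        parameters within 0.1%."""
        data, _ = simulate_itc(self.TRUTH, noise_sd=0.0, seed=1)
        res = fit_itc(data)
        assert res.K_D == pytest.approx(self.TRUTH[0], rel=1e-3)
        assert res.delta_H == pytest.approx(self.TRUTH[1], rel=1e-3)
        assert res.N == pytest.approx(self.TRUTH[2], rel=1e-3)

    def test_zero_noise_recovery_across_c_values(self):
        for c in (5.0, 50.0, 400.0):
            kd = 1.04 * 0.029e-3 / c
            data, _ = simulate_itc((kd, -8.0, 1.04), noise_sd=0.0, seed=2)
            res = fit_itc(data)
            assert res.K_D == pytest.approx(kd, rel=5e-3)

    def test_thermodynamic_identity(self):
        data, _ = simulate_itc(self.TRUTH, noise_sd=0.01, seed=5)
        res = fit_itc(data)
        rt = 1.98720425e-3 * res.temperature
        assert abs(res.delta_G - rt * math.log(res.K_D)) < 1e-9
        assert abs(res.minus_T_delta_S - (res.delta_G - res.delta_H)) < 1e-9

    def test_all_zero_heats_degenerate(self):
        sched = ITC_SCHEDULE_DEFAULT()
        with pytest.raises(FitError):
            fit_itc(sched)

    def test_too_few_injections(self):
        data = TitrationData(
            cell_conc=1e-5,
            syringe_conc=1e-4,
            cell_volume=2e-4,
            injection_volumes=[2e-6] * 4,
            heats=[1e-9] * 4,
        )
        with pytest.raises(FitError, match="6 injections"):
            fit_itc(data)


class TestMstModel:
    def test_half_saturation(self):
        assert mst_fraction_bound(51e-6, 1e-12, 51e-6) == pytest.approx(0.5, abs=1e-4)

    def test_saturation_limit(self):
        assert mst_fraction_bound(10.0, 1e-8, 51e-6) == pytest.approx(1.0, abs=1e-4)

    def test_quadratic_matches_approximation_at_low_receptor(self):
        """At 10 nM receptor and K_D = 51 μM, receptor depletion is
        negligible: the exact quadratic equals L/(L+K)."""
        exact = mst_fraction_bound(51e-6, 10e-9, 51e-6)
        assert exact == pytest.approx(0.5000, abs=1e-4)

    def test_zero_noise_recovery(self):
        data, _ = simulate_mst(51e-6, noise_sd=0.0, seed=3)
        kd, baseline, amplitude, _ = fit_mst(data)
        assert kd == pytest.approx(51e-6, rel=1e-3)
        assert baseline == pytest.approx(850.0, rel=1e-3)
        assert amplitude == pytest.approx(25.0, rel=1e-3)

    def test_flat_response_rejected(self):
        data, _ = simulate_mst(51e-6, noise_sd=0.0, seed=3)
        data.responses = [850.0] * len(data.responses)
        with pytest.raises(FitError, match="flat|amplitude"):
            fit_mst(data)

    def test_dilution_series_spans_printed_range(self):
        data, _ = simulate_mst(51e-6, noise_sd=0.0, seed=0)
        assert max(data.ligand_concs) == pytest.approx(5e-3)
        assert min(data.ligand_concs) == pytest.approx(5e-3 / 2**15)
        assert min(data.ligand_concs) == pytest.approx(0.00015e-3, rel=0.02)


class TestAffinityTable:
    def test_published_inputs_reproduce_derived_columns(self):
        table = build_affinity_table(affinity_measurements())
        row = table.set_index(["oligo", "modification"])

        def pct(oligo, mod, col):
            return round(row.loc[(oligo, mod), col])

        assert pct("HA6", "3AA", "percent_kb_tsg6") == 218
        assert pct("HA4", "3AA", "percent_kb_cd44") == 260
        assert pct("HA6", "2AA", "percent_kb_cd44") == 57
        assert pct("HA8", "5AI", "percent_kb_tsg6") == 207
        # full-precision ratios sit within a couple of hundredths of the
        # values printed from integer percents
        assert row.loc[("HA6", "4AA"), "discrimination"] == pytest.approx(3.80, abs=0.03)
        assert row.loc[("HA8", "2A4MBA"), "discrimination"] == pytest.approx(0.15, abs=0.01)
        assert row.loc[("HA6", "2AA"), "hc_substrate"] == "Yes"

    def test_unmodified_reference_rows(self):
        table = build_affinity_table(affinity_measurements())
        row = table.set_index(["oligo", "modification"])
        assert row.loc[("HA6", ""), "percent_kb_tsg6"] == pytest.approx(100.0)
        assert row.loc[("HA6", ""), "discrimination"] == pytest.approx(1.0)

    def test_missing_measurement_propagates_as_absent(self):
        """The fluorescence-interference case (6AQ) has no CD44 K_D, so the
        discrimination ratio is absent rather than an error."""
        table = build_affinity_table(affinity_measurements())
        row = table.set_index(["oligo", "modification"])
        assert row.loc[("HA6", "6AQ"), "percent_kb_cd44"] is None or np.isnan(
            row.loc[("HA6", "6AQ"), "percent_kb_cd44"]
        )
        assert row.loc[("HA6", "6AQ"), "discrimination"] is None or np.isnan(
            row.loc[("HA6", "6AQ"), "discrimination"]
        )

    def test_single_unmodified_entry(self):
        table = build_affinity_table(
            [{"oligo": "HA6", "modification": "", "protein": "TSG6", "kd": 1e-6}]
        )
        assert table.iloc[0]["percent_kb_tsg6"] == pytest.approx(100.0)
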