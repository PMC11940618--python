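"""Normalization, logistic fitting and censored POD derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from nephroscreen._censored import CensoredValue
from nephroscreen.doseresponse import (
    DoseResponseModel,
    DoseResponseResults,
    InsufficientDataError,
    NormalizationError,
    derive_pod,
    fit_screen,
    invert_logistic,
    normalize_to_vehicle,
)
from nephroscreen.simulate import TruthParams, generate_plate_dataset

PANEL = np.array([0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0])


def _records(conc, signal, cell_source="A", drug="d"):
    return pd.DataFrame(
        {
            "cell_source": cell_source,
            "drug": drug,
            "concentration_uM": conc,
            "replicate": np.arange(1, len(conc) + 1),
            "signal": signal,
        }
    )


def _results(top=100.0, bottom=0.0, ec50=10.0, hill=1.0, fit_ok=True, cmax=300.0):
    bse = {"bottom": 0.0, "log10_ec50": 0.0, "hill": 0.0}
    return DoseResponseResults(
        "A", "d", top, bottom, ec50, hill, bse, 0.0, 21, 0.0, fit_ok, cmax
    )


class TestNormalize:
    @pytest.mark.parametrize(
        "treated,expected", [(500.0, 50.0), (1000.0, 100.0), (0.0, 0.0)]
    )
    def test_percent_of_vehicle_arithmetic(self, treated, expected):
        df = _records([0, 0, 0, 10], [1000.0, 1000.0, 1000.0, treated])
        out = normalize_to_vehicle(df)
        assert out.loc[out.concentration_uM == 10, "viability"].iloc[0] == expected

    def test_vehicle_wells_retained_and_average_100(self):
        df = _records([0, 0, 10], [900.0, 1100.0, 500.0])
        out = normalize_to_vehicle(df)
        veh = out.loc[out.concentration_uM == 0, "viability"]
        assert len(veh) == 2 and veh.mean() == pytest.approx(100.0)

    def test_no_vehicle_wells_raises(self):
        with pytest.raises(NormalizationError, match="no vehicle"):
            normalize_to_vehicle(_records([1, 10], [500.0, 400.0]))

    def test_nonpositive_vehicle_mean_raises(self):
        with pytest.raises(NormalizationError, match="vehicle mean"):
            normalize_to_vehicle(_records([0, 0, 10], [1.0, -1.0, 5.0]))

    def test_groups_normalized_independently(self):
        df = pd.concat(
            [
                _records([0, 10], [1000.0, 500.0], drug="d1"),
                _records([0, 10], [2000.0, 500.0], drug="d2"),
            ]
        )
        out = normalize_to_vehicle(df).set_index(["drug", "concentration_uM"])
        assert float(out.loc[("d1", 10), "viability"]) == 50.0
        assert float(out.loc[("d2", 10), "viability"]) == 25.0


class TestFit:
    @pytest.mark.parametrize("hill", [0.7, 1.0, 2.0, 3.0])
    @pytest.mark.parametrize("ec50", [1.0, 10.0, 100.0])
    def test_noiseless_recovery(self, hill, ec50):
        params = TruthParams(noise_cv=0.0, bottom=0.0, ec50_true=ec50, hill=hill)
        norm = normalize_to_vehicle(generate_plate_dataset(params))
        res = DoseResponseModel.from_dataframe(norm).fit()
        assert res.fit_ok
        assert res.ec50 == pytest.approx(ec50, rel=1e-6)
        assert res.hill == pytest.approx(hill, rel=1e-4)
        assert res.bottom == pytest.approx(0.0, abs=1e-3)

    def test_flat_response_censors_both_pods(self):
        viab = np.full(PANEL.size, 100.0)
        res = DoseResponseModel(PANEL, viab).fit()
        assert not res.fit_ok
        assert res.ec50_pod == CensoredValue(300.0, censored=True)
        assert res.ic10_pod == CensoredValue(300.0, censored=True)

    def test_noisy_fit_beats_brute_force_grid(self):
        params = TruthParams(noise_cv=0.1, bottom=0.0, ec50_true=10.0, hill=1.0, seed=3)
        norm = normalize_to_vehicle(generate_plate_dataset(params))
        model = DoseResponseModel.from_dataframe(norm)
        res = model.fit()
        # independent oracle: exhaustive 50x50x50 grid over (bottom, ec50, hill)
        conc, viab = model.conc, model.viab
        bottoms = np.linspace(0, 100, 50)
        ec50s = np.logspace(np.log10(0.03), np.log10(3000), 50)
        hills = np.linspace(0.1, 10, 50)
        best = np.inf
        for h in hills:
            frac = 1.0 / (1.0 + (conc[None, :] / ec50s[:, None]) ** h)  # (50, n)
            curves = bottoms[:, None, None] + (100 - bottoms[:, None, None]) * frac[None]
            sse = ((curves - viab) ** 2).sum(axis=-1)
            best = min(best, sse.min())
        assert res.sse <= best + 1e-9

    def test_insufficient_concentrations_rejected(self):
        with pytest.raises(InsufficientDataError):
            DoseResponseModel([0, 1, 10, 100], [100, 90, 50, 10])

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseModel(PANEL, [np.nan] * PANEL.size)

    def test_standard_errors_shrink_with_replicates(self):
        se = {}
        for n in (2, 10):
            params = TruthParams(noise_cv=0.1, n_replicates=n, seed=5)
            norm = normalize_to_vehicle(generate_plate_dataset(params))
            se[n] = DoseResponseModel.from_dataframe(norm).fit().bse["log10_ec50"]
        assert se[10] < se[2]

    def test_summary_renders(self, noiseless_points):
        res = DoseResponseModel.from_dataframe(noiseless_points).fit()
        text = res.summary()
        assert "EC50" in text and "hill" in text

    def test_fit_screen_one_row_per_series(self):
        design = {
            ("A", "d1"): TruthParams(seed=1),
            ("A", "d2"): TruthParams(seed=2),
            ("B", "d1"): TruthParams(seed=3),
        }
        from nephroscreen.simulate import generate_screen_dataset

        pods = fit_screen(normalize_to_vehicle(generate_screen_dataset(design)))
        assert len(pods) == 3
        assert set(zip(pods.cell_source, pods.drug)) == set(design)


class TestDerivePod:
    def test_midpoint_identity(self):
        pod = derive_pod(_results(), 50.0)
        assert pod == CensoredValue(10.0)

    def test_ic10_closed_form(self):
        pod = derive_pod(_results(), 90.0)
        assert pod.value == pytest.approx(10.0 / 9.0, rel=1e-12)

    def test_high_bottom_censors(self):
        pod = derive_pod(_results(bottom=60.0), 50.0)
        assert pod == CensoredValue(300.0, censored=True)

    def test_solution_beyond_range_censors(self):
        pod = derive_pod(_results(ec50=500.0), 50.0)
        assert pod == CensoredValue(300.0, censored=True)

    def test_failed_fit_censors(self):
        pod = derive_pod(_results(fit_ok=False), 50.0)
        assert pod.censored

    @pytest.mark.parametrize("threshold", [0.0, 100.0, -5.0, 150.0])
    def test_threshold_out_of_range_rejected(self, threshold):
        with pytest.raises(ValueError):
            derive_pod(_results(), threshold)

    def test_closed_form_matches_bisection_grid(self):
        # oracle: root finding on the fitted curve itself
        for bottom in (0.0, 20.0, 45.0):
            for ec50 in (0.5, 10.0, 150.0):
                for hill in (0.5, 1.0, 4.0):
                    for thr in (90.0, 50.0):
                        c = invert_logistic(100.0, bottom, ec50, hill, thr)
                        if c is None or c > 1e6:
                            continue
                        f = lambda x: bottom + (100 - bottom) / (1 + (x / ec50) ** hill) - thr
                        root = brentq(f, 1e-12, 1e7, xtol=1e-15, rtol=1e-14)
                        assert c == pytest.approx(root, rel=1e-9)

    @given(
        bottom=st.floats(0.0, 45.0),
        ec50=st.floats(0.1, 200.0),
        hill=st.floats(0.3, 8.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_ic10_never_exceeds_ec50_pod(self, bottom, ec50, hill):
        """On a monotone-decreasing curve the 10% POD precedes the 50% POD."""
        res = _results(bottom=bottom, ec50=ec50, hill=hill, cmax=1e12)
        ic10, ec50_pod = res.pod(90.0), res.pod(50.0)
        assert not ic10.censored and not ec50_pod.censored
        assert ic10.value <= ec50_pod.value + 1e-9

    def test_raising_cmax_only_uncensors(self):
        res = _results(ec50=500.0)
        low = derive_pod(res, 50.0, c_max_tested=300.0)
        high = derive_pod(res, 50.0, c_max_tested=3000.0)
        assert low.censored and not high.censored
        assert high.value == pytest.approx(500.0)
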