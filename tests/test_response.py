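import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from cuniqg import presets
from cuniqg.objectives import BreedingObjective
from cuniqg.response import (RecordType, RecordingPlan, ResponseParameters,
                             SchemeConfig, predict_response,
                             selection_intensity,
                             variance_reduction_factor)


class TestSelectionIntensity:
    def test_select_all_gives_zero(self):
        assert selection_intensity(1.0) == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            selection_intensity(0.0)

    @pytest.mark.parametrize("p", [0.15, 0.25, 0.5, 0.05])
    def test_matches_truncated_normal_quadrature(self, p):
        z = norm.ppf(1 - p)
        num, _ = integrate.quad(lambda x: x * norm.pdf(x), z, 10.0)
        assert selection_intensity(p) == pytest.approx(num / p, abs=1e-8)

    def test_finite_population_reduces_intensity(self):
        i_inf = selection_intensity(0.25)
        i_490 = selection_intensity(0.25, N=490)
        assert i_490 < i_inf
        assert i_490 == pytest.approx(i_inf, rel=0.01)  # mild at N=490

    def test_variance_reduction_factor_in_unit_interval(self):
        for p in (0.05, 0.15, 0.25, 0.5, 0.9):
            k = variance_reduction_factor(p)
            assert 0.0 < k < 1.0


def single_trait_params(h2=0.3, s2p=100.0):
    s2a = h2 * s2p
    return ResponseParameters(
        traits=["T"],
        G=np.array([[s2a]]),
        records={"T": RecordType("T", "T", var_resid=s2p - s2a)},
    )


def mass_selection_scheme():
    rp = RecordingPlan(own=("T",), sib_recorded=(), dam_records=0)
    return SchemeConfig(recording=rp, selected_fraction_males=0.15,
                        selected_fraction_females=0.15,
                        finite_intensity=False)


class TestPredictResponse:
    def test_zero_genetic_variance_zero_response(self):
        params = presets.response_parameters()
        params.G = np.zeros_like(params.G)
        scheme = presets.nucleus_scheme("HProduction")
        pred = predict_response(scheme, params,
                                presets.standard_objectives()["HProduction"])
        assert all(v == 0.0 for v in pred.responses.values())

    def test_mass_selection_matches_theory_and_stochastic_sim(self):
        """Single trait, own record only, no Bulmer: response = i h^2
        sigma_p, checked against 50,000 simulated candidates."""
        h2, s2p, p = 0.3, 100.0, 0.15
        params = single_trait_params(h2, s2p)
        pred = predict_response(mass_selection_scheme(), params,
                                BreedingObjective("m", {"T": 1.0}),
                                bulmer=False)
        i = selection_intensity(p)
        theory = i * h2 * math.sqrt(s2p)
        assert pred.responses["T"] == pytest.approx(theory, rel=1e-10)

        rng = np.random.default_rng(17)
        n = 50_000
        bv = rng.normal(0, math.sqrt(h2 * s2p), n)
        ph = bv + rng.normal(0, math.sqrt((1 - h2) * s2p), n)
        sel = ph >= np.quantile(ph, 1 - p)
        mc = bv[sel].mean()
        mc_se = bv[sel].std() / math.sqrt(sel.sum())
        assert pred.responses["T"] == pytest.approx(mc, abs=4 * mc_se)

    def test_doubling_weights_leaves_responses_unchanged(self):
        params = presets.response_parameters()
        objs = presets.standard_objectives()
        scheme = presets.nucleus_scheme("HResist_S_Ch", ch_records=True)
        base = objs["HResist_S_Ch"]
        double = BreedingObjective(
            "2x", {k: 2 * v for k, v in base.weights.items()})
        r1 = predict_response(scheme, params, base).responses
        r2 = predict_response(scheme, params, double).responses
        for t in r1:
            assert r2[t] == pytest.approx(r1[t], rel=1e-9)

    def test_bulmer_recursion_monotone_and_converged(self):
        params = presets.response_parameters()
        scheme = presets.nucleus_scheme("HProduction")
        obj = presets.standard_objectives()["HProduction"]
        pred = predict_response(scheme, params, obj)
        # equilibrium genetic variances never exceed the base ones
        assert (np.diag(pred.equilibrium_G) <= np.diag(params.G) + 1e-9).all()
        # and re-running from the equilibrium is a fixed point
        params2 = ResponseParameters(
            traits=params.traits, G=params.G, records=params.records,
            resid_cov=params.resid_cov)
        pred2 = predict_response(scheme, params2, obj)
        assert np.allclose(pred.equilibrium_G, pred2.equilibrium_G)
        assert pred.accuracy < 1.0

    def test_bulmer_reduces_response(self):
        params = presets.response_parameters()
        scheme = presets.nucleus_scheme("HProduction")
        obj = presets.standard_objectives()["HProduction"]
        with_b = predict_response(scheme, params, obj)
        without = predict_response(scheme, params, obj, bulmer=False)
        assert abs(with_b.responses["WW_direct"]) < \
            abs(without.responses["WW_direct"])

    def test_ch_recording_never_decreases_accuracy_or_ch_response(self):
        params = presets.response_parameters()
        objs = presets.standard_objectives()
        for name in ("HResist_S", "HResist_Ch", "HResist_S_Ch"):
            no = predict_response(presets.nucleus_scheme(name, False),
                                  params, objs[name])
            yes = predict_response(presets.nucleus_scheme(name, True),
                                   params, objs[name])
            assert yes.responses["Resist_Ch"] <= no.responses["Resist_Ch"]

    def test_production_only_gives_extreme_responses(self):
        params = presets.response_parameters()
        objs = presets.standard_objectives()
        preds = {}
        for name in objs:
            for ch in ((False,) if name == "HProduction" else (True, False)):
                preds[(name, ch)] = predict_response(
                    presets.nucleus_scheme(name, ch), params, objs[name])
        prod = preds[("HProduction", False)]
        others = [p for k, p in preds.items() if k[0] != "HProduction"]
        assert prod.responses["WW_direct"] > \
            max(p.responses["WW_direct"] for p in others)
        for trait in ("Resist_S", "Resist_Ch"):
            assert abs(prod.responses[trait]) < \
                min(abs(p.responses[trait]) for p in others)

    def test_disease_response_vanishes_without_genetic_correlation(self):
        params = presets.response_parameters()
        G = params.G.copy()
        G[3, :3] = G[:3, 3] = 0.0
        G[4, :3] = G[:3, 4] = 0.0
        params.G = G
        scheme = presets.nucleus_scheme("HProduction")
        pred = predict_response(scheme, params,
                                presets.standard_objectives()["HProduction"])
        assert pred.responses["Resist_S"] == pytest.approx(0.0, abs=1e-9)
        assert pred.responses["Resist_Ch"] == pytest.approx(0.0, abs=1e-9)
        # with the fitted (favorable) correlations the correlated response
        # is favorable (negative)
        pred2 = predict_response(scheme, presets.response_parameters(),
                                 presets.standard_objectives()["HProduction"])
        assert pred2.responses["Resist_S"] < 0
        assert pred2.responses["Resist_Ch"] < 0

    def test_non_psd_matrix_rejected(self):
        params = presets.response_parameters()
        G = params.G.copy()
        G[0, 1] = G[1, 0] = 10 * math.sqrt(G[0, 0] * G[1, 1])
        params.G = G
        with pytest.raises(ValueError, match="PSD"):
            predict_response(presets.nucleus_scheme("HProduction"), params,
                             presets.standard_objectives()["HProduction"])
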