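"""Limited-information fit statistics and EAP-based domain correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_benchmark_items, simulate_single_group, single_domain_spec
from saqirt.calibrate import calibrate_domain
from saqirt.fit import (
    _Margins,
    domain_correlations,
    independence_baseline,
    m2_statistic,
    marginal_reliability,
    rmsea_nnfi,
)
from saqirt.grm import slope_to_loading
from saqirt.instrument import InstrumentSpec, ResponseMatrix
from saqirt.pipeline import result_from_items
from saqirt.scoring import score_matrix
from saqirt.simulate import GroupMix, SimulationConfig, generate_dataset


class TestM2:
    def test_df_counting(self, recovery_calib, recovery_dataset):
        matrix, _ = recovery_dataset
        m2, df, p = m2_statistic(recovery_calib, matrix)
        # 5 items, K=5: 5*4 univariate + 10*16 bivariate margins - 25 params
        assert df == 5 * 4 + 10 * 16 - 25 == 155
        assert m2 >= 0
        assert 0 <= p <= 1

    def test_invariant_to_item_ordering(self, recovery_calib, recovery_dataset, bench_spec):
        matrix, _ = recovery_dataset
        m2_a, df_a, _ = m2_statistic(recovery_calib, matrix)
        perm = ("D3", "D1", "D5", "D2", "D4")
        permuted = result_from_items(
            [recovery_calib.items[i] for i in perm], "D", perm
        )
        permuted.em = recovery_calib.em
        m2_b, df_b, _ = m2_statistic(permuted, matrix)
        assert df_a == df_b
        assert m2_a == pytest.approx(m2_b, rel=1e-6)

    def test_implied_margins_match_large_sample_simulation(self, bench_spec, bench_items):
        # quadrature-implied margins vs a 50k-draw Monte-Carlo estimate
        matrix, _ = simulate_single_group(bench_spec, bench_items, n=50_000, seed=8)
        x = matrix.codes().astype(int)
        calib = result_from_items(list(bench_items.values()), "D", bench_spec.item_ids)
        margins = _Margins([5] * 5)
        from saqirt.fit import _grm_prob_tables

        grid = calib.em.grid()
        pi = margins.mean_vector(
            _grm_prob_tables(calib.item_list, grid.nodes, 5), grid.weights
        )
        obs = margins.observed(x)
        se = np.sqrt(np.maximum(pi * (1 - pi), 1e-12) / 50_000)
        assert np.all(np.abs(obs - pi) <= 3.5 * se)

    def test_type_one_error_calibrated(self):
        """M2 p-values behave like a null test when the model is true."""
        items = make_benchmark_items(n_items=3, seed=3, base_thresholds=(-1.0, 1.0))
        spec = single_domain_spec(tuple(items), k=3)
        pvals = []
        for seed in range(40):
            matrix, _ = simulate_single_group(spec, items, n=1200, seed=seed)
            res = calibrate_domain(matrix, "D", spec)
            pvals.append(m2_statistic(res, matrix)[2])
        pvals = np.asarray(pvals)
        assert np.mean(pvals < 0.05) <= 0.15
        assert 0.25 < pvals.mean() < 0.75

    def test_multigroup_rejected(self, bench_spec, bench_items):
        cfg = SimulationConfig(
            n_respondents=600,
            spec=bench_spec,
            true_items=bench_items,
            group_mix=(GroupMix("a", 0.5), GroupMix("b", 0.5, -0.3, 1.0)),
            latent_corr=np.eye(1),
            seed=0,
        )
        matrix, _ = generate_dataset(cfg)
        res = calibrate_domain(matrix, "D", bench_spec, groups=True)
        with pytest.raises(ValueError, match="single-group"):
            m2_statistic(res, matrix)


class TestRmseaNnfi:
    def test_truncation_at_zero(self):
        rmsea, _ = rmsea_nnfi(100.0, 155, 1000, (5000.0, 160))
        assert rmsea == 0.0

    def test_formulas(self):
        rmsea, nnfi = rmsea_nnfi(310.0, 155, 1000, (3200.0, 160))
        assert rmsea == pytest.approx(np.sqrt((310 - 155) / (155 * 1000)))
        assert nnfi == pytest.approx((20.0 - 2.0) / (20.0 - 1.0))

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            rmsea_nnfi(10.0, 0, 100, (100.0, 10))
        with pytest.raises(ValueError):
            rmsea_nnfi(10.0, 5, 100, (100.0, 0))

    def test_misfit_ordering_reverse_keyed_item(self, bench_spec, bench_items):
        """A reverse-keyed item (negative dependence the GRM cannot express)
        must show strictly worse fit than the clean data."""
        rmseas = {}
        for tag in ("clean", "reversed"):
            matrix, _ = simulate_single_group(bench_spec, bench_items, n=3000, seed=6)
            if tag == "reversed":
                data = matrix.data.copy()
                data["D5"] = pd.array(6 - data["D5"].to_numpy(int), dtype="Int64")
                matrix = ResponseMatrix(data=data)
            res = calibrate_domain(matrix, "D", bench_spec)
            m2, df, _ = m2_statistic(res, matrix)
            rmseas[tag], _ = rmsea_nnfi(
                m2, df, matrix.n_respondents, independence_baseline(res, matrix)
            )
        assert rmseas["reversed"] > rmseas["clean"]


class TestDomainCorrelations:
    @staticmethod
    def _two_domain_scores(rho, n, seed):
        ids = tuple(f"{p}{k}" for p in "AB" for k in range(1, 6))
        spec = InstrumentSpec(
            domains=(("A", ids[:5]), ("B", ids[5:])),
            n_categories={i: 5 for i in ids},
        )
        items = make_benchmark_items(n_items=10, prefix="X", seed=1)
        items = {new: type(it)(new, it.a, it.c) for new, it in zip(ids, items.values())}
        corr = np.array([[1.0, rho], [rho, 1.0]]) if rho else np.eye(2)
        cfg = SimulationConfig(
            n_respondents=n,
            spec=spec,
            true_items=items,
            group_mix=(GroupMix("all", 1.0, 0.0, 1.0),),
            latent_corr=corr,
            seed=seed,
        )
        matrix, _ = generate_dataset(cfg)
        calibs = {
            d: result_from_items([items[i] for i in spec.items_for(d)], d, spec.items_for(d))
            for d in ("A", "B")
        }
        scores = score_matrix(matrix, calibs, spec)
        theta = scores[["A_theta", "B_theta"]].set_axis(["A", "B"], axis=1)
        rel = {d: marginal_reliability(scores[f"{d}_psd"]) for d in ("A", "B")}
        return theta, rel

    def test_attenuation_and_disattenuated_recovery(self):
        theta, rel = self._two_domain_scores(rho=0.85, n=10_000, seed=2)
        raw, dis = domain_correlations(theta, rel)
        assert raw.loc["A", "B"] < 0.85
        assert dis.loc["A", "B"] == pytest.approx(0.85, abs=0.05)

    def test_independent_traits_near_zero(self):
        theta, rel = self._two_domain_scores(rho=0.0, n=10_000, seed=3)
        raw, dis = domain_correlations(theta, rel)
        assert abs(raw.loc["A", "B"]) < 0.03

    def test_duplicated_domain_perfect_correlation(self):
        theta, rel = self._two_domain_scores(rho=0.85, n=500, seed=4)
        dup = pd.DataFrame({"A": theta["A"], "A2": theta["A"]})
        raw, _ = domain_correlations(dup)
        assert raw.loc["A", "A2"] == pytest.approx(1.0)

    def test_disattenuated_at_least_raw(self):
        theta, rel = self._two_domain_scores(rho=0.85, n=2000, seed=5)
        raw, dis = domain_correlations(theta, rel)
        assert abs(dis.loc["A", "B"]) >= abs(raw.loc["A", "B"])

    def test_zero_variance_rejected(self):
        frame = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="zero-variance"):
            domain_correlations(frame)

    def test_reliability_definition(self):
        psd = np.array([0.4, 0.5, 0.3])
        assert marginal_reliability(psd) == pytest.approx(1 - np.mean(psd**2))


def test_loadings_preserve_slope_order(recovery_calib):
    slopes = [recovery_calib.items[i].a for i in recovery_calib.item_order]
    lams = [slope_to_loading(a) for a in slopes]
    assert np.argsort(slopes).tolist() == np.argsort(lams).tolist()
    assert all(0 < l < 1 for l in lams)
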