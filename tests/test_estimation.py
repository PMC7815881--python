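"""Post-stratified estimation, panel averaging, ranges, classification."""

import math

import numpy as np
import pandas as pd
import pytest

import foreststab as fs
from foreststab.estimation import Z95, classify

from conftest import quiet_config


def _records(values, strata=None, plot_ids=None, **extra):
    n = len(values)
    df = pd.DataFrame({
        "plot_id": plot_ids or [f"p{i}" for i in range(n)],
        "stratum_id": strata or ["s0"] * n,
        "fsi": values,
    })
    for k, v in extra.items():
        df[k] = v
    return df


class TestPoststratified:
    def test_single_stratum_collapses_to_sample_mean(self):
        y = [0.1, -0.2, 0.4, 0.3, -0.1]
        est = fs.poststratified_estimate(
            _records(y), fs.StratificationScheme.single().__class__(
                weights={"s0": 1.0}))
        assert est["mean"] == pytest.approx(np.mean(y), rel=1e-12)
        assert est["variance"] == pytest.approx(np.var(y, ddof=1) / len(y), rel=1e-12)

    def test_two_equal_strata(self):
        df = _records([1.0, 1.0, 3.0, 3.0], strata=["a", "a", "b", "b"])
        est = fs.poststratified_estimate(
            df, fs.StratificationScheme(weights={"a": 0.5, "b": 0.5}))
        assert est["mean"] == pytest.approx(2.0)

    def test_unknown_stratum_errors_with_offenders(self):
        df = _records([1.0, 2.0], strata=["a", "zz"])
        with pytest.raises(ValueError, match="zz"):
            fs.poststratified_estimate(
                df, fs.StratificationScheme(weights={"a": 1.0}))

    def test_singleton_stratum_collapsed_and_flagged(self):
        df = _records([1.0, 2.0, 3.0, 9.0], strata=["a", "a", "a", "b"])
        est = fs.poststratified_estimate(
            df, fs.StratificationScheme(weights={"a": 0.9, "b": 0.1}))
        assert any("collapsed" in f for f in est["flags"])
        assert est["mean"] == pytest.approx(np.mean([1, 2, 3, 9]))  # merged

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            fs.StratificationScheme(weights={"a": 0.5, "b": 0.4})

    def test_covariance_carried_for_ratio(self):
        rng = np.random.default_rng(0)
        rd = rng.uniform(0.2, 0.8, 40)
        y = -0.01 * rd + rng.normal(0, 0.001, 40)
        df = _records(list(y), rd_t1=rd)
        est = fs.poststratified_estimate(
            df, fs.StratificationScheme(weights={"s0": 1.0}), aux_col="rd_t1")
        n = len(y)
        assert est["covariance"] == pytest.approx(
            float(np.cov(y, rd, ddof=1)[0, 1]) / n, rel=1e-12)


class TestMovingAverage:
    def test_single_panel_identity(self):
        p = {"mean": 0.3, "variance": 0.04, "n_plots": 10}
        est = fs.moving_average_panels([p])
        assert est["mean"] == 0.3 and est["variance"] == 0.04

    def test_equal_weight_combination(self):
        panels = [{"mean": m, "variance": 0.09, "n_plots": 5} for m in (-1, 0, 1)]
        est = fs.moving_average_panels(panels)
        assert est["mean"] == pytest.approx(0.0)
        assert est["variance"] == pytest.approx(0.09 / 3)

    def test_eight_panels_variance_shrinks(self):
        panels = [{"mean": 0.1, "variance": 0.64, "n_plots": 5}] * 8
        est = fs.moving_average_panels(panels)
        assert est["variance"] == pytest.approx(8 * 0.64 / 64)
        assert est["variance"] < 0.64  # narrower than any single panel

    def test_zero_panels_rejected(self):
        with pytest.raises(ValueError):
            fs.moving_average_panels([])


class TestClassification:
    def test_trichotomy_exhaustive_exclusive(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            m, sd = float(rng.normal(0, 1)), float(rng.uniform(0.01, 2))
            ci = (m - Z95 * sd, m + Z95 * sd)
            c = classify(ci)
            assert c in {"expanding", "declining", "stable"}
            assert (c == "declining") == (ci[1] < 0)
            assert (c == "expanding") == (ci[0] > 0)
            assert (c == "stable") == (ci[0] <= 0 <= ci[1])


class TestDefineRange:
    def test_range_is_detected_subsections(self):
        df = pd.DataFrame({
            "species": [202, 202, 202, 108],
            "rd_t1": [0.1, 0.0, 0.0, 0.2],
            "rd_t2": [0.1, 0.0, 0.1, 0.2],
            "ecoregion_subsection": ["A", "B", "C", "A"],
        })
        r = fs.define_range(df)
        assert r[202] == {"A", "C"}  # B has no detection at either census
        assert r[108] == {"A"}

    def test_undetected_species_estimation_refuses(self):
        df = pd.DataFrame({
            "plot_id": ["p0", "p1"], "species": [202, 202],
            "rd_t1": [0.0, 0.0], "rd_t2": [0.0, 0.0],
            "fsi": [0.0, 0.0], "delta_t": [10.0, 10.0],
            "panel_year": [2015, 2015], "stratum_id": ["s0", "s0"],
            "ecoregion_subsection": ["A", "B"],
        })
        with pytest.raises(ValueError, match="never detected"):
            fs.grouped_estimates(
                df, fs.StratificationScheme(weights={"s0": 1.0}))


class TestGroupedEstimates:
    def _landscape_records(self, seed=6, n=150, **kw):
        cen, truth = fs.generate_landscape(quiet_config(seed, n, **kw))
        pairs, _ = fs.filter_change_analysis(cen)
        a = {i: truth.frontier[i][0] for i in range(3)}
        r = {i: truth.frontier[i][1] for i in range(3)}
        model = fs.SizeDensityModel.from_parameters(a, r)
        rec = fs.change_records(pairs, model)
        scheme = fs.StratificationScheme(weights=truth.stratum_weights)
        return rec, scheme, truth

    def test_all_zero_landscape_all_stable(self):
        rec, scheme, _ = self._landscape_records()
        for e in fs.grouped_estimates(rec, scheme):
            assert e.classification == "stable"
            assert e.mean_fsi == pytest.approx(0.0, abs=1e-15)

    def test_deterministic_ordering_and_grouping(self):
        rec, scheme, _ = self._landscape_records()
        ests = fs.grouped_estimates(rec, scheme,
                                    ("species", "ecoregion_division"))
        keys = [(e.group["species"], e.group["ecoregion_division"]) for e in ests]
        assert keys == sorted(keys)

    def test_percent_fsi_is_ratio_of_means(self):
        rng = np.random.default_rng(9)
        n = 60
        rd = rng.uniform(0.2, 0.8, n)
        y = -0.01 * rd  # exact −1 %/yr for every plot
        df = pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(n)], "species": 202,
            "rd_t1": rd, "rd_t2": rd + 10 * y, "fsi": y, "delta_t": 10.0,
            "panel_year": 2015, "stratum_id": "s0",
            "ecoregion_subsection": "A",
        })
        (est,) = fs.grouped_estimates(
            df, fs.StratificationScheme(weights={"s0": 1.0}))
        assert est.percent_fsi == pytest.approx(-1.0, rel=1e-9)

    def test_coverage_of_poststratified_ci(self):
        """Monte-Carlo: the 95% CI of the post-stratified mean covers the
        generating mean at close to the nominal rate."""
        rng = np.random.default_rng(12)
        weights = {"a": 0.5, "b": 0.3, "c": 0.2}
        scheme = fs.StratificationScheme(weights=weights)
        true_means = {"a": -0.01, "b": 0.0, "c": 0.02}
        truth = sum(w * true_means[s] for s, w in weights.items())
        hits = 0
        reps = 400
        for _ in range(reps):
            strata = rng.choice(list(weights), size=120, p=list(weights.values()))
            y = np.array([true_means[s] for s in strata]) + rng.normal(0, 0.02, 120)
            est = fs.poststratified_estimate(_records(list(y), strata=list(strata)),
                                             scheme)
            half = Z95 * math.sqrt(est["variance"])
            hits += abs(est["mean"] - truth) <= half
        # Binomial(400, .95): 3σ ≈ 0.033
        assert hits / reps == pytest.approx(0.95, abs=0.04)
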