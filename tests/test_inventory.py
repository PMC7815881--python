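"""Inventory I/O, stand summaries, and eligibility filters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import foreststab as fs
from foreststab.inventory import SchemaError, ValidationError

from conftest import dbh_for_ba, make_tree, quiet_config


def _census(plot_id="p1", year=2015, trees=(), **kw):
    return fs.PlotCensus(plot_id=plot_id, census_year=year, forest_type=1,
                         trees=list(trees), **kw)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


class TestSummarizeStand:
    def test_tph_ba_and_mean_size(self):
        trees = [make_tree(dbh_for_ba(0.01), 100.0), make_tree(dbh_for_ba(0.03), 100.0)]
        s = fs.summarize_stand(_census(trees=trees))
        assert s.tph == pytest.approx(200.0)
        assert s.ba_per_ha == pytest.approx(4.0)
        assert s.mean_tree_ba == pytest.approx(0.02)

    def test_basal_area_unit_conversion(self):
        t = make_tree(10.0, 74.97)
        assert t.basal_area == pytest.approx(math.pi * 100 / 40000, rel=1e-12)
        s = fs.summarize_stand(_census(trees=[t]))
        assert s.tph == pytest.approx(74.97)

    def test_dead_and_sub_threshold_stems_excluded(self):
        trees = [make_tree(10.0, 50.0),
                 make_tree(30.0, 50.0, status="dead"),
                 make_tree(2.0, 500.0)]  # below the 2.54 cm threshold
        s = fs.summarize_stand(_census(trees=trees))
        assert s.tph == pytest.approx(50.0)
        assert s.n_stems == 1

    @pytest.mark.parametrize("dbhs, expected", [
        ([10, 20, 30], 0.0),  # symmetric
        ([3, 3, 3, 30], 1.1547),  # g1 = m3/m2^1.5 with n-denominators
    ])
    def test_skewness_population_g1(self, dbhs, expected):
        trees = [make_tree(float(d), 10.0, tree_id=f"t{i}")
                 for i, d in enumerate(dbhs)]
        s = fs.summarize_stand(_census(trees=trees))
        assert s.diameter_skewness == pytest.approx(expected, abs=1e-4)
        # cross-check against scipy's biased estimator
        assert s.diameter_skewness == pytest.approx(
            float(sps.skew(np.array(dbhs, float), bias=True)), rel=1e-12)

    def test_empty_stand_flagged_undefined(self):
        s = fs.summarize_stand(_census())
        assert s.tph == 0.0
        assert s.mean_tree_ba is None
        assert s.diameter_skewness is None

    def test_tph_additive_over_merged_tree_lists(self):
        rng = np.random.default_rng(0)
        a = [make_tree(float(d), float(w), tree_id=f"a{i}")
             for i, (d, w) in enumerate(zip(rng.uniform(5, 50, 8), rng.uniform(1, 40, 8)))]
        b = [make_tree(float(d), float(w), tree_id=f"b{i}")
             for i, (d, w) in enumerate(zip(rng.uniform(5, 50, 5), rng.uniform(1, 40, 5)))]
        s_a, s_b = fs.summarize_stand(_census(trees=a)), fs.summarize_stand(_census(trees=b))
        s_ab = fs.summarize_stand(_census(trees=a + b))
        assert s_ab.tph == pytest.approx(s_a.tph + s_b.tph, rel=1e-12)
        assert s_ab.ba_per_ha == pytest.approx(s_a.ba_per_ha + s_b.ba_per_ha, rel=1e-12)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _write_tables(tmp_path, plot_rows, tree_rows):
    pp, tp = tmp_path / "plots.csv", tmp_path / "trees.csv"
    pd.DataFrame(plot_rows).to_csv(pp, index=False)
    pd.DataFrame(tree_rows).to_csv(tp, index=False)
    return pp, tp


def _plot_row(cn, year, prev="", **kw):
    row = {"CN": cn, "PREV_PLT_CN": prev, "MEASYEAR": year, "FORTYPCD": 1,
           "SITECLCD": 3, "ECODIV": "D0", "ECOSUBCD": "S00", "STRATUM_CN": "ST0",
           "DSTRBCD1": 0, "DSTRBCD2": 0, "DSTRBCD3": 0,
           "TRTCD1": 0, "TRTCD2": 0, "TRTCD3": 0,
           "TRTYR1": 0, "TRTYR2": 0, "TRTYR3": 0}
    row.update(kw)
    return row


class TestReadInventory:
    def test_fia_units_normalized(self, tmp_path):
        # 1-inch DBH and 1 tree/acre become 2.54 cm and 2.4710538 stems/ha
        pp, tp = _write_tables(
            tmp_path,
            [_plot_row("a", 2015)],
            [{"PLT_CN": "a", "CN": "t1", "SPCD": 202, "DIA": 1.0,
              "STATUSCD": 1, "TPA_UNADJ": 1.0}],
        )
        (census,) = fs.read_inventory(pp, tp)
        assert census.trees[0].dbh == pytest.approx(2.54)
        assert census.trees[0].density_factor == pytest.approx(2.4710538)

    def test_pairing_via_previous_plot_key(self, tmp_path):
        pp, tp = _write_tables(
            tmp_path,
            [_plot_row("a", 2005), _plot_row("b", 2015, prev="a"),
             _plot_row("c", 2016, prev="missing")],
            [{"PLT_CN": "a", "CN": "t1", "SPCD": 202, "DIA": 5.0,
              "STATUSCD": 1, "TPA_UNADJ": 10.0}],
        )
        by_id = {c.plot_id: c for c in fs.read_inventory(pp, tp)}
        assert by_id["b"].paired and by_id["b"].delta_t == 10.0
        assert by_id["b"].previous_census is by_id["a"]
        assert not by_id["c"].paired  # dangling key: retained but unpaired

    def test_missing_column_names_it(self, tmp_path):
        pp, tp = _write_tables(
            tmp_path, [_plot_row("a", 2015)],
            [{"PLT_CN": "a", "CN": "t", "SPCD": 202, "DIA": 5.0, "STATUSCD": 1}],
        )
        with pytest.raises(SchemaError, match="TPA_UNADJ"):
            fs.read_inventory(pp, tp)

    def test_nonpositive_interval_rejected(self, tmp_path):
        pp, tp = _write_tables(
            tmp_path,
            [_plot_row("a", 2015), _plot_row("b", 2015, prev="a")],
            [{"PLT_CN": "a", "CN": "t", "SPCD": 202, "DIA": 5.0,
              "STATUSCD": 1, "TPA_UNADJ": 1.0}],
        )
        with pytest.raises(ValidationError, match="non-positive"):
            fs.read_inventory(pp, tp)

    def test_disturbance_code_mapping(self, tmp_path):
        pp, tp = _write_tables(
            tmp_path,
            [_plot_row("a", 2015, DSTRBCD1=30, DSTRBCD2=12, DSTRBCD3=95)],
            [{"PLT_CN": "a", "CN": "t", "SPCD": 202, "DIA": 5.0,
              "STATUSCD": 1, "TPA_UNADJ": 1.0}],
        )
        (census,) = fs.read_inventory(pp, tp)
        assert census.disturbance_flags == {"fire": 1, "insect": 1, "disease": 0}
        assert census.other_disturbance_codes == (95,)

    def test_roundtrip_canonical_dialect(self, tmp_path):
        censuses, _ = fs.generate_landscape(quiet_config(3, 20, treated_fraction=0.3))
        fs.write_inventory(censuses, tmp_path / "p.csv", tmp_path / "t.csv")
        back = fs.read_inventory(tmp_path / "p.csv", tmp_path / "t.csv",
                                 fs.Dialect.canonical())
        orig = {c.plot_id: c for c in censuses}
        assert set(orig) == {c.plot_id for c in back}
        for c in back:
            o = orig[c.plot_id]
            assert (c.census_year, c.forest_type, c.stratum_id) == \
                   (o.census_year, o.forest_type, o.stratum_id)
            assert c.disturbance_flags == o.disturbance_flags
            assert c.treatment_flag == o.treatment_flag
            assert c.paired == o.paired
            got = sorted((t.tree_id, t.species_code) for t in c.trees)
            want = sorted((t.tree_id, t.species_code) for t in o.trees)
            assert got == want
            np.testing.assert_allclose(
                sorted(t.dbh for t in c.trees),
                sorted(t.dbh for t in o.trees), rtol=1e-9)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _paired(plot="p", t1=2005, t2=2015, trees=None, flags=None,
            trt_flag=0, trt_year=None):
    trees = trees if trees is not None else [
        make_tree(float(d), 10.0, tree_id=f"t{i}") for i, d in enumerate((10, 20, 30))]
    first = _census(plot_id=plot + "_1", year=t1, trees=trees)
    return _census(
        plot_id=plot + "_2", year=t2, trees=trees,
        previous_census=first, delta_t=float(t2 - t1),
        disturbance_flags=dict(flags or {}),
        treatment_flag=trt_flag, treatment_year=trt_year,
    )


class TestFilters:
    def test_disturbed_plot_excluded_from_training(self):
        c = _paired(flags={"fire": 1})
        kept, excl = fs.filter_frontier_training([c])
        assert kept == [] and excl[c.plot_id] == "disturbed"

    def test_clean_symmetric_plot_trains(self):
        kept, excl = fs.filter_frontier_training([_paired()])
        assert len(kept) == 1 and excl == {}

    def test_skewed_diameters_excluded(self):
        trees = [make_tree(float(d), 10.0, tree_id=f"t{i}")
                 for i, d in enumerate((3, 3, 3, 30))]  # g1 ≈ 1.155 > 1
        c = _paired(trees=trees)
        _, excl = fs.filter_frontier_training([c])
        assert excl[c.plot_id] == "skewness"

    def test_tiny_stand_cannot_be_screened(self):
        c = _paired(trees=[make_tree(10.0, 5.0)])
        _, excl = fs.filter_frontier_training([c])
        assert excl[c.plot_id] == "too_few_trees"

    def test_recent_treatment_excludes_pair(self):
        c = _paired(trt_flag=1, trt_year=2002)  # 3 years before t1=2005
        kept, excl = fs.filter_change_analysis([c])
        assert kept == [] and excl[c.plot_id] == "treated"

    def test_disturbance_does_not_exclude_pair(self):
        c = _paired(flags={"fire": 1})
        kept, _ = fs.filter_change_analysis([c])
        assert kept == [c]

    def test_old_treatment_retained(self):
        c = _paired(trt_flag=1, trt_year=1995)  # 10 years before t1
        kept, _ = fs.filter_change_analysis([c])
        assert kept == [c]

    def test_filters_idempotent_and_order_independent(self):
        censuses = [
            _paired("a"), _paired("b", flags={"insect": 1}),
            _paired("c", trt_flag=1, trt_year=2003),
        ]
        kept1, _ = fs.filter_frontier_training(censuses)
        kept2, _ = fs.filter_frontier_training(kept1)
        assert [c.plot_id for c in kept1] == [c.plot_id for c in kept2]
        # training ∘ change == change ∘ training on the kept sets
        ab, _ = fs.filter_change_analysis(censuses)
        ba1, _ = fs.filter_frontier_training(ab)
        ab2, _ = fs.filter_change_analysis(kept1)
        assert {c.plot_id for c in ba1} == {c.plot_id for c in ab2}
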