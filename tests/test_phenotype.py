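"""Normalization, clustering, rule engine and T-cell state calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from plexcell.phenotype import (CaseTCellState, CellTypeRule, ClusterProfile,
                                NormalizationParams, RuleTieError, UNASSIGNED,
                                assign_cell_types, classify_cluster,
                                classify_tcell_state, cluster_phenograph,
                                composition, load_rules, normalize,
                                profile_clusters)
from plexcell.synth import default_tissue_spec, generate_cell_table


def _table(values: dict, case_id="t"):
    df = pd.DataFrame(values)
    n = len(df)
    base = pd.DataFrame({
        "cell_id": np.arange(1, n + 1), "case_id": case_id,
        "x_um": np.zeros(n), "y_um": np.zeros(n), "area_um2": np.ones(n),
    })
    return pd.concat([base, df], axis=1)


class TestNormalize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        t = _table({"CD3": rng.exponential(40, 300)})
        out = normalize(t)
        assert abs(out["CD3"].mean()) < 1e-9
        assert abs(out["CD3"].std(ddof=0) - 1) < 1e-9

    def test_constant_column_becomes_zero_with_warning(self):
        t = _table({"CD3": np.full(10, 7.0)})
        with pytest.warns(UserWarning, match="constant"):
            out = normalize(t)
        assert (out["CD3"] == 0).all()

    def test_outlier_clipped_to_percentile(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 1, 500)
        x[0] = 10000.0
        t = _table({"CD3": x})
        # oracle: after clipping at the 99th percentile, the max z-score
        # is that of the clip value
        hi = np.percentile(x, 99.0)
        clipped = np.minimum(x, hi)
        expected_max = (hi - clipped.mean()) / clipped.std()
        out = normalize(t)
        assert out["CD3"].max() == pytest.approx(expected_max, rel=1e-9)

    def test_arcsinh_option(self):
        rng = np.random.default_rng(2)
        t = _table({"CD3": rng.exponential(40, 200)})
        out = normalize(t, params=NormalizationParams(arcsinh_cofactor=5.0))
        assert abs(out["CD3"].mean()) < 1e-9

    def test_needs_two_cells(self):
        with pytest.raises(ValueError, match="2 cells"):
            normalize(_table({"CD3": [1.0]}))


class TestClusterPhenograph:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 1, (200, 5)), rng.normal(10, 1, (200, 5))]
        t = _table({f"m{i}": x[:, i] for i in range(5)})
        labels = cluster_phenograph(t, k=15, seed=0)
        truth = np.r_[np.zeros(200), np.ones(200)]
        assert labels.max() == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_points_single_cluster(self):
        t = _table({"CD3": np.ones(50), "CD8": np.zeros(50)})
        labels = cluster_phenograph(t, k=5, seed=0)
        assert labels.max() == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (150, 4))
        t = _table({f"m{i}": x[:, i] for i in range(4)})
        a = cluster_phenograph(t, k=10, seed=7)
        b = cluster_phenograph(t, k=10, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_k_at_least_n_rejected(self):
        t = _table({"CD3": np.arange(10.0)})
        with pytest.raises(ValueError, match="k"):
            cluster_phenograph(t, k=10)


class TestProfilesAndRules:
    def _profile(self, frac, n=100):
        return ClusterProfile(cluster_id=1, n_cells=n,
                              mean_expr={m: 0.0 for m in frac},
                              frac_positive=frac)

    def test_all_positive_cells_give_frac_one(self):
        t = _table({"CD3": np.full(20, 3.0)})
        profs = profile_clusters(t, np.ones(20, dtype=int))
        assert profs[0].frac_positive["CD3"] == 1.0

    def test_infinite_threshold_gives_zero(self):
        t = _table({"CD3": np.full(20, 3.0)})
        profs = profile_clusters(t, np.ones(20, dtype=int),
                                 thresholds={"CD3": np.inf})
        assert profs[0].frac_positive["CD3"] == 0.0

    def test_tam_rule(self):
        p = self._profile({"CD16": 0.6, "CD68": 0.9, "CD163": 0.8, "CD3": 0.05,
                           "CD45": 0.9})
        assert classify_cluster(p, load_rules()) == "TAM"

    def test_nk_rule(self):
        p = self._profile({"CD45": 0.8, "CD3": 0.1, "GranzymeB": 0.5,
                           "Granulysin": 0.4, "CD20": 0.0})
        assert classify_cluster(p, load_rules()) == "NK"

    def test_inflammatory_monocyte_rule(self):
        p = self._profile({"LYZ": 0.7, "VISTA": 0.6, "CD68": 0.1, "CD163": 0.05,
                           "CD3": 0.0, "CD45": 0.9, "CD20": 0.0, "CD16": 0.2,
                           "GranzymeB": 0.0, "Granulysin": 0.0})
        assert classify_cluster(p, load_rules()) == "InflammatoryMonocyte"

    def test_all_negative_unassigned(self):
        p = self._profile({m: 0.0 for m in
                           ("CD45", "CD3", "CD68", "CD163", "CD16", "LYZ", "VISTA")})
        assert classify_cluster(p, load_rules()) == UNASSIGNED

    def test_exactly_one_third_counts_as_positive(self):
        p = self._profile({"CD45": 1 / 3, "CD3": 0.0, "CD20": 0.0})
        assert classify_cluster(p, load_rules()) == "MonoMac_undefined"

    def test_duplicate_priority_tie_raises(self):
        rules = [
            CellTypeRule("TAM", ("CD68",), (), priority=5),
            CellTypeRule("Histiocyte", ("CD163",), (), priority=5),
        ]
        p = self._profile({"CD68": 0.9, "CD163": 0.9})
        with pytest.raises(RuleTieError):
            classify_cluster(p, rules)

    def test_markers_not_in_rules_ignored(self):
        p1 = self._profile({"CD16": 0.6, "CD68": 0.9, "CD163": 0.8, "CD3": 0.0})
        p2 = self._profile({"CD16": 0.6, "CD68": 0.9, "CD163": 0.8, "CD3": 0.0,
                            "IrrelevantMarker": 1.0})
        rules = load_rules()
        assert classify_cluster(p1, rules) == classify_cluster(p2, rules) == "TAM"

    def test_overlapping_pos_neg_rejected(self):
        with pytest.raises(Exception, match="required and forbidden"):
            CellTypeRule("TAM", ("CD68",), ("CD68",), priority=1)


class TestTCellState:
    def _typed_table(self, n_cd4, n_cd8, n_nk, pd1, tcf7, n_other=0):
        types = (["CD4_T"] * n_cd4 + ["CD8_T"] * n_cd8 + ["NK"] * n_nk
                 + ["TAM"] * n_other)
        n = len(types)
        rng = np.random.default_rng(0)
        df = _table({
            "PD1": np.zeros(n), "TCF7": np.zeros(n),
        })
        df["cell_type"] = types
        cd8 = df["cell_type"] == "CD8_T"
        n8 = int(cd8.sum())
        if n8:
            df.loc[cd8, "PD1"] = np.where(np.arange(n8) < round(pd1 * n8), 2.0, -1.0)
            df.loc[cd8, "TCF7"] = np.where(np.arange(n8) < round(tcf7 * n8), 2.0, -1.0)
        return df

    def test_sparse_infiltrate_is_deserted(self):
        t = self._typed_table(10, 15, 5, pd1=0.9, tcf7=0.0)
        state = classify_tcell_state(t, area_mm2=1.0)
        assert state.state == "Deserted"
        assert state.lymphocyte_density_per_mm2 == 30.0

    def test_boundary_59_vs_60_per_mm2(self):
        t59 = self._typed_table(20, 34, 5, pd1=0.9, tcf7=0.0)
        t60 = self._typed_table(20, 35, 5, pd1=0.9, tcf7=0.0)
        assert classify_tcell_state(t59, 1.0).state == "Deserted"
        assert classify_tcell_state(t60, 1.0).state == "T_ex-acute"

    def test_pd1_high_tcf7_low_is_acute(self):
        t = self._typed_table(50, 100, 50, pd1=0.8, tcf7=0.05)
        assert classify_tcell_state(t, 1.0).state == "T_ex-acute"

    def test_tcf7_present_pd1_low_is_chronic(self):
        t = self._typed_table(50, 100, 50, pd1=0.1, tcf7=0.5)
        assert classify_tcell_state(t, 1.0).state == "T_ex-chronic"

    def test_both_high_is_mixed(self):
        t = self._typed_table(50, 100, 50, pd1=0.5, tcf7=0.5)
        assert classify_tcell_state(t, 1.0).state == "T_ex-mixed"

    def test_no_cd8_with_dense_infiltrate_warns_deserted(self):
        t = self._typed_table(100, 0, 0, pd1=0, tcf7=0)
        with pytest.warns(UserWarning, match="no CD8"):
            state = classify_tcell_state(t, 1.0)
        assert state.state == "Deserted"

    @settings(max_examples=60, deadline=None)
    @given(n_cd8=st.integers(0, 200), pd1=st.floats(0, 1), tcf7=st.floats(0, 1))
    def test_partition_always_exactly_one_state(self, n_cd8, pd1, tcf7):
        t = self._typed_table(30, n_cd8, 10, pd1=pd1, tcf7=tcf7)
        state = classify_tcell_state(t, area_mm2=1.0)
        assert state.state in ("T_ex-acute", "T_ex-chronic", "T_ex-mixed", "Deserted")


class TestComposition:
    def test_even_split(self):
        t = _table({"CD3": np.zeros(100)})
        t["cell_type"] = ["TAM"] * 50 + ["CD8_T"] * 50
        comp = composition(t)
        assert comp == {"TAM": 50.0, "CD8_T": 50.0}

    def test_single_type_is_100(self):
        t = _table({"CD3": np.zeros(10)})
        t["cell_type"] = "NK"
        assert composition(t) == {"NK": 100.0}

    def test_unassigned_excluded_and_sums_to_100(self):
        t = _table({"CD3": np.zeros(90)})
        t["cell_type"] = ["TAM"] * 30 + ["CD8_T"] * 30 + [UNASSIGNED] * 30
        comp = composition(t)
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)
        assert UNASSIGNED not in comp

    def test_no_typed_cells_empty(self):
        t = _table({"CD3": np.zeros(5)})
        t["cell_type"] = UNASSIGNED
        assert composition(t) == {}


class TestEndToEndTyping:
    def test_default_mixture_types_recovered(self):
        spec = default_tissue_spec(n_cells=5000)
        cells, truth, profiles, cmap = _run_chain(spec, seed=1)
        # every named cluster type matches the dominant truth type of its cells
        for cid, tname in cmap.items():
            sub = truth.loc[cells["cluster_id"] == cid, "true_type"]
            dominant = sub.mode()[0]
            if tname != UNASSIGNED:
                assert tname == dominant
            else:
                assert dominant == "Tumor"


def _run_chain(spec, seed):
    table, truth = generate_cell_table(spec, seed)
    normalized = normalize(table)
    labels = cluster_phenograph(normalized, k=30, seed=seed)
    cells, profiles, cmap = assign_cell_types(normalized, labels)
    return cells, truth, profiles, cmap
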