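"""Operator core: group means, deviations, distances, reference function.

The key check is oracle equivalence: a naive per-case, per-partition double
loop (written directly from the operator definitions) must reproduce the
vectorized table transform bit for bit.
"""

import numpy as np
import pandas as pd
import pytest

from warfptml import fusion
from warfptml import pt_operators as pt
from warfptml.pt_operators import F_REF, delta_name, ed_name


@pytest.fixture()
def tiny_means(tiny_table, tiny_scheme):
    return pt.fit_group_means(tiny_table, tiny_scheme)


class TestFitGroupMeans:
    def test_group_means_by_hand(self, tiny_scheme):
        table = pd.DataFrame(
            {
                "surgery_type": ["MVR", "MVR", "AVR"],
                "genotype_CYP2C9": ["*1/*1"] * 3,
                "x1": [2.0, 4.0, 3.0],
                "x2": [0.0, 0.0, 0.0],
                "x3": [1.0, 1.0, 1.0],
                "x4": [0.0, 0.0, 0.0],
                "output_class": ["Within", "Out", "Within"],
            }
        )
        means = pt.fit_group_means(table, tiny_scheme)
        assert means.group_mean("TypeCat", "MVR", "x1") == 3.0
        assert means.group_mean("TypeCat", "AVR", "x1") == 3.0  # single member
        assert means.global_means["x1"] == 3.0  # unweighted over all cases

    def test_every_training_label_present(self, tiny_means, tiny_table):
        for pname, col in [("TypeCat", "surgery_type"), ("PKGeneCat", "genotype_CYP2C9")]:
            assert set(tiny_means.means[pname].index) == set(tiny_table[col].unique())

    def test_missing_label_column_rejected(self, tiny_table, tiny_scheme):
        with pytest.raises(KeyError):
            pt.fit_group_means(tiny_table.drop(columns=["surgery_type"]), tiny_scheme)

    def test_json_round_trip(self, tmp_path, tiny_means):
        path = tmp_path / "means.json"
        tiny_means.to_json(path)
        back = pt.GroupMeanTable.from_json(path)
        for p in tiny_means.means:
            pd.testing.assert_frame_equal(
                back.means[p].sort_index(), tiny_means.means[p].sort_index(),
                check_names=False,
            )
        pd.testing.assert_series_equal(
            back.global_means, tiny_means.global_means, check_names=False
        )


class TestFirstOrder:
    def test_deviation_from_group_mean(self, tiny_scheme):
        table = pd.DataFrame(
            {
                "surgery_type": ["MVR", "MVR"],
                "genotype_CYP2C9": ["*1/*1", "*1/*1"],
                "x1": [2.0, 4.0], "x2": [0.0, 0.0], "x3": [0.0, 0.0], "x4": [0.0, 0.0],
                "output_class": ["Within", "Out"],
            }
        )
        means = pt.fit_group_means(table, tiny_scheme)
        cfg = pt.PTConfig.preset("ma")
        deltas = pt.first_order(table.iloc[1], means, cfg, tiny_scheme)
        assert deltas[delta_name("x1", "TypeCat")] == 1.0  # 4 - mean(2,4)

    def test_alpha_zero_returns_raw_value(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig.preset("raw")
        deltas = pt.first_order(tiny_table.iloc[0], tiny_means, cfg, tiny_scheme)
        assert deltas[delta_name("x1", "TypeCat")] == tiny_table["x1"].iloc[0]

    def test_mean_centering_identity(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig.preset("ma")
        feats = pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)
        for pname, col in tiny_scheme.partitions.items():
            for var in tiny_scheme.continuous_vars:
                sums = feats[delta_name(var, pname)].groupby(tiny_table[col]).sum()
                assert np.abs(sums.to_numpy()).max() < 1e-9

    def test_unseen_label_backs_off_to_global_mean(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig.preset("ma")
        case = tiny_table.iloc[0].copy()
        case["surgery_type"] = "TVR"  # never seen in training
        deltas = pt.first_order(case, tiny_means, cfg, tiny_scheme)
        expected = case["x1"] - tiny_means.global_means["x1"]
        assert deltas[delta_name("x1", "TypeCat")] == pytest.approx(expected)


class TestSecondOrder:
    def test_three_four_five(self):
        cfg = pt.PTConfig.preset("ed")
        assert pt.second_order({"a": 3.0, "b": 4.0}, ["a", "b"], cfg) == pytest.approx(5.0)

    def test_zero_deltas_give_zero(self):
        cfg = pt.PTConfig.preset("ed")
        assert pt.second_order({"a": 0.0, "b": 0.0}, ["a", "b"], cfg) == 0.0

    def test_singleton_group_is_absolute_value(self):
        cfg = pt.PTConfig.preset("ed")
        assert pt.second_order({"a": -2.0}, ["a"], cfg) == pytest.approx(2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pt.second_order({"a": 1.0}, [], pt.PTConfig.preset("ed"))


class TestReferenceFunction:
    def _train(self):
        return pd.DataFrame(
            {
                "surgery_type": ["MVR"] * 4 + ["AVR"] * 2,
                "genotype_CYP2C9": ["*1/*1"] * 6,
                "output_class": ["Within", "Within", "Within", "Out", "Out", "Out"],
                **{v: np.zeros(6) for v in ("x1", "x2", "x3", "x4")},
            }
        )

    def test_joint_prevalence(self, tiny_scheme):
        cfg = pt.PTConfig(f_ref_mode="joint", f_ref_min_group=1)
        case = self._train().iloc[0]
        assert pt.reference_function(self._train(), case, cfg, tiny_scheme) == 0.75

    def test_unseen_label_backs_off_to_global(self, tiny_scheme):
        cfg = pt.PTConfig(f_ref_mode="joint", f_ref_min_group=1)
        case = self._train().iloc[0].copy()
        case["surgery_type"] = "TVR"
        assert pt.reference_function(self._train(), case, cfg, tiny_scheme) == 0.5

    def test_small_cell_backs_off(self, tiny_scheme):
        cfg = pt.PTConfig(f_ref_mode="joint", f_ref_min_group=10)
        case = self._train().iloc[0]
        assert pt.reference_function(self._train(), case, cfg, tiny_scheme) == 0.5

    def test_all_within_gives_one(self, tiny_scheme):
        cfg = pt.PTConfig(f_ref_mode="global")
        train = self._train().assign(output_class="Within")
        assert pt.reference_function(train, train.iloc[0], cfg, tiny_scheme) == 1.0

    def test_empty_train_rejected(self, tiny_scheme):
        with pytest.raises(ValueError):
            pt.reference_function(self._train().iloc[:0], self._train().iloc[0],
                                  pt.PTConfig(), tiny_scheme)


class TestBuildFeatures:
    def test_raw_features_identical_to_inputs(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig.preset("raw")
        feats = pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)
        for var in tiny_scheme.continuous_vars:
            np.testing.assert_array_equal(feats[var], tiny_table[var].astype(float))

    def test_ma_arity_partitions_times_variables(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig.preset("ma")
        feats = pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)
        assert feats.shape[1] == 1 + 2 * 4  # f_ref + |partitions| x |variables|

    def test_ed_arity_and_nonnegativity(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig.preset("ed")
        feats = pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)
        assert feats.shape[1] == 1 + 2 * 2  # f_ref + |partitions| x |groups|
        assert (feats.drop(columns=[F_REF]) >= 0).all().all()

    def test_f_ref_is_probability(self, tiny_table, tiny_scheme, tiny_means):
        for level in ("raw", "ma", "ed"):
            cfg = pt.PTConfig.preset(level)
            feats = pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)
            assert feats[F_REF].between(0, 1).all()

    def test_ed_singleton_groups_equal_abs_ma(self, tiny_table, tiny_means):
        singleton = fusion.PartitionScheme(
            name="tiny",  # same name so the fitted means stay applicable
            partitions={"TypeCat": "surgery_type"},
            variable_groups={v: [v] for v in ("x1", "x2", "x3", "x4")},
            continuous_vars=["x1", "x2", "x3", "x4"],
        )
        ma = pt.build_features(tiny_table, tiny_means, tiny_table,
                               pt.PTConfig.preset("ma"), singleton)
        ed = pt.build_features(tiny_table, tiny_means, tiny_table,
                               pt.PTConfig.preset("ed"), singleton)
        for v in singleton.continuous_vars:
            np.testing.assert_allclose(
                ed[ed_name(v, "TypeCat")], np.abs(ma[delta_name(v, "TypeCat")])
            )

    def test_centering_idempotent(self, tiny_table, tiny_scheme, tiny_means):
        # refitting means on the delta columns yields all-zero group means
        cfg = pt.PTConfig.preset("ma")
        feats = pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)
        delta_cols = [c for c in feats.columns if c != F_REF]
        second = pd.concat(
            [tiny_table[["surgery_type", "genotype_CYP2C9", "output_class"]], feats], axis=1
        )
        scheme2 = fusion.PartitionScheme(
            name="tiny2",
            partitions=dict(tiny_scheme.partitions),
            variable_groups={},
            continuous_vars=delta_cols,
        )
        means2 = pt.fit_group_means(second, scheme2)
        for pname, col in scheme2.partitions.items():
            own = [delta_name(v, pname) for v in ("x1", "x2", "x3", "x4")]
            assert np.abs(means2.means[pname][own].to_numpy()).max() < 1e-9

    def test_scheme_mismatch_rejected(self, tiny_table, tiny_scheme, tiny_means):
        other = fusion.PartitionScheme(
            name="other",
            partitions=dict(tiny_scheme.partitions),
            variable_groups=dict(tiny_scheme.variable_groups),
            continuous_vars=list(tiny_scheme.continuous_vars),
        )
        with pytest.raises(ValueError, match="scheme"):
            pt.build_features(tiny_table, tiny_means, tiny_table,
                              pt.PTConfig.preset("ma"), other)

    def test_non_preset_config_rejected(self, tiny_table, tiny_scheme, tiny_means):
        cfg = pt.PTConfig(alpha=1.0, q=3.0, r=0.5)
        with pytest.raises(ValueError):
            pt.build_features(tiny_table, tiny_means, tiny_table, cfg, tiny_scheme)


class TestOracleEquivalence:
    """Naive double-loop oracle vs vectorized transform on a 30-case fixture."""

    @pytest.fixture()
    def fixture_30(self, tiny_scheme):
        rng = np.random.default_rng(17)
        n = 30
        return pd.DataFrame(
            {
                "surgery_type": rng.choice(["MVR", "AVR", "DVR"], n),
                "genotype_CYP2C9": rng.choice(["*1/*1", "*1/*3"], n, p=[0.8, 0.2]),
                "output_class": rng.choice(["Within", "Out"], n),
                "x1": rng.normal(2, 1, n),
                "x2": rng.normal(0, 3, n),
                "x3": rng.uniform(0, 10, n),
                "x4": rng.normal(-5, 2, n),
            }
        )

    def test_ma_level_bit_identical(self, fixture_30, tiny_scheme):
        means = pt.fit_group_means(fixture_30, tiny_scheme)
        cfg = pt.PTConfig.preset("ma")
        feats = pt.build_features(fixture_30, means, fixture_30, cfg, tiny_scheme)
        for i in range(len(fixture_30)):
            case = fixture_30.iloc[i]
            naive = pt.first_order(case, means, cfg, tiny_scheme)
            for name, val in naive.items():
                assert feats[name].iloc[i] == val  # exact, no tolerance

    def test_ed_level_matches_naive_composition(self, fixture_30, tiny_scheme):
        means = pt.fit_group_means(fixture_30, tiny_scheme)
        ma_cfg = pt.PTConfig.preset("ma")
        ed_cfg = pt.PTConfig.preset("ed")
        feats = pt.build_features(fixture_30, means, fixture_30, ed_cfg, tiny_scheme)
        for i in range(len(fixture_30)):
            deltas = pt.first_order(fixture_30.iloc[i], means, ma_cfg, tiny_scheme)
            for pname in tiny_scheme.partitions:
                for gname, members in tiny_scheme.variable_groups.items():
                    named = {m: deltas[delta_name(m, pname)] for m in members}
                    naive = pt.second_order(named, members, ed_cfg)
                    assert feats[ed_name(gname, pname)].iloc[i] == pytest.approx(
                        naive, rel=1e-12, abs=1e-12
                    )

    def test_f_ref_matches_naive(self, fixture_30, tiny_scheme):
        cfg = pt.PTConfig(f_ref_mode="joint", f_ref_min_group=2)
        means = pt.fit_group_means(fixture_30, tiny_scheme)
        feats = pt.build_features(fixture_30, means, fixture_30,
                                  pt.PTConfig.preset("ma", f_ref_mode="joint",
                                                     f_ref_min_group=2), tiny_scheme)
        for i in range(len(fixture_30)):
            naive = pt.reference_function(fixture_30, fixture_30.iloc[i], cfg, tiny_scheme)
            assert feats[F_REF].iloc[i] == naive
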