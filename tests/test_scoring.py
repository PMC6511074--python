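"""Normalization, metric-score aggregation, ranking, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from sklearn.base import clone

from asmscore import (
    AssemblyScorer,
    DatasetInfo,
    Direction,
    MetricNormalizer,
    NonNormalizableError,
    RawMetricMatrix,
    builtin_registry,
    cluster_profiles,
    metric_score,
    normalize_matrix,
    normalize_vector,
    overall_metric_score,
    rank_assemblers,
)
from asmscore.simulate import PlantedDesign, gen_metric_matrix

from conftest import per_cell_tolerance


def ms_brute_force(raw_by_metric, directions):
    """Direct evaluation of the scoring definition: per metric, min-max
    normalize across assemblers (inverting penalties), then sum per
    assembler. Independent of the pipeline's pandas plumbing."""
    n_asm = len(next(iter(raw_by_metric.values())))
    totals = [0.0] * n_asm
    for mid, values in raw_by_metric.items():
        vmin, vmax = min(values), max(values)
        for k, v in enumerate(values):
            if vmax == vmin:
                n = 0.5
            elif directions[mid] == "higher_better":
                n = (v - vmin) / (vmax - vmin)
            else:
                n = (vmax - v) / (vmax - vmin)
            totals[k] += n
    return totals


finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=12
)


class TestNormalizeVector:
    def test_published_mapping_rate_vector(self):
        v = (77.0, 49.1, 95.7, 56.6, 87.4, 71.1, 34.3, 76.7, 88.0, 89.0)
        expected = (0.70, 0.24, 1.00, 0.36, 0.86, 0.60, 0.00, 0.69, 0.88, 0.89)
        out = normalize_vector(v, Direction.HIGHER_BETTER)
        assert np.abs(out - np.array(expected)).max() <= 0.02

    def test_published_misassembly_vector_inverted(self):
        v = (3378, 216127, 2743, 279, 7329, 5603, 302, 2837, 2022, 5126)
        expected = (0.99, 0.00, 0.99, 1.00, 0.97, 0.98, 1.00, 0.99, 0.99, 0.98)
        out = normalize_vector(v, Direction.LOWER_BETTER)
        assert np.abs(out - np.array(expected)).max() <= 0.02

    @pytest.mark.parametrize("direction", list(Direction))
    def test_constant_vector_is_neutral(self, direction):
        assert normalize_vector([5, 5, 5], direction).tolist() == [0.5, 0.5, 0.5]

    def test_degenerate_value_configurable(self):
        assert normalize_vector([2, 2], "higher_better", degenerate_value=0.0).tolist() == [0.0, 0.0]

    def test_missing_values_pass_through_and_skip_extremes(self):
        out = normalize_vector([1.0, math.nan, 3.0], "higher_better")
        assert math.isnan(out[1])
        assert out[0] == 0.0 and out[2] == 1.0

    def test_all_missing_is_an_error(self):
        with pytest.raises(NonNormalizableError):
            normalize_vector([math.nan, math.nan], "higher_better")

    @given(finite_vectors)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_lower_is_complement_of_higher(self, v):
        hi = normalize_vector(v, Direction.HIGHER_BETTER)
        lo = normalize_vector(v, Direction.LOWER_BETTER)
        if max(v) == min(v):
            assert np.allclose(hi, lo)  # both neutral
        else:
            assert np.allclose(lo, 1.0 - hi, atol=1e-12)

    @given(
        finite_vectors,
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=-1e6, max_value=1e6),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_affine_invariance(self, v, a, b):
        """normalize(a*v + b) == normalize(v) for a > 0 — so z-scoring first
        and then min-max rescaling gives identical output."""
        base = normalize_vector(v, Direction.HIGHER_BETTER)
        shifted = normalize_vector([a * x + b for x in v], Direction.HIGHER_BETTER)
        assert np.allclose(base, shifted, atol=1e-6)

    @given(finite_vectors)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_z_score_then_normalize_is_identity(self, v):
        arr = np.asarray(v)
        sd = arr.std()
        if sd == 0:
            return
        z = (arr - arr.mean()) / sd
        assert np.allclose(
            normalize_vector(v, Direction.HIGHER_BETTER),
            normalize_vector(z, Direction.HIGHER_BETTER),
            atol=1e-9,
        )

    @given(finite_vectors)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_output_bounds_and_extremes(self, v):
        out = normalize_vector(v, Direction.HIGHER_BETTER)
        assert out.min() >= 0.0 and out.max() <= 1.0
        if max(v) > min(v):
            assert out.max() == 1.0 and out.min() == 0.0


class TestNormalizeMatrix:
    def test_reproduces_published_normalized_table(self, registry, table2):
        raw, info, norm_printed, _ = table2
        norm = normalize_matrix(raw, registry, [info])
        wide = norm.pivot("hsa")
        assert wide.shape == (20, 10)
        for mid in norm_printed.index:
            diff = np.abs(
                wide.loc[mid, norm_printed.columns].to_numpy()
                - norm_printed.loc[mid].to_numpy()
            )
            assert diff.max() <= per_cell_tolerance(mid), mid

    def test_single_end_dataset_drops_paired_only_metrics(self, registry, table2):
        raw, _, _, _ = table2
        se = DatasetInfo("hsa", "single_end")
        norm = normalize_matrix(raw, registry, [se])
        assert norm.pivot("hsa").shape == (18, 10)

    def test_assembler_permutation_symmetry(self, registry, table2):
        raw, info, _, _ = table2
        shuffled = RawMetricMatrix(
            raw.data.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        a = normalize_matrix(raw, registry, [info]).pivot("hsa")
        b = normalize_matrix(shuffled, registry, [info]).pivot("hsa")
        pd.testing.assert_frame_equal(a.sort_index(axis=1), b.sort_index(axis=1).loc[a.sort_index(axis=1).index])

    def test_single_assembler_matrix_is_neutral(self, registry):
        m = RawMetricMatrix.from_records([("d", "only", "misassemblies", 42.0)])
        norm = normalize_matrix(m, registry, [DatasetInfo("d")])
        assert norm.get("d", "only", "misassemblies") == 0.5

    def test_empty_matrix_is_an_error(self, registry):
        empty = RawMetricMatrix(
            pd.DataFrame(columns=["dataset", "assembler", "metric", "value"])
        )
        with pytest.raises(ValueError):
            normalize_matrix(empty, registry)


class TestMetricScore:
    def test_published_ms_values(self, registry, table2):
        raw, info, _, ms_printed = table2
        norm = normalize_matrix(raw, registry, [info])
        for assembler, expected in ms_printed.items():
            assert metric_score(norm, "hsa", assembler) == pytest.approx(
                expected, abs=0.06
            )

    def test_all_best_assembler_attains_metric_count(self, registry):
        rows = []
        for mdef in registry:
            sign = 1.0 if mdef.direction is Direction.HIGHER_BETTER else -1.0
            rows += [
                ("d", "best", mdef.metric_id, sign * 10.0),
                ("d", "mid", mdef.metric_id, 0.0),
                ("d", "worst", mdef.metric_id, -sign * 10.0),
            ]
        norm = normalize_matrix(RawMetricMatrix.from_records(rows), registry, [DatasetInfo("d")])
        assert metric_score(norm, "d", "best") == pytest.approx(20.0)
        assert metric_score(norm, "d", "worst") == pytest.approx(0.0)

    def test_hand_computed_three_by_two(self, registry):
        # raws (10,20,30) higher-better and (1,2,3) lower-better: each
        # assembler pairs 0/0.5/1 with its mirror, so every MS is 1.0
        rows = [
            ("d", "a1", "ex90n50", 10), ("d", "a2", "ex90n50", 20), ("d", "a3", "ex90n50", 30),
            ("d", "a1", "misassemblies", 1), ("d", "a2", "misassemblies", 2), ("d", "a3", "misassemblies", 3),
        ]
        norm = normalize_matrix(RawMetricMatrix.from_records(rows), registry, [DatasetInfo("d")])
        for a in ("a1", "a2", "a3"):
            assert metric_score(norm, "d", a) == pytest.approx(1.0)

    def test_missing_cell_policies(self, registry):
        rows = [
            ("d", "a1", "ex90n50", 10.0), ("d", "a2", "ex90n50", 20.0),
            ("d", "a1", "kc_score", float("nan")), ("d", "a2", "kc_score", 0.4),
            ("d", "a1", "misassemblies", 5.0), ("d", "a2", "misassemblies", 1.0),
        ]
        norm = normalize_matrix(RawMetricMatrix.from_records(rows), registry, [DatasetInfo("d")])
        # a1: ex90n50 0, misassemblies 0, kc_score missing
        assert metric_score(norm, "d", "a1", "zero") == pytest.approx(0.0)
        assert metric_score(norm, "d", "a1", "omit") == pytest.approx(0.0)
        # a2 best on everything present
        assert metric_score(norm, "d", "a2", "zero") == pytest.approx(2.5)
        with pytest.raises(ValueError):
            metric_score(norm, "d", "a1", "average")

    def test_agrees_with_brute_force_on_small_instances(self, registry):
        rng = np.random.default_rng(20240917)
        directions = {m.metric_id: m.direction.value for m in registry}
        metric_ids = [m.metric_id for m in registry]
        for _ in range(25):
            n_asm = int(rng.integers(2, 5))
            n_met = int(rng.integers(1, 4))
            chosen = list(rng.choice(metric_ids, size=n_met, replace=False))
            raw_by_metric = {
                mid: [float(x) for x in rng.normal(0, 10, size=n_asm)]
                for mid in chosen
            }
            rows = [
                ("d", f"a{k}", mid, raw_by_metric[mid][k])
                for mid in chosen
                for k in range(n_asm)
            ]
            norm = normalize_matrix(
                RawMetricMatrix.from_records(rows), registry, [DatasetInfo("d")]
            )
            expected = ms_brute_force(
                raw_by_metric, {m: directions[m] for m in chosen}
            )
            for k in range(n_asm):
                assert metric_score(norm, "d", f"a{k}") == pytest.approx(
                    expected[k], abs=1e-12
                )

    def test_self_monotonicity(self, registry):
        """Raising one assembler's raw value on a quality metric never
        lowers that assembler's own normalized score or MS."""
        rng = np.random.default_rng(11)
        base_rows = [
            ("d", f"a{k}", mid, float(rng.normal()))
            for mid in ("ex90n50", "kc_score", "misassemblies")
            for k in range(4)
        ]
        raw = RawMetricMatrix.from_records(base_rows)
        norm0 = normalize_matrix(raw, registry, [DatasetInfo("d")])
        ms0 = metric_score(norm0, "d", "a0")
        for bump in (0.1, 1.0, 10.0):
            data = raw.data.copy()
            sel = (data["assembler"] == "a0") & (data["metric"] == "ex90n50")
            data.loc[sel, "value"] += bump
            norm1 = normalize_matrix(RawMetricMatrix(data), registry, [DatasetInfo("d")])
            assert metric_score(norm1, "d", "a0") >= ms0 - 1e-12
            assert norm1.get("d", "a0", "ex90n50") >= norm0.get("d", "a0", "ex90n50") - 1e-12


class TestOverallMetricScore:
    def test_replicate_group_contributes_its_mean(self):
        """The three published infected-timepoint MS values enter as their
        arithmetic mean: (14.35 + 14.11 + 13.87) / 3."""
        ms = pd.DataFrame(
            {"asm": [14.35, 14.11, 13.87]}, index=["e3h", "e7h", "e23h"]
        )
        datasets = [DatasetInfo(d, replicate_group="ebov") for d in ms.index]
        oms = overall_metric_score(ms, datasets)
        assert oms["asm"] == pytest.approx((14.35 + 14.11 + 13.87) / 3)
        assert oms["asm"] == pytest.approx(14.11, abs=0.001)

    def test_no_groups_is_plain_sum(self):
        ms = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["d1", "d2"])
        oms = overall_metric_score(ms, [DatasetInfo("d1"), DatasetInfo("d2")])
        assert oms["a"] == 3.0 and oms["b"] == 7.0

    def test_group_of_equal_scores_counts_once(self):
        # group of identical MS m plus k ungrouped datasets at m -> (k+1)*m
        m, k = 7.5, 3
        index = ["g1", "g2", "g3"] + [f"s{i}" for i in range(k)]
        ms = pd.DataFrame({"a": [m] * len(index)}, index=index)
        datasets = [DatasetInfo(d, replicate_group="g") for d in ("g1", "g2", "g3")]
        datasets += [DatasetInfo(f"s{i}") for i in range(k)]
        assert overall_metric_score(ms, datasets)["a"] == pytest.approx((k + 1) * m)

    def test_incomplete_group_uses_available_members(self):
        ms = pd.DataFrame({"a": [10.0, 20.0]}, index=["g1", "g2"])
        datasets = [
            DatasetInfo("g1", replicate_group="g"),
            DatasetInfo("g2", replicate_group="g"),
            DatasetInfo("g3", replicate_group="g"),  # no MS row
        ]
        assert overall_metric_score(ms, datasets)["a"] == pytest.approx(15.0)


class TestRankAssemblers:
    def test_published_overall_ranking(self):
        oms = {
            "Trinity": 95.9, "SPAdes-sc": 95.8, "Trans-ABySS": 94.8,
            "SPAdes-rna": 93.3, "Bridger": 89.3, "SOAPdenovo-Trans": 87.3,
            "Shannon": 74.8, "IDBA-Tran": 73.3, "Oases": 62.6, "BinPacker": 54.1,
        }
        order = rank_assemblers(oms)
        assert order[0] == "Trinity"
        assert order[-1] == "BinPacker"
        assert order == sorted(oms, key=lambda a: -oms[a])

    def test_single_entry(self):
        assert rank_assemblers({"only": 1.0}) == ["only"]

    def test_ties_break_lexicographically(self):
        assert rank_assemblers({"b": 1.0, "a": 1.0, "c": 2.0}) == ["c", "a", "b"]

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            rank_assemblers({})


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        ms = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]},
                          index=["d1", "d2"])
        link, _ = cluster_profiles(ms)
        assert link[0, 2] == 0.0
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_top_split_separates_planted_tiers(self, registry):
        design = PlantedDesign(
            n_datasets=4, n_assemblers=6,
            quality=[10.0, 9.9, 9.8, 0.2, 0.1, 0.0],  # tier gap >> noise
            noise_sd=0.1, seed=5,
        )
        raw, _ = gen_metric_matrix(design)
        scorer = AssemblyScorer(registry=registry, datasets=design.dataset_sheet()).fit(raw)
        link, _ = cluster_profiles(scorer.ms_)
        labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
        by_label = {}
        for aid, lab in zip(scorer.ms_.columns, labels):
            by_label.setdefault(lab, set()).add(aid)
        assert sorted(map(sorted, by_label.values())) == [
            ["asm00", "asm01", "asm02"], ["asm03", "asm04", "asm05"],
        ]

    def test_duplicated_dataset_column_keeps_leaf_order(self):
        rng = np.random.default_rng(3)
        ms = pd.DataFrame(
            rng.uniform(0, 20, size=(3, 5)),
            index=["d1", "d2", "d3"],
            columns=[f"a{k}" for k in range(5)],
        )
        _, order1 = cluster_profiles(ms)
        doubled = pd.concat([ms, ms.set_index(ms.index + "_dup")])
        _, order2 = cluster_profiles(doubled)
        assert order1 == order2

    def test_fewer_than_two_assemblers_is_an_error(self):
        ms = pd.DataFrame({"a": [1.0]}, index=["d"])
        with pytest.raises(ValueError):
            cluster_profiles(ms)


class TestPlantedRankRecovery:
    def test_noise_free_matrix_recovers_planted_order(self, registry):
        design = PlantedDesign(n_datasets=9, n_assemblers=10, noise_sd=0.0, seed=42)
        raw, planted = gen_metric_matrix(design)
        scorer = AssemblyScorer(registry=registry, datasets=design.dataset_sheet()).fit(raw)
        assert scorer.ranking_ == planted

    def test_noise_free_best_assembler_attains_maximum(self, registry):
        design = PlantedDesign(n_datasets=3, n_assemblers=5, noise_sd=0.0, seed=1)
        raw, planted = gen_metric_matrix(design)
        scorer = AssemblyScorer(registry=registry, datasets=design.dataset_sheet()).fit(raw)
        best = planted[0]
        for did in scorer.ms_.index:
            assert scorer.ms_.loc[did, best] == pytest.approx(
                float(scorer.max_possible_[did])
            )

    def test_ms_bounds_hold_under_random_raws(self, registry):
        design = PlantedDesign(n_datasets=5, n_assemblers=8, noise_sd=2.0, seed=9)
        raw, _ = gen_metric_matrix(design)
        scorer = AssemblyScorer(registry=registry, datasets=design.dataset_sheet()).fit(raw)
        for did in scorer.ms_.index:
            col = scorer.ms_.loc[did]
            assert (col >= -1e-9).all()
            assert (col <= float(scorer.max_possible_[did]) + 1e-9).all()


class TestEstimatorSurface:
    def test_normalizer_fit_transform_matches_function(self, registry, table2):
        raw, info, _, _ = table2
        est = MetricNormalizer(registry=registry, datasets=[info])
        out = est.fit(raw).transform(raw)
        ref = normalize_matrix(raw, registry, [info])
        pd.testing.assert_frame_equal(
            out.data.sort_values(["metric", "assembler"]).reset_index(drop=True),
            ref.data.sort_values(["metric", "assembler"]).reset_index(drop=True),
        )

    def test_estimators_are_cloneable_with_params(self, registry):
        scorer = AssemblyScorer(registry=registry, missing_policy="omit")
        cloned = clone(scorer)
        assert cloned.get_params()["missing_policy"] == "omit"
        cloned.set_params(degenerate_value=0.0)
        assert cloned.degenerate_value == 0.0

    def test_scorer_exposes_fitted_attributes(self, registry, table2):
        raw, info, _, ms_printed = table2
        scorer = AssemblyScorer(registry=registry, datasets=[info]).fit(raw)
        assert scorer.max_possible_["hsa"] == 20
        assert scorer.oms_["Trans-ABySS"] == pytest.approx(14.24, abs=0.06)
        assert scorer.ranking_[0] == "Trans-ABySS"
        table = scorer.score_table()
        assert table.ms.loc["hsa", "Trinity"] == pytest.approx(12.38, abs=0.06)
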