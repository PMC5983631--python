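"""Modification scan, reduction ratios, clustering, concurrent scenarios."""

import numpy as np
import pandas as pd
import pytest

import floodmet as fm
from floodmet.errors import ParameterError

from conftest import make_chain


def matrix_from(values: np.ndarray, rows, cols, direction="over"):
    idx = pd.Index(rows, name="reaction")
    c = pd.Index(cols, name="metabolite")
    return fm.ReductionMatrix(
        values=pd.DataFrame(values, index=idx, columns=c),
        direction=pd.DataFrame(direction, index=idx, columns=c),
    )


class TestReductionRatio:
    def test_identity_scenario_gives_one(self, soybean_model, baseline_profile):
        scenario = fm.ModificationScenario({})
        for pool in soybean_model.target_pools:
            ratio = fm.reduction_ratio(
                soybean_model, scenario, pool, baseline_profile=baseline_profile
            )
            assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_overexpression_drains_substrate(self, chain_model):
        ratio = fm.reduction_ratio(chain_model, fm.ModificationScenario({"T1": 4.0}), "A")
        assert ratio < 1.0

    def test_consistent_with_direct_auc_quotient(self, chain_model):
        scenario = fm.ModificationScenario({"T1": 4.0})
        base = fm.simulate_profiles(chain_model)
        mod = fm.simulate_profiles(fm.apply_modification(chain_model, scenario))
        expected = fm.accumulation_auc(mod, "A") / fm.accumulation_auc(base, "A")
        assert fm.reduction_ratio(chain_model, scenario, "A") == pytest.approx(expected)


class TestModificationScan:
    def test_full_scan_shape(self, soybean_scan):
        assert soybean_scan.values.shape == (15, 16)
        assert set(soybean_scan.direction.to_numpy().ravel()) <= {"over", "under"}

    def test_cells_match_fresh_reduction_ratio(self, soybean_model, soybean_scan, baseline_profile):
        rng = np.random.default_rng(0)
        folds = {"over": soybean_scan.over_fold, "under": soybean_scan.under_fold}
        for _ in range(20):
            rid = rng.choice(soybean_scan.reactions)
            mid = rng.choice(soybean_scan.metabolites)
            fold = folds[soybean_scan.direction.at[rid, mid]]
            fresh = fm.reduction_ratio(
                soybean_model, fm.ModificationScenario({rid: fold}), mid,
                baseline_profile=baseline_profile,
            )
            assert soybean_scan.values.at[rid, mid] == pytest.approx(fresh, rel=1e-9)

    def test_disconnected_branch_is_unaffected(self):
        # two branches fed by one source; modifying one branch leaves the
        # other branch's metabolite at ratio ~ 1
        config = {
            "pools": [
                {"id": "ROOT", "initial_amount": 100.0, "is_target_fitting": True},
                {"id": "X", "initial_amount": 10.0, "is_target_fitting": True},
                {"id": "Y", "initial_amount": 10.0, "is_target_fitting": True},
            ],
            "reactions": [
                {"id": "SRC", "substrates": [], "products": [["ROOT", 1.0]], "km": {}, "vmax": 50.0},
                {"id": "BX", "substrates": [["ROOT", 1.0]], "products": [["X", 1.0]],
                 "km": {"ROOT": 1e6}, "vmax": 1e4, "modifiable": True, "pathway": "glycolysis"},
                {"id": "BY", "substrates": [["ROOT", 1.0]], "products": [["Y", 1.0]],
                 "km": {"ROOT": 1e6}, "vmax": 1e4, "modifiable": True, "pathway": "tca"},
                {"id": "SX", "substrates": [["X", 1.0]], "products": [], "km": {"X": 10.0}, "vmax": 60.0},
                {"id": "SY", "substrates": [["Y", 1.0]], "products": [], "km": {"Y": 10.0}, "vmax": 60.0},
            ],
        }
        model = fm.build_model(config)
        ratio = fm.reduction_ratio(model, fm.ModificationScenario({"BX": 4.0}), "Y")
        # branch BY sees only the shared-root depletion, a second-order effect
        assert ratio == pytest.approx(1.0, abs=0.15)
        direct = fm.reduction_ratio(model, fm.ModificationScenario({"BX": 4.0}), "X")
        assert abs(direct - 1.0) > abs(ratio - 1.0)

    def test_zero_flux_reaction_ties_to_over(self):
        # modifiable enzyme whose substrate pool is empty and never fed:
        # both folds leave every profile identical, so direction is "over"
        config = {
            "pools": [
                {"id": "DEAD", "initial_amount": 0.0},
                {"id": "B", "initial_amount": 10.0, "is_target_fitting": True},
                {"id": "C", "initial_amount": 1.0, "is_target_fitting": True},
            ],
            "reactions": [
                {"id": "RM", "substrates": [["DEAD", 1.0]], "products": [["B", 1.0]],
                 "km": {"DEAD": 1.0}, "vmax": 5.0, "modifiable": True, "pathway": "tca"},
                {"id": "RB", "substrates": [["B", 1.0]], "products": [["C", 1.0]],
                 "km": {"B": 10.0}, "vmax": 5.0},
            ],
        }
        scan = fm.modification_scan(fm.build_model(config))
        assert scan.values.loc["RM"].to_numpy() == pytest.approx(1.0, abs=1e-9)
        assert (scan.direction.loc["RM"] == "over").all()


class TestClustering:
    def test_recovers_planted_row_blocks(self):
        rng = np.random.default_rng(1)
        patterns = np.array([[0.3] * 8, [1.0] * 8, [0.7] * 4 + [1.2] * 4])
        rows, names = [], []
        for b, pattern in enumerate(patterns):
            for i in range(3):
                rows.append(pattern + rng.normal(0, 0.01, size=8))
                names.append(f"B{b}_{i}")
        matrix = matrix_from(np.abs(np.array(rows)), names, [f"m{j}" for j in range(8)])
        grouping = fm.cluster_groups(matrix, k_enzymes=3, k_metabolites=2)
        parts = {frozenset(v) for v in grouping.enzyme_groups.values()}
        expected = {frozenset(f"B{b}_{i}" for i in range(3)) for b in range(3)}
        assert parts == expected

    def test_block_means_order_labels(self):
        # E1 must be the strongest-reducing (lowest mean ratio) group
        values = np.array([[0.2, 0.2], [0.21, 0.2], [1.0, 1.0], [0.99, 1.01]])
        matrix = matrix_from(values, ["a", "b", "c", "d"], ["m1", "m2"])
        grouping = fm.cluster_groups(matrix, k_enzymes=2, k_metabolites=1)
        assert set(grouping.enzyme_groups["E1"]) == {"a", "b"}
        assert set(grouping.enzyme_groups["E2"]) == {"c", "d"}

    def test_identical_rows_merge_first(self):
        values = np.array([[0.5, 0.5], [0.5, 0.5], [2.0, 3.0]])
        matrix = matrix_from(values, ["a", "b", "c"], ["m1", "m2"])
        grouping = fm.cluster_groups(matrix, k_enzymes=2, k_metabolites=1)
        assert {frozenset(v) for v in grouping.enzyme_groups.values()} == {
            frozenset({"a", "b"}),
            frozenset({"c"}),
        }

    def test_k_equal_to_item_count_gives_singletons(self, soybean_scan):
        grouping = fm.cluster_groups(soybean_scan, k_enzymes=15, k_metabolites=4)
        assert all(len(v) == 1 for v in grouping.enzyme_groups.values())
        assert len(grouping.enzyme_groups) == 15

    def test_k_too_large_rejected(self, soybean_scan):
        with pytest.raises(ParameterError):
            fm.cluster_groups(soybean_scan, k_enzymes=16)

    def test_partition_invariant_under_permutation(self, soybean_scan):
        grouping = fm.cluster_groups(soybean_scan)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(soybean_scan.reactions))
        shuffled = fm.ReductionMatrix(
            values=soybean_scan.values.iloc[perm],
            direction=soybean_scan.direction.iloc[perm],
        )
        regrouped = fm.cluster_groups(shuffled)
        assert {frozenset(v) for v in grouping.enzyme_groups.values()} == {
            frozenset(v) for v in regrouped.enzyme_groups.values()
        }

    def test_covers_every_item_exactly_once(self, soybean_scan):
        grouping = fm.cluster_groups(soybean_scan)
        enz = [r for v in grouping.enzyme_groups.values() for r in v]
        met = [m for v in grouping.metabolite_groups.values() for m in v]
        assert sorted(enz) == sorted(soybean_scan.reactions)
        assert sorted(met) == sorted(soybean_scan.metabolites)


class TestEffectivePairs:
    def test_all_ones_matrix_empty(self):
        matrix = matrix_from(np.ones((2, 3)), ["a", "b"], ["x", "y", "z"])
        assert fm.effective_pairs(matrix) == set()

    def test_single_cell_below_threshold(self):
        values = np.ones((2, 3))
        values[1, 2] = 0.85
        matrix = matrix_from(values, ["a", "b"], ["x", "y", "z"])
        assert fm.effective_pairs(matrix) == {("b", "z")}

    def test_threshold_one_matches_any_reduction(self, chain_model):
        scan = fm.modification_scan(chain_model)
        pairs = fm.effective_pairs(scan, threshold=1.0)
        brute = {
            (r, m)
            for r in scan.reactions
            for m in scan.metabolites
            if scan.values.at[r, m] < 1.0
        }
        assert pairs == brute

    def test_invalid_threshold(self, chain_model):
        scan = fm.modification_scan(chain_model)
        with pytest.raises(ParameterError):
            fm.effective_pairs(scan, threshold=1.5)


class TestConcurrent:
    def test_empty_candidate_set_is_null(self, chain_model):
        report = fm.concurrent_modification(chain_model, {})
        assert report.average_reduction_ratio == pytest.approx(1.0, abs=1e-9)
        assert report.effect == pytest.approx(0.0, abs=1e-9)
        assert report.reduced_set == []

    def test_single_candidate_matches_reduction_ratio(self, chain_model):
        report = fm.concurrent_modification(chain_model, {"T1": 2.0})
        base = fm.simulate_profiles(chain_model)
        for pool in chain_model.target_pools:
            direct = fm.reduction_ratio(
                chain_model, fm.ModificationScenario({"T1": 2.0}), pool,
                baseline_profile=base,
            )
            assert report.ratios[pool] == pytest.approx(direct)

    def test_average_is_mean_over_targets(self, soybean_model):
        report = fm.concurrent_modification(soybean_model, {"R1": 3.2, "R28": 1.8, "R3": 1.6})
        assert len(report.ratios) == 16
        assert report.average_reduction_ratio == pytest.approx(
            np.mean(list(report.ratios.values()))
        )
        assert set(report.reduced_set) == {
            m for m, r in report.ratios.items() if r < 1.0
        }

    def test_concurrent_differs_from_single_product(self, chain_model):
        # the joint scenario is a genuine simulation, not a product of
        # single-modification ratios; only direct simulation is asserted
        report = fm.concurrent_modification(chain_model, {"T1": 4.0, "T2": 4.0})
        base = fm.simulate_profiles(chain_model)
        joint = fm.simulate_profiles(
            fm.apply_modification(
                chain_model, fm.ModificationScenario({"T1": 4.0, "T2": 4.0})
            )
        )
        for pool in "ABC":
            expected = fm.accumulation_auc(joint, pool) / fm.accumulation_auc(base, pool)
            assert report.ratios[pool] == pytest.approx(expected)
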