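import numpy as np
import pandas as pd
import pytest

from gemtailor.comparative_analysis import (
    build_flux_matrix,
    cluster_profiles,
    flux_sum_matrix,
    fold_change,
    model_census,
    occurrence_percentage,
)
from gemtailor.expression_context import ContextKey
from gemtailor.flux_analysis import FluxSolution, fba_min_norm
from gemtailor.gimme_tailoring import ContextGEM
from gemtailor.synthetic_data import generate_toy_gem
from oracles import agglomerate_oracle


def _sol(fluxes):
    return FluxSolution(fluxes=dict(fluxes), objective_value=0.0, status="optimal")


C1, D1 = ContextKey("control", 1), ContextKey("drought", 1)
C2, D2 = ContextKey("control", 2), ContextKey("drought", 2)


class TestBuildFluxMatrix:
    def test_fill_is_tenth_of_min_positive(self):
        solutions = {C1: _sol({"RA": 0.5, "RB": 2.0}), D1: _sol({"RA": 1.0})}
        memberships = {C1: {"RA", "RB"}, D1: {"RA"}}
        matrix = build_flux_matrix(solutions, memberships)
        assert matrix.fill_value == pytest.approx(0.05)
        assert matrix.values.loc[(D1.condition, D1.day), "RB"] == pytest.approx(0.05)
        assert bool(matrix.imputed_mask.loc[(D1.condition, D1.day), "RB"])

    def test_present_everywhere_not_imputed(self):
        solutions = {C1: _sol({"RA": 0.5}), D1: _sol({"RA": 1.0})}
        memberships = {C1: {"RA"}, D1: {"RA"}}
        matrix = build_flux_matrix(solutions, memberships)
        assert not matrix.imputed_mask.values.any()

    def test_exactly_one_imputed_cell(self):
        solutions = {C1: _sol({"RA": 0.5, "RB": 1.0}), D1: _sol({"RA": 1.0})}
        memberships = {C1: {"RA", "RB"}, D1: {"RA"}}
        matrix = build_flux_matrix(solutions, memberships)
        assert int(matrix.imputed_mask.values.sum()) == 1

    def test_zero_flux_of_present_reaction_floored(self):
        solutions = {C1: _sol({"RA": 0.0, "RB": 1.0}), D1: _sol({"RA": 2.0, "RB": 1.0})}
        memberships = {C1: {"RA", "RB"}, D1: {"RA", "RB"}}
        matrix = build_flux_matrix(solutions, memberships)
        assert bool(matrix.floored_mask.loc[(C1.condition, C1.day), "RA"])
        assert matrix.values.loc[(C1.condition, C1.day), "RA"] == matrix.fill_value

    def test_fill_strictly_positive_and_minimal(self, rng):
        fluxes = {f"R{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 5, 8))}
        solutions = {C1: _sol(fluxes), D1: _sol({k: v * 2 for k, v in fluxes.items()})}
        memberships = {C1: set(fluxes), D1: set(list(fluxes)[:5])}
        matrix = build_flux_matrix(solutions, memberships)
        positives = matrix.values.values[~matrix.fill_mask.values]
        assert matrix.fill_value > 0
        assert matrix.fill_value <= positives.min()

    def test_all_zero_errors(self):
        solutions = {C1: _sol({"RA": 0.0})}
        with pytest.raises(ValueError, match="fill"):
            build_flux_matrix(solutions, {C1: {"RA"}})

    def test_magnitudes_used_for_reversed_flux(self):
        solutions = {C1: _sol({"RA": -2.0}), D1: _sol({"RA": 1.0})}
        matrix = build_flux_matrix(solutions, {C1: {"RA"}, D1: {"RA"}})
        assert matrix.values.loc[(C1.condition, C1.day), "RA"] == pytest.approx(2.0)


class TestFoldChange:
    def _matrix(self, control, drought):
        solutions = {C1: _sol(control), D1: _sol(drought)}
        memberships = {C1: set(control), D1: set(drought)}
        return build_flux_matrix(solutions, memberships)

    def test_double_is_one_and_flagged(self):
        table = fold_change(self._matrix({"RA": 2.0}, {"RA": 4.0}))
        assert table.values.at[1, "RA"] == pytest.approx(1.0)
        assert bool(table.flagged.at[1, "RA"])

    def test_equal_is_zero_unflagged(self):
        table = fold_change(self._matrix({"RA": 3.0}, {"RA": 3.0}))
        assert table.values.at[1, "RA"] == pytest.approx(0.0)
        assert not bool(table.flagged.at[1, "RA"])

    def test_imputed_ratio(self):
        # drought lacks RB -> filled with 0.4/10 = 0.04... use exact spec numbers
        matrix = self._matrix({"RA": 0.5, "RB": 0.4}, {"RA": 0.5})
        table = fold_change(matrix)
        assert matrix.fill_value == pytest.approx(0.04)
        assert table.values.at[1, "RB"] == pytest.approx(np.log2(0.04 / 0.4))
        assert bool(table.flagged.at[1, "RB"])
        assert bool(table.imputed.at[1, "RB"])

    def test_antisymmetry_under_condition_swap(self, rng):
        control = {f"R{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 4, 6))}
        drought = {f"R{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 4, 6))}
        matrix = self._matrix(control, drought)
        forward = fold_change(matrix)
        backward = fold_change(matrix, numerator="control", denominator="drought")
        assert np.allclose(forward.values.values, -backward.values.values)

    def test_missing_pair_errors(self):
        solutions = {C1: _sol({"RA": 1.0})}
        matrix = build_flux_matrix(solutions, {C1: {"RA"}})
        with pytest.raises(ValueError, match="pair"):
            fold_change(matrix, days=[1])

    def test_finite_everywhere(self):
        matrix = self._matrix({"RA": 0.0, "RB": 1.0}, {"RA": 5.0})
        table = fold_change(matrix)
        assert np.isfinite(table.values.values).all()


class TestFluxSumMatrix:
    def test_toy1_metabolite_entry(self, toy1):
        sol = fba_min_norm(toy1)
        solutions = {C1: sol, D1: sol}
        models = {C1: toy1, D1: toy1}
        matrix = flux_sum_matrix(solutions, models)
        assert matrix.values.loc[(C1.condition, C1.day), "A_c"] == pytest.approx(10.0, rel=1e-4)
        assert not matrix.imputed_mask.values.any()

    def test_single_reaction_metabolite_tracks_flux_fold_change(self):
        # B is touched only by RA (in) and BIO (out); doubling RA's route
        # doubles B's flux-sum, so the fold-changes coincide
        gem = generate_toy_gem(0, "minimal")
        sol_c = _sol({"EX_A": 4.0, "R1": 4.0, "R2": 0.0, "BIO": 4.0})
        sol_d = _sol({"EX_A": 8.0, "R1": 8.0, "R2": 0.0, "BIO": 8.0})
        fm = build_flux_matrix({C1: sol_c, D1: sol_d},
                               {C1: {"EX_A", "R1", "BIO"}, D1: {"EX_A", "R1", "BIO"}})
        fsm = flux_sum_matrix({C1: sol_c, D1: sol_d}, {C1: gem, D1: gem})
        flux_fc = fold_change(fm).values.at[1, "R1"]
        sum_fc = fold_change(fsm).values.at[1, "B_c"]
        assert sum_fc == pytest.approx(flux_fc, abs=1e-9)


class TestClusterProfiles:
    def test_identical_profiles_grouped(self):
        profiles = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [3, 2, 1]], index=["a", "b", "c"], dtype=float
        )
        out = cluster_profiles(profiles)
        assert out.labels["a"] == out.labels["b"]
        assert out.labels["a"] != out.labels["c"]

    def test_negated_profile_separate(self):
        profiles = pd.DataFrame([[1, 2, 3], [-1, -2, -3]], index=["a", "b"], dtype=float)
        out = cluster_profiles(profiles)
        assert out.labels["a"] != out.labels["b"]

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(12, 7)).cumsum(axis=1)
        items = [f"item{i:02d}" for i in range(12)]
        profiles = pd.DataFrame(X, index=items)
        out = cluster_profiles(profiles, cut_distance=0.5)
        mine = {frozenset(out.members(c)) for c in set(out.labels.values())}
        oracle = agglomerate_oracle({i: X[k] for k, i in enumerate(items)}, 0.5)
        assert mine == oracle

    def test_item_order_invariance(self, rng):
        X = rng.normal(size=(10, 6)).cumsum(axis=1)
        items = [f"i{k}" for k in range(10)]
        profiles = pd.DataFrame(X, index=items)
        base = cluster_profiles(profiles)
        perm = rng.permutation(10)
        shuffled = cluster_profiles(profiles.iloc[perm])
        base_parts = {frozenset(base.members(c)) for c in set(base.labels.values())}
        shuf_parts = {frozenset(shuffled.members(c)) for c in set(shuffled.labels.values())}
        assert base_parts == shuf_parts

    def test_constant_profile_singleton(self):
        profiles = pd.DataFrame(
            [[1, 2, 3], [1, 2, 3.1], [5, 5, 5]], index=["a", "b", "flat"], dtype=float
        )
        out = cluster_profiles(profiles)
        assert out.singletons == ["flat"]
        assert out.members(out.labels["flat"]) == ["flat"]

    def test_labels_ordered_by_size(self, rng):
        X = np.vstack([
            np.tile([1.0, 2.0, 3.0], (3, 1)) + rng.normal(0, 1e-3, (3, 3)),
            [[3.0, 2.0, 1.0]],
        ])
        profiles = pd.DataFrame(X, index=["a", "b", "c", "z"])
        out = cluster_profiles(profiles)
        assert out.labels["a"] == 1  # biggest cluster labelled first
        assert out.labels["z"] == 2

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1, 2]], index=["a"], dtype=float))


def _fake_gem(model, condition, day, reinserted=frozenset()):
    ids = {r.id for r in model.reactions}
    return ContextGEM(
        model=model, context=ContextKey(condition, day),
        kept_reactions=ids, removed_reactions=set(),
        reinserted_reactions=set(reinserted),
        gimme_objective=0.0, biomass_rate=1.0,
    )


class TestOccurrence:
    def test_ratio(self, toy1):
        gem = _fake_gem(toy1, "control", 1)
        reported = ["A_c", "B_c", "unknown1", "unknown2"]
        assert occurrence_percentage(gem, reported, toy1) == pytest.approx(100.0)

    def test_partial_presence(self, toy1):
        sub = toy1.copy()
        sub.reactions = [r for r in sub.reactions if r.id == "EX_A"]
        sub.metabolites = [m for m in sub.metabolites if m.id == "A_c"]
        gem = _fake_gem(sub, "drought", 1)
        assert occurrence_percentage(gem, ["A_c", "B_c"], toy1) == pytest.approx(50.0)

    def test_absent_from_global_excluded(self, toy1):
        gem = _fake_gem(toy1, "control", 1)
        # 10 of 11 reported ids are not in the global model -> denominator 1
        reported = ["A_c"] + [f"ghost{i}" for i in range(10)]
        assert occurrence_percentage(gem, reported, toy1) == pytest.approx(100.0)

    def test_all_excluded_errors(self, toy1):
        gem = _fake_gem(toy1, "control", 1)
        with pytest.raises(ValueError):
            occurrence_percentage(gem, ["ghost"], toy1)


class TestModelCensus:
    def test_identical_gems_no_specific_members(self, toy1):
        gems = [_fake_gem(toy1, "control", 1), _fake_gem(toy1, "drought", 1)]
        tables = model_census(gems)
        row = tables.condition_specific.iloc[0]
        assert row["reactions_only_control"] == 0
        assert row["reactions_only_drought"] == 0
        assert row["reactions_common"] == 4

    def test_counts_match_kept_sizes(self, tailored):
        gems, _ = tailored
        tables = model_census(gems)
        for gem in gems:
            row = tables.totals[
                (tables.totals["condition"] == gem.context.condition)
                & (tables.totals["day"] == gem.context.day)
            ].iloc[0]
            assert row["n_reactions"] == len(gem.kept_reactions)

    def test_planted_drought_only_recovery(self, scenario, tailored):
        gems, _ = tailored
        tables = model_census(gems)
        for day in scenario.truths["late_days"]:
            drought_only = tables.specific_members[(day, "drought")]
            assert set(scenario.truths["drought_only_late_reactions"]) <= drought_only
            # exact match against the realized planted active sets
            truth_c = scenario.truths["active_reactions"][ContextKey("control", day)]
            truth_d = scenario.truths["active_reactions"][ContextKey("drought", day)]
            assert drought_only == set(truth_d) - set(truth_c)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            model_census([])
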