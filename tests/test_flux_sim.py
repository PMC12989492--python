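"""GPR activity, expression-scaled bounds and the two-stage LP."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from lentiflux.flux_sim import (
    FluxProblem,
    FluxSolverError,
    cohort_activities,
    energy_objective,
    reaction_activity,
    set_expression_bounds,
    simulate_cohort,
    solve_sample_flux,
)
from lentiflux.model_io import MetabolicModel, Reaction, parse_gpr


class TestReactionActivity:
    @pytest.mark.parametrize(
        "rule,expr,expected",
        [
            ("G1 and G2", {"G1": 2, "G2": 3}, 2.0),
            ("G1 or G2", {"G1": 2, "G2": 3}, 5.0),
            ("(G1 and G2) or G3", {"G1": 2, "G2": 3, "G3": 1}, 3.0),
            ("G1", {"G1": 7.5}, 7.5),
            ("G1 and G2", {"G1": 2}, 2.0),  # absent AND-child skipped
            ("G1 or G2", {"G2": 4}, 4.0),   # absent OR-child dropped
            ("G1 and G2", {}, None),
            ("", {"G1": 2}, None),
        ],
    )
    def test_min_sum_semantics(self, rule, expr, expected):
        assert reaction_activity(parse_gpr(rule), expr) == expected

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            reaction_activity(parse_gpr("G1"), {"G1": -1.0})

    def test_cohort_activities_flags_unconstrained(self, toy_model, demo_tpm):
        acts = cohort_activities(toy_model, demo_tpm.values)
        assert acts.shape == (26, 14)
        assert acts.loc["EX_glc"].isna().all()
        assert acts.loc["DHCRD2"].notna().all()


def chain_model():
    """EX_A -> A -> B -> C -> out with a 4-unit bottleneck on B->C."""
    return MetabolicModel(
        metabolites=["A", "B", "C"],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -1000, 0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 10),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0, 4),
            Reaction("R3", {"C": -1.0}, 0, 7),
        ],
    )


def indicator(model, rid):
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(rid)] = 1.0
    return c


class TestExpressionBounds:
    def gated_model(self):
        return MetabolicModel(
            metabolites=["A", "B"],
            reactions=[
                Reaction("EX_A", {"A": -1.0}, -1000, 0),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 1000, "", parse_gpr("G1")),
                Reaction("R2", {"A": -1.0, "B": 1.0}, -1000, 1000, "", parse_gpr("G2")),
                Reaction("EX_B", {"B": -1.0}, 0, 1000),
            ],
        )

    def test_zero_activity_blocks_the_reaction(self):
        model = self.gated_model()
        problem = set_expression_bounds(
            model, {"R1": 0.0, "R2": 100.0}, objective=indicator(model, "EX_B")
        )
        i = model.reaction_ids.index("R1")
        assert problem.lb_eff[i] == 0.0 and problem.ub_eff[i] == 0.0

    def test_activity_at_percentile_keeps_default_bounds(self):
        model = self.gated_model()
        problem = set_expression_bounds(
            model, {"R1": 100.0, "R2": 50.0}, objective=indicator(model, "EX_B")
        )
        i1, i2 = model.reaction_ids.index("R1"), model.reaction_ids.index("R2")
        # R1 sits above the 95th percentile -> clipped to 1 -> defaults kept
        assert problem.ub_eff[i1] == pytest.approx(1000.0)
        # reversible R2 has both bounds scaled by the same factor
        assert problem.ub_eff[i2] == pytest.approx(-problem.lb_eff[i2])
        assert problem.ub_eff[i2] < 1000.0

    def test_unconstrained_reactions_keep_defaults(self):
        model = self.gated_model()
        problem = set_expression_bounds(
            model, {"R1": 10.0, "R2": 10.0}, objective=indicator(model, "EX_B")
        )
        i = model.reaction_ids.index("EX_A")
        assert (problem.lb_eff[i], problem.ub_eff[i]) == (-1000.0, 0.0)

    def test_all_zero_activities_raise_naming_sample(self):
        model = self.gated_model()
        with pytest.raises(ValueError, match="s99"):
            set_expression_bounds(
                model,
                {"R1": 0.0, "R2": 0.0},
                objective=indicator(model, "EX_B"),
                sample_id="s99",
            )

    def test_halving_a_gene_never_raises_any_raw_activity(self, toy_model):
        # AND -> min and OR -> sum are both monotone in every gene
        rng = np.random.default_rng(17)
        genes = sorted(toy_model.genes)
        for _ in range(20):
            expr = {g: float(rng.gamma(2.0, 50.0)) for g in genes}
            victim = genes[rng.integers(len(genes))]
            expr2 = dict(expr, **{victim: expr[victim] / 2})
            for rxn in toy_model.reactions:
                before = reaction_activity(rxn.gpr, expr)
                after = reaction_activity(rxn.gpr, expr2)
                if before is not None:
                    assert after <= before + 1e-12

    def test_lowering_bottleneck_gene_never_raises_its_bound(self, toy_model):
        # with the normalizer anchored by the housekeeping enzymes, scaling
        # a branch gene down weakly tightens that branch's effective bound
        genes = sorted(toy_model.genes)
        expr = {g: 100.0 for g in genes}
        expr.update({"GAPDH_toy": 5000.0, "NDUFA_toy": 5000.0})
        j = toy_model.reaction_ids.index("DHCRD2")
        previous = np.inf
        for scale in (1.0, 0.5, 0.25, 0.1, 0.0):
            expr2 = dict(expr, DEGS1_toy=100.0 * scale)
            acts = {
                r.id: reaction_activity(r.gpr, expr2) for r in toy_model.reactions
            }
            ub = set_expression_bounds(toy_model, acts).ub_eff[j]
            assert ub <= previous + 1e-9
            previous = ub


class TestEnergyObjective:
    def test_toy_model_has_nine_objective_reactions(self, toy_model):
        c = energy_objective(toy_model)
        assert int(c.sum()) == 9

    def test_slash_synonym_is_canonicalized(self):
        model = MetabolicModel(
            metabolites=["A", "B"],
            reactions=[
                Reaction("EX_A", {"A": -1.0}, -10, 0),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 10,
                         "Glycolysis/Gluconeogenesis"),
                Reaction("EX_B", {"B": -1.0}, 0, 10),
            ],
        )
        assert energy_objective(model).tolist() == [0.0, 1.0, 0.0]

    def test_no_energy_subsystem_raises(self):
        model = MetabolicModel(
            metabolites=["A"], reactions=[Reaction("EX_A", {"A": -1.0}, -1, 1)]
        )
        with pytest.raises(ValueError, match="energy"):
            energy_objective(model)


def min_total_flux_oracle(model, c, z_star):
    """Independent pFBA oracle: unsplit LP with |v| <= t epigraph variables."""
    n = len(model.reactions)
    S = model.stoichiometric_matrix().toarray()
    m = S.shape[0]
    # variables [v, t]
    A_eq = np.hstack([S, np.zeros((m, n))])
    A_ub = np.vstack(
        [
            np.hstack([np.eye(n), -np.eye(n)]),    # v - t <= 0
            np.hstack([-np.eye(n), -np.eye(n)]),   # -v - t <= 0
            np.hstack([-c, np.zeros(n)])[None],    # c.v >= z*
        ]
    )
    b_ub = np.concatenate([np.zeros(2 * n), [-(z_star - 1e-9 * max(1, abs(z_star)))]])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions] + [
        (0, None)
    ] * n
    obj = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m),
                  bounds=bounds, method="highs")
    assert res.status == 0
    return res.fun


class TestSolveSampleFlux:
    def test_chain_bottleneck_sets_all_fluxes(self):
        model = chain_model()
        problem = FluxProblem.from_default_bounds(
            model, objective=indicator(model, "R2")
        )
        sol = solve_sample_flux(problem)
        assert sol.fluxes["R1"] == pytest.approx(4.0, abs=1e-9)
        assert sol.fluxes["R2"] == pytest.approx(4.0, abs=1e-9)
        assert sol.fluxes["R3"] == pytest.approx(4.0, abs=1e-9)
        assert sol.fluxes["EX_A"] == pytest.approx(-4.0, abs=1e-9)

    def test_all_bounds_zero_gives_zero_flux(self):
        model = chain_model()
        problem = FluxProblem(
            model, np.zeros(4), np.zeros(4), indicator(model, "R2")
        )
        sol = solve_sample_flux(problem)
        assert sol.objective_value == pytest.approx(0.0)
        assert np.allclose(sol.fluxes, 0.0)

    def test_parallel_paths_carry_no_futile_duplication(self):
        model = MetabolicModel(
            metabolites=["A", "B"],
            reactions=[
                Reaction("EX_A", {"A": -1.0}, -1000, 0),
                Reaction("P1", {"A": -1.0, "B": 1.0}, 0, 10),
                Reaction("P2", {"A": -1.0, "B": 1.0}, 0, 10),
                Reaction("SINK", {"B": -1.0}, 0, 5),
            ],
        )
        problem = FluxProblem.from_default_bounds(
            model, objective=indicator(model, "SINK")
        )
        sol = solve_sample_flux(problem)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)
        assert sol.fluxes["P1"] + sol.fluxes["P2"] == pytest.approx(5.0, abs=1e-9)
        # total |v| matches the independent pFBA oracle (no futile cycling)
        total = np.abs(sol.fluxes).sum()
        oracle = min_total_flux_oracle(
            model, indicator(model, "SINK"), sol.objective_value
        )
        assert total == pytest.approx(oracle, abs=1e-6)

    def test_stage2_matches_oracle_on_chain(self):
        model = chain_model()
        c = indicator(model, "R2")
        sol = solve_sample_flux(FluxProblem.from_default_bounds(model, objective=c))
        oracle = min_total_flux_oracle(model, c, sol.objective_value)
        assert np.abs(sol.fluxes).sum() == pytest.approx(oracle, abs=1e-6)

    def test_infeasible_problem_names_the_sample(self):
        model = chain_model()
        lb = np.array([0.0, 5.0, 0.0, 0.0])   # force R1 >= 5
        ub = np.array([0.0, 10.0, 0.0, 0.0])  # but block everything else
        problem = FluxProblem(model, lb, ub, indicator(model, "R2"), sample_id="sX")
        with pytest.raises(FluxSolverError, match="sX"):
            solve_sample_flux(problem)


class TestSimulateCohort:
    def test_one_solution_per_sample_at_steady_state(self, toy_model, demo_fluxes):
        table = demo_fluxes.flux_table
        assert table.shape[1] == 14
        S = toy_model.stoichiometric_matrix()
        assert np.abs(S @ table.to_numpy()).max() <= 1e-6
        assert (demo_fluxes.statuses == "optimal").all()

    def test_identical_tpm_columns_give_identical_fluxes(self, toy_model, demo_tpm):
        dup = pd.concat(
            [demo_tpm.values.iloc[:, [0]], demo_tpm.values.iloc[:, [0]]], axis=1
        )
        dup.columns = ["a", "b"]
        cohort = simulate_cohort(toy_model, dup)
        np.testing.assert_array_equal(
            cohort.flux_table["a"].to_numpy(), cohort.flux_table["b"].to_numpy()
        )

    def test_tpm_rescaling_leaves_fluxes_unchanged(self, toy_model, demo_tpm):
        base = simulate_cohort(toy_model, demo_tpm.values.iloc[:, :2])
        for lam in (0.1, 10.0):
            scaled = simulate_cohort(toy_model, demo_tpm.values.iloc[:, :2] * lam)
            np.testing.assert_allclose(
                scaled.flux_table.to_numpy(),
                base.flux_table.to_numpy(),
                atol=1e-9,
            )

    def test_planted_knockdown_reduces_sentinel_flux(self, demo_tpm, demo_fluxes):
        flux = demo_fluxes.flux_table
        lesion = demo_tpm.group_samples("lesion")
        control = demo_tpm.group_samples("control")
        assert flux.loc["DHCRD2", lesion].mean() < flux.loc["DHCRD2", control].mean()
        assert flux.loc["PSDm_hs", lesion].mean() > flux.loc["PSDm_hs", control].mean()

    def test_collect_mode_flags_failures(self, toy_model, demo_tpm):
        broken = demo_tpm.values.iloc[:, :2].copy()
        broken.iloc[:, 0] = 0.0  # no enzyme evidence at all in sample 1
        cohort = simulate_cohort(toy_model, broken, on_error="collect")
        assert cohort.statuses.iloc[0] == "failed"
        assert cohort.statuses.iloc[1] == "optimal"
        assert list(cohort.failures) == [broken.columns[0]]
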