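"""Model I/O, GPR category algebra, and the solve/FVA contract."""

import cobra
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from merge.core import (
    CATEGORIES,
    InfeasibleProblemError,
    LinearConstraint,
    ModelIntegrityError,
    evaluate_gpr_dependence,
    format_equation,
    fva,
    gpr_category,
    model_census,
    parse_equation,
    read_model_tables,
    read_sbml,
    solve,
    write_model_tables,
    write_sbml,
)
from merge.fixtures import make_toy
from oracles import stoichiometry_matrix, vertex_enumeration_max, linprog_flux


def _random_lp_model(seed, n_rxns=6, n_mets=4):
    rng = np.random.default_rng(seed)
    m = cobra.Model(f"lp{seed}")
    mets = [cobra.Metabolite(f"m{i}[c]", compartment="c") for i in range(n_mets)]
    m.add_metabolites(mets)
    for j in range(n_rxns):
        rxn = cobra.Reaction(f"r{j}")
        m.add_reactions([rxn])
        chosen = rng.choice(n_mets, size=2, replace=False)
        rxn.add_metabolites({mets[chosen[0]]: -1.0, mets[chosen[1]]: 1.0})
        rxn.bounds = (float(rng.choice([-5.0, 0.0])), float(rng.integers(1, 8)))
    # boundary reactions so something can flow
    src = cobra.Reaction("src")
    snk = cobra.Reaction("snk")
    m.add_reactions([src, snk])
    src.add_metabolites({mets[0]: 1.0})
    src.bounds = (0.0, 5.0)
    snk.add_metabolites({mets[-1]: -1.0})
    snk.bounds = (0.0, 10.0)
    return m


class TestModelIO:
    @pytest.mark.parametrize("motif", ["gene_centered", "dual_system"])
    def test_tsv_round_trip(self, motif, tmp_path):
        toy = make_toy(motif, seed=3)
        write_model_tables(toy.model, tmp_path)
        back = read_model_tables(tmp_path / "reactions.tsv", tmp_path / "metabolites.tsv")
        assert len(back.reactions) == len(toy.model.reactions)
        for rxn in toy.model.reactions:
            other = back.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert {m.id: c for m, c in other.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }
            assert sorted(g.id for g in other.genes) == sorted(g.id for g in rxn.genes)
            assert other.annotation.get("reaction_class") == rxn.annotation.get("reaction_class")

    def test_sbml_round_trip(self, tmp_path, dual_system):
        path = tmp_path / "model.xml"
        write_sbml(dual_system.model, path)
        back = read_sbml(path)
        assert model_census(back) == model_census(dual_system.model)
        for rxn in dual_system.model.reactions:
            other = back.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert other.annotation.get("reaction_class") == rxn.annotation.get("reaction_class")

    def test_empty_model_census(self):
        assert model_census(cobra.Model("empty")) == {
            "genes": 0,
            "reactions": 0,
            "unique_metabolites": 0,
            "metabolite_species": 0,
        }

    def test_census_counts(self, dual_system):
        census = model_census(dual_system.model)
        assert census["genes"] == 7
        assert census["reactions"] == 18
        assert census["unique_metabolites"] == 9

    def test_undeclared_metabolite_rejected(self, tmp_path):
        (tmp_path / "reactions.tsv").write_text(
            "id\tequation\tgpr\tlower_bound\tupper_bound\tclass\n"
            "R1\tA[c] -> B[c]\t\t0\t1000\tinternal\n"
        )
        (tmp_path / "metabolites.tsv").write_text("id\tname\tcompartment\nA[c]\tA\tc\n")
        with pytest.raises(ModelIntegrityError, match="B\\[c\\]"):
            read_model_tables(tmp_path / "reactions.tsv", tmp_path / "metabolites.tsv")

    def test_equation_parser_round_trip(self, dual_system):
        for rxn in dual_system.model.reactions:
            stoich, reversible = parse_equation(format_equation(rxn))
            assert stoich == {m.id: c for m, c in rxn.metabolites.items()}
            assert reversible == rxn.reversibility


class TestGPR:
    @pytest.mark.parametrize(
        "rule,cats,expected",
        [
            ("a", {"a": "high"}, {"high_only": True, "depends_on_rare": False}),
            # OR takes the better category
            ("a or b", {"a": "rare", "b": "high"}, {"high_only": True, "depends_on_rare": False}),
            # AND takes the worse category
            ("a and b", {"a": "high", "b": "rare"}, {"high_only": False, "depends_on_rare": True}),
            ("a and b", {"a": "high", "b": "low"}, {"depends_on_low": True, "high_only": False}),
            ("(a and b) or c", {"a": "high", "b": "rare", "c": "moderate"}, {"effective": "moderate"}),
        ],
    )
    def test_dependence_examples(self, rule, cats, expected):
        result = evaluate_gpr_dependence(rule, cats)
        for key, value in expected.items():
            assert result[key] == value

    def test_missing_gene_raises(self):
        with pytest.raises(KeyError, match="gene b"):
            gpr_category("a and b", {"a": "high"})

    @given(
        cats=st.lists(st.sampled_from(CATEGORIES), min_size=2, max_size=5),
        op=st.sampled_from(["and", "or"]),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_operand_order_invariance(self, cats, op, data):
        """Category evaluation is invariant to operand order and duplication."""
        genes = {f"g{i}": c for i, c in enumerate(cats)}
        names = list(genes)
        rule = f" {op} ".join(names)
        perm = data.draw(st.permutations(names))
        rule_perm = f" {op} ".join(perm)
        rule_dup = f" {op} ".join(names + [names[0]])
        assert gpr_category(rule, genes) == gpr_category(rule_perm, genes)
        assert gpr_category(rule, genes) == gpr_category(rule_dup, genes)


class TestSolve:
    def test_chain_objective(self):
        m = cobra.Model("chain")
        a = cobra.Metabolite("A[c]", compartment="c")
        b = cobra.Metabolite("B[c]", compartment="c")
        m.add_metabolites([a, b])
        for rid, sto, bounds in [
            ("EX_A", {a: 1}, (0, 5)),
            ("R", {a: -1, b: 1}, (0, 1000)),
            ("EX_B", {b: -1}, (0, 1000)),
        ]:
            r = cobra.Reaction(rid)
            m.add_reactions([r])
            r.add_metabolites(sto)
            r.bounds = bounds
        fd = solve(m, {"EX_B": 1.0}, "max")
        assert fd.objective_value == pytest.approx(5.0)
        # mass balance of the returned vector
        S, mets, rxns = stoichiometry_matrix(m)
        assert np.abs(S @ fd.fluxes[rxns].to_numpy()).max() < 1e-6

    def test_contradictory_constraints_infeasible(self, gene_centered):
        cons = [
            LinearConstraint({"RX1": 1.0}, lb=1.0, ub=1.0),
            LinearConstraint({"RX1": 1.0}, lb=2.0, ub=2.0),
        ]
        with pytest.raises(InfeasibleProblemError):
            solve(gene_centered.model, {"RX1": 1.0}, "max", extra_constraints=cons)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_network_matches_vertex_enumeration(self, seed):
        m = _random_lp_model(seed)
        fd = solve(m, {"snk": 1.0}, "max")
        oracle = vertex_enumeration_max(m, {"snk": 1.0})
        assert fd.objective_value == pytest.approx(oracle, abs=1e-6)


class TestFVA:
    def test_dead_end_and_chain(self):
        m = cobra.Model("chain")
        a = cobra.Metabolite("A[c]", compartment="c")
        b = cobra.Metabolite("B[c]", compartment="c")
        d = cobra.Metabolite("D[c]", compartment="c")
        m.add_metabolites([a, b, d])
        specs = [
            ("EX_A", {a: 1}, (0, 5)),
            ("R", {a: -1, b: 1}, (0, 1000)),
            ("EX_B", {b: -1}, (0, 1000)),
            ("DEAD", {a: -1, d: 1}, (0, 1000)),  # d has no outlet
        ]
        for rid, sto, bounds in specs:
            r = cobra.Reaction(rid)
            m.add_reactions([r])
            r.add_metabolites(sto)
            r.bounds = bounds
        table = fva(m)
        assert table.loc["DEAD"].tolist() == [0.0, 0.0]
        for rid in ("EX_A", "R", "EX_B"):
            assert table.loc[rid, "minimum"] == pytest.approx(0.0, abs=1e-9)
            assert table.loc[rid, "maximum"] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_per_reaction_lp_oracle(self, seed):
        m = _random_lp_model(seed)
        table = fva(m)
        for rxn in m.reactions:
            lo = linprog_flux(m, {rxn.id: 1.0}, "min")[0]
            hi = linprog_flux(m, {rxn.id: 1.0}, "max")[0]
            assert table.loc[rxn.id, "minimum"] == pytest.approx(lo, abs=1e-6)
            assert table.loc[rxn.id, "maximum"] == pytest.approx(hi, abs=1e-6)

    def test_bounds_contain_random_feasible_points(self, dual_system):
        """Randomized-objective solutions always lie inside the FVA ranges."""
        m = dual_system.model
        table = fva(m)
        rng = np.random.default_rng(0)
        rxns = [r.id for r in m.reactions]
        for _ in range(20):
            coefs = {rid: float(c) for rid, c in zip(rxns, rng.uniform(-1, 1, len(rxns)))}
            fd = solve(m, coefs, "max")
            for rid in rxns:
                assert table.loc[rid, "minimum"] - 1e-6 <= fd[rid] <= table.loc[rid, "maximum"] + 1e-6
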