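"""Flux potential analysis: splitting, coefficients, distances, the LP."""

import cobra
import numpy as np
import pandas as pd
import pytest

from merge.fixtures import make_toy, random_split_network
from merge.fpa import (
    FPAConfig,
    FluxPotential,
    _adjacency,
    default_hub_metabolites,
    expression_coefficients,
    flux_potential,
    merged_stoichiometry,
    metabolic_distance,
    split_irreversible,
)
from oracles import shortest_valid_distances


def _chain_weights(toy, n):
    """Closed-form chain weights: w_i = c_i / (1 + d_i)^n with d_i the
    step count from the terminal target."""
    tpm = toy.tpm
    k = len(toy.meta["chain"])
    out = {}
    for ctx in tpm.columns:
        out[ctx] = sum(
            (tpm.loc[f"g{i}"].max() / tpm.loc[f"g{i}", ctx]) / (1 + (k - i)) ** n
            for i in range(1, k + 1)
        )
    out["super"] = sum(1.0 / (1 + (k - i)) ** n for i in range(1, k + 1))
    return out


class TestSplit:
    def test_counts(self):
        m = cobra.Model("mix")
        mets = [cobra.Metabolite(f"m{i}[c]", compartment="c") for i in range(3)]
        m.add_metabolites(mets)
        bounds = [(-1000, 1000), (-5, 10), (0, 1000), (0, 7), (0, 3)]
        for i, b in enumerate(bounds):
            r = cobra.Reaction(f"r{i}")
            m.add_reactions([r])
            r.add_metabolites({mets[i % 3]: -1, mets[(i + 1) % 3]: 1})
            r.bounds = b
        split, smap = split_irreversible(m)
        assert len(split.reactions) == 7  # 2 reversible -> 4, 3 irreversible
        assert set(smap.twin) == {"r0_f", "r0_r", "r1_f", "r1_r"}

    def test_remerge_recovers_stoichiometry(self, dual_system):
        split, smap = split_irreversible(dual_system.model)
        merged = merged_stoichiometry(split, smap)
        for rxn in dual_system.model.reactions:
            assert merged[rxn.id] == {m.id: c for m, c in rxn.metabolites.items()}

    def test_signed_flux_maps_to_nonnegative_vector(self, dual_system):
        from merge.core import solve
        from oracles import stoichiometry_matrix

        fd = solve(dual_system.model, {"DM_biom": 1.0}, "max")
        split, smap = split_irreversible(dual_system.model)
        vec = pd.Series(0.0, index=[r.id for r in split.reactions])
        for rid, v in fd.fluxes.items():
            if abs(v) < 1e-9:
                continue
            if v > 0:
                vec[smap.forward.get(rid, smap.reverse.get(rid))] = abs(v)
            else:
                vec[smap.reverse[rid]] = abs(v)
        assert (vec >= 0).all()
        S, _, rxns = stoichiometry_matrix(split)
        assert np.abs(S @ vec[rxns].to_numpy()).max() < 1e-6


class TestCoefficients:
    CONTEXTS = ["c0", "c1"]

    def _model(self, gpr):
        m = cobra.Model("coef")
        a = cobra.Metabolite("a[c]", compartment="c")
        m.add_metabolites([a])
        r = cobra.Reaction("R")
        m.add_reactions([r])
        r.add_metabolites({a: 1})
        r.bounds = (0, 1000)
        if gpr:
            r.gene_reaction_rule = gpr
        r.annotation["reaction_class"] = "internal"
        return m

    def test_single_gene_max_context_gets_one(self):
        tpm = pd.DataFrame({"c0": {"g1": 50.0}, "c1": {"g1": 25.0}})
        m = self._model("g1")
        assert expression_coefficients(m, tpm, "c0")["R"] == 1.0
        assert expression_coefficients(m, tpm, "c1")["R"] == 2.0

    def test_isozymes_sum_then_normalize(self):
        # context c0 sums to 40, c1 to 80: c(c0) = 80/40 = 2
        tpm = pd.DataFrame({"c0": {"g1": 10.0, "g2": 30.0}, "c1": {"g1": 50.0, "g2": 30.0}})
        m = self._model("g1 or g2")
        assert expression_coefficients(m, tpm, "c0")["R"] == pytest.approx(2.0)
        assert expression_coefficients(m, tpm, "c1")["R"] == pytest.approx(1.0)

    def test_complex_takes_worst_subunit(self):
        # per-protein coefficients 1.5 and 4 -> complex coefficient 4
        tpm = pd.DataFrame({"c0": {"g1": 20.0, "g2": 10.0}, "c1": {"g1": 30.0, "g2": 40.0}})
        m = self._model("g1 and g2")
        assert expression_coefficients(m, tpm, "c0")["R"] == pytest.approx(4.0)

    def test_zero_expression_capped(self):
        tpm = pd.DataFrame({"c0": {"g1": 0.0}, "c1": {"g1": 10.0}})
        m = self._model("g1")
        assert expression_coefficients(m, tpm, "c0")["R"] == 1e4

    def test_geneless_one_exempt_zero(self):
        m = self._model("")
        tpm = pd.DataFrame({"c0": {"g1": 1.0}, "c1": {"g1": 1.0}})
        assert expression_coefficients(m, tpm, "c0")["R"] == 1.0
        m.reactions.R.annotation["reaction_class"] = "exchange"
        assert expression_coefficients(m, tpm, "c0")["R"] == 0.0

    def test_super_system_is_all_ones(self, chain):
        coefs = expression_coefficients(chain.model, chain.tpm, None)
        for rid in chain.meta["chain"]:
            assert coefs[rid] == 1.0
        assert coefs["EX_in"] == 0.0


class TestDistance:
    def test_adjacent_and_self(self, chain):
        split, smap = split_irreversible(chain.model)
        dm = metabolic_distance(split, hubs=[], twin=smap.twin)
        assert dm.matrix.loc["R1", "R1"] == 0
        assert dm.matrix.loc["R1", "R2"] == 1
        assert dm.matrix.loc["R1", "R3"] == 2

    def test_hub_metabolite_breaks_adjacency(self):
        toy = make_toy("isolated_target", seed=2)
        split, smap = split_irreversible(toy.model)
        dm_hub = metabolic_distance(split, hubs=["atp"], twin=smap.twin)
        dm_all = metabolic_distance(split, hubs=[], twin=smap.twin)
        # with atp as a hub, the far chain is unreachable from the target
        # and sits at the maximum observed distance
        assert dm_all.matrix.loc["RT", "F1"] == 1
        assert dm_hub.matrix.loc["RT", "F1"] == dm_hub.dmax
        assert dm_hub.matrix.loc["RT", "F1"] > 1

    def test_symmetry_diagonal_integers(self):
        for seed in (0, 5, 9):
            split, smap = random_split_network(seed)
            dm = metabolic_distance(split, hubs=[], twin=smap.twin)
            M = dm.matrix.to_numpy()
            assert (M == M.T).all()
            assert (np.diag(M) == 0).all()
            assert np.issubdtype(M.dtype, np.integer)

    def test_matches_exhaustive_oracle(self):
        """Agreement with the exhaustive valid-path oracle is >= 99%
        aggregated over random reversible networks (the loop-correction
        compromise touches under 1% of pairs)."""
        total = agree = 0
        for seed in range(50):
            split, smap = random_split_network(seed, reversible_frac=0.35)
            dm = metabolic_distance(split, hubs=[], twin=smap.twin)
            oracle = shortest_valid_distances(split, smap.twin, _adjacency(split, set()))
            eq = dm.matrix.to_numpy() == oracle.to_numpy()
            total += eq.size
            agree += eq.sum()
        assert agree / total >= 0.99

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_on_loop_free(self, seed):
        split, smap = random_split_network(100 + seed, reversible_frac=0.0)
        dm = metabolic_distance(split, hubs=[], twin=smap.twin)
        oracle = shortest_valid_distances(split, smap.twin, _adjacency(split, set()))
        assert (dm.matrix.to_numpy() == oracle.to_numpy()).all()

    def test_default_hub_list_by_degree(self, dual_system):
        hubs = default_hub_metabolites(dual_system.model, n_hubs=3)
        assert len(hubs) == 3
        # atp/adp/glc are the busiest metabolites of this toy
        assert "glc" in hubs


class TestFluxPotentialLP:
    def test_chain_closed_form(self, chain):
        cfg = FPAConfig(distance_order=1.0, allowance=1.0)
        fp = FluxPotential(chain.model, chain.tpm, config=cfg, hubs=[],
                           background_load=chain.meta["background_load"])
        res = fp.reaction((chain.meta["target"], "fwd"))
        weights = _chain_weights(chain, 1.0)
        for ctx in chain.tpm.columns:
            assert res.fp[ctx] == pytest.approx((1.0 - 0.5) / weights[ctx], abs=1e-9)
        assert res.fp_super == pytest.approx((1.0 - 0.5) / weights["super"], abs=1e-9)

    def test_rfp_bounds_and_super_normalization(self, chain):
        fp = FluxPotential(chain.model, chain.tpm, config=FPAConfig(), hubs=[])
        res = fp.reaction((chain.meta["target"], "fwd"))
        assert ((res.rfp >= 0) & (res.rfp <= 1)).all()

    def test_context_matching_super_gets_rfp_one(self, chain):
        # a context expressing every gene at the cross-context maximum has
        # the super system's coefficients
        tpm = chain.tpm.copy()
        tpm["peak"] = tpm.max(axis=1)
        fp = FluxPotential(chain.model, tpm, config=FPAConfig(), hubs=[])
        res = fp.reaction((chain.meta["target"], "fwd"))
        assert res.rfp["peak"] == pytest.approx(1.0, abs=1e-9)

    def test_high_distance_order_converges_to_target_expression(self):
        toy = make_toy("isolated_target", seed=2)
        fp = FluxPotential(toy.model, toy.tpm, config=FPAConfig(distance_order=12.0),
                           hubs=toy.meta["hubs"])
        res = fp.reaction((toy.meta["target"], "fwd"))
        nge = toy.tpm.loc[toy.meta["gene"]] / toy.tpm.loc[toy.meta["gene"]].max()
        assert (res.rfp - nge).abs().max() <= 1e-6

    def test_monotone_in_coefficients(self, chain):
        """Raising any single reaction's coefficient never raises FP."""
        split, smap = split_irreversible(chain.model)
        cfg = FPAConfig(distance_order=1.0)
        coefs = expression_coefficients(split, chain.tpm, "neuron")
        dm = metabolic_distance(split, hubs=[], twin=smap.twin)
        base, _ = flux_potential(split, "R3", coefs, dm.row("R3"), cfg)
        for rid in chain.meta["chain"]:
            bumped = coefs.copy()
            bumped[rid] *= 3.0
            fp_b, _ = flux_potential(split, "R3", bumped, dm.row("R3"), cfg)
            assert fp_b <= base + 1e-12

    def test_target_outside_network_returns_zero(self, chain):
        split_ids = [r.id for r in split_irreversible(chain.model)[0].reactions]
        networks = {ctx: set() for ctx in chain.tpm.columns}
        fp = FluxPotential(chain.model, chain.tpm, config=FPAConfig(), hubs=[],
                           networks={ctx: set() for ctx in chain.tpm.columns})
        res = fp.reaction((chain.meta["target"], "fwd"))
        assert (res.fp == 0).all()
        assert res.fp_super > 0  # the super system is never network-restricted

    def test_network_blocking_equals_manual_bounds(self, chain):
        """FPA on a restricted network equals FPA on a model whose
        excluded reactions are bound to zero."""
        cfg = FPAConfig(distance_order=1.0)
        split, smap = split_irreversible(chain.model)
        coefs = expression_coefficients(split, chain.tpm, "muscle")
        dm = metabolic_distance(split, hubs=[], twin=smap.twin)
        allowed = {"EX_in", "R1", "R2", "R3", "EX_out"}
        via_network, _ = flux_potential(split, "R3", coefs, dm.row("R3"), cfg, allowed=allowed)
        manual = split.copy()
        for rxn in manual.reactions:
            if rxn.id not in allowed:
                rxn.bounds = (0.0, 0.0)
        via_bounds, _ = flux_potential(manual, "R3", coefs, dm.row("R3"), cfg)
        assert via_network == pytest.approx(via_bounds, abs=1e-9)


@pytest.fixture(scope="module")
def exporters():
    """A metabolite with two alternative exporters."""
    m = cobra.Model("exporters")
    a = cobra.Metabolite("a[c]", compartment="c")
    e1 = cobra.Metabolite("a[e]", compartment="e")
    m.add_metabolites([a, e1])
    specs = [
        ("EX_up", {a: 1}, (0, 1000), "exchange", ""),
        ("PROD", {a: -1, e1: 1}, (0, 1000), "internal", "gp"),
        ("T1", {a: -1}, (0, 1000), "transport", "t1g"),
        ("T2", {a: -1}, (0, 1000), "transport", "t2g"),
        ("EX_e", {e1: -1}, (0, 1000), "exchange", ""),
    ]
    for rid, sto, bounds, cls, gpr in specs:
        r = cobra.Reaction(rid)
        m.add_reactions([r])
        r.add_metabolites(sto)
        r.bounds = bounds
        r.annotation["reaction_class"] = cls
        if gpr:
            r.gene_reaction_rule = gpr
    tpm = pd.DataFrame(
        {"c0": {"gp": 10.0, "t1g": 5.0, "t2g": 40.0}, "c1": {"gp": 20.0, "t1g": 10.0, "t2g": 4.0}}
    )
    return m, tpm


class TestMetaboliteLevel:

    def test_targeting_one_exporter_blocks_the_other(self, exporters):
        m, tpm = exporters
        fp = FluxPotential(m, tpm, config=FPAConfig(distance_order=1.0), hubs=[])
        res = fp.metabolite("a", mode="production", compartment_suffix="c")
        # the chosen drain is the first transport; with T2 blocked, only
        # T1's gene and the upstream reactions set the weights
        assert res.target == "T1"
        assert res.fp_super > 0
        assert ((res.rfp >= 0) & (res.rfp <= 1)).all()

    def test_absent_metabolite_rejected(self, exporters):
        m, tpm = exporters
        fp = FluxPotential(m, tpm, config=FPAConfig(), hubs=[])
        from merge.core import ConfigurationError

        with pytest.raises(ConfigurationError):
            fp.metabolite("nonexistent")

    def test_inserted_demand_is_temporary(self, exporters):
        m, tpm = exporters
        fp = FluxPotential(m, tpm, config=FPAConfig(), hubs=[])
        n_before = len(fp.split.reactions)
        fp.metabolite("a", mode="degradation", compartment_suffix="e")
        assert len(fp.split.reactions) == n_before

    def test_single_producer_profile_matches_reaction_level_ranking(self, chain):
        """Production potential of a single-producer metabolite orders the
        contexts exactly like reaction-level FPA of the producer."""
        fp = FluxPotential(chain.model, chain.tpm, config=FPAConfig(distance_order=1.0), hubs=[])
        res_rxn = fp.reaction(("R3", "fwd"))
        res_met = fp.metabolite("M3", mode="production")
        order_rxn = res_rxn.rfp.sort_values().index.tolist()
        order_met = res_met.rfp.sort_values().index.tolist()
        assert order_rxn == order_met
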