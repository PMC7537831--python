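"""Dual-tissue expansion of a single-compartment model.

The four compartments are the intestinal lumen (L), the intestine (I), one
other tissue (X), and the extracellular space (E) through which I and X
exchange metabolites.  Bacterial food enters through L, is degraded in I,
and transportable nutrients reach X via E.  Internal reactions are
duplicated into I and X — except bacterial-degradation-dependent reactions,
which exist only in I.  Exchange reactions bring nutrients in through L and
secrete by-products through E; a small set of metabolites (oxygen, water,
orthophosphate, protons by default) is freely exchangeable in both
directions through E.

Identifier scheme (stable, see docs/methods.md): cytosolic metabolite
``A[c]`` becomes ``A[c_I]`` / ``A[c_X]``; extracellular ``A[e]`` becomes
``A[l]`` (lumen) and ``A[e]`` (E).  Reaction copies are suffixed ``_I``,
``_X``, ``_IE`` (intestine<->E transport), ``_L`` and ``_E`` (boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra
import pandas as pd

from .core import (
    ConfigurationError,
    FluxDistribution,
    ModelIntegrityError,
    base_metabolite_id,
    reaction_class,
    set_reaction_class,
)

__all__ = [
    "NutrientPolicy",
    "DualTissueModel",
    "build_dual_tissue",
    "apply_nutrient_policy",
    "embed_single_flux",
    "combine_tissue_exchanges",
    "prepare_intestine_model",
]


@dataclass
class NutrientPolicy:
    """Uptake policy keeping the diet bacterially dominated.

    Fractions are of bacterial intake *by mass*; maintenance_flux is the
    ATP-maintenance lower bound (flux units) applied in both I and X.
    """

    side_total_frac: float = 0.02
    side_each_frac: float = 0.005
    storage_total_frac: float = 0.01
    maintenance_flux: float = 10.0
    maintenance_reaction: str = "RCC0005"
    free_exchange_base_ids: tuple[str, ...] = ("o2", "h2o", "pi", "h")

    def __post_init__(self):
        self.free_exchange_base_ids = tuple(self.free_exchange_base_ids)
        for name in ("side_total_frac", "side_each_frac", "storage_total_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be within [0, 1], got {v}")
        if self.maintenance_flux < 0:
            raise ConfigurationError("maintenance_flux must be nonnegative")


@dataclass
class DualTissueModel:
    """The expanded model plus the source->copy bookkeeping."""

    model: cobra.Model
    i_copy: dict[str, str] = field(default_factory=dict)
    x_copy: dict[str, str] = field(default_factory=dict)
    ie_copy: dict[str, str] = field(default_factory=dict)
    lumen_exchange: dict[str, str] = field(default_factory=dict)
    e_exchange: dict[str, str] = field(default_factory=dict)
    bacterial_uptake: str | None = None
    policy: NutrientPolicy | None = None

    def reactions_in(self, compartment: str) -> list[cobra.Reaction]:
        return [
            r
            for r in self.model.reactions
            if r.annotation.get("tissue_compartment") == compartment
        ]

    def copy(self) -> "DualTissueModel":
        return DualTissueModel(
            model=self.model.copy(),
            i_copy=dict(self.i_copy),
            x_copy=dict(self.x_copy),
            ie_copy=dict(self.ie_copy),
            lumen_exchange=dict(self.lumen_exchange),
            e_exchange=dict(self.e_exchange),
            bacterial_uptake=self.bacterial_uptake,
            policy=self.policy,
        )


def _dual_met(model: cobra.Model, cache: dict, source: cobra.Metabolite, suffix: str) -> cobra.Metabolite:
    base = base_metabolite_id(source.id)
    new_id = f"{base}[{suffix}]"
    if new_id not in cache:
        met = cobra.Metabolite(new_id, name=source.name, compartment=suffix)
        if "mass_g_per_mmol" in source.annotation:
            met.annotation["mass_g_per_mmol"] = source.annotation["mass_g_per_mmol"]
        model.add_metabolites([met])
        cache[new_id] = met
    return cache[new_id]


def _copy_reaction(
    model: cobra.Model,
    cache: dict,
    source: cobra.Reaction,
    suffix: str,
    met_suffix_map,
    compartment: str,
) -> cobra.Reaction:
    rxn = cobra.Reaction(f"{source.id}_{suffix}")
    model.add_reactions([rxn])
    rxn.add_metabolites(
        {
            _dual_met(model, cache, met, met_suffix_map(met)): coef
            for met, coef in source.metabolites.items()
        }
    )
    rxn.bounds = source.bounds
    if source.gene_reaction_rule:
        rxn.gene_reaction_rule = source.gene_reaction_rule
    set_reaction_class(rxn, reaction_class(source))
    if "nutrient_role" in source.annotation:
        rxn.annotation["nutrient_role"] = source.annotation["nutrient_role"]
    rxn.annotation["tissue_compartment"] = compartment
    rxn.annotation["source_reaction"] = source.id
    return rxn


def _uptake_capacity(rxn: cobra.Reaction) -> float:
    """Net inflow capacity of a boundary reaction, whichever way it is written."""
    coef = next(iter(rxn.metabolites.values()))
    if coef > 0:
        return max(rxn.upper_bound, 0.0)
    return max(-rxn.lower_bound, 0.0)


def build_dual_tissue(
    model: cobra.Model, free_exchange_base_ids: Iterable[str] = ("o2", "h2o", "pi", "h")
) -> DualTissueModel:
    """Expand a classified single-compartment model into the L/I/X/E form."""
    free_ids = set(free_exchange_base_ids)
    dual_model = cobra.Model(f"{model.id}_dual")
    cache: dict[str, cobra.Metabolite] = {}
    dual = DualTissueModel(model=dual_model)

    def cyto(suffix):
        def mapper(met):
            # extracellular metabolites keep their E identity inside
            # transport copies; cytosolic ones get the tissue suffix
            if met.compartment == "e" or met.id.endswith("[e]"):
                return "e"
            return suffix

        return mapper

    for source in model.reactions:
        cls = reaction_class(source)
        if cls in ("internal", "demand", "sink"):
            dual.i_copy[source.id] = _copy_reaction(
                dual_model, cache, source, "I", lambda m: "c_I", "I"
            ).id
            dual.x_copy[source.id] = _copy_reaction(
                dual_model, cache, source, "X", lambda m: "c_X", "X"
            ).id
        elif cls == "bacterial_degradation":
            dual.i_copy[source.id] = _copy_reaction(
                dual_model, cache, source, "I", lambda m: "l" if m.id.endswith("[e]") else "c_I", "I"
            ).id
        elif cls == "transport":
            dual.i_copy[source.id] = _copy_reaction(
                dual_model,
                cache,
                source,
                "I",
                lambda m: "l" if m.id.endswith("[e]") else "c_I",
                "I",
            ).id
            dual.ie_copy[source.id] = _copy_reaction(
                dual_model,
                cache,
                source,
                "IE",
                lambda m: "e" if m.id.endswith("[e]") else "c_I",
                "I",
            ).id
            dual.x_copy[source.id] = _copy_reaction(
                dual_model,
                cache,
                source,
                "X",
                lambda m: "e" if m.id.endswith("[e]") else "c_X",
                "X",
            ).id
        elif cls == "exchange":
            if len(source.metabolites) != 1:
                raise ModelIntegrityError(f"exchange {source.id} must involve one metabolite")
            met = next(iter(source.metabolites))
            base = base_metabolite_id(met.id)
            cap = _uptake_capacity(source)
            if cap > 0:
                lrxn = cobra.Reaction(f"{source.id}_L")
                dual_model.add_reactions([lrxn])
                lrxn.add_metabolites({_dual_met(dual_model, cache, met, "l"): 1.0})
                lrxn.bounds = (0.0, cap)
                set_reaction_class(lrxn, "exchange")
                lrxn.annotation["tissue_compartment"] = "L"
                lrxn.annotation["source_reaction"] = source.id
                if "nutrient_role" in source.annotation:
                    lrxn.annotation["nutrient_role"] = source.annotation["nutrient_role"]
                dual.lumen_exchange[source.id] = lrxn.id
                if source.annotation.get("nutrient_role") == "bacterial":
                    dual.bacterial_uptake = lrxn.id
            erxn = cobra.Reaction(f"{source.id}_E")
            dual_model.add_reactions([erxn])
            erxn.add_metabolites({_dual_met(dual_model, cache, met, "e"): -1.0})
            erxn.bounds = (-1000.0, 1000.0) if base in free_ids else (0.0, 1000.0)
            set_reaction_class(erxn, "exchange")
            erxn.annotation["tissue_compartment"] = "E"
            erxn.annotation["source_reaction"] = source.id
            dual.e_exchange[source.id] = erxn.id
        else:  # pragma: no cover - class set is closed
            raise ModelIntegrityError(f"reaction {source.id}: unclassified ({cls})")
    return dual


def _exchange_flux_vars(dual: DualTissueModel, rid: str):
    rxn = dual.model.reactions.get_by_id(rid)
    return rxn.forward_variable - rxn.reverse_variable


def _mass_of(dual: DualTissueModel, rid: str) -> float:
    rxn = dual.model.reactions.get_by_id(rid)
    met = next(iter(rxn.metabolites))
    mass = met.annotation.get("mass_g_per_mmol")
    if mass is None:
        raise ConfigurationError(f"metabolite {met.id} has no mass_g_per_mmol annotation")
    return float(mass)


def apply_nutrient_policy(dual: DualTissueModel, policy: NutrientPolicy | None = None) -> DualTissueModel:
    """Add the mass-coupling caps and the maintenance bound, in place.

    Side nutrients:   sum_i m_i v_i <= side_total_frac * m_BAC * v_BAC and
    each individually <= side_each_frac * m_BAC * v_BAC; stored metabolites
    jointly <= storage_total_frac * m_BAC * v_BAC.
    """
    policy = policy or NutrientPolicy()
    model = dual.model
    if dual.bacterial_uptake is None:
        raise ConfigurationError("no bacterial uptake reaction (nutrient_role=bacterial) in model")
    bac_mass = _mass_of(dual, dual.bacterial_uptake)
    v_bac = _exchange_flux_vars(dual, dual.bacterial_uptake)

    def uptakes(role):
        return [
            rid
            for rid in dual.lumen_exchange.values()
            if model.reactions.get_by_id(rid).annotation.get("nutrient_role") == role
        ]

    side = uptakes("side")
    storage = uptakes("storage")
    missing = []
    for rid in side + storage:
        try:
            _mass_of(dual, rid)
        except ConfigurationError:
            missing.append(rid)
    if missing:
        raise ConfigurationError(
            "missing metabolite masses for nutrient uptakes: " + ", ".join(sorted(missing))
        )
    cons = []
    interface = model.problem
    if side:
        expr = sum(_mass_of(dual, rid) * _exchange_flux_vars(dual, rid) for rid in side)
        cons.append(
            interface.Constraint(
                expr - policy.side_total_frac * bac_mass * v_bac, ub=0.0, name="side_total_cap"
            )
        )
        for rid in side:
            cons.append(
                interface.Constraint(
                    _mass_of(dual, rid) * _exchange_flux_vars(dual, rid)
                    - policy.side_each_frac * bac_mass * v_bac,
                    ub=0.0,
                    name=f"side_cap_{rid}",
                )
            )
    if storage:
        expr = sum(_mass_of(dual, rid) * _exchange_flux_vars(dual, rid) for rid in storage)
        cons.append(
            interface.Constraint(
                expr - policy.storage_total_frac * bac_mass * v_bac,
                ub=0.0,
                name="storage_total_cap",
            )
        )
    if cons:
        model.add_cons_vars(cons)
    for suffix in ("I", "X"):
        rid = f"{policy.maintenance_reaction}_{suffix}"
        if rid in model.reactions:
            rxn = model.reactions.get_by_id(rid)
            rxn.lower_bound = max(rxn.lower_bound, policy.maintenance_flux)
    dual.policy = policy
    return dual


def embed_single_flux(dual: DualTissueModel, fluxes: pd.Series) -> pd.Series:
    """Map a single-model flux vector onto the dual model with X silent.

    Internal / degradation fluxes go to the I copies; transport fluxes go
    to the I<->L copy when the transported metabolite is net-imported in
    the source solution and to the I<->E copy when net-exported.
    """
    out = pd.Series(0.0, index=[r.id for r in dual.model.reactions])
    # non-transport reactions map straight onto their I copies
    for rid, v in fluxes.items():
        if rid in dual.i_copy and rid not in dual.ie_copy:
            out[dual.i_copy[rid]] = v
    # boundary reactions: net uptake goes through the L exchange, net
    # secretion through the E exchange
    secreted_bases: set[str] = set()
    for src_id in set(dual.lumen_exchange) | set(dual.e_exchange):
        if src_id not in fluxes.index:
            continue
        v = float(fluxes[src_id])
        if v == 0.0:
            continue
        src = None
        e_id = dual.e_exchange.get(src_id)
        base = base_metabolite_id(
            next(iter(dual.model.reactions.get_by_id(e_id).metabolites)).id
        )
        if v > 0 and src_id in dual.lumen_exchange:
            out[dual.lumen_exchange[src_id]] = v
        else:
            # v < 0 on an uptake-oriented exchange, or a secretion-oriented
            # exchange: route the outflow through E
            out[e_id] = abs(v)
            secreted_bases.add(base)
    # transports: I<->L by default, I<->E when the metabolite leaves the body
    for src_id, v in fluxes.items():
        if src_id not in dual.ie_copy or v == 0.0:
            continue
        irxn = dual.model.reactions.get_by_id(dual.i_copy[src_id])
        bases = {base_metabolite_id(m.id) for m in irxn.metabolites if m.compartment == "l"}
        if bases & secreted_bases:
            out[dual.ie_copy[src_id]] = v
        else:
            out[dual.i_copy[src_id]] = v
    return out


def combine_tissue_exchanges(
    dual: DualTissueModel,
    flux_distributions: Mapping[str, FluxDistribution | pd.Series],
    weights: Mapping[str, float],
) -> pd.Series:
    """Weighted net consumption of each E metabolite by the X side.

    For each non-intestine context the net transport into X is read off
    the X<->E transport fluxes; the weighted sum over contexts gives the
    metabolite demand the intestine must supply through E.  Positive
    values mean the combined tissue consumes the metabolite.
    """
    missing = [c for c in weights if c not in flux_distributions]
    if missing:
        raise ConfigurationError(f"missing flux distributions for contexts: {missing}")
    model = dual.model
    e_mets = sorted(m.id for m in model.metabolites if m.compartment == "e")
    demand = pd.Series(0.0, index=e_mets)
    x_transports = [model.reactions.get_by_id(rid) for rid in dual.x_copy.values()]
    x_transports = [r for r in x_transports if reaction_class(r) == "transport"]
    for context, w in weights.items():
        fd = flux_distributions[context]
        fluxes = fd.fluxes if isinstance(fd, FluxDistribution) else fd
        for rxn in x_transports:
            v = float(fluxes.get(rxn.id, 0.0))
            if v == 0.0:
                continue
            for met, coef in rxn.metabolites.items():
                if met.compartment == "e":
                    # negative coefficient: E metabolite consumed when v > 0
                    demand[met.id] += w * (-coef) * v
    return demand


def prepare_intestine_model(dual: DualTissueModel, demands: pd.Series) -> DualTissueModel:
    """Copy of the dual model configured for the intestine integration:
    X blocked and the combined tissue demands fixed as E exchanges."""
    intestine = dual.copy()
    model = intestine.model
    for rxn in intestine.reactions_in("X"):
        rxn.bounds = (0.0, 0.0)
    for met_id, value in demands.items():
        if abs(value) < 1e-12:
            continue
        met = model.metabolites.get_by_id(met_id)
        td = cobra.Reaction(f"TD_{base_metabolite_id(met_id)}")
        model.add_reactions([td])
        td.add_metabolites({met: -1.0})
        td.bounds = (value, value)
        set_reaction_class(td, "demand")
        td.annotation["tissue_compartment"] = "E"
    return intestine
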