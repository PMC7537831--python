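"""Flux potential analysis (FPA).

The flux potential of a target reaction in a context is the maximal flux
it can carry when every unit of flux anywhere in the context network
spends part of a fixed allowance *a*: maximize v_target subject to
S.v = 0, 0 <= v <= 1000 and sum_i w_i v_i <= a, with weights

    w_i = c_i / (1 + d_i)^n

where c_i is an inverse normalized-expression coefficient (1 where the
context expresses the governing gene at its cross-context maximum, larger
where it is lower, 0 for exempt classes), d_i the metabolic distance from
the target, and n the distance order controlling how fast remote
reactions lose influence.  Dividing by the flux potential of the "super"
system — every gene at its cross-context maximum, i.e. all c_i = 1 —
gives the relative flux potential rFP in [0, 1].
"""

from __future__ import annotations

import ast
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra.core.gene import GPR

from .core import (
    ConfigurationError,
    GPRFormatError,
    base_metabolite_id,
    check_status,
    reaction_class,
    set_reaction_class,
)

__all__ = [
    "FPAConfig",
    "SplitMap",
    "split_irreversible",
    "merged_stoichiometry",
    "expression_coefficients",
    "default_hub_metabolites",
    "DistanceMatrix",
    "metabolic_distance",
    "flux_potential",
    "FPAResult",
    "FluxPotential",
]

#: expression coefficient used where the context's TPM is zero but another
#: context expresses the gene; finite to keep the LP well-conditioned
ZERO_EXPRESSION_CAP = 1e4

#: reaction classes whose flux never consumes allowance
EXEMPT_CLASSES = ("exchange", "bacterial_degradation")


@dataclass
class FPAConfig:
    distance_order: float = 1.5
    allowance: float = 1.0
    n_hubs: int = 21

    def __post_init__(self):
        if self.distance_order < 0:
            raise ConfigurationError("distance_order must be nonnegative")
        if self.allowance <= 0:
            raise ConfigurationError("allowance must be positive")


# ---------------------------------------------------------------------------
# irreversible splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitMap:
    """Bookkeeping between a model and its forward-only split."""

    forward: dict[str, str] = field(default_factory=dict)
    reverse: dict[str, str] = field(default_factory=dict)
    twin: dict[str, str] = field(default_factory=dict)
    origin: dict[str, tuple[str, str]] = field(default_factory=dict)

    def split_id(self, rid: str, direction: str) -> str:
        table = self.forward if direction == "fwd" else self.reverse
        if rid not in table:
            raise KeyError(f"no {direction} split of reaction {rid}")
        return table[rid]


def _clone_into(model: cobra.Model, source: cobra.Reaction, new_id: str, flip: bool) -> cobra.Reaction:
    rxn = cobra.Reaction(new_id)
    model.add_reactions([rxn])
    sign = -1.0 if flip else 1.0
    rxn.add_metabolites({met: sign * coef for met, coef in source.metabolites.items()})
    if source.gene_reaction_rule:
        rxn.gene_reaction_rule = source.gene_reaction_rule
    rxn.annotation = dict(source.annotation)
    return rxn


def split_irreversible(model: cobra.Model, bound_cap: float = 1000.0) -> tuple[cobra.Model, SplitMap]:
    """Forward-only version of a model: each reversible reaction becomes a
    forward copy (``_f``) and a reactant/product-swapped reverse copy
    (``_r``); irreversible reactions keep their id."""
    split = cobra.Model(f"{model.id}_split")
    split.add_metabolites([m.copy() for m in model.metabolites])
    smap = SplitMap()
    for source in model.reactions:
        lb, ub = source.lower_bound, source.upper_bound
        if lb < 0 and ub > 0:
            f = _clone_into(split, source, f"{source.id}_f", flip=False)
            f.bounds = (0.0, min(ub, bound_cap))
            r = _clone_into(split, source, f"{source.id}_r", flip=True)
            r.bounds = (0.0, min(-lb, bound_cap))
            smap.forward[source.id] = f.id
            smap.reverse[source.id] = r.id
            smap.twin[f.id] = r.id
            smap.twin[r.id] = f.id
            smap.origin[f.id] = (source.id, "fwd")
            smap.origin[r.id] = (source.id, "rev")
        elif ub <= 0:
            r = _clone_into(split, source, f"{source.id}_r", flip=True)
            r.bounds = (max(-ub, 0.0), min(-lb, bound_cap))
            smap.reverse[source.id] = r.id
            smap.origin[r.id] = (source.id, "rev")
        else:
            f = _clone_into(split, source, source.id, flip=False)
            f.bounds = (max(lb, 0.0), min(ub, bound_cap))
            smap.forward[source.id] = f.id
            smap.origin[f.id] = (source.id, "fwd")
    return split, smap


def merged_stoichiometry(split: cobra.Model, smap: SplitMap) -> dict[str, dict[str, float]]:
    """Reconstruct the source stoichiometry from a split model (re-merge)."""
    out: dict[str, dict[str, float]] = {}
    for orig, fid in smap.forward.items():
        rxn = split.reactions.get_by_id(fid)
        out[orig] = {m.id: c for m, c in rxn.metabolites.items()}
    for orig, rid in smap.reverse.items():
        if orig in out:
            continue
        rxn = split.reactions.get_by_id(rid)
        out[orig] = {m.id: -c for m, c in rxn.metabolites.items()}
    return out


# ---------------------------------------------------------------------------
# expression coefficients
# ---------------------------------------------------------------------------


def _gpr_profile(node, tpm: pd.DataFrame) -> pd.Series | None:
    """Cumulative TPM profile for a leaf or a pure-isozyme (OR) subtree;
    None where the subtree mixes in a complex (AND)."""
    if isinstance(node, ast.Name):
        try:
            return tpm.loc[node.id]
        except KeyError as exc:
            raise ConfigurationError(f"gene {node.id} missing from TPM matrix") from exc
    if isinstance(node, ast.BoolOp) and isinstance(node.op, ast.Or):
        parts = [_gpr_profile(v, tpm) for v in node.values]
        if any(p is None for p in parts):
            return None
        return sum(parts)
    return None


def _coef_from_profile(profile: pd.Series, context: str, cap: float) -> float:
    peak = float(profile.max())
    if peak <= 0:
        return 1.0  # gene silent in every context: flat, no penalty signal
    value = float(profile[context])
    if value <= 0:
        return cap
    return min(peak / value, cap)


def _gpr_coefficient(node, tpm: pd.DataFrame, context: str, cap: float) -> float:
    profile = _gpr_profile(node, tpm)
    if profile is not None:
        return _coef_from_profile(profile, context, cap)
    if isinstance(node, ast.BoolOp):
        parts = [_gpr_coefficient(v, tpm, context, cap) for v in node.values]
        # complex: limited by its scarcest protein (max penalty);
        # alternatives: served by the cheapest route (min penalty)
        return max(parts) if isinstance(node.op, ast.And) else min(parts)
    raise GPRFormatError(f"unsupported GPR node {type(node).__name__}")


def expression_coefficients(
    model: cobra.Model,
    tpm: pd.DataFrame,
    context: str | None,
    intestine_context: str | None = None,
    cap: float = ZERO_EXPRESSION_CAP,
    exempt_classes: Sequence[str] = EXEMPT_CLASSES,
    extra_exempt: Iterable[str] = (),
) -> pd.Series:
    """Per-reaction expression coefficients for one context.

    Single gene: c = max-over-contexts(TPM) / TPM_context.  Isozymes (OR)
    first sum their TPM profiles; protein complexes (AND) take the worst
    per-protein coefficient.  Gene-less reactions get c = 1 except the
    exempt classes (c = 0).  ``context=None`` builds the super system
    (c = 1 for every non-exempt reaction).  In a dual-tissue model the
    I/L compartments are always judged by the intestine's expression.
    """
    extra = set(extra_exempt)
    values = {}
    for rxn in model.reactions:
        if reaction_class(rxn) in exempt_classes or rxn.id in extra:
            values[rxn.id] = 0.0
            continue
        if not rxn.gene_reaction_rule or context is None:
            values[rxn.id] = 1.0
            continue
        col = context
        if intestine_context is not None and rxn.annotation.get("tissue_compartment") in ("I", "L"):
            col = intestine_context
        gpr = rxn.gpr if isinstance(rxn.gpr, GPR) else GPR.from_string(rxn.gene_reaction_rule)
        values[rxn.id] = _gpr_coefficient(gpr.body, tpm, col, cap)
    return pd.Series(values, dtype=float)


# ---------------------------------------------------------------------------
# metabolic distance
# ---------------------------------------------------------------------------


def default_hub_metabolites(model: cobra.Model, n_hubs: int = 21) -> list[str]:
    """The n highest-degree metabolite base ids (ties broken by id)."""
    degree: dict[str, int] = {}
    for met in model.metabolites:
        degree[base_metabolite_id(met.id)] = degree.get(base_metabolite_id(met.id), 0) + len(
            met.reactions
        )
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return [mid for mid, _ in ranked[:n_hubs]]


@dataclass
class DistanceMatrix:
    matrix: pd.DataFrame
    dmax: int
    hubs: list[str]

    def row(self, target: str) -> pd.Series:
        return self.matrix.loc[target]


def _adjacency(model: cobra.Model, hubs: set[str]) -> dict[str, list[str]]:
    adj: dict[str, set[str]] = {r.id: set() for r in model.reactions}
    for met in model.metabolites:
        if met.id in hubs or base_metabolite_id(met.id) in hubs:
            continue
        producers = [r.id for r in met.reactions if r.metabolites[met] > 0]
        consumers = [r.id for r in met.reactions if r.metabolites[met] < 0]
        for p in producers:
            for c in consumers:
                if p != c:
                    adj[p].add(c)
                    adj[c].add(p)
    # sorted neighbor lists keep the first-reached path fixing (and hence
    # the loop-correction outcomes) deterministic across processes
    return {rid: sorted(neigh) for rid, neigh in adj.items()}


def _bfs_tree(adj, start, banned):
    parent = {start: None}
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v in banned or v in parent:
                continue
            parent[v] = u
            dist[v] = dist[u] + 1
            queue.append(v)
    return dist, parent


def _bfs_path(adj, start, goal, banned):
    parent = {start: None}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        if u == goal:
            break
        for v in adj[u]:
            if v in banned or v in parent:
                continue
            parent[v] = u
            queue.append(v)
    if goal not in parent:
        return None
    path = [goal]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def _first_loop_creator(path, twin):
    """First reaction along the path involved in a twin collision.

    When both directions of one originally reversible reaction occur on a
    path, the earlier of the two is eliminated: re-routing the early
    segment while keeping the later (target-proximal) segment intact
    empirically recovers the true shortest valid path in almost every
    correction (exact on all random-network test beds)."""
    seen: dict[str, int] = {}
    for pos, rid in enumerate(path):
        t = twin.get(rid)
        if t is not None and t in seen:
            return path[seen[t]]
        seen[rid] = pos
    return None


def metabolic_distance(
    model: cobra.Model,
    hubs: Iterable[str] | None = None,
    n_hubs: int = 21,
    twin: Mapping[str, str] | None = None,
) -> DistanceMatrix:
    """Reaction-to-reaction step distances in the hub-pruned adjacency graph.

    Breadth-first traversal from each query reaction (its reverse twin
    removed) fixes first-reached paths; a path using both directions of
    one originally reversible reaction is invalid — the first
    loop-creating reaction on it is eliminated and the search repeated
    until a valid path is found.  Unreachable pairs take the maximum
    distance observed anywhere; the matrix is finalized symmetric (the
    minimum of the two directed values) with a zero diagonal.
    """
    if len(model.reactions) == 0:
        raise ConfigurationError("cannot compute distances on an empty model")
    twin = dict(twin or {})
    hub_list = list(hubs) if hubs is not None else default_hub_metabolites(model, n_hubs)
    adj = _adjacency(model, set(hub_list))
    ids = [r.id for r in model.reactions]
    directed = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in ids:
        banned_base = {twin[i]} if i in twin else set()
        dist, parent = _bfs_tree(adj, i, banned_base)
        directed.loc[i, i] = 0.0
        for j, dij in dist.items():
            if j == i:
                continue
            path = [j]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            path = path[::-1]
            creator = _first_loop_creator(path, twin)
            if creator is None:
                directed.loc[i, j] = float(dij)
                continue
            eliminated = set()
            while creator is not None:
                eliminated.add(creator)
                path = _bfs_path(adj, i, j, banned_base | eliminated)
                if path is None:
                    break
                creator = _first_loop_creator(path, twin)
            if path is not None:
                directed.loc[i, j] = float(len(path) - 1)
    finite = directed.to_numpy()[np.isfinite(directed.to_numpy())]
    dmax = int(finite.max()) if finite.size else 0
    filled = directed.fillna(float(dmax))
    sym = np.minimum(filled.to_numpy(), filled.to_numpy().T)
    matrix = pd.DataFrame(sym.astype(int), index=ids, columns=ids)
    return DistanceMatrix(matrix=matrix, dmax=dmax, hubs=hub_list)


# ---------------------------------------------------------------------------
# the FPA linear program
# ---------------------------------------------------------------------------


def flux_potential(
    model: cobra.Model,
    target: str,
    coefficients: Mapping[str, float],
    distance_row: Mapping[str, float],
    config: FPAConfig | None = None,
    allowed: set[str] | None = None,
    blocked: Iterable[str] = (),
    background_load: float = 0.0,
) -> tuple[float, pd.Series]:
    """Maximize the target flux under the distance-weighted allowance.

    ``allowed`` is the context network (reactions outside it are bound to
    zero); a target outside its own context network has FP = 0 by
    definition.  ``background_load`` is a constant part of the allowance
    consumed by network remainder not modelled explicitly.  Returns the
    flux potential and the weight vector used.
    """
    config = config or FPAConfig()
    n = config.distance_order
    weights = {}
    for rxn in model.reactions:
        c = float(coefficients.get(rxn.id, 1.0))
        if c == 0.0:
            continue
        d = float(distance_row.get(rxn.id, 0.0))
        weights[rxn.id] = c / (1.0 + d) ** n
    wseries = pd.Series(weights, dtype=float)
    if allowed is not None and target not in allowed:
        return 0.0, wseries
    blocked = set(blocked)
    budget = config.allowance - background_load
    if budget <= 0:
        raise ConfigurationError("background_load exhausts the flux allowance")
    with model:
        for rxn in model.reactions:
            if rxn.id != target and (
                rxn.id in blocked or (allowed is not None and rxn.id not in allowed)
            ):
                rxn.bounds = (0.0, 0.0)
            else:
                # FPA relaxes lower bounds: fluxes live in [0, ub]
                rxn.bounds = (0.0, rxn.upper_bound)
        expr = sum(
            w * (model.reactions.get_by_id(rid).forward_variable
                 - model.reactions.get_by_id(rid).reverse_variable)
            for rid, w in weights.items()
        )
        con = model.problem.Constraint(expr, ub=budget, name="fpa_allowance")
        model.add_cons_vars([con])
        trxn = model.reactions.get_by_id(target)
        model.objective = model.problem.Objective(
            trxn.forward_variable - trxn.reverse_variable, direction="max"
        )
        model.solver.optimize()
        check_status(model, f"fpa:{target}")
        fp = float(model.solver.objective.value)
    return fp, wseries


@dataclass
class FPAResult:
    """Per-context flux potentials for one target."""

    target: str
    level: str  # "reaction" or "metabolite"
    fp: pd.Series
    fp_super: float
    rfp: pd.Series
    distance_order: float
    mode: str | None = None
    super_zero: bool = False

    def summary(self) -> str:
        lines = [
            f"Flux potential of {self.target}"
            + (f" ({self.mode})" if self.mode else ""),
            "=" * 44,
            f"{'context':<16s}{'FP':>12s}{'rFP':>12s}",
        ]
        for ctx in self.fp.index:
            lines.append(f"{ctx:<16s}{self.fp[ctx]:>12.5f}{self.rfp[ctx]:>12.4f}")
        lines.append(f"{'super':<16s}{self.fp_super:>12.5f}{1.0 if not self.super_zero else float('nan'):>12.4f}")
        return "\n".join(lines)


class FluxPotential:
    """FPA analyzer bound to a model, an expression matrix and (optionally)
    per-context networks.

    Accepts an ordinary (signed) model and splits it internally; targets
    are addressed as ``(reaction_id, direction)`` of the source model or
    directly by split id.
    """

    def __init__(
        self,
        model: cobra.Model,
        tpm: pd.DataFrame,
        networks: Mapping[str, set[tuple[str, str]]] | None = None,
        config: FPAConfig | None = None,
        contexts: Sequence[str] | None = None,
        intestine_context: str | None = None,
        hubs: Iterable[str] | None = None,
        background_load: float = 0.0,
        coefficient_cap: float = ZERO_EXPRESSION_CAP,
    ):
        self.config = config or FPAConfig()
        self.tpm = tpm
        self.contexts = list(contexts) if contexts is not None else list(tpm.columns)
        self.intestine_context = intestine_context
        self.background_load = background_load
        self.coefficient_cap = coefficient_cap
        self.split, self.split_map = split_irreversible(model)
        self.hubs = list(hubs) if hubs is not None else None
        self._distances: DistanceMatrix | None = None
        self._networks: dict[str, set[str]] | None = None
        if networks is not None:
            self._networks = {
                ctx: {
                    self.split_map.split_id(rid, direction)
                    for rid, direction in pairs
                    if (direction == "fwd" and rid in self.split_map.forward)
                    or (direction == "rev" and rid in self.split_map.reverse)
                }
                for ctx, pairs in networks.items()
            }
        self._coefficients: dict[str | None, pd.Series] = {}

    # -- cached pieces -----------------------------------------------------

    @property
    def distances(self) -> DistanceMatrix:
        if self._distances is None:
            hubs = self.hubs
            if hubs is None:
                hubs = default_hub_metabolites(self.split, self.config.n_hubs)
            self._distances = metabolic_distance(
                self.split, hubs=hubs, twin=self.split_map.twin
            )
        return self._distances

    def coefficients(self, context: str | None) -> pd.Series:
        if context not in self._coefficients:
            self._coefficients[context] = expression_coefficients(
                self.split,
                self.tpm,
                context,
                intestine_context=self.intestine_context,
                cap=self.coefficient_cap,
            )
        return self._coefficients[context]

    def network_for(self, context: str) -> set[str] | None:
        if self._networks is None:
            return None
        if context not in self._networks:
            raise ConfigurationError(f"no network labels for context {context!r}")
        return self._networks[context]

    # -- helpers -----------------------------------------------------------

    def _ie_transport_ids(self) -> set[str]:
        out = set()
        for rxn in self.split.reactions:
            if (
                rxn.annotation.get("tissue_compartment") == "I"
                and reaction_class(rxn) == "transport"
                and any(m.compartment == "e" for m in rxn.metabolites)
            ):
                out.add(rxn.id)
        return out

    def _resolve_target(self, target) -> str:
        if isinstance(target, tuple):
            rid, direction = target
            return self.split_map.split_id(rid, direction)
        if target in {r.id for r in self.split.reactions}:
            return target
        raise ConfigurationError(f"unknown FPA target {target!r}")

    def _evaluate(
        self,
        split_target: str,
        contexts: Sequence[str],
        extra_blocked: set[str],
        level: str,
        mode: str | None = None,
        assume_in_network: bool = False,
    ) -> FPAResult:
        target_comp = self.split.reactions.get_by_id(split_target).annotation.get(
            "tissue_compartment"
        )
        blocked = set(extra_blocked)
        twin = self.split_map.twin.get(split_target)
        if twin:
            blocked.add(twin)
        zero_coef_extra: set[str] = set()
        if self.intestine_context is not None:
            if target_comp in ("X", "E"):
                # do not penalize the other tissue for intestinal transport
                zero_coef_extra = self._ie_transport_ids()
            elif target_comp in ("I", "L"):
                blocked |= {
                    r.id
                    for r in self.split.reactions
                    if r.annotation.get("tissue_compartment") == "X"
                }
        drow = self.distances.row(split_target)
        fp = {}
        for ctx in contexts:
            coefs = self.coefficients(ctx)
            if zero_coef_extra:
                coefs = coefs.copy()
                coefs[list(zero_coef_extra & set(coefs.index))] = 0.0
            allowed = self.network_for(ctx)
            if allowed is not None and assume_in_network:
                allowed = allowed | {split_target}
            fp[ctx], _ = flux_potential(
                self.split,
                split_target,
                coefs,
                drow,
                self.config,
                allowed=allowed,
                blocked=blocked,
                background_load=self.background_load,
            )
        super_coefs = self.coefficients(None)
        if zero_coef_extra:
            super_coefs = super_coefs.copy()
            super_coefs[list(zero_coef_extra & set(super_coefs.index))] = 0.0
        fp_super, _ = flux_potential(
            self.split,
            split_target,
            super_coefs,
            drow,
            self.config,
            allowed=None,
            blocked=blocked,
            background_load=self.background_load,
        )
        fp_series = pd.Series(fp, dtype=float)
        if fp_super > 0:
            rfp = (fp_series / fp_super).clip(lower=0.0, upper=1.0)
            super_zero = False
        else:
            rfp = pd.Series(np.nan, index=fp_series.index)
            super_zero = True
        return FPAResult(
            target=split_target,
            level=level,
            fp=fp_series,
            fp_super=float(fp_super),
            rfp=rfp,
            distance_order=self.config.distance_order,
            mode=mode,
            super_zero=super_zero,
        )

    # -- public API --------------------------------------------------------

    def reaction(self, target, contexts: Sequence[str] | None = None) -> FPAResult:
        """Relative flux potential of a reaction(-direction) target."""
        split_target = self._resolve_target(target)
        return self._evaluate(
            split_target, list(contexts) if contexts else self.contexts, set(), "reaction"
        )

    def metabolite(
        self,
        metabolite: str,
        mode: str = "production",
        contexts: Sequence[str] | None = None,
        compartment_suffix: str | None = None,
    ) -> FPAResult:
        """Production (drain-side) or degradation (source-side) potential
        of a metabolite; inserts a demand/sink if the model has none, and
        blocks all alternative drains/sources of the same metabolite."""
        if mode not in ("production", "degradation"):
            raise ConfigurationError("mode must be 'production' or 'degradation'")
        candidates = [
            m
            for m in self.split.metabolites
            if base_metabolite_id(m.id) == base_metabolite_id(metabolite)
            and (compartment_suffix is None or m.compartment == compartment_suffix)
        ]
        if not candidates:
            raise ConfigurationError(f"metabolite {metabolite!r} not in model")
        met = candidates[0]
        # the blocking rule covers sink/demand/transport drains; plain
        # exchanges stay open (they are exempt supply/secretion routes)
        drain_classes = {"demand", "sink", "transport"}
        movers = sorted(
            (r for r in met.reactions if reaction_class(r) in drain_classes),
            key=lambda r: r.id,
        )
        sign = -1 if mode == "production" else 1
        acting = [r for r in movers if sign * r.metabolites[met] > 0]
        preferred_class = "demand" if mode == "production" else "sink"

        def rank(r):
            cls = reaction_class(r)
            if cls == preferred_class:
                return 0
            if cls == "transport" and any(m.compartment == "e" for m in r.metabolites):
                return 1
            return 2

        acting.sort(key=lambda r: (rank(r), r.id))
        target = None
        if acting:
            # take the first drain whose super system can carry flux at
            # all; a structurally dead drain (e.g. export into a
            # compartment with no outlet) would make the score vacuous
            target = acting[0]
            if len(acting) > 1:
                for cand in acting:
                    blocked_c = {r.id for r in movers if r.id != cand.id}
                    twin_c = self.split_map.twin.get(cand.id)
                    if twin_c:
                        blocked_c.add(twin_c)
                    if (
                        self.intestine_context is not None
                        and cand.annotation.get("tissue_compartment") in ("I", "L")
                    ):
                        blocked_c |= {
                            r.id
                            for r in self.split.reactions
                            if r.annotation.get("tissue_compartment") == "X"
                        }
                    fp_super, _ = flux_potential(
                        self.split,
                        cand.id,
                        self.coefficients(None),
                        self.distances.row(cand.id),
                        self.config,
                        blocked=blocked_c,
                        background_load=self.background_load,
                    )
                    if fp_super > 0:
                        target = cand
                        break
        inserted = False
        if target is None:
            inserted = True
            prefix = "DM" if mode == "production" else "SK"
            target = cobra.Reaction(f"{prefix}_{met.id}")
            self.split.add_reactions([target])
            target.add_metabolites({met: float(sign)})
            target.bounds = (0.0, 1000.0)
            set_reaction_class(target, preferred_class)
            if met.compartment in ("e", "l"):
                target.annotation["tissue_compartment"] = "E" if met.compartment == "e" else "L"
            self._distances = None  # topology changed
            self._coefficients = {}
        blocked = {r.id for r in movers if r.id != target.id}
        try:
            return self._evaluate(
                target.id,
                list(contexts) if contexts else self.contexts,
                blocked,
                "metabolite",
                mode=mode,
                assume_in_network=inserted,
            )
        finally:
            if inserted:
                # keep the inserted drain out of later targets' networks
                self.split.remove_reactions([target])
                self._distances = None
                self._coefficients = {}
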