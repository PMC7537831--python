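"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own solution paths:
linear programs go through scipy.optimize.linprog or explicit
basic-feasible-solution enumeration, and shortest valid-path distances
through an exhaustive state-space breadth-first search.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pandas as pd
from scipy.optimize import linprog


def stoichiometry_matrix(model) -> tuple[np.ndarray, list[str], list[str]]:
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[midx[met.id], j] = coef
    return S, mets, rxns


def vertex_enumeration_max(model, objective: dict[str, float]) -> float:
    """LP optimum by enumerating basic feasible solutions of
    {S v = 0, lb <= v <= ub}: fix n - rank(S) variables at a bound, solve
    the square system for the rest, keep feasible vertices."""
    S, _, rxns = stoichiometry_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([objective.get(rid, 0.0) for rid in rxns])
    n = len(rxns)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    best = None
    for basic in itertools.combinations(range(n), rank):
        nonbasic = [j for j in range(n) if j not in basic]
        B = S[:, list(basic)]
        if np.linalg.matrix_rank(B) < rank:
            continue
        for bounds_choice in itertools.product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            v[nonbasic] = [lb[j] if k == 0 else ub[j] for j, k in zip(nonbasic, bounds_choice)]
            rhs = -S[:, nonbasic] @ v[nonbasic]
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[list(basic)] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    if best is None:
        raise ValueError("no basic feasible solution found")
    return best


def linprog_flux(model, objective: dict[str, float], sense: str = "max",
                 forced: dict[str, float] | None = None,
                 blocked: tuple[str, ...] = ()):
    """Optimize a flux objective with scipy's HiGHS interior LP (handles
    signed fluxes by a positive/negative split).  Returns (value, fluxes)
    or None when infeasible."""
    S, _, rxns = stoichiometry_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    forced = forced or {}
    for rid, eps in forced.items():
        j = rxns.index(rid)
        lb[j] = max(lb[j], eps)
    for rid in blocked:
        j = rxns.index(rid)
        lb[j] = ub[j] = 0.0
    c = np.array([objective.get(rid, 0.0) for rid in rxns], dtype=float)
    if sense == "max":
        c = -c
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    value = float(res.fun if sense == "min" else -res.fun)
    return value, pd.Series(res.x, index=rxns)


def total_flux_min(model, forced=None, blocked=()):
    """Minimal total absolute flux via a split-variable scipy LP."""
    S, _, rxns = stoichiometry_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    forced = forced or {}
    for rid, eps in forced.items():
        j = rxns.index(rid)
        lb[j] = max(lb[j], eps)
    for rid in blocked:
        j = rxns.index(rid)
        lb[j] = ub[j] = 0.0
    n = len(rxns)
    # v = p - q, |v| <= p + q, p,q >= 0
    A_eq = np.hstack([S, -S])
    c = np.ones(2 * n)
    bounds = [(max(l, 0.0), max(u, 0.0)) for l, u in zip(lb, ub)] + [
        (max(-u, 0.0), max(-l, 0.0)) for l, u in zip(lb, ub)
    ]
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if not res.success:
        return None
    fluxes = pd.Series(res.x[:n] - res.x[n:], index=rxns)
    return float(res.fun), fluxes


def enumerate_imat_fit(model, r_on: list[str], r_off: list[str], genes_of: dict[str, list[str]],
                       eps: float):
    """Exhaustive enumeration of the expression-fitting MILP on an
    all-irreversible toy: every subset of high reactions forced >= eps and
    of rare reactions blocked, scored as (# genes with a forced reaction)
    + (# blocked rare reactions); returns (best score, minimal total flux
    over score-optimal assignments)."""
    best_score = -1
    best_total = None
    for on_subset in itertools.chain.from_iterable(
        itertools.combinations(r_on, k) for k in range(len(r_on) + 1)
    ):
        for off_subset in itertools.chain.from_iterable(
            itertools.combinations(r_off, k) for k in range(len(r_off) + 1)
        ):
            forced = {rid: eps for rid in on_subset}
            feas = linprog_flux(model, {}, "max", forced=forced, blocked=tuple(off_subset))
            if feas is None:
                continue
            score = sum(
                1 for g, rxns in genes_of.items() if any(r in on_subset for r in rxns)
            ) + len(off_subset)
            if score < best_score:
                continue
            tf = total_flux_min(model, forced=forced, blocked=tuple(off_subset))
            if tf is None:
                continue
            if score > best_score:
                best_score = score
                best_total = tf[0]
            else:
                best_total = min(best_total, tf[0])
    return best_score, best_total


def shortest_valid_distances(split, twin: dict[str, str], adjacency: dict[str, set[str]]) -> pd.DataFrame:
    """Exhaustive shortest valid-path distances: breadth-first search over
    (reaction, set-of-twinned-reactions-used) states, so a path never
    contains both directions of one originally reversible reaction.
    Finalized exactly like the production matrix (unreachable -> max
    observed, symmetrized by the minimum, zero diagonal)."""
    ids = [r.id for r in split.reactions]
    directed = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in ids:
        banned = {twin[i]} if i in twin else set()
        start_used = frozenset({i} if i in twin else set())
        best = {i: 0}
        seen = {(i, start_used)}
        queue = deque([(i, start_used, 0)])
        while queue:
            u, used, d = queue.popleft()
            for v in adjacency[u]:
                if v in banned or twin.get(v) in used:
                    continue
                nused = used | ({v} if v in twin else set())
                if (v, nused) in seen:
                    continue
                seen.add((v, nused))
                if v not in best or d + 1 < best[v]:
                    best[v] = d + 1
                queue.append((v, nused, d + 1))
        for j, d in best.items():
            directed.loc[i, j] = float(d)
    finite = directed.to_numpy()[np.isfinite(directed.to_numpy())]
    dmax = finite.max() if finite.size else 0.0
    filled = directed.fillna(dmax)
    sym = np.minimum(filled.to_numpy(), filled.to_numpy().T)
    return pd.DataFrame(sym, index=ids, columns=ids)
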