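"""Context network extraction: label each reaction-direction OFD/ALT/NONE.

Inside the fitting space frozen by the expression integration (Z_fit
pinned, low-flux and total-flux caps, latent forcing), a direction that
carries flux in the OFD is labelled OFD; one with nonzero FVA capacity is
ALT (active only in alternate optima); one with zero capacity is NONE and
is excluded from the context network consumed by flux potential analysis.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import CAPACITY_TOL, ConfigurationError, check_status
from .imat import ImatResults

__all__ = [
    "classify_reactions",
    "apply_intestine_rule",
    "network_reaction_set",
    "tissue_network_table",
]


def _directions(rxn):
    dirs = []
    if rxn.upper_bound > 0:
        dirs.append("fwd")
    if rxn.lower_bound < 0:
        dirs.append("rev")
    return dirs


def classify_reactions(
    results: ImatResults,
    tolerance: float = CAPACITY_TOL,
    screen_rounds: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Label every reaction-direction for one integrated context.

    ``screen_rounds`` > 0 enables the fast variant: a small batch of
    randomized-objective solves first marks directions observed active
    (proving nonzero capacity without a dedicated FVA solve); exact
    per-direction FVA runs only on the remainder.  The screening can only
    ever skip solves whose answer it has already witnessed, so labels are
    identical to the exhaustive variant.
    """
    m = results.frozen_model
    ofd = results.ofd.fluxes
    rows: list[dict] = []
    pending: list[tuple[str, str]] = []
    for rxn in m.reactions:
        v = float(ofd.get(rxn.id, 0.0))
        for direction in _directions(rxn):
            signed = v if direction == "fwd" else -v
            if signed > tolerance:
                label = "OFD"
            else:
                label = None
                pending.append((rxn.id, direction))
            rows.append(
                {
                    "reaction": rxn.id,
                    "direction": direction,
                    "label": label,
                    "compartment": rxn.annotation.get("tissue_compartment", ""),
                }
            )
    table = pd.DataFrame(rows).set_index(["reaction", "direction"])

    witnessed: set[tuple[str, str]] = set()
    if screen_rounds > 0 and pending:
        rng = np.random.default_rng(seed)
        rxns = list(m.reactions)
        for _ in range(screen_rounds):
            coefs = rng.uniform(-1.0, 1.0, size=len(rxns))
            expr = sum(
                c * (r.forward_variable - r.reverse_variable) for c, r in zip(coefs, rxns)
            )
            m.objective = m.problem.Objective(expr, direction="max")
            m.solver.optimize()
            if m.solver.status != "optimal":
                continue
            for r in rxns:
                flux = r.forward_variable.primal - r.reverse_variable.primal
                if flux > tolerance:
                    witnessed.add((r.id, "fwd"))
                elif flux < -tolerance:
                    witnessed.add((r.id, "rev"))

    for rid, direction in pending:
        if (rid, direction) in witnessed:
            table.loc[(rid, direction), "label"] = "ALT"
            continue
        rxn = m.reactions.get_by_id(rid)
        expr = rxn.forward_variable - rxn.reverse_variable
        sense = "max" if direction == "fwd" else "min"
        m.objective = m.problem.Objective(expr, direction=sense)
        m.solver.optimize()
        check_status(m, f"network-fva:{rid}:{direction}")
        capacity = float(m.solver.objective.value)
        capacity = capacity if direction == "fwd" else -capacity
        table.loc[(rid, direction), "label"] = "ALT" if capacity > tolerance else "NONE"
    return table.reset_index()


def apply_intestine_rule(
    labels_by_context: Mapping[str, pd.DataFrame], intestine: str
) -> pd.DataFrame:
    """Demote intestine ALT reactions unsupported by any other integration.

    An I/L-compartment direction labelled ALT for the intestine but with
    zero capacity (NONE) in the I/L side of every non-intestine
    integration is removed from the intestine network.
    """
    if intestine not in labels_by_context:
        raise ConfigurationError(f"missing intestine context {intestine!r}")
    others = [c for c in labels_by_context if c != intestine]
    if not others:
        raise ConfigurationError("need at least one non-intestine context")
    table = labels_by_context[intestine].copy()
    key = ["reaction", "direction"]
    other_labels = [
        labels_by_context[c].set_index(key)["label"] for c in others
    ]
    for c, lab in zip(others, other_labels):
        if lab.index.has_duplicates:
            raise ConfigurationError(f"duplicate reaction-direction rows in context {c}")
    idx = table.set_index(key).index
    demote = np.zeros(len(table), dtype=bool)
    candidate = (
        table["label"].eq("ALT") & table["compartment"].isin(["I", "L"])
    ).to_numpy()
    for pos, row_key in enumerate(idx):
        if not candidate[pos]:
            continue
        states = []
        for lab in other_labels:
            if row_key not in lab.index:
                raise ConfigurationError(f"context missing labels for {row_key}")
            states.append(lab.loc[row_key])
        if all(s == "NONE" for s in states):
            demote[pos] = True
    table.loc[demote, "label"] = "NONE"
    return table


def network_reaction_set(labels: pd.DataFrame) -> set[tuple[str, str]]:
    """Reaction-directions in the context network (OFD plus ALT)."""
    inside = labels[labels["label"].isin(["OFD", "ALT"])]
    return set(zip(inside["reaction"], inside["direction"]))


def tissue_network_table(labels: pd.DataFrame, is_intestine: bool) -> pd.DataFrame:
    """Single-tissue view: I/L rows for the intestine, X/E for the rest.
    Rows without a compartment tag (single-compartment models) pass
    through unchanged."""
    comp = labels["compartment"]
    if comp.eq("").all():
        return labels.copy()
    wanted = ("I", "L") if is_intestine else ("X", "E")
    return labels[comp.isin(wanted)].copy()
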