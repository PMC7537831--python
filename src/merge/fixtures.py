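"""Deterministic toy models and synthetic expression data.

Every downstream stage is testable offline from these generators:

``gene_centered``
    one highly expressed gene mapped to two reactions of which one
    suffices, plus a latent branch of a second high gene — exercises the
    gene-centering and latent-forcing behavior of the integration MILP;

``shared_gene_shunt``
    a bypass pathway gated by a control gene that is high in only two of
    seven contexts, its other genes shared with a second pathway —
    bypass flux should appear only where the control gene is high;

``fpa_chain``
    a linear chain where mass balance forces all fluxes equal, so the
    flux potential has the closed form (a - background)/sum(w);

``isolated_target``
    a gene-bearing target whose only companions with nonzero FPA weight
    sit behind a hub metabolite (distance = maximum observed), so the
    high-distance-order limit rFP -> normalized gene expression is exact;

``dual_system``
    a miniature whole-animal world (bacterial food, side/storage
    nutrients, glycolysis-like energy pathway, lactate fermentation,
    biomass demand) that supports the full dual-tissue pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .core import ConfigurationError, set_reaction_class

__all__ = ["ToyData", "make_toy", "synth_expression", "random_split_network", "CONTEXTS"]

#: default context (tissue) names, intestine first
CONTEXTS = ("intestine", "hypodermis", "neuron", "muscle", "gonad", "glia", "pharynx")


@dataclass
class ToyData:
    model: cobra.Model
    tpm: pd.DataFrame | None = None
    categories: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _reaction(model, rid, stoich, bounds, cls, gpr="", role=None):
    rxn = cobra.Reaction(rid)
    model.add_reactions([rxn])
    mets = {}
    for mid, coef in stoich.items():
        if mid in model.metabolites:
            met = model.metabolites.get_by_id(mid)
        else:
            comp = mid[mid.rfind("[") + 1 : -1] if "[" in mid else "c"
            met = cobra.Metabolite(mid, compartment=comp)
            model.add_metabolites([met])
        mets[met] = coef
    rxn.add_metabolites(mets)
    rxn.bounds = bounds
    if gpr:
        rxn.gene_reaction_rule = gpr
    set_reaction_class(rxn, cls)
    if role:
        rxn.annotation["nutrient_role"] = role
    return rxn


def _tpm_frame(values: dict[str, list[float]], contexts) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(contexts)).T.astype(float)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------


def _gene_centered(seed: int, **kw) -> ToyData:
    # gene y maps to two parallel reactions fed by different substrates
    # (one suffices); gene x has one used route and one latent branch
    # whose reactant stays available; DM_A provides a baseline flux load
    # so the 5% parsimony slack is realistic relative to epsilon
    m = cobra.Model("gene_centered")
    _reaction(m, "EX_A", {"A[c]": 1}, (0, 10), "exchange")
    _reaction(m, "DM_A", {"A[c]": -1}, (1, 1000), "demand")
    _reaction(m, "RB1", {"A[c]": -1, "B1[c]": 1}, (0, 1000), "internal", gpr="m1")
    _reaction(m, "RB2", {"A[c]": -1, "B2[c]": 1}, (0, 1000), "internal", gpr="m2")
    _reaction(m, "RY1", {"B1[c]": -1, "C[c]": 1}, (0, 1000), "internal", gpr="y")
    _reaction(m, "RY2", {"B2[c]": -1, "C[c]": 1}, (0, 1000), "internal", gpr="y")
    _reaction(m, "RX1", {"A[c]": -1, "C[c]": 1}, (0, 1000), "internal", gpr="x")
    _reaction(m, "RX2", {"A[c]": -1, "E[c]": 1}, (0, 1000), "internal", gpr="x")
    _reaction(m, "EX_C", {"C[c]": -1}, (0, 1000), "exchange")
    _reaction(m, "EX_E", {"E[c]": -1}, (0, 1000), "exchange")
    cats = pd.DataFrame(
        {"t1": {"x": "high", "y": "high", "m1": "moderate", "m2": "moderate"}}
    )
    return ToyData(
        model=m,
        categories=cats,
        meta={"latent_branch": "RX2", "multi_gene": ("RY1", "RY2")},
    )


def _shared_gene_shunt(seed: int, n_contexts: int = 7, **kw) -> ToyData:
    m = cobra.Model("shared_gene_shunt")
    _reaction(m, "EX_P", {"P[c]": 1}, (0, 10), "exchange")
    _reaction(m, "EX_V", {"V[c]": 1}, (0, 10), "exchange")
    _reaction(m, "RCAN", {"P[c]": -1, "Q[c]": 1}, (0, 1000), "internal", gpr="c1")
    _reaction(m, "RS1", {"P[c]": -1, "S[c]": 1}, (0, 1000), "internal", gpr="ctrl")
    _reaction(m, "RS2", {"S[c]": -1, "Q[c]": 1}, (0, 1000), "internal", gpr="sh")
    _reaction(m, "RVAL", {"V[c]": -1, "Q[c]": 1}, (0, 1000), "internal", gpr="sh")
    _reaction(m, "EX_Q", {"Q[c]": -1}, (0, 1000), "exchange")
    contexts = list(CONTEXTS[:n_contexts])
    cats = {}
    for i, ctx in enumerate(contexts):
        cats[ctx] = {
            "c1": "high",
            "sh": "high",
            "ctrl": "high" if i < 2 else "rare",
        }
    return ToyData(
        model=m,
        categories=pd.DataFrame(cats),
        meta={"bypass": "RS1", "control_gene": "ctrl", "high_contexts": contexts[:2]},
    )


def _fpa_chain(seed: int, k: int = 3, n_contexts: int = 7, **kw) -> ToyData:
    if k < 1:
        raise ConfigurationError("chain length k must be >= 1")
    rng = np.random.default_rng(seed)
    m = cobra.Model("fpa_chain")
    _reaction(m, "EX_in", {"M0[c]": 1}, (0, 1000), "exchange")
    for i in range(1, k + 1):
        _reaction(
            m,
            f"R{i}",
            {f"M{i-1}[c]": -1, f"M{i}[c]": 1},
            (0, 1000),
            "internal",
            gpr=f"g{i}",
        )
    _reaction(m, "EX_out", {f"M{k}[c]": -1}, (0, 1000), "exchange")
    contexts = list(CONTEXTS[:n_contexts])
    tpm = _tpm_frame(
        {f"g{i}": rng.integers(5, 200, size=n_contexts).astype(float) for i in range(1, k + 1)},
        contexts,
    )
    return ToyData(
        model=m,
        tpm=tpm,
        meta={"target": f"R{k}", "background_load": 0.5, "chain": [f"R{i}" for i in range(1, k + 1)]},
    )


def _isolated_target(seed: int, far_length: int = 7, n_contexts: int = 7, **kw) -> ToyData:
    rng = np.random.default_rng(seed)
    m = cobra.Model("isolated_target")
    _reaction(m, "EX_A", {"A[c]": 1}, (0, 1000), "exchange")
    _reaction(m, "RT", {"A[c]": -1, "B[c]": 1, "atp[c]": 1}, (0, 1000), "internal", gpr="gt")
    _reaction(m, "EX_B", {"B[c]": -1}, (0, 1000), "exchange")
    _reaction(m, "DM_atp", {"atp[c]": -1}, (0, 1000), "demand")
    # far component, reachable from the target only through the hub
    # metabolite atp, hence at the maximum observed distance
    _reaction(m, "EX_C", {"C0[c]": 1}, (0, 1000), "exchange")
    genes = {}
    for i in range(1, far_length + 1):
        stoich = {f"C{i-1}[c]": -1, f"C{i}[c]": 1}
        if i == 1:
            stoich["atp[c]"] = -1
        _reaction(m, f"F{i}", stoich, (0, 1000), "internal", gpr=f"gf{i}")
        genes[f"gf{i}"] = rng.integers(5, 200, size=n_contexts).astype(float)
    _reaction(m, "EX_F", {f"C{far_length}[c]": -1}, (0, 1000), "exchange")
    contexts = list(CONTEXTS[:n_contexts])
    genes["gt"] = rng.integers(20, 400, size=n_contexts).astype(float)
    tpm = _tpm_frame(genes, contexts)
    return ToyData(model=m, tpm=tpm, meta={"target": "RT", "gene": "gt", "hubs": ["atp"]})


#: TPM profiles of the dual_system model genes over the seven contexts
#: (intestine, hypodermis, neuron, muscle, gonad, glia, pharynx); patterns
#: chosen so lactate fermentation is a neuron/muscle feature, trehalose
#: breakdown a muscle feature, and the core machinery broadly expressed.
_DUAL_TPM = {
    "tglc": [200, 180, 220, 210, 190, 185, 205],
    "taa": [150, 140, 160, 150, 170, 145, 155],
    "treh": [1, 1, 1, 300, 1, 1, 1],
    "gly1": [120, 100, 400, 350, 110, 105, 115],
    "ldh": [3, 30, 400, 300, 3, 3, 3],
    "res1": [150, 140, 200, 260, 130, 135, 160],
    "syn1": [100, 120, 80, 90, 150, 85, 95],
}


def _dual_system(seed: int, n_contexts: int = 7, **kw) -> ToyData:
    m = cobra.Model("dual_system")
    masses = {"bac[e]": 10.0, "glc[e]": 0.18, "aa[e]": 0.1, "tre[e]": 0.34}
    _reaction(m, "EX_bac", {"bac[e]": 1}, (0, 1000), "exchange", role="bacterial")
    _reaction(m, "EX_glc", {"glc[e]": 1}, (0, 1000), "exchange", role="side")
    _reaction(m, "EX_aa", {"aa[e]": 1}, (0, 1000), "exchange", role="side")
    _reaction(m, "EX_tre", {"tre[e]": 1}, (0, 1000), "exchange", role="storage")
    _reaction(m, "EX_lac", {"lac[e]": -1}, (0, 1000), "exchange")
    _reaction(m, "T_bac", {"bac[e]": -1, "bac[c]": 1}, (0, 1000), "bacterial_degradation")
    _reaction(m, "DEG", {"bac[c]": -1, "glc[c]": 3, "aa[c]": 2}, (0, 1000), "bacterial_degradation")
    _reaction(m, "T_glc", {"glc[e]": -1, "glc[c]": 1}, (-1000, 1000), "transport", gpr="tglc")
    _reaction(m, "T_aa", {"aa[e]": -1, "aa[c]": 1}, (-1000, 1000), "transport", gpr="taa")
    _reaction(m, "T_tre", {"tre[e]": -1, "tre[c]": 1}, (-1000, 1000), "transport")
    _reaction(m, "TREH", {"tre[c]": -1, "glc[c]": 2}, (0, 1000), "internal", gpr="treh")
    _reaction(
        m,
        "GLY",
        {"glc[c]": -1, "adp[c]": -2, "pyr[c]": 2, "atp[c]": 2},
        (0, 1000),
        "internal",
        gpr="gly1",
    )
    _reaction(m, "LDH", {"pyr[c]": -1, "lac[c]": 1}, (-1000, 1000), "internal", gpr="ldh")
    _reaction(m, "T_lac", {"lac[c]": -1, "lac[e]": 1}, (-1000, 1000), "transport")
    _reaction(
        m,
        "RES",
        {"pyr[c]": -1, "adp[c]": -5, "atp[c]": 5},
        (0, 1000),
        "internal",
        gpr="res1",
    )
    _reaction(m, "RCC0005", {"atp[c]": -1, "adp[c]": 1}, (0, 1000), "internal")
    _reaction(
        m,
        "SYN",
        {"aa[c]": -1, "atp[c]": -1, "biom[c]": 1, "adp[c]": 1},
        (0, 1000),
        "internal",
        gpr="syn1",
    )
    _reaction(m, "DM_biom", {"biom[c]": -1}, (0, 1000), "demand")
    for mid, mass in masses.items():
        m.metabolites.get_by_id(mid).annotation["mass_g_per_mmol"] = mass
    contexts = list(CONTEXTS[:n_contexts])
    tpm = _tpm_frame({g: vals[:n_contexts] for g, vals in _DUAL_TPM.items()}, contexts)
    return ToyData(
        model=m,
        tpm=tpm,
        meta={
            "intestine": "intestine",
            "side_nutrients": ["EX_glc", "EX_aa"],
            "storage": ["EX_tre"],
            "bacterial": "EX_bac",
            "masses": masses,
        },
    )


_MOTIFS = {
    "gene_centered": _gene_centered,
    "shared_gene_shunt": _shared_gene_shunt,
    "fpa_chain": _fpa_chain,
    "isolated_target": _isolated_target,
    "dual_system": _dual_system,
}


def make_toy(motif: str, seed: int = 0, **params) -> ToyData:
    """Build a toy world by motif name; same seed, same world."""
    try:
        builder = _MOTIFS[motif]
    except KeyError:
        raise ConfigurationError(
            f"unknown motif {motif!r}; choose from {sorted(_MOTIFS)}"
        ) from None
    for key in ("k", "n_contexts", "far_length"):
        if key in params and params[key] < 1:
            raise ConfigurationError(f"size parameter {key} must be positive")
    return builder(seed, **params)


# ---------------------------------------------------------------------------
# synthetic expression
# ---------------------------------------------------------------------------


def synth_expression(
    n_genes: int = 5000,
    mu: tuple[float, float] = (1.0, 6.0),
    sigma: tuple[float, float] = (1.0, 1.0),
    weights: tuple[float, float] = (0.5, 0.5),
    n_contexts: int = 7,
    jitter: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """TPM matrix drawn from a two-component log2-scale Gaussian mixture.

    Each gene gets a mixture component (LES first, HES second), a mean
    log2 expression from that component, and per-context Gaussian jitter
    (sigma 0.3 log2 units by default — small against the 1.5-fold
    relative-recategorization threshold).  Returns the TPM frame and the
    ground-truth component labels ("LES"/"HES").
    """
    if n_genes < 1 or n_contexts < 1:
        raise ConfigurationError("n_genes and n_contexts must be positive")
    if not np.isclose(sum(weights), 1.0):
        raise ConfigurationError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    component = rng.choice(2, size=n_genes, p=list(weights))
    means = np.where(component == 1, mu[1], mu[0]) + rng.normal(
        0.0, 1.0, size=n_genes
    ) * np.where(component == 1, sigma[1], sigma[0])
    log2_vals = means[:, None] + rng.normal(0.0, jitter, size=(n_genes, n_contexts))
    tpm = np.power(2.0, log2_vals)
    contexts = [CONTEXTS[i] if i < len(CONTEXTS) else f"context{i}" for i in range(n_contexts)]
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    frame = pd.DataFrame(tpm, index=genes, columns=contexts)
    labels = pd.Series(np.where(component == 1, "HES", "LES"), index=genes)
    return frame, labels


def random_split_network(
    seed: int,
    n_reactions: int = 8,
    n_metabolites: int = 8,
    reversible_frac: float = 0.3,
):
    """Random small signed network and its forward-only split, for
    distance-algorithm stress tests (<= 2 * n_reactions split nodes)."""
    from .fpa import split_irreversible

    rng = np.random.default_rng(seed)
    m = cobra.Model(f"random_{seed}")
    mets = [f"m{i}[c]" for i in range(n_metabolites)]
    for i in range(n_reactions):
        n_sub = rng.integers(1, 3)
        n_prod = rng.integers(1, 3)
        chosen = rng.choice(n_metabolites, size=min(n_sub + n_prod, n_metabolites), replace=False)
        stoich = {}
        for j, mi in enumerate(chosen):
            stoich[mets[mi]] = -1.0 if j < n_sub else 1.0
        if not any(c > 0 for c in stoich.values()):
            stoich[mets[rng.integers(n_metabolites)]] = 1.0
        reversible = rng.random() < reversible_frac
        _reaction(
            m,
            f"r{i}",
            stoich,
            (-1000, 1000) if reversible else (0, 1000),
            "internal",
        )
    return split_irreversible(m)
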