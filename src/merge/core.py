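"""Model representation, standard-format I/O, GPR evaluation and solving.

The in-memory container is a :class:`cobra.Model`.  Two extra pieces of
information that plain COBRA models do not carry are stored in per-object
annotation dictionaries:

``reaction.annotation["reaction_class"]``
    one of :data:`REACTION_CLASSES` (internal / transport / exchange /
    demand / sink / bacterial_degradation), driving the dual-tissue
    expansion and the FPA coefficient exemptions;

``metabolite.annotation["mass_g_per_mmol"]``
    molecular mass used by the nutrient-policy mass-coupling constraints.

Reactions may additionally carry ``annotation["nutrient_role"]`` on their
exchanged metabolite (``bacterial`` / ``side`` / ``storage``) and, after
dual-tissue expansion, ``annotation["tissue_compartment"]`` in
``{"I", "X", "L", "E"}``.
"""

from __future__ import annotations

import ast
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
from cobra.core.gene import GPR

__all__ = [
    "CATEGORIES",
    "CATEGORY_RANK",
    "REACTION_CLASSES",
    "FLUX_ZERO",
    "CAPACITY_TOL",
    "BIG_M",
    "MergeError",
    "GPRFormatError",
    "ModelIntegrityError",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "ConfigurationError",
    "FluxDistribution",
    "load_model",
    "read_model_tables",
    "write_model_tables",
    "read_sbml",
    "write_sbml",
    "model_census",
    "validate_model",
    "reaction_class",
    "set_reaction_class",
    "gpr_category",
    "evaluate_gpr_dependence",
    "solve",
    "fva",
]

# Category lattice used by the AND/OR algebra: AND takes the worse (min),
# OR the better (max).
CATEGORIES = ("rare", "low", "moderate", "high")
CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}

REACTION_CLASSES = frozenset(
    {"internal", "transport", "exchange", "demand", "sink", "bacterial_degradation"}
)

#: |v| below this is "no flux" throughout the pipeline.
FLUX_ZERO = 1e-9
#: FVA capacity above this counts as "can carry flux" (network labelling).
CAPACITY_TOL = 1e-6
#: big-M for indicator constraints; just above the default 1000 flux bound.
BIG_M = 1001.0


class MergeError(Exception):
    """Base class for all errors raised by this package."""


class GPRFormatError(MergeError):
    pass


class ModelIntegrityError(MergeError):
    pass


class ConfigurationError(MergeError):
    pass


class InfeasibleProblemError(MergeError):
    def __init__(self, stage: str, status: str = "infeasible"):
        self.stage = stage
        self.status = status
        super().__init__(f"optimization infeasible at stage '{stage}' (status: {status})")


class UnboundedProblemError(MergeError):
    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"optimization unbounded at stage '{stage}'")


# ---------------------------------------------------------------------------
# flux distributions
# ---------------------------------------------------------------------------


@dataclass
class FluxDistribution:
    """A solved flux vector with its objective value and solver status."""

    fluxes: pd.Series
    objective_value: float
    status: str = "optimal"

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])

    def active(self, tol: float = FLUX_ZERO) -> pd.Series:
        return self.fluxes[self.fluxes.abs() > tol]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "objective_value": self.objective_value,
            "status": self.status,
            "fluxes": {k: float(v) for k, v in self.fluxes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FluxDistribution":
        payload = json.loads(Path(path).read_text())
        return cls(
            fluxes=pd.Series(payload["fluxes"], dtype=float),
            objective_value=payload["objective_value"],
            status=payload["status"],
        )


# ---------------------------------------------------------------------------
# reaction class tags
# ---------------------------------------------------------------------------


def reaction_class(reaction: cobra.Reaction) -> str:
    """Class tag of a reaction, inferring boundary classes when untagged."""
    tag = reaction.annotation.get("reaction_class")
    if tag is None:
        tag = _infer_class(reaction)
    if tag not in REACTION_CLASSES:
        raise ModelIntegrityError(f"reaction {reaction.id}: unknown class tag {tag!r}")
    return tag


def set_reaction_class(reaction: cobra.Reaction, tag: str) -> None:
    if tag not in REACTION_CLASSES:
        raise ModelIntegrityError(f"unknown reaction class {tag!r}")
    reaction.annotation["reaction_class"] = tag


def _infer_class(reaction: cobra.Reaction) -> str:
    mets = reaction.metabolites
    if len(mets) == 1:
        coef = next(iter(mets.values()))
        rid = reaction.id.upper()
        if rid.startswith("DM_") or (coef < 0 and reaction.lower_bound >= 0 and not rid.startswith(("EX_", "SK_"))):
            return "demand" if rid.startswith("DM_") else "exchange"
        if rid.startswith("SK_"):
            return "sink"
        return "exchange"
    compartments = {m.compartment for m in mets if m.compartment}
    if len(compartments) > 1:
        return "transport"
    return "internal"


# ---------------------------------------------------------------------------
# tabular model dialect
# ---------------------------------------------------------------------------

_MET_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S.*)$")


def _parse_side(text: str) -> dict[str, float]:
    text = text.strip()
    if not text:
        return {}
    out: dict[str, float] = {}
    for term in text.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _MET_TOKEN.match(term)
        if m is None:
            raise ModelIntegrityError(f"cannot parse equation term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2).strip()
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A[c] + B[c] -> C[c]"`` into a stoichiometry map.

    Returns the metabolite->coefficient map (reactants negative) and a
    reversibility flag (``"<=>"`` vs ``"->"``).
    """
    if "<=>" in text:
        lhs, rhs = text.split("<=>")
        reversible = True
    elif "->" in text:
        lhs, rhs = text.split("->")
        reversible = False
    else:
        raise ModelIntegrityError(f"equation {text!r} has no '->' or '<=>' arrow")
    stoich: dict[str, float] = {}
    for met, coef in _parse_side(lhs).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(rhs).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    return {m: c for m, c in stoich.items() if c != 0.0}, reversible


def format_equation(reaction: cobra.Reaction) -> str:
    lhs = []
    rhs = []
    for met, coef in sorted(reaction.metabolites.items(), key=lambda kv: kv[0].id):
        token = met.id if abs(coef) == 1 else f"{abs(coef):g} {met.id}"
        (lhs if coef < 0 else rhs).append(token)
    arrow = "<=>" if reaction.reversibility else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


_COMPARTMENT_RE = re.compile(r"\[([^\]]+)\]$")


def _compartment_of(met_id: str) -> str:
    m = _COMPARTMENT_RE.search(met_id)
    return m.group(1) if m else "c"


def base_metabolite_id(met_id: str) -> str:
    """Metabolite id stripped of its bracketed compartment suffix."""
    return _COMPARTMENT_RE.sub("", met_id)


def read_model_tables(
    reactions_tsv: str | Path, metabolites_tsv: str | Path, model_id: str = "model"
) -> cobra.Model:
    """Load the two-table TSV dialect (id/equation/gpr/bounds/class +
    id/name/compartment, mirroring a supplementary-table layout)."""
    rxns = pd.read_csv(reactions_tsv, sep="\t", dtype=str).fillna("")
    mets = pd.read_csv(metabolites_tsv, sep="\t", dtype=str).fillna("")
    model = cobra.Model(model_id)
    met_objs: dict[str, cobra.Metabolite] = {}
    for _, row in mets.iterrows():
        met = cobra.Metabolite(
            row["id"], name=row.get("name", ""), compartment=row.get("compartment") or _compartment_of(row["id"])
        )
        if row.get("mass_g_per_mmol", ""):
            met.annotation["mass_g_per_mmol"] = float(row["mass_g_per_mmol"])
        met_objs[met.id] = met
    for _, row in rxns.iterrows():
        rid = row["id"]
        stoich, reversible = parse_equation(row["equation"])
        missing = [m for m in stoich if m not in met_objs]
        if missing:
            raise ModelIntegrityError(
                f"reaction {rid} references undeclared metabolite(s): {', '.join(missing)}"
            )
        rxn = cobra.Reaction(rid)
        lb = float(row["lower_bound"]) if row.get("lower_bound", "") != "" else (-1000.0 if reversible else 0.0)
        ub = float(row["upper_bound"]) if row.get("upper_bound", "") != "" else 1000.0
        model.add_reactions([rxn])
        rxn.add_metabolites({met_objs[m]: c for m, c in stoich.items()})
        rxn.bounds = (lb, ub)
        gpr_text = row.get("gpr", "")
        if gpr_text:
            try:
                rxn.gene_reaction_rule = gpr_text
            except Exception as exc:  # pragma: no cover - cobra raises various types
                raise GPRFormatError(f"reaction {rid}: malformed GPR {gpr_text!r}") from exc
            _check_gpr(rxn)
        if row.get("class", ""):
            set_reaction_class(rxn, row["class"])
        if row.get("nutrient_role", ""):
            rxn.annotation["nutrient_role"] = row["nutrient_role"]
    validate_model(model)
    return model


def write_model_tables(model: cobra.Model, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rrows = []
    for rxn in model.reactions:
        rrows.append(
            {
                "id": rxn.id,
                "equation": format_equation(rxn),
                "gpr": rxn.gene_reaction_rule,
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "class": reaction_class(rxn),
                "nutrient_role": rxn.annotation.get("nutrient_role", ""),
            }
        )
    mrows = []
    for met in model.metabolites:
        mrows.append(
            {
                "id": met.id,
                "name": met.name,
                "compartment": met.compartment,
                "mass_g_per_mmol": met.annotation.get("mass_g_per_mmol", ""),
            }
        )
    rpath = out / "reactions.tsv"
    mpath = out / "metabolites.tsv"
    pd.DataFrame(rrows).to_csv(rpath, sep="\t", index=False)
    pd.DataFrame(mrows).to_csv(mpath, sep="\t", index=False)
    return rpath, mpath


def read_sbml(path: str | Path) -> cobra.Model:
    model = cobra.io.read_sbml_model(str(path))
    for rxn in model.reactions:
        tag = rxn.notes.get("reaction_class")
        if tag:
            set_reaction_class(rxn, tag)
    for met in model.metabolites:
        mass = met.notes.get("mass_g_per_mmol")
        if mass is not None:
            met.annotation["mass_g_per_mmol"] = float(mass)
    validate_model(model)
    return model


def write_sbml(model: cobra.Model, path: str | Path) -> None:
    # class tags and masses survive the round trip through SBML notes
    for rxn in model.reactions:
        rxn.notes["reaction_class"] = reaction_class(rxn)
    for met in model.metabolites:
        if "mass_g_per_mmol" in met.annotation:
            met.notes["mass_g_per_mmol"] = str(met.annotation["mass_g_per_mmol"])
    cobra.io.write_sbml_model(model, str(path))


def load_model(source, metabolites=None, model_id: str = "model") -> cobra.Model:
    """Load a model from SBML (single path) or the TSV dialect (two paths)."""
    if metabolites is not None:
        return read_model_tables(source, metabolites, model_id=model_id)
    source = Path(source)
    if source.suffix.lower() in {".xml", ".sbml"}:
        return read_sbml(source)
    raise ConfigurationError(f"cannot infer model format for {source}")


def model_census(model: cobra.Model) -> dict[str, int]:
    """Counts reported on load: genes, reactions, unique metabolites
    (compartment suffixes ignored) and total species."""
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "unique_metabolites": len({base_metabolite_id(m.id) for m in model.metabolites}),
        "metabolite_species": len(model.metabolites),
    }


def validate_model(model: cobra.Model) -> None:
    gene_ids = {g.id for g in model.genes}
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelIntegrityError(f"reaction {rxn.id}: lower bound above upper bound")
        for g in rxn.genes:
            if g.id not in gene_ids:  # pragma: no cover - cobra keeps this consistent
                raise ModelIntegrityError(f"reaction {rxn.id}: gene {g.id} not in model")


# ---------------------------------------------------------------------------
# GPR category algebra
# ---------------------------------------------------------------------------


def _check_gpr(rxn: cobra.Reaction) -> None:
    if rxn.gene_reaction_rule and not rxn.genes:
        raise GPRFormatError(f"reaction {rxn.id}: GPR parsed to no genes")


def gpr_category(gpr: GPR | str, categories: Mapping[str, str]) -> str | None:
    """Effective expression category of a boolean GPR.

    AND combines by the worse (min) category — a complex is only as
    available as its scarcest subunit; OR by the better (max) — any
    isozyme suffices.  Returns ``None`` for an empty GPR.
    """
    if isinstance(gpr, str):
        if not gpr.strip():
            return None
        gpr = GPR.from_string(gpr)
    if gpr.body is None:
        return None
    rank = _eval_node(gpr.body, categories)
    return CATEGORIES[rank] if rank is not None else None


def _eval_node(node, categories: Mapping[str, str]) -> int | None:
    if isinstance(node, ast.Name):
        try:
            return CATEGORY_RANK[categories[node.id]]
        except KeyError as exc:
            raise KeyError(f"gene {node.id} missing from category table") from exc
    if isinstance(node, ast.BoolOp):
        ranks = [_eval_node(v, categories) for v in node.values]
        ranks = [r for r in ranks if r is not None]
        if not ranks:
            return None
        return min(ranks) if isinstance(node.op, ast.And) else max(ranks)
    if isinstance(node, ast.Expression):  # pragma: no cover
        return _eval_node(node.body, categories)
    raise GPRFormatError(f"unsupported GPR node {type(node).__name__}")


def evaluate_gpr_dependence(gpr: GPR | str, categories: Mapping[str, str]) -> dict[str, bool]:
    """Dependence flags derived from the effective category of a GPR."""
    eff = gpr_category(gpr, categories)
    return {
        "effective": eff,
        "depends_on_rare": eff == "rare",
        "depends_on_low": eff in ("low", "rare"),
        "high_only": eff == "high",
    }


# ---------------------------------------------------------------------------
# solving contract
# ---------------------------------------------------------------------------


@dataclass
class LinearConstraint:
    """``lb <= sum(coef * v_rxn) <= ub`` over reaction fluxes."""

    coefficients: dict[str, float]
    lb: float | None = None
    ub: float | None = None
    name: str = ""


def _flux_expression(model: cobra.Model, coefficients: Mapping[str, float]):
    expr = 0
    for rid, coef in coefficients.items():
        rxn = model.reactions.get_by_id(rid)
        expr = expr + coef * (rxn.forward_variable - rxn.reverse_variable)
    return expr


def _extract_fluxes(model: cobra.Model) -> pd.Series:
    vals = {r.id: r.forward_variable.primal - r.reverse_variable.primal for r in model.reactions}
    return pd.Series(vals, dtype=float)


def check_status(model: cobra.Model, stage: str) -> None:
    status = model.solver.status
    if status == "optimal":
        return
    if status in ("infeasible", "undefined"):
        raise InfeasibleProblemError(stage, status)
    if status == "unbounded":
        raise UnboundedProblemError(stage)
    raise MergeError(f"solver returned status {status!r} at stage '{stage}'")


def solve(
    model: cobra.Model,
    objective: Mapping[str, float],
    sense: str = "max",
    extra_constraints: Iterable[LinearConstraint] = (),
    stage: str = "solve",
) -> FluxDistribution:
    """Optimize a linear flux objective, optionally under extra constraints.

    Infeasibility and unboundedness surface as explicit exceptions, never
    as a silent zero vector.
    """
    if sense not in ("max", "min"):
        raise ConfigurationError(f"sense must be 'max' or 'min', got {sense!r}")
    with model:
        added = []
        for con in extra_constraints:
            c = model.problem.Constraint(
                _flux_expression(model, con.coefficients), lb=con.lb, ub=con.ub, name=con.name or None
            )
            added.append(c)
        if added:
            model.add_cons_vars(added)
        model.objective = model.problem.Objective(
            _flux_expression(model, objective), direction=sense
        )
        model.solver.optimize()
        check_status(model, stage)
        fluxes = _extract_fluxes(model)
        obj = model.solver.objective.value
    return FluxDistribution(fluxes=fluxes, objective_value=float(obj), status="optimal")


def fva(
    model: cobra.Model,
    reactions: Iterable[str] | None = None,
    extra_constraints: Iterable[LinearConstraint] = (),
) -> pd.DataFrame:
    """Tight per-reaction flux ranges under the model's constraints.

    Feasibility of the base problem is checked once, before any
    per-reaction solve.
    """
    rids = [r.id for r in model.reactions] if reactions is None else list(reactions)
    with model:
        added = []
        for con in extra_constraints:
            c = model.problem.Constraint(
                _flux_expression(model, con.coefficients), lb=con.lb, ub=con.ub, name=con.name or None
            )
            added.append(c)
        if added:
            model.add_cons_vars(added)
        model.objective = model.problem.Objective(0)
        model.solver.optimize()
        check_status(model, "fva-base")
        rows = {}
        for rid in rids:
            rxn = model.reactions.get_by_id(rid)
            expr = rxn.forward_variable - rxn.reverse_variable
            bounds = []
            for direction in ("min", "max"):
                model.objective = model.problem.Objective(expr, direction=direction)
                model.solver.optimize()
                check_status(model, f"fva:{rid}:{direction}")
                bounds.append(float(model.solver.objective.value))
            rows[rid] = {"minimum": bounds[0], "maximum": bounds[1]}
    return pd.DataFrame.from_dict(rows, orient="index").loc[rids]
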