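"""Gene-centered expression integration (iMAT++).

The MILP activates reactions of highly expressed genes (crediting each
gene at most once, however many reactions it maps to), blocks reactions
depending on rarely expressed genes where possible, then minimizes flux
through low/rare-dependent reactions and total flux (parsimonious step),
yielding the preliminary flux distribution (PFD).  Latent reactions —
zero-flux reactions of highly expressed genes whose reactants are active
— are then iteratively forced, and the final minimal-flux vector is the
optimal flux distribution (OFD).

Each stage's optimum is frozen as a constraint for all later stages:

    max Z_fit   -> Z_fit = Z_fit_max
    min Z_low   -> Z_low <= Z_low_min + delta_low        (delta_low = 1e-5)
    min Z_total -> Z_total <= Z_total_min * (1 + 0.05)   (PFD here)
    repeat {find latent; max Z_latent -> freeze; re-min Z_total} until
    no new latent reaction appears (OFD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd

from .core import (
    BIG_M,
    CAPACITY_TOL,
    FLUX_ZERO,
    ConfigurationError,
    FluxDistribution,
    MergeError,
    check_status,
    fva,
    gpr_category,
)
from .dual_tissue import DualTissueModel

__all__ = [
    "ImatConfig",
    "ThresholdTable",
    "compute_flux_thresholds",
    "effective_categories",
    "find_latent",
    "Imat",
    "ImatResults",
    "run_imatpp",
]


@dataclass
class ImatConfig:
    eps_default: float = 0.01
    delta_low: float = 1e-5
    delta_total_frac: float = 0.05
    max_latent_iterations: int = 20
    big_m: float = BIG_M
    flux_zero: float = FLUX_ZERO
    active_tol: float = 1e-6

    def __post_init__(self):
        for name in ("eps_default", "delta_low", "delta_total_frac"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


class ThresholdTable:
    """Per-reaction, per-direction minimum significant flux (epsilon)."""

    def __init__(self, table: pd.DataFrame):
        # columns: fwd, rev; index: reaction ids
        self.table = table

    def eps(self, rid: str, direction: str) -> float:
        if rid not in self.table.index:
            return 0.0
        return float(self.table.loc[rid, direction])

    @classmethod
    def uniform(cls, model: cobra.Model, eps: float = 0.01) -> "ThresholdTable":
        rows = {
            r.id: {
                "fwd": eps if r.upper_bound > 0 else 0.0,
                "rev": eps if r.lower_bound < 0 else 0.0,
            }
            for r in model.reactions
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index"))


def compute_flux_thresholds(
    model: cobra.Model | DualTissueModel,
    config: ImatConfig | None = None,
    bacterial_unit: float = 1.0,
    nutrient_cap_frac: float = 0.01,
) -> ThresholdTable:
    """FVA-derived epsilon: half the maximal capacity per direction, capped
    at the default 0.01; blocked directions get epsilon 0 (and are never
    forced).

    For a dual-tissue model the FVA is run with bacterial intake fixed at
    one unit and each side/storage uptake capped at 1% of the bacterial
    intake by mass, mirroring the scaling convention used to define
    significant flux.
    """
    config = config or ImatConfig()
    if isinstance(model, DualTissueModel):
        dual = model
        m = dual.model
        with m:
            if dual.bacterial_uptake is not None:
                bac = m.reactions.get_by_id(dual.bacterial_uptake)
                bac_mass = next(iter(bac.metabolites)).annotation.get("mass_g_per_mmol", 1.0)
                bac.bounds = (bacterial_unit, bacterial_unit)
                for rid in dual.lumen_exchange.values():
                    rxn = m.reactions.get_by_id(rid)
                    if rxn.annotation.get("nutrient_role") in ("side", "storage"):
                        mass = next(iter(rxn.metabolites)).annotation.get("mass_g_per_mmol")
                        if mass:
                            cap = nutrient_cap_frac * bac_mass * bacterial_unit / mass
                            rxn.upper_bound = min(rxn.upper_bound, cap)
            ranges = fva(m)
    else:
        ranges = fva(model)
    fwd = ranges["maximum"].clip(lower=0.0)
    rev = (-ranges["minimum"]).clip(lower=0.0)

    def eps_of(cap: pd.Series) -> pd.Series:
        eps = np.minimum(config.eps_default, cap / 2.0)
        eps[cap <= CAPACITY_TOL] = 0.0
        return eps

    return ThresholdTable(pd.DataFrame({"fwd": eps_of(fwd), "rev": eps_of(rev)}))


def effective_categories(
    model: cobra.Model,
    categories: Mapping[str, str],
    intestine_categories: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Effective expression category per gene-associated reaction.

    Reactions tagged with tissue compartment I or L are judged by the
    intestine categories when those are supplied; in that (non-intestine)
    integration mode only their low/rare outcomes constrain the fit —
    highly expressed intestine genes are ignored, so an effective "high"
    or "moderate" is masked out.
    """
    missing = sorted(
        g.id
        for g in model.genes
        if g.id not in categories
        and not (intestine_categories is not None and g.id in intestine_categories)
    )
    if missing and intestine_categories is None:
        raise ConfigurationError(f"genes missing from category table: {missing}")
    out: dict[str, str] = {}
    for rxn in model.reactions:
        if not rxn.gene_reaction_rule:
            continue
        compartment = rxn.annotation.get("tissue_compartment")
        if intestine_categories is not None and compartment in ("I", "L"):
            eff = gpr_category(rxn.gpr, intestine_categories)
            if eff in ("low", "rare"):
                out[rxn.id] = eff
        else:
            out[rxn.id] = gpr_category(rxn.gpr, categories)
    return {k: v for k, v in out.items() if v is not None}


def find_latent(
    model: cobra.Model,
    fluxes: pd.Series,
    effective: Mapping[str, str],
    thresholds: ThresholdTable,
    exclude: Sequence[tuple[str, str]] = (),
    active_tol: float = 1e-6,
    flux_zero: float = FLUX_ZERO,
) -> list[tuple[str, str]]:
    """Zero-flux reaction-directions of highly expressed genes whose
    reactants are all active in the given flux state.

    A metabolite is active when the product sum of |coefficient x flux|
    over its reactions is nonzero; reversible reactions are assessed per
    direction (reactants of the reverse direction are the products).
    """
    excluded = set(exclude)
    activity: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        v = abs(float(fluxes.get(rxn.id, 0.0)))
        if v <= flux_zero:
            continue
        for met, coef in rxn.metabolites.items():
            activity[met.id] += abs(coef) * v
    latent: list[tuple[str, str]] = []
    for rid, eff in effective.items():
        if eff != "high":
            continue
        if abs(float(fluxes.get(rid, 0.0))) > flux_zero:
            continue
        rxn = model.reactions.get_by_id(rid)
        for direction, open_dir, sign in (
            ("fwd", rxn.upper_bound > 0, -1),
            ("rev", rxn.lower_bound < 0, +1),
        ):
            if not open_dir or (rid, direction) in excluded:
                continue
            if thresholds.eps(rid, direction) <= 0:
                continue
            reactants = [m for m, c in rxn.metabolites.items() if sign * c > 0]
            if reactants and all(activity[m.id] > active_tol for m in reactants):
                latent.append((rid, direction))
    return latent


@dataclass
class ImatResults:
    """Fit output: flux vectors, the frozen optima that define the fitting
    space, and the solved model carrying those constraints (consumed by
    the network-labelling FVA)."""

    pfd: FluxDistribution
    ofd: FluxDistribution
    z_fit_max: float
    z_low_min: float
    z_total_min: float
    z_total_final: float
    z_latent: list[float]
    latent_forced: list[tuple[str, str]]
    r_on: list[str]
    r_off: list[str]
    low_set: list[str]
    g_on: list[str]
    n_latent_iterations: int
    frozen_model: cobra.Model = field(repr=False)
    thresholds: ThresholdTable = field(repr=False)
    config: ImatConfig = field(repr=False)

    def summary(self) -> str:
        lines = [
            "iMAT++ integration results",
            "=" * 40,
            f"{'R_ON (high-only reactions)':35s}{len(self.r_on):>5d}",
            f"{'R_OFF (rare-dependent)':35s}{len(self.r_off):>5d}",
            f"{'low/rare flux-minimized set':35s}{len(self.low_set):>5d}",
            f"{'G_ON (high genes)':35s}{len(self.g_on):>5d}",
            "-" * 40,
            f"{'Z_fit_max':25s}{self.z_fit_max:>15.6f}",
            f"{'Z_low_min':25s}{self.z_low_min:>15.6f}",
            f"{'Z_total_min (PFD)':25s}{self.z_total_min:>15.6f}",
            f"{'Z_total (OFD)':25s}{self.z_total_final:>15.6f}",
            f"{'latent iterations':25s}{self.n_latent_iterations:>15d}",
            f"{'latent forced':25s}{len(self.latent_forced):>15d}",
            f"{'OFD active reactions':25s}{len(self.ofd.active()):>15d}",
        ]
        return "\n".join(lines)

    def state_dict(self) -> dict:
        return {
            "z_fit_max": self.z_fit_max,
            "z_low_min": self.z_low_min,
            "z_total_min": self.z_total_min,
            "z_total_final": self.z_total_final,
            "z_latent": list(self.z_latent),
            "latent_forced": [list(t) for t in self.latent_forced],
            "n_latent_iterations": self.n_latent_iterations,
            "r_on": list(self.r_on),
            "r_off": list(self.r_off),
            "g_on": list(self.g_on),
        }


class Imat:
    """iMAT++ problem bound to a model and a categorized expression column.

    Parameters
    ----------
    model:
        A classified single-compartment model or a :class:`DualTissueModel`
        (nutrient policy applied by the caller).
    categories:
        gene -> category for the target context.
    intestine_categories:
        When integrating a non-intestine context of a dual model, the
        intestine's gene -> category map; only its low/rare entries
        constrain I/L reactions.
    """

    def __init__(
        self,
        model: cobra.Model | DualTissueModel,
        categories: Mapping[str, str],
        intestine_categories: Mapping[str, str] | None = None,
        thresholds: ThresholdTable | None = None,
        config: ImatConfig | None = None,
    ):
        self.source = model
        self.model = model.model if isinstance(model, DualTissueModel) else model
        self.categories = dict(categories)
        self.intestine_categories = (
            dict(intestine_categories) if intestine_categories is not None else None
        )
        self.config = config or ImatConfig()
        self.thresholds = thresholds or ThresholdTable.uniform(self.model, self.config.eps_default)
        self.effective = effective_categories(
            self.model, self.categories, self.intestine_categories
        )

    # -- MILP construction -------------------------------------------------

    def _build(self, m: cobra.Model):
        cfg = self.config
        interface = m.problem
        M = cfg.big_m
        r_off = sorted(r for r, e in self.effective.items() if e == "rare")
        low_set = sorted(r for r, e in self.effective.items() if e in ("low", "rare"))
        r_on: list[str] = []
        y_off = {}
        y_on: dict[tuple[str, str], object] = {}
        cons = []
        for rid in r_off:
            rxn = m.reactions.get_by_id(rid)
            y = interface.Variable(f"yoff_{rid}", type="binary")
            cons.append(
                interface.Constraint(
                    rxn.forward_variable + rxn.reverse_variable + M * y, ub=M, name=f"off_{rid}"
                )
            )
            y_off[rid] = y
        for rid, eff in self.effective.items():
            if eff != "high":
                continue
            rxn = m.reactions.get_by_id(rid)
            eps_f = self.thresholds.eps(rid, "fwd")
            eps_r = self.thresholds.eps(rid, "rev")
            flux = rxn.forward_variable - rxn.reverse_variable
            if rxn.upper_bound > 0 and eps_f > 0:
                y = interface.Variable(f"yon_f_{rid}", type="binary")
                cons.append(
                    interface.Constraint(flux - M * y, lb=eps_f - M, name=f"on_f_{rid}")
                )
                y_on[(rid, "fwd")] = y
            if rxn.lower_bound < 0 and eps_r > 0:
                y = interface.Variable(f"yon_r_{rid}", type="binary")
                cons.append(
                    interface.Constraint(-flux - M * y, lb=eps_r - M, name=f"on_r_{rid}")
                )
                y_on[(rid, "rev")] = y
            if (rid, "fwd") in y_on and (rid, "rev") in y_on:
                cons.append(
                    interface.Constraint(
                        y_on[(rid, "fwd")] + y_on[(rid, "rev")], ub=1, name=f"dir_{rid}"
                    )
                )
            if (rid, "fwd") in y_on or (rid, "rev") in y_on:
                r_on.append(rid)
        r_on = sorted(set(r_on))
        # gene variables: credit each high gene once, however many of its
        # reactions carry flux
        g_on: list[str] = []
        z = {}
        target_cats = self.categories
        for gene in sorted(g.id for g in m.genes):
            if target_cats.get(gene) != "high":
                continue
            assoc = [
                y
                for (rid, _d), y in y_on.items()
                if gene in {g.id for g in m.reactions.get_by_id(rid).genes}
            ]
            if not assoc:
                continue
            zv = interface.Variable(f"z_{gene}", type="integer", lb=0, ub=1)
            cons.append(interface.Constraint(sum(assoc) - zv, lb=0, name=f"gene_{gene}"))
            z[gene] = zv
            g_on.append(gene)
        m.add_cons_vars(list(y_off.values()) + list(y_on.values()) + list(z.values()) + cons)
        return r_off, r_on, low_set, g_on, y_off, y_on, z

    @staticmethod
    def _optimize(m: cobra.Model, expr, direction: str, stage: str) -> float:
        m.objective = m.problem.Objective(expr, direction=direction)
        m.solver.optimize()
        check_status(m, stage)
        return float(m.solver.objective.value)

    @staticmethod
    def _fluxes(m: cobra.Model) -> pd.Series:
        return pd.Series(
            {r.id: r.forward_variable.primal - r.reverse_variable.primal for r in m.reactions},
            dtype=float,
        )

    # -- staged fit --------------------------------------------------------

    def fit(self) -> ImatResults:
        cfg = self.config
        m = self.model.copy()
        interface = m.problem
        r_off, r_on, low_set, g_on, y_off, y_on, z = self._build(m)

        abs_flux = {
            r.id: r.forward_variable + r.reverse_variable for r in m.reactions
        }
        total_expr = sum(abs_flux.values())

        # stage 1: fit the categories
        fit_terms = list(z.values()) + list(y_off.values())
        if fit_terms:
            fit_expr = sum(fit_terms)
            z_fit_max = self._optimize(m, fit_expr, "max", "fit")
            z_fit_max = float(round(z_fit_max))
            m.add_cons_vars(
                [interface.Constraint(fit_expr, lb=z_fit_max - 1e-6, name="freeze_fit")]
            )
        else:
            z_fit_max = 0.0

        # stage 2: minimal flux through low/rare-dependent reactions
        if low_set:
            low_expr = sum(abs_flux[rid] for rid in low_set)
            z_low_min = self._optimize(m, low_expr, "min", "low-flux-min")
            m.add_cons_vars(
                [
                    interface.Constraint(
                        low_expr, ub=z_low_min + cfg.delta_low, name="freeze_low"
                    )
                ]
            )
        else:
            z_low_min = 0.0

        # stage 3: parsimonious total-flux minimization -> PFD
        z_total_min = self._optimize(m, total_expr, "min", "total-flux-min")
        pfd_fluxes = self._fluxes(m)
        total_cap = interface.Constraint(
            total_expr, ub=z_total_min * (1.0 + cfg.delta_total_frac), name="cap_total"
        )
        m.add_cons_vars([total_cap])

        # latent iteration -> OFD
        current = pfd_fluxes
        z_total_final = z_total_min
        z_latent: list[float] = []
        forced: list[tuple[str, str]] = []
        considered: set[tuple[str, str]] = set()
        iterations = 0
        while True:
            latent = [
                d
                for d in find_latent(
                    m,
                    current,
                    self.effective,
                    self.thresholds,
                    exclude=considered,
                    active_tol=cfg.active_tol,
                    flux_zero=cfg.flux_zero,
                )
                if d in y_on
            ]
            if not latent:
                break
            iterations += 1
            if iterations > cfg.max_latent_iterations:
                raise MergeError(
                    f"latent iteration cap ({cfg.max_latent_iterations}) exceeded; "
                    f"last latent set: {latent}"
                )
            considered.update(latent)
            latent_expr = sum(y_on[d] for d in latent)
            zl = self._optimize(m, latent_expr, "max", f"latent-fit-{iterations}")
            zl = float(round(zl))
            m.add_cons_vars(
                [
                    interface.Constraint(
                        latent_expr, lb=zl - 1e-6, name=f"freeze_latent_{iterations}"
                    )
                ]
            )
            z_latent.append(zl)
            forced.extend(latent)
            # re-minimize and re-freeze the total-flux cap
            z_total_final = self._optimize(
                m, total_expr, "min", f"latent-minflux-{iterations}"
            )
            total_cap.ub = z_total_final * (1.0 + cfg.delta_total_frac)
            current = self._fluxes(m)

        ofd_fluxes = current
        return ImatResults(
            pfd=FluxDistribution(pfd_fluxes, objective_value=z_total_min),
            ofd=FluxDistribution(ofd_fluxes, objective_value=z_total_final),
            z_fit_max=z_fit_max,
            z_low_min=z_low_min,
            z_total_min=z_total_min,
            z_total_final=z_total_final,
            z_latent=z_latent,
            latent_forced=forced,
            r_on=r_on,
            r_off=r_off,
            low_set=low_set,
            g_on=g_on,
            n_latent_iterations=iterations,
            frozen_model=m,
            thresholds=self.thresholds,
            config=cfg,
        )


def run_imatpp(
    model: cobra.Model | DualTissueModel,
    categories: Mapping[str, str],
    intestine_categories: Mapping[str, str] | None = None,
    thresholds: ThresholdTable | None = None,
    config: ImatConfig | None = None,
) -> ImatResults:
    """Functional wrapper around :class:`Imat`."""
    return Imat(model, categories, intestine_categories, thresholds, config).fit()
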