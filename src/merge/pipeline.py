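"""End-to-end orchestration: categorize -> integrate (x7) -> combine ->
intestine -> label networks -> FPA -> site calls.

Stage outputs are plain TSV/JSON artifacts under one output directory,
described by a manifest (input hashes, parameters, package version).  A
re-run with an unchanged manifest reuses finished stage outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, load_model, model_census
from .dual_tissue import (
    NutrientPolicy,
    apply_nutrient_policy,
    build_dual_tissue,
    combine_tissue_exchanges,
    prepare_intestine_model,
)
from .expression import categorize, read_tpm, write_categories
from .fpa import FPAConfig, FluxPotential
from .imat import Imat, ImatConfig, ThresholdTable, compute_flux_thresholds
from .network import apply_intestine_rule, classify_reactions, network_reaction_set
from .sites import SiteCallParams, assign_sites

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    model_reactions: str
    model_metabolites: str
    expression: str
    out_dir: str
    contexts: list[str]
    intestine: str
    weights: dict[str, float] | None = None
    metabolite_targets: list[str] | None = None
    policy: NutrientPolicy = field(default_factory=NutrientPolicy)
    imat: ImatConfig = field(default_factory=ImatConfig)
    fpa: FPAConfig = field(default_factory=FPAConfig)
    sites: SiteCallParams = field(default_factory=SiteCallParams)
    fpa_hubs: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.contexts.count(self.intestine) != 1:
            raise ConfigurationError(
                f"intestine context {self.intestine!r} must appear exactly once in contexts"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (
            ("policy", NutrientPolicy),
            ("imat", ImatConfig),
            ("fpa", FPAConfig),
            ("sites", SiteCallParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    def params_dict(self) -> dict:
        raw = asdict(self)
        raw.pop("out_dir")
        return raw


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _manifest(config: PipelineConfig) -> dict:
    return {
        "version": __version__,
        "inputs": {
            "model_reactions": _hash_file(config.model_reactions),
            "model_metabolites": _hash_file(config.model_metabolites),
            "expression": _hash_file(config.expression),
        },
        "parameters": json.loads(json.dumps(config.params_dict(), default=str)),
    }


class _Stages:
    """Stage bookkeeping: a stage is skipped when its artifacts exist and
    the stored manifest matches the current one."""

    def __init__(self, out: Path, manifest: dict, resume: bool):
        self.out = out
        self.manifest = manifest
        mpath = out / "manifest.json"
        self.reusable = False
        if resume and mpath.exists():
            stored = json.loads(mpath.read_text())
            self.reusable = stored.get("inputs") == manifest["inputs"] and stored.get(
                "parameters"
            ) == manifest["parameters"]

    def fresh(self, *artifacts: str) -> bool:
        if not self.reusable:
            return True
        return not all((self.out / a).exists() for a in artifacts)


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    stages = _Stages(out, manifest, resume)
    log: list[dict] = []

    def note(stage, **info):
        entry = {"stage": stage, **info}
        log.append(entry)

    model = load_model(config.model_reactions, config.model_metabolites)
    census = model_census(model)
    note("load_model", **census)

    tpm = read_tpm(config.expression)
    missing = [c for c in config.contexts if c not in tpm.columns]
    if missing:
        raise ConfigurationError(f"expression matrix lacks contexts: {missing}")
    tpm = tpm[config.contexts]

    # -- categorize --------------------------------------------------------
    cats_path = out / "categories.tsv"
    if stages.fresh("categories.tsv"):
        cats, thresholds, fit = categorize(tpm, seed=config.seed)
        write_categories(cats, cats_path, thresholds)
    else:
        from .expression import read_categories

        cats = read_categories(cats_path)
    model_genes = [g.id for g in model.genes]
    absent = sorted(set(model_genes) - set(cats.index))
    if absent:
        raise ConfigurationError(f"expression matrix lacks model genes: {absent}")
    note("categorize", genes=len(cats))

    # -- dual model and thresholds ----------------------------------------
    dual = build_dual_tissue(model, config.policy.free_exchange_base_ids)
    apply_nutrient_policy(dual, config.policy)
    eps = compute_flux_thresholds(dual, config.imat)
    eps.table.to_csv(out / "thresholds_eps.tsv", sep="\t")
    note("flux_thresholds", reactions=len(eps.table))

    non_intestine = [c for c in config.contexts if c != config.intestine]
    cat_of = {ctx: cats[ctx].to_dict() for ctx in config.contexts}

    # -- six non-intestine integrations -----------------------------------
    results = {}
    labels = {}
    for ctx in non_intestine:
        res = Imat(
            dual,
            cat_of[ctx],
            intestine_categories=cat_of[config.intestine],
            thresholds=eps,
            config=config.imat,
        ).fit()
        results[ctx] = res
        res.ofd.fluxes.rename("flux").to_csv(out / f"ofd_{ctx}.tsv", sep="\t")
        (out / f"imat_state_{ctx}.json").write_text(json.dumps(res.state_dict(), indent=1))
        labels[ctx] = classify_reactions(res, seed=config.seed)
        labels[ctx].to_csv(out / f"labels_{ctx}.tsv", sep="\t", index=False)
        note("integrate", context=ctx, **{k: res.state_dict()[k] for k in ("z_fit_max", "z_total_min")})

    # -- combine and intestine integration --------------------------------
    if config.weights is None:
        weights = {c: 1.0 / len(non_intestine) for c in non_intestine}
    else:
        total = sum(config.weights[c] for c in non_intestine)
        weights = {c: config.weights[c] / total for c in non_intestine}
    demands = combine_tissue_exchanges(dual, {c: r.ofd for c, r in results.items()}, weights)
    demands.rename("flux").to_csv(out / "demands.tsv", sep="\t")
    note("combine", metabolites=int((demands.abs() > 1e-9).sum()))

    intestine_dual = prepare_intestine_model(dual, demands)
    eps_intestine = ThresholdTable(eps.table.copy())
    x_ids = [r.id for r in intestine_dual.reactions_in("X") if r.id in eps_intestine.table.index]
    eps_intestine.table.loc[x_ids] = 0.0  # X is blocked in this run
    res_int = Imat(
        intestine_dual,
        cat_of[config.intestine],
        thresholds=eps_intestine,
        config=config.imat,
    ).fit()
    results[config.intestine] = res_int
    res_int.ofd.fluxes.rename("flux").to_csv(out / f"ofd_{config.intestine}.tsv", sep="\t")
    (out / f"imat_state_{config.intestine}.json").write_text(
        json.dumps(res_int.state_dict(), indent=1)
    )
    labels[config.intestine] = classify_reactions(res_int, seed=config.seed)
    note("integrate_intestine", z_fit_max=res_int.z_fit_max)

    # -- network labels ----------------------------------------------------
    labels[config.intestine] = apply_intestine_rule(labels, config.intestine)
    labels[config.intestine].to_csv(
        out / f"labels_{config.intestine}.tsv", sep="\t", index=False
    )
    merged = pd.concat(
        [df.assign(context=ctx) for ctx, df in labels.items()], ignore_index=True
    )
    merged.to_csv(out / "labels_all.tsv", sep="\t", index=False)
    note("label_networks", rows=len(merged))

    # -- flux potential analysis ------------------------------------------
    networks = {ctx: network_reaction_set(df) for ctx, df in labels.items()}
    fp = FluxPotential(
        dual.model,
        tpm,
        networks=networks,
        config=config.fpa,
        contexts=config.contexts,
        intestine_context=config.intestine,
        hubs=config.fpa_hubs,
    )
    rfp_rows = {}
    support_rows = {}
    from .core import reaction_class

    internal_sources = [
        rid
        for rid, _copy in dual.i_copy.items()
        if rid in dual.x_copy and reaction_class(model.reactions.get_by_id(rid)) == "internal"
    ]
    for rid in sorted(internal_sources):
        i_id, x_id = dual.i_copy[rid], dual.x_copy[rid]
        for direction in ("fwd", "rev"):
            try:
                fp.split_map.split_id(i_id, direction)
                fp.split_map.split_id(x_id, direction)
            except KeyError:
                continue
            # the X copy scores the six non-intestine tissues, the I copy
            # scores the intestine; each is normalized by its own super
            res_x = fp.reaction((x_id, direction), contexts=non_intestine)
            res_i = fp.reaction((i_id, direction), contexts=[config.intestine])
            profile = {}
            support = {}
            for ctx in config.contexts:
                res, copy = (
                    (res_i, i_id) if ctx == config.intestine else (res_x, x_id)
                )
                profile[ctx] = res.rfp[ctx] if not res.super_zero else float("nan")
                flux = results[ctx].ofd.fluxes.get(copy, 0.0)
                support[ctx] = (flux if direction == "fwd" else -flux) > 1e-6
            rfp_rows[f"{rid}_{direction[0]}"] = profile
            support_rows[f"{rid}_{direction[0]}"] = support
    rfp_reactions = pd.DataFrame(rfp_rows).T.reindex(columns=config.contexts)
    rfp_reactions.rename_axis("target").to_csv(out / "rfp_reactions.tsv", sep="\t")
    ofd_support = pd.DataFrame(support_rows).T.reindex(columns=config.contexts)
    note("fpa_reactions", targets=len(rfp_reactions))

    met_targets = config.metabolite_targets
    if met_targets is None:
        # transportable metabolites, assessed in the cytosol of each tissue
        met_targets = sorted(
            {m.id.split("[")[0] for m in dual.model.metabolites if m.compartment == "e"}
        )
    rfp_met_rows = {}
    for met in met_targets:
        for mode in ("production", "degradation"):
            profile = {}
            try:
                res_x = fp.metabolite(
                    met, mode=mode, contexts=non_intestine, compartment_suffix="c_X"
                )
                res_i = fp.metabolite(
                    met, mode=mode, contexts=[config.intestine], compartment_suffix="c_I"
                )
            except ConfigurationError:
                continue
            for ctx in config.contexts:
                res = res_i if ctx == config.intestine else res_x
                profile[ctx] = res.rfp[ctx] if not res.super_zero else float("nan")
            rfp_met_rows[f"{met}:{mode}"] = profile
    rfp_metabolites = pd.DataFrame(rfp_met_rows).T.reindex(columns=config.contexts)
    rfp_metabolites.rename_axis("target").to_csv(out / "rfp_metabolites.tsv", sep="\t")
    note("fpa_metabolites", targets=len(rfp_metabolites))

    # -- site calls --------------------------------------------------------
    calls = assign_sites(
        rfp_reactions.dropna(), ofd_support.loc[rfp_reactions.dropna().index], config.sites
    )
    calls.to_csv(out / "site_calls_reactions.tsv", sep="\t")
    if len(rfp_metabolites):
        met_calls = assign_sites(
            rfp_metabolites.dropna(), None, config.sites, level="metabolite"
        )
        met_calls.to_csv(out / "site_calls_metabolites.tsv", sep="\t")
    note("site_calls", enriched=int(calls["enriched"].sum()))

    manifest["stages"] = log
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
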