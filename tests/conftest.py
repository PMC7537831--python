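import pandas as pd
import pytest

from merge.core import write_model_tables
from merge.fixtures import CONTEXTS, make_toy, synth_expression
from merge.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def gene_centered():
    return make_toy("gene_centered", seed=1)


@pytest.fixture(scope="session")
def shunt():
    return make_toy("shared_gene_shunt", seed=1)


@pytest.fixture(scope="session")
def chain():
    return make_toy("fpa_chain", seed=1, k=3)


@pytest.fixture(scope="session")
def dual_system():
    return make_toy("dual_system", seed=1)


@pytest.fixture(scope="session")
def pipeline_inputs(tmp_path_factory, dual_system):
    """Model tables plus an expression matrix (synthetic bimodal background
    so threshold fitting has a realistic gene population, with the model
    genes' designed profiles appended)."""
    out = tmp_path_factory.mktemp("pipeline_inputs")
    background, _ = synth_expression(n_genes=2000, seed=11)
    tpm = pd.concat([background, dual_system.tpm])
    write_model_tables(dual_system.model, out)
    tpm.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
    return out


def make_pipeline_config(inputs, out_dir, **overrides):
    base = dict(
        model_reactions=str(inputs / "reactions.tsv"),
        model_metabolites=str(inputs / "metabolites.tsv"),
        expression=str(inputs / "expression.tsv"),
        out_dir=str(out_dir),
        contexts=list(CONTEXTS),
        intestine="intestine",
        seed=1,
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, pipeline_inputs):
    out = tmp_path_factory.mktemp("pipeline_out")
    config = make_pipeline_config(pipeline_inputs, out)
    manifest = run_pipeline(config)
    return out, config, manifest
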