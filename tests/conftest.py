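import json

import pytest

from redbridge.pipeline import PipelineConfig, run_pipeline
from redbridge.registry import MockRegistry
from redbridge.synthetic import cargo_like, generate

COHORT_SEED = 7


@pytest.fixture(scope="session")
def ref_config() -> PipelineConfig:
    return PipelineConfig.reference()


@pytest.fixture(scope="session")
def mapping(ref_config):
    return ref_config.mapping


@pytest.fixture(scope="session")
def terms(ref_config):
    return ref_config.terms


@pytest.fixture(scope="session")
def cargo_run(tmp_path_factory, ref_config):
    """One full pipeline run on the 1000-patient validation cohort, shared by
    the end-to-end tests: export + sidecar truth + live registry state."""
    out = tmp_path_factory.mktemp("cargo")
    export, sidecar = generate(cargo_like(COHORT_SEED), out)
    truth = json.loads(sidecar.read_text(encoding="utf-8"))
    registry = MockRegistry()
    result = run_pipeline(export, ref_config, registry=registry,
                          report_dir=out / "report")
    return {
        "export": export,
        "truth": truth,
        "registry": registry,
        "result": result,
        "config": ref_config,
        "report_dir": out / "report",
    }
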