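import pandas as pd
import pytest

from ehrqc import (PipelineConfig, SimConfig, build_macrovisits,
                   generate_bundle, index_events, run_pipeline, select_cohort)


@pytest.fixture(scope="session")
def small_sim():
    """A small 3-site bundle with all default pathologies planted."""
    cfg = SimConfig(n_sites=3, patients_per_site=250, seed=7)
    bundle, gt = generate_bundle(cfg)
    return cfg, bundle, gt


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    cfg, bundle, gt = small_sim
    mv = build_macrovisits(bundle.visit_occurrence)
    cohort = select_cohort(bundle, mv, index_events(gt))
    return mv, cohort


@pytest.fixture(scope="session")
def pipeline_run(small_sim, tmp_path_factory):
    cfg, bundle, gt = small_sim
    out_dir = tmp_path_factory.mktemp("run")
    pc = PipelineConfig(bundle_path="unused", out_dir=str(out_dir), seed=7)
    return run_pipeline(pc, bundle=bundle, index_events=index_events(gt))


def day(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)
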