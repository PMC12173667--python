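import numpy as np
import pandas as pd
import pytest

from topform import filtering, pipeline, synth


@pytest.fixture(scope="session")
def small_reference():
    return synth.make_reference_db(20, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return synth.make_cohort(24, 3, seed=8)


@pytest.fixture(scope="session")
def small_study(small_reference, small_cohort):
    """A compact default-condition study used across module tests."""
    return synth.simulate_study(small_reference, small_cohort, seed=9)


@pytest.fixture(scope="session")
def small_true_prsms(small_study):
    """True-match target PrSMs of the small study (identification layer)."""
    df = small_study.prsms
    return df[(~df["is_decoy"]) & (df["truth_id"] >= 0)].reset_index(drop=True)


@pytest.fixture(scope="session")
def full_pipeline(tmp_path_factory):
    """One full-scale end-to-end run shared by pipeline-level tests."""
    outdir = str(tmp_path_factory.mktemp("pipeline"))
    cfg = pipeline.PipelineConfig(
        outdir=outdir, n_genes=300, n_samples=36, n_batches=3, seed=5
    )
    manifest = pipeline.run_pipeline(cfg)
    return cfg, manifest


def make_quant_matrix(values, batch=None, extra=None, mode="intensity"):
    """Helper: wrap an array into a QuantMatrix with minimal metadata."""
    from topform.types import QuantMatrix

    values = np.asarray(values, dtype=float if mode == "intensity" else int)
    cols = [f"S{i:03d}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"sample_id": cols})
    meta["batch"] = batch if batch is not None else 1
    if extra:
        for k, v in extra.items():
            meta[k] = v
    meta = meta.set_index("sample_id", drop=False)
    vals = pd.DataFrame(values, columns=cols)
    proteo = pd.DataFrame(index=vals.index)
    return QuantMatrix(vals, meta, proteo, mode)
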