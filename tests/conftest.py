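import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ccam.preprocess import ExpressionMatrix, SampleAnnotation
from ccam.synthetic_fixtures import SyntheticConfig


def em(values, genes=None, samples=None, provenance="test") -> ExpressionMatrix:
    """Build a small ExpressionMatrix with auto-named ids."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, provenance)


def annotation(sample_ids, groups, batches=None, **clinical) -> SampleAnnotation:
    data = {"group": groups}
    if batches is not None:
        data["batch"] = batches
    data.update(clinical)
    return SampleAnnotation(
        pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    )


@pytest.fixture(scope="session")
def demo_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=20120101, n_disease_samples=60)


@pytest.fixture(scope="session")
def pipeline_artifacts(demo_cfg):
    from ccam.viz_cli.cli import run_pipeline

    return run_pipeline(demo_cfg)
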