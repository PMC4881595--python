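import numpy as np
import pandas as pd
import pytest

from xmeta.manifest_io import MCAO, SHAM, StudyExpression
from xmeta.preprocess import preprocess_collection
from xmeta.synthetic_data import SimulationConfig, simulate_collection


def make_study(values, groups, study_id="S1", level="gene", is_log2=True):
    """Build a StudyExpression from a plain nested list / array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = [f"G{i + 1}" for i in range(n_feat)]
    samples = [f"s{j + 1}" for j in range(n_samp)]
    return StudyExpression(
        study_id=study_id,
        values=pd.DataFrame(values, index=features, columns=samples),
        groups=pd.Series(list(groups), index=samples),
        level=level,
        is_log2=is_log2,
    )


@pytest.fixture(scope="session")
def small_collection():
    """Four small probe-level studies with 5% true DEGs of effect 2."""
    cfg = SimulationConfig(
        n_genes=300,
        k_studies=4,
        n_mcao=5,
        n_sham=5,
        frac_deg=0.05,
        delta=2.0,
        tau2=0.1,
        missing_rate=0.02,
        platform_dropout=0.05,
        probes_per_gene=2,
        seed=101,
    )
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_collection):
    studies, truth = small_collection
    preprocessed, genes = preprocess_collection(studies, probe_map=truth.probe_map)
    return preprocessed, genes, truth
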