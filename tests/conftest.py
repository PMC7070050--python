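import numpy as np
import pandas as pd
import pytest

from lineagespec import quantify, synthetic_data
from lineagespec.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study at seed 1 (shared, read-only)."""
    return synthetic_data.generate_bundle(synthetic_data.StudyDesign(seed=1))


@pytest.fixture(scope="session")
def pipeline_summary(tmp_path_factory):
    """One full pipeline run on the default synthetic config, seed 1."""
    out = tmp_path_factory.mktemp("pipeline")
    return run_all(PipelineConfig(outdir=str(out), seed=1))


@pytest.fixture(scope="session")
def noiseless_em():
    """Expression matrix holding the exact expected class profiles.

    One sample per cell type, FPKM equal to the canonical planted profile of
    each class (30 genes per maintained group, plus fate-class genes), for
    zero-noise recovery checks.
    """
    effect = synthetic_data.EffectConfig()
    profiles = synthetic_data.class_profiles(effect)
    rows, gene_ids, classes = [], [], []
    for cls in (*synthetic_data.ACL_GROUPS, *synthetic_data.BCL_GROUPS,
                *synthetic_data.FATE_CLASSES):
        for i in range(30):
            gene_ids.append(f"{cls}_{i:02d}")
            classes.append(cls)
            rows.append(profiles[cls])
    fpkm = pd.DataFrame(
        np.asarray(rows), index=gene_ids,
        columns=list(synthetic_data.CELL_TYPES),
    )
    samples = pd.DataFrame(
        {"cell_type": list(synthetic_data.CELL_TYPES),
         "replicate": [1] * len(synthetic_data.CELL_TYPES)},
        index=pd.Index(list(synthetic_data.CELL_TYPES), name="sample_id"),
    )
    em = quantify.ExpressionMatrix(fpkm=fpkm, samples=samples)
    truth = pd.Series(classes, index=pd.Index(gene_ids))
    return em, truth


def make_count_matrix(counts, lengths=None, cell_types=None):
    """Small CountMatrix helper for unit tests."""
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    else:
        lengths = pd.Series(lengths, index=counts.index)
    if cell_types is None:
        cell_types = ["A"] * counts.shape[1]
    samples = pd.DataFrame(
        {"cell_type": cell_types,
         "replicate": list(range(1, counts.shape[1] + 1))},
        index=counts.columns,
    )
    return quantify.CountMatrix(counts=counts, lengths=lengths,
                                samples=samples)
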