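import numpy as np
import pandas as pd
import pytest

from kinsig.io import ANNOTATION_COLUMNS, METADATA_COLUMNS, ExpressionMatrix


def toy_matrix(values: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    """Matrix with placeholder annotations from {cluster_id: row values}."""
    ann = pd.DataFrame(
        {
            "cluster_id": list(values),
            "chrom": "chr1",
            "start": 100,
            "end": 300,
            "strand": "+",
            "gene_id": [f"g_{cid}" for cid in values],
            "biotype": "protein_coding",
            "gene_length": 10_000,
        },
        columns=ANNOTATION_COLUMNS,
    ).set_index("cluster_id")
    vals = pd.DataFrame.from_dict(values, orient="index", columns=samples).astype(float)
    vals.index.name = "cluster_id"
    return ExpressionMatrix(ann, vals)


def toy_metadata(samples, times, replicates, mapped_tags=None) -> pd.DataFrame:
    if mapped_tags is None:
        mapped_tags = [1_000_000] * len(samples)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "treatment": "stim",
            "time_min": times,
            "replicate": replicates,
            "mapped_tags": mapped_tags,
        },
        columns=METADATA_COLUMNS,
    )


@pytest.fixture
def six_sample_design():
    """3 time points x 2 replicates."""
    samples = ["s1", "s2", "s3", "s4", "s5", "s6"]
    meta = toy_metadata(samples, [0, 0, 60, 60, 120, 120], [1, 2, 1, 2, 1, 2])
    return samples, meta
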