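import numpy as np
import pandas as pd
import pytest

from mwastools.mwas import MethylationMatrix, RelatednessMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_standardized_matrix(rng, n_probes, n_samples, prefix="cg"):
    """Random standardized probe x sample matrix with simple ids."""
    values = rng.standard_normal((n_probes, n_samples))
    values = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=1, keepdims=True
    )
    return MethylationMatrix(
        values,
        np.array([f"{prefix}{j:05d}" for j in range(n_probes)], dtype=object),
        np.array([f"S{i:05d}" for i in range(n_samples)], dtype=object),
        scale="standardized-M",
    )


def identity_kernel(sample_ids, kind="GRM"):
    n = len(sample_ids)
    return RelatednessMatrix(np.eye(n), np.asarray(sample_ids, dtype=object), kind=kind)


def make_annotation(probe_ids, spacing=200, per_chrom=None):
    m = len(probe_ids)
    per_chrom = per_chrom or m
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": [f"chr{1 + j // per_chrom}" for j in range(m)],
            "position": [1 + (j % per_chrom) * spacing for j in range(m)],
            "gene": [f"GENE{j % 10}" for j in range(m)],
            "on_450k": True,
            "on_epic": True,
            "is_smoking_proxy": False,
        }
    )
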