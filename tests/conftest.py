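import numpy as np
import pandas as pd
import pytest

from lncregnet.io_formats import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
)


@pytest.fixture
def small_design() -> SampleDesign:
    patients = [f"RA{i:03d}" for i in range(1, 6)]
    return SampleDesign(pd.DataFrame({
        "sample_id": [f"{p}_control" for p in patients]
                     + [f"{p}_treated" for p in patients],
        "patient_id": patients * 2,
        "condition": ["control"] * 5 + ["treated"] * 5,
    }))


def make_matrix(values, probe_ids=None, sample_ids=None, flags=None,
                scale_tag="log2") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"P{i}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(probe_ids=probe_ids, sample_ids=sample_ids,
                            values=values, flags=flags, scale_tag=scale_tag)


@pytest.fixture
def paired_matrix(small_design) -> ExpressionMatrix:
    """10-sample log2 matrix aligned with small_design's sample ids."""
    rng = np.random.default_rng(42)
    sample_ids = list(small_design.frame["sample_id"])
    values = rng.normal(8.0, 1.0, size=(20, 10))
    return make_matrix(values, sample_ids=sample_ids)


def make_annotation(rows) -> ProbeAnnotation:
    """rows: (probe_id, transcript_type, gene_symbol, chrom, start, end, strand)."""
    return ProbeAnnotation(pd.DataFrame(
        rows, columns=["probe_id", "transcript_type", "gene_symbol",
                       "chromosome", "start", "end", "strand"]))
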