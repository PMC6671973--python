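"""Log transform, quantile normalization and detection-flag filtering.

Pipeline order is fixed: log2 -> quantile normalize the full matrix ->
flag filter. Filtering after normalization matches common microarray
practice; the flag filter cannot change the normalization target because
normalization only looks at values, not flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, FormatError, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class FilterRule:
    """Keep probes that, in at least one condition, carry ``required_flag``
    in at least ``min_fraction_per_condition`` of that condition's samples."""

    required_flag: str = "P"
    min_fraction_per_condition: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction_per_condition <= 1.0:
            raise ValueError("min_fraction_per_condition must be in [0, 1]")
        if self.required_flag not in ("P", "A", "M"):
            raise ValueError(f"unknown flag {self.required_flag!r}")


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """value -> log2(value + offset). Requires raw scale and non-negative input."""
    if matrix.scale_tag != "raw":
        raise FormatError(f"log2_transform requires raw scale, got {matrix.scale_tag}")
    if np.any(matrix.values < 0):
        i, j = np.argwhere(matrix.values < 0)[0]
        raise FormatError(
            f"negative intensity at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    if offset < 0:
        raise ValueError("offset must be non-negative")
    with np.errstate(divide="ignore"):  # log2(0) -> -inf is the caller's choice
        transformed = np.log2(matrix.values + offset)
    return matrix.with_values(transformed, scale_tag="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization.

    Within each sample the k-th smallest value is replaced by the mean of
    the k-th smallest values across all samples; values tied within a sample
    receive the mean of the reference values at their tied ranks.
    """
    if matrix.scale_tag not in ("raw", "log2"):
        raise FormatError(
            f"quantile_normalize requires raw or log2 scale, got {matrix.scale_tag}"
        )
    if matrix.n_samples < 2:
        raise FormatError("quantile normalization needs at least 2 samples")
    values = matrix.values
    if np.isnan(values).any():
        raise FormatError("missing values are not supported")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # ties within the column share the mean of their ranks' reference values
        out[:, j] = pd.Series(mapped).groupby(col, sort=False).transform("mean").to_numpy()
    return matrix.with_values(out, scale_tag="normalized")


def filter_by_flags(matrix: ExpressionMatrix, design: SampleDesign,
                    rule: FilterRule | None = None) -> ExpressionMatrix:
    """Keep probes present (per `rule`) in at least one of the two conditions.

    Sample set and probe order are unchanged; the operation is idempotent.
    """
    if rule is None:
        rule = FilterRule()
    design.check_matrix(matrix)
    flags = matrix.effective_flags()
    keep = np.zeros(matrix.n_probes, dtype=bool)
    for condition in ("control", "treated"):
        sample_ids = list(design.samples_for(condition).values())
        cols = [matrix.sample_ids.index(s) for s in sample_ids]
        frac = (flags[:, cols] == rule.required_flag).mean(axis=1)
        keep |= frac >= rule.min_fraction_per_condition
    removed = int((~keep).sum())
    if removed:
        logger.info("flag filter removed %d of %d probes", removed, matrix.n_probes)
    return matrix.subset_probes(keep)


def preprocess(matrix: ExpressionMatrix, design: SampleDesign,
               rule: FilterRule | None = None, offset: float = 0.0,
               ) -> tuple[ExpressionMatrix, dict]:
    """Full preprocessing: log2 (if raw) -> quantile normalize -> flag filter.

    Returns the filtered normalized matrix and a report dict with probe
    counts before/after filtering.
    """
    if matrix.scale_tag == "raw":
        matrix = log2_transform(matrix, offset=offset)
    normalized = quantile_normalize(matrix)
    filtered = filter_by_flags(normalized, design, rule)
    report = {
        "probes_before_filter": normalized.n_probes,
        "probes_after_filter": filtered.n_probes,
        "samples": normalized.n_samples,
    }
    return filtered, report
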