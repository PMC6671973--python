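"""Paired differential expression on log2 intensities.

The test is the one-sample t-test applied to per-patient log2 differences
(treated minus control), which is exactly the paired t-test for this
design. Fold change is the anti-logged absolute mean log2 difference with
direction carried separately. Multiple testing uses Benjamini-Hochberg.

Zero-variance probes (all per-patient differences identical) cannot be
tested; they are flagged degenerate, carry NaN statistics and are excluded
from FDR correction and from selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, FormatError, ProbeAnnotation, SampleDesign

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "probe_id", "gene_symbol", "transcript_type", "mean_log2_diff",
    "fold_change", "direction", "t_statistic", "p_value", "q_value",
    "degenerate",
]


@dataclass
class ThresholdConfig:
    """Selection thresholds; boundary-inclusive (FC >= fc_min, P <= p_max)."""

    fc_min: float = 2.0
    p_max: float = 0.05
    use_q: bool = False
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_min < 1.0:
            raise ValueError("fc_min must be >= 1")
        for name in ("p_max", "q_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def paired_differences(matrix: ExpressionMatrix, design: SampleDesign,
                       ) -> tuple[list[str], np.ndarray]:
    """Per-probe, per-patient treated-minus-control log2 differences.

    Returns (ordered patient ids, probes x patients array).
    """
    design.check_matrix(matrix)
    patients = design.patients
    treated = design.samples_for("treated")
    control = design.samples_for("control")
    t_cols = [matrix.sample_ids.index(treated[p]) for p in patients]
    c_cols = [matrix.sample_ids.index(control[p]) for p in patients]
    diffs = matrix.values[:, t_cols] - matrix.values[:, c_cols]
    return patients, diffs


def t_test_on_differences(diffs: np.ndarray) -> pd.DataFrame:
    """Vectorized one-sample t-test of each row of `diffs` against zero.

    Columns: mean_log2_diff, t_statistic, p_value, degenerate.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[1]
    if n < 2:
        raise FormatError("paired t-test needs at least 2 patient pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame({
        "mean_log2_diff": mean,
        "t_statistic": t,
        "p_value": p,
        "degenerate": degenerate,
    })


def paired_t_test(matrix: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Paired t-test per probe; matrix must be log2-scale (or normalized)."""
    if matrix.scale_tag == "raw":
        raise FormatError("paired_t_test requires log2 or normalized values")
    _, diffs = paired_differences(matrix, design)
    out = t_test_on_differences(diffs)
    out.insert(0, "probe_id", matrix.probe_ids)
    n_degenerate = int(out["degenerate"].sum())
    if n_degenerate:
        logger.info("excluded %d zero-variance probes from testing", n_degenerate)
    return out


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) on the sorted vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~((p > 0.0) & (p <= 1.0))):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def differential_expression(matrix: ExpressionMatrix, design: SampleDesign,
                            annotation: ProbeAnnotation) -> pd.DataFrame:
    """Full per-probe differential table (see RESULT_COLUMNS).

    q-values are BH-adjusted across all non-degenerate probes jointly.
    """
    res = paired_t_test(matrix, design)
    ann = annotation.frame.set_index("probe_id")
    missing = [p for p in res["probe_id"] if p not in ann.index]
    if missing:
        raise FormatError(f"probes without annotation: {missing[:5]}")
    res["gene_symbol"] = [ann.at[p, "gene_symbol"] for p in res["probe_id"]]
    res["transcript_type"] = [ann.at[p, "transcript_type"] for p in res["probe_id"]]
    res["fold_change"] = 2.0 ** np.abs(res["mean_log2_diff"])
    res["direction"] = np.where(res["mean_log2_diff"] > 0, "up", "down")
    q = np.full(len(res), np.nan)
    ok = ~res["degenerate"].to_numpy()
    if ok.any():
        q[ok] = bh_fdr(res.loc[ok, "p_value"].to_numpy())
    res["q_value"] = q
    return res[RESULT_COLUMNS]


def select_differential(results: pd.DataFrame,
                        thresholds: ThresholdConfig | None = None,
                        transcript_type: str | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold selection, partitioned by direction: (up, down)."""
    if thresholds is None:
        thresholds = ThresholdConfig()
    sub = results[~results["degenerate"]]
    if transcript_type is not None:
        sub = sub[sub["transcript_type"] == transcript_type]
    passed = sub["fold_change"] >= thresholds.fc_min
    if thresholds.use_q:
        passed &= sub["q_value"] <= thresholds.q_max
    else:
        passed &= sub["p_value"] <= thresholds.p_max
    selected = sub[passed]
    up = selected[selected["direction"] == "up"].reset_index(drop=True)
    down = selected[selected["direction"] == "down"].reset_index(drop=True)
    return up, down


def summarize_selection(up: pd.DataFrame, down: pd.DataFrame) -> dict:
    return {"up": len(up), "down": len(down), "total": len(up) + len(down)}
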