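"""Bootstrap power analysis for the paired design.

The resampling unit is the patient (the control/treated pair). For each
evaluated sample size m, patients are drawn with replacement n_bootstrap
times; each replicate reruns the paired t-test on the resampled per-patient
differences and BH correction over the full tested probe set, and a target
gene counts as detected when any of its probes passes the detection rule.
Power is the detection fraction across replicates.

Degenerate resamples (zero variance of differences, e.g. every draw is the
same patient) count as non-detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ThresholdConfig, bh_fdr, paired_differences, t_test_on_differences
from .io_formats import ExpressionMatrix, ProbeAnnotation, SampleDesign

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["gene_symbol", "sample_size", "power", "standard_error",
                 "n_bootstrap"]


@dataclass
class PowerConfig:
    sample_sizes: list[int] = field(default_factory=lambda: [3, 4, 5])
    n_bootstrap: int = 1000
    detection: ThresholdConfig = field(
        default_factory=lambda: ThresholdConfig(use_q=True, q_max=0.5))
    target_genes: list[str] = field(default_factory=list)
    power_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 2 for m in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.detection.q_max < 1.0:
            raise ValueError("q_max must lie in (0, 1)")


def bootstrap_power(matrix: ExpressionMatrix, design: SampleDesign,
                    annotation: ProbeAnnotation, config: PowerConfig,
                    ) -> pd.DataFrame:
    """Per (gene, sample size) bootstrap power estimate with binomial SE."""
    if not config.target_genes:
        raise ValueError("config.target_genes is empty")
    _, diffs = paired_differences(matrix, design)
    n_patients = diffs.shape[1]

    symbol_by_probe = dict(zip(annotation.frame["probe_id"],
                               annotation.frame["gene_symbol"]))
    probe_rows: dict[str, list[int]] = {g: [] for g in config.target_genes}
    for i, probe in enumerate(matrix.probe_ids):
        sym = symbol_by_probe.get(probe)
        if sym in probe_rows:
            probe_rows[sym].append(i)
    missing = [g for g, rows in probe_rows.items() if not rows]
    if missing:
        raise ValueError(f"target genes absent from matrix: {missing}")

    rng = np.random.default_rng(config.seed)
    rule = config.detection
    records = []
    for m in config.sample_sizes:
        detected = {g: 0 for g in config.target_genes}
        for _ in range(config.n_bootstrap):
            draw = rng.integers(0, n_patients, size=m)
            res = t_test_on_differences(diffs[:, draw])
            ok = ~res["degenerate"].to_numpy()
            passed = np.zeros(len(res), dtype=bool)
            if ok.any():
                p = res.loc[ok, "p_value"].to_numpy()
                fc = 2.0 ** np.abs(res.loc[ok, "mean_log2_diff"].to_numpy())
                if rule.use_q:
                    stat_ok = bh_fdr(p) <= rule.q_max
                else:
                    stat_ok = p <= rule.p_max
                passed[np.flatnonzero(ok)] = stat_ok & (fc >= rule.fc_min)
            for g, rows in probe_rows.items():
                if passed[rows].any():
                    detected[g] += 1
        for g in config.target_genes:
            phat = detected[g] / config.n_bootstrap
            records.append({
                "gene_symbol": g,
                "sample_size": m,
                "power": phat,
                "standard_error": float(np.sqrt(phat * (1 - phat) / config.n_bootstrap)),
                "n_bootstrap": config.n_bootstrap,
            })
    return pd.DataFrame(records, columns=CURVE_COLUMNS)


def minimum_sample_size(curve: pd.DataFrame, power_threshold: float = 0.8,
                        ) -> dict[str, int | None]:
    """Smallest evaluated sample size reaching the power threshold per gene;
    ``None`` when the threshold is never met."""
    if curve["sample_size"].nunique() < 2:
        raise ValueError("curve must cover at least 2 sample sizes")
    out: dict[str, int | None] = {}
    for gene, sub in curve.groupby("gene_symbol", sort=False):
        sub = sub.sort_values("sample_size")
        hit = sub[sub["power"] >= power_threshold]
        out[str(gene)] = int(hit["sample_size"].iloc[0]) if not hit.empty else None
    return out
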