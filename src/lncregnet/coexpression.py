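"""lncRNA-mRNA co-expression screening and cis/trans classification.

Pearson correlations are computed across all arrays jointly (both
conditions); with five patients per condition that gives n = 10 points per
pair, which is what makes correlation P-values of ~1e-4 at |r| = 0.9
attainable. Strong negative pairs (r at or below the negative threshold,
correlation P within bound) are retained; a pair is classified cis when
both members share a chromosome, the gap between their intervals is within
the window (default 100 kb) and the correlation P meets the stricter cis
bound; every other retained pair is trans. Strand is ignored throughout.

Coordinates are 1-based inclusive; for disjoint ordered intervals the gap
is ``start2 - end1 - 1`` (overlapping intervals have gap 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "lncrna_probe_id", "mrna_probe_id", "lncrna_gene_symbol", "mrna_gene_symbol",
    "r", "corr_p", "same_chromosome", "genomic_gap", "regulation_class",
]


@dataclass
class PairScreenConfig:
    corr_p_max: float = 0.05
    r_max: float = -0.9            # keep pairs with r <= r_max (boundary inclusive)
    cis_window: int = 100_000
    cis_corr_p_max: float = 0.01
    restrict_to_differential: bool = True

    def __post_init__(self) -> None:
        if self.r_max >= 0:
            raise ValueError("r_max must be negative")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if self.cis_corr_p_max > self.corr_p_max:
            raise ValueError("cis_corr_p_max must not exceed corr_p_max")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN for constant input (pair skipped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        logger.info("constant vector in correlation; returning NaN")
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided P for a Pearson correlation via the t transform,
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.

    |r| = 1 returns 0.0 (the limiting value).
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(r)
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit norm; constant rows become NaN."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norms
    z[norms[:, 0] == 0.0] = np.nan
    return z


def correlation_matrix(matrix: ExpressionMatrix, row_probes: list[str],
                       col_probes: list[str]) -> np.ndarray:
    """Pearson r for every (row probe, col probe) combination; rows/cols
    with constant expression yield NaN."""
    idx = {p: i for i, p in enumerate(matrix.probe_ids)}
    rows = matrix.values[[idx[p] for p in row_probes]]
    cols = matrix.values[[idx[p] for p in col_probes]]
    r = _standardize_rows(rows) @ _standardize_rows(cols).T
    return np.clip(r, -1.0, 1.0, out=r)


def correlation_p_matrix(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided correlation P for an array of r values."""
    r = np.asarray(r, dtype=float)
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r[interior] * np.sqrt((n - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    return p


def genomic_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 when they
    overlap or touch."""
    if start1 > start2:
        start1, end1, start2, end2 = start2, end2, start1, end1
    return max(0, start2 - end1 - 1)


def screen_negative_pairs(matrix: ExpressionMatrix, annotation: ProbeAnnotation,
                          de_lncrna: list[str] | None = None,
                          de_mrna: list[str] | None = None,
                          config: PairScreenConfig | None = None) -> pd.DataFrame:
    """All lncRNA x mRNA pairs with corr P <= corr_p_max and r <= r_max,
    annotated with chromosome sharing, gap and cis/trans class.

    With ``restrict_to_differential`` both members must appear in the
    supplied differential lists.
    """
    if config is None:
        config = PairScreenConfig()
    in_matrix = set(matrix.probe_ids)
    lnc = [p for p in annotation.probes_of_type("lncRNA") if p in in_matrix]
    mrna = [p for p in annotation.probes_of_type("mRNA") if p in in_matrix]
    if config.restrict_to_differential:
        if de_lncrna is None or de_mrna is None:
            raise ValueError(
                "restrict_to_differential requires de_lncrna and de_mrna lists"
            )
        lnc = [p for p in lnc if p in set(de_lncrna)]
        mrna = [p for p in mrna if p in set(de_mrna)]
    if not lnc or not mrna:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    n = matrix.n_samples
    r = correlation_matrix(matrix, lnc, mrna)
    p = correlation_p_matrix(r, n)
    with np.errstate(invalid="ignore"):
        hit = (r <= config.r_max) & (p <= config.corr_p_max)
    hit &= ~np.isnan(r)
    li, mi = np.nonzero(hit)
    records = []
    for i, j in zip(li, mi):
        records.append({
            "lncrna_probe_id": lnc[i],
            "mrna_probe_id": mrna[j],
            "lncrna_gene_symbol": annotation.symbol_of(lnc[i]),
            "mrna_gene_symbol": annotation.symbol_of(mrna[j]),
            "r": float(r[i, j]),
            "corr_p": float(p[i, j]),
        })
    pairs = pd.DataFrame(records, columns=PAIR_COLUMNS[:6])
    return classify_cis_trans(pairs, annotation, config)


def classify_cis_trans(pairs: pd.DataFrame, annotation: ProbeAnnotation,
                       config: PairScreenConfig | None = None) -> pd.DataFrame:
    """Set same_chromosome, genomic_gap and regulation_class per pair.

    cis requires: same chromosome, gap <= cis_window, corr_p <= cis_corr_p_max.
    Pairs with a member missing from the annotation are left unclassified.
    """
    if config is None:
        config = PairScreenConfig()
    pairs = pairs.copy()
    same, gaps, classes = [], [], []
    for rec in pairs.itertuples(index=False):
        if rec.lncrna_probe_id not in annotation or rec.mrna_probe_id not in annotation:
            logger.info("pair (%s, %s) missing annotation; unclassified",
                        rec.lncrna_probe_id, rec.mrna_probe_id)
            same.append(False)
            gaps.append(np.nan)
            classes.append("unclassified")
            continue
        a = annotation.record(rec.lncrna_probe_id)
        b = annotation.record(rec.mrna_probe_id)
        if a["chromosome"] != b["chromosome"]:
            same.append(False)
            gaps.append(np.nan)
            classes.append("trans")
            continue
        gap = genomic_gap(int(a["start"]), int(a["end"]), int(b["start"]), int(b["end"]))
        same.append(True)
        gaps.append(float(gap))
        is_cis = gap <= config.cis_window and rec.corr_p <= config.cis_corr_p_max
        classes.append("cis" if is_cis else "trans")
    pairs["same_chromosome"] = pd.Series(same, dtype=bool)
    pairs["genomic_gap"] = gaps
    pairs["regulation_class"] = classes
    return pairs[PAIR_COLUMNS]


def chromosome_distribution(pairs: pd.DataFrame, annotation: ProbeAnnotation) -> dict[str, int]:
    """Counts of same-chromosome pairs keyed by chromosome label."""
    counts: dict[str, int] = {}
    if pairs.empty:
        return counts
    same = pairs[pairs["same_chromosome"]]
    for probe in same["lncrna_probe_id"]:
        chrom = str(annotation.record(probe)["chromosome"])
        counts[chrom] = counts.get(chrom, 0) + 1
    return counts


def paired_permutation_null(matrix: ExpressionMatrix, design, rng) -> ExpressionMatrix:
    """Permutation null preserving the paired-sample structure.

    For each probe independently, patient blocks (control/treated column
    pairs) are permuted and conditions optionally swapped within a patient.
    This breaks cross-probe alignment while keeping each probe's own
    duplicate-per-patient structure, which is what makes it a valid null
    for pairwise correlation under this design: a full per-sample shuffle
    destroys the pairing and understates the null tail.
    """
    patients = design.patients
    control = design.samples_for("control")
    treated = design.samples_for("treated")
    c_cols = np.array([matrix.sample_ids.index(control[p]) for p in patients])
    t_cols = np.array([matrix.sample_ids.index(treated[p]) for p in patients])
    n_pat = len(patients)
    out = matrix.values.copy()
    for i in range(out.shape[0]):
        blocks = rng.permutation(n_pat)
        swap = rng.integers(0, 2, n_pat).astype(bool)
        src_c = np.where(swap, t_cols[blocks], c_cols[blocks])
        src_t = np.where(swap, c_cols[blocks], t_cols[blocks])
        row = out[i].copy()
        out[i, c_cols] = row[src_c]
        out[i, t_cols] = row[src_t]
    return matrix.with_values(out, matrix.scale_tag)


def coexpressed_genes(lncrna_probe: str, matrix: ExpressionMatrix,
                      annotation: ProbeAnnotation, p_max: float = 0.05,
                      ) -> list[str]:
    """Gene symbols of mRNAs co-expressed with one lncRNA (any-sign Pearson
    correlation with P < p_max across all samples). Used for functional
    prediction and TF association."""
    in_matrix = set(matrix.probe_ids)
    mrna = [p for p in annotation.probes_of_type("mRNA") if p in in_matrix]
    if lncrna_probe not in in_matrix:
        raise KeyError(f"lncRNA probe {lncrna_probe!r} not in matrix")
    r = correlation_matrix(matrix, [lncrna_probe], mrna)[0]
    p = correlation_p_matrix(r, matrix.n_samples)
    with np.errstate(invalid="ignore"):
        hits = np.flatnonzero(~np.isnan(p) & (p < p_max))
    symbols: dict[str, None] = {}
    for j in hits:
        symbols.setdefault(annotation.symbol_of(mrna[j]), None)
    return list(symbols)
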