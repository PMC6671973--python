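"""Paired two-condition synthetic expression data with planted,
recoverable ground truth.

Generative model, per probe g, patient i, condition c (log2 scale):

    y = baseline_g + patient_{g,i} + delta_g * 1[c = treated] + eps,
    eps ~ Normal(0, residual_sd)

Patient effects are additive in log2 space and shared across the two
conditions of a patient, so the paired t-test on per-patient differences is
the correctly specified analysis. Patient effects are drawn independently
per probe, which keeps distinct probes uncorrelated unless a coupling is
planted.

Planted structure
-----------------
* Differential probes: |delta| drawn from ``log2fc_range``, random sign.
* Negatively coupled lncRNA-mRNA pairs: the mRNA profile is an exact
  negative affine transform of the lncRNA profile plus a noise component
  constructed orthogonally so that the realized across-sample Pearson r
  equals ``coupling_r_target`` exactly (pre-normalization). cis pairs are
  placed on one chromosome with an inter-interval gap below ``cis_max_gap``;
  trans pairs on different chromosomes. Both members carry differential
  effects of opposite sign.
* TF modules: a driver lncRNA whose patient-level variation is a latent
  module factor; member mRNAs load on the same factor (driving strong
  driver-member correlation) and share a differential-effect sign with
  magnitude jitter. Because the factor is patient-level it cancels from the
  paired differences and leaves the differential test well specified. TF
  target sets contain the members plus null-gene decoys.
* Function sets: one set per module (the members), one set enriched in the
  independently planted differential mRNA symbols, and null decoy sets.

Values are emitted on the linear (raw) scale, ``2**y``, so the full
preprocessing path (log2 -> quantile normalization -> flag filter) is
exercised downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffexpr import paired_differences
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ProbeAnnotation,
    SampleDesign,
    write_expression_matrix,
    write_gmt,
    write_probe_annotation,
    write_sample_design,
)

CHROMOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimulationConfig:
    n_patients: int = 5
    n_mrna: int = 2000
    n_lncrna: int = 1000
    frac_de_mrna: float = 0.015
    frac_de_lncrna: float = 0.02
    log2fc_range: tuple[float, float] = (1.0, 4.2)
    patient_effect_sd: float = 0.3
    residual_sd: float = 0.15
    n_cis_pairs: int = 10
    n_trans_pairs: int = 10
    coupling_r_target: float = -0.95
    cis_max_gap: int = 90_000
    n_tf_modules: int = 5
    tf_module_size: int = 15
    tf_decoys_per_set: int = 15
    module_factor_sd: float = 1.5
    module_loading: float = 1.0
    n_null_function_sets: int = 10
    n_forced_absent_one_condition: int = 5
    n_forced_absent_all: int = 5
    flag_absent_prob: float = 0.02
    baseline_mean: float = 9.0
    baseline_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de_mrna", "frac_de_lncrna", "flag_absent_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("patient_effect_sd", "residual_sd", "module_factor_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.coupling_r_target < 0.0:
            raise ValueError("coupling_r_target must lie in (-1, 0)")
        if not 0 < self.cis_max_gap < 100_000:
            raise ValueError("cis_max_gap must lie in (0, 100000)")
        lo, hi = self.log2fc_range
        if not 0 < lo <= hi:
            raise ValueError("log2fc_range must satisfy 0 < lo <= hi")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["log2fc_range"] = list(self.log2fc_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("log2fc_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_recovery_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale dataset with 50 independently planted differential probes
    (30 mRNA + 20 lncRNA) at |log2FC| in [1.5, 4], 10 cis + 10 trans pairs
    and 5 TF modules."""
    return SimulationConfig(
        n_mrna=2000, n_lncrna=1000,
        frac_de_mrna=30 / 2000, frac_de_lncrna=20 / 1000,
        log2fc_range=(1.5, 4.0),
        n_cis_pairs=10, n_trans_pairs=10,
        n_tf_modules=5,
        seed=seed,
    )


@dataclass
class GroundTruthManifest:
    """Everything planted: differential probes with signed log2fc, coupled
    pairs with target r and cis/trans label, TF modules, and null probes."""

    de_probes: list[dict] = field(default_factory=list)
    pairs: list[dict] = field(default_factory=list)
    tf_modules: list[dict] = field(default_factory=list)
    null_probe_ids: list[str] = field(default_factory=list)

    def de_probe_ids(self) -> list[str]:
        return [d["probe_id"] for d in self.de_probes]

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(p["lncrna_probe_id"], p["mrna_probe_id"]) for p in self.pairs}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        return cls(**d)


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    design: SampleDesign
    annotation: ProbeAnnotation
    function_sets: GeneSetCollection
    tf_sets: GeneSetCollection
    truth: GroundTruthManifest
    config: SimulationConfig


def _validate_truth(dataset: SimulatedDataset) -> None:
    ann = dataset.annotation
    cfg = dataset.config
    for d in dataset.truth.de_probes:
        if d["probe_id"] not in ann:
            raise ValueError(f"planted DE probe {d['probe_id']} missing annotation")
    for p in dataset.truth.pairs:
        a = ann.record(p["lncrna_probe_id"])
        b = ann.record(p["mrna_probe_id"])
        if p["label"] == "cis":
            if a["chromosome"] != b["chromosome"]:
                raise ValueError("planted cis pair spans chromosomes")
            from .coexpression import genomic_gap
            gap = genomic_gap(int(a["start"]), int(a["end"]),
                              int(b["start"]), int(b["end"]))
            if gap >= cfg.cis_max_gap:
                raise ValueError("planted cis pair gap exceeds cis_max_gap")
        elif a["chromosome"] == b["chromosome"]:
            raise ValueError("planted trans pair shares a chromosome")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    P = config.n_patients
    S = 2 * P
    lo, hi = config.log2fc_range

    # --- samples / design (control columns first, then treated) ----------
    patients = [f"RA{i + 1:03d}" for i in range(P)]
    control_ids = [f"{p}_control" for p in patients]
    treated_ids = [f"{p}_treated" for p in patients]
    sample_ids = control_ids + treated_ids
    cond = np.array([0] * P + [1] * P)          # per-column condition indicator
    patient_col = np.array(list(range(P)) * 2)  # per-column patient index
    design = SampleDesign(pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": patients * 2,
        "condition": ["control"] * P + ["treated"] * P,
    }))

    # --- probes and baseline annotation -----------------------------------
    mrna_ids = [f"PM{i + 1:05d}" for i in range(config.n_mrna)]
    mrna_symbols = [f"GENE{i + 1:05d}" for i in range(config.n_mrna)]
    lnc_ids = [f"PL{i + 1:05d}" for i in range(config.n_lncrna)]
    lnc_symbols = [f"LNC{i + 1:05d}" for i in range(config.n_lncrna)]
    probe_ids = mrna_ids + lnc_ids
    n_probes = len(probe_ids)

    chrom = rng.choice(CHROMOSOMES, size=n_probes)
    start = rng.integers(1_000_000, 200_000_000, size=n_probes)
    length = rng.integers(500, 50_000, size=n_probes)
    strand = rng.choice(["+", "-"], size=n_probes)

    # --- role assignment ---------------------------------------------------
    n_pairs = config.n_cis_pairs + config.n_trans_pairs
    n_module_genes = config.n_tf_modules * config.tf_module_size
    n_de_mrna = int(round(config.frac_de_mrna * config.n_mrna))
    n_de_lncrna = int(round(config.frac_de_lncrna * config.n_lncrna))
    if n_pairs + n_module_genes + n_de_mrna > config.n_mrna:
        raise ValueError("config requests more planted mRNA probes than available")
    if n_pairs + config.n_tf_modules + n_de_lncrna > config.n_lncrna:
        raise ValueError("config requests more planted lncRNA probes than available")

    mrna_pool = rng.permutation(config.n_mrna)
    lnc_pool = rng.permutation(config.n_lncrna)
    pair_mrna = mrna_pool[:n_pairs]
    module_mrna = mrna_pool[n_pairs:n_pairs + n_module_genes].reshape(
        config.n_tf_modules, config.tf_module_size)
    de_mrna_idx = mrna_pool[n_pairs + n_module_genes:
                            n_pairs + n_module_genes + n_de_mrna]
    null_mrna_idx = mrna_pool[n_pairs + n_module_genes + n_de_mrna:]
    pair_lnc = lnc_pool[:n_pairs]
    driver_lnc = lnc_pool[n_pairs:n_pairs + config.n_tf_modules]
    de_lnc_idx = lnc_pool[n_pairs + config.n_tf_modules:
                          n_pairs + config.n_tf_modules + n_de_lncrna]
    null_lnc_idx = lnc_pool[n_pairs + config.n_tf_modules + n_de_lncrna:]

    # --- base expression ---------------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    patient_effects = rng.normal(0.0, config.patient_effect_sd, size=(n_probes, P))
    eps = rng.normal(0.0, config.residual_sd, size=(n_probes, S))
    values = (baseline[:, None]
              + patient_effects[:, patient_col]
              + eps)

    delta = np.zeros(n_probes)
    truth = GroundTruthManifest()

    def plant_de(row: int, magnitude: float, sign: int, role: str) -> None:
        delta[row] = sign * magnitude
        truth.de_probes.append({
            "probe_id": probe_ids[row],
            "log2fc": float(sign * magnitude),
            "direction": "up" if sign > 0 else "down",
            "role": role,
        })

    # independently planted differential probes
    for idx, base in ((de_mrna_idx, 0), (de_lnc_idx, config.n_mrna)):
        for i in idx:
            mag = rng.uniform(lo, hi)
            sign = int(rng.choice([-1, 1]))
            plant_de(base + i, mag, sign, "independent")

    # --- TF modules --------------------------------------------------------
    # Module factors are patient-level (cancel from paired differences). With
    # few patients, independently drawn factor vectors are collinear by
    # chance, which would couple distinct modules; simplex-contrast vectors
    # (pairwise correlation exactly -1/(P-1)) avoid that when the module
    # count fits in patient space.
    if config.n_tf_modules <= P:
        contrasts = np.eye(P) - 1.0 / P
        contrasts = contrasts[rng.permutation(P)[:config.n_tf_modules]]
        contrasts /= contrasts.std(axis=1, ddof=1)[:, None]
        factors = contrasts * config.module_factor_sd
    else:
        factors = rng.normal(0.0, config.module_factor_sd,
                             size=(config.n_tf_modules, P))
    tf_sets_list: list[GeneSet] = []
    function_sets_list: list[GeneSet] = []
    for m in range(config.n_tf_modules):
        drow = config.n_mrna + driver_lnc[m]
        factor = factors[m]
        d_lo = max(lo, 1.5)
        d_hi = max(d_lo + 0.1, min(hi, 2.2))
        driver_mag = rng.uniform(d_lo, d_hi)
        module_sign = int(rng.choice([-1, 1]))
        # driver: its patient-level variation IS the module factor
        values[drow] = (baseline[drow] + factor[patient_col]
                        + eps[drow] * 0.5)
        plant_de(drow, driver_mag, module_sign, "tf_driver")

        m_lo = max(lo, 1.8)
        m_hi = max(m_lo + 0.1, min(hi, 3.0))
        base_mag = rng.uniform(m_lo, m_hi)
        member_rows = [int(r) for r in module_mrna[m]]
        for row in member_rows:
            mag = max(1.2, base_mag + rng.normal(0.0, 0.15))
            values[row] = values[row] + config.module_loading * factor[patient_col]
            plant_de(row, mag, module_sign, "tf_member")

        member_symbols = [mrna_symbols[r] for r in member_rows]
        decoys = [mrna_symbols[i] for i in
                  rng.choice(null_mrna_idx, size=config.tf_decoys_per_set,
                             replace=False)]
        tf_name = f"TF{m + 1}"
        tf_sets_list.append(GeneSet(tf_name, f"targets of {tf_name}",
                                    member_symbols + decoys))
        function_sets_list.append(GeneSet(f"FUNC_MOD{m + 1}",
                                          f"module {m + 1} program",
                                          list(member_symbols)))
        truth.tf_modules.append({
            "tf": tf_name,
            "function_set": f"FUNC_MOD{m + 1}",
            "driver_lncrna_probe_id": probe_ids[drow],
            "member_probe_ids": [probe_ids[r] for r in member_rows],
            "member_symbols": member_symbols,
        })

    # apply condition effects planted so far (pairs handled after this,
    # because the coupled mRNA is rebuilt from the finished lncRNA profile)
    values += np.outer(delta, cond)

    # --- negatively coupled pairs ------------------------------------------
    r_mag = abs(config.coupling_r_target)
    lam = np.sqrt(1.0 / (r_mag * r_mag) - 1.0)
    p_lo = min(max(lo, 1.8), hi)
    labels = ["cis"] * config.n_cis_pairs + ["trans"] * config.n_trans_pairs
    for j, label in enumerate(labels):
        lrow = config.n_mrna + pair_lnc[j]
        mrow = int(pair_mrna[j])
        mag = rng.uniform(p_lo, hi)
        sign = int(rng.choice([-1, 1]))
        # lncRNA member: ordinary planted differential probe
        values[lrow] += sign * mag * cond
        delta[lrow] = sign * mag
        truth.de_probes.append({
            "probe_id": probe_ids[lrow], "log2fc": float(sign * mag),
            "direction": "up" if sign > 0 else "down", "role": "pair_lncrna",
        })
        # mRNA member: exact-r negative transform of the lncRNA profile
        L = values[lrow]
        Lc = L - L.mean()
        nl = np.linalg.norm(Lc)
        u = Lc / nl
        z = rng.standard_normal(S)
        z -= z.mean()
        z -= (z @ u) * u
        z /= np.linalg.norm(z)
        Mc = -(u + lam * z) / np.sqrt(1.0 + lam * lam) * nl
        values[mrow] = baseline[mrow] + Mc
        realized_delta = float(Mc[P:].mean() - Mc[:P].mean())
        delta[mrow] = realized_delta
        truth.de_probes.append({
            "probe_id": probe_ids[mrow], "log2fc": realized_delta,
            "direction": "up" if realized_delta > 0 else "down",
            "role": "pair_mrna",
        })
        truth.pairs.append({
            "lncrna_probe_id": probe_ids[lrow],
            "mrna_probe_id": probe_ids[mrow],
            "label": label,
            "target_r": config.coupling_r_target,
        })
        # genomic placement
        if label == "cis":
            c = rng.choice(CHROMOSOMES)
            l_start = int(rng.integers(1_000_000, 150_000_000))
            l_len = int(rng.integers(500, 10_000))
            gap = int(rng.integers(1_000, config.cis_max_gap - 1))
            m_len = int(rng.integers(500, 30_000))
            chrom[lrow], start[lrow], length[lrow] = c, l_start, l_len
            chrom[mrow] = c
            start[mrow] = l_start + l_len - 1 + gap + 1
            length[mrow] = m_len
        else:
            c_l, c_m = rng.choice(CHROMOSOMES, size=2, replace=False)
            chrom[lrow], chrom[mrow] = c_l, c_m

    truth.null_probe_ids = ([mrna_ids[i] for i in null_mrna_idx]
                            + [lnc_ids[i] for i in null_lnc_idx])

    # --- gene sets ---------------------------------------------------------
    de_symbols = [mrna_symbols[i] for i in de_mrna_idx]
    if de_symbols:
        n_core = max(1, int(round(0.8 * len(de_symbols))))
        core = [de_symbols[i] for i in
                rng.choice(len(de_symbols), size=n_core, replace=False)]
        filler = [mrna_symbols[i] for i in
                  rng.choice(null_mrna_idx, size=max(1, len(de_symbols) - n_core),
                             replace=False)]
        function_sets_list.append(
            GeneSet("FUNC_DE_ENRICHED", "planted differential program",
                    core + filler))
    for j in range(config.n_null_function_sets):
        members = [mrna_symbols[i] for i in
                   rng.choice(null_mrna_idx, size=20, replace=False)]
        function_sets_list.append(GeneSet(f"FUNC_NULL{j + 1}", "decoy", members))

    # --- flags -------------------------------------------------------------
    flags = np.where(rng.random(size=(n_probes, S)) < config.flag_absent_prob,
                     "A", "P").astype("<U1")
    forced_pool = [int(i) for i in null_mrna_idx]
    n_one = min(config.n_forced_absent_one_condition, len(forced_pool))
    n_all = min(config.n_forced_absent_all, max(0, len(forced_pool) - n_one))
    one_cond_rows = forced_pool[:n_one]
    all_rows = forced_pool[n_one:n_one + n_all]
    for row in one_cond_rows:          # absent in control only: still retained
        flags[row, :P] = "A"
        flags[row, P:] = "P"
    for row in all_rows:               # absent everywhere: removed by filter
        flags[row, :] = "A"

    annotation = ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "transcript_type": ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
        "gene_symbol": mrna_symbols + lnc_symbols,
        "chromosome": chrom,
        "start": start,
        "end": start + length - 1,
        "strand": strand,
    }))
    matrix = ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        values=np.power(2.0, values),
        flags=flags,
        scale_tag="raw",
    )
    dataset = SimulatedDataset(
        matrix=matrix, design=design, annotation=annotation,
        function_sets=GeneSetCollection(function_sets_list, kind_tag="function"),
        tf_sets=GeneSetCollection(tf_sets_list, kind_tag="tf_targets"),
        truth=truth, config=config,
    )
    _validate_truth(dataset)
    return dataset


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

DATASET_FILES = {
    "matrix": "matrix.tsv",
    "flags": "flags.tsv",
    "design": "design.tsv",
    "annotation": "annotation.tsv",
    "function_sets": "function_sets.gmt",
    "tf_sets": "tf_target_sets.gmt",
    "truth": "truth.json",
    "config": "config.yaml",
}


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in DATASET_FILES.items()}
    write_expression_matrix(dataset.matrix, paths["matrix"], paths["flags"])
    write_sample_design(dataset.design, paths["design"])
    write_probe_annotation(dataset.annotation, paths["annotation"])
    write_gmt(dataset.function_sets, paths["function_sets"])
    write_gmt(dataset.tf_sets, paths["tf_sets"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=1, sort_keys=True)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths


def read_truth(path: str | Path) -> GroundTruthManifest:
    with open(path) as fh:
        return GroundTruthManifest.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# realized statistics
# ---------------------------------------------------------------------------

def realized_truth_stats(matrix: ExpressionMatrix, design: SampleDesign,
                         manifest: GroundTruthManifest) -> dict[str, pd.DataFrame]:
    """Realized per-probe effect sizes and per-pair correlations for every
    planted entity (computed on log2 values; raw matrices are transformed)."""
    known = set(matrix.probe_ids)
    for d in manifest.de_probes:
        if d["probe_id"] not in known:
            raise KeyError(f"manifest probe {d['probe_id']} not in matrix")
    for p in manifest.pairs:
        for key in ("lncrna_probe_id", "mrna_probe_id"):
            if p[key] not in known:
                raise KeyError(f"manifest probe {p[key]} not in matrix")
    if matrix.scale_tag == "raw":
        work = matrix.with_values(np.log2(np.maximum(matrix.values, 1e-12)),
                                  scale_tag="log2")
    else:
        work = matrix
    _, diffs = paired_differences(work, design)
    mean_diff = dict(zip(work.probe_ids, diffs.mean(axis=1)))

    de_rows = [{
        "probe_id": d["probe_id"],
        "planted_log2fc": d["log2fc"],
        "realized_log2fc": float(mean_diff[d["probe_id"]]),
    } for d in manifest.de_probes]

    from .coexpression import pearson_r
    pair_rows = []
    for p in manifest.pairs:
        i = work.probe_index(p["lncrna_probe_id"])
        j = work.probe_index(p["mrna_probe_id"])
        pair_rows.append({
            "lncrna_probe_id": p["lncrna_probe_id"],
            "mrna_probe_id": p["mrna_probe_id"],
            "label": p["label"],
            "target_r": p["target_r"],
            "realized_r": pearson_r(work.values[i], work.values[j]),
        })
    null_rows = [{
        "probe_id": pid,
        "realized_log2fc": float(mean_diff[pid]),
    } for pid in manifest.null_probe_ids if pid in known]
    return {
        "de": pd.DataFrame(de_rows,
                           columns=["probe_id", "planted_log2fc", "realized_log2fc"]),
        "pairs": pd.DataFrame(pair_rows,
                              columns=["lncrna_probe_id", "mrna_probe_id", "label",
                                       "target_r", "realized_r"]),
        "null": pd.DataFrame(null_rows, columns=["probe_id", "realized_log2fc"]),
    }
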