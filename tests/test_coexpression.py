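import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncregnet.coexpression import (
    PairScreenConfig,
    chromosome_distribution,
    classify_cis_trans,
    coexpressed_genes,
    correlation_p,
    correlation_matrix,
    genomic_gap,
    pearson_r,
    screen_negative_pairs,
)

from conftest import make_annotation, make_matrix


# ---------------------------------------------------------------------------
# pearson r and its P
# ---------------------------------------------------------------------------

def test_perfect_negative():
    assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)


def test_known_r_value():
    assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805, abs=1e-6)


def test_affine_invariance_exact():
    x = np.array([1.0, 2.0, 3.0, 7.0])
    for a, b in [(0.0, 1.0), (5.0, 2.5), (-3.0, 0.1)]:
        assert pearson_r(x, a + b * x) == pytest.approx(1.0)
        assert pearson_r(x, a - b * x) == pytest.approx(-1.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=4, max_size=12),
       st.floats(-10, 10), st.floats(0.1, 5))
def test_affine_invariance_property(xs, a, b):
    x = np.asarray(xs)
    if np.ptp(x) < 1e-6:  # (near-)constant input underflows to NaN by contract
        return
    # 1e-6 tolerance: near-constant vectors lose precision to cancellation
    assert pearson_r(x, a + b * x) == pytest.approx(1.0, abs=1e-6)
    # antisymmetric under negation of one vector (negation is exact)
    y = a + b * x + np.sin(x)
    if np.ptp(y) == 0:
        return
    r1 = pearson_r(x, y)
    r2 = pearson_r(x, -y)
    assert r1 == pytest.approx(-r2, abs=1e-12)


def test_constant_vector_gives_nan():
    assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))


def test_correlation_p_values():
    assert correlation_p(0.0, 10) == pytest.approx(1.0)
    # r=-0.9, n=10 -> t ~ -5.840, P ~ 3.9e-4
    p = correlation_p(-0.9, 10)
    assert p == pytest.approx(3.9e-4, rel=0.02)
    assert correlation_p(0.9, 10) == pytest.approx(p)  # two-sided symmetry
    assert correlation_p(1.0, 5) == 0.0
    assert correlation_p(-1.0, 5) == 0.0


def test_correlation_p_matches_scipy():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(4, 15))
        x, y = rng.normal(size=(2, n))
        r_exp, p_exp = stats.pearsonr(x, y)
        assert pearson_r(x, y) == pytest.approx(r_exp, abs=1e-12)
        assert correlation_p(pearson_r(x, y), n) == pytest.approx(p_exp, abs=1e-12)


# ---------------------------------------------------------------------------
# gap arithmetic and classification
# ---------------------------------------------------------------------------

def test_genomic_gap():
    assert genomic_gap(100, 200, 301, 400) == 100
    assert genomic_gap(301, 400, 100, 200) == 100  # order independent
    assert genomic_gap(100, 200, 150, 250) == 0    # overlap
    assert genomic_gap(100, 200, 201, 300) == 0    # touching


def _pairs_frame(rows):
    return pd.DataFrame(rows, columns=[
        "lncrna_probe_id", "mrna_probe_id", "lncrna_gene_symbol",
        "mrna_gene_symbol", "r", "corr_p"])


CLASSIFY_ANN = make_annotation([
    ("L1", "lncRNA", "LNC1", "chr1", 200_000, 210_000, "+"),
    ("M_near", "mRNA", "G1", "chr1", 150_000, 160_000, "+"),
    ("M_other", "mRNA", "G2", "chr2", 150_000, 160_000, "+"),
    ("M_far", "mRNA", "G3", "chr1", 320_001, 330_000, "+"),
])


def test_cis_within_window():
    pairs = _pairs_frame([("L1", "M_near", "LNC1", "G1", -0.95, 0.005)])
    out = classify_cis_trans(pairs, CLASSIFY_ANN)
    assert out.loc[0, "regulation_class"] == "cis"
    assert out.loc[0, "same_chromosome"]
    assert out.loc[0, "genomic_gap"] == 39_999


def test_trans_on_other_chromosome():
    pairs = _pairs_frame([("L1", "M_other", "LNC1", "G2", -0.95, 0.005)])
    out = classify_cis_trans(pairs, CLASSIFY_ANN)
    assert out.loc[0, "regulation_class"] == "trans"
    assert not out.loc[0, "same_chromosome"]
    assert np.isnan(out.loc[0, "genomic_gap"])


def test_trans_beyond_window_same_chromosome():
    pairs = _pairs_frame([("L1", "M_far", "LNC1", "G3", -0.95, 0.005)])
    out = classify_cis_trans(pairs, CLASSIFY_ANN)
    assert out.loc[0, "genomic_gap"] == 110_000
    assert out.loc[0, "regulation_class"] == "trans"


def test_cis_requires_stringent_p():
    pairs = _pairs_frame([("L1", "M_near", "LNC1", "G1", -0.95, 0.02)])
    out = classify_cis_trans(pairs, CLASSIFY_ANN)
    assert out.loc[0, "regulation_class"] == "trans"  # corr_p > 0.01


def test_missing_annotation_unclassified():
    pairs = _pairs_frame([("L1", "M_unknown", "LNC1", "G9", -0.95, 0.005)])
    out = classify_cis_trans(pairs, CLASSIFY_ANN)
    assert out.loc[0, "regulation_class"] == "unclassified"


def test_cis_monotone_in_window():
    pairs = _pairs_frame([("L1", "M_near", "LNC1", "G1", -0.95, 0.005)])
    wide = classify_cis_trans(pairs, CLASSIFY_ANN, PairScreenConfig(cis_window=100_000))
    narrow = classify_cis_trans(pairs, CLASSIFY_ANN, PairScreenConfig(cis_window=10_000))
    assert wide.loc[0, "regulation_class"] == "cis"
    assert narrow.loc[0, "regulation_class"] == "trans"


def test_chromosome_distribution_counts():
    ann = make_annotation(
        [(f"L{i}", "lncRNA", f"LNC{i}", c, 100, 200, "+")
         for i, c in enumerate(["chr6"] * 3 + ["chr17"] * 2 + ["chr1"])])
    pairs = pd.DataFrame({
        "lncrna_probe_id": [f"L{i}" for i in range(6)],
        "mrna_probe_id": ["M"] * 6,
        "same_chromosome": [True] * 5 + [False],
    })
    counts = chromosome_distribution(pairs, ann)
    assert counts == {"chr6": 3, "chr17": 2}
    assert sum(counts.values()) == int(pairs["same_chromosome"].sum())
    assert chromosome_distribution(pairs.iloc[:0], ann) == {}


# ---------------------------------------------------------------------------
# screening vs brute-force oracle
# ---------------------------------------------------------------------------

def _random_instance(seed, n_lnc=12, n_mrna=15, n_samples=10):
    rng = np.random.default_rng(seed)
    probes = [f"L{i}" for i in range(n_lnc)] + [f"M{j}" for j in range(n_mrna)]
    values = rng.normal(size=(n_lnc + n_mrna, n_samples))
    # plant a few strong negative couplings
    for k in range(4):
        values[n_lnc + k] = -values[k] + rng.normal(0, 0.1, n_samples)
    ann = make_annotation(
        [(p, "lncRNA" if p.startswith("L") else "mRNA", f"S_{p}",
          f"chr{1 + (hash(p) % 5)}", 1000, 2000, "+") for p in probes])
    matrix = make_matrix(values, probe_ids=probes, scale_tag="normalized")
    return matrix, ann


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_screen_matches_bruteforce(seed):
    matrix, ann = _random_instance(seed)
    cfg = PairScreenConfig(restrict_to_differential=False)
    got = screen_negative_pairs(matrix, ann, config=cfg)
    got_keys = set(zip(got["lncrna_probe_id"], got["mrna_probe_id"]))
    expected = set()
    lnc = [p for p in matrix.probe_ids if p.startswith("L")]
    mrna = [p for p in matrix.probe_ids if p.startswith("M")]
    for lp in lnc:
        for mp in mrna:
            x = matrix.values[matrix.probe_index(lp)]
            y = matrix.values[matrix.probe_index(mp)]
            r, p = stats.pearsonr(x, y)
            if r <= cfg.r_max and p <= cfg.corr_p_max:
                expected.add((lp, mp))
    assert got_keys == expected
    # reported r/p match the scipy oracle
    for rec in got.itertuples(index=False):
        x = matrix.values[matrix.probe_index(rec.lncrna_probe_id)]
        y = matrix.values[matrix.probe_index(rec.mrna_probe_id)]
        r, p = stats.pearsonr(x, y)
        assert rec.r == pytest.approx(r, abs=1e-10)
        assert rec.corr_p == pytest.approx(p, abs=1e-10)


def test_screen_restrict_to_differential():
    matrix, ann = _random_instance(3)
    cfg = PairScreenConfig(restrict_to_differential=True)
    got = screen_negative_pairs(matrix, ann, de_lncrna=["L0"], de_mrna=["M0"],
                                config=cfg)
    assert set(got["lncrna_probe_id"]) <= {"L0"}
    assert set(got["mrna_probe_id"]) <= {"M0"}
    with pytest.raises(ValueError):
        screen_negative_pairs(matrix, ann, config=cfg)


def test_screen_empty_lists_give_empty_table():
    matrix, ann = _random_instance(4)
    got = screen_negative_pairs(matrix, ann, de_lncrna=[], de_mrna=[],
                                config=PairScreenConfig())
    assert got.empty


def test_screen_boundary_r_inclusive():
    # an exact r == r_max pair must be retained
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    rng = np.random.default_rng(9)
    z = rng.normal(size=10)
    xc = x - x.mean()
    z = z - z.mean()
    z -= (z @ xc) / (xc @ xc) * xc
    lam = np.sqrt(1 / 0.9 ** 2 - 1.0)
    y = -(xc / np.linalg.norm(xc) + lam * z / np.linalg.norm(z))
    matrix = make_matrix(np.stack([x, y]), probe_ids=["L0", "M0"],
                         scale_tag="normalized")
    ann = make_annotation([("L0", "lncRNA", "A", "chr1", 1, 2, "+"),
                           ("M0", "mRNA", "B", "chr2", 1, 2, "+")])
    # r_max set to the exact value the screen itself computes for this pair:
    # boundary-inclusive means the pair must still be retained
    realized = float(correlation_matrix(matrix, ["L0"], ["M0"])[0, 0])
    assert realized == pytest.approx(-0.9, abs=1e-12)
    cfg = PairScreenConfig(r_max=realized, restrict_to_differential=False)
    got = screen_negative_pairs(matrix, ann, config=cfg)
    assert len(got) == 1
    assert got.loc[0, "r"] == pytest.approx(-0.9, abs=1e-12)


def test_coexpressed_genes_dedup_and_threshold():
    rng = np.random.default_rng(17)
    probes = ["L0", "M0", "M1", "M2"]
    values = rng.normal(size=(4, 10))
    values[1] = values[0] * 2 + 1              # perfectly correlated
    values[2] = -values[0] + rng.normal(0, 0.05, 10)
    ann = make_annotation([
        ("L0", "lncRNA", "LNC", "chr1", 1, 2, "+"),
        ("M0", "mRNA", "SHARED", "chr1", 1, 2, "+"),
        ("M1", "mRNA", "SHARED", "chr2", 1, 2, "+"),  # same symbol as M0
        ("M2", "mRNA", "OTHER", "chr3", 1, 2, "+"),
    ])
    matrix = make_matrix(values, probe_ids=probes, scale_tag="normalized")
    genes = coexpressed_genes("L0", matrix, ann, p_max=0.05)
    assert "SHARED" in genes
    assert genes.count("SHARED") == 1  # deduplicated by symbol
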