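"""Count I/O, FPKM/TPM identities, replicate QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernapipe.expression import (
    FormatError,
    normalize,
    read_counts,
    replicate_qc,
)

from conftest import make_matrix


# ------------------------------------------------------------------ I/O

def _write(tmp_path, text, name="counts.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_counts_round_trip(tmp_path):
    p = _write(tmp_path,
               "gene_id\tA_1\tA_2\tB_1\tB_2\n"
               "g1\t1\t2\t3\t4\n" "g2\t0\t0\t0\t0\n" "g3\t9\t8\t7\t6\n")
    m = read_counts(p)
    assert m.values.shape == (3, 4)
    assert m.stage_order == ["A", "B"]
    assert m.unit == "count"


@pytest.mark.parametrize("body, message", [
    ("g1\t1\t-1\t3\t4\n", "negative"),
    ("g1\t1\t2.5\t3\t4\n", "non-integer"),
    ("g1\t1\t2\t3\t4\ng1\t1\t2\t3\t4\n", "duplicate"),
])
def test_read_counts_rejects_malformed_cells(tmp_path, body, message):
    p = _write(tmp_path, "gene_id\tA_1\tA_2\tB_1\tB_2\n" + body)
    with pytest.raises(FormatError, match=message):
        read_counts(p)


def test_read_counts_rejects_empty_file(tmp_path):
    with pytest.raises(FormatError):
        read_counts(_write(tmp_path, ""))


def test_read_counts_reports_unknown_genes(tmp_path):
    p = _write(tmp_path, "gene_id\tA_1\tA_2\n" "g1\t1\t2\n" "weird\t3\t4\n")
    with pytest.warns(UserWarning, match="not in annotation"):
        m = read_counts(p, annotation=["g1"])
    assert m.unknown_genes == ["weird"]


# ------------------------------------------------------- normalization

def test_fpkm_worked_example():
    """c=10, L=1000 bp, N=1e6 -> FPKM exactly 10."""
    m = make_matrix([[10], [1_000_000 - 10]], stages=("A",), reps=1,
                    gene_ids=["g", "filler"])
    out = normalize(m, {"g": 1000, "filler": 1000}, "fpkm")
    assert out.values[0, 0] == pytest.approx(10.0)
    assert out.unit == "FPKM"


def test_fpkm_length_inverse_proportionality():
    m = make_matrix([[100], [100]], stages=("A",), reps=1, gene_ids=["a", "b"])
    out = normalize(m, {"a": 500, "b": 1000}, "fpkm")
    assert out.values[0, 0] / out.values[1, 0] == pytest.approx(2.0)


def test_fpkm_invariant_to_doubling_a_column():
    m = make_matrix([[10, 10], [30, 30]], stages=("A",), reps=2)
    out1 = normalize(m, {"g0": 100, "g1": 200}, "fpkm")
    m2 = make_matrix([[10, 20], [30, 60]], stages=("A",), reps=2)
    out2 = normalize(m2, {"g0": 100, "g1": 200}, "fpkm")
    np.testing.assert_allclose(out1.values[:, 1], out2.values[:, 1])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.lists(st.integers(0, 10_000), min_size=3, max_size=3),
                min_size=2, max_size=12))
def test_tpm_columns_sum_to_a_million(rows):
    values = np.asarray(rows, dtype=float)
    m = make_matrix(values, stages=("A", "B", "C"), reps=1)
    lengths = {g: 100 * (i + 1) for i, g in enumerate(m.gene_ids)}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero columns are expected here
        out = normalize(m, lengths, "tpm")
    sums = out.values.sum(axis=0)
    nonzero = values.sum(axis=0) > 0
    assert np.allclose(sums[nonzero], 1e6, rtol=1e-6)
    assert np.all(sums[~nonzero] == 0)


def test_tpm_zero_column_warns():
    m = make_matrix([[0, 5], [0, 5]], stages=("A",), reps=2)
    with pytest.warns(UserWarning, match="all-zero"):
        out = normalize(m, {"g0": 100, "g1": 100}, "tpm")
    assert np.all(out.values[:, 0] == 0)


# ------------------------------------------------------------------ QC

def _pearson_double_loop(X):
    """Brute-force sample-sample Pearson on log2(x+1) columns."""
    X = np.log2(X + 1.0)
    n = X.shape[1]
    R = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = X[:, i], X[:, j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum()
                          * ((xj - xj.mean()) ** 2).sum())
            R[i, j] = num / den
    return R


def test_pearson_matches_brute_force():
    rng = np.random.default_rng(0)
    X = rng.gamma(2.0, 50.0, size=(10, 6))
    m = make_matrix(X, stages=("A", "B", "C"), reps=2)
    qc = replicate_qc(m)
    np.testing.assert_allclose(qc.pearson.to_numpy(),
                               _pearson_double_loop(X), atol=1e-12)


def test_duplicated_sample_column_is_perfectly_correlated():
    rng = np.random.default_rng(1)
    col = rng.gamma(2.0, 50.0, size=20)
    X = np.column_stack([col, col, rng.gamma(2.0, 50.0, size=20),
                         rng.gamma(2.0, 50.0, size=20)])
    qc = replicate_qc(make_matrix(X, stages=("A", "B"), reps=2))
    assert qc.pearson.iloc[0, 1] == pytest.approx(1.0)
    np.testing.assert_allclose(qc.pca_scores.iloc[0].to_numpy(),
                               qc.pca_scores.iloc[1].to_numpy(), atol=1e-8)


def test_low_pair_boundary_at_0_8():
    """A within-stage pair below 0.8 lands in low_pairs; a pair at
    exactly r = 0.80 does not (strict threshold)."""
    # on the log2(x+1) scale these two columns are the integer vectors
    # (0,0,0,0,0,1) and (0,0,0,1,1,2), whose Pearson correlation is
    # exactly 0.8 in float64 arithmetic
    a = np.array([0, 0, 0, 0, 0, 1], dtype=float)
    b = np.array([0, 0, 0, 1, 1, 2], dtype=float)
    X = np.column_stack([2**a - 1, 2**b - 1])
    qc = replicate_qc(make_matrix(X, stages=("A",), reps=2), k=1)
    assert qc.pearson.iloc[0, 1] == 0.8
    assert qc.low_pairs == []

    # breaking the pattern drops the correlation below the threshold
    b_low = np.array([2, 0, 0, 1, 1, 0], dtype=float)
    X = np.column_stack([2**a - 1, 2**b_low - 1])
    qc = replicate_qc(make_matrix(X, stages=("A",), reps=2), k=1)
    assert qc.pearson.iloc[0, 1] < 0.8
    assert len(qc.low_pairs) == 1


def test_pca_variance_fractions_sorted_and_match_full_spectrum():
    rng = np.random.default_rng(3)
    X = rng.gamma(2.0, 50.0, size=(20, 12))
    m = make_matrix(X, stages=("A", "B", "C", "D"), reps=3)
    qc = replicate_qc(m, k=12)
    frac = qc.pca_variance_fraction
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() <= 1.0 + 1e-9
    # independent full-spectrum recomputation via covariance eigenvalues
    L = np.log2(X + 1.0).T
    C = np.cov(L, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(C))[::-1]
    np.testing.assert_allclose(frac[:11], (eig / eig.sum())[:11], atol=1e-9)


def test_constant_column_flagged_undefined():
    X = np.array([[5.0, 1.0, 2.0], [5.0, 3.0, 1.0], [5.0, 8.0, 9.0]])
    qc = replicate_qc(make_matrix(X, stages=("A",), reps=3), k=1)
    assert qc.undefined_samples == ["A_1"]
    assert np.isnan(qc.pearson.iloc[0, 1])
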