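"""Expression matrices: count I/O, FPKM/TPM normalization, replicate QC.

The central container is :class:`ExpressionMatrix`, a genes x samples
array with an ordered stage design and a unit tag (``count``, ``FPKM``
or ``TPM``).  Sample columns are named ``STAGE_REP`` and grouped by
stage in stage order.

Normalization formulas
----------------------
FPKM_ij = c_ij * 1e9 / (L_i * N_j), with N_j the column (library) sum.
TPM_ij  = 1e6 * (c_ij / L_i) / sum_g (c_gj / L_g), so every nonzero
column sums to exactly 1e6.

Replicate QC computes the sample-sample Pearson matrix and a PCA, both
on log2(x + 1)-transformed columns.  Within-stage pairs with r < 0.8
are flagged as low-correlation replicates; flagging is report-only, the
decision to drop a sample is left to the analyst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

Unit = Literal["count", "FPKM", "TPM"]


class FormatError(ValueError):
    """Raised for malformed count tables."""


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    samples: list[tuple[str, int]]  # (stage, replicate), grouped by stage
    stage_order: list[str]
    values: np.ndarray  # genes x samples, non-negative
    unit: Unit = "count"
    unknown_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("values shape does not match gene/sample lists")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        seen_stages = [s for s, _ in self.samples]
        for st in self.stage_order:
            if seen_stages.count(st) < 1:
                raise ValueError(f"stage {st!r} has no replicate")
        # replicates must be contiguous and in stage order
        expect = [s for st in self.stage_order for s in seen_stages if s == st]
        if seen_stages != expect:
            raise ValueError("columns not grouped by stage in stage order")

    # -- convenience -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def columns(self) -> list[str]:
        return [f"{st}_{rep}" for st, rep in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.columns)

    def stage_columns(self, stage: str) -> np.ndarray:
        idx = [i for i, (st, _) in enumerate(self.samples) if st == stage]
        return np.asarray(idx, dtype=int)

    def stage_means(self) -> pd.DataFrame:
        """Mean over replicates, genes x stages in stage order."""
        cols = {st: self.values[:, self.stage_columns(st)].mean(axis=1)
                for st in self.stage_order}
        return pd.DataFrame(cols, index=self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.samples), list(self.stage_order),
            self.values[idx], self.unit,
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        if self.unit == "count":
            df = df.astype(int)
        df.to_csv(path, sep="\t", index_label="gene_id")


def _parse_sample_columns(columns: Sequence[str]) -> tuple[list[tuple[str, int]], list[str]]:
    samples, stage_order = [], []
    for col in columns:
        stage, _, rep = col.rpartition("_")
        if not stage or not rep.isdigit():
            raise FormatError(f"sample column {col!r} is not STAGE_REP formatted")
        samples.append((stage, int(rep)))
        if stage not in stage_order:
            stage_order.append(stage)
    return samples, stage_order


def read_counts(path: str | Path, annotation: Sequence | None = None) -> ExpressionMatrix:
    """Read an integer count TSV (genes x samples, ``STAGE_REP`` header).

    ``annotation`` may be a list of :class:`~cernapipe.gffio.GeneModel`
    or plain gene ids; gene ids absent from it are recorded on the
    returned matrix (and warned about), not dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty count file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: no genes or no samples")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    for col in df.columns:
        vals = df[col]
        bad = ~vals.map(lambda v: isinstance(v, (int, np.integer)) or float(v).is_integer())
        if bad.any():
            raise FormatError(
                f"{path}: non-integer count at gene {vals.index[bad][0]!r}, column {col!r}")
        neg = vals < 0
        if neg.any():
            raise FormatError(
                f"{path}: negative count at gene {vals.index[neg][0]!r}, column {col!r}")
    samples, stage_order = _parse_sample_columns(df.columns)
    unknown: list[str] = []
    if annotation is not None:
        known = {getattr(g, "gene_id", g) for g in annotation}
        unknown = [g for g in df.index if g not in known]
        if unknown:
            warnings.warn(f"{len(unknown)} gene ids not in annotation "
                          f"(e.g. {unknown[:3]})", stacklevel=2)
    return ExpressionMatrix(
        gene_ids=df.index.tolist(), samples=samples, stage_order=stage_order,
        values=df.to_numpy(dtype=float), unit="count", unknown_genes=unknown,
    )


def normalize(counts: ExpressionMatrix, lengths: Mapping[str, int],
              mode: Literal["fpkm", "tpm"]) -> ExpressionMatrix:
    """Length/depth normalization of a count matrix to FPKM or TPM."""
    if counts.unit != "count":
        raise ValueError(f"normalize expects counts, got unit={counts.unit}")
    L = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    if np.any(L < 1):
        raise ValueError("gene length < 1 bp")
    c = counts.values
    if mode == "fpkm":
        N = c.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(N > 0, c * 1e9 / (L[:, None] * N[None, :]), 0.0)
        unit: Unit = "FPKM"
    elif mode == "tpm":
        rate = c / L[:, None]
        denom = rate.sum(axis=0)
        zero_cols = denom == 0
        if zero_cols.any():
            warnings.warn(f"all-zero columns in TPM normalization: "
                          f"{[counts.columns[i] for i in np.where(zero_cols)[0]]}",
                          stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(~zero_cols[None, :], 1e6 * rate / denom[None, :], 0.0)
        unit = "TPM"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.samples), list(counts.stage_order),
        out, unit,
    )


@dataclass
class QCReport:
    pearson: pd.DataFrame          # samples x samples; NaN where undefined
    low_pairs: list[tuple[str, str, float]]  # within-stage pairs with r < 0.8
    pca_scores: pd.DataFrame       # samples x k, centered
    pca_variance_fraction: np.ndarray
    undefined_samples: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "low_pairs": [[a, b, r] for a, b, r in self.low_pairs],
            "undefined_samples": self.undefined_samples,
            "pca_variance_fraction": self.pca_variance_fraction.tolist(),
        }


def replicate_qc(expr: ExpressionMatrix, k: int = 2,
                 low_r: float = 0.8) -> QCReport:
    """Sample-level QC: Pearson matrix and PCA on log2(x+1) columns.

    Constant columns get flagged as undefined (their correlations are
    reported as NaN rather than propagating through silently).
    """
    if expr.n_samples < 2:
        raise ValueError("replicate_qc needs >= 2 samples")
    if k > expr.n_samples:
        raise ValueError("k exceeds sample count")
    X = np.log2(expr.values + 1.0)  # genes x samples
    sd = X.std(axis=0)
    undefined = [expr.columns[i] for i in np.where(sd == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X.T)
    R = np.asarray(R, dtype=float)
    for i in np.where(sd == 0)[0]:
        R[i, :] = np.nan
        R[:, i] = np.nan
    np.fill_diagonal(R, 1.0)
    cols = expr.columns
    pearson = pd.DataFrame(R, index=cols, columns=cols)

    low_pairs = []
    for stage in expr.stage_order:
        idx = expr.stage_columns(stage)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r = R[idx[a], idx[b]]
                if np.isfinite(r) and r < low_r:
                    low_pairs.append((cols[idx[a]], cols[idx[b]], float(r)))

    # PCA: samples as observations, genes as features, covariance-based
    M = X.T - X.T.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    eig = S**2 / max(expr.n_samples - 1, 1)
    total_var = M.var(axis=0, ddof=1).sum()
    frac = eig / total_var if total_var > 0 else np.zeros_like(eig)
    scores = (U * S)[:, :k]
    return QCReport(
        pearson=pearson,
        low_pairs=low_pairs,
        pca_scores=pd.DataFrame(scores, index=cols,
                                columns=[f"PC{i+1}" for i in range(k)]),
        pca_variance_fraction=frac[:k],
        undefined_samples=undefined,
    )
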