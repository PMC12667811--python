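"""Regulon-based transcription-factor activity from fold-change vectors.

A TF's activity in a neuron is inferred from the behavior of its target
genes: the per-gene differential-expression log2 fold changes are
regressed jointly on all TF regulon weight columns (multivariate linear
model with intercept), and the activity score is the t-statistic of each
TF's coefficient.  Significant activity requires a BH-adjusted p < 0.05
within the neuron and detection of the TF transcript in that neuron at
one of the compared stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["RegulonMatrix", "ActivityRecord", "mlm_activity", "filter_activity"]


@dataclass
class RegulonMatrix:
    """Signed gene x TF regulon weights (0 = gene not in the regulon)."""

    weights: pd.DataFrame  # gene x TF

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("regulon weights must be finite")

    @property
    def tf_names(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def gene_names(self) -> list[str]:
        return list(self.weights.index)

    def testable(self) -> list[str]:
        """TFs with at least two nonzero target weights."""
        nz = (self.weights != 0).sum(axis=0)
        return list(nz.index[nz >= 2])


@dataclass
class ActivityRecord:
    tf: str
    neuron_class: str
    score: float  # coefficient t-statistic
    p: float
    p_adj: float = np.nan
    detected: bool = False
    significant: bool = False
    tested: bool = True


def mlm_activity(
    logfc: pd.Series, regulons: RegulonMatrix, neuron_class: str = ""
) -> list[ActivityRecord]:
    """Joint OLS of the fold-change vector on all regulon columns.

    The design has an intercept plus one column per TF; scores are the
    coefficient t-statistics with two-sided p-values on the residual
    degrees of freedom.  Collinear columns are dropped with a warning and
    the affected TFs reported as untested.
    """
    genes = [g for g in logfc.index if g in set(regulons.gene_names)]
    W = regulons.weights.loc[genes]
    y = logfc.loc[genes].to_numpy(dtype=float)
    tfs = list(W.columns)
    X = np.column_stack([np.ones(len(genes)), W.to_numpy(dtype=float)])
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more genes than TFs + 1 to fit the model")

    # drop collinear columns (never the intercept) via rank-revealing QR
    keep = [0]
    dropped: list[int] = []
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(j)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} collinear regulon column(s): "
            f"{[tfs[j - 1] for j in dropped]}",
            stacklevel=2,
        )
    Xk = X[:, keep]
    nobs, ncol = Xk.shape
    df_resid = nobs - ncol
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    beta = xtx_inv @ (Xk.T @ y)
    resid = y - Xk @ beta
    rss = float(resid @ resid)
    sigma2 = rss / df_resid if df_resid > 0 else 0.0
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))

    records: list[ActivityRecord] = []
    coef_by_col = dict(zip(keep, range(len(keep))))
    for j, tf in enumerate(tfs, start=1):
        if j in coef_by_col:
            b = beta[coef_by_col[j]]
            s = se[coef_by_col[j]]
            if s > 0:
                t = b / s
                p = float(2 * stats.t.sf(abs(t), df=df_resid))
            elif abs(b) < 1e-12:
                t, p = 0.0, 1.0  # perfectly flat fit: no evidence either way
            else:
                t = np.inf if b > 0 else -np.inf  # exact fit with signal
                p = 0.0
            records.append(
                ActivityRecord(tf=tf, neuron_class=neuron_class, score=float(t), p=p)
            )
        else:
            records.append(
                ActivityRecord(
                    tf=tf, neuron_class=neuron_class, score=np.nan, p=np.nan,
                    tested=False,
                )
            )
    return records


def filter_activity(
    records: list[ActivityRecord],
    detection: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> list[ActivityRecord]:
    """BH-adjust within each neuron and keep significant, detected TFs.

    `detection` maps stage labels to gene x class binary matrices; a TF
    counts as detected when its transcript is called in the record's
    neuron class at one or more stages.  Returns only the significant
    records (p_adj < alpha and detected); all input records gain p_adj,
    detected and significant flags in place.
    """
    by_class: dict[str, list[ActivityRecord]] = {}
    for r in records:
        if r.tested:
            by_class.setdefault(r.neuron_class, []).append(r)
    for cls, recs in by_class.items():
        padj = multipletests([r.p for r in recs], method="fdr_bh")[1]
        for r, q in zip(recs, padj):
            r.p_adj = float(q)
    for r in records:
        det = False
        for mat in detection.values():
            if r.tf in mat.index and r.neuron_class in mat.columns:
                det = det or bool(mat.loc[r.tf, r.neuron_class])
        r.detected = det
        r.significant = bool(r.tested and r.p_adj < alpha and det)
    return [r for r in records if r.significant]
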