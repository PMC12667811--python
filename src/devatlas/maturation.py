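"""Maturation indices from a 2-D embedding and gene–maturation correlation.

For a newly born neuron class, the embedding distance of each cell from
the branch point separating the progenitor cluster from the post-mitotic
cells serves as a pseudo-temporal maturation axis.  The Euclidean
distance is the maturation index proper; the Manhattan distance is
computed and reported alongside it but not consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MaturationResult", "maturation_index", "correlate_with_maturation"]


@dataclass
class MaturationResult:
    index: np.ndarray  # Euclidean distance from baseline, per cell
    manhattan: np.ndarray
    baseline: np.ndarray


def maturation_index(
    coords: np.ndarray, baseline: tuple[float, float] | np.ndarray
) -> MaturationResult:
    """Euclidean (index) and Manhattan distances of each cell from baseline.

    The baseline is a user-chosen embedding coordinate at the
    progenitor / post-mitotic branch point.
    """
    coords = np.asarray(coords, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or baseline.shape != (2,):
        raise ValueError("coords must be n x 2 and baseline a 2-vector")
    if not (np.isfinite(coords).all() and np.isfinite(baseline).all()):
        raise ValueError("coordinates must be finite")
    delta = coords - baseline[None, :]
    return MaturationResult(
        index=np.sqrt((delta**2).sum(axis=1)),
        manhattan=np.abs(delta).sum(axis=1),
        baseline=baseline,
    )


def correlate_with_maturation(
    expr: pd.DataFrame,
    result: MaturationResult,
    log_transform: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between expression and the index.

    Expression should be restricted to cells of one post-mitotic class.
    By default expression is log2(x + 1)-transformed first.  Constant
    genes have undefined correlation: they are reported with r = NaN and
    excluded from the Bonferroni denominator.  Returns a DataFrame with
    columns r, p, p_bonf, significant indexed by gene.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 cells to correlate")
    if expr.shape[0] != result.index.size:
        raise ValueError("expression rows must match maturation cells")
    x = result.index
    vals = expr.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    constant = np.ptp(vals, axis=0) == 0
    if np.ptp(x) == 0:
        raise ValueError("maturation index is constant across cells")
    n_tested = int((~constant).sum())
    r = np.full(vals.shape[1], np.nan)
    p = np.full(vals.shape[1], np.nan)
    xc = x - x.mean()
    vc = vals - vals.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (vc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r[~constant] = ((xc[:, None] * vc).sum(axis=0) / denom)[~constant]
    r = np.clip(r, -1.0, 1.0)
    n = vals.shape[0]
    # two-sided p from the t transform of r
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p[~constant] = 2 * stats.t.sf(np.abs(t[~constant]), df=n - 2)
    p_bonf = np.minimum(1.0, p * n_tested)
    out = pd.DataFrame(
        {
            "r": r,
            "p": p,
            "p_bonf": p_bonf,
            "significant": p_bonf < alpha,
        },
        index=expr.columns,
    )
    out.loc[constant, "significant"] = False
    return out
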