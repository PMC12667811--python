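"""Pseudobulk aggregation and dynamic per-gene expression thresholding.

Single cells are size-factor normalized, averaged within each neuron
class, and rescaled so every class column sums to one million (a TPM-like
scale).  A gene is then thresholded dynamically: its cutoff is a fixed
fraction of its *own* maximum detection proportion across classes, so
broadly and sparsely detected genes are treated on their own scale.
Threshold stringency is calibrated against a curated binary ground truth
by computing TPR / FPR / FDR across a grid of fractions, with BCa
confidence intervals from a stratified bootstrap over ground-truth genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SingleCellDataset

__all__ = [
    "PseudobulkProfile",
    "ThresholdedExpression",
    "CalibrationTable",
    "size_factor_normalize",
    "aggregate_profiles",
    "prefilter_genes",
    "dynamic_threshold",
    "confusion_rates",
    "calibrate_thresholds",
    "select_levels",
    "default_fraction_grid",
]

TPM_SCALE = 1_000_000.0


@dataclass
class PseudobulkProfile:
    """Per-class detection proportions and TPM-scaled mean expression."""

    proportion: pd.DataFrame  # gene x class, in [0, 1]
    tpm: pd.DataFrame  # gene x class, columns sum to 1e6
    n_cells: pd.Series  # per-class cell counts


@dataclass
class ThresholdedExpression:
    """Expression after dynamic thresholding at one fraction."""

    tpm_thresholded: pd.DataFrame
    fraction: float
    per_gene_cutoff: pd.Series
    retained_ubiquitous: list[str] = field(default_factory=list)
    removed_low: list[str] = field(default_factory=list)
    level: int | None = None

    def binary(self) -> pd.DataFrame:
        """Binarized expression calls (TPM > 0)."""
        return (self.tpm_thresholded > 0).astype(int)


@dataclass
class CalibrationTable:
    """TPR/FPR/FDR point estimates with BCa intervals per fraction."""

    table: pd.DataFrame
    n_boot: int
    seed: int


def default_fraction_grid(n: int = 272) -> np.ndarray:
    """Evenly spaced fraction grid on [0, 1] inclusive."""
    return np.linspace(0.0, 1.0, n)


def size_factor_normalize(dataset: SingleCellDataset) -> pd.DataFrame:
    """Divide each cell's counts by its size factor.

    The size factor is the cell's total UMI count divided by the
    geometric mean of all cells' totals, so the factors themselves have
    geometric mean 1.
    """
    totals = dataset.counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell index {zero[0]} has zero total UMI count")
    geo = np.exp(np.mean(np.log(totals)))
    factors = totals / geo
    norm = dataset.counts / factors[:, None]
    return pd.DataFrame(norm, columns=dataset.gene_names)


def aggregate_profiles(
    normalized: pd.DataFrame, cell_class: pd.Series
) -> PseudobulkProfile:
    """Aggregate normalized single cells into per-class pseudobulk.

    Detection proportion counts cells with any signal (>= 1 raw UMI,
    equivalently nonzero normalized expression since size factors are
    positive).  TPM is the per-class mean normalized expression rescaled
    so each class column sums to one million.
    """
    labels = pd.Series(np.asarray(cell_class), name="cell_class")
    if len(labels) != normalized.shape[0]:
        raise ValueError("cell_class length does not match cell count")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("every class must contain at least one cell")
    mean = normalized.groupby(labels.to_numpy()).mean().T  # gene x class
    prop = (normalized > 0).groupby(labels.to_numpy()).mean().T
    colsum = mean.sum(axis=0)
    tpm = mean * (TPM_SCALE / colsum.replace(0, np.nan))
    tpm = tpm.fillna(0.0)
    return PseudobulkProfile(
        proportion=prop, tpm=tpm, n_cells=counts.reindex(mean.columns)
    )


def prefilter_genes(
    profile: PseudobulkProfile,
    ubiq_prop: float = 0.01,
    low_prop: float = 0.02,
) -> dict[str, list[str]]:
    """Partition genes before dynamic thresholding.

    Genes detected in > ubiq_prop of cells of *every* class are kept
    unthresholded (ubiquitous); genes below low_prop in every class are
    removed as not expressed; the remainder go on to dynamic
    thresholding.  A gene satisfying both rules counts as ubiquitous,
    with a warning (the overlap is pathological in real data).
    """
    prop = profile.proportion
    ubiq = (prop > ubiq_prop).all(axis=1)
    low = (prop < low_prop).all(axis=1)
    both = ubiq & low
    if both.any():
        warnings.warn(
            f"{int(both.sum())} gene(s) satisfy both the ubiquitous and "
            "low-expression prefilters; keeping them as ubiquitous",
            stacklevel=2,
        )
    low = low & ~ubiq
    rest = ~ubiq & ~low
    return {
        "retained_ubiquitous": list(prop.index[ubiq]),
        "removed_low": list(prop.index[low]),
        "to_threshold": list(prop.index[rest]),
    }


def dynamic_threshold(
    profile: PseudobulkProfile,
    fraction: float,
    gene_set: list[str] | None = None,
    retained_ubiquitous: list[str] | None = None,
    removed_low: list[str] | None = None,
    level: int | None = None,
) -> ThresholdedExpression:
    """Zero out TPM where detection falls below the per-gene cutoff.

    The cutoff for gene g is fraction x (its maximum detection proportion
    over classes); a class is zeroed when its proportion is strictly
    below the cutoff, so a class sitting exactly at the cutoff keeps its
    continuous TPM.  Ubiquitous genes pass through unthresholded and
    removed genes are zeroed everywhere.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    prop, tpm = profile.proportion, profile.tpm
    if gene_set is None:
        gene_set = list(prop.index)
    retained_ubiquitous = retained_ubiquitous or []
    removed_low = removed_low or []

    maxprop = prop.loc[gene_set].max(axis=1)
    if (maxprop == 0).any():
        bad = maxprop.index[maxprop == 0][0]
        raise ValueError(
            f"gene {bad!r} has maximum detection proportion 0; it should "
            "have been removed by the prefilter"
        )
    cutoff = fraction * maxprop
    out = tpm.copy()
    zero_mask = prop.loc[gene_set].lt(cutoff, axis=0)
    out.loc[gene_set] = tpm.loc[gene_set].where(~zero_mask, 0.0)
    if removed_low:
        out.loc[removed_low] = 0.0
    # ubiquitous genes keep their unthresholded TPM
    if retained_ubiquitous:
        out.loc[retained_ubiquitous] = tpm.loc[retained_ubiquitous]
    full_cutoff = pd.Series(0.0, index=tpm.index)
    full_cutoff.loc[gene_set] = cutoff
    return ThresholdedExpression(
        tpm_thresholded=out,
        fraction=fraction,
        per_gene_cutoff=full_cutoff,
        retained_ubiquitous=list(retained_ubiquitous),
        removed_low=list(removed_low),
        level=level,
    )


def confusion_rates(
    calls: pd.DataFrame | np.ndarray, truth: pd.DataFrame | np.ndarray
) -> tuple[float, float, float]:
    """TPR, FPR and FDR of binary calls against binary truth.

    FDR is defined as 0 when no positives are predicted, so a fully
    conservative caller scores (0, 0, 0) rather than NaN.
    """
    c = np.asarray(calls, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if c.shape != t.shape:
        raise ValueError(f"shape mismatch: calls {c.shape} vs truth {t.shape}")
    tp = int(np.sum(c & t))
    fp = int(np.sum(c & ~t))
    fn = int(np.sum(~c & t))
    tn = int(np.sum(~c & ~t))
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return tpr, fpr, fdr


def _per_gene_confusion(calls: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-gene (TP, FP, FN, TN) counts over classes; shape (G, 4)."""
    c = calls.astype(bool)
    t = truth.astype(bool)
    return np.stack(
        [
            (c & t).sum(axis=1),
            (c & ~t).sum(axis=1),
            (~c & t).sum(axis=1),
            (~c & ~t).sum(axis=1),
        ],
        axis=1,
    ).astype(float)


def _rates_from_counts(counts: np.ndarray) -> np.ndarray:
    """(tpr, fpr, fdr) from summed (TP, FP, FN, TN) counts."""
    tp, fp, fn, tn = counts
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return np.array([tpr, fpr, fdr])


def _strata(truth: np.ndarray, n_bins: int = 4) -> list[np.ndarray]:
    """Quartile strata of genes by their positive-class fraction.

    Strata with fewer than two genes are merged with their neighbor (with
    a warning) so resampling within each stratum is meaningful.
    """
    pos_frac = truth.mean(axis=1)
    qs = np.quantile(pos_frac, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    bins = np.clip(np.searchsorted(edges, pos_frac, side="right") - 1, 0, len(edges) - 2)
    groups = [np.flatnonzero(bins == b) for b in range(len(edges) - 1)]
    groups = [g for g in groups if g.size > 0]
    merged: list[np.ndarray] = []
    for g in groups:
        if g.size < 2 and merged:
            warnings.warn("merging a bootstrap stratum with <2 genes into its neighbor",
                          stacklevel=2)
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    if len(merged) > 1 and merged[0].size < 2:
        warnings.warn("merging a bootstrap stratum with <2 genes into its neighbor",
                      stacklevel=2)
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]
    return merged


def _bca_interval(
    boot: np.ndarray, point: float, jack: np.ndarray, ci: float
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from bootstrap replicates.

    z0 comes from the fraction of replicates below the point estimate;
    the acceleration constant from the skew of leave-one-out jackknife
    values.  Degenerate (constant) bootstrap distributions collapse to
    the point estimate.
    """
    if np.allclose(boot, boot[0]) or np.allclose(jack, jack.mean()):
        return float(point), float(point)
    alpha = (1.0 - ci) / 2.0
    # midrank convention keeps z0 finite when point sits at an edge
    prop = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / boot.size
    prop = np.clip(prop, 1.0 / (boot.size + 1), 1.0 - 1.0 / (boot.size + 1))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    zlo, zhi = stats.norm.ppf([alpha, 1.0 - alpha])
    lo_p = stats.norm.cdf(z0 + (z0 + zlo) / (1.0 - a * (z0 + zlo)))
    hi_p = stats.norm.cdf(z0 + (z0 + zhi) / (1.0 - a * (z0 + zhi)))
    lo, hi = np.quantile(boot, [lo_p, hi_p])
    return float(lo), float(hi)


def calibrate_thresholds(
    profile: PseudobulkProfile,
    truth: pd.DataFrame,
    fractions: np.ndarray | list[float] | None = None,
    n_boot: int = 5000,
    ci: float = 0.95,
    seed: int = 0,
    gene_partition: dict[str, list[str]] | None = None,
) -> CalibrationTable:
    """TPR/FPR/FDR across a fraction grid, with stratified-bootstrap BCa CIs.

    For each fraction the thresholded expression on ground-truth genes is
    binarized and compared against the truth matrix; point estimates use
    all ground-truth genes directly (they do not depend on the bootstrap
    seed).  Confidence intervals resample genes with replacement within
    strata defined by each gene's positive-class fraction (quartile bins),
    with acceleration from a leave-one-gene-out jackknife.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if fractions is None:
        fractions = default_fraction_grid()
    fractions = np.asarray(fractions, dtype=float)
    genes = list(truth.index)
    missing = [g for g in genes if g not in profile.proportion.index]
    if missing:
        raise ValueError(f"truth genes absent from profile: {missing[:5]}")
    truth_m = truth.to_numpy().astype(bool)
    classes = list(truth.columns)

    rng = np.random.default_rng(seed)
    strata = _strata(truth_m)
    n_genes = len(genes)
    # one shared set of stratified resample indices across fractions keeps
    # replicate-to-replicate comparisons across the grid coherent
    boot_idx = np.empty((n_boot, n_genes), dtype=np.intp)
    col = 0
    for g in strata:
        boot_idx[:, col : col + g.size] = rng.choice(g, size=(n_boot, g.size))
        col += g.size

    if gene_partition is not None:
        kwargs = {
            "gene_set": gene_partition["to_threshold"],
            "retained_ubiquitous": gene_partition["retained_ubiquitous"],
            "removed_low": gene_partition["removed_low"],
        }
    else:
        # never-detected genes cannot carry a dynamic cutoff; treat them as
        # removed so they are called negative at every fraction
        maxprop = profile.proportion.max(axis=1)
        kwargs = {
            "gene_set": list(maxprop.index[maxprop > 0]),
            "retained_ubiquitous": [],
            "removed_low": list(maxprop.index[maxprop == 0]),
        }

    rows = []
    for frac in fractions:
        thr = dynamic_threshold(profile, float(frac), **kwargs)
        calls = (thr.tpm_thresholded.loc[genes, classes].to_numpy() > 0)
        per_gene = _per_gene_confusion(calls, truth_m)
        total = per_gene.sum(axis=0)
        point = _rates_from_counts(total)

        boot_counts = per_gene[boot_idx].sum(axis=1)  # n_boot x 4
        tp, fp, fn, tn = boot_counts.T
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_rates = np.stack(
                [
                    np.where(tp + fn > 0, tp / (tp + fn), 0.0),
                    np.where(fp + tn > 0, fp / (fp + tn), 0.0),
                    np.where(tp + fp > 0, fp / (tp + fp), 0.0),
                ],
                axis=1,
            )
        jack_counts = total[None, :] - per_gene  # leave-one-gene-out
        jtp, jfp, jfn, jtn = jack_counts.T
        with np.errstate(invalid="ignore", divide="ignore"):
            jack_rates = np.stack(
                [
                    np.where(jtp + jfn > 0, jtp / (jtp + jfn), 0.0),
                    np.where(jfp + jtn > 0, jfp / (jfp + jtn), 0.0),
                    np.where(jtp + jfp > 0, jfp / (jtp + jfp), 0.0),
                ],
                axis=1,
            )
        row = {"fraction": float(frac)}
        for i, name in enumerate(("tpr", "fpr", "fdr")):
            lo, hi = _bca_interval(boot_rates[:, i], point[i], jack_rates[:, i], ci)
            # the interval must bracket the (bootstrap-free) point estimate
            lo, hi = min(lo, point[i]), max(hi, point[i])
            row[name] = float(point[i])
            row[f"{name}_ci_lo"] = lo
            row[f"{name}_ci_hi"] = hi
        rows.append(row)
    return CalibrationTable(table=pd.DataFrame(rows), n_boot=n_boot, seed=seed)


def select_levels(
    table: CalibrationTable, target_rates: list[tuple[float, float, float]]
) -> list[float]:
    """Grid fractions best matching target (TPR, FPR, FDR) triples.

    Minimizes the summed absolute deviation from the target rates; ties
    break toward the smaller fraction.
    """
    df = table.table
    if df.empty:
        raise ValueError("empty calibration table")
    df = df.sort_values("fraction", kind="stable").reset_index(drop=True)
    out = []
    for tpr, fpr, fdr in target_rates:
        dev = (
            (df["tpr"] - tpr).abs() + (df["fpr"] - fpr).abs() + (df["fdr"] - fdr).abs()
        )
        out.append(float(df.loc[dev.idxmin(), "fraction"]))
    return out
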