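"""Cross-stage differential expression, stability and enrichment metrics.

Stage-to-stage comparisons test each gene within each neuron class with a
two-sided Wilcoxon rank-sum test on log-normalized expression, report an
average log2 fold change whose positive direction means higher expression
in the older stage, and retain hits passing four criteria: BH-adjusted
p < 0.05, |avg_log2fc| >= 1, detection in > 10% of cells and in > 5 cells
of the higher-expressing stage.  Companion metrics quantify per-gene
expression stability across stages and category fold-enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import SingleCellDataset
from .threshold import size_factor_normalize

__all__ = [
    "DERecord",
    "wilcoxon_de",
    "filter_de",
    "stability_jaccard",
    "fold_enrichment",
    "broad_downregulation",
    "direction_consistency",
    "compare_stage_datasets",
    "records_to_frame",
]

EXACT_LIMIT = 200_000  # max rank-assignment enumerations for the exact test


@dataclass
class DERecord:
    """One gene x neuron-class differential-expression result."""

    gene: str
    neuron_class: str
    avg_log2fc: float  # positive => higher in the older stage
    p: float
    p_adj: float = np.nan
    pct_older: float = np.nan
    pct_younger: float = np.nan
    n_detect_older: int = 0
    n_detect_younger: int = 0


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value.

    Uses exact enumeration of the rank-sum null distribution (with
    midranks for ties) when the number of group assignments is small,
    and the tie-corrected normal approximation otherwise.  No continuity
    correction is applied, so identical groups give p = 1 exactly.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if comb(n, n1) <= EXACT_LIMIT:
        dev = abs(w - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return count / total
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def wilcoxon_de(
    cells_a: np.ndarray, cells_b: np.ndarray, pseudocount: float = 1.0
) -> tuple[float, float]:
    """(avg_log2fc, p) between two groups of log-normalized expression.

    Group a is the older stage.  The fold change compares group means on
    the de-logged (normalized) scale with `pseudocount` added before
    taking log2, so genes absent from one group stay finite.
    """
    a = np.asarray(cells_a, dtype=float)
    b = np.asarray(cells_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one cell")
    lfc = float(
        np.log2(np.expm1(a).mean() + pseudocount)
        - np.log2(np.expm1(b).mean() + pseudocount)
    )
    return lfc, _ranksum_p(a, b)


def filter_de(
    records: list[DERecord],
    exclusion: list[str] | None = None,
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    min_pct: float = 0.10,
    min_cells: int = 5,
) -> list[DERecord]:
    """Retain records passing the four-criterion filter.

    Keeps p_adj < alpha, |avg_log2fc| >= min_lfc, detection fraction
    strictly above min_pct and detection in strictly more than min_cells
    cells, both assessed in the higher-expressing stage; records whose
    gene is on the exclusion list are dropped.
    """
    excl = set(exclusion or [])
    out = []
    for r in records:
        if r.gene in excl:
            continue
        if not (r.p_adj < alpha and abs(r.avg_log2fc) >= min_lfc):
            continue
        if r.avg_log2fc > 0:
            pct, ndet = r.pct_older, r.n_detect_older
        else:
            pct, ndet = r.pct_younger, r.n_detect_younger
        if pct > min_pct and ndet > min_cells:
            out.append(r)
    return out


def stability_jaccard(
    bin_young: pd.DataFrame, bin_old: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene stability and Jaccard similarity of binary detection.

    stability = |both| / (|both| + |young only|): the fraction of classes
    expressing the gene at the younger stage that still express it at the
    older stage; undefined (NaN) for genes never detected when young.
    jaccard = |both| / |either|; undefined for genes detected at neither
    stage.  Both matrices must share the same class set.
    """
    if set(bin_young.columns) != set(bin_old.columns):
        raise ValueError("class sets differ between stages")
    old = bin_old[bin_young.columns]
    genes = bin_young.index.union(old.index)
    y = bin_young.reindex(index=genes, fill_value=0).to_numpy().astype(bool)
    o = old.reindex(index=genes, fill_value=0).to_numpy().astype(bool)
    both = (y & o).sum(axis=1)
    only_y = (y & ~o).sum(axis=1)
    only_o = (~y & o).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stability = np.where(both + only_y > 0, both / (both + only_y), np.nan)
        either = both + only_y + only_o
        jaccard = np.where(either > 0, both / either, np.nan)
    return pd.DataFrame(
        {
            "stability": stability,
            "jaccard": jaccard,
            "n_both": both,
            "n_only_young": only_y,
            "n_only_old": only_o,
        },
        index=genes,
    )


def fold_enrichment(
    k: int, n: int, K: int, N: int, n_categories: int = 1
) -> tuple[float, float, float]:
    """Fold enrichment of a query set in a category, with Fisher p.

    fold = (k/n) / (K/N) where k of the n query genes and K of the N
    background genes fall in the category.  The Fisher test is one-sided
    for over-representation; p_bonf applies a Bonferroni factor of
    n_categories.  K = 0 yields an undefined (NaN) fold.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError("counts must satisfy k <= n <= N, k <= K <= N")
    fold = (k / n) / (K / N) if K > 0 and n > 0 else float("nan")
    table = [[k, n - k], [K - k, N - n - (K - k)]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return fold, float(p), float(min(1.0, p * n_categories))


def broad_downregulation(
    de_young_pair: list[DERecord],
    de_old_pair: list[DERecord],
    min_old: int = 10,
    min_young: int = 40,
    frac: float = 0.75,
) -> list[str]:
    """Genes broadly downregulated as neurons mature.

    de_young_pair holds (already filtered) embryo-vs-younger-larva
    records, de_old_pair the younger-vs-older larval records; in both the
    positive fold-change direction means higher in the older stage.  A
    gene qualifies when it is differentially expressed in strictly more
    than min_old classes in the larval comparison with at least `frac` of
    those higher at the younger larval stage, and in strictly more than
    min_young classes in the embryo comparison with at least `frac`
    higher in the embryo.
    """

    def passing(records: list[DERecord], min_classes: int) -> set[str]:
        per_gene: dict[str, list[float]] = {}
        for r in records:
            per_gene.setdefault(r.gene, []).append(r.avg_log2fc)
        ok = set()
        for gene, lfcs in per_gene.items():
            if len(lfcs) > min_classes:
                down = sum(1 for x in lfcs if x < 0)
                if down / len(lfcs) >= frac:
                    ok.add(gene)
        return ok

    return sorted(passing(de_old_pair, min_old) & passing(de_young_pair, min_young))


def direction_consistency(records: list[DERecord]) -> dict[str, str]:
    """Classify multi-class DE genes by fold-change direction agreement.

    Genes differentially expressed in more than one class are labeled
    consistent_up / consistent_down when every class agrees in sign, and
    mixed otherwise; single-class genes are excluded.
    """
    per_gene: dict[str, list[float]] = {}
    for r in records:
        per_gene.setdefault(r.gene, []).append(r.avg_log2fc)
    out = {}
    for gene, lfcs in per_gene.items():
        if len(lfcs) < 2:
            continue
        if all(x > 0 for x in lfcs):
            out[gene] = "consistent_up"
        elif all(x < 0 for x in lfcs):
            out[gene] = "consistent_down"
        else:
            out[gene] = "mixed"
    return out


def compare_stage_datasets(
    young: SingleCellDataset,
    old: SingleCellDataset,
    class_pairs: dict[str, str] | None = None,
    pseudocount: float = 1.0,
) -> list[DERecord]:
    """Per-class differential expression between two stage datasets.

    The stages are merged over shared genes and jointly size-factor
    normalized before log1p transformation (merge-then-normalize); each
    shared class is tested gene by gene and BH-adjusted within the class.
    class_pairs maps young-stage class names to their older-stage
    counterparts (identity by default).
    """
    shared_genes = [g for g in young.gene_names if g in set(old.gene_names)]
    yi = [young.gene_names.index(g) for g in shared_genes]
    oi = [old.gene_names.index(g) for g in shared_genes]
    merged = SingleCellDataset(
        counts=np.vstack([young.counts[:, yi], old.counts[:, oi]]),
        cell_class=pd.concat([young.cell_class, old.cell_class], ignore_index=True),
        cell_stage=pd.Series(
            ["young"] * young.n_cells + ["old"] * old.n_cells, name="cell_stage"
        ),
        sample_id=pd.concat([young.sample_id, old.sample_id], ignore_index=True),
        gene_names=shared_genes,
    )
    norm = size_factor_normalize(merged)
    logn = np.log1p(norm.to_numpy())
    stage = merged.cell_stage.to_numpy()
    cls = merged.cell_class.to_numpy()
    raw = merged.counts

    if class_pairs is None:
        yc = set(young.cell_class)
        oc = set(old.cell_class)
        class_pairs = {c: c for c in sorted(yc & oc)}

    records: list[DERecord] = []
    for c_young, c_old in class_pairs.items():
        ymask = (stage == "young") & (cls == c_young)
        omask = (stage == "old") & (cls == c_old)
        if not (ymask.any() and omask.any()):
            raise ValueError(f"class pair ({c_young}, {c_old}) missing cells")
        cl_records = []
        for j, gene in enumerate(shared_genes):
            a = logn[omask, j]  # older stage is group a
            b = logn[ymask, j]
            lfc, p = wilcoxon_de(a, b, pseudocount=pseudocount)
            cl_records.append(
                DERecord(
                    gene=gene,
                    neuron_class=c_old,
                    avg_log2fc=lfc,
                    p=p,
                    pct_older=float((raw[omask, j] > 0).mean()),
                    pct_younger=float((raw[ymask, j] > 0).mean()),
                    n_detect_older=int((raw[omask, j] > 0).sum()),
                    n_detect_younger=int((raw[ymask, j] > 0).sum()),
                )
            )
        padj = multipletests([r.p for r in cl_records], method="fdr_bh")[1]
        for r, q in zip(cl_records, padj):
            r.p_adj = float(q)
        records.extend(cl_records)
    return records


def records_to_frame(records: list[DERecord]) -> pd.DataFrame:
    """Long-format DataFrame view of DE records."""
    return pd.DataFrame([vars(r) for r in records])
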