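"""Connectome-conditioned gene enrichment.

Cell-level electron-microscopy contact and synapse matrices are collapsed
to neuron-class resolution (summing left/right and other within-class
members, keeping only entries confirmed in replicate reconstructions).
For a focal neuron, candidate surface genes are then tested with Welch's
unequal-variance t-test between the classes that contact it and those
that do not, or — conditioning on contact — between its synaptic partners
and adjacent-only neighbors, with a 1e-5 pseudocount log2 fold change and
BH adjustment across the genes tested within each focal neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClassConnectome",
    "EnrichmentResult",
    "welch_t",
    "collapse_connectome",
    "contact_enrichment",
    "synaptic_enrichment",
    "annotate_binding_partners",
    "synapse_fraction_summary",
]

LOG2FC_PSEUDOCOUNT = 1e-5


@dataclass
class ClassConnectome:
    contact: pd.DataFrame  # class x class, nonnegative
    synapse: pd.DataFrame  # class x class, directed pre -> post
    provenance: list[str]

    def contacted(self, focal: str) -> list[str]:
        """Classes with any membrane contact to focal (symmetrized by max)."""
        sym = np.maximum(self.contact.to_numpy(), self.contact.to_numpy().T)
        sym_df = pd.DataFrame(sym, index=self.contact.index, columns=self.contact.columns)
        row = sym_df.loc[focal]
        return [c for c in row.index if c != focal and row[c] > 0]


@dataclass
class EnrichmentResult:
    gene: str
    focal_neuron: str
    direction: str  # contact | input | output
    t_stat: float
    df: float
    p: float
    log2fc: float
    mean_in_group: float
    mean_out_group: float
    p_adj: float = np.nan
    has_expressed_partner: bool = False
    tested: bool = True


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t with Welch–Satterthwaite df.

    Returns (t, df, two-sided p).  Two groups with zero variance and
    equal means score t = 0, p = 1 rather than 0/0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    num = a.mean() - b.mean()
    s2 = va / na + vb / nb
    if s2 == 0:
        if num == 0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(num) * np.inf), float(na + nb - 2), 0.0
    t = num / np.sqrt(s2)
    df = s2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * stats.t.sf(abs(t), df=df))
    return float(t), float(df), p


def _log2fc(mean_in: float, mean_out: float) -> float:
    return float(
        np.log2(mean_in + LOG2FC_PSEUDOCOUNT) - np.log2(mean_out + LOG2FC_PSEUDOCOUNT)
    )


def collapse_connectome(
    cell_matrices: dict[str, pd.DataFrame],
    cell_to_class: pd.Series,
    primary: str,
    confirmers: list[str] | None = None,
) -> ClassConnectome:
    """Sum a cell-level adjacency to class level with replicate filtering.

    Class entries are sums over member-cell entries of the primary
    dataset; an entry survives only when the corresponding class-level
    entry is nonzero in every confirmer dataset.  Returns the collapsed
    matrix in the `contact` slot; call twice (contacts, synapses) and
    assemble a :class:`ClassConnectome` for enrichment.
    """
    confirmers = confirmers or []

    def collapse(mat: pd.DataFrame) -> pd.DataFrame:
        unmapped = [c for c in mat.index if c not in cell_to_class.index]
        unmapped += [c for c in mat.columns if c not in cell_to_class.index]
        if unmapped:
            raise KeyError(f"cells not mapped to a class: {sorted(set(unmapped))[:5]}")
        rows = cell_to_class.loc[mat.index].to_numpy()
        cols = cell_to_class.loc[mat.columns].to_numpy()
        return mat.groupby(rows).sum().T.groupby(cols).sum().T

    out = collapse(cell_matrices[primary])
    for conf in confirmers:
        cm = collapse(cell_matrices[conf]).reindex(
            index=out.index, columns=out.columns, fill_value=0
        )
        out = out.where(cm > 0, 0)
    return ClassConnectome(contact=out, synapse=out * 0, provenance=[primary, *confirmers])


def _welch_gene_tests(
    expr: pd.DataFrame,
    group_in: list[str],
    group_out: list[str],
    focal: str,
    direction: str,
    cam_genes: list[str],
) -> list[EnrichmentResult]:
    """Welch tests per gene between two class groups, BH within focal.

    The BH denominator is the number of candidate genes actually tested
    (expressed in at least one class among the two groups); a gene with
    no expression anywhere contributes nothing and is flagged untested.
    """
    results: list[EnrichmentResult] = []
    group_len_ok = len(group_in) >= 2 and len(group_out) >= 2
    for gene in cam_genes:
        if gene not in expr.index:
            raise KeyError(f"gene {gene!r} missing from expression matrix")
        a = expr.loc[gene, group_in].to_numpy(dtype=float)
        b = expr.loc[gene, group_out].to_numpy(dtype=float)
        expressed = (a > 0).any() or (b > 0).any()
        if not (group_len_ok and expressed):
            results.append(
                EnrichmentResult(
                    gene=gene, focal_neuron=focal, direction=direction,
                    t_stat=np.nan, df=np.nan, p=np.nan,
                    log2fc=_log2fc(a.mean(), b.mean()) if group_len_ok else np.nan,
                    mean_in_group=a.mean() if a.size else np.nan,
                    mean_out_group=b.mean() if b.size else np.nan,
                    tested=False,
                )
            )
            continue
        t, df, p = welch_t(a, b)
        results.append(
            EnrichmentResult(
                gene=gene, focal_neuron=focal, direction=direction,
                t_stat=t, df=df, p=p, log2fc=_log2fc(a.mean(), b.mean()),
                mean_in_group=float(a.mean()), mean_out_group=float(b.mean()),
            )
        )
    tested = [r for r in results if r.tested]
    if tested:
        padj = multipletests([r.p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, padj):
            r.p_adj = float(q)
    return results


def contact_enrichment(
    expr: pd.DataFrame,
    connectome: ClassConnectome,
    focal: str,
    cam_genes: list[str],
) -> list[EnrichmentResult]:
    """Gene enrichment in classes contacting the focal neuron.

    Per gene, Welch's t compares expression across contacted vs
    non-contacted classes (the focal neuron excluded from both groups);
    positive t means enriched in the contacted group.
    """
    contacted = connectome.contacted(focal)
    others = [c for c in expr.columns if c != focal and c in connectome.contact.index]
    non_contacted = [c for c in others if c not in set(contacted)]
    return _welch_gene_tests(expr, contacted, non_contacted, focal, "contact", cam_genes)


def synaptic_enrichment(
    expr: pd.DataFrame,
    connectome: ClassConnectome,
    focal: str,
    direction: str,
    cam_genes: list[str],
    min_partners: int = 3,
) -> list[EnrichmentResult]:
    """Gene enrichment in synaptic partners vs adjacent-only neighbors.

    Conditioning on membrane contact with the focal neuron, classes split
    into synaptic partners (presynaptic inputs or postsynaptic outputs,
    per `direction`) and adjacent-only classes.  Focal neurons with fewer
    than min_partners synaptic partners are skipped entirely (empty
    result).  Positive t means enriched in the synaptic partners.
    """
    if direction not in ("input", "output"):
        raise ValueError("direction must be 'input' or 'output'")
    contacted = connectome.contacted(focal)
    syn = connectome.synapse
    if direction == "output":
        partners = [c for c in contacted if syn.loc[focal, c] > 0]
    else:
        partners = [c for c in contacted if syn.loc[c, focal] > 0]
    if len(partners) < min_partners:
        return []
    adjacent_only = [c for c in contacted if c not in set(partners)]
    return _welch_gene_tests(expr, partners, adjacent_only, focal, direction, cam_genes)


def annotate_binding_partners(
    results: list[EnrichmentResult],
    ppi: pd.DataFrame,
    expr_bin: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Flag results whose gene has a PPI partner expressed in the focal.

    `ppi` rows are unordered gene pairs (columns gene_a, gene_b);
    homophilic pairs (g, g) are honored.  Modifies and returns the
    results.
    """
    partners: dict[str, set[str]] = {}
    for _, row in ppi.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    for r in results:
        flag = False
        for partner in partners.get(r.gene, ()):  # absent gene -> no partners
            if partner in expr_bin.index and r.focal_neuron in expr_bin.columns:
                if expr_bin.loc[partner, r.focal_neuron] > 0:
                    flag = True
                    break
        r.has_expressed_partner = flag
    return results


def synapse_fraction_summary(connectome: ClassConnectome) -> pd.DataFrame:
    """Per-class fractions of contacted classes that are synaptic partners.

    frac_any counts partners in either direction, frac_output classes the
    focal sends output to, frac_input classes providing input.  Classes
    with no contacts get NaN and are excluded from the medians (reported
    in the DataFrame attrs).
    """
    rows = []
    syn = connectome.synapse
    for cls in connectome.contact.index:
        contacted = connectome.contacted(cls)
        if not contacted:
            rows.append({"neuron_class": cls, "frac_any": np.nan,
                         "frac_output": np.nan, "frac_input": np.nan})
            continue
        out_p = sum(1 for c in contacted if syn.loc[cls, c] > 0)
        in_p = sum(1 for c in contacted if syn.loc[c, cls] > 0)
        any_p = sum(
            1 for c in contacted if syn.loc[cls, c] > 0 or syn.loc[c, cls] > 0
        )
        n = len(contacted)
        rows.append(
            {
                "neuron_class": cls,
                "frac_any": any_p / n,
                "frac_output": out_p / n,
                "frac_input": in_p / n,
            }
        )
    df = pd.DataFrame(rows).set_index("neuron_class")
    df.attrs["medians"] = df.median(skipna=True).to_dict()
    return df
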