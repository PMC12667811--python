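"""Spatially constrained neuropeptide ligand–receptor networks.

For each high-potency neuropeptide precursor (NPP) / receptor (GPCR)
pair, an edge i -> j exists when class i expresses the NPP, class j
expresses the GPCR, and the two classes are within diffusion range —
the same neuronal process bundle (short range) or the same body region
(head / midbody / tail; mid range).  Per-pair binary layers sum into a
weighted network whose weights count the pairs connecting two classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProximityMatrix",
    "PairLayer",
    "NeuropeptideNetwork",
    "filter_interactions",
    "build_proximity",
    "build_pair_network",
    "aggregate_network",
    "degrees",
    "classify_topology",
    "compare_stages",
    "to_graphml",
]


@dataclass
class ProximityMatrix:
    reachable: pd.DataFrame  # class x class binary, symmetric, diagonal 1
    range_mode: str  # "short" or "mid"
    bundles: pd.Series
    regions: pd.Series


@dataclass
class PairLayer:
    npp_gene: str
    gpcr_gene: str
    ec50_nM: float
    adjacency: pd.DataFrame  # class x class binary, i -> j

    @property
    def name(self) -> str:
        return f"{self.npp_gene}/{self.gpcr_gene}"


@dataclass
class NeuropeptideNetwork:
    weighted: pd.DataFrame  # class x class, counts of supporting pairs
    layers: list[PairLayer]
    stage: str


def filter_interactions(
    table: pd.DataFrame,
    expr_stages: list[pd.DataFrame],
    max_ec50: float = 500.0,
) -> pd.DataFrame:
    """High-potency pairs whose genes are expressed at every stage.

    Keeps rows with ec50 <= max_ec50 (inclusive) whose NPP and GPCR genes
    are each detected in at least one class in every supplied stage-level
    binary expression matrix.
    """
    cols = {"npp_gene", "gpcr_gene", "ec50_nM"}
    if not cols.issubset(table.columns):
        raise ValueError(f"interaction table must have columns {sorted(cols)}")
    keep = table["ec50_nM"] <= max_ec50
    for expr in expr_stages:
        detected = set(expr.index[(expr > 0).any(axis=1)])
        keep &= table["npp_gene"].isin(detected) & table["gpcr_gene"].isin(detected)
    return table[keep].reset_index(drop=True)


def build_proximity(
    bundles: pd.Series, regions: pd.Series, range_mode: str
) -> ProximityMatrix:
    """Reachability between classes at short (bundle) or mid (region) range."""
    if range_mode not in ("short", "mid"):
        raise ValueError("range_mode must be 'short' or 'mid'")
    if bundles.isna().any() or regions.isna().any():
        bad = bundles.index[bundles.isna() | regions.isna()][0]
        raise ValueError(f"class {bad!r} has no bundle/region assignment")
    classes = list(bundles.index)
    key = bundles if range_mode == "short" else regions.loc[classes]
    vals = key.to_numpy()
    reach = (vals[:, None] == vals[None, :]).astype(int)
    np.fill_diagonal(reach, 1)
    return ProximityMatrix(
        reachable=pd.DataFrame(reach, index=classes, columns=classes),
        range_mode=range_mode,
        bundles=bundles,
        regions=regions.loc[classes],
    )


def build_pair_network(
    expr_bin: pd.DataFrame,
    pair: tuple[str, str, float],
    proximity: ProximityMatrix,
    allow_self_edges: bool = True,
) -> PairLayer:
    """Binary layer for one NPP/GPCR pair under the proximity mask.

    adjacency[i, j] = NPP(i) x GPCR(j) x reachable(i, j); a class
    expressing both genes gets a self-edge unless disabled.
    """
    npp, gpcr, ec50 = pair
    for g in (npp, gpcr):
        if g not in expr_bin.index:
            raise KeyError(f"gene {g!r} missing from expression matrix")
    classes = list(proximity.reachable.index)
    send = (expr_bin.loc[npp, classes].to_numpy() > 0).astype(int)
    recv = (expr_bin.loc[gpcr, classes].to_numpy() > 0).astype(int)
    adj = np.outer(send, recv) * proximity.reachable.to_numpy()
    if not allow_self_edges:
        np.fill_diagonal(adj, 0)
    return PairLayer(
        npp_gene=npp,
        gpcr_gene=gpcr,
        ec50_nM=float(ec50),
        adjacency=pd.DataFrame(adj, index=classes, columns=classes),
    )


def aggregate_network(
    layers: list[PairLayer], stage: str = "", classes: list[str] | None = None
) -> NeuropeptideNetwork:
    """Sum per-pair layers into the weighted network.

    An empty layer list with an explicit class set yields a zero matrix.
    """
    if not layers:
        if classes is None:
            raise ValueError("an empty layer list needs an explicit class set")
        zero = pd.DataFrame(0, index=classes, columns=classes)
        return NeuropeptideNetwork(weighted=zero, layers=[], stage=stage)
    classes = list(layers[0].adjacency.index)
    for lay in layers[1:]:
        if list(lay.adjacency.index) != classes:
            raise ValueError("layers do not share a class set")
    weighted = sum(lay.adjacency.to_numpy() for lay in layers)
    return NeuropeptideNetwork(
        weighted=pd.DataFrame(weighted, index=classes, columns=classes),
        layers=layers,
        stage=stage,
    )


def degrees(network: NeuropeptideNetwork) -> pd.DataFrame:
    """Binarized in/out/total degree per class.

    in_degree counts distinct senders, out_degree distinct receivers,
    degree their sum, on the binarized directed network.
    """
    binary = (network.weighted.to_numpy() > 0).astype(int)
    ind = binary.sum(axis=0)
    outd = binary.sum(axis=1)
    return pd.DataFrame(
        {"in_degree": ind, "out_degree": outd, "degree": ind + outd},
        index=network.weighted.index,
    )


def classify_topology(
    expr_bin: pd.DataFrame,
    pair: tuple[str, str],
    cutoff: int = 50,
    class_sizes: pd.Series | None = None,
) -> str:
    """Topology class of one NPP/GPCR pair from expression breadth.

    Expression of each side is restricted when it covers <= cutoff
    neurons (counted per individual neuron when class_sizes is supplied,
    per class otherwise): both restricted = local, both broad =
    pervasive, restricted ligand with broad receptor = broadcaster, and
    the converse = integrative.
    """
    npp, gpcr = pair[0], pair[1]

    def breadth(gene: str) -> float:
        expressed = expr_bin.columns[(expr_bin.loc[gene] > 0).to_numpy()]
        if class_sizes is not None:
            return float(class_sizes.loc[list(expressed)].sum())
        return float(len(expressed))

    npp_restricted = breadth(npp) <= cutoff
    gpcr_restricted = breadth(gpcr) <= cutoff
    if npp_restricted and gpcr_restricted:
        return "local"
    if not npp_restricted and not gpcr_restricted:
        return "pervasive"
    if npp_restricted:
        return "broadcaster"
    return "integrative"


def compare_stages(
    net_a: NeuropeptideNetwork, net_b: NeuropeptideNetwork
) -> tuple[pd.DataFrame, dict]:
    """Edge-level conservation taxonomy between two stage networks.

    Every ordered class pair carrying an edge in either stage is
    classified: conserved_identical (same pair sets), conserved_shared
    (at least one but not all pairs in common), conserved_different
    (edges in both stages via disjoint pair sets), or a_only / b_only.
    The summary reports conserved fractions with per-stage denominators
    (conserved edges / edges present in that stage).
    """
    classes = list(net_a.weighted.index)
    if list(net_b.weighted.index) != classes:
        shared = [c for c in classes if c in set(net_b.weighted.index)]
        if not shared:
            raise ValueError("networks share no classes")
        net_a = _restrict(net_a, shared)
        net_b = _restrict(net_b, shared)
        classes = shared

    def pair_sets(net: NeuropeptideNetwork) -> dict[tuple[str, str], set[str]]:
        out: dict[tuple[str, str], set[str]] = {}
        for lay in net.layers:
            adj = lay.adjacency.to_numpy()
            ii, jj = np.nonzero(adj)
            for i, j in zip(ii, jj):
                out.setdefault((classes[i], classes[j]), set()).add(lay.name)
        return out

    pa, pb = pair_sets(net_a), pair_sets(net_b)
    rows = []
    for edge in sorted(set(pa) | set(pb)):
        sa, sb = pa.get(edge), pb.get(edge)
        if sa and sb:
            if sa == sb:
                cat = "conserved_identical"
            elif sa & sb:
                cat = "conserved_shared"
            else:
                cat = "conserved_different"
        elif sa:
            cat = "a_only"
        else:
            cat = "b_only"
        rows.append({"sender": edge[0], "receiver": edge[1], "category": cat})
    taxonomy = pd.DataFrame(rows, columns=["sender", "receiver", "category"])
    counts = taxonomy["category"].value_counts().to_dict()
    conserved = sum(
        counts.get(c, 0)
        for c in ("conserved_identical", "conserved_shared", "conserved_different")
    )
    n_a, n_b = len(pa), len(pb)
    summary = {
        "counts": counts,
        "n_edges_a": n_a,
        "n_edges_b": n_b,
        "conserved_frac_a": conserved / n_a if n_a else np.nan,
        "conserved_frac_b": conserved / n_b if n_b else np.nan,
    }
    return taxonomy, summary


def _restrict(net: NeuropeptideNetwork, classes: list[str]) -> NeuropeptideNetwork:
    layers = [
        PairLayer(
            lay.npp_gene, lay.gpcr_gene, lay.ec50_nM,
            lay.adjacency.loc[classes, classes],
        )
        for lay in net.layers
    ]
    return NeuropeptideNetwork(
        weighted=net.weighted.loc[classes, classes], layers=layers, stage=net.stage
    )


def to_graphml(network: NeuropeptideNetwork, path: str) -> None:
    """Write the weighted network as GraphML for external viewers."""
    import networkx as nx

    g = nx.DiGraph(stage=network.stage)
    g.add_nodes_from(network.weighted.index)
    w = network.weighted
    for i in w.index:
        for j in w.columns:
            if w.loc[i, j] > 0:
                g.add_edge(i, j, weight=int(w.loc[i, j]))
    nx.write_graphml(g, path)
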