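"""Synthetic input generators for the atlas analyses.

Every generator is seeded and deterministic: the same seed yields
byte-identical outputs.  The generators emulate the statistical structure
the downstream analyses assume — per-class detection probabilities with
negative-binomial UMI counts and library-size variation, a consistent
binary ground truth, branch-structured 2-D embeddings with
maturation-correlated genes, EC50-annotated ligand–receptor tables, and
contact graphs with a planted synaptic subgraph and planted gene
enrichment — without emulating doublets, ambient RNA or batch effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SingleCellDataset",
    "EmbeddedLineage",
    "ConnectomeSim",
    "generate_counts",
    "generate_ground_truth",
    "generate_lineage",
    "generate_interactions",
    "generate_connectome",
    "generate_two_stage",
    "write_10x_dir",
    "read_10x_dir",
]

REGIONS = ("head", "midbody", "tail")


@dataclass
class SimulationConfig:
    """Parameters of the UMI count simulator.

    detection_prob is a gene x class matrix of probabilities: the chance
    that a gene is detected (>= 1 UMI) in a cell of that class.  nb_mean
    and nb_dispersion parameterize the negative-binomial count magnitude
    of detected genes (variance = mu + mu^2 / dispersion); libsize_sigma
    is the sigma of a log-normal per-cell library scaling applied to the
    NB mean.
    """

    n_classes: int
    cells_per_class: int | list[int]
    n_genes: int
    detection_prob: np.ndarray
    nb_mean: float = 2.0
    nb_dispersion: float = 1.0
    libsize_sigma: float = 0.3
    seed: int = 0
    class_names: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.detection_prob = np.asarray(self.detection_prob, dtype=float)
        if self.n_classes <= 0 or self.n_genes <= 0:
            raise ValueError("n_classes and n_genes must be positive")
        if self.detection_prob.shape != (self.n_genes, self.n_classes):
            raise ValueError(
                f"detection_prob shape {self.detection_prob.shape} inconsistent "
                f"with (n_genes, n_classes)=({self.n_genes}, {self.n_classes})"
            )
        if np.any(self.detection_prob < 0) or np.any(self.detection_prob > 1):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be nonnegative")
        if isinstance(self.cells_per_class, int):
            if self.cells_per_class <= 0:
                raise ValueError("cells_per_class must be positive")
            self.cells_per_class = [self.cells_per_class] * self.n_classes
        if len(self.cells_per_class) != self.n_classes:
            raise ValueError("cells_per_class length must equal n_classes")
        if not self.class_names:
            self.class_names = [f"class{c}" for c in range(self.n_classes)]
        if not self.gene_names:
            self.gene_names = [f"gene{g}" for g in range(self.n_genes)]


@dataclass
class SingleCellDataset:
    """UMI counts plus per-cell class / stage / sample labels."""

    counts: np.ndarray  # cell x gene, nonnegative integers
    cell_class: pd.Series
    cell_stage: pd.Series
    sample_id: pd.Series
    gene_names: list[str]

    def __post_init__(self) -> None:
        n = self.counts.shape[0]
        for lbl, name in (
            (self.cell_class, "cell_class"),
            (self.cell_stage, "cell_stage"),
            (self.sample_id, "sample_id"),
        ):
            if len(lbl) != n:
                raise ValueError(f"{name} length {len(lbl)} != {n} cells")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class EmbeddedLineage:
    """Branching 2-D embedding with a planted maturation axis.

    coords holds per-cell embedding coordinates; branch_id is
    "progenitor" or "branch<k>"; true_distance is the planted maturation
    (0 for progenitors); planted_genes records (gene, branch, sign)
    monotone-trend annotations.
    """

    coords: np.ndarray
    branch_id: pd.Series
    true_distance: np.ndarray
    planted_genes: list[tuple[str, str, int]]


def generate_counts(config: SimulationConfig) -> SingleCellDataset:
    """Simulate a UMI count matrix under the detection / NB library model.

    Detection of gene g in a cell of class c is Bernoulli with probability
    detection_prob[g, c]; detected entries draw a zero-truncated negative
    binomial count whose mean is nb_mean scaled by the cell's log-normal
    library factor.
    """
    rng = np.random.default_rng(config.seed)
    blocks, classes = [], []
    for c, n_cells in enumerate(config.cells_per_class):
        p = config.detection_prob[:, c]  # per-gene
        detected = rng.random((n_cells, config.n_genes)) < p[None, :]
        lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))
        mu = config.nb_mean * lib[:, None]
        counts = np.zeros((n_cells, config.n_genes), dtype=np.int64)
        if detected.any():
            counts[detected] = _ztnb(rng, mu=np.broadcast_to(mu, detected.shape)[detected],
                                     size_param=config.nb_dispersion)
        blocks.append(counts)
        classes.extend([config.class_names[c]] * n_cells)
    counts = np.vstack(blocks)
    n = counts.shape[0]
    return SingleCellDataset(
        counts=counts,
        cell_class=pd.Series(classes, name="cell_class"),
        cell_stage=pd.Series(["L1"] * n, name="cell_stage"),
        sample_id=pd.Series(["sim0"] * n, name="sample_id"),
        gene_names=list(config.gene_names),
    )


def _ztnb(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Zero-truncated negative binomial draws (mean mu before truncation)."""
    r = size_param
    p = r / (r + mu)
    out = rng.negative_binomial(r, p)
    # redraw zeros until none remain; geometric redraw preserves the
    # truncated distribution exactly
    zero = out == 0
    while zero.any():
        out[zero] = rng.negative_binomial(r, p[zero] if p.ndim else p)
        zero = out == 0
    return out


def generate_ground_truth(
    config: SimulationConfig,
    p_on: float,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Binary gene x class truth: 1 iff detection_prob >= p_on (inclusive).

    Restricted to `genes` (the designated ground-truth genes) when given.
    """
    if not 0 < p_on < 1:
        raise ValueError("p_on must lie in (0, 1)")
    truth = (config.detection_prob >= p_on).astype(int)
    df = pd.DataFrame(truth, index=config.gene_names, columns=config.class_names)
    if genes is not None:
        df = df.loc[genes]
    return df


def generate_lineage(
    n_branches: int,
    cells_per_branch: int,
    n_planted: int,
    noise_sd: float,
    seed: int,
    n_genes: int = 100,
    slope: int = 3,
) -> tuple[EmbeddedLineage, SingleCellDataset]:
    """Branching embedding with genes whose counts trend with maturation.

    A progenitor cluster sits at the origin; each branch radiates outward
    with cells placed at integer maturation steps.  Planted genes rise or
    fall linearly (slope counts per step) along their assigned branch, so
    at noise_sd=0 their expression is exactly linear in true_distance.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    coords, branches, dist = [], [], []
    # progenitors: true_distance exactly 0, small positional jitter
    for _ in range(cells_per_branch):
        coords.append(rng.normal(0.0, 0.05, size=2))
        branches.append("progenitor")
        dist.append(0.0)
    angles = np.linspace(0.0, 2 * np.pi, n_branches, endpoint=False)
    for b in range(n_branches):
        u = np.array([np.cos(angles[b]), np.sin(angles[b])])
        for k in range(1, cells_per_branch + 1):
            coords.append(u * k + rng.normal(0.0, 0.05, size=2))
            branches.append(f"branch{b}")
            dist.append(float(k))
    coords = np.asarray(coords)
    dist = np.asarray(dist)
    branch_s = pd.Series(branches, name="branch_id")

    gene_names = [f"gene{g}" for g in range(n_genes)]
    counts = rng.poisson(1.0, size=(len(dist), n_genes)).astype(np.int64)
    planted: list[tuple[str, str, int]] = []
    kmax = cells_per_branch
    for i in range(n_planted):
        g = i  # planted genes occupy the first n_planted columns
        b = i % n_branches
        sign = 1 if (i // n_branches) % 2 == 0 else -1
        mask = branch_s == f"branch{b}"
        k = dist[mask.to_numpy()]
        base = slope * k if sign > 0 else slope * (kmax - k)
        vals = base + rng.normal(0.0, noise_sd, size=base.shape)
        counts[mask.to_numpy(), g] = np.maximum(0, np.rint(vals)).astype(np.int64)
        planted.append((gene_names[g], f"branch{b}", sign))

    lineage = EmbeddedLineage(
        coords=coords, branch_id=branch_s, true_distance=dist, planted_genes=planted
    )
    n = len(dist)
    ds = SingleCellDataset(
        counts=counts,
        cell_class=branch_s.rename("cell_class"),
        cell_stage=pd.Series(["L1"] * n, name="cell_stage"),
        sample_id=pd.Series(["sim0"] * n, name="sample_id"),
        gene_names=gene_names,
    )
    return lineage, ds


def generate_interactions(
    n_npp: int,
    n_gpcr: int,
    frac_high_potency: float,
    seed: int,
    n_pairs: int | None = None,
) -> pd.DataFrame:
    """Ligand–receptor table with EC50 potencies.

    Approximately frac_high_potency of rows get EC50 <= 500 nM (the
    high-potency regime); the rest fall in (500, 5000].  Defaults to one
    pair per neuropeptide precursor gene.
    """
    if n_npp <= 0 or n_gpcr <= 0:
        raise ValueError("n_npp and n_gpcr must be positive")
    rng = np.random.default_rng(seed)
    if n_pairs is None:
        n_pairs = n_npp
    npp = [f"npp{i % n_npp}" for i in range(n_pairs)]
    gpcr = [f"gpcr{int(g)}" for g in rng.integers(0, n_gpcr, size=n_pairs)]
    n_high = int(round(frac_high_potency * n_pairs))
    ec50 = np.empty(n_pairs)
    hi = rng.permutation(n_pairs)[:n_high]
    mask = np.zeros(n_pairs, dtype=bool)
    mask[hi] = True
    ec50[mask] = rng.uniform(1.0, 500.0, size=n_high)
    ec50[~mask] = rng.uniform(500.0 + 1e-9, 5000.0, size=n_pairs - n_high)
    return pd.DataFrame({"npp_gene": npp, "gpcr_gene": gpcr, "ec50_nM": ec50})


@dataclass
class ConnectomeSim:
    """Connectome simulation outputs and their planted truth."""

    assignments: pd.DataFrame  # class, bundle, region
    contact: pd.DataFrame  # class x class
    synapse: pd.DataFrame  # class x class, directed pre->post
    expression: pd.DataFrame  # gene x class, normalized scale
    planted: list[dict]  # {"gene", "focal", "direction", "effect"}


def generate_connectome(
    classes: list[str],
    n_bundles: int,
    contact_density: float,
    synapse_frac: float,
    planted_genes: list[str],
    effect: float,
    seed: int,
    n_genes: int = 30,
    directed_contacts: bool = False,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
) -> ConnectomeSim:
    """Contact graph with a planted synaptic subgraph and gene enrichment.

    Each class is assigned one bundle and one region (bundles nest within
    head/midbody/tail).  Contacts are Bernoulli(contact_density)
    (symmetric unless directed_contacts); each contact edge is
    independently promoted to a synapse with probability synapse_frac, so
    synapses are a subset of contacts by construction.  For each planted
    gene a focal class is chosen and the gene's expression is shifted by
    `effect` in that focal's synaptic output partners; the truth record
    stores what was planted.
    """
    if synapse_frac > 1:
        raise ValueError("synapse_frac must be <= 1")
    rng = np.random.default_rng(seed)
    k = len(classes)
    bundles = rng.integers(0, n_bundles, size=k)
    bundle_region = [REGIONS[b % len(REGIONS)] for b in range(n_bundles)]
    regions = [bundle_region[b] for b in bundles]
    assignments = pd.DataFrame(
        {"neuron_class": classes, "bundle": bundles, "region": regions}
    )

    contact = (rng.random((k, k)) < contact_density).astype(int)
    np.fill_diagonal(contact, 0)
    if not directed_contacts:
        contact = np.triu(contact, 1)
        contact = contact + contact.T
    synapse = np.where(rng.random((k, k)) < synapse_frac, contact, 0)

    gene_names = [f"cam{g}" for g in range(n_genes)]
    for g in planted_genes:
        if g not in gene_names:
            gene_names.append(g)
    expr = rng.normal(baseline_mean, baseline_sd, size=(len(gene_names), k))
    expr = np.maximum(expr, 0.0)
    expr_df = pd.DataFrame(expr, index=gene_names, columns=classes)

    planted: list[dict] = []
    contact_df = pd.DataFrame(contact, index=classes, columns=classes)
    synapse_df = pd.DataFrame(synapse, index=classes, columns=classes)
    if planted_genes:
        # pick focal classes with the most synaptic outputs so an effect
        # is actually attributable to a partner group
        out_deg = (synapse_df > 0).sum(axis=1)
        focals = out_deg.sort_values(ascending=False).index
        for i, g in enumerate(planted_genes):
            focal = focals[i % k]
            partners = synapse_df.columns[(synapse_df.loc[focal] > 0).to_numpy()]
            expr_df.loc[g, partners] = expr_df.loc[g, partners] + effect
            planted.append(
                {"gene": g, "focal": focal, "direction": "output", "effect": effect}
            )
    return ConnectomeSim(assignments, contact_df, synapse_df, expr_df, planted)


def generate_two_stage(
    n_genes: int,
    n_planted: int,
    fold: float,
    cells_per_group: int,
    nb_mean: float,
    nb_dispersion: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-stage NB counts with planted fold changes in the older stage.

    Returns (counts_young, counts_old, planted_mask); planted genes have
    NB mean fold x nb_mean in the older stage, all other genes share the
    same mean in both stages.
    """
    rng = np.random.default_rng(seed)
    r = nb_dispersion
    mu_young = np.full(n_genes, nb_mean)
    mu_old = mu_young.copy()
    planted = np.zeros(n_genes, dtype=bool)
    planted[:n_planted] = True
    mu_old[planted] *= fold

    def draw(mu: np.ndarray) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p[None, :], size=(cells_per_group, n_genes))

    return draw(mu_young), draw(mu_old), planted


# ---------------------------------------------------------------------------
# 10x-style triplet IO


def write_10x_dir(ds: SingleCellDataset, out_dir: str | Path) -> None:
    """Write counts as MatrixMarket triplet with genes.tsv / cells.tsv."""
    from scipy import io as spio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # genes x cells orientation, as 10x does
    spio.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(ds.counts.T))
    pd.Series(ds.gene_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    meta = pd.DataFrame(
        {
            "cell": [f"cell{i}" for i in range(ds.n_cells)],
            "cell_class": ds.cell_class.to_numpy(),
            "cell_stage": ds.cell_stage.to_numpy(),
            "sample_id": ds.sample_id.to_numpy(),
        }
    )
    meta.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_10x_dir(in_dir: str | Path) -> SingleCellDataset:
    """Read a dataset written by :func:`write_10x_dir`."""
    from scipy import io as spio

    p = Path(in_dir)
    mat = spio.mmread(str(p / "matrix.mtx")).toarray().T.astype(np.int64)
    genes = pd.read_csv(p / "genes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(p / "cells.tsv", sep="\t")
    return SingleCellDataset(
        counts=mat,
        cell_class=meta["cell_class"],
        cell_stage=meta["cell_stage"],
        sample_id=meta["sample_id"],
        gene_names=[str(g) for g in genes],
    )


def write_truth_record(planted: list[dict] | list[tuple], path: str | Path) -> None:
    """Persist a planted-truth record as JSON."""
    with open(path, "w") as fh:
        json.dump([list(p) if isinstance(p, tuple) else p for p in planted], fh, indent=1)
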