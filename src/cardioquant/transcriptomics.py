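"""Expression-level maturation analytics.

A bulk FPKM matrix (genes x samples) is reduced to a sample-level
topology and per-sample maturation scores:

1. **Variable-gene filter** — keep genes with variance > 0.5 (on the
   log2(x+1) scale) that are expressed above 1 FPKM in more than two
   samples.
2. **PC-loading gene selection** — PCA on the filtered, log-transformed,
   gene-centered matrix; per principal component 1..5, genes whose
   absolute loading (scaled to unit maximum per PC) exceeds 0.2, capped
   at the top 50 per PC so no single component swamps the analysis.
3. **Sample correlation network** — Pearson correlation between samples
   over the selected genes; an edge when r exceeds a threshold (0.6 by
   default; 0.4 is the common visualization alternative).
4. **Cumulative category score** — per sample, the sum of per-gene
   z-scores over a named gene set (sarcomere, cell junctions, electron
   transport chain, fatty acid metabolism).
5. **Ratiometric maturation signature** — adult/fetal isoform ratios
   Tnni3/Tnni1 and Myl2/Myl7, linear and log2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "filter_variable_genes",
    "pca_gene_selection",
    "sample_correlation_network",
    "layout_network",
    "cumulative_category_score",
    "maturation_ratios",
    "log_transform",
]


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform of an FPKM matrix."""
    return np.log2(matrix + 1.0)


def filter_variable_genes(
    matrix: pd.DataFrame,
    min_variance: float = 0.5,
    min_fpkm: float = 1.0,
    min_samples: int = 3,
) -> list[str]:
    """Genes with log-scale variance above ``min_variance`` that exceed
    ``min_fpkm`` in at least ``min_samples`` samples ("more than two")."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    log = log_transform(matrix)
    variance = log.var(axis=1, ddof=1)
    expressed = (matrix > min_fpkm).sum(axis=1) >= min_samples
    keep = (variance > min_variance) & expressed
    return matrix.index[keep].tolist()


@dataclass
class GeneSelection:
    genes: list[str]
    per_pc: dict[int, list[str]] = field(default_factory=dict)
    loadings: pd.DataFrame | None = None


def pca_gene_selection(
    matrix: pd.DataFrame,
    genes: Sequence[str] | None = None,
    n_pcs: int = 5,
    loading_threshold: float = 0.2,
    cap_per_pc: int = 50,
) -> GeneSelection:
    """Select genes driving the top principal components.

    PCA runs on the log2(x+1), gene-centered matrix restricted to
    ``genes`` (default: all rows). Loadings are the gene-side singular
    vectors scaled by their singular value and normalized to unit maximum
    absolute value per PC, so the threshold is applied on a comparable
    scale across components. Per PC the genes above the threshold are
    ranked by |loading| (ties broken by gene ID) and capped; the union is
    returned with per-PC provenance.
    """
    sub = matrix.loc[list(genes)] if genes is not None else matrix
    log = log_transform(sub)
    centered = log.sub(log.mean(axis=1), axis=0)
    u, s, _ = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum()) if s.size else 0
    if rank < n_pcs:
        raise ValueError(
            f"matrix rank {rank} is below the requested {n_pcs} components"
        )
    per_pc: dict[int, list[str]] = {}
    loadings = {}
    ids = np.asarray(sub.index)
    for k in range(n_pcs):
        raw = u[:, k] * s[k]
        scaled = raw / np.abs(raw).max()
        loadings[f"PC{k + 1}"] = scaled
        above = np.abs(scaled) > loading_threshold
        order = sorted(
            np.nonzero(above)[0], key=lambda i: (-abs(scaled[i]), ids[i])
        )[:cap_per_pc]
        per_pc[k + 1] = [ids[i] for i in order]
    union = sorted(set().union(*per_pc.values())) if per_pc else []
    return GeneSelection(
        genes=union,
        per_pc=per_pc,
        loadings=pd.DataFrame(loadings, index=sub.index),
    )


def sample_correlation_network(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    r_threshold: float = 0.6,
) -> nx.Graph:
    """Pairwise Pearson network over the selected genes.

    Nodes are samples; an (undirected, weighted) edge connects two
    samples when their Pearson correlation on the log2(x+1) scale
    strictly exceeds ``r_threshold``. Samples with zero variance over the
    selected genes have undefined correlations and stay isolated (with a
    warning).
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a correlation network")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    log = log_transform(matrix.loc[list(genes)])
    data = log.to_numpy()
    sd = data.std(axis=0)
    degenerate = np.nonzero(sd == 0)[0]
    for j in degenerate:
        warnings.warn(
            f"sample {log.columns[j]!r} has zero variance over selected genes; "
            "left isolated",
            stacklevel=2,
        )
    graph = nx.Graph()
    graph.add_nodes_from(log.columns)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data.T)
    n = data.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isfinite(r) and r > r_threshold:
                graph.add_edge(log.columns[i], log.columns[j], weight=float(r))
    graph.graph["r_threshold"] = r_threshold
    graph.graph["n_genes"] = len(genes)
    return graph


def layout_network(network: nx.Graph, seed: int = 0) -> dict:
    """Seeded Fruchterman-Reingold (force-directed) 2-D layout."""
    if network.number_of_nodes() == 0:
        return {}
    if network.number_of_nodes() == 1:
        return {next(iter(network.nodes)): np.zeros(2)}
    return nx.spring_layout(network, seed=seed)


def cumulative_category_score(
    matrix: pd.DataFrame,
    categories: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-sample cumulative score per gene category.

    Each matched gene is standardized across samples (z-score of its
    log2(x+1) expression); a sample's category score is the sum of
    z-scores over the category's genes. Genes absent from the matrix or
    constant across samples are dropped with a warning; a category with
    no usable genes is an error.
    """
    log = log_transform(matrix)
    scores = {}
    for name, genes in categories.items():
        present = [g for g in genes if g in log.index]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(
                f"category {name!r}: {len(missing)} genes not in matrix", stacklevel=2
            )
        sub = log.loc[present]
        sd = sub.std(axis=1, ddof=0)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"category {name!r}: dropping {int(constant.sum())} constant genes",
                stacklevel=2,
            )
            sub = sub.loc[~constant]
            sd = sd[~constant]
        if sub.empty:
            raise ValueError(f"category {name!r} has no usable genes in the matrix")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        scores[name] = z.sum(axis=0)
    return pd.DataFrame(scores)


def maturation_ratios(matrix: pd.DataFrame) -> pd.DataFrame:
    """Adult/fetal isoform ratios per sample: Tnni3/Tnni1 and Myl2/Myl7.

    Returns linear and log2 ratios; samples with a zero (or missing)
    denominator get NaN and a ``flagged`` mark for that pair.
    """
    pairs = {"Tnni3_Tnni1": ("Tnni3", "Tnni1"), "Myl2_Myl7": ("Myl2", "Myl7")}
    out = {}
    for name, (adult, fetal) in pairs.items():
        if adult not in matrix.index or fetal not in matrix.index:
            raise KeyError(f"matrix lacks {adult!r} or {fetal!r}")
        num = matrix.loc[adult].astype(float)
        den = matrix.loc[fetal].astype(float)
        ratio = num / den.where(den > 0)
        out[name] = ratio
        out[f"log2_{name}"] = np.log2(ratio)
        out[f"{name}_flagged"] = den <= 0
    return pd.DataFrame(out)
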