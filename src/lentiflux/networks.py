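"""Consensus clustering, co-expression networks and over-representation.

Per-gene log2 fold-change profiles are median-centered and repeatedly
clustered with k-means (Euclidean distance, k-means++ init) on gene
subsamples; the consensus matrix records how often each gene pair
co-clusters and doubles as a co-expression similarity.  The number of
clusters is picked by the delta-area criterion on the consensus CDF.
Protein-interaction edge lists (STRING-style TSV) are ingested offline, and
gene-set over-representation is the upper-tail hypergeometric test with
BH-FDR across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .expression import bh_fdr

__all__ = [
    "ConsensusResult",
    "median_center",
    "consensus_cluster",
    "select_k",
    "consensus_network",
    "ppi_ingest",
    "network_topology",
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_ora",
    "write_edge_list",
]


def median_center(profiles: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median across features (rows end at median 0)."""
    return profiles.sub(profiles.median(axis=1), axis=0)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF areas, assignments and the chosen k."""

    gene_ids: list[str]
    matrices: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    assignments: dict[int, np.ndarray]
    never_cosampled: dict[int, np.ndarray]
    chosen_k: int

    @property
    def consensus(self) -> np.ndarray:
        return self.matrices[self.chosen_k]

    @property
    def assignment(self) -> pd.Series:
        return pd.Series(
            self.assignments[self.chosen_k], index=self.gene_ids, name="cluster"
        )


def _ecdf_area(matrix: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus entries."""
    iu = np.triu_indices_from(matrix, k=1)
    vals = np.sort(matrix[iu])
    m = vals.size
    if m == 0:
        return 0.0
    # Integrate the step function F over [0, 1].
    grid = np.concatenate([vals, [1.0]])
    heights = np.arange(1, m + 1) / m
    return float(np.sum((grid[1:] - grid[:-1]) * heights))


def _consensus_assignment(matrix: np.ndarray, k: int) -> np.ndarray:
    dist = 1.0 - matrix
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def _pac(matrix: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: pairs with consensus in
    (lower, upper) — 0 for a perfectly crisp consensus."""
    iu = np.triu_indices_from(matrix, k=1)
    vals = matrix[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > lower) & (vals < upper)))


def select_k(
    cdf_areas: Mapping[int, float],
    matrices: Mapping[int, np.ndarray] | None = None,
) -> int:
    """Pick k by the relative gain in consensus-CDF area, guarded by PAC.

    Among k above the smallest candidate, the winner maximizes the relative
    delta-area (A(k) - A(k-1)) / A(k-1); ties resolve to the smaller k.
    Because the consensus CDF area grows mechanically with k, the smallest
    candidate has no delta of its own; when consensus matrices are supplied
    it is still returned if its consensus is crisper (lower proportion of
    ambiguous pairs) than the delta-area winner's, which covers designs
    whose true cluster count is the bottom of the range.
    """
    ks = sorted(cdf_areas)
    if len(ks) == 1:
        return ks[0]
    best_k, best_delta = None, -np.inf
    prev = cdf_areas[ks[0]]
    for k in ks[1:]:
        delta = (cdf_areas[k] - prev) / prev if prev > 0 else cdf_areas[k]
        if delta > best_delta:
            best_k, best_delta = k, delta
        prev = cdf_areas[k]
    if matrices is not None and _pac(matrices[ks[0]]) < _pac(matrices[best_k]):
        return ks[0]
    return best_k


def consensus_cluster(
    profiles: pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    reps: int = 30,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> ConsensusResult:
    """Consensus k-means over gene subsamples.

    Profiles are median-centered per gene first.  For each k and rep, a
    ``subsample_frac`` fraction of genes is drawn without replacement and
    clustered with k-means; M_k[i, j] is the fraction of co-sampled reps in
    which i and j landed in the same cluster (never-co-sampled pairs get 0
    and are flagged).  Final assignments cut an average-linkage tree of
    1 - M_k; the returned ``chosen_k`` maximizes the delta-area criterion.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = profiles.shape[0]
    if not ks or ks[0] < 2:
        raise ValueError("k_range must contain integers >= 2")
    if ks[-1] >= n:
        raise ValueError(f"largest k ({ks[-1]}) must be < number of genes ({n})")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    x = median_center(profiles).to_numpy()
    n_sub = max(ks[-1] + 1, int(round(subsample_frac * n)))
    n_sub = min(n_sub, n)

    matrices: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    flags: dict[int, np.ndarray] = {}
    for k in ks:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(reps):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_init,
                max_iter=max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            )
            labels = km.fit_predict(x[idx])
            both[np.ix_(idx, idx)] += 1
            for c in range(k):
                members = idx[labels == c]
                co[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore"):
            m = np.where(both > 0, co / np.maximum(both, 1), 0.0)
        np.fill_diagonal(m, 1.0)
        never = both == 0
        np.fill_diagonal(never, False)
        matrices[k] = m
        areas[k] = _ecdf_area(m)
        assignments[k] = _consensus_assignment(m, k)
        flags[k] = never
    chosen = select_k(areas, matrices)
    return ConsensusResult(
        gene_ids=list(profiles.index),
        matrices=matrices,
        cdf_areas=areas,
        assignments=assignments,
        never_cosampled=flags,
        chosen_k=chosen,
    )


def consensus_network(
    result: ConsensusResult, threshold: float = 0.5
) -> nx.Graph:
    """Undirected network with an edge wherever consensus >= threshold."""
    m = result.consensus
    genes = result.gene_ids
    clusters = result.assignment
    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, cluster=int(clusters[gene]))
    rows, cols = np.nonzero(np.triu(m >= threshold, k=1))
    for i, j in zip(rows, cols):
        g.add_edge(genes[i], genes[j], weight=float(m[i, j]))
    return g


def ppi_ingest(path: str | Path, score_min: float = 0.4) -> nx.Graph:
    """Read a STRING-style edge TSV (protein1, protein2, combined_score).

    Scores above 1 are assumed to be on STRING's 0-1000 scale and rescaled
    to [0, 1].  Self-loops are dropped, duplicate pairs are collapsed to
    their maximum score, and edges below ``score_min`` are discarded.  The
    number of collapsed duplicates is reported in ``graph.graph``.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    cols = list(table.columns[:3])
    scores = table[cols[2]].astype(float)
    if (scores > 1).any():
        scores = scores / 1000.0
    g = nx.Graph()
    duplicates = 0
    self_loops = 0
    for a, b, score in zip(table[cols[0]], table[cols[1]], scores):
        if a == b:
            self_loops += 1
            continue
        if score < score_min:
            continue
        if g.has_edge(a, b):
            duplicates += 1
            g[a][b]["weight"] = max(g[a][b]["weight"], float(score))
        else:
            g.add_edge(a, b, weight=float(score))
    g.graph["duplicates_dropped"] = duplicates
    g.graph["self_loops_dropped"] = self_loops
    return g


def network_topology(g: nx.Graph) -> dict:
    """Degrees, connected-component membership and overall density."""
    components = list(nx.connected_components(g))
    membership = {}
    for i, comp in enumerate(components):
        for node in comp:
            membership[node] = i
    return {
        "degrees": dict(g.degree()),
        "density": nx.density(g),
        "n_components": len(components),
        "component": membership,
    }


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    out_of_universe: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                self.out_of_universe[name] = frozenset(stray)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (set name, description, members, tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def hypergeom_ora(
    selected: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH-FDR across sets.

    p = P(X >= overlap) with population N = |universe|, K = |set| and
    n = |selection| (both intersected with the universe first).
    """
    universe = collection.universe
    sel = frozenset(selected) & universe
    n_pop, n_sel = len(universe), len(sel)
    records = []
    for name, members in collection.sets.items():
        in_univ = members & universe
        overlap = len(in_univ & sel)
        p = float(stats.hypergeom.sf(overlap - 1, n_pop, len(in_univ), n_sel))
        records.append(
            {
                "set": name,
                "set_size": len(in_univ),
                "overlap": overlap,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame.from_records(records).set_index("set")
    table["fdr"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table


def write_edge_list(g: nx.Graph, path: str | Path, header: str | None = None) -> None:
    """Write a weighted edge-list TSV (optionally with a comment header)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("source\ttarget\tweight\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.6g}\n")
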