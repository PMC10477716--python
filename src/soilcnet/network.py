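"""Co-occurrence network inference and module analysis on OTU tables.

Edges are statistically significant Spearman rank correlations between OTU
abundance profiles: all pairwise correlations are computed on
prevalence-filtered taxa, two-sided p-values are Benjamini-Hochberg
adjusted over the upper triangle, and pairs with adjusted p below the
cutoff (default 0.01) become signed edges. Nodes are the endpoints of
retained edges. Downstream utilities compute topology metrics (average
clustering coefficient as the complexity proxy, degree, signed edge
counts), Louvain modules, WGCNA-style module eigengenes, and permutation
association tests (eigengene-environment Pearson, Mantel).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import upper_triangle
from .community import DistanceMatrix, OTUTable

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceNetwork:
    """Signed undirected co-occurrence graph over OTUs.

    ``graph`` edges carry rho, p_raw, p_adj, sign and weight_abs (=|rho|);
    ``modules`` maps node -> module id (1 = largest) after
    :func:`detect_modules`; ``provenance`` records filter settings.
    """

    graph: nx.Graph
    alpha: float
    modules: dict | None = None
    modularity: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = []
        mods = self.modules or {}
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "otu_a": u,
                    "otu_b": v,
                    "rho": d["rho"],
                    "p_raw": d["p_raw"],
                    "p_adj": d["p_adj"],
                    "sign": d["sign"],
                    "module_a": mods.get(u),
                    "module_b": mods.get(v),
                }
            )
        cols = ["otu_a", "otu_b", "rho", "p_raw", "p_adj", "sign", "module_a", "module_b"]
        return pd.DataFrame(rows, columns=cols)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.modules:
            nx.set_node_attributes(g, self.modules, "module")
        nx.write_graphml(g, path)


@dataclass
class TopologyMetrics:
    nodes: int
    edges: int
    average_clustering_coefficient: float
    average_degree: float
    positive_edges: int
    negative_edges: int

    def as_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": self.edges,
            "average_clustering_coefficient": self.average_clustering_coefficient,
            "average_degree": self.average_degree,
            "positive_edges": self.positive_edges,
            "negative_edges": self.negative_edges,
        }


@dataclass
class ModuleEigengene:
    """First principal component of a module's standardized abundances."""

    module_id: int
    values: pd.Series  # per-sample eigengene
    variance_explained: float


def prevalence_filter(table: OTUTable, min_fraction: float = 0.5) -> OTUTable:
    """Retain OTUs present (count > 0) in strictly more than ``min_fraction``
    of the samples."""
    if table.counts.empty:
        raise ValueError("empty OTU table")
    prev = (table.counts > 0).sum(axis=1) / table.counts.shape[1]
    keep = prev > min_fraction
    if not keep.any():
        raise ValueError(
            f"no OTU passes prevalence > {min_fraction}; lower the threshold"
        )
    return OTUTable(
        counts=table.counts.loc[keep],
        taxonomy=table.taxonomy.loc[table.taxonomy.index.intersection(table.counts.index[keep])],
        metadata=table.metadata,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho at very small n.

    Enumerates all permutations of y (valid with ties, since average ranks
    are recomputed only through the rank vector, which permutes with y).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return np.nan
    hits = 0
    total = 0
    for perm in _permutations(range(n)):
        r = float(np.dot(sx, sy[list(perm)]) / denom)
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return hits / total


def correlation_network(
    table: OTUTable,
    alpha: float = 0.01,
    method: str = "spearman",
) -> CooccurrenceNetwork:
    """Build the significant-correlation co-occurrence network.

    All pairwise Spearman correlations (average ranks for ties) with
    two-sided p-values; Benjamini-Hochberg adjustment is applied over the
    upper triangle only, and edges with adjusted p < ``alpha`` are retained.
    Constant-abundance OTUs have undefined correlations; their pairs are
    excluded with a logged count. Nodes are the endpoints of retained edges.
    P-values use the t approximation for n >= 10 and exact permutation
    enumeration for n <= 7 (between, the t approximation is used with a
    warning).
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    x = table.counts.to_numpy(dtype=float)
    otus = table.otu_ids
    n_taxa, n_samples = x.shape
    if n_samples < 5:
        raise ValueError("rank correlation needs >= 5 samples")

    const = x.std(axis=1) == 0
    if const.any():
        logger.info("excluding %d constant-abundance OTU(s) from correlation", int(const.sum()))

    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((z**2).sum(axis=1))
    norms[norms == 0] = np.nan
    rho = (z @ z.T) / np.outer(norms, norms)
    rho = np.clip(rho, -1.0, 1.0)

    iu = np.triu_indices(n_taxa, k=1)
    rho_u = rho[iu]
    valid = np.isfinite(rho_u)

    if n_samples >= 10:
        # Two-sided p from the t approximation.
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rho_u * np.sqrt((n_samples - 2) / np.maximum(1 - rho_u**2, 1e-300))
        p_u = 2 * stats.t.sf(np.abs(tstat), df=n_samples - 2)
        p_u[np.abs(rho_u) >= 1.0] = 0.0
    elif n_samples <= 7:
        p_u = np.full(rho_u.shape, np.nan)
        for k, (i, j) in enumerate(zip(*iu)):
            if valid[k]:
                p_u[k] = _spearman_exact_p(x[i], x[j], rho_u[k])
    else:
        warnings.warn(
            "7 < n < 10 samples: exact enumeration infeasible, using t approximation",
            stacklevel=2,
        )
        tstat = rho_u * np.sqrt((n_samples - 2) / np.maximum(1 - rho_u**2, 1e-300))
        p_u = 2 * stats.t.sf(np.abs(tstat), df=n_samples - 2)

    p_adj = np.full(p_u.shape, np.nan)
    if valid.any():
        p_adj[valid] = multipletests(p_u[valid], method="fdr_bh")[1]

    g = nx.Graph()
    sig = valid & (p_adj < alpha)
    for k in np.nonzero(sig)[0]:
        i, j = iu[0][k], iu[1][k]
        r = float(rho_u[k])
        g.add_edge(
            otus[i],
            otus[j],
            rho=r,
            p_raw=float(p_u[k]),
            p_adj=float(p_adj[k]),
            sign=1 if r > 0 else -1,
            weight_abs=abs(r),
        )
    tax = table.taxonomy
    for node in g.nodes:
        if node in tax.index:
            for rank, label in tax.loc[node].items():
                g.nodes[node][str(rank)] = str(label)
    return CooccurrenceNetwork(
        graph=g,
        alpha=alpha,
        provenance={
            "method": method,
            "alpha": alpha,
            "n_samples": n_samples,
            "n_taxa_tested": n_taxa,
            "n_constant_excluded": int(const.sum()),
            "n_pairs_tested": int(valid.sum()),
        },
    )


def treatment_subnetwork(
    network: CooccurrenceNetwork,
    table: OTUTable,
    treatment: str,
    min_fraction: float = 0.5,
) -> CooccurrenceNetwork:
    """Induced subgraph on OTUs present in more than ``min_fraction`` of the
    treatment's replicate samples."""
    meta = table.metadata
    samples = meta.index[meta["treatment"] == treatment]
    if len(samples) == 0:
        raise ValueError(f"unknown treatment label: {treatment!r}")
    sub_counts = table.counts[list(samples)]
    prev = (sub_counts > 0).sum(axis=1) / len(samples)
    present = set(sub_counts.index[prev > min_fraction])
    keep = [n for n in network.graph.nodes if n in present]
    sub = network.graph.subgraph(keep).copy()
    return CooccurrenceNetwork(
        graph=sub,
        alpha=network.alpha,
        provenance={**network.provenance, "treatment": treatment, "subnetwork_min_fraction": min_fraction},
    )


def topology(network: CooccurrenceNetwork) -> TopologyMetrics:
    """Node/edge counts, signed edge split, average degree and average
    clustering coefficient (unsigned simple graph; degree < 2 nodes
    contribute 0)."""
    g = network.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        warnings.warn("empty network: topology metrics are all zero", stacklevel=2)
        return TopologyMetrics(0, 0, 0.0, 0.0, 0, 0)
    acc = float(nx.average_clustering(g))  # unweighted; deg<2 contributes 0
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    return TopologyMetrics(
        nodes=n,
        edges=e,
        average_clustering_coefficient=acc,
        average_degree=2.0 * e / n,
        positive_edges=pos,
        negative_edges=e - pos,
    )


def detect_modules(
    network: CooccurrenceNetwork,
    seed: int = 0,
    resolution: float = 1.0,
) -> tuple[dict, float]:
    """Louvain modularity maximization on |rho| weights.

    Modules are labeled by descending size (module 1 is the largest); the
    assignment and modularity Q are also stored on the network.
    """
    g = network.graph
    if g.number_of_edges() < 1:
        raise ValueError("network has no edges")
    comms = nx.community.louvain_communities(
        g, weight="weight_abs", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    assignment = {node: i + 1 for i, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(g, comms, weight="weight_abs", resolution=resolution)
    network.modules = assignment
    network.modularity = float(q)
    return assignment, float(q)


def module_eigengene(
    table: OTUTable | pd.DataFrame,
    members: list[str],
    module_id: int = 0,
) -> ModuleEigengene:
    """WGCNA-style module eigengene.

    First principal component of the z-scored abundances of the module's
    member taxa across samples, sign-oriented so its correlation with the
    mean member profile is non-negative. Zero-variance members are dropped
    with a log message.
    """
    df = table.counts if isinstance(table, OTUTable) else table
    if len(members) < 2:
        raise ValueError("module must have >= 2 members")
    sub = df.loc[list(members)].astype(float)
    sd = sub.std(axis=1, ddof=1)
    drop = sd[sd == 0].index
    if len(drop):
        logger.info("dropping %d zero-variance member(s) from module %s", len(drop), module_id)
        sub = sub.drop(index=drop)
    if sub.shape[0] == 0:
        raise ValueError("all module members have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    data = z.to_numpy().T  # samples x members
    u, s, _ = np.linalg.svd(data, full_matrices=False)
    eigen = u[:, 0] * s[0]
    mean_profile = data.mean(axis=1)
    if np.dot(eigen, mean_profile) < 0:
        eigen = -eigen
    return ModuleEigengene(
        module_id=module_id,
        values=pd.Series(eigen, index=sub.columns, name=f"ME{module_id}"),
        variance_explained=float(s[0] ** 2 / (s**2).sum()),
    )


def module_env_association(
    eigengenes: pd.DataFrame,
    env: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlation of module eigengenes with environmental variables.

    Returns a long table with r, analytic p, seeded permutation p (two
    sided) and significance stars (* p<0.05, ** p<0.01, on the permutation
    p). Constant variables yield missing associations.
    """
    shared = eigengenes.index.intersection(env.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    eg = eigengenes.loc[shared]
    ev = env.loc[shared]
    rng = np.random.default_rng(seed)
    rows = []
    n = len(shared)
    for mod in eg.columns:
        a = eg[mod].to_numpy(float)
        for var in ev.columns:
            b = ev[var].to_numpy(float)
            if np.std(a) == 0 or np.std(b) == 0 or not np.isfinite(b).all():
                rows.append({"module": mod, "variable": var, "r": np.nan, "p_analytic": np.nan, "p_perm": np.nan, "stars": ""})
                continue
            r, p_an = stats.pearsonr(a, b)
            az = (a - a.mean()) / a.std()
            bz = (b - b.mean()) / b.std()
            hits = 0
            for _ in range(n_permutations):
                rp = float(np.dot(az, bz[rng.permutation(n)]) / n)
                if abs(rp) >= abs(r) - 1e-15:
                    hits += 1
            p_perm = (1 + hits) / (n_permutations + 1)
            stars = "**" if p_perm < 0.01 else ("*" if p_perm < 0.05 else "")
            rows.append(
                {"module": mod, "variable": var, "r": float(r), "p_analytic": float(p_an), "p_perm": p_perm, "stars": stars}
            )
    return pd.DataFrame(rows)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    r is computed on the off-diagonal upper-triangle vectors; the one-sided
    p-value permutes rows and columns of the second matrix jointly.
    """
    if d1.sample_ids != d2.sample_ids:
        if set(d1.sample_ids) != set(d2.sample_ids):
            raise ValueError("distance matrices cover different sample sets")
        order = [d2.sample_ids.index(s) for s in d1.sample_ids]
        m2 = d2.matrix[np.ix_(order, order)]
    else:
        m2 = d2.matrix
    v1 = upper_triangle(d1.matrix)
    r_obs = float(stats.pearsonr(v1, upper_triangle(m2))[0])
    rng = np.random.default_rng(seed)
    n = d1.matrix.shape[0]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = float(stats.pearsonr(v1, upper_triangle(m2[np.ix_(perm, perm)]))[0])
        if r_p >= r_obs - 1e-15:
            hits += 1
    return r_obs, (1 + hits) / (n_permutations + 1)
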