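"""Community composition summaries and ordination on OTU tables.

Holds the OTU count container, taxonomic relative-abundance aggregation,
Bray-Curtis dissimilarity, classical PCoA (double-centering plus
eigendecomposition), and a one-way PERMANOVA (Adonis-style) with seeded
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class OTUTable:
    """OTU counts (taxa x samples) with taxonomy and sample metadata.

    ``counts``: DataFrame indexed by OTU id, columns = sample ids.
    ``taxonomy``: DataFrame indexed by OTU id with ranked label columns.
    ``metadata``: DataFrame indexed by sample id with at least ``treatment``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any() or not np.isfinite(self.counts.to_numpy()).all():
            raise ValueError("counts must be finite and >= 0")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "treatment" not in self.metadata.columns:
            raise ValueError("metadata must have a 'treatment' column")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, sample_ids) -> "OTUTable":
        return OTUTable(
            counts=self.counts[list(sample_ids)],
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[list(sample_ids)],
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, counts_path, metadata_path) -> None:
        out = self.counts.copy()
        out = pd.concat([self.taxonomy.reindex(out.index), out], axis=1)
        out.index.name = "otu_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.metadata.copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "OTUTable":
        raw = pd.read_csv(counts_path, sep="\t", index_col=0)
        tax_cols = [c for c in raw.columns if c in TAXONOMY_RANKS]
        taxonomy = raw[tax_cols]
        counts = raw.drop(columns=tax_cols)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts=counts, taxonomy=taxonomy, metadata=metadata)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )


def relative_abundance(table: OTUTable, rank: str = "class") -> pd.DataFrame:
    """Aggregate counts at a taxonomic rank and normalize to proportions.

    Taxa unassigned at ``rank`` are pooled into ``unclassified`` so that every
    column still sums to 1.
    """
    if rank not in table.taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy (have {list(table.taxonomy.columns)})")
    labels = table.taxonomy[rank].reindex(table.counts.index).fillna("unclassified")
    labels = labels.replace("", "unclassified")
    agg = table.counts.groupby(labels.to_numpy()).sum()
    totals = agg.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return agg / totals


def bray_curtis(data: OTUTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    Accepts an OTU table or any taxa-x-samples abundance DataFrame.
    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), in [0, 1].
    """
    df = data.counts if isinstance(data, OTUTable) else data
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = df.to_numpy(dtype=float).T  # samples x taxa
    zero_rows = np.nonzero(x.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        raise ValueError(
            "Bray-Curtis undefined between all-zero samples: "
            f"{[df.columns[i] for i in zero_rows]}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(sample_ids=list(df.columns), matrix=d)


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    fractions: np.ndarray  # positive-eigenvalue fractions per retained axis


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues are
    reported but excluded from the variance fractions.
    """
    D = d.matrix
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10 * max(abs(vals[0]), 1.0), 1e-12)
    pos = vals > tol
    vecs = vecs[:, pos]
    # Deterministic sign convention: orient each axis so its largest-
    # magnitude coordinate is positive (makes output equivariant under
    # sample reordering).
    for a in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, a])), a] < 0:
            vecs[:, a] = -vecs[:, a]
    coords = vecs * np.sqrt(vals[pos])
    fractions = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        sample_ids=list(d.sample_ids),
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=axes),
        eigenvalues=vals,
        fractions=fractions,
    )


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) on a distance matrix.

    R^2 = SS_between / SS_total from the Gower-centered partition of squared
    distances; the p-value counts permuted pseudo-F statistics at least as
    large as the observed one, with the +1 correction.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    groups = np.asarray(pd.Series(groups, index=d.sample_ids).loc[d.sample_ids])
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n, a = len(groups), len(labels)
    d2 = d.matrix**2
    ss_total, ss_within = _permanova_ss(d2, groups)
    if ss_total <= 0:
        raise ValueError("degenerate distances: SS_total = 0")
    ss_between = ss_total - ss_within

    def pseudo_f(ss_w: float) -> float:
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(ss_within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        _, ss_w = _permanova_ss(d2, perm)
        if pseudo_f(ss_w) >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return PermanovaResult(
        r_squared=ss_between / ss_total,
        pseudo_f=f_obs,
        p_value=p,
        n_permutations=n_permutations,
    )
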