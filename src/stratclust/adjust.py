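"""Ancestry principal components, orthogonal-projection adjustment, and
reference-panel ancestry assignment.

The stratification correction projects each disease-SNP column onto the
orthogonal complement of the span of the top ancestry PCs (computed from a
high-FST AIM panel):

    G' = (I - A (A^T A)^{-1} A^T) G

Missing genotypes never enter the projection and stay missing in G'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import pairwise_distance, pam, silhouette
from .genotypes import GenotypeMatrix, StandardizedMatrix, standardize

__all__ = [
    "PCBasis",
    "AdjustedGenotypes",
    "AncestryAssignment",
    "compute_pcs",
    "adjust_genotypes",
    "assign_ancestry",
]


@dataclass
class PCBasis:
    """Sample-space principal components of a standardised genotype matrix.

    ``components`` is n x k with orthonormal columns (the top-k left singular
    vectors); ``explained_fraction[i]`` is sigma_i^2 / sum(sigma^2) over all
    singular values, so the fractions refer to the total variance of the
    input panel.
    """

    components: np.ndarray
    explained_fraction: np.ndarray
    k: int
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.components, dtype=float)
        gram = A.T @ A
        if not np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8):
            raise ValueError("PC columns must be pairwise orthogonal")
        if np.any(np.diff(self.explained_fraction) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.components, index=self.sample_ids or None,
                            columns=cols)


@dataclass
class AdjustedGenotypes:
    """Ancestry-adjusted genotype values; NaN where the source call was missing."""

    values: np.ndarray
    source: GenotypeMatrix
    mode: str
    standardized_input: bool

    def __post_init__(self) -> None:
        if self.values.shape != self.source.values.shape:
            raise ValueError("adjusted values must match the source shape")
        if not np.array_equal(np.isnan(self.values), self.source.missing_mask):
            raise ValueError("missing mask must match the source exactly")


@dataclass
class AncestryAssignment:
    labels: pd.Series              # per query sample
    silhouette_widths: pd.Series   # per query sample
    cluster_ids: pd.Series         # per query sample (1..k)
    cluster_label_map: dict
    panel_mismatches: pd.DataFrame  # panel samples whose cluster majority disagrees
    panel_pure: bool


def compute_pcs(S: StandardizedMatrix, k: int) -> PCBasis:
    """Top-k sample-space principal components of the standardised AIM matrix.

    Signs are fixed deterministically: within each component the
    largest-magnitude entry is made positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = S.values
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    U, sing, _ = np.linalg.svd(X, full_matrices=False)
    tol = sing.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((sing > tol).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds the matrix rank {rank}")
    total = float((sing**2).sum())
    comps = U[:, :k].copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(comps[:, j])))
        if comps[i_max, j] < 0:
            comps[:, j] = -comps[:, j]
    frac = sing[:k] ** 2 / total
    return PCBasis(components=comps, explained_fraction=frac, k=k,
                   sample_ids=list(S.sample_ids))


def adjust_genotypes(G: GenotypeMatrix, A: PCBasis, mode: str = "available_case",
                     standardized: bool = True) -> AdjustedGenotypes:
    """Project genotypes onto the complement of the ancestry-PC span.

    By default the disease-SNP matrix is standardised first so distances stay
    scale-comparable across SNPs; set ``standardized=False`` to project the
    raw 0/1/2 codes.  An intercept column accompanies the PCs, so each
    adjusted column is also centred.

    ``available_case`` (default): per column, the observed entries are
    regressed on [1, A] restricted to the observed rows and replaced by the
    residuals; missing entries never enter and remain missing.
    ``impute_zero``: the closed-form projection is applied to the zero-filled
    standardised matrix, after which missing entries are restored to NaN.
    Both coincide with the plain orthogonal projection on complete data.
    """
    if mode not in ("available_case", "impute_zero"):
        raise ValueError(f"unknown mode {mode!r}")
    if A.components.shape[0] != G.n:
        raise ValueError("PC basis and genotype matrix have different sample counts")
    mask = G.missing_mask
    if standardized:
        X = standardize(G).values.copy()
        X[mask] = np.nan
    else:
        X = G.values.astype(float).copy()
    k = A.k
    design = np.column_stack([np.ones(G.n), A.components])

    out = np.full_like(X, np.nan)
    if mode == "impute_zero":
        Z = np.nan_to_num(X)
        beta, *_ = np.linalg.lstsq(design, Z, rcond=None)
        resid = Z - design @ beta
        resid[mask] = np.nan
        out = resid
    else:
        for j in range(G.m):
            rows = ~mask[:, j]
            n_obs = int(rows.sum())
            # k+1 parameters (intercept + PCs); fewer rows is underdetermined
            if n_obs < k + 1:
                raise ValueError(
                    f"marker {G.marker_ids[j]!r} has only {n_obs} observed calls; "
                    f"need at least k+1={k + 1} for the projection regression"
                )
            Dj = design[rows]
            if np.linalg.matrix_rank(Dj) < design.shape[1]:
                raise ValueError(
                    f"PC design is rank-deficient on the observed rows of marker "
                    f"{G.marker_ids[j]!r}"
                )
            beta, *_ = np.linalg.lstsq(Dj, X[rows, j], rcond=None)
            out[rows, j] = X[rows, j] - Dj @ beta
    return AdjustedGenotypes(values=out, source=G, mode=mode,
                             standardized_input=standardized)


def assign_ancestry(query: GenotypeMatrix, panel: GenotypeMatrix,
                    panel_labels, seed: int | None = None) -> AncestryAssignment:
    """Label query samples by PAM-clustering them together with a labelled
    reference panel on shared ancestry markers (Euclidean distance).

    k equals the number of panel populations; each cluster takes the majority
    population among its panel members and query samples inherit their
    cluster's label.  Per-sample silhouette widths measure how well each
    individual sits in its attributed population.  The purity report lists
    panel samples whose own population disagrees with their cluster label.
    """
    if list(query.marker_ids) != list(panel.marker_ids):
        raise ValueError("query and panel must share an identical marker set")
    panel_labels = pd.Series(
        np.asarray(panel_labels, dtype=object), index=panel.sample_ids
    )
    pops = sorted(set(panel_labels))
    if len(pops) < 2:
        raise ValueError("panel must contain at least two populations")
    counts = panel_labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every panel population needs at least two members")

    combined = np.vstack([query.values, panel.values])
    D = pairwise_distance(combined, metric="euclidean")
    res = pam(D, k=len(pops), seed=seed)
    labels = res.partition.labels
    sil = silhouette(D, labels)

    n_q = query.n
    is_panel = np.zeros(len(labels), dtype=bool)
    is_panel[n_q:] = True

    cluster_label_map: dict[int, str] = {}
    for c in range(1, len(pops) + 1):
        members = (labels == c) & is_panel
        if not members.any():
            raise ValueError(f"cluster {c} contains no panel members; label undefined")
        pops_in = panel_labels.iloc[np.flatnonzero(members[n_q:])]
        cluster_label_map[c] = pops_in.value_counts().idxmax()

    panel_assigned = pd.Series([cluster_label_map[c] for c in labels[n_q:]],
                               index=panel.sample_ids)
    mismatch = panel_assigned != panel_labels
    mismatches = pd.DataFrame({
        "population": panel_labels[mismatch],
        "cluster_label": panel_assigned[mismatch],
    })

    q_ids = query.sample_ids
    return AncestryAssignment(
        labels=pd.Series([cluster_label_map[c] for c in labels[:n_q]], index=q_ids),
        silhouette_widths=pd.Series(sil.widths[:n_q], index=q_ids),
        cluster_ids=pd.Series(labels[:n_q], index=q_ids),
        cluster_label_map=cluster_label_map,
        panel_mismatches=mismatches,
        panel_pure=bool(~mismatch.any()),
    )
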