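"""Similarity construction for the two heterogeneous networks.

Four similarity sources feed the model:

* disease semantic similarity from MeSH-style disease DAGs, using the
  information-content contribution of shared ancestors;
* miRNA functional similarity, lifting disease similarity to miRNAs through
  their associated disease sets (best-match averaging);
* Gaussian interaction profile (GIP) kernel similarity for both entity
  types, computed from the rows/columns of the binary association matrix;
* the integrated matrices: diseases average semantic and GIP similarity,
  miRNAs keep functional similarity and fall back to GIP where it is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from scplpa.core_io import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix

__all__ = [
    "ContributionTable",
    "GIPParams",
    "ancestor_contribution",
    "semantic_value",
    "disease_semantic_similarity",
    "set_association",
    "mirna_functional_similarity",
    "gip_similarity",
    "gip_pair",
    "integrate_disease",
    "integrate_mirna",
]

logger = logging.getLogger(__name__)


@dataclass
class ContributionTable:
    """Ancestor-term information-content contributions and per-disease semantic values."""

    contributions: dict[str, float]
    semantic_values: dict[str, float]


@dataclass
class GIPParams:
    """Kernel bandwidths of the two GIP kernels."""

    gamma_d: float | None = None
    gamma_m: float | None = None


def ancestor_contribution(
    dag_set: DiseaseDAGSet, log_base: float | None = None
) -> ContributionTable:
    """Information-content contribution of every ancestor term.

    A term appearing in ``k`` of the ``N`` disease DAGs contributes
    ``-log(k / N)`` (natural log unless ``log_base`` is given), so a term
    shared by every disease contributes nothing and rare terms contribute
    most.  The per-disease semantic value is the sum over its ancestor set.
    """
    if dag_set.universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    counts: dict[str, int] = {}
    for anc in dag_set.ancestors.values():
        for term in anc:
            counts[term] = counts.get(term, 0) + 1
    scale = 1.0 if log_base is None else 1.0 / np.log(log_base)
    contributions = {
        term: -np.log(k / dag_set.universe_size) * scale for term, k in counts.items()
    }
    semantic_values = {
        d: float(sum(contributions[t] for t in anc))
        for d, anc in dag_set.ancestors.items()
    }
    return ContributionTable(contributions=contributions, semantic_values=semantic_values)


def semantic_value(disease: str, table: ContributionTable) -> float:
    """Semantic value DV(d): total contribution of the disease's ancestor set."""
    try:
        return table.semantic_values[disease]
    except KeyError:
        raise KeyError(f"unknown disease {disease!r}") from None


def disease_semantic_similarity(
    dag_set: DiseaseDAGSet, log_base: float | None = None
) -> SimilarityMatrix:
    """Semantic similarity: shared-ancestor contribution over summed semantic values.

    DD(i, j) = sum over shared ancestors t of 2 D(t), divided by
    DV(i) + DV(j).  Pairs whose DAGs carry only universal (zero-contribution)
    terms have DV sums of 0; those get similarity 0 with a warning rather
    than an error so degenerate hierarchies stay usable.
    """
    table = ancestor_contribution(dag_set, log_base=log_base)
    diseases = dag_set.diseases
    n = len(diseases)
    dv = np.array([table.semantic_values[d] for d in diseases])
    dd = np.zeros((n, n))
    warned = False
    for i in range(n):
        anc_i = dag_set.ancestors[diseases[i]]
        for j in range(i, n):
            denom = dv[i] + dv[j]
            if denom <= 0:
                if not warned:
                    logger.warning(
                        "disease pair with zero total semantic value; similarity set to 0"
                    )
                    warned = True
                continue
            shared = anc_i & dag_set.ancestors[diseases[j]]
            num = 2.0 * sum(table.contributions[t] for t in shared)
            dd[i, j] = dd[j, i] = num / denom
    # clip tiny float overshoot on the diagonal (num == denom there)
    np.clip(dd, 0.0, 1.0, out=dd)
    return SimilarityMatrix(dd, diseases, kind="semantic")


def set_association(disease: str, disease_set: Sequence[str], dd: SimilarityMatrix) -> float:
    """Best-match association of one disease to a disease set: max similarity."""
    if len(disease_set) == 0:
        raise ValueError("disease set must be nonempty")
    pos = {n: i for i, n in enumerate(dd.names)}
    try:
        i = pos[disease]
        idx = [pos[d] for d in disease_set]
    except KeyError as exc:
        raise KeyError(f"disease missing from similarity matrix: {exc}") from None
    return float(dd.values[i, idx].max())


def mirna_functional_similarity(
    assoc: AssociationMatrix, dd: SimilarityMatrix
) -> SimilarityMatrix:
    """Lift disease similarity to miRNAs via best-match averaging.

    MM(i, j) averages, over both associated-disease sets D(mi) and D(mj),
    the best similarity each disease achieves in the other set.  miRNAs
    with no associated diseases get off-diagonal similarity 0 (the GIP
    kernel then stands in through the integration fallback) and diagonal 1.
    """
    dd = dd.reindex(assoc.disease_names)
    md = assoc.values
    nm = assoc.nm
    disease_sets = [np.flatnonzero(md[i] == 1) for i in range(nm)]
    # best_match[i] = for miRNA i, max similarity of every disease to D(mi)
    best_match = [
        dd.values[:, ds].max(axis=1) if ds.size else None for ds in disease_sets
    ]
    mm = np.zeros((nm, nm))
    for i in range(nm):
        if best_match[i] is None:
            continue
        for j in range(i, nm):
            if best_match[j] is None:
                continue
            di, dj = disease_sets[i], disease_sets[j]
            num = best_match[j][di].sum() + best_match[i][dj].sum()
            mm[i, j] = mm[j, i] = num / (di.size + dj.size)
    np.fill_diagonal(mm, 1.0)
    np.clip(mm, 0.0, 1.0, out=mm)
    return SimilarityMatrix(mm, assoc.mirna_names, kind="functional")


def gip_similarity(
    profiles: np.ndarray, names: Sequence[str]
) -> tuple[SimilarityMatrix, float]:
    """Gaussian interaction profile kernel over binary profiles (one per row).

    The bandwidth is the reciprocal of the mean squared profile norm,
    gamma = n / sum_i ||profile_i||^2, and
    K(i, j) = exp(-gamma ||profile_i - profile_j||^2).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] != len(names):
        raise ValueError("profiles must be 2-D with one row per entity")
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0:
        raise ValueError("all profiles are zero; GIP bandwidth undefined")
    gamma = 1.0 / mean_sq_norm
    if len(names) == 1:
        kernel = np.ones((1, 1))
    else:
        sq_dist = squareform(pdist(profiles, metric="sqeuclidean"))
        kernel = np.exp(-gamma * sq_dist)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix(kernel, tuple(names), kind="gip"), gamma


def gip_pair(assoc: AssociationMatrix) -> tuple[SimilarityMatrix, SimilarityMatrix, GIPParams]:
    """GIP kernels for both sides of the association matrix.

    Disease profiles are columns of MD (which miRNAs hit the disease);
    miRNA profiles are rows (which diseases the miRNA hits).
    """
    gd, gamma_d = gip_similarity(assoc.values.T, assoc.disease_names)
    gm, gamma_m = gip_similarity(assoc.values, assoc.mirna_names)
    return gd, gm, GIPParams(gamma_d=gamma_d, gamma_m=gamma_m)


def _check_same_labels(a: SimilarityMatrix, b: SimilarityMatrix) -> None:
    if a.names != b.names:
        raise ValueError("similarity matrices have mismatched labels")
    if a.values.shape != b.values.shape:
        raise ValueError("similarity matrices have mismatched shapes")


def integrate_disease(dd: SimilarityMatrix, gd: SimilarityMatrix) -> SimilarityMatrix:
    """Heterogeneous disease similarity: elementwise mean of semantic and GIP."""
    _check_same_labels(dd, gd)
    return SimilarityMatrix((dd.values + gd.values) / 2.0, dd.names, kind="integrated")


def integrate_mirna(mm: SimilarityMatrix, gm: SimilarityMatrix) -> SimilarityMatrix:
    """Heterogeneous miRNA similarity: functional where nonzero, GIP elsewhere."""
    _check_same_labels(mm, gm)
    values = np.where(mm.values != 0, mm.values, gm.values)
    return SimilarityMatrix(values, mm.names, kind="integrated")
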