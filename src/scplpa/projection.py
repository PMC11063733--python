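"""Network consistency projection and the full SCPLPA pipeline.

A pair (miRNA i, disease j) is scored by projecting the miRNA's similarity
vector onto the estimated score column of disease j (and symmetrically the
disease's similarity vector onto miRNA i's score row), normalized by the
Euclidean norm of the projected-onto vector.  The two projections are mixed
by epsilon into the final score matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scplpa.core_io import (
    AssociationMatrix,
    DiseaseDAGSet,
    SCPLPAConfig,
    ScoreBundle,
    SimilarityMatrix,
)
from scplpa.propagation import estimate_scores, label_propagate, normalize_network
from scplpa import similarity as sim

__all__ = [
    "project_mirna",
    "project_disease",
    "combine_projections",
    "HeterogeneousNetworks",
    "build_networks",
    "score_networks",
    "run_scplpa",
]


def _safe_divide(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


def project_mirna(mmf: np.ndarray | SimilarityMatrix, fe: np.ndarray) -> np.ndarray:
    """miRNA-side consistency projection.

    MDpm(i, j) = (MMf row i . Fe column j) / ||Fe column j||_2, with
    zero-norm columns mapped to 0 instead of NaN.
    """
    m = mmf.values if isinstance(mmf, SimilarityMatrix) else np.asarray(mmf, float)
    fe = np.asarray(fe, dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[1] != fe.shape[0]:
        raise ValueError(f"shape mismatch: MMf {m.shape} vs Fe {fe.shape}")
    col_norms = np.linalg.norm(fe, axis=0)
    return _safe_divide(m @ fe, col_norms[None, :])


def project_disease(ddf: np.ndarray | SimilarityMatrix, fe: np.ndarray) -> np.ndarray:
    """Disease-side consistency projection, emitted miRNA x disease.

    MDpd(i, j) = (DDf row j . Fe row i) / ||Fe row i||_2, with zero-norm
    rows mapped to 0.
    """
    d = ddf.values if isinstance(ddf, SimilarityMatrix) else np.asarray(ddf, float)
    fe = np.asarray(fe, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != fe.shape[1]:
        raise ValueError(f"shape mismatch: DDf {d.shape} vs Fe {fe.shape}")
    row_norms = np.linalg.norm(fe, axis=1)
    return _safe_divide(fe @ d.T, row_norms[:, None])


def combine_projections(
    md_pm: np.ndarray,
    md_pd: np.ndarray,
    epsilon: float,
    literal_pd_transpose: bool = False,
) -> np.ndarray:
    """Final scores MD* = epsilon MDpm + (1 - epsilon) MDpd.

    ``literal_pd_transpose`` applies the disease-side projection transposed
    (only meaningful for square problems); the default keeps both terms in
    miRNA x disease orientation.
    """
    md_pm = np.asarray(md_pm, dtype=float)
    md_pd = np.asarray(md_pd, dtype=float)
    if not 0 <= epsilon <= 1:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if literal_pd_transpose:
        md_pd = md_pd.T
    if md_pm.shape != md_pd.shape:
        raise ValueError(f"shape mismatch: MDpm {md_pm.shape} vs MDpd {md_pd.shape}")
    return epsilon * md_pm + (1.0 - epsilon) * md_pd


@dataclass
class HeterogeneousNetworks:
    """The two integrated similarity networks and their normalized forms."""

    ddf: SimilarityMatrix
    mmf: SimilarityMatrix
    dd_norm: np.ndarray
    mm_norm: np.ndarray
    dd: SimilarityMatrix
    mm: SimilarityMatrix
    gd: SimilarityMatrix
    gm: SimilarityMatrix
    gip: sim.GIPParams


def build_networks(
    assoc: AssociationMatrix,
    dags: DiseaseDAGSet | None = None,
    dd: SimilarityMatrix | None = None,
    mm: SimilarityMatrix | None = None,
    config: SCPLPAConfig | None = None,
) -> HeterogeneousNetworks:
    """Assemble the heterogeneous disease and miRNA networks.

    Disease similarity comes from DAG semantics (``dags``) or a precomputed
    matrix (``dd``); miRNA functional similarity is derived from ``dd`` and
    the association matrix unless supplied precomputed.  GIP kernels for
    both sides are always computed from the association matrix.
    """
    config = config or SCPLPAConfig()
    if dd is None:
        if dags is None:
            raise ValueError("either a disease DAG set or a precomputed DD is required")
        dd = sim.disease_semantic_similarity(dags, log_base=config.log_base)
    dd = dd.reindex(assoc.disease_names)
    if mm is None:
        mm = sim.mirna_functional_similarity(assoc, dd)
    mm = mm.reindex(assoc.mirna_names)
    gd, gm, gip = sim.gip_pair(assoc)
    ddf = sim.integrate_disease(dd, gd)
    mmf = sim.integrate_mirna(mm, gm)
    dd_norm = normalize_network(ddf, config.normalization_mode, provenance="disease").values
    mm_norm = normalize_network(mmf, config.normalization_mode, provenance="mirna").values
    return HeterogeneousNetworks(
        ddf=ddf, mmf=mmf, dd_norm=dd_norm, mm_norm=mm_norm,
        dd=dd, mm=mm, gd=gd, gm=gm, gip=gip,
    )


def score_networks(
    nets: HeterogeneousNetworks,
    md: np.ndarray,
    assoc: AssociationMatrix,
    config: SCPLPAConfig,
) -> ScoreBundle:
    """Propagate + project a (possibly masked) association matrix on fixed networks."""
    fd = label_propagate(
        nets.dd_norm, md.T, config.alpha, config.tolerance, config.max_iterations
    )
    fm = label_propagate(
        nets.mm_norm, md, config.beta, config.tolerance, config.max_iterations
    )
    fe = estimate_scores(fd, fm, config.delta)
    md_pm = project_mirna(nets.mmf, fe)
    md_pd = project_disease(nets.ddf, fe)
    md_star = combine_projections(
        md_pm, md_pd, config.epsilon, literal_pd_transpose=config.literal_pd_transpose
    )
    return ScoreBundle(
        fd_star=fd.fixed_point.T,
        fm_star=fm.fixed_point,
        fe=fe,
        md_pm=md_pm,
        md_pd=md_pd,
        md_star=md_star,
        mirna_names=assoc.mirna_names,
        disease_names=assoc.disease_names,
        fd_converged=fd.converged,
        fm_converged=fm.converged,
        fd_iterations=fd.iterations,
        fm_iterations=fm.iterations,
    )


def run_scplpa(
    assoc: AssociationMatrix,
    dags: DiseaseDAGSet | None = None,
    dd: SimilarityMatrix | None = None,
    mm: SimilarityMatrix | None = None,
    config: SCPLPAConfig | None = None,
) -> ScoreBundle:
    """Run the full pipeline: similarities -> integration -> propagation -> projection.

    Returns every intermediate matrix in a :class:`ScoreBundle`;
    non-convergence of either propagation is flagged there, not raised.
    """
    config = config or SCPLPAConfig()
    nets = build_networks(assoc, dags=dags, dd=dd, mm=mm, config=config)
    return score_networks(nets, assoc.values, assoc, config)
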