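"""Domain types and delimited-text readers/writers.

All on-disk formats are plain text: edge-list TSV for associations and DAG
edges, dense CSV/TSV with a header row and column for matrices, YAML for
configuration.  Label order is always sorted, so every downstream matrix is
reproducible bit-for-bit from the same files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssociationMatrix",
    "DiseaseDAGSet",
    "SimilarityMatrix",
    "ScoreBundle",
    "SCPLPAConfig",
    "read_association_table",
    "write_association_table",
    "read_dag_edges",
    "read_similarity_matrix",
    "write_predictions",
    "write_run_manifest",
]


def _check_unique(names: Sequence[str], what: str) -> tuple[str, ...]:
    names = tuple(str(n) for n in names)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate {what} names")
    if not names:
        raise ValueError(f"empty {what} name list")
    return names


@dataclass
class AssociationMatrix:
    """Binary miRNA-disease association matrix.

    Rows index miRNAs (``nm``), columns index diseases (``nd``); entry
    (i, j) is 1 iff miRNA i has a known association with disease j.
    """

    values: np.ndarray
    mirna_names: tuple[str, ...]
    disease_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_names = _check_unique(self.mirna_names, "miRNA")
        self.disease_names = _check_unique(self.disease_names, "disease")
        if self.values.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValueError(
                f"association shape {self.values.shape} does not match "
                f"{len(self.mirna_names)} miRNAs x {len(self.disease_names)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = np.unique(self.values[~np.isin(self.values, (0.0, 1.0))])
            raise ValueError(f"association entries must be 0/1, found {bad}")

    @property
    def nm(self) -> int:
        return len(self.mirna_names)

    @property
    def nd(self) -> int:
        return len(self.disease_names)

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(values, self.mirna_names, self.disease_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=list(self.mirna_names),
            columns=list(self.disease_names),
        )


@dataclass
class DiseaseDAGSet:
    """Per-disease ancestor sets N(d) and edge sets E(d).

    ``ancestors[d]`` always contains ``d`` itself; edges run child -> parent
    and are acyclic.  ``universe_size`` is the denominator used when turning
    ancestor frequency into an information-content contribution.
    """

    ancestors: dict[str, frozenset[str]]
    edges: dict[str, frozenset[tuple[str, str]]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        for d, anc in self.ancestors.items():
            if d not in anc:
                raise ValueError(f"disease {d!r} missing from its own ancestor set")

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.ancestors)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        diseases: Sequence[str] | None = None,
        universe_size: int | None = None,
    ) -> "DiseaseDAGSet":
        """Build ancestor sets by transitive closure over child->parent edges.

        ``diseases`` restricts which nodes get a DAG of their own (default:
        every node in the edge file).  Raises on any directed cycle.
        """
        graph = nx.DiGraph()
        for child, parent in edges:
            graph.add_edge(str(child), str(parent))
        if diseases is not None:
            graph.add_nodes_from(str(d) for d in diseases)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"disease hierarchy contains a cycle: {cycle}")
        if diseases is None:
            targets = sorted(graph.nodes)
        else:
            # diseases absent from the edge file become singleton DAGs {d}
            targets = [str(d) for d in diseases]
        ancestors: dict[str, frozenset[str]] = {}
        edge_sets: dict[str, frozenset[tuple[str, str]]] = {}
        for d in targets:
            anc = {d} | nx.descendants(graph, d)  # child->parent, so "descendants" climb up
            ancestors[d] = frozenset(anc)
            edge_sets[d] = frozenset(
                (u, v) for u, v in graph.edges if u in anc and v in anc
            )
        n = universe_size if universe_size is not None else len(targets)
        return cls(ancestors=ancestors, edges=edge_sets, universe_size=n)


_SIM_KINDS = ("semantic", "functional", "gip", "integrated")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    names: tuple[str, ...]
    kind: str = "integrated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = _check_unique(self.names, "entity")
        if self.kind not in _SIM_KINDS:
            raise ValueError(f"kind must be one of {_SIM_KINDS}")
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")
        self.validate()

    def validate(self, tol: float = 1e-12) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("similarity contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > tol:
            raise ValueError("similarity is not symmetric")
        if self.values.min(initial=0.0) < -tol or self.values.max(initial=0.0) > 1 + tol:
            raise ValueError("similarity entries outside [0, 1]")

    def reindex(self, names: Sequence[str]) -> "SimilarityMatrix":
        """Restrict/reorder to ``names`` (all must be present)."""
        pos = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"names absent from similarity matrix: {missing}")
        idx = np.array([pos[n] for n in names])
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], tuple(names), self.kind)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))
        df.to_csv(path, float_format="%.17g")


@dataclass
class ScoreBundle:
    """All intermediate and final score matrices, oriented miRNA x disease."""

    fd_star: np.ndarray  # disease-network propagation fixed point, transposed to nm x nd
    fm_star: np.ndarray  # miRNA-network propagation fixed point
    fe: np.ndarray  # estimated scores
    md_pm: np.ndarray  # miRNA-side consistency projection
    md_pd: np.ndarray  # disease-side consistency projection
    md_star: np.ndarray  # final scores
    mirna_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    fd_converged: bool = True
    fm_converged: bool = True
    fd_iterations: int = 0
    fm_iterations: int = 0

    def __post_init__(self) -> None:
        shape = (len(self.mirna_names), len(self.disease_names))
        for name in ("fd_star", "fm_star", "fe", "md_pm", "md_pd", "md_star"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)

    @property
    def converged(self) -> bool:
        return self.fd_converged and self.fm_converged


@dataclass
class SCPLPAConfig:
    """Model parameters.

    alpha/beta are the restart weights of the two label-propagation runs,
    delta mixes the two propagation results, epsilon mixes the two
    projection scores.  Defaults are the optimal set from the original
    parameter sweep (alpha = beta = 0.9, delta = 0.9, epsilon = 0.6).
    """

    alpha: float = 0.9
    beta: float = 0.9
    delta: float = 0.9
    epsilon: float = 0.6
    tolerance: float = 1e-6
    max_iterations: int = 1000
    log_base: float | None = None  # None -> natural log
    normalization_mode: str = "degree_sum"  # or "symmetric"
    refresh_gip_per_fold: bool = False
    threshold_mode: str | float = "youden"
    literal_pd_transpose: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("delta", "epsilon"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.normalization_mode not in ("degree_sum", "symmetric"):
            raise ValueError("normalization_mode must be 'degree_sum' or 'symmetric'")
        if self.log_base is not None and self.log_base <= 1:
            raise ValueError("log_base must be > 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SCPLPAConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def updated(self, **kwargs) -> "SCPLPAConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_association_table(path: str | Path, format: str = "edge_list") -> AssociationMatrix:
    """Read a binary association table.

    ``edge_list`` rows are (miRNA, disease[, value]); the universes are the
    names appearing anywhere in the file, sorted.  ``dense`` is a matrix
    with header row/column of names, rows = miRNAs.
    """
    path = Path(path)
    if format == "edge_list":
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#", names=[0, 1, 2]
        )
        if df.empty:
            raise ValueError(f"empty association file: {path}")
        if df[[0, 1]].isna().any().any():
            raise ValueError("edge list rows must be (miRNA, disease[, value])")
        df[2] = df[2].fillna("1")
        vals = pd.to_numeric(df[2], errors="raise").to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("edge-list values must be binary 0/1")
        mirnas = tuple(sorted(df[0].unique()))
        diseases = tuple(sorted(df[1].unique()))
        mat = np.zeros((len(mirnas), len(diseases)))
        mi = {m: i for i, m in enumerate(mirnas)}
        di = {d: j for j, d in enumerate(diseases)}
        for m, d, v in zip(df[0], df[1], vals):
            # duplicates collapse via max: (m,d,1) beats an explicit 0
            mat[mi[m], di[d]] = max(mat[mi[m], di[d]], v)
        return AssociationMatrix(mat, mirnas, diseases)
    if format == "dense":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        if df.empty:
            raise ValueError(f"empty association file: {path}")
        df = df.sort_index().sort_index(axis=1)
        return AssociationMatrix(
            df.to_numpy(dtype=float), tuple(df.index.astype(str)), tuple(df.columns.astype(str))
        )
    raise ValueError(f"unknown format {format!r}")


def write_association_table(
    assoc: AssociationMatrix, path: str | Path, format: str = "edge_list"
) -> None:
    """Write an association table; round trips losslessly via :func:`read_association_table`.

    The edge list carries all positive pairs plus one explicit-zero row per
    all-zero miRNA/disease so the universes survive the round trip.
    """
    path = Path(path)
    if format == "dense":
        assoc.to_frame().to_csv(path, sep=_sep_for(path))
        return
    if format != "edge_list":
        raise ValueError(f"unknown format {format!r}")
    rows: list[tuple[str, str, int]] = []
    for i, m in enumerate(assoc.mirna_names):
        for j, d in enumerate(assoc.disease_names):
            if assoc.values[i, j] == 1:
                rows.append((m, d, 1))
    zero_m = [m for i, m in enumerate(assoc.mirna_names) if assoc.values[i].sum() == 0]
    zero_d = [d for j, d in enumerate(assoc.disease_names) if assoc.values[:, j].sum() == 0]
    anchor_d = assoc.disease_names[0]
    anchor_m = assoc.mirna_names[0]
    rows += [(m, anchor_d, 0) for m in zero_m]
    rows += [(anchor_m, d, 0) for d in zero_d if d != anchor_d or not zero_m]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_dag_edges(
    path: str | Path,
    diseases: Sequence[str] | None = None,
    universe_size: int | None = None,
) -> DiseaseDAGSet:
    """Read child->parent DAG edges (TSV) into per-disease ancestor sets."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("DAG edge rows must be (child, parent)")
    edges = list(zip(df[0], df[1]))
    return DiseaseDAGSet.from_edges(edges, diseases=diseases, universe_size=universe_size)


def write_dag_edges(dag_set: DiseaseDAGSet, path: str | Path) -> None:
    all_edges = sorted(set().union(*dag_set.edges.values())) if dag_set.edges else []
    pd.DataFrame(all_edges).to_csv(path, sep="\t", header=False, index=False)


def read_similarity_matrix(path: str | Path, kind: str = "integrated") -> SimilarityMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("similarity matrix header row and column disagree")
    return SimilarityMatrix(df.to_numpy(dtype=float), tuple(df.index.astype(str)), kind)


def write_predictions(
    bundle: ScoreBundle,
    known_mask: np.ndarray,
    path: str | Path,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Write the ranked prediction table.

    Rows are (rank, miRNA, disease, score, known_flag) sorted by descending
    score with ties broken by (miRNA, disease) lexical order.
    """
    known_mask = np.asarray(known_mask)
    if known_mask.shape != bundle.md_star.shape:
        raise ValueError(
            f"known mask shape {known_mask.shape} != scores {bundle.md_star.shape}"
        )
    records = []
    for i, m in enumerate(bundle.mirna_names):
        for j, d in enumerate(bundle.disease_names):
            records.append((m, d, bundle.md_star[i, j], int(known_mask[i, j] != 0)))
    df = pd.DataFrame(records, columns=["mirna", "disease", "score", "known"])
    df = df.sort_values(
        ["score", "mirna", "disease"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if top_k is not None:
        df = df.head(top_k)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df


def write_run_manifest(
    out_dir: str | Path,
    config: SCPLPAConfig | Mapping | None,
    inputs: Mapping[str, str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a deterministic provenance manifest next to the outputs."""
    from scplpa import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {}
    for label, p in (inputs or {}).items():
        p = Path(p)
        digests[label] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None,
        }
    manifest = {
        "package": "scplpa",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict() if isinstance(config, SCPLPAConfig) else dict(config or {}),
        "inputs": digests,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
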