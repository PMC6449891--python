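"""Core containers and plain-text I/O for expression matrices and networks.

Everything downstream works on three containers: an expression matrix
(genes x experiments), a symmetric score matrix over genes, and an
undirected edge list.  All file formats are tab-separated text so that
intermediate artifacts remain diffable and stage-restartable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScoredNetwork",
    "EdgeList",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "threshold_network",
    "minmax_normalize",
    "read_config",
    "write_config",
]


@dataclass
class ExpressionMatrix:
    """Real-valued genes x experiments matrix with row/column labels.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in
    experiment ``experiment_ids[j]``.
    """

    gene_ids: list[str]
    experiment_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.experiment_ids)


@dataclass
class ScoredNetwork:
    """Gene x gene score matrix (co-membership G, fused W, confidence C, refined R).

    ``symmetric`` declares the matrix undirected; ``score_range`` declares
    the admissible value interval after any normalisation.
    """

    gene_ids: list[str]
    scores: np.ndarray
    symmetric: bool = True
    score_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(f"score matrix shape {self.scores.shape} != ({n}, {n})")
        if self.symmetric and not np.allclose(self.scores, self.scores.T, atol=1e-9):
            raise ValueError("network flagged symmetric but score matrix is not")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def copy_with(self, scores: np.ndarray, **kw) -> "ScoredNetwork":
        params = dict(gene_ids=list(self.gene_ids), scores=scores,
                      symmetric=self.symmetric, score_range=self.score_range)
        params.update(kw)
        return ScoredNetwork(**params)


@dataclass
class EdgeList:
    """Undirected weighted edges; no self-loops, one record per unordered pair."""

    records: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.records}

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.records:
            out.add(a)
            out.add(b)
        return out

    def restrict_to(self, genes: Iterable[str]) -> "EdgeList":
        """Drop edges with an endpoint outside ``genes`` (logged count)."""
        keep = set(genes)
        kept = [r for r in self.records if r[0] in keep and r[1] in keep]
        dropped = len(self.records) - len(kept)
        if dropped:
            logger.info("dropped %d edges with endpoints outside the gene set", dropped)
        return EdgeList(kept)


def _dedup_edges(raw: Iterable[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    """Collapse duplicate unordered pairs keeping the max weight; drop self-loops."""
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    n_loops = 0
    for a, b, w in raw:
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in best:
            best[key] = w
            order.append(key)
        else:
            best[key] = max(best[key], w)
    if n_loops:
        logger.warning("dropped %d self-loop edges", n_loops)
    return [(a, b, best[(a, b)]) for a, b in order]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with experiment labels in the header row and gene labels in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {path}: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric expression value at gene {bad!r}, experiment {col!r}")
        df[col] = coerced
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        experiment_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        expr.to_frame().to_csv(fh, sep="\t", float_format="%.12g")


def read_edge_list(path: str | Path, default_weight: float = 1.0) -> EdgeList:
    """Read a 2- or 3-column TSV edge list (SIF-compatible); undirected semantics."""
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            w = float(parts[2]) if len(parts) >= 3 else float(default_weight)
            raw.append((a, b, w))
    return EdgeList(_dedup_edges(raw))


def write_edge_list(edges: EdgeList, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.12g}\n")


def threshold_network(net: ScoredNetwork, cutoff: float) -> EdgeList:
    """Emit each unordered pair (i < j in gene order) with score >= cutoff."""
    if not net.symmetric:
        raise ValueError("threshold_network expects a symmetric network")
    recs: list[tuple[str, str, float]] = []
    n = net.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            s = net.scores[i, j]
            if s >= cutoff:
                recs.append((net.gene_ids[i], net.gene_ids[j], float(s)))
    return EdgeList(recs)


def minmax_normalize(net: ScoredNetwork) -> ScoredNetwork:
    """Affinely map off-diagonal scores onto [0, 1]; the diagonal stays 0."""
    n = net.n_genes
    if n < 2:
        raise ValueError("need at least two genes to normalize")
    off = ~np.eye(n, dtype=bool)
    vals = net.scores[off]
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("non-finite scores cannot be normalized")
    if hi - lo == 0:
        raise ValueError("constant score matrix: min-max normalization undefined")
    out = np.zeros_like(net.scores)
    out[off] = (net.scores[off] - lo) / (hi - lo)
    return net.copy_with(out, score_range=(0.0, 1.0))


def read_config(path: str | Path) -> dict:
    """Flat key-value configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} must be a flat mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def scores_to_frame(net: ScoredNetwork) -> pd.DataFrame:
    return pd.DataFrame(net.scores, index=net.gene_ids, columns=net.gene_ids)


def write_scores(net: ScoredNetwork, path: str | Path) -> None:
    scores_to_frame(net).to_csv(path, sep="\t", float_format="%.12g")


def read_scores(path: str | Path, symmetric: bool = True) -> ScoredNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoredNetwork(
        gene_ids=[str(g) for g in df.index],
        scores=df.to_numpy(dtype=float),
        symmetric=symmetric,
        score_range=(float(df.values.min()), float(df.values.max())),
    )
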