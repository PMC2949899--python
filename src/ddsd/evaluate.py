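"""Retrieval harness and evaluation statistics.

A benchmark is a set of shapes with group labels (conformers of the same
molecule share a group).  Each shape in turn queries the rest of the
database; retrieved shapes are ranked by ascending descriptor
dissimilarity.  Quality is summarized by precision-recall curves,
nearest-neighbour accuracy, the E-measure over the first 64 retrieved
shapes, and the F-measure (harmonic mean of precision and recall).

Protocol: the query is excluded both from the database being ranked and
from its own relevant set, so a perfect retrieval scores exactly 1.0.
At retrieval size s, precision = TP / s and recall = TP / (group size - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptor import ShapeDescriptor, compare_descriptors

__all__ = [
    "BenchmarkManifest",
    "RetrievalRun",
    "rank_database",
    "precision_recall",
    "average_precision_recall",
    "e_measure",
    "f_measure",
    "nearest_neighbor_accuracy",
    "evaluate_descriptors",
]

E_MEASURE_SIZE = 64


@dataclass
class BenchmarkManifest:
    """Maps shape ids to file paths and group labels."""

    entries: list[tuple[str, str, str]]  # (shape_id, path, group)
    groups: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate shape ids in manifest")
        self.groups = {}
        for shape_id, _, group in self.entries:
            self.groups.setdefault(group, []).append(shape_id)
        if any(len(v) == 0 for v in self.groups.values()):
            raise ValueError("empty group in manifest")

    def group_of(self, shape_id: str) -> str:
        for sid, _, group in self.entries:
            if sid == shape_id:
                return group
        raise KeyError(shape_id)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BenchmarkManifest":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["id", "path", "group"], dtype=str)
        return cls(entries=list(df.itertuples(index=False, name=None)))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RetrievalRun:
    """Ranked retrieval result for one query."""

    query_id: str
    ranked_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if (np.diff(s) < -1e-12).any():
            raise ValueError("scores must be non-decreasing along the ranking")
        self.scores = s


def rank_database(
    query_id: str,
    query: ShapeDescriptor,
    db: dict[str, ShapeDescriptor],
    metric: str = "L1",
) -> RetrievalRun:
    """Rank all non-query shapes by ascending dissimilarity to the query.

    Ties are broken by lexicographic shape id, making the ranking
    deterministic.
    """
    others = [(sid, d) for sid, d in db.items() if sid != query_id]
    if not others:
        raise ValueError("empty database: nothing to rank")
    scored = sorted(
        ((compare_descriptors(query, d, metric), sid) for sid, d in others),
    )
    return RetrievalRun(
        query_id=query_id,
        ranked_ids=[sid for _, sid in scored],
        scores=np.array([s for s, _ in scored]),
    )


def _relevance(run: RetrievalRun, manifest: BenchmarkManifest) -> np.ndarray:
    group = manifest.group_of(run.query_id)
    members = set(manifest.groups[group]) - {run.query_id}
    if not members:
        raise ValueError(
            f"query {run.query_id!r} is the only member of group {group!r}; "
            "recall is undefined"
        )
    return np.array([sid in members for sid in run.ranked_ids], dtype=bool)


def precision_recall(
    run: RetrievalRun, manifest: BenchmarkManifest
) -> list[tuple[float, float]]:
    """Per-query (recall, precision) at every retrieval size 1..N."""
    rel = _relevance(run, manifest)
    n_relevant = int(rel.sum())
    tp = np.cumsum(rel)
    sizes = np.arange(1, len(rel) + 1)
    precision = tp / sizes
    recall = tp / n_relevant
    return list(zip(recall.tolist(), precision.tolist()))


def average_precision_recall(
    runs: list[RetrievalRun],
    manifest: BenchmarkManifest,
    recall_levels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Average per-query PR curves at fixed recall levels.

    Each query's precision is linearly interpolated over its recall range
    at the requested levels, then averaged across queries.  Queries from
    singleton groups are skipped with a warning.
    """
    if recall_levels is None:
        recall_levels = np.linspace(0.0, 1.0, 21)
    curves = []
    for run in runs:
        try:
            pr = precision_recall(run, manifest)
        except ValueError as err:
            warnings.warn(str(err), stacklevel=2)
            continue
        rec = np.array([r for r, _ in pr])
        prec = np.array([p for _, p in pr])
        # take the best precision at each distinct recall value, then
        # interpolate; recall 0 extends the first observed precision
        distinct = {}
        for r, p in zip(rec, prec):
            distinct[r] = max(distinct.get(r, 0.0), p)
        rs = np.array(sorted(distinct))
        ps = np.array([distinct[r] for r in rs])
        if rs[0] > 0:
            rs = np.concatenate([[0.0], rs])
            ps = np.concatenate([[ps[0]], ps])
        curves.append(np.interp(recall_levels, rs, ps))
    if not curves:
        raise ValueError("no evaluable queries (all groups singletons)")
    mean = np.mean(curves, axis=0)
    return pd.DataFrame({"recall": recall_levels, "precision": mean})


def _pr_at_size(run: RetrievalRun, manifest: BenchmarkManifest, size: int) -> tuple[float, float]:
    rel = _relevance(run, manifest)
    size = min(size, len(rel))
    tp = int(rel[:size].sum())
    precision = tp / size
    recall = tp / int(rel.sum())
    return precision, recall


def e_measure(
    run: RetrievalRun, manifest: BenchmarkManifest, size: int = E_MEASURE_SIZE
) -> float:
    """Composite of precision and recall over the first ``size`` retrieved.

    E = 2 / (1/precision + 1/recall) at retrieval size min(size, db);
    1.0 is the best score, 0 when nothing relevant is retrieved.
    """
    precision, recall = _pr_at_size(run, manifest, size)
    if precision == 0 or recall == 0:
        return 0.0
    return 2.0 / (1.0 / precision + 1.0 / recall)


def f_measure(
    run: RetrievalRun, manifest: BenchmarkManifest, size: int | None = None
) -> float:
    """Harmonic mean of precision and recall at a retrieval size.

    Default size is (group size - 1) for the query's group, so a perfect
    retrieval scores 1.0.
    """
    if size is None:
        group = manifest.group_of(run.query_id)
        size = len(manifest.groups[group]) - 1
    precision, recall = _pr_at_size(run, manifest, size)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def nearest_neighbor_accuracy(
    runs: list[RetrievalRun], manifest: BenchmarkManifest
) -> float:
    """Fraction of queries whose top-ranked shape is from their own group."""
    hits = 0
    for run in runs:
        group = manifest.group_of(run.query_id)
        hits += manifest.group_of(run.ranked_ids[0]) == group
    return hits / len(runs)


def plot_pr_curves(curves: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Plot averaged precision-recall curves, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.plot(curve["recall"], curve["precision"], marker="o", ms=3, label=name)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_descriptors(
    descriptors: dict[str, ShapeDescriptor],
    manifest: BenchmarkManifest,
    metric: str = "L1",
) -> dict:
    """All-queries retrieval evaluation of a descriptor database.

    Returns mean nearest-neighbour accuracy, mean F- and E-measures and
    the averaged PR curve, using every shape as a query in turn.
    """
    runs = [
        rank_database(sid, desc, descriptors, metric)
        for sid, desc in descriptors.items()
    ]
    evaluable = [
        r for r in runs if len(manifest.groups[manifest.group_of(r.query_id)]) > 1
    ]
    return {
        "nn_accuracy": nearest_neighbor_accuracy(evaluable, manifest),
        "f_measure": float(np.mean([f_measure(r, manifest) for r in evaluable])),
        "e_measure": float(np.mean([e_measure(r, manifest) for r in evaluable])),
        "pr_curve": average_precision_recall(evaluable, manifest),
        "n_queries": len(evaluable),
    }
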