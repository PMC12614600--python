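"""Cross-modal retrieval evaluation: R@k and median rank per task.

Trained tasks are the two directions between the anchor and each other
modality (2(n-1) of them); emergent tasks are all ordered pairs of
non-anchor modalities ((n-1)(n-2)), which were never co-trained. The
rank of the true counterpart is 1 plus the number of candidates with
strictly greater cosine similarity (optimistic tie rule), so for
independent random embeddings ranks are uniform on 1..N and the median
rank sits at N/2.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

__all__ = ["RetrievalTask", "TaskReport", "RetrievalReport", "enumerate_tasks",
           "rank_of_match", "ranks_of_matches", "recall_at_k", "median_rank",
           "evaluate_alignment"]


@dataclasses.dataclass(frozen=True)
class RetrievalTask:
    query: str
    candidate: str
    trained: bool

    def __post_init__(self) -> None:
        if self.query == self.candidate:
            raise ValueError("query and candidate modality must differ")


@dataclasses.dataclass
class TaskReport:
    task: RetrievalTask
    recalls: dict[int, float]
    median_rank: float
    n: int


@dataclasses.dataclass
class RetrievalReport:
    tasks: list[TaskReport]

    def rows(self) -> list[dict]:
        out = []
        for t in self.tasks:
            row = {"query": t.task.query, "candidate": t.task.candidate,
                   "trained": int(t.task.trained), "MR": t.median_rank,
                   "N": t.n}
            for k, v in t.recalls.items():
                row[f"R@{k}"] = v
            out.append(row)
        return out


def enumerate_tasks(modalities: Sequence[str], anchor: str
                    ) -> list[RetrievalTask]:
    """2(n-1) trained directions plus (n-1)(n-2) emergent directions."""
    if len(set(modalities)) != len(modalities):
        raise ValueError("duplicate modalities")
    if anchor not in modalities:
        raise ValueError("anchor must be among the modalities")
    if len(modalities) < 2:
        raise ValueError("need at least 2 modalities")
    others = [m for m in modalities if m != anchor]
    tasks = []
    for m in others:
        tasks.append(RetrievalTask(anchor, m, trained=True))
        tasks.append(RetrievalTask(m, anchor, trained=True))
    for a in others:
        for b in others:
            if a != b:
                tasks.append(RetrievalTask(a, b, trained=False))
    return tasks


def rank_of_match(query: np.ndarray, candidates: np.ndarray,
                  true_index: int, tol: float = 1e-4) -> int:
    """1 + number of candidates strictly more similar than the true one."""
    query = np.asarray(query, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.ndim != 2 or not 0 <= true_index < len(candidates):
        raise ValueError("invalid candidates or true index")
    if abs(np.linalg.norm(query) - 1.0) > tol or np.any(
            np.abs(np.linalg.norm(candidates, axis=1) - 1.0) > tol):
        raise ValueError("inputs must be unit vectors")
    sims = candidates @ query
    return int(1 + np.sum(sims > sims[true_index]))


def ranks_of_matches(queries: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Vectorized ranks for identity pairing (query i matches candidate i)."""
    sims = np.asarray(queries) @ np.asarray(candidates).T
    true_sims = np.diag(sims)
    return 1 + (sims > true_sims[:, None]).sum(axis=1)


def recall_at_k(ranks: Sequence[int], k: int) -> float:
    ranks = np.asarray(ranks)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    if np.any(ranks < 1):
        raise ValueError("ranks must be >= 1")
    return float(np.mean(ranks <= k))


def median_rank(ranks: Sequence[int]) -> float:
    ranks = np.asarray(ranks)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    return float(np.median(ranks))


def evaluate_alignment(embeddings: Mapping[str, Mapping[str, np.ndarray]],
                       anchor: str = "sequence",
                       ks: Sequence[int] = (1, 10, 100),
                       tasks: Sequence[RetrievalTask] | None = None
                       ) -> RetrievalReport:
    """Evaluate every retrieval task over per-modality id->vector maps.

    For each task, the test set is the ids present in both modalities;
    each query's counterpart is ranked among all candidates.
    """
    if tasks is None:
        tasks = enumerate_tasks(list(embeddings), anchor)
    reports = []
    for task in tasks:
        q_map, c_map = embeddings[task.query], embeddings[task.candidate]
        ids = [i for i in q_map if i in c_map]
        if not ids:
            raise ValueError(f"no shared ids for task "
                             f"{task.query}->{task.candidate}")
        Q = np.stack([q_map[i] for i in ids])
        C = np.stack([c_map[i] for i in ids])
        ranks = ranks_of_matches(Q, C)
        reports.append(TaskReport(
            task=task,
            recalls={k: recall_at_k(ranks, k) for k in ks},
            median_rank=median_rank(ranks),
            n=len(ids)))
    return RetrievalReport(tasks=reports)
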