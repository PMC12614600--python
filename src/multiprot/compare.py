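"""Model-comparison machinery: rank-sum tests, IQR summaries, normalized
performance drops, and the exhaustive modality-ablation runner.

The two-sample Wilcoxon rank-sum test uses average ranks on ties; with a
combined sample of at most 12 values and no ties the null distribution
is enumerated exactly, otherwise a normal approximation with tie and
continuity corrections is used. Quartiles use linear interpolation of
order statistics; the paper-matching outlier column counts values
strictly below Q1 - 1.5*IQR (high-side outliers are reported separately).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclasses.dataclass
class ComparisonResult:
    sample_x: str
    sample_y: str
    task: str | None
    statistic: float
    p_value: float
    alternative: str
    exact: bool


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided",
                      task: str | None = None,
                      names: tuple[str, str] = ("x", "y")) -> ComparisonResult:
    """Two-sample rank-sum test; ``alternative='greater'`` tests x > y."""
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[:nx].sum())  # rank sum of x

    has_ties = len(np.unique(combined)) < combined.size
    exact = (nx + ny <= 12) and not has_ties
    if exact:
        # enumerate all placements of x's ranks among 1..nx+ny
        all_ranks = np.arange(1, nx + ny + 1)
        sums = np.array([sum(c) for c in itertools.combinations(all_ranks, nx)])
        total = sums.size
        if alternative == "greater":
            p = np.count_nonzero(sums >= w) / total
        elif alternative == "less":
            p = np.count_nonzero(sums <= w) / total
        else:
            p_hi = np.count_nonzero(sums >= w) / total
            p_lo = np.count_nonzero(sums <= w) / total
            p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        mean = nx * (nx + ny + 1) / 2.0
        n = nx + ny
        _, counts = np.unique(combined, return_counts=True)
        tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1.0))
        var = nx * ny / 12.0 * ((n + 1.0) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "greater":
                z = (w - mean - 0.5) / sd
                p = 1.0 - _ndtr(z)
            elif alternative == "less":
                z = (w - mean + 0.5) / sd
                p = _ndtr(z)
            else:
                z = (abs(w - mean) - 0.5) / sd
                p = 2.0 * (1.0 - _ndtr(max(z, 0.0)))
                p = min(1.0, p)
    return ComparisonResult(sample_x=names[0], sample_y=names[1], task=task,
                            statistic=w, p_value=float(p),
                            alternative=alternative, exact=exact)


def _ndtr(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IqrSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    iqr: float
    n_low_outliers: int
    n_high_outliers: int


def iqr_summary(values: Sequence[float]) -> IqrSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    low_fence = q1 - 1.5 * iqr
    high_fence = q3 + 1.5 * iqr
    return IqrSummary(minimum=float(v.min()), q1=float(q1), median=float(med),
                      q3=float(q3), maximum=float(v.max()), iqr=float(iqr),
                      n_low_outliers=int(np.sum(v < low_fence)),
                      n_high_outliers=int(np.sum(v > high_fence)))


def normalized_drop(perf_x: float, perf_y: float) -> float:
    """(Perf_y - Perf_x) / Perf_x; negative means y is inferior to x."""
    if perf_x == 0:
        raise ZeroDivisionError("reference performance is zero")
    return (perf_y - perf_x) / perf_x


@dataclasses.dataclass
class DropMatrix:
    models: list[str]
    task: str
    matrix: np.ndarray  # [x, y] = normalized_drop(perf_x, perf_y)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.diag(self.matrix) == 0.0):
            raise ValueError("drop matrix diagonal must be exactly zero")

    def to_rows(self) -> list[dict]:
        rows = []
        for i, x in enumerate(self.models):
            row = {"model": x}
            for j, y in enumerate(self.models):
                row[y] = self.matrix[i, j]
            rows.append(row)
        return rows

    @classmethod
    def from_performances(cls, perfs: Mapping[str, float], task: str
                          ) -> "DropMatrix":
        models = list(perfs)
        m = np.zeros((len(models), len(models)))
        for i, x in enumerate(models):
            for j, y in enumerate(models):
                if i != j:
                    m[i, j] = normalized_drop(perfs[x], perfs[y])
        return cls(models=models, task=task, matrix=m)


# ---------------------------------------------------------------------------
# Ablation orchestration
# ---------------------------------------------------------------------------

def enumerate_ablation_subsets(optional_modalities: Sequence[str],
                               anchor: str = "sequence"
                               ) -> list[tuple[str, ...]]:
    """All 2^m - 1 nonempty optional subsets, each including the anchor."""
    seen: set[tuple[str, ...]] = set()
    unique = []
    for m in optional_modalities:
        if m in unique:
            warnings.warn(f"duplicate modality '{m}' deduplicated")
            continue
        unique.append(m)
    subsets = []
    for r in range(1, len(unique) + 1):
        for combo in itertools.combinations(unique, r):
            key = (anchor,) + combo
            if key not in seen:
                seen.add(key)
                subsets.append(key)
    return subsets


def ablation_run(optional_modalities: Sequence[str],
                 train_and_eval: Callable[[tuple[str, ...], int], Mapping[str, float]],
                 seeds: Sequence[int] = (0,),
                 anchor: str = "sequence") -> dict:
    """Train one model per modality subset and assemble comparison data.

    ``train_and_eval(subset, seed)`` returns task -> performance for one
    trained model. Returns per-subset metric values, one DropMatrix per
    task (built from mean performances), and pairwise one-sided rank-sum
    results across seeds.
    """
    subsets = enumerate_ablation_subsets(optional_modalities, anchor)
    names = ["+".join(s) for s in subsets]
    values: dict[str, dict[str, list[float]]] = {n: {} for n in names}
    for subset, name in zip(subsets, names):
        for seed in seeds:
            perf = train_and_eval(subset, seed)
            for task, v in perf.items():
                values[name].setdefault(task, []).append(float(v))

    tasks = sorted({t for model in values.values() for t in model})
    drop_matrices = {}
    comparisons = []
    for task in tasks:
        means = {n: float(np.mean(values[n][task])) for n in names
                 if task in values[n]}
        drop_matrices[task] = DropMatrix.from_performances(means, task)
        for a in names:
            for b in names:
                if a < b and task in values[a] and task in values[b]:
                    comparisons.append(wilcoxon_rank_sum(
                        values[a][task], values[b][task],
                        alternative="greater", task=task, names=(a, b)))
    return {"subsets": subsets, "models": names, "values": values,
            "drop_matrices": drop_matrices, "comparisons": comparisons}
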