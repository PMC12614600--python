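"""Zero-shot analyses on frozen embeddings.

* Evolutionary relatedness: rank aligned family members by Hamming
  distance to the reference (gaps count as a 21st symbol), take the
  closest / most distant groups plus an unrelated control, and compare
  cosine-similarity distributions; the separation margin is the
  difference of group medians (a minimum-gap variant is available).
* Cavity-pair discrimination: cosine similarities of labeled pairs,
  swept over thresholds into a ROC, summarized by its AUC (computed as
  the normalized U statistic).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .probing import roc_auc
from .synthetic import MSAFamily


@dataclasses.dataclass
class RelatednessGroups:
    reference: str
    similar: list[str]
    divergent: list[str]
    unrelated: list[str]


@dataclasses.dataclass(frozen=True)
class LabeledPair:
    id_a: str
    id_b: str
    similar: bool


def hamming_distance(a: str, b: str) -> int:
    """Column mismatch count; the gap character is its own symbol."""
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y)


def rank_family(family: MSAFamily, n_similar: int = 50, n_divergent: int = 50
                ) -> RelatednessGroups:
    """Split aligned members into closest / most distant groups by
    Hamming distance to the reference; ties keep input order."""
    aligned = family.similar + family.divergent
    if n_similar + n_divergent > len(aligned):
        raise ValueError("not enough aligned members for requested groups")
    distances = [hamming_distance(family.reference, m) for m in aligned]
    order = np.argsort(distances, kind="stable")
    similar = [aligned[i] for i in order[:n_similar]]
    divergent = [aligned[i] for i in order[len(order) - n_divergent:]] \
        if n_divergent else []
    return RelatednessGroups(reference=family.reference, similar=similar,
                             divergent=divergent,
                             unrelated=list(family.unrelated))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


@dataclasses.dataclass
class CosineGroupResult:
    similar: np.ndarray
    divergent: np.ndarray
    unrelated: np.ndarray
    margin: float           # median(divergent) - median(unrelated)
    min_gap_margin: float   # min(divergent) - max(unrelated)


def cosine_groups(embeddings: Mapping[str, np.ndarray],
                  groups: RelatednessGroups,
                  reference_key: str = "reference") -> CosineGroupResult:
    """Cosine similarity of the reference against each group member.

    ``embeddings`` maps keys to vectors; group members are keyed by their
    sequence string, the reference by ``reference_key`` (falling back to
    the reference sequence itself).
    """
    ref_key = reference_key if reference_key in embeddings \
        else groups.reference
    if ref_key not in embeddings:
        raise KeyError("missing reference embedding")
    ref = embeddings[ref_key]

    def sims(members: Sequence[str]) -> np.ndarray:
        missing = [m for m in members if m not in embeddings]
        if missing:
            raise KeyError(f"missing embeddings for {len(missing)} members")
        return np.array([_cosine(ref, embeddings[m]) for m in members])

    sim = sims(groups.similar)
    div = sims(groups.divergent)
    unr = sims(groups.unrelated)
    margin = float(np.median(div) - np.median(unr)) if div.size and unr.size \
        else float("nan")
    min_gap = float(div.min() - unr.max()) if div.size and unr.size \
        else float("nan")
    return CosineGroupResult(similar=sim, divergent=div, unrelated=unr,
                             margin=margin, min_gap_margin=min_gap)


def pair_auc(embeddings: Mapping[str, np.ndarray],
             pairs: Sequence[LabeledPair]) -> float:
    """ROC AUC of cosine similarity separating similar from dissimilar
    pairs."""
    seen = set()
    for p in pairs:
        key = frozenset((p.id_a, p.id_b))
        if key in seen:
            raise ValueError(f"duplicate unordered pair {tuple(key)}")
        seen.add(key)
    sims_pos = [_cosine(embeddings[p.id_a], embeddings[p.id_b])
                for p in pairs if p.similar]
    sims_neg = [_cosine(embeddings[p.id_a], embeddings[p.id_b])
                for p in pairs if not p.similar]
    if not sims_pos or not sims_neg:
        raise ValueError("need at least one similar and one dissimilar pair")
    return roc_auc(sims_pos, sims_neg)
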