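"""Top-k retrieval in the aligned space, input augmentation, the
nearest-neighbor description proxy, and ROUGE-L / BLEU scoring.

Retrieval queries the candidate pool (by default the training split) with a
projected graph embedding and ranks pool entries by cosine similarity,
excluding the query's own ID.  The description "prediction" is a proxy for a
generative model: it returns the best neighbor's description verbatim, so
its ROUGE/BLEU against the query's true description measures how much usable
information the aligned space retrieves.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._util import as_2d, check_unit_rows

__all__ = [
    "RetrievalIndex",
    "RetrievalResult",
    "build_index",
    "retrieve_top_k",
    "augment_description_input",
    "nearest_description_predict",
    "rouge_l",
    "bleu",
]

AUGMENT_HEADER = "Related proteins:"


@dataclass
class RetrievalIndex:
    ids: list[str]
    embeddings: np.ndarray          # (n, d), unit rows
    descriptions: list[str]
    pool_label: str = "train"

    def __len__(self) -> int:
        return len(self.ids)

    def vector(self, protein_id: str) -> np.ndarray:
        return self.embeddings[self.ids.index(protein_id)]

    def description(self, protein_id: str) -> str:
        return self.descriptions[self.ids.index(protein_id)]


@dataclass
class RetrievalResult:
    neighbors: list[tuple[str, float]]   # (protein_id, cosine), descending


def build_index(ids, projected_graph_embeddings, descriptions,
                pool_label: str = "train") -> RetrievalIndex:
    ids = list(ids)
    descriptions = list(descriptions)
    if len(ids) == 0:
        return RetrievalIndex(ids=[], embeddings=np.zeros((0, 0)),
                              descriptions=[], pool_label=pool_label)
    if len(set(ids)) != len(ids):
        raise KeyError("duplicate protein id in index")
    emb = as_2d(projected_graph_embeddings, "embeddings")
    if not (len(ids) == emb.shape[0] == len(descriptions)):
        raise ValueError("ids, embeddings and descriptions must align")
    check_unit_rows(emb, "index embeddings")
    return RetrievalIndex(ids=ids, embeddings=emb.copy(),
                          descriptions=descriptions, pool_label=pool_label)


def retrieve_top_k(index: RetrievalIndex, query_id: str, query_embedding,
                   k: int) -> RetrievalResult:
    """k highest-cosine pool entries, query's own id excluded, ties broken
    by lexicographic id."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(index) == 0 or k == 0:
        return RetrievalResult(neighbors=[])
    q = np.asarray(query_embedding, dtype=float).ravel()
    if q.shape[0] != index.embeddings.shape[1]:
        raise ValueError("query dimension does not match index")
    sims = index.embeddings @ q
    order = sorted(
        (i for i in range(len(index)) if index.ids[i] != query_id),
        key=lambda i: (-sims[i], index.ids[i]),
    )
    top = order[:k]
    return RetrievalResult(neighbors=[(index.ids[i], float(sims[i])) for i in top])


def augment_description_input(query_description: str,
                              result: RetrievalResult,
                              index: RetrievalIndex) -> str:
    """Original description followed by the neighbors' descriptions in rank
    order under a fixed header; unchanged when there are no neighbors."""
    if not result.neighbors:
        return query_description
    parts = [query_description, AUGMENT_HEADER]
    for rank, (pid, _) in enumerate(result.neighbors, 1):
        parts.append(f"[{rank}] {index.description(pid)}")
    return "\n".join(parts)


def nearest_description_predict(index: RetrievalIndex, query_embedding,
                                query_id: str = "") -> str:
    """Rank-1 neighbor's description: the retrieval proxy prediction."""
    if len(index) == 0:
        raise ValueError("empty retrieval index")
    res = retrieve_top_k(index, query_id, query_embedding, k=1)
    if not res.neighbors:
        raise ValueError("no candidates besides the query itself")
    return index.description(res.neighbors[0][0])


# ---------------------------------------------------------------------------
# text-overlap metrics (lowercased whitespace tokenization)


def _tokens(text: str) -> list[str]:
    return text.lower().split()


def _lcs_len(a: list[str], b: list[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, 1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def rouge_l(candidate: str, reference: str) -> float:
    """LCS-based F-measure with equal precision/recall weighting."""
    ref = _tokens(reference)
    if not ref:
        raise ValueError("undefined ROUGE-L score: empty reference")
    cand = _tokens(candidate)
    if not cand:
        return 0.0
    lcs = _lcs_len(cand, ref)
    if lcs == 0:
        return 0.0
    p = lcs / len(cand)
    r = lcs / len(ref)
    return 2 * p * r / (p + r)


def bleu(candidate: str, reference: str, max_n: int = 4,
         smooth_eps: float = 1e-9) -> float:
    """Geometric mean of modified n-gram precisions up to ``max_n`` with a
    brevity penalty; zero-count levels are floored at ``smooth_eps``."""
    ref = _tokens(reference)
    if not ref:
        raise ValueError("undefined BLEU score: empty reference")
    cand = _tokens(candidate)
    if not cand:
        return 0.0
    log_p = 0.0
    for n in range(1, max_n + 1):
        cand_ngrams = Counter(tuple(cand[i:i + n]) for i in range(len(cand) - n + 1))
        ref_ngrams = Counter(tuple(ref[i:i + n]) for i in range(len(ref) - n + 1))
        total = sum(cand_ngrams.values())
        if total == 0:
            log_p += math.log(smooth_eps)
            continue
        clipped = sum(min(c, ref_ngrams[g]) for g, c in cand_ngrams.items())
        log_p += math.log(max(clipped / total, smooth_eps))
    bp = 1.0 if len(cand) >= len(ref) else math.exp(1.0 - len(ref) / len(cand))
    return bp * math.exp(log_p / max_n)
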