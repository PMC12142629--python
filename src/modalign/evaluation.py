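"""Alignment scoring and the stratified / sweep analyses.

The model-pair alignment score F_similarity = F_positive − F_negative, where
F_positive is the mean cosine of the N positive (same-protein) pairs and
F_negative is the mean *absolute* cosine over all M = N(N−1) ordered
cross-protein pairs.  Per-protein scores are raw (unshifted) cosines: unlike
the training loss they can be negative, which is exactly what the
structure-blind-encoder analyses look at.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._util import as_2d
from .alignment import (ProjectionHeadSpec, TrainedPair, TrainingConfig,
                        project, train_projection_heads)
from .synthetic import (EmbeddingDataset, EmbeddingSpec, UniverseConfig,
                        make_dataset)

__all__ = [
    "AlignmentReport",
    "per_protein_alignment",
    "alignment_report",
    "evaluate_pair",
    "model_pair_correlation",
    "classify_rarity",
    "length_trend",
    "stratified_summary",
    "dimension_sweep",
    "depth_sweep",
]


@dataclass(frozen=True)
class AlignmentReport:
    n_proteins: int
    n_negative_pairs: int
    positive_score: float
    negative_score: float
    alignment_score: float
    per_protein_scores: np.ndarray


def per_protein_alignment(graph_proj, text_proj) -> np.ndarray:
    """Cosine of each positive pair (rows assumed unit-normalised)."""
    G = as_2d(graph_proj, "graph_proj")
    T = as_2d(text_proj, "text_proj")
    if G.shape != T.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {T.shape}")
    return (G * T).sum(axis=1)


def alignment_report(graph_proj, text_proj) -> AlignmentReport:
    """F_positive, F_negative and their difference over one projected set."""
    G = as_2d(graph_proj, "graph_proj")
    T = as_2d(text_proj, "text_proj")
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 proteins: negative score undefined")
    S = G @ T.T
    pos = np.diag(S)
    f_pos = float(pos.mean())
    m = n * (n - 1)
    f_neg = float((np.abs(S).sum() - np.abs(pos).sum()) / m)
    return AlignmentReport(
        n_proteins=n,
        n_negative_pairs=m,
        positive_score=f_pos,
        negative_score=f_neg,
        alignment_score=f_pos - f_neg,
        per_protein_scores=pos,
    )


def evaluate_pair(pair: TrainedPair, dataset: EmbeddingDataset,
                  split: str = "test") -> AlignmentReport:
    """Project one split through a trained pair and score it."""
    idx = dataset.rows(split) if split else np.arange(dataset.n)
    G = project(pair.graph_head, dataset.graph_embeddings[idx])
    T = project(pair.text_head, dataset.text_embeddings[idx])
    return alignment_report(G, T)


def model_pair_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every pair of model-pair score columns."""
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 proteins and >= 2 model pairs")
    for col in table.columns:
        if np.isclose(table[col].std(ddof=0), 0.0):
            raise ValueError(f"undefined correlation: column {col!r} has zero variance")
    return table.corr(method="pearson")


def classify_rarity(table: pd.DataFrame, popular_min: int = 5,
                    rare_max: int = 1) -> pd.Series:
    """Label entries popular/rare/intermediate by the frequency of their
    (molecule, organism) class.  Thresholds are artifact choices; the
    underlying studies hand-picked examples without stating cutoffs."""
    if popular_min <= rare_max:
        raise ValueError("popular_min must exceed rare_max")
    counts = table["popularity_count"]
    labels = np.where(counts >= popular_min, "popular",
                      np.where(counts <= rare_max, "rare", "intermediate"))
    return pd.Series(labels, index=table.index, name="rarity")


def length_trend(scores, lengths) -> dict:
    """OLS fit of alignment score on sequence length: {slope, intercept, r}."""
    s = np.asarray(scores, dtype=float)
    x = np.asarray(lengths, dtype=float)
    if s.shape != x.shape or len(s) < 3:
        raise ValueError("need matching score/length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: lengths are constant")
    fit = stats.linregress(x, s)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue)}


def stratified_summary(scores, labels) -> pd.DataFrame:
    """Per-group count / mean / median / IQR of alignment scores."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if len(s) != len(lab):
        raise ValueError("scores and labels must have equal length")
    if len(s) == 0:
        raise ValueError("empty input")
    df = pd.DataFrame({"score": s, "group": lab})
    out = df.groupby("group")["score"].agg(
        count="size", mean="mean", median="median",
        iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
    )
    out["scores"] = df.groupby("group")["score"].apply(list)
    return out


def _default_specs(d_g: int, d_t: int, graph_layers: int = 1
                   ) -> tuple[ProjectionHeadSpec, ProjectionHeadSpec]:
    hidden = tuple([d_t] * (graph_layers - 1))
    return (ProjectionHeadSpec(d_g, d_t, graph_layers, hidden),
            ProjectionHeadSpec(d_t, d_t, 1))


def dimension_sweep(
    dims: list[int],
    universe: UniverseConfig,
    spec_base: EmbeddingSpec,
    train_cfg: TrainingConfig = TrainingConfig(),
) -> pd.DataFrame:
    """Regenerate the graph channel at each dimension (latents fixed by the
    shared seed), train heads, and record the test F_similarity."""
    if not dims or min(dims) < 1:
        raise ValueError("dims must be a non-empty list of dimensions >= 1")
    rows = []
    for d in dims:
        spec = replace(spec_base, graph_dim=int(d))
        try:
            ds = make_dataset(universe, spec)
            gs, ts = _default_specs(spec.graph_dim, spec.text_dim)
            pair = train_projection_heads(ds, gs, ts, train_cfg)
            rep = evaluate_pair(pair, ds, "test")
            rows.append({"graph_dim": d, "f_similarity": rep.alignment_score,
                         "f_positive": rep.positive_score,
                         "f_negative": rep.negative_score, "error": ""})
        except Exception as exc:   # record and continue the sweep
            rows.append({"graph_dim": d, "f_similarity": np.nan,
                         "f_positive": np.nan, "f_negative": np.nan,
                         "error": str(exc)})
    return pd.DataFrame(rows)


def depth_sweep(
    depths: list[int],
    dataset: EmbeddingDataset,
    train_cfg: TrainingConfig = TrainingConfig(),
) -> pd.DataFrame:
    """Vary the graph-side head depth (text side fixed at one layer)."""
    if any(d not in (1, 2, 3) for d in depths):
        raise ValueError("depths must be a subset of {1, 2, 3}")
    d_g = dataset.graph_embeddings.shape[1]
    d_t = dataset.text_embeddings.shape[1]
    rows = []
    for depth in depths:
        gs, ts = _default_specs(d_g, d_t, graph_layers=depth)
        pair = train_projection_heads(dataset, gs, ts, train_cfg)
        rep = evaluate_pair(pair, dataset, "test")
        rows.append({"depth": depth, "f_similarity": rep.alignment_score,
                     "f_positive": rep.positive_score,
                     "f_negative": rep.negative_score})
    return pd.DataFrame(rows)
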