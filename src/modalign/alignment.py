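"""Projection heads, the shifted-cosine InfoNCE objective, its rarity-
reweighted variant, the multi-task binary cross-entropy objective, and the
training loops.

The contrastive setup: two projection heads — one per modality — map encoder
embeddings into a shared space of the text-side dimension and unit-normalise
the output.  Training maximises the shifted cosine (cos+1)/2 of positive
pairs against in-batch negatives under a temperature-scaled softmax
(InfoNCE).  Note the asymmetry kept on purpose throughout the package: the
*loss* sees shifted similarities of in-batch negatives only, while the
evaluation metric averages raw cosines over all test-set pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._util import as_2d, substream
from .nn import MLP, Adam
from .synthetic import EmbeddingDataset, MultiLabelDataset

__all__ = [
    "ProjectionHeadSpec",
    "TrainingConfig",
    "ProjectionHead",
    "TrainedPair",
    "SampleWeights",
    "shifted_cosine",
    "project",
    "infonce_batch_loss",
    "reweighted_batch_loss",
    "default_rarity_weights",
    "multitask_bce_loss",
    "initialize_pair",
    "train_projection_heads",
    "MultitaskEncoder",
    "train_multitask_encoder",
]


@dataclass(frozen=True)
class ProjectionHeadSpec:
    """Architecture of one projection head: 1–3 linear layers with ReLU
    between them, output unit-normalised into the shared space."""

    input_dim: int
    output_dim: int
    n_layers: int = 1
    hidden_dims: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be in {1, 2, 3}")
        if len(self.hidden_dims) != self.n_layers - 1:
            raise ValueError("hidden_dims must have n_layers - 1 entries")
        if min(self.input_dim, self.output_dim, *(self.hidden_dims or (1,))) < 1:
            raise ValueError("all dimensions must be >= 1")

    @property
    def dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_dims, self.output_dim]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 40
    learning_rate: float = 1e-3
    batch_size: int = 32
    temperature: float = 0.2
    seed: int = 42
    checkpoint_on_validation: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


class ProjectionHead:
    """A spec plus its (possibly trained) parameters."""

    def __init__(self, spec: ProjectionHeadSpec, rng: np.random.Generator):
        self.spec = spec
        self.mlp = MLP(spec.dims, rng)

    def copy(self) -> "ProjectionHead":
        out = ProjectionHead.__new__(ProjectionHead)
        out.spec = self.spec
        out.mlp = self.mlp.copy()
        return out


@dataclass
class TrainedPair:
    graph_head: ProjectionHead
    text_head: ProjectionHead
    history: pd.DataFrame          # columns: epoch, train_loss, val_loss
    best_epoch: int = 0


@dataclass
class SampleWeights:
    """Per-protein positive weights, rescaled to mean 1 on construction."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if len(vals) == 0 or np.any(vals <= 0):
            raise ValueError("weights must be a non-empty map of positive values")
        mean = vals.mean()
        self.weights = {k: float(v / mean) for k, v in self.weights.items()}

    def for_ids(self, ids: list[str]) -> np.ndarray:
        try:
            return np.array([self.weights[i] for i in ids], dtype=float)
        except KeyError as exc:
            raise KeyError(f"no weight for protein id {exc.args[0]!r}") from exc


def shifted_cosine(u, v) -> float:
    """Cosine similarity mapped to [0, 1] via (cos + 1) / 2."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("shifted cosine undefined for a zero vector")
    return float((u @ v / (nu * nv) + 1.0) / 2.0)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=-1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("degenerate projection: zero-norm output")
    return X / norms


def project(head: ProjectionHead, embedding) -> np.ndarray:
    """Map embeddings through the head and unit-normalise the output."""
    X = np.asarray(embedding, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != head.spec.input_dim:
        raise ValueError(
            f"embedding dim {X.shape[1]} != head input dim {head.spec.input_dim}")
    out = _normalize_rows(head.mlp(X))
    return out[0] if single else out


def _shifted_sim_matrix(G: np.ndarray, T: np.ndarray) -> np.ndarray:
    return (G @ T.T + 1.0) / 2.0


def _per_anchor_losses(G: np.ndarray, T: np.ndarray, tau: float) -> np.ndarray:
    S = _shifted_sim_matrix(G, T) / tau
    m = S.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(S - m).sum(axis=1))
    return lse - np.diag(S)


def infonce_batch_loss(graph_proj, text_proj, tau: float = 0.2) -> float:
    """Modified InfoNCE over one batch of unit-normalised projections.

    L = (1/B) Σ_i −log[ exp(s_ii/τ) / Σ_j exp(s_ij/τ) ] with s the shifted
    cosine; negatives are the other in-batch pairs only.
    """
    G = as_2d(graph_proj, "graph_proj")
    T = as_2d(text_proj, "text_proj")
    if G.shape[0] != T.shape[0]:
        raise ValueError("batch sizes differ between modalities")
    if G.shape[0] == 0:
        raise ValueError("empty batch")
    if not (np.isfinite(G).all() and np.isfinite(T).all()):
        raise ValueError("non-finite projections")
    return float(_per_anchor_losses(G, T, tau).mean())


def reweighted_batch_loss(graph_proj, text_proj, tau: float,
                          weights: np.ndarray) -> float:
    """Weighted-mean InfoNCE: Σ_i w_i ℓ_i / Σ_i w_i."""
    G = as_2d(graph_proj, "graph_proj")
    T = as_2d(text_proj, "text_proj")
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != G.shape[0]:
        raise ValueError("one weight per anchor required")
    losses = _per_anchor_losses(G, T, tau)
    return float((w * losses).sum() / w.sum())


def default_rarity_weights(table: pd.DataFrame, exponent: float = 1.0) -> SampleWeights:
    """w_i ∝ popularity_count_i^(−exponent), rescaled to mean 1.

    Upweights entries of rarely-documented (molecule, organism) classes so
    their contrastive errors carry higher penalty during training.
    """
    counts = table["popularity_count"].to_numpy(dtype=float)
    if np.any(counts < 1):
        raise ValueError("popularity_count must be >= 1")
    raw = counts ** (-float(exponent))
    return SampleWeights(dict(zip(table["protein_id"], raw)))


def multitask_bce_loss(pred, labels, eps: float = 1e-7) -> float:
    """Binary cross-entropy summed over tasks, averaged over samples."""
    P = np.clip(as_2d(pred, "pred"), eps, 1.0 - eps)
    Y = as_2d(labels, "labels")
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: pred {P.shape} vs labels {Y.shape}")
    return float(-(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# training


def initialize_pair(graph_spec: ProjectionHeadSpec, text_spec: ProjectionHeadSpec,
                    seed: int = 42) -> TrainedPair:
    """Randomly initialised heads with no optimizer step: the untrained
    baseline against which trained alignment is compared."""
    if graph_spec.output_dim != text_spec.output_dim:
        raise ValueError("graph and text heads must share output_dim")
    rng = substream(seed, "init")
    return TrainedPair(
        graph_head=ProjectionHead(graph_spec, rng),
        text_head=ProjectionHead(text_spec, rng),
        history=pd.DataFrame(columns=["epoch", "train_loss", "val_loss"]),
        best_epoch=0,
    )


def _loss_and_grads(gh: ProjectionHead, th: ProjectionHead,
                    Gb: np.ndarray, Tb: np.ndarray, tau: float,
                    w: Optional[np.ndarray]):
    """Forward + analytic backward for one batch.  Returns (loss, grads)."""
    g_raw, g_cache = gh.mlp.forward(Gb)
    t_raw, t_cache = th.mlp.forward(Tb)
    g_norm = np.linalg.norm(g_raw, axis=1, keepdims=True)
    t_norm = np.linalg.norm(t_raw, axis=1, keepdims=True)
    G = g_raw / g_norm
    T = t_raw / t_norm

    B = G.shape[0]
    S = _shifted_sim_matrix(G, T) / tau
    m = S.max(axis=1, keepdims=True)
    E = np.exp(S - m)
    P = E / E.sum(axis=1, keepdims=True)
    losses = (m[:, 0] + np.log(E.sum(axis=1))) - np.diag(S)

    if w is None:
        coef = np.full(B, 1.0 / B)
        loss = float(losses.mean())
    else:
        coef = w / w.sum()
        loss = float((coef * losses).sum())

    dS = coef[:, None] * (P - np.eye(B)) / (2.0 * tau)   # 1/2 from the shift
    dG = dS @ T
    dT = dS.T @ G
    # back through row normalisation: d(x/|x|) pullback
    dg_raw = (dG - (dG * G).sum(axis=1, keepdims=True) * G) / g_norm
    dt_raw = (dT - (dT * T).sum(axis=1, keepdims=True) * T) / t_norm
    grads = gh.mlp.backward(g_cache, dg_raw) + th.mlp.backward(t_cache, dt_raw)
    return loss, grads


def _eval_loss(gh: ProjectionHead, th: ProjectionHead, G: np.ndarray,
               T: np.ndarray, tau: float, batch_size: int) -> float:
    """Mean per-anchor InfoNCE over fixed-order batches of the given split."""
    n = G.shape[0]
    total = 0.0
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        gp = _normalize_rows(gh.mlp(G[sl]))
        tp = _normalize_rows(th.mlp(T[sl]))
        total += _per_anchor_losses(gp, tp, tau).sum()
    return total / n


def train_projection_heads(
    dataset: EmbeddingDataset,
    graph_spec: ProjectionHeadSpec,
    text_spec: ProjectionHeadSpec,
    config: TrainingConfig = TrainingConfig(),
    weights: Optional[SampleWeights] = None,
) -> TrainedPair:
    """Jointly train both heads on the training split with Adam.

    Validation loss is computed each epoch; with checkpointing enabled the
    returned parameters are those of the last epoch where the validation
    loss decreased (strictly), earlier epoch kept on ties.
    """
    if graph_spec.output_dim != text_spec.output_dim:
        raise ValueError("graph and text heads must share output_dim")
    tr = dataset.rows("train")
    va = dataset.rows("val")
    Gtr, Ttr = dataset.graph_embeddings[tr], dataset.text_embeddings[tr]
    Gva, Tva = dataset.graph_embeddings[va], dataset.text_embeddings[va]
    ids_tr = [dataset.protein_ids[i] for i in tr]

    if Gtr.shape[1] != graph_spec.input_dim or Ttr.shape[1] != text_spec.input_dim:
        raise ValueError("head input dims do not match dataset dims")

    pair = initialize_pair(graph_spec, text_spec, seed=config.seed)
    gh, th = pair.graph_head, pair.text_head
    params = gh.mlp.params() + th.mlp.params()
    opt = Adam(params, lr=config.learning_rate)
    shuffle_rng = substream(config.seed, "shuffle")

    w_tr = None
    if weights is not None:
        w_tr = weights.for_ids(ids_tr)
        w_tr = w_tr / w_tr.mean()      # mean 1 over the training split

    n_tr = len(tr)
    B = config.batch_size
    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = 0
    rows = []
    for epoch in range(1, config.epochs + 1):
        perm = shuffle_rng.permutation(n_tr)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n_tr, B):
            idx = perm[start:start + B]
            wb = None if w_tr is None else w_tr[idx]
            loss, grads = _loss_and_grads(gh, th, Gtr[idx], Ttr[idx],
                                          config.temperature, wb)
            opt.step(params, grads)          # in-place on the model arrays
            ep_loss += loss
            n_batches += 1
        val_loss = (_eval_loss(gh, th, Gva, Tva, config.temperature, B)
                    if len(va) else np.nan)
        rows.append({"epoch": epoch, "train_loss": ep_loss / n_batches,
                     "val_loss": val_loss})
        track = val_loss if len(va) else rows[-1]["train_loss"]
        if not config.checkpoint_on_validation or track < best_val:
            best_val = track if np.isfinite(track) else best_val
            best_params = [p.copy() for p in gh.mlp.params() + th.mlp.params()]
            best_epoch = epoch

    gh.mlp.set_params(best_params[:gh.mlp.n_layers * 2])
    th.mlp.set_params(best_params[gh.mlp.n_layers * 2:])
    pair.history = pd.DataFrame(rows)
    pair.best_epoch = best_epoch
    return pair


# ---------------------------------------------------------------------------
# multi-task function prediction (the dimension-sweep pretraining objective)


class MultitaskEncoder:
    """feature → ReLU(linear) representation of ``output_dim`` → k sigmoid
    task heads, trained under the summed binary cross-entropy."""

    def __init__(self, p: int, output_dim: int, k: int, rng: np.random.Generator):
        self.body = MLP([p, output_dim], rng)
        self.head = MLP([output_dim, k], rng)
        self.output_dim = output_dim

    def representation(self, X) -> np.ndarray:
        return np.maximum(self.body(np.asarray(X, dtype=float)), 0.0)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.head(self.representation(X))
        return 1.0 / (1.0 + np.exp(-logits))


def train_multitask_encoder(
    data: MultiLabelDataset,
    output_dim: int,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[MultitaskEncoder, pd.DataFrame]:
    """Train the small encoder on the multi-label task; returns the model and
    its per-epoch training-loss history."""
    if output_dim < 1:
        raise ValueError("output_dim must be >= 1")
    X = data.features
    Y = data.labels.astype(float)
    n, p = X.shape
    enc = MultitaskEncoder(p, output_dim, data.task_count,
                           substream(config.seed, "init"))
    params = enc.body.params() + enc.head.params()
    opt = Adam(params, lr=config.learning_rate)
    shuffle_rng = substream(config.seed, "shuffle")
    B = config.batch_size
    rows = []
    for epoch in range(1, config.epochs + 1):
        perm = shuffle_rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, B):
            idx = perm[start:start + B]
            h_raw, b_cache = enc.body.forward(X[idx])
            h = np.maximum(h_raw, 0.0)
            logits, h_cache = enc.head.forward(h)
            prob = 1.0 / (1.0 + np.exp(-logits))
            ep_loss += multitask_bce_loss(prob, Y[idx])
            nb += 1
            dlogits = (prob - Y[idx]) / len(idx)
            g_head = enc.head.backward(h_cache, dlogits)
            dh = dlogits @ enc.head.W[0].T
            g_body = enc.body.backward(b_cache, dh * (h_raw > 0.0))
            opt.step(params, g_body + g_head)
        rows.append({"epoch": epoch, "train_loss": ep_loss / nb})
    return enc, pd.DataFrame(rows)
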