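"""Synthetic protein universes and paired two-modality embeddings.

The generator emulates the statistical structure that cross-modal protein
alignment studies presuppose, without downloading anything:

* a catalogue of base proteins whose (molecule name, organism) class recurs
  under several distinct PDB-style IDs when the protein is popular, and occurs
  exactly once when it is rare;
* a shared latent signal behind both modalities, mixed with a homology-cluster
  centroid so that "negative" pairs of related proteins are correlated rather
  than orthogonal;
* a text channel that is a (noisy) linear image of the latent, and a graph
  channel that blends a latent image with structure-blind noise — the blend
  fraction emulates how much 3-D geometry an encoder actually captures;
* inflated measurement noise on rare entries, emulating their poorer
  documentation;
* FASTA/PDB text fixtures and a multi-label function dataset for the
  downstream stages.

Every generator is a pure function of its inputs and a seed; the master seed
spawns an independent substream per operation so adding one operation never
perturbs another's randomness.  Ground-truth latents and linear maps are kept
on the dataset so tests can recompute residuals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._util import substream

__all__ = [
    "UniverseConfig",
    "EmbeddingSpec",
    "EmbeddingDataset",
    "MultiLabelDataset",
    "generate_protein_universe",
    "generate_embedding_pairs",
    "split_dataset",
    "make_dataset",
    "generate_fasta_fixture",
    "generate_pdb_fixture",
    "generate_multilabel_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Word pools for synthetic (molecule, organism) classes.  They include the
# field's canonical popular/rare worked examples so fixtures read naturally.
_MOLECULE_STEMS = [
    "carbonic anhydrase", "spectinomycin phosphotransferase", "lysozyme",
    "RNA polymerase II", "hemoglobin subunit", "myoglobin", "ubiquitin ligase",
    "serine protease", "alcohol dehydrogenase", "triosephosphate isomerase",
    "cytochrome c oxidase", "DNA gyrase", "glutamine synthetase",
    "beta-lactamase", "ferredoxin reductase", "pyruvate kinase",
    "aspartate transaminase", "chorismate mutase", "enolase", "thioredoxin",
]
_MOLECULE_MODS = [
    "", "putative ", "mitochondrial ", "chloroplastic ", "periplasmic ",
    "thermostable ", "zinc-dependent ", "NADP-dependent ", "membrane-bound ",
    "truncated ",
]
_ORGANISMS = [
    "Homo sapiens", "Legionella pneumophila", "Escherichia coli",
    "Saccharomyces cerevisiae", "Mus musculus", "Thermus thermophilus",
    "Bacillus subtilis", "Drosophila melanogaster", "Arabidopsis thaliana",
    "Pyrococcus furiosus", "Mycobacterium tuberculosis", "Gallus gallus",
    "Rattus norvegicus", "Pseudomonas aeruginosa", "Danio rerio",
]

_ID_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


@dataclass(frozen=True)
class UniverseConfig:
    """Generative settings for one synthetic protein universe.

    ``popularity_law`` is a (name, shape) pair; only a truncated Zipf law is
    implemented: the number of database entries per base protein is drawn
    with P(k) ∝ k^(−shape) on 1..max_duplicates, so most base proteins occur
    once (rare) and a heavy tail recurs under several IDs (popular).
    ``homology_mixing`` is the fraction ρ of each latent drawn from its
    homology-cluster centroid rather than an independent draw.
    """

    # Studied clusters average ~2.26 entries per base under Zipf(1.2, max 6),
    # understudied clusters exactly 1; at half each, 307 base proteins give
    # ≈500 database entries, the dataset size the analyses assume.
    n_base_proteins: int = 307
    popularity_law: tuple[str, float] = ("zipf", 1.2)
    max_duplicates: int = 6
    homology_cluster_count: int = 10
    homology_mixing: float = 0.6
    rare_noise_inflation: float = 2.0
    length_range: tuple[int, int] = (50, 500)
    multi_chain_fraction: float = 0.3
    master_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_base_proteins < 2:
            raise ValueError("invalid config: n_base_proteins must be >= 2")
        if not 0.0 <= self.homology_mixing <= 1.0:
            raise ValueError("invalid config: homology_mixing must be in [0, 1]")
        if self.rare_noise_inflation < 1.0:
            raise ValueError("invalid config: rare_noise_inflation must be >= 1")
        if self.max_duplicates < 1:
            raise ValueError("invalid config: max_duplicates must be >= 1")
        if self.popularity_law[0] != "zipf":
            raise ValueError(f"unknown popularity law {self.popularity_law[0]!r}")
        if not 0.0 <= self.multi_chain_fraction <= 1.0:
            raise ValueError("invalid config: multi_chain_fraction must be in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid config: length_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class EmbeddingSpec:
    """Shapes and signal structure of one paired-embedding draw.

    ``graph_signal_fraction`` blends the latent image into the graph channel:
    0 emulates a structure-blind encoder whose output carries no shared
    signal, values near 1 emulate geometry-aware encoders.  With
    ``nonlinear_link`` the graph-side latent image passes through an elementwise
    magnitude (absolute value), so no single linear layer can align it to
    the (linear) text channel while a deeper head can.
    """

    latent_dim: int = 16
    graph_dim: int = 64
    text_dim: int = 96
    graph_signal_fraction: float = 0.9
    noise_sd: float = 0.05
    nonlinear_link: bool = False

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.graph_dim, self.text_dim) < 1:
            raise ValueError("invalid spec: all dimensions must be >= 1")
        if not 0.0 <= self.graph_signal_fraction <= 1.0:
            raise ValueError("invalid spec: graph_signal_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("invalid spec: noise_sd must be >= 0")


@dataclass
class EmbeddingDataset:
    """Paired modality matrices aligned row-for-row with protein metadata."""

    protein_ids: list[str]
    graph_embeddings: np.ndarray          # (n, d_g)
    text_embeddings: np.ndarray           # (n, d_t)
    metadata: pd.DataFrame                # one row per protein_id, same order
    split_labels: Optional[np.ndarray] = None   # "train"/"val"/"test"
    ground_truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.protein_ids)

    def rows(self, split: str) -> np.ndarray:
        if self.split_labels is None:
            raise ValueError("dataset has no split labels; call split_dataset first")
        return np.flatnonzero(self.split_labels == split)

    def subset(self, idx: np.ndarray) -> "EmbeddingDataset":
        return EmbeddingDataset(
            protein_ids=[self.protein_ids[i] for i in idx],
            graph_embeddings=self.graph_embeddings[idx],
            text_embeddings=self.text_embeddings[idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            split_labels=None if self.split_labels is None else self.split_labels[idx],
            ground_truth=self.ground_truth,
        )


@dataclass
class MultiLabelDataset:
    features: np.ndarray   # (n, p)
    labels: np.ndarray     # (n, k) in {0, 1}
    task_count: int


def _truncated_zipf_counts(rng: np.random.Generator, n: int, shape: float,
                           kmax: int) -> np.ndarray:
    ks = np.arange(1, kmax + 1)
    p = ks.astype(float) ** (-shape)
    p /= p.sum()
    return rng.choice(ks, size=n, p=p)


def _unique_ids(rng: np.random.Generator, n: int) -> list[str]:
    ids: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        pid = "".join(rng.choice(list(_ID_ALPHABET), size=4))
        if pid[0].isdigit() and pid not in ids:   # PDB-style: leading digit
            ids.add(pid)
            out.append(pid)
    return out


def generate_protein_universe(config: UniverseConfig) -> pd.DataFrame:
    """Emit the protein table: one row per database entry (protein ID).

    Popular base proteins are expanded into several entries sharing
    ``base_protein_key`` and near-identical metadata; rare (molecule,
    organism) classes occur exactly once.  ``popularity_count`` is the actual
    frequency of the (molecule_name, organism) class within the table.
    """
    rng = substream(config.master_seed, "universe")
    nb = config.n_base_proteins

    # unique (molecule, organism) class per base protein
    n_mol = len(_MOLECULE_STEMS) * len(_MOLECULE_MODS)
    grid = n_mol * len(_ORGANISMS)
    if nb > grid:
        raise ValueError(f"invalid config: at most {grid} base proteins supported")
    cells = rng.choice(grid, size=nb, replace=False)
    molecules = [
        _MOLECULE_MODS[(c // len(_ORGANISMS)) // len(_MOLECULE_STEMS)]
        + _MOLECULE_STEMS[(c // len(_ORGANISMS)) % len(_MOLECULE_STEMS)]
        for c in cells
    ]
    organisms = [_ORGANISMS[c % len(_ORGANISMS)] for c in cells]

    clusters = rng.integers(0, config.homology_cluster_count, size=nb)
    # Documentation imbalance is family-structured: half the homology
    # clusters are "understudied" and never accumulate duplicate entries,
    # so rare proteins concentrate in specific latent regions rather than
    # being uniformly scattered noise.
    nc = config.homology_cluster_count
    understudied = np.zeros(nc, dtype=bool)
    understudied[rng.permutation(nc)[: nc // 2]] = True
    shape = config.popularity_law[1]
    dup_counts = (_truncated_zipf_counts(rng, nb, shape, config.max_duplicates)
                  if config.max_duplicates > 1 else np.ones(nb, dtype=int))
    dup_counts = np.where(understudied[clusters], 1, dup_counts)
    lo, hi = config.length_range
    base_lengths = rng.integers(lo, hi + 1, size=nb)
    base_chains = np.where(rng.random(nb) < config.multi_chain_fraction,
                           rng.integers(2, 5, size=nb), 1)

    n_rows = int(dup_counts.sum())
    ids = _unique_ids(rng, n_rows)
    rows = []
    r = 0
    for b in range(nb):
        for _ in range(int(dup_counts[b])):
            # duplicates: same class/chains, slightly jittered length
            length = int(np.clip(base_lengths[b] + rng.integers(-2, 3), lo, hi))
            rows.append({
                "protein_id": ids[r],
                "base_protein_key": f"base{b:04d}",
                "molecule_name": molecules[b],
                "organism": organisms[b],
                "sequence_length": length,
                "chain_count": int(base_chains[b]),
                "homology_cluster": int(clusters[b]),
            })
            r += 1
    table = pd.DataFrame(rows)
    counts = table.groupby(["molecule_name", "organism"])["protein_id"].transform("size")
    table["popularity_count"] = counts.astype(int)
    return table


def generate_embedding_pairs(
    table: pd.DataFrame,
    spec: EmbeddingSpec,
    seed: int,
    homology_mixing: float = 0.6,
    rare_noise_inflation: float = 2.0,
) -> EmbeddingDataset:
    """Draw paired graph/text embeddings over a shared latent.

    Per base protein b: latent z_b = (1−ρ)·u_b + ρ·c_cluster(b), with u_b and
    cluster centroids standard normal.  Duplicate entries share z_b up to a
    small jitter.  Then

        text_i  = T z_i + ε_i,                    ε_i ~ N(0, σ_i²)
        graph_i = f·link(G z_i) + (1−f)·η_i + ε'_i,  η_i ~ N(0, 1)

    where f is ``graph_signal_fraction``, link is identity or an elementwise
    magnitude, and σ_i = noise_sd × rare_noise_inflation for entries whose
    (molecule, organism) class occurs exactly once.
    """
    if table.empty:
        raise ValueError("protein table is empty")
    n = len(table)
    rho = float(homology_mixing)

    latent_rng = substream(seed, "latent")
    base_keys = table["base_protein_key"].tolist()
    uniq_bases = list(dict.fromkeys(base_keys))          # stable order
    u = latent_rng.standard_normal((len(uniq_bases), spec.latent_dim))
    n_clusters = int(table["homology_cluster"].max()) + 1
    centroids = latent_rng.standard_normal((n_clusters, spec.latent_dim))
    base_cluster = table.drop_duplicates("base_protein_key").set_index(
        "base_protein_key")["homology_cluster"]
    z_base = {
        bk: (1.0 - rho) * u[i] + rho * centroids[int(base_cluster[bk])]
        for i, bk in enumerate(uniq_bases)
    }
    jitter = substream(seed, "jitter").standard_normal((n, spec.latent_dim)) * 0.05
    z = np.stack([z_base[bk] for bk in base_keys]) + jitter

    t_map = substream(seed, "text_map").standard_normal(
        (spec.latent_dim, spec.text_dim)) / np.sqrt(spec.latent_dim)
    g_map = substream(seed, "graph_map").standard_normal(
        (spec.latent_dim, spec.graph_dim)) / np.sqrt(spec.latent_dim)

    infl = np.where(table["popularity_count"].to_numpy() == 1,
                    float(rare_noise_inflation), 1.0)
    sd = spec.noise_sd * infl[:, None]

    t_noise_rng = substream(seed, "text_noise")
    g_noise_rng = substream(seed, "graph_noise")
    text = z @ t_map + t_noise_rng.standard_normal((n, spec.text_dim)) * sd

    signal = z @ g_map
    if spec.nonlinear_link:
        # magnitude link: |a·z| carries (almost) no globally linear signal,
        # but latents concentrate near cluster centroids, so the inverse is
        # locally linear per cluster — expressible by a depth-2 ReLU head,
        # not by a single linear layer.
        signal = np.abs(signal)
    f = spec.graph_signal_fraction
    blind = g_noise_rng.standard_normal((n, spec.graph_dim))
    meas = g_noise_rng.standard_normal((n, spec.graph_dim)) * sd
    graph = f * signal + (1.0 - f) * blind + meas

    return EmbeddingDataset(
        protein_ids=table["protein_id"].tolist(),
        graph_embeddings=graph,
        text_embeddings=text,
        metadata=table.reset_index(drop=True),
        ground_truth={
            "latents": z, "text_map": t_map, "graph_map": g_map,
            "noise_sd_per_row": sd[:, 0], "spec": spec,
            "homology_mixing": rho,
        },
    )


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainder
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def split_dataset(
    dataset: EmbeddingDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 42,
    group_by_base: bool = False,
) -> EmbeddingDataset:
    """Assign train/val/test labels (80/10/10 by default).

    With ``group_by_base`` every duplicate of a base protein lands in one
    split.  The default keeps duplicates independent, as a database snapshot
    split at the entry level would — popular proteins are then seen during
    training under other IDs, which is exactly the documentation-imbalance
    effect the rarity analyses measure.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("invalid fractions: must sum to 1")
    rng = substream(seed, "split")
    n = dataset.n
    labels = np.empty(n, dtype=object)
    names = ("train", "val", "test")
    targets = _split_counts(n, tuple(fractions))

    if not group_by_base:
        perm = rng.permutation(n)
        start = 0
        for name, cnt in zip(names, targets):
            labels[perm[start:start + cnt]] = name
            start += cnt
    else:
        keys = dataset.metadata["base_protein_key"].to_numpy()
        uniq = list(dict.fromkeys(keys))
        order = rng.permutation(len(uniq))
        filled = [0, 0, 0]
        for gi in order:
            members = np.flatnonzero(keys == uniq[gi])
            deficits = [targets[s] - filled[s] for s in range(3)]
            s = int(np.argmax(deficits))
            labels[members] = names[s]
            filled[s] += len(members)

    out = replace_splits(dataset, labels)
    return out


def replace_splits(dataset: EmbeddingDataset, labels: np.ndarray) -> EmbeddingDataset:
    return EmbeddingDataset(
        protein_ids=dataset.protein_ids,
        graph_embeddings=dataset.graph_embeddings,
        text_embeddings=dataset.text_embeddings,
        metadata=dataset.metadata,
        split_labels=np.asarray(labels, dtype=object),
        ground_truth=dataset.ground_truth,
    )


def make_dataset(
    universe: UniverseConfig,
    spec: EmbeddingSpec,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    group_by_base: bool = False,
) -> EmbeddingDataset:
    """Universe → paired embeddings → split, all from the master seed."""
    table = generate_protein_universe(universe)
    ds = generate_embedding_pairs(
        table, spec, universe.master_seed,
        homology_mixing=universe.homology_mixing,
        rare_noise_inflation=universe.rare_noise_inflation,
    )
    return split_dataset(ds, fractions, seed=universe.master_seed,
                         group_by_base=group_by_base)


# ---------------------------------------------------------------------------
# text-format fixtures


def _chain_ids(k: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(k)]


def _chain_lengths(total: int, k: int) -> list[int]:
    base = total // k
    lens = [base] * k
    lens[0] += total - base * k
    return lens


def generate_fasta_fixture(table: pd.DataFrame, seed: int) -> str:
    """Render the table as RCSB-dialect FASTA, one entity record per chain.

    Header: ``>ID_entity|Chain X|molecule|organism``; the summed per-chain
    sequence lengths equal the recorded sequence_length.
    """
    if table.empty:
        raise ValueError("protein table is empty")
    rng = substream(seed, "fasta")
    out = []
    for row in table.itertuples(index=False):
        lens = _chain_lengths(int(row.sequence_length), int(row.chain_count))
        for e, (cid, ln) in enumerate(zip(_chain_ids(int(row.chain_count)), lens), 1):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=ln))
            out.append(f">{row.protein_id}_{e}|Chain {cid}|"
                       f"{row.molecule_name}|{row.organism}")
            for i in range(0, ln, 60):
                out.append(seq[i:i + 60])
    return "\n".join(out) + "\n"


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def generate_pdb_fixture(record, seed: int) -> str:
    """Emit a minimal PDB file for one table row (or any object with
    ``protein_id``, ``sequence_length``, ``chain_count`` attributes).

    Backbone atoms (N, CA, C, O) are laid out along a random walk with
    consecutive CA–CA distances of 3.8 Å; within-residue offsets use idealised
    bond lengths.  Not a physical fold — just parseable geometry.
    """
    length = int(record.sequence_length)
    if length < 1:
        raise ValueError("sequence_length must be >= 1")
    n_chains = int(getattr(record, "chain_count", 1))
    rng = substream(seed, "pdb")
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))

    lines = []
    serial = 1
    pos = np.zeros(3)
    res_i = 0
    lens = _chain_lengths(length, n_chains)
    for cid, ln in zip(_chain_ids(n_chains), lens):
        pos = pos + np.array([20.0, 0.0, 0.0])   # separate chains in space
        for r in range(1, ln + 1):
            step = rng.standard_normal(3)
            step = 3.8 * step / np.linalg.norm(step)
            pos = pos + step
            res3 = _AA3[seq[res_i]]
            offsets = {
                "N": np.array([-1.46, 0.0, 0.0]),
                "CA": np.zeros(3),
                "C": np.array([1.52, 0.0, 0.0]),
                "O": np.array([1.52, 1.23, 0.0]),
            }
            for atom, off in offsets.items():
                x, y, z = pos + off
                elem = atom[0]
                lines.append(
                    f"ATOM  {serial:5d} {atom:^4s}{res3:>3s} {cid}{r:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
                )
                serial += 1
            res_i += 1
        lines.append(f"TER   {serial:5d}      {res3:>3s} {cid}{ln:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_multilabel_dataset(
    n: int, p: int, k: int, seed: int, margin: float = 4.0
) -> MultiLabelDataset:
    """Features X ~ N(0, I); per task j a unit direction w_j and label
    y_ij ~ Bernoulli(sigmoid(margin · x_i·w_j)).  Symmetric logits keep the
    class balance near 1/2; larger ``margin`` makes tasks closer to separable.
    """
    if min(n, p, k) < 1:
        raise ValueError("n, p, k must all be >= 1")
    rng = substream(seed, "multilabel")
    X = rng.standard_normal((n, p))
    W = rng.standard_normal((p, k))
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    probs = 1.0 / (1.0 + np.exp(-margin * (X @ W)))
    Y = (rng.random((n, k)) < probs).astype(int)
    return MultiLabelDataset(features=X, labels=Y, task_count=k)
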