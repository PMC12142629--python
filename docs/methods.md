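# Methods

## Overview

`modalign` studies how well two unimodal protein representations — a
graph/structure embedding and a text-description embedding — can be mapped
into a common space. The pipeline has four stages: (1) a synthetic generator
producing paired embeddings with controlled statistical structure (plus
FASTA/PDB fixtures for the preprocessing stage), (2) contrastive training of
two projection heads, (3) alignment scoring and stratified analyses, and
(4) retrieval augmentation for a nearest-neighbor description proxy.

## Generative model

Protein catalogue. A universe of `n_base_proteins` base proteins is drawn;
each base carries a unique (molecule name, organism) class, a homology
cluster, a sequence length (uniform over `length_range`, residues), and a
chain count (single with probability 1 − `multi_chain_fraction`, otherwise
2–4). The number of database entries per base follows a truncated Zipf law,
P(k) ∝ k^(−shape) on 1..`max_duplicates` (shape 1.2, max 6): most proteins
appear once, a heavy tail recurs under several distinct PDB-style IDs with
near-identical metadata. `popularity_count` is always the realised frequency
of the class in the emitted table, never the sampled parameter.

Documentation imbalance is family-structured: exactly half of the homology
clusters are marked understudied and never accumulate duplicates. This models
how structural biology coverage concentrates on well-studied protein
families. Without it, rarity degenerates into independent per-row noise with
no latent-space structure, and none of the rarity analyses have anything to
measure.

Embeddings. Each base protein has latent z = (1 − ρ)·u + ρ·c, with u an
independent standard normal draw and c its cluster centroid; ρ
(`homology_mixing`, default 0.6) controls how strongly homologous proteins
correlate. Duplicate entries share the base latent up to N(0, 0.05²) jitter —
re-depositions of one protein are nearly identical. Channels:

    text  = T z + ε,                ε  ~ N(0, σ_i²)
    graph = f·link(G z) + (1 − f)·η + ε′,   η ~ N(0, 1)

T and G are fixed random linear maps (entries N(0, 1/latent_dim), kept on the
dataset as ground truth for oracle tests). f = `graph_signal_fraction`
interpolates between a structure-blind encoder (f ≈ 0: output dominated by
the unit-scale noise channel η) and a geometry-aware one (f ≈ 0.9, the
default). σ_i = `noise_sd` (default 0.05) times `rare_noise_inflation`
(default 2) for entries whose class occurs once — rare proteins are
documented more poorly, hence noisier.

The nonlinear link is the elementwise magnitude, link(x) = |x|. This choice
is deliberate: a magnitude has (almost) no globally linear correlation with
the latent, yet because latents concentrate near cluster centroids its
inverse is locally linear per cluster — exactly the function class a
two-layer ReLU head can express and a single linear layer cannot. Earlier
candidates (tanh, ReLU) retain a dominant linear component, so one linear
layer already aligns them and head depth has nothing to add; they fail to
instantiate the regime the depth analysis is about.

Splits are 80/10/10 at the entry level by default, so duplicates of a popular
protein typically span train and test. This is intentional: it reproduces the
leakage structure of a real database snapshot, and it is the mechanism by
which popular proteins align better at test time. A `group_by_base` option
keeps all duplicates in one split for leakage-free protocols.

Scale: the default universe is 307 base proteins ≈ 500 entries (≈ 400 train /
50 validation / 50 test), latent 16, graph 64, text 96. These sizes keep
every experiment in the package, including the full sweeps and the complete
test suite, within seconds on one CPU core.

## Projection heads and training

Heads are 1–3 linear layers with ReLU between layers; only the final output
is L2-normalised. Weights are fan-in-scaled uniform; biases start at zero — a
random bias adds one direction shared by every output vector, which after
normalisation manufactures spurious pairwise similarity in untrained heads.
Both heads are trained jointly by a single Adam optimizer (lr 1e−3, betas
0.9/0.999) on the shifted-cosine InfoNCE loss (τ = 0.2, batch 32, 40 epochs),
with in-batch negatives only, exactly as the loss is written. Validation loss
is computed each epoch on fixed-order batches; checkpointing keeps the
parameters of the last epoch that strictly improved the best validation loss
(ties keep the earlier epoch). All computation is float64 and every source of
randomness flows from named substreams of one seed, so reruns are
bit-identical.

The untrained baseline is a pair of randomly initialised heads with no
optimizer step, reported as the mean test alignment over 10 independent
initialisations (seeds config_seed + 0..9). A single draw carries
initialisation noise of roughly ±0.04 in F_similarity at this output
dimension and test-set size; the averaged estimator reports the expected
untrained alignment, the quantity the trained/untrained comparison is about.
At the scales of full encoder studies (output dimensions in the thousands,
thousands of test proteins) this estimator noise is negligible and a single
draw would do.

## Evaluation

F_positive is the mean raw cosine over positive pairs; F_negative the mean
absolute cosine over all M = N(N−1) ordered cross pairs; F_similarity their
difference. Per-protein scores are raw cosines and may be negative — that is
what the structure-blind-encoder analyses look at. Rarity labels use
popularity_count ≥ 5 for popular and ≤ 1 for rare (configurable; the
thresholds are artifact choices, as published analyses hand-picked examples
without stating cutoffs). Sequence-length trends are ordinary least squares
of score on length; model-pair correlation is Pearson on per-protein score
columns. Sweeps hold the latent draw fixed (latents come from a substream
independent of the manipulated factor) so differences are attributable to
the factor, not resampling.

The rarity and reweighting analyses default to the magnitude-link generator.
With a linear link the one-layer heads are well-specified, every group aligns
near ceiling (≈ 0.96+) and the popular−rare gap collapses to a ~0.01 noise
effect; rarity as a *significant* phenomenon exists only when encoders are
imperfectly invertible and head capacity has to be rationed across latent
regions.

Reweighting (w ∝ popularity_count^(−α), mean-normalised over the training
split, α = 1 by default) raises the rare-group alignment on the training
split and typically nudges the rare-group test mean upward, but in this
generator it does not raise the overall test score: held-out rare proteins'
individual latent components were never observed, so their test alignment is
a generalisation floor largely insensitive to weighting, while downweighting
popular anchors weakens the duplicate-memorisation channel that popular test
scores ride on. The acceptance script reports both weighted and unweighted
scores so this trade-off is visible rather than hidden.

## Retrieval proxy and text metrics

The retrieval index stores projected graph embeddings (unit vectors) and
template descriptions for the training pool. Queries rank pool entries by
cosine, excluding the query's own ID, ties broken lexicographically. The
description "prediction" for a test protein is the rank-1 neighbor's
description verbatim — a deliberately simple stand-in for a generative
model, measuring how much usable description content the aligned space
retrieves. With k = 0 no retrieved information exists, so the proxy falls
back to a uniformly random pool description (the unconditioned floor).
ROUGE-L is the LCS F-measure with equal precision/recall weight; BLEU is the
geometric mean of modified n-gram precisions up to n = 4 with brevity
penalty and ε = 1e−9 smoothing of zero counts. Both use lowercased
whitespace tokens. Because all descriptions share one template, both metrics
have a high floor; gains above the k = 0 baseline measure matching of the
protein-specific slots (ID, length, chains, name, organism).

## Preprocessing

FASTA parsing accepts the RCSB header dialect only
(`>ID_entity|Chains A, B|molecule|organism`), merging entities by protein ID;
each chain listed on an entity contributes one copy of the entity sequence to
the total length. Other dialects raise a parse error naming the offending
header. Multichain entries with differing per-chain organisms render the
distinct organisms joined by "; " — a deterministic rule rather than a
generative model. The description template is fixed and excludes the raw
amino-acid sequence (only its length appears).

PDB files are read with gemmi. Residue coordinate records keep one [x, y, z]
triple per residue (CA) by default or four (N, CA, C, O) in `backbone4` mode;
residues missing a required atom are skipped with a warning; order follows
the file; coordinates stay in Å with no recentering. The atom graph uses
heavy atoms with edges at pairwise distance ≤ 1.9 Å (covalent-bond range for
C/N/O/S), built with a KD-tree but tested against an O(n²) oracle. Generated
PDB fixtures are random walks with CA–CA steps of 3.8 Å and idealised
within-residue offsets — parseable geometry, not physical folds.

## Limitations

* The generator's linear(+magnitude) maps cannot emulate any specific
  pretrained encoder's geometry; conclusions are about the alignment
  machinery and the relative effects of signal fraction, dimension, depth and
  rarity, not about absolute scores of real model pairs.
* Homology is modelled as Gaussian cluster mixing; real homolog pairs can be
  far closer to duplicates than ρ = 0.6 implies, which matters for how much
  of a rare protein's alignment deficit is recoverable by reweighting (see
  above).
* The description proxy never generates text; ROUGE/BLEU deltas measure
  retrieval quality, not language-model quality. The scoring code accepts
  externally generated text for when a generative model is available.
* Multichain FASTA handling covers the RCSB dialect's regular structure;
  exotic header variants are rejected rather than guessed.
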