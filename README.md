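# modalign

Cross-modal representation alignment analysis for proteins: how well can the
embedding a *geometric* encoder assigns to a protein's 3-D structure be mapped
into the same space as the embedding a *language* model assigns to the
protein's textual description?

The package is aimed at researchers studying multimodal protein models. It
implements the full analysis pipeline — projection-head training under a
modified InfoNCE objective, an alignment-score metric, stratified analyses by
sequence length / rarity / chain multiplicity, dimension and depth sweeps,
rarity reweighting, and top-k retrieval augmentation for a description task —
driven by a seeded synthetic generator of paired embeddings, so every
experiment runs on a desk in seconds with no downloads or GPUs. Real-format
inputs are supported through a FASTA/PDB preprocessing stage, and externally
produced embedding tables can be ingested through the CLI.

## The model

Each protein *i* has a graph-modality embedding and a text-modality embedding.
Two trainable projection heads (1–3 linear layers, ReLU between layers, output
L2-normalised) map both into a shared space of the text-side dimension,
producing unit vectors g_i and t_i. Training minimises a modified InfoNCE loss
over batches of size B with temperature τ, using the *shifted cosine*
s(u, v) = (cos(u, v) + 1)/2 so that similarity lives in [0, 1]:

    L = (1/B) Σ_i −log [ exp(s(g_i, t_i)/τ) / Σ_j exp(s(g_i, t_j)/τ) ]

Defaults: τ = 0.2, B = 32, Adam with learning rate 1e−3, 40 epochs, seed 42,
checkpointing on validation-loss decrease. A rarity-reweighted variant scales
each anchor's term by w_i ∝ popularity_count_i^(−α).

Alignment of a trained pair is scored on held-out proteins as

    F_similarity = F_positive − F_negative
    F_positive   = (1/N) Σ_i cos(g_i, t_i)
    F_negative   = (1/M) Σ_i Σ_{j≠i} |cos(g_i, t_j)|,   M = N(N−1)

so a well-aligned pair has positive pairs near 1 and cross-protein pairs near
0. Note the deliberate asymmetry: the loss sees shifted similarities of
in-batch negatives only; the metric averages raw cosines over all ordered
test-set pairs.

The synthetic generator draws a shared latent per protein, mixes in a
homology-cluster centroid (so "negatives" of related proteins correlate),
expands popular proteins into several database entries under distinct
PDB-style IDs, inflates noise on rare entries, and exposes its ground-truth
maps so tests can verify every statistical claim against oracles.

## Worked example

```python
from modalign import UniverseConfig, EmbeddingSpec
from modalign.experiments import trained_vs_untrained

universe = UniverseConfig(master_seed=42)   # ~500 synthetic PDB-style entries
spec = EmbeddingSpec()                      # latent 16, graph 64, text 96

res = trained_vs_untrained(universe, spec)
rep = res["trained_report"]
print(f"test proteins        : {rep.n_proteins}")
print(f"F_positive           : {rep.positive_score:.4f}")
print(f"F_negative           : {rep.negative_score:.4f}")
print(f"F_similarity trained : {rep.alignment_score:.4f}")
print(f"F_similarity untrained (mean of 10 random inits): "
      f"{res['f_similarity_untrained']:.4f}")
```

prints

```
test proteins        : 50
F_positive           : 0.9704
F_negative           : 0.2015
F_similarity trained : 0.7689
F_similarity untrained (mean of 10 random inits): -0.0835
```

Trained heads recover strong alignment (F_similarity 0.77): positive pairs
average cosine 0.97 while cross-protein pairs retain |cos| ≈ 0.20 — the
residue of homologous proteins and duplicate database entries, which the
contrastive loss cannot push to zero. Untrained heads show no meaningful
alignment (−0.08, within the random-projection noise floor at this output
dimension).

The same pipeline is scriptable from a shell:

```bash
modalign simulate --seed 42 --out sim/
modalign train --embeddings sim/ --epochs 40 --tau 0.2 --out run/
modalign evaluate --pair run/pair.pkl --embeddings sim/ --report report.json
modalign retrieve --index sim/ --pair run/pair.pkl --query <ID> --k 3
```

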