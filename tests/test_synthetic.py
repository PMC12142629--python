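"""Generator contracts: popularity bookkeeping, latent structure, fixtures,
splits and determinism."""

import numpy as np
import pandas as pd
import pytest

from modalign.preprocessing import parse_fasta
from modalign.synthetic import (EmbeddingSpec, UniverseConfig,
                                generate_embedding_pairs,
                                generate_fasta_fixture,
                                generate_multilabel_dataset,
                                generate_pdb_fixture,
                                generate_protein_universe, make_dataset,
                                split_dataset)


class TestProteinUniverse:
    def test_rejects_degenerate_config(self):
        with pytest.raises(ValueError, match="n_base_proteins"):
            UniverseConfig(n_base_proteins=1)
        with pytest.raises(ValueError):
            UniverseConfig(homology_mixing=1.5)
        with pytest.raises(ValueError):
            UniverseConfig(rare_noise_inflation=0.5)

    def test_no_duplication_when_max_duplicates_is_one(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=30, max_duplicates=1, master_seed=3))
        assert table.base_protein_key.value_counts().max() == 1
        assert (table.popularity_count == 1).all()

    def test_popularity_counts_match_recount_oracle(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=200, popularity_law=("zipf", 1.2),
                           max_duplicates=6, master_seed=42))
        # brute-force recount of each (molecule, organism) class
        for _, row in table.iterrows():
            n = sum((table.molecule_name == row.molecule_name)
                    & (table.organism == row.organism))
            assert row.popularity_count == n

    def test_duplicates_share_base_metadata(self, small_table):
        for _, grp in small_table.groupby("base_protein_key"):
            assert grp.molecule_name.nunique() == 1
            assert grp.organism.nunique() == 1
            assert grp.homology_cluster.nunique() == 1
            assert grp.chain_count.nunique() == 1

    def test_protein_ids_unique_and_chain_counts_positive(self, small_table):
        assert small_table.protein_id.is_unique
        assert (small_table.chain_count >= 1).all()

    def test_identical_seed_reproduces_table(self, small_universe, small_table):
        again = generate_protein_universe(small_universe)
        pd.testing.assert_frame_equal(again, small_table)


class TestEmbeddingPairs:
    def test_noiseless_limit_is_exact_linear_image(self, small_table):
        spec = EmbeddingSpec(latent_dim=8, graph_dim=16, text_dim=16,
                             graph_signal_fraction=1.0, noise_sd=0.0)
        ds = generate_embedding_pairs(small_table, spec, seed=5,
                                      homology_mixing=0.0)
        gt = ds.ground_truth
        np.testing.assert_allclose(ds.text_embeddings,
                                   gt["latents"] @ gt["text_map"], atol=1e-12)
        np.testing.assert_allclose(ds.graph_embeddings,
                                   gt["latents"] @ gt["graph_map"], atol=1e-12)

    def test_determinism_bitwise(self, small_table):
        spec = EmbeddingSpec(latent_dim=8, graph_dim=24, text_dim=32)
        a = generate_embedding_pairs(small_table, spec, seed=11)
        b = generate_embedding_pairs(small_table, spec, seed=11)
        assert np.array_equal(a.graph_embeddings, b.graph_embeddings)
        assert np.array_equal(a.text_embeddings, b.text_embeddings)

    def test_homology_clusters_correlate_text_embeddings(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=60, homology_cluster_count=10,
                           max_duplicates=1, master_seed=7))
        ds = generate_embedding_pairs(
            table, EmbeddingSpec(latent_dim=8, graph_dim=16, text_dim=24),
            seed=7, homology_mixing=0.6)
        T = ds.text_embeddings
        clusters = table.homology_cluster.to_numpy()
        within, between = [], []
        for i in range(len(T)):            # double-loop oracle
            for j in range(i + 1, len(T)):
                c = float(T[i] @ T[j] /
                          (np.linalg.norm(T[i]) * np.linalg.norm(T[j])))
                (within if clusters[i] == clusters[j] else between).append(c)
        assert np.mean(within) > np.mean(between)

    def test_rare_rows_have_larger_noise_residuals(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=120, master_seed=9))
        spec = EmbeddingSpec(latent_dim=8, graph_dim=24, text_dim=32,
                             noise_sd=0.2)
        ds = generate_embedding_pairs(table, spec, seed=9,
                                      rare_noise_inflation=3.0)
        gt = ds.ground_truth
        resid = ds.text_embeddings - gt["latents"] @ gt["text_map"]
        mags = np.linalg.norm(resid, axis=1)
        rare = table.popularity_count.to_numpy() == 1
        assert rare.any() and (~rare).any()
        assert mags[rare].mean() > mags[~rare].mean()

    def test_signal_fraction_monotone_in_noiseless_limit(self, small_table):
        # positive-pair cosine after mapping the graph channel back through
        # the known ground-truth maps (graph -> latent -> text space) rises
        # with the signal fraction; at f=1, noiseless, it is exactly 1
        means = []
        for f in (0.0, 0.3, 0.7, 1.0):
            spec = EmbeddingSpec(latent_dim=8, graph_dim=32, text_dim=32,
                                 graph_signal_fraction=f, noise_sd=0.0)
            ds = generate_embedding_pairs(small_table, spec, seed=3,
                                          homology_mixing=0.0)
            gt = ds.ground_truth
            aligned = ds.graph_embeddings @ np.linalg.pinv(gt["graph_map"]) \
                @ gt["text_map"]
            T = ds.text_embeddings
            cos = [aligned[i] @ T[i]
                   / (np.linalg.norm(aligned[i]) * np.linalg.norm(T[i]))
                   for i in range(len(T))]
            means.append(np.mean(cos))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] == pytest.approx(1.0, abs=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            generate_embedding_pairs(pd.DataFrame(), EmbeddingSpec(), seed=1)


class TestSplits:
    def test_exact_fraction_arithmetic(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=10, max_duplicates=1, master_seed=2))
        ds = generate_embedding_pairs(table, EmbeddingSpec(latent_dim=4,
                                      graph_dim=4, text_dim=4), seed=2)
        out = split_dataset(ds, (0.8, 0.1, 0.1), seed=0)
        sizes = pd.Series(out.split_labels).value_counts()
        assert (sizes["train"], sizes["val"], sizes["test"]) == (8, 1, 1)

    def test_grouped_split_keeps_duplicates_together(self, small_dataset):
        out = split_dataset(small_dataset, seed=4, group_by_base=True)
        df = pd.DataFrame({"base": out.metadata.base_protein_key,
                           "split": out.split_labels})
        assert (df.groupby("base")["split"].nunique() == 1).all()

    def test_split_determinism(self, small_dataset):
        a = split_dataset(small_dataset, seed=6)
        b = split_dataset(small_dataset, seed=6)
        assert np.array_equal(a.split_labels, b.split_labels)

    def test_bad_fractions_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="fractions"):
            split_dataset(small_dataset, (0.7, 0.2, 0.2), seed=0)


class TestFixtures:
    def test_fasta_single_chain_roundtrip(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=12, multi_chain_fraction=0.0,
                           master_seed=8))
        text = generate_fasta_fixture(table, seed=8)
        records = {r.protein_id: r for r in parse_fasta(text)}
        assert len(records) == len(table)
        for _, row in table.iterrows():
            rec = records[row.protein_id]
            assert len(rec.chains) == 1
            assert rec.sequence_length == row.sequence_length

    def test_fasta_multichain_roundtrip(self):
        table = generate_protein_universe(
            UniverseConfig(n_base_proteins=12, multi_chain_fraction=1.0,
                           master_seed=8))
        text = generate_fasta_fixture(table, seed=8)
        records = {r.protein_id: r for r in parse_fasta(text)}
        for _, row in table.iterrows():
            rec = records[row.protein_id]
            assert len(rec.chains) == row.chain_count
            assert rec.sequence_length == row.sequence_length
            assert rec.molecule_name == row.molecule_name

    def test_pdb_ca_distances_and_determinism(self, small_table):
        row = next(small_table.head(1).itertuples(index=False))
        text = generate_pdb_fixture(row, seed=5)
        assert text == generate_pdb_fixture(row, seed=5)
        # recompute CA-CA distances directly from the ATOM lines, per chain
        cas = {}
        for line in text.splitlines():
            if line.startswith("ATOM") and line[12:16].strip() == "CA":
                chain = line[21]
                cas.setdefault(chain, []).append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])])
        n_res = sum(len(v) for v in cas.values())
        assert n_res == row.sequence_length
        for pts in cas.values():
            pts = np.asarray(pts)
            d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert ((d >= 3.7) & (d <= 3.9)).all()

    def test_pdb_single_residue(self):
        class Row:
            protein_id = "1TST"
            sequence_length = 1
            chain_count = 1
        text = generate_pdb_fixture(Row(), seed=1)
        atoms = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(atoms) == 4      # backbone N, CA, C, O only


class TestMultiLabel:
    def test_labels_binary_and_shapes(self):
        d = generate_multilabel_dataset(50, 6, 3, seed=2)
        assert d.features.shape == (50, 6)
        assert d.labels.shape == (50, 3)
        assert set(np.unique(d.labels)) <= {0, 1}

    def test_class_balance_within_bounds(self):
        d = generate_multilabel_dataset(500, 10, 4, seed=3)
        balance = d.labels.mean(axis=0)
        assert ((balance >= 0.2) & (balance <= 0.8)).all()

    def test_separable_task_learnable_by_linear_probe(self):
        from sklearn.linear_model import LogisticRegression
        d = generate_multilabel_dataset(300, 8, 1, seed=4, margin=6.0)
        clf = LogisticRegression(max_iter=1000).fit(d.features, d.labels[:, 0])
        assert clf.score(d.features, d.labels[:, 0]) > 0.9

    def test_seed_reproducibility(self):
        a = generate_multilabel_dataset(40, 5, 2, seed=6)
        b = generate_multilabel_dataset(40, 5, 2, seed=6)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)


def test_make_dataset_split_fractions(small_universe):
    ds = make_dataset(small_universe, EmbeddingSpec(latent_dim=8, graph_dim=16,
                                                    text_dim=16))
    sizes = pd.Series(ds.split_labels).value_counts()
    assert sizes.sum() == ds.n
    assert abs(sizes["train"] / ds.n - 0.8) < 0.02
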