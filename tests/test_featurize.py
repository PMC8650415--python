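import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epa import (
    EmbeddingModel,
    MoleculeSentence,
    NgramFrames,
    assemble_pcm2vec,
    combine,
    embed_molecule,
    embed_protein,
    featurize_table,
    make_toy_corpora,
    mol_sentence,
    prot_ngrams,
    train_skipgram,
)
from epa.featurize import read_fasta
from epa.fixtures import write_fasta


class TestMolSentence:
    def test_ethane_symmetry(self):
        # two equivalent atoms: identifiers alternate (r0, r1) per atom
        s = mol_sentence("CC")
        assert len(s) == 4
        assert s.identifiers[0] == s.identifiers[2]
        assert s.identifiers[1] == s.identifiers[3]
        assert s.identifiers[0] != s.identifiers[1]

    def test_isolated_atom_has_only_radius0(self):
        # methane has no bonds, hence no radius-1 environment
        assert len(mol_sentence("C")) == 1

    def test_bonded_molecule_has_two_ids_per_atom(self):
        from rdkit import Chem
        for smi in ["CCO", "c1ccccc1", "CC(=O)Nc1ccccc1"]:
            n_atoms = Chem.MolFromSmiles(smi).GetNumAtoms()
            assert len(mol_sentence(smi)) == 2 * n_atoms

    def test_unparsable_smiles_raises(self):
        with pytest.raises(ValueError, match="not_a_smiles"):
            mol_sentence("not_a_smiles")

    def test_deterministic(self):
        assert mol_sentence("CCO") == mol_sentence("CCO")


class TestProtNgrams:
    def test_three_frames_by_enumeration(self):
        frames = prot_ngrams("MKVLAT").frames
        assert frames == (("MKV", "LAT"), ("KVL",), ("VLA",))

    def test_too_short_sequence(self):
        assert prot_ngrams("MK").frames == ((), (), ())

    def test_frame_sizes(self):
        sizes = tuple(len(f) for f in prot_ngrams("AAAAAAAAA").frames)
        assert sizes == (3, 2, 2)

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=60, deadline=None)
    def test_frame_word_counts_formula(self, length):
        seq = "A" * length
        frames = prot_ngrams(seq).frames
        for k in range(3):
            assert len(frames[k]) == max(0, (length - k)) // 3

    def test_all_words_have_length_three(self):
        for frame in prot_ngrams("MKVLATRQWERTYIPASDFG").frames:
            assert all(len(w) == 3 for w in frame)


class TestSkipgram:
    @pytest.fixture(scope="class")
    def corpus(self):
        rng = np.random.default_rng(0)
        toks = list("ABCDEFGH")
        return [[toks[i] for i in rng.integers(0, 8, size=12)] for _ in range(10)]

    def test_vector_dimension(self, corpus):
        model = train_skipgram(corpus, dim=8, epochs=2, seed=1)
        assert model.dim == 8
        assert all(v.shape == (8,) for v in model.vocabulary.values())

    def test_deterministic_under_seed(self, corpus):
        m1 = train_skipgram(corpus, dim=8, epochs=2, seed=7)
        m2 = train_skipgram(corpus, dim=8, epochs=2, seed=7)
        assert m1.vocabulary.keys() == m2.vocabulary.keys()
        for tok in m1.vocabulary:
            np.testing.assert_array_equal(m1.vocabulary[tok], m2.vocabulary[tok])

    def test_absent_token_not_in_vocabulary(self, corpus):
        model = train_skipgram(corpus, dim=4, epochs=1, seed=0)
        assert "Z" not in model
        np.testing.assert_array_equal(model.vector("Z"), np.zeros(4))

    def test_invalid_dim_rejected(self, corpus):
        with pytest.raises(ValueError):
            train_skipgram(corpus, dim=0)

    def test_text_roundtrip(self, corpus, tmp_path):
        model = train_skipgram(corpus, dim=6, epochs=1, seed=3)
        path = tmp_path / "vecs.txt"
        model.save_text(path)
        loaded = EmbeddingModel.load_text(path)
        assert loaded.dim == 6
        for tok, vec in model.vocabulary.items():
            np.testing.assert_allclose(loaded.vocabulary[tok], vec, rtol=1e-6)


class TestEmbedding:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(2)
        vocab = {str(t): rng.normal(size=5) for t in [10, 20, 30, "AAA", "KVL", "MKV"]}
        return EmbeddingModel(vocab, 5)

    def test_empty_sentence_embeds_to_zero(self, model):
        np.testing.assert_array_equal(
            embed_molecule(MoleculeSentence(()), model), np.zeros(5))

    def test_singleton_sentence_equals_token_vector(self, model):
        out = embed_molecule(MoleculeSentence((10,)), model)
        np.testing.assert_array_equal(out, model.vector(10))

    def test_duplicate_identifier_doubles_contribution(self, model):
        once = embed_molecule(MoleculeSentence((10, 20)), model)
        twice = embed_molecule(MoleculeSentence((10, 20, 20)), model)
        np.testing.assert_allclose(twice - once, model.vector(20), atol=1e-12)

    def test_molecule_sum_matches_bruteforce(self, model):
        sent = MoleculeSentence((10, 20, 30, 10, 99))
        expected = sum((model.vector(t) for t in sent.identifiers), np.zeros(5))
        np.testing.assert_allclose(embed_molecule(sent, model), expected, atol=1e-12)

    def test_empty_frames_sum_and_concat(self, model):
        empty = NgramFrames(((), (), ()))
        np.testing.assert_array_equal(embed_protein(empty, model, "sum"), np.zeros(5))
        np.testing.assert_array_equal(embed_protein(empty, model, "concat"), np.zeros(15))

    def test_single_nonempty_frame_equals_frame_vector(self, model):
        frames = NgramFrames((("AAA", "KVL"), (), ()))
        expected = model.vector("AAA") + model.vector("KVL")
        np.testing.assert_allclose(embed_protein(frames, model, "sum"), expected)

    def test_protein_sum_matches_bruteforce(self, model):
        frames = prot_ngrams("MKVLAAAKVLMKV")
        brute = np.zeros(5)
        for frame in frames.frames:
            for gram in frame:
                brute += model.vector(gram)
        np.testing.assert_allclose(embed_protein(frames, model, "sum"), brute, atol=1e-12)


class TestCombination:
    @pytest.mark.parametrize("scheme,dc,dp,total", [
        ("c1", 100, 100, 200),
        ("c2", 300, 300, 600),
        ("c3", 300, 300, 600),
    ])
    def test_output_lengths(self, scheme, dc, dp, total):
        out = combine(np.ones(dc), np.zeros(dp), scheme)
        assert out.shape == (total,)
        np.testing.assert_array_equal(out[:dc], 1.0)  # compound first

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine(np.ones(300), np.ones(300), "c1")

    def test_assemble_appends_label_last(self):
        row = assemble_pcm2vec(np.zeros(600), 7.3)
        assert row.shape == (601,)
        assert row[-1] == 7.3

    def test_assemble_other_dims(self):
        assert assemble_pcm2vec(np.zeros(200), 6.0).shape == (201,)

    def test_assemble_rejects_nan(self):
        with pytest.raises(ValueError):
            assemble_pcm2vec(np.zeros(600), float("nan"))


class TestTableFeaturization:
    def test_corpus_to_dataset(self, tmp_path):
        import pandas as pd

        smiles, proteins = make_toy_corpora(n_molecules=5, n_proteins=3, seed=0)
        mol_corpus = [mol_sentence(s).identifiers for s in smiles]
        prot_corpus = []
        for _, seq in proteins:
            prot_corpus.extend(prot_ngrams(seq).frames)
        # three frame sequences per protein
        assert len(prot_corpus) == 3 * len(proteins)

        mol_model = train_skipgram(mol_corpus, dim=300, epochs=1, seed=1)
        prot_model = train_skipgram(prot_corpus, dim=300, epochs=1, seed=1)
        std = pd.DataFrame({
            "smiles": smiles[:3],
            "kinase_id": [p[0] for p in proteins],
            "p_affinity": [7.0, 5.5, 8.2],
        })
        ds = featurize_table(std, dict(proteins), mol_model, prot_model, "c2")
        assert len(ds) == 3 and ds.dim == 600
        np.testing.assert_allclose(ds.y, [7.0, 5.5, 8.2])

    def test_fasta_roundtrip(self, tmp_path):
        _, proteins = make_toy_corpora(n_molecules=1, n_proteins=4, seed=2)
        path = tmp_path / "prot.fasta"
        write_fasta(proteins, path)
        seqs = read_fasta(path)
        assert seqs == dict(proteins)
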