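import numpy as np
import pytest
from rdkit import Chem

from molgrow import (
    GraphMatrix,
    GraphState,
    MoleculeRecord,
    brics_leaf_fragments,
    decode_graph,
    encode_graph,
    enumerate_pairs,
    graph_position_index,
    valence_mask,
)
from molgrow.graph_codec import (
    BLANK_IDX,
    END_IDX,
    GO_IDX,
    DecodeError,
    N_BOND_TYPES,
    state_from_scaffold,
)


class TestVocabularyContract:
    def test_exactly_four_bond_types(self, graph_vocab):
        assert N_BOND_TYPES == 4
        assert graph_vocab.n_words == len(graph_vocab) * 4

    def test_word_index_formula_and_injectivity(self, graph_vocab):
        assert graph_vocab.word_index(0, 0) == 0
        assert graph_vocab.word_index(1, 3) == 7
        assert graph_vocab.word_index(9, 2) == 38
        seen = {
            graph_vocab.word_index(a, b)
            for a in range(len(graph_vocab))
            for b in range(4)
        }
        assert len(seen) == len(graph_vocab) * 4

    def test_word_index_range_checks(self, graph_vocab):
        with pytest.raises(ValueError):
            graph_vocab.word_index(0, 4)
        with pytest.raises(ValueError):
            graph_vocab.word_index(len(graph_vocab), 0)

    def test_at_least_38_atom_types(self, graph_vocab):
        assert len(graph_vocab) >= 38

    def test_position_index_formula(self):
        assert graph_position_index(0, 0, 80) == 0
        assert graph_position_index(2, 1, 80) == 161
        assert graph_position_index(1, 1, 100) == 101
        with pytest.raises(ValueError):
            graph_position_index(80, 0, 80)

    def test_vocab_save_load(self, graph_vocab, tmp_path):
        path = tmp_path / "atoms.txt"
        graph_vocab.save(path)
        again = type(graph_vocab).load(path)
        assert again.atom_tokens == graph_vocab.atom_tokens


class TestEncodeDecode:
    def test_methane_single_fragment_column(self, graph_vocab):
        m = encode_graph(MoleculeRecord("C"), ["C"], graph_vocab)
        assert m.data[0, 0] == GO_IDX
        assert m.data[4, 1] == 1  # fragment index 1
        assert decode_graph(m, graph_vocab).smiles == "C"

    def test_benzene_kekulized_bond_alternation(self, graph_vocab):
        m = encode_graph(MoleculeRecord("c1ccccc1"), ["c1ccccc1"], graph_vocab)
        ring_bonds = sorted(m.data[1, (m.data[1] > 0)])
        assert ring_bonds == [1, 1, 1, 2, 2, 2]  # three single, three double
        assert decode_graph(m, graph_vocab).smiles == "c1ccccc1"

    def test_fragment_rows_labeled_and_sections_ordered(self, graph_vocab):
        m = encode_graph(
            MoleculeRecord("CCc1ccc(O)cc1"), ["c1ccccc1", "CC"], graph_vocab
        )
        frag_row = m.data[4]
        n_frag = int((frag_row >= 1).sum())
        # fragment block is contiguous at the front, growing/linking all zero
        assert set(frag_row[1 : 1 + n_frag]) == {1, 2}
        assert (frag_row[1 + n_frag :] == 0).all()
        # exactly two end-token columns
        assert (m.data[0] == END_IDX).sum() == 2

    def test_round_trip_library_times_all_subsets(self, small_library, graph_vocab):
        for rec in small_library:
            fs = brics_leaf_fragments(rec)
            for pair in enumerate_pairs(fs, rng_seed=11):
                m = encode_graph(
                    MoleculeRecord(pair.molecule_smiles), pair.scaffold, graph_vocab
                )
                out = decode_graph(m, graph_vocab)
                assert Chem.CanonSmiles(out.smiles) == Chem.CanonSmiles(
                    pair.molecule_smiles
                )

    def test_unmatched_fragment_raises(self, graph_vocab):
        from molgrow.graph_codec import EncodeError

        with pytest.raises(EncodeError):
            encode_graph(MoleculeRecord("CCO"), ["c1ccccc1"], graph_vocab)

    def test_empty_matrix_is_a_decode_error(self, graph_vocab):
        end_only = GraphMatrix(
            np.array([[GO_IDX, END_IDX], [0, 0], [0, 0], [0, 0], [0, 0]])
        )
        with pytest.raises(DecodeError):
            decode_graph(end_only, graph_vocab)

    def test_tsv_round_trip(self, graph_vocab, tmp_path):
        m = encode_graph(MoleculeRecord("CCO"), ["CC"], graph_vocab)
        path = tmp_path / "matrix.tsv"
        m.to_tsv(path)
        assert np.array_equal(GraphMatrix.from_tsv(path).data, m.data)


class TestValenceMask:
    def test_saturated_carbon_accepts_no_more_bonds(self, graph_vocab):
        state, _ = state_from_scaffold("C(F)(F)(F)F", graph_vocab, 20)
        carbon = 0  # first emitted atom of the fragment
        assert state.remaining[carbon] == 0
        for bond in (1, 2, 3):
            assert carbon not in state.allowed_connections(
                graph_vocab.index["C"], bond
            )

    def test_fresh_nitrogen_allows_up_to_triple(self, graph_vocab):
        state = GraphState(graph_vocab, 20)
        state.apply((graph_vocab.index["N"], 0, 0, 0))
        masks = valence_mask(state)
        n_tok = graph_vocab.index["C"]
        assert masks.bonds[n_tok] == {1, 2, 3}

    def test_oxygen_with_double_bond_is_exhausted(self, graph_vocab):
        state = GraphState(graph_vocab, 20)
        state.apply((graph_vocab.index["C"], 0, 0, 0))
        state.apply((graph_vocab.index["O"], 2, 0, 1))
        oxygen = 1
        for bond in (1, 2, 3):
            assert oxygen not in state.allowed_connections(
                graph_vocab.index["C"], bond
            )

    def test_end_token_always_available_while_growing(self, graph_vocab, rng):
        state, _ = state_from_scaffold("CC.O", graph_vocab, 20)
        for _ in range(30):
            masks = valence_mask(state)
            assert masks.atoms, "mask must never be empty"
            if state.phase == state.GROW:
                assert END_IDX in masks.atoms
            choice = int(rng.choice(sorted(masks.atoms)))
            b = int(rng.choice(sorted(masks.bonds[choice])))
            conns = sorted(masks.connections[(choice, b)])
            c = int(rng.choice(conns)) if conns else 0
            curs = sorted(masks.currents.get((choice, b, c), {0}))
            state.apply((choice, b, c, int(rng.choice(curs))))
            if state.phase == state.DONE:
                break

    def test_linking_phase_only_joins_components_with_single_bonds(
        self, graph_vocab
    ):
        state, _ = state_from_scaffold("CC.O", graph_vocab, 20)
        state.apply((END_IDX, 0, 0, 0))  # enter linking
        assert state.phase == state.LINK
        masks = valence_mask(state)
        assert masks.bonds[BLANK_IDX] == {1}
        # all permitted pairs span the two components
        for (a, b), conns in masks.connections.items():
            if a != BLANK_IDX:
                continue
            for c in conns:
                for k in masks.currents[(a, b, c)]:
                    assert state._find(c) != state._find(k)
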