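import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers_oracles as oracles
from conftest import random_segment, random_segment_set
from m5cboost.encoders import (
    DinucleotidePropertyTable,
    EncoderConfig,
    FeatureMatrix,
    encode_all,
    encode_anf,
    encode_binary,
    encode_cksnap,
    encode_enac,
    encode_ncp,
    encode_scpsednc,
    encode_word2vec,
    feature_names,
    train_embedding,
)
from m5cboost.word2vec import tokenize, train_cbow

BLOCK_DIMS = {
    "ENAC": 148,
    "CKSNAP": 96,
    "ANF": 41,
    "NCP": 123,
    "BIN": 164,
    "SCPDNC": 136,
    "W2V": 100,
}


def test_property_table_standardized():
    table = DinucleotidePropertyTable.default()
    arr = table.as_array()
    assert arr.shape == (6, 16)
    assert np.allclose(arr.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(arr.std(axis=1), 1, atol=1e-9)
    assert table.index_names == ["Roll", "Rise", "Shift", "Twist", "Slide", "Tilt"]


def test_property_table_missing_dinucleotide():
    broken = pd.DataFrame({"AA": [1.0]}, index=["Roll"])
    with pytest.raises(ValueError, match="missing"):
        DinucleotidePropertyTable(broken)


def test_anf_worked_example():
    # densities of the running-prefix frequency for AUCUCAUGAG; note the 5th
    # position is the second C of the prefix, hence 2/5 = 0.40
    result = encode_anf("AUCUCAUGAG")
    expected = [1.00, 0.50, 1 / 3, 0.50, 0.40, 1 / 3, 3 / 7, 0.125, 1 / 3, 0.20]
    assert np.allclose(result, expected)


def test_homopolymer_edge_cases():
    poly_c = "C" * 41
    assert np.all(encode_anf(poly_c) == 1.0)
    enac = encode_enac(poly_c).reshape(-1, 4)
    assert np.all(enac == [0, 1, 0, 0])
    cksnap = encode_cksnap(poly_c).reshape(6, 16)
    assert np.all(cksnap[:, 5] == 1.0)  # C*C pair
    assert cksnap.sum() == 6.0


def test_ncp_and_binary_codes():
    seq = "AUGC" + "G" * 16 + "C" + "G" * 20
    ncp = encode_ncp(seq).reshape(-1, 3)
    assert tuple(ncp[0]) == (1, 1, 1)  # A
    assert tuple(ncp[1]) == (1, 0, 0)  # U
    assert tuple(ncp[2]) == (0, 0, 1)  # G
    assert tuple(ncp[3]) == (0, 1, 0)  # C
    bin_ = encode_binary(seq).reshape(-1, 4)
    assert np.all(bin_.sum(axis=1) == 1)
    assert tuple(bin_[0]) == (1, 0, 0, 0)
    assert tuple(bin_[20]) == (0, 1, 0, 0)  # center C one-hot


def test_scpsednc_hand_computed_toy():
    """Six-nt toy with one unstandardized index, evaluated by hand.

    For ACGUCA with P(AC)=1, P(CG)=2, P(GU)=3, P(UC)=4, P(CA)=5 and w=0.5:
    theta_1 = (1*2 + 2*3 + 3*4)/3 = 20/3, theta_2 = (1*3 + 2*4)/2 = 11/2,
    denominator 1 + 0.5*(20/3 + 11/2) = 85/12.
    """
    values = {d: [0.0] for d in oracles.DINUCLEOTIDES}
    for duo, val in zip(["AC", "CG", "GU", "UC", "CA"], [1, 2, 3, 4, 5]):
        values[duo] = [float(val)]
    table = DinucleotidePropertyTable(
        pd.DataFrame({d: values[d] for d in oracles.DINUCLEOTIDES}, index=["toy"]),
        standardize=False,
    )
    out = encode_scpsednc("ACGUCA", lam=2, weight=0.5, table=table)
    assert len(out) == 16 + 2
    ac_index = oracles.DINUCLEOTIDES.index("AC")
    assert out[ac_index] == pytest.approx(12 / 425, abs=1e-12)
    assert out[16] == pytest.approx(8 / 17, abs=1e-12)
    assert out[17] == pytest.approx(33 / 85, abs=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_encoders_match_naive_oracles(seed):
    """Vectorized encoders equal plain-loop re-derivations on random input."""
    rng = np.random.default_rng(seed)
    table = DinucleotidePropertyTable.default()
    prop = {d: list(table.values[d]) for d in oracles.DINUCLEOTIDES}
    for _ in range(25):
        seq = random_segment(rng).sequence
        assert np.allclose(encode_enac(seq, 5), oracles.oracle_enac(seq, 5), atol=1e-12)
        assert np.allclose(
            encode_cksnap(seq, 5), oracles.oracle_cksnap(seq, 5), atol=1e-12
        )
        assert np.allclose(encode_anf(seq), oracles.oracle_anf(seq), atol=1e-12)
        assert np.allclose(encode_ncp(seq), oracles.oracle_ncp(seq), atol=1e-12)
        assert np.allclose(encode_binary(seq), oracles.oracle_binary(seq), atol=1e-12)
        assert np.allclose(
            encode_scpsednc(seq, 20, 0.9, table),
            oracles.oracle_scpsednc(seq, 20, 0.9, prop),
            atol=1e-12,
        )


def test_normalization_invariants():
    rng = np.random.default_rng(12)
    for _ in range(50):
        seq = random_segment(rng).sequence
        assert np.allclose(encode_enac(seq).reshape(-1, 4).sum(axis=1), 1.0)
        assert np.allclose(encode_cksnap(seq).reshape(6, 16).sum(axis=1), 1.0)
        assert np.allclose(encode_scpsednc(seq).sum(), 1.0, atol=1e-9)
        assert np.allclose(encode_binary(seq).reshape(-1, 4).sum(axis=1), 1.0)
        anf = encode_anf(seq)
        assert np.all((anf > 0) & (anf <= 1))


@st.composite
def segments_41nt(draw):
    chars = draw(
        st.lists(st.sampled_from("ACGU"), min_size=41, max_size=41)
    )
    chars[20] = "C"
    return "".join(chars)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(segments_41nt())
def test_normalization_invariants_hold_for_any_segment(seq):
    assert np.allclose(encode_enac(seq).reshape(-1, 4).sum(axis=1), 1.0)
    assert np.allclose(encode_cksnap(seq).reshape(6, 16).sum(axis=1), 1.0)
    assert np.allclose(encode_scpsednc(seq).sum(), 1.0, atol=1e-9)
    anf = encode_anf(seq)
    assert np.all((anf > 0) & (anf <= 1))
    ncp = encode_ncp(seq)
    assert set(np.unique(ncp)) <= {0.0, 1.0}


def test_encode_all_canonical_layout(small_matrix):
    assert small_matrix.data.shape[1] == 808
    sizes = {
        b: stop - start for b, (start, stop) in small_matrix.block_map.items()
    }
    assert sizes == BLOCK_DIMS
    assert list(small_matrix.block_map) == list(BLOCK_DIMS)
    assert len(set(small_matrix.names)) == 808


def test_encode_all_is_pure(small_labeled_set, small_embedding):
    cfg = EncoderConfig()
    first = encode_all(small_labeled_set, cfg, model=small_embedding)
    second = encode_all(small_labeled_set, cfg, model=small_embedding)
    pd.testing.assert_frame_equal(first.data, second.data)


def test_encode_all_block_subset(small_labeled_set):
    cfg = EncoderConfig(blocks=("ENAC", "CKSNAP", "ANF", "NCP", "BIN", "SCPDNC"))
    fm = encode_all(small_labeled_set, cfg)
    assert fm.data.shape[1] == 708
    assert "W2V" not in fm.block_map


def test_encode_all_requires_embedding_for_w2v(small_labeled_set):
    with pytest.raises(ValueError, match="W2V"):
        encode_all(small_labeled_set, EncoderConfig())


def test_feature_matrix_csv_round_trip(small_matrix, tmp_path):
    path = small_matrix.to_csv(tmp_path / "features.csv")
    back = FeatureMatrix.from_csv(path)
    assert back.names == small_matrix.names
    assert back.block_map == small_matrix.block_map
    assert np.allclose(back.values, small_matrix.values)
    assert (back.labels == small_matrix.labels).all()


def test_embedding_determinism_and_shape(small_labeled_set):
    cfg = EncoderConfig(embed_epochs=3)
    first = train_embedding(small_labeled_set, cfg, seed=5)
    second = train_embedding(small_labeled_set, cfg, seed=5)
    assert first.vectors.shape[1] == 100
    assert np.array_equal(first.vectors, second.vectors)
    assert first.vocab == second.vocab
    other_seed = train_embedding(small_labeled_set, cfg, seed=6)
    assert not np.array_equal(first.vectors, other_seed.vectors)


def test_embedding_disjoint_corpora_disjoint_vocab():
    a = train_cbow([tokenize("A" * 12, 3)], dim=8, epochs=1, seed=0)
    g = train_cbow([tokenize("G" * 12, 3)], dim=8, epochs=1, seed=0)
    assert set(a.vocab).isdisjoint(g.vocab)


def test_word2vec_encoding_is_token_mean(small_labeled_set, small_embedding):
    seq = small_labeled_set[0].sequence
    vec = encode_word2vec(seq, small_embedding)
    assert vec.shape == (100,)
    assert np.allclose(vec, oracles.oracle_word2vec(seq, small_embedding), atol=1e-12)
    # a sequence over a single token has that token's exact vector
    mono = "A" * 10
    tok_vec = small_embedding.vector("AAA")
    assert np.allclose(encode_word2vec(mono, small_embedding), tok_vec)


def test_word2vec_oov_contributes_zero():
    model = train_cbow([tokenize("A" * 12, 3)], dim=8, epochs=1, seed=0)
    assert set(model.vocab) == {"AAA"}
    # AAAG tokenizes to AAA, AAG; the OOV token adds a zero vector but still
    # counts in the mean's denominator
    assert np.allclose(model.encode("AAAG"), model.vector("AAA") / 2)


def test_feature_names_stable(small_matrix):
    names = feature_names(EncoderConfig())
    flat = [n for block in names.values() for n in block]
    assert flat == small_matrix.names
    assert names["ENAC"][:4] == [
        "ENAC_win1_A",
        "ENAC_win1_C",
        "ENAC_win1_G",
        "ENAC_win1_U",
    ]
    assert names["CKSNAP"][0] == "CKSNAP_k0_AA"
    assert names["BIN"][-1] == "BIN_p41_U"
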