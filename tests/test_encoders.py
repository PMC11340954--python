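import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stackpep import tables
from stackpep.encoders import (
    EncodingError, encode_aaindex, encode_binary, encode_blosum62,
    encode_cksaap, encode_ctd, encode_ctriad, encode_eaac, encode_gaac_family,
    encode_kmer, encode_paac, encode_zscale, encoding_dimensions,
    kmer_feature_names, make_encoder,
)

SEQS = st.text(alphabet=tables.ALPHABET, min_size=6, max_size=30)


class TestKmer:
    def test_dimer_homopolymer(self):
        v = encode_kmer("AAA", 2)
        assert v[0] == 1.0 and v.sum() == 1.0 and v.size == 400

    def test_trimer_hand_enumeration(self):
        v = encode_kmer("ACDG", 3)
        names = kmer_feature_names(3)
        nz = {names[i]: x for i, x in enumerate(v) if x}
        assert nz == {"ACD": 0.5, "CDG": 0.5}

    @pytest.mark.parametrize("k,dim", [(1, 20), (2, 400), (3, 8000)])
    def test_dimensions(self, k, dim):
        assert encode_kmer("ACDEFGH", k).size == dim

    def test_too_short(self):
        with pytest.raises(EncodingError):
            encode_kmer("AC", 3)

    @settings(deadline=None, derandomize=True)
    @given(SEQS)
    def test_normalised_and_order_invariant_aac(self, seq):
        v = encode_kmer(seq, 1)
        assert np.isclose(v.sum(), 1.0)
        shuffled = "".join(sorted(seq))
        assert np.allclose(v, encode_kmer(shuffled, 1))


class TestCksaap:
    def test_hand_enumeration_ACA(self):
        v = encode_cksaap("ACA", k_max=1)
        names = kmer_feature_names(2)
        g0 = {names[i]: x for i, x in enumerate(v[:400]) if x}
        g1 = {names[i]: x for i, x in enumerate(v[400:]) if x}
        assert g0 == {"AC": 0.5, "CA": 0.5}
        assert g1 == {"AA": 1.0}

    @settings(deadline=None, derandomize=True)
    @given(SEQS)
    def test_gap0_block_equals_dpc(self, seq):
        assert np.allclose(encode_cksaap(seq)[:400], encode_kmer(seq, 2))

    def test_default_dimension(self):
        assert encode_cksaap("ACDEFGHIK").size == 2400

    def test_short_sequence_zero_block_with_warning(self):
        with pytest.warns(UserWarning, match="zero block"):
            v = encode_cksaap("ACD", k_max=5)
        assert v[400 * 2:].sum() == 0  # gaps 2..5 unpopulated

    @settings(deadline=None, derandomize=True)
    @given(SEQS)
    def test_populated_blocks_sum_to_one(self, seq):
        v = encode_cksaap(seq, k_max=3)
        for g in range(4):
            if len(seq) >= g + 2:
                assert np.isclose(v[400 * g:400 * (g + 1)].sum(), 1.0)


class TestGrouped:
    def test_gaac_single_group(self):
        v = encode_gaac_family("GGGG", 1)
        assert v[0] == 1.0  # G is aliphatic (g1)

    def test_gaac_two_groups(self):
        v = encode_gaac_family("KD", 1)
        assert v[2] == 0.5 and v[3] == 0.5  # K positive (g3), D negative (g4)

    def test_gdpc_transitions_hand_enumeration(self):
        v = encode_gaac_family("KDKD", 2)
        # grouped dimers: g3g4, g4g3, g3g4 over 3 positions
        assert np.isclose(v[2 * 5 + 3], 2 / 3)
        assert np.isclose(v[3 * 5 + 2], 1 / 3)

    @pytest.mark.parametrize("order,dim", [(1, 5), (2, 25), (3, 125)])
    def test_dimensions(self, order, dim):
        assert encode_gaac_family("ACDEFG", order).size == dim

    @settings(deadline=None, derandomize=True)
    @given(SEQS)
    def test_normalised(self, seq):
        for order in (1, 2, 3):
            assert np.isclose(encode_gaac_family(seq, order).sum(), 1.0)

    def test_groups_partition_alphabet(self):
        groups = tables.gaac_groups()
        assert groups["g1"] == "GAVLMI" and groups["g2"] == "FYW"
        assert sorted("".join(groups.values())) == sorted(tables.ALPHABET)


class TestCTriad:
    def test_homotriad(self):
        v = encode_ctriad("AAA")
        assert v.size == 343 and v.max() == 1.0 and v.sum() == 1.0

    def test_two_triads_hand_enumeration(self):
        v = encode_ctriad("AVKR")  # triads AVK, VKR
        gmap, names = tables.ctriad_map(), sorted(tables.ctriad_groups())
        gi = {g: i for i, g in enumerate(names)}
        def code(t):
            a, b, c = (gi[gmap[x]] for x in t)
            return a * 49 + b * 7 + c
        assert v[code("AVK")] == 0.5 and v[code("VKR")] == 0.5

    @settings(deadline=None, derandomize=True)
    @given(SEQS)
    def test_normalised(self, seq):
        assert np.isclose(encode_ctriad(seq).sum(), 1.0)

    def test_too_short(self):
        with pytest.raises(EncodingError):
            encode_ctriad("AC")


class TestCTD:
    def test_homopolymer_no_transitions(self):
        assert encode_ctd("AAAAA", "T").sum() == 0.0

    def test_homopolymer_composition_one_group_per_property(self):
        v = encode_ctd("AAAAA", "C").reshape(13, 3)
        assert (v.sum(axis=1) == 1.0).all()
        assert (v.max(axis=1) == 1.0).all()

    def test_composition_vector_sums_to_13(self):
        assert np.isclose(encode_ctd("ACDEFGHIKLMNPQRSTVWY", "C").sum(), 13.0)

    def test_distribution_hand_computed_positions(self):
        # polarity groups: C in g1, A in g2; ACACA -> C at 2,4; A at 1,3,5
        v = encode_ctd("ACACA", "D")
        prop_idx = list(tables.ctd_properties()).index("polarity")
        block = v[prop_idx * 15:(prop_idx + 1) * 15]
        assert np.allclose(block[0:5], [40, 40, 40, 40, 80])   # g1 = C
        assert np.allclose(block[5:10], [20, 20, 20, 60, 100])  # g2 = A
        assert np.allclose(block[10:15], 0.0)                   # g3 absent

    @pytest.mark.parametrize("part,dim", [("C", 39), ("T", 39), ("D", 195)])
    def test_dimensions(self, part, dim):
        assert encode_ctd("ACDEFGHIK", part).size == dim

    def test_transition_needs_two_residues(self):
        with pytest.raises(EncodingError):
            encode_ctd("A", "T")


class TestPAAC:
    def test_dimension(self):
        assert encode_paac("ACDEFGHIK", lam=5).size == 25

    def test_lambda_zero_reduces_to_aac(self):
        assert np.allclose(encode_paac("ACDEFGHIK", lam=0),
                           encode_kmer("ACDEFGHIK", 1))

    def test_rank1_correlation_brute_force(self):
        seq = "ACDEFG"
        props = tables.paac_properties().to_numpy()
        props = (props - props.mean(0)) / props.std(0)
        idx = {aa: i for i, aa in enumerate(tables.ALPHABET)}
        theta1 = np.mean([np.mean((props[idx[seq[i + 1]]]
                                   - props[idx[seq[i]]]) ** 2)
                          for i in range(5)])
        v = encode_paac(seq, lam=1, w=0.05)
        denom = 1 + 0.05 * theta1
        assert np.isclose(v[-1], 0.05 * theta1 / denom)
        assert np.isclose(v.sum(), (1 + 0.05 * theta1) / denom)

    def test_too_short(self):
        with pytest.raises(EncodingError):
            encode_paac("ACD", lam=5)


class TestPositional:
    def test_binary_single_residues(self):
        a = encode_binary("A", 1)
        assert a[0] == 1 and a[1:].sum() == 0
        y = encode_binary("Y", 1)
        assert y[-1] == 1 and y[:-1].sum() == 0

    def test_binary_padding(self):
        v = encode_binary("AC", 4).reshape(4, 20)
        assert v[0][0] == 1 and v[1][1] == 1
        assert v[2:].sum() == 0

    def test_binary_too_long(self):
        with pytest.raises(EncodingError):
            encode_binary("ACDEF", 3)

    def test_blosum62_row_and_symmetry(self):
        m = tables.blosum62()
        v = encode_blosum62("A", 1)
        assert v[0] == 4.0  # published A self-score
        assert np.allclose(v, m.loc["A"])
        assert np.allclose(m.to_numpy(), m.to_numpy().T)

    def test_blosum62_padding(self):
        assert encode_blosum62("AC", 3)[40:].sum() == 0

    def test_zscale_published_values(self):
        assert np.allclose(encode_zscale("A", 1),
                           [0.24, -2.32, 0.60, -0.14, 1.30])
        assert encode_zscale("ACD", 25).size == 125
        assert encode_zscale("ACD", 25)[15:].sum() == 0

    def test_eaac_single_window(self):
        v = encode_eaac("AAAAA", window=5, L_max=5)
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_eaac_counts(self):
        v = encode_eaac("AAAAC", window=5, L_max=5)
        assert v[0] == 4 / 5 and v[1] == 1 / 5

    def test_eaac_dimension(self):
        assert encode_eaac("ACDEFGHIKL", window=5, L_max=10).size == 120

    def test_eaac_too_short(self):
        with pytest.raises(EncodingError):
            encode_eaac("ACD", window=5)


class TestAAindex:
    def test_homopolymer_gives_column(self):
        table = tables.aaindex_snapshot()
        assert np.allclose(encode_aaindex("AAAA"), table["A"])

    def test_mean_of_two(self):
        table = tables.aaindex_snapshot()
        assert np.allclose(encode_aaindex("AC"),
                           (table["A"] + table["C"]) / 2)

    def test_dimension_follows_table(self):
        mini = tables.aaindex_snapshot().iloc[:3]
        assert encode_aaindex("ACD", table=mini).size == 3


def test_printed_dimensionality_table():
    assert encoding_dimensions() == {
        "AAC": 20, "DPC": 400, "TPC": 8000, "PAAC": 25, "CKSAAP": 2400,
        "GAAC": 5, "GDPC": 25, "GTPC": 125, "CTriad": 343,
        "CTDC": 39, "CTDT": 39, "CTDD": 195,
    }


def test_padded_encoder_learns_lmax(random_peptides):
    enc = make_encoder("BE")
    fm = enc.fit_transform(random_peptides)
    assert fm.n_features == 20 * max(len(s) for s in random_peptides)


def test_encoders_deterministic(random_peptides):
    for name in ("AAC", "CKSAAP", "CTDD", "PAAC", "ZSCALE"):
        enc1 = make_encoder(name).fit(random_peptides)
        enc2 = make_encoder(name).fit(random_peptides)
        assert np.array_equal(enc1.transform(random_peptides).values,
                              enc2.transform(random_peptides).values)
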