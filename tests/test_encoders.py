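import numpy as np
import pytest

import oracles
from nmstack import encoders as enc
from nmstack.encoders import (
    BpbProfile,
    EncoderError,
    PseKncSpec,
    bpb_encode,
    bpb_fit,
    encoder_registry,
    get_encoder,
    npps_encode,
    npps_fit,
    profile_from_json,
    profile_to_json,
    pseknc_encode,
    w2v_encode,
    w2v_fit,
)

SEQ41 = "ACGUA" * 8 + "C"

# dimensions at L=41 with default parameters
EXPECTED_DIMS = {
    "Binary": 164, "ENAC": 148, "NCP": 123, "ANF": 41, "EIIP": 64,
    "DNC": 16, "TNC": 64, "CKSNAP": 96, "RCKmer": 10, "PseEIIP": 64,
    "BPB": 82, "CTD": 30, "Kmer": 256, "NCP-ND": 164, "NPS": 64,
    "NPPS": 40, "PseKNC": 18, "W2V": 64,
}


@pytest.fixture(scope="module")
def fitted_states(request):
    rng = np.random.default_rng(11)
    pos = ["".join(rng.choice(list("ACGU"), size=41)) for _ in range(20)]
    neg = ["".join(rng.choice(list("ACGU"), size=41)) for _ in range(20)]
    return {
        "BPB": bpb_fit(pos, neg),
        "NPPS": npps_fit(pos, neg),
        "W2V": w2v_fit(pos + neg, epochs=1, seed=5),
    }


class TestRegistry:
    def test_eighteen_unique_ids(self):
        reg = encoder_registry()
        assert len(reg) == 18
        assert len({e.id for e in reg}) == 18

    def test_exactly_three_fit_dependent(self):
        fitdep = [e.id for e in encoder_registry() if e.requires_fit]
        assert sorted(fitdep) == ["BPB", "NPPS", "W2V"]

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            get_encoder("PseFNORD")


class TestDimensions:
    @pytest.mark.parametrize("encoder_id", sorted(EXPECTED_DIMS))
    def test_default_dims_at_41(self, encoder_id, fitted_states):
        spec = get_encoder(encoder_id)
        state = fitted_states.get(encoder_id)
        fv = spec.transform(SEQ41, state) if spec.requires_fit else spec.transform(SEQ41)
        assert len(fv) == EXPECTED_DIMS[encoder_id]

    def test_dims_derive_from_length(self):
        # a shorter window shrinks positional encoders accordingly
        seq = "ACGUACGUACG"  # L = 11
        assert len(enc.binary_encode(seq)) == 44
        assert len(enc.enac_encode(seq)) == 4 * 7
        assert len(enc.anf_encode(seq)) == 11


class TestFrozenExamples:
    """Hand-verified single-sequence values."""

    def test_binary_single_nucleotides(self):
        np.testing.assert_array_equal(enc.binary_encode("A").values, [1, 0, 0, 0])
        np.testing.assert_array_equal(
            enc.binary_encode("ACGU").values, np.eye(4).ravel()
        )

    def test_ncp_triples(self):
        np.testing.assert_array_equal(enc.ncp_encode("A").values, [1, 1, 1])
        np.testing.assert_array_equal(enc.ncp_encode("C").values, [0, 1, 0])
        np.testing.assert_array_equal(enc.ncp_encode("G").values, [1, 0, 0])
        np.testing.assert_array_equal(enc.ncp_encode("U").values, [0, 0, 1])

    def test_enac_first_window_hand_count(self):
        fv = enc.enac_encode("ACGUA" + "C" * 36, window=5)
        np.testing.assert_allclose(fv.values[:4], [0.4, 0.2, 0.2, 0.2])

    def test_enac_homopolymer_window(self):
        fv = enc.enac_encode("AAAAA", window=5)
        np.testing.assert_allclose(fv.values, [1, 0, 0, 0])

    def test_anf_hand_values(self):
        np.testing.assert_allclose(enc.anf_encode("AAAA").values, [1, 1, 1, 1])
        np.testing.assert_allclose(
            enc.anf_encode("ACGU").values, [1, 0.5, 1 / 3, 0.25]
        )

    def test_eiip_homopolymers(self):
        fv = enc.eiip_encode("AAA")
        assert fv.names[0] == "EIIP_AAA"
        np.testing.assert_allclose(fv.values[0], 0.378)
        assert np.count_nonzero(fv.values) == 1
        fv = enc.eiip_encode("GGG")
        np.testing.assert_allclose(fv.values[fv.names.index("EIIP_GGG")], 0.2418)

    def test_pse_eiip_is_one_third_of_eiip(self):
        fv = enc.pse_eiip_encode("AAA")
        np.testing.assert_allclose(fv.values[0], 0.1260)
        seq = SEQ41
        np.testing.assert_allclose(
            enc.pse_eiip_encode(seq).values, enc.eiip_encode(seq).values / 3.0
        )

    def test_dnc_hand_counts(self):
        fv = enc.dnc_encode("AACG")
        vals = dict(zip(fv.names, fv.values))
        assert vals["DNC_AA"] == vals["DNC_AC"] == vals["DNC_CG"] == pytest.approx(1 / 3)
        np.testing.assert_allclose(
            enc.dnc_encode("AAAA").values[0], 1.0
        )

    def test_tnc_hand_counts(self):
        fv = enc.tnc_encode("ACGUA")
        vals = dict(zip(fv.names, fv.values))
        for m in ("ACG", "CGU", "GUA"):
            assert vals[f"TNC_{m}"] == pytest.approx(1 / 3)
        assert enc.tnc_encode("AAAA").values[0] == 1.0

    def test_cksnap_hand_counts(self):
        fv = enc.cksnap_encode("ACGU", gaps=(0,))
        vals = dict(zip(fv.names, fv.values))
        assert vals["gap0_AC"] == vals["gap0_CG"] == vals["gap0_GU"] == pytest.approx(1 / 3)
        fv = enc.cksnap_encode("AAA", gaps=(1,))
        vals = dict(zip(fv.names, fv.values))
        assert vals["gap1_AA"] == 1.0
        assert sum(fv.values) == pytest.approx(1.0)

    def test_rckmer_canonicalization(self):
        assert enc.canonical_kmer("UU") == "AA"
        fv = enc.rckmer_encode("UU", k=2)
        vals = dict(zip(fv.names, fv.values))
        assert vals["RCKmer_AA"] == 1.0
        fv = enc.rckmer_encode("AAUU", k=2)
        vals = dict(zip(fv.names, fv.values))
        assert vals["RCKmer_AA"] == pytest.approx(2 / 3)
        assert vals["RCKmer_AU"] == pytest.approx(1 / 3)

    def test_kmer_dims(self):
        assert len(enc.kmer_encode("ACGUACGU", k=2)) == 16
        assert enc.kmer_encode("AAAA", k=2).values[0] == 1.0

    def test_ctd_homopolymer(self):
        fv = enc.ctd_encode("AAAA")
        vals = dict(zip(fv.names, fv.values))
        assert vals["comp_A"] == 1.0
        assert all(vals[n] == 0.0 for n in fv.names if n.startswith("trans"))

    def test_ncp_nd_hand_values(self):
        fv = enc.ncp_nd_encode("ACGU")
        np.testing.assert_allclose(fv.values[:4], [1, 1, 1, 1.0])
        np.testing.assert_allclose(fv.values[4:8], [0, 1, 0, 0.5])

    def test_ncp_nd_homopolymer_density(self):
        fv = enc.ncp_nd_encode("GGGGG")
        assert all(fv.values[3::4] == 1.0)

    def test_nps_adjacent_block(self):
        fv = enc.nps_encode("AAA", d_max=1)
        vals = dict(zip(fv.names, fv.values))
        assert vals["k0_AA"] == 1.0
        assert vals["k1_AA"] == 1.0


class TestNormalizationInvariants:
    @pytest.mark.parametrize("L", [5, 17, 41])
    def test_frequency_encoders_sum_to_one(self, make_seq, L):
        seq = make_seq(L)
        assert enc.dnc_encode(seq).values.sum() == pytest.approx(1.0)
        assert enc.tnc_encode(seq).values.sum() == pytest.approx(1.0)
        assert enc.kmer_encode(seq, k=2).values.sum() == pytest.approx(1.0)
        assert enc.rckmer_encode(seq).values.sum() == pytest.approx(1.0)

    def test_block_normalization(self, make_seq):
        seq = make_seq(41)
        cks = enc.cksnap_encode(seq).values.reshape(6, 16)
        np.testing.assert_allclose(cks.sum(axis=1), 1.0)
        nps = enc.nps_encode(seq).values.reshape(4, 16)
        np.testing.assert_allclose(nps.sum(axis=1), 1.0)
        enac = enc.enac_encode(seq).values.reshape(-1, 4)
        np.testing.assert_allclose(enac.sum(axis=1), 1.0)


class TestPositionSensitivity:
    def test_positional_encoders_see_a_transposition(self):
        s1 = "AAC" + "G" * 38
        s2 = "ACA" + "G" * 38  # same composition, positions 2-3 swapped
        for fn in (enc.binary_encode, enc.ncp_encode, enc.anf_encode,
                   enc.enac_encode, enc.ncp_nd_encode):
            assert not np.array_equal(fn(s1).values, fn(s2).values), fn.__name__

    def test_dnc_invariant_under_dinucleotide_multiset_preserving_permutation(self):
        # AACGCA and ACGCAA share the same multiset of adjacent pairs
        np.testing.assert_allclose(
            enc.dnc_encode("AACGCA").values, enc.dnc_encode("ACGCAA").values
        )

    def test_rckmer_invariant_under_reverse_complement(self, make_seq):
        seq = make_seq(41)
        np.testing.assert_allclose(
            enc.rckmer_encode(seq).values,
            enc.rckmer_encode(enc.reverse_complement(seq)).values,
        )

    def test_composition_block_shuffle_invariant(self, rng, make_seq):
        seq = make_seq(41)
        shuffled = "".join(rng.permutation(list(seq)))
        np.testing.assert_allclose(
            enc.ctd_encode(seq).values[:4], enc.ctd_encode(shuffled).values[:4]
        )


class TestBpb:
    def test_degenerate_column(self):
        prof = bpb_fit(["AAA", "AAA"], ["CCC"], pseudocount=0.0)
        assert prof.pos_matrix[0, 2] == 1.0  # all-A positives at position 3

    def test_smoothed_frequency_hand_value(self):
        prof = bpb_fit(["AC"], ["GG"], pseudocount=0.25)
        assert prof.pos_matrix[0, 0] == pytest.approx((1 + 0.25) / (1 + 1))

    def test_columns_sum_to_one(self, rng):
        pos = ["".join(rng.choice(list("ACGU"), size=9)) for _ in range(7)]
        neg = ["".join(rng.choice(list("ACGU"), size=9)) for _ in range(5)]
        prof = bpb_fit(pos, neg, pseudocount=0.25)
        np.testing.assert_allclose(prof.pos_matrix.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(prof.neg_matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_symmetric_profiles_give_equal_halves(self, make_seq):
        seqs = [make_seq(11) for _ in range(4)]
        prof = bpb_fit(seqs, seqs)
        fv = bpb_encode(make_seq(11), prof)
        np.testing.assert_allclose(fv.values[:11], fv.values[11:])

    def test_class_separated_training_positive_scores_higher(self):
        # positives deterministically A at position 1; negatives C
        pos = ["A" + "G" * 8] * 5
        neg = ["C" + "G" * 8] * 5
        prof = bpb_fit(pos, neg, pseudocount=0.25)
        fv = bpb_encode(pos[0], prof)
        assert fv.values[0] > fv.values[9]  # p+_1 > p-_1

    def test_empty_class_errors(self):
        with pytest.raises(EncoderError):
            bpb_fit([], ["AC"])

    def test_length_mismatch_errors(self):
        prof = bpb_fit(["ACGUA"], ["GGGGG"])
        with pytest.raises(EncoderError):
            bpb_encode("ACG", prof)


class TestNpps:
    def test_dims(self, fitted_states):
        fv = npps_encode(SEQ41, fitted_states["NPPS"])
        assert len(fv) == 40

    def test_identical_profiles_zero_vector(self, make_seq):
        seqs = [make_seq(9) for _ in range(6)]
        prof = npps_fit(seqs, seqs)
        fv = npps_encode(make_seq(9), prof)
        np.testing.assert_allclose(fv.values, 0.0, atol=1e-12)

    def test_degenerate_pair_probability(self):
        prof = npps_fit(["AG"], ["CC"], k=0, pseudocount=0.0)
        # positives all AG at position 1
        assert prof.fd_pos[4 * 0 + 2, 0] == 1.0

    def test_two_sequence_frequency(self):
        prof = npps_fit(["AC", "AG"], ["UU"], k=0, pseudocount=0.0)
        assert prof.fd_pos[1, 0] == 0.5  # AC at position 1

    def test_hand_toy_value(self):
        # pos {AC, AA}, neg {AG}, pc=0.25, seq AC:
        # p+ = ((1+.25)/(2+4)) / ((1+.25)/(2+1)) = 0.5
        # p- = ((0+.25)/(1+4)) / ((0+.25)/(1+1)) = 0.4
        prof = npps_fit(["AC", "AA"], ["AG"], k=0, pseudocount=0.25)
        fv = npps_encode("AC", prof)
        np.testing.assert_allclose(fv.values, [0.5 - 0.4])

    def test_zero_pseudocount_division_guidance(self):
        prof = npps_fit(["AA"], ["CC"], k=0, pseudocount=0.0)
        with pytest.raises(EncoderError, match="pseudocount"):
            npps_encode("AC", prof)

    def test_column_normalization(self, rng):
        pos = ["".join(rng.choice(list("ACGU"), size=9)) for _ in range(8)]
        neg = ["".join(rng.choice(list("ACGU"), size=9)) for _ in range(8)]
        prof = npps_fit(pos, neg, pseudocount=0.25)
        for mat in (prof.fs_pos, prof.fs_neg, prof.fd_pos, prof.fd_neg):
            np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-9)


class TestPseKnc:
    def test_dims(self):
        assert len(pseknc_encode(SEQ41)) == 18

    def test_homopolymer_theta_zero(self):
        fv = pseknc_encode("A" * 20)
        # all dinucleotides identical -> every correlation tier is 0
        np.testing.assert_allclose(fv.values[16:], 0.0, atol=1e-12)
        np.testing.assert_allclose(fv.values[:16].sum(), 1.0)

    def test_unstandardized_table_rejected(self):
        props = {"flat": {d: 1.0 for d in enc.kmer_list(2)}}
        with pytest.raises(EncoderError, match="standardized"):
            PseKncSpec(props=props)

    def test_lambda_bound(self):
        with pytest.raises(EncoderError):
            pseknc_encode("ACG", PseKncSpec(lam=2))


class TestW2v:
    def test_deterministic_given_seed(self, make_seq):
        corpus = [make_seq(21) for _ in range(8)]
        m1 = w2v_fit(corpus, epochs=1, seed=9)
        m2 = w2v_fit(corpus, epochs=1, seed=9)
        for tok in m1.table:
            np.testing.assert_array_equal(m1.table[tok], m2.table[tok])

    def test_vector_lengths(self, fitted_states):
        model = fitted_states["W2V"]
        assert all(v.shape == (64,) for v in model.table.values())
        assert len(w2v_encode(SEQ41, model)) == 64

    def test_single_token_sequence_equals_its_vector(self, fitted_states):
        model = fitted_states["W2V"]
        tok = next(iter(model.table))
        fv = w2v_encode(tok, model)  # L=3 -> one token
        np.testing.assert_allclose(fv.values, model.table[tok])

    def test_single_token_corpus_trains_finite(self):
        model = w2v_fit(["ACG"], epochs=1, seed=0)
        assert np.all(np.isfinite(model.table["ACG"]))

    def test_empty_corpus_errors(self):
        with pytest.raises(EncoderError):
            w2v_fit([])

    def test_oov_token_maps_to_zero(self):
        model = w2v_fit(["AAAA"], epochs=1, seed=0)
        fv = w2v_encode("CCC", model)
        np.testing.assert_allclose(fv.values, 0.0)


class TestProfileSerialization:
    @pytest.mark.parametrize("kind", ["BPB", "NPPS", "W2V"])
    def test_round_trip(self, kind, fitted_states):
        state = fitted_states[kind]
        back = profile_from_json(profile_to_json(state))
        spec = get_encoder(kind)
        np.testing.assert_allclose(
            spec.transform(SEQ41, state).values,
            spec.transform(SEQ41, back).values,
        )


class TestOracleSpotChecks:
    """Brute-force equivalence on a handful of sequences (the exhaustive
    sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("L", [5, 12, 41])
    def test_stateless_match_naive_counting(self, make_seq, L):
        seq = make_seq(L)
        gaps = tuple(range(min(5, L - 2) + 1))
        checks = [
            (enc.binary_encode(seq), oracles.binary(seq)),
            (enc.enac_encode(seq), oracles.enac(seq)),
            (enc.ncp_encode(seq), oracles.ncp(seq)),
            (enc.anf_encode(seq), oracles.anf(seq)),
            (enc.eiip_encode(seq), oracles.eiip(seq)),
            (enc.dnc_encode(seq), oracles.kmer_freq(seq, 2)),
            (enc.tnc_encode(seq), oracles.kmer_freq(seq, 3)),
            (enc.cksnap_encode(seq, gaps=gaps), oracles.cksnap(seq, gaps)),
            (enc.rckmer_encode(seq), oracles.rckmer(seq)),
            (enc.pse_eiip_encode(seq), oracles.pse_eiip(seq)),
            (enc.ctd_encode(seq), oracles.ctd(seq)),
            (enc.kmer_encode(seq, k=4), oracles.kmer_freq(seq, 4)),
            (enc.ncp_nd_encode(seq), oracles.ncp_nd(seq)),
            (enc.nps_encode(seq), oracles.nps(seq)),
        ]
        for fv, expected in checks:
            np.testing.assert_allclose(
                fv.values, expected, atol=1e-12, err_msg=fv.encoder_id
            )
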