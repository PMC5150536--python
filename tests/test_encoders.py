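"""Encoder correctness: hand-counted examples, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerkit.encoders import (
    FeatureMatrix,
    NC_FEATURE_NAMES,
    BPBModel,
    bpb_feature_names,
    encode_bpb,
    encode_dataset,
    encode_nc,
    encode_psenc,
    fit_bpb,
)
from enhancerkit.sequence_io import (
    NEGATIVE,
    POSITIVE,
    SequenceRecord,
    validate_dataset,
)

from conftest import (
    naive_bpb_encode,
    naive_bpb_profiles,
    naive_nc,
    naive_psenc,
    random_records,
)

dna = st.text(alphabet="ACGT", min_size=3, max_size=12)


class TestFitBpb:
    def test_hand_counted_profiles(self, toy_bpb_records):
        pos, neg = toy_bpb_records
        model = fit_bpb(pos, neg)
        # position 2 of the positives: C twice, T once
        np.testing.assert_allclose(model.pos_freq[:, 1], [0, 2 / 3, 0, 1 / 3])
        # position 1 of the negatives: always T
        np.testing.assert_allclose(model.neg_freq[:, 0], [0, 0, 0, 1])

    def test_singleton_class_gives_indicator_columns(self):
        pos = [SequenceRecord("p", "ACGT", POSITIVE)]
        neg = [SequenceRecord("n", "TTTT", NEGATIVE)]
        model = fit_bpb(pos, neg)
        assert set(np.unique(model.pos_freq)) == {0.0, 1.0}
        assert (model.pos_freq.sum(axis=0) == 1).all()

    def test_identical_positives_match_their_sequence(self):
        pos = [SequenceRecord(f"p{i}", "GGCA", POSITIVE) for i in range(5)]
        neg = [SequenceRecord("n", "TTTT", NEGATIVE)]
        model = fit_bpb(pos, neg)
        rec = SequenceRecord("q", "GGCA", POSITIVE)
        np.testing.assert_array_equal(encode_bpb(model, rec)[:4], np.ones(4))

    def test_empty_class_rejected(self, toy_bpb_records):
        pos, _ = toy_bpb_records
        with pytest.raises(ValueError, match="non-empty"):
            fit_bpb(pos, [])

    def test_length_mismatch_rejected(self, toy_bpb_records):
        pos, neg = toy_bpb_records
        with pytest.raises(ValueError, match="length"):
            fit_bpb(pos + [SequenceRecord("px", "ACGT", POSITIVE)], neg, n=3)

    def test_column_stochastic(self, rng):
        pos = random_records(rng, 9, 40, POSITIVE)
        neg = random_records(rng, 7, 40, NEGATIVE)
        model = fit_bpb(pos, neg)
        np.testing.assert_allclose(model.pos_freq.sum(axis=0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(model.neg_freq.sum(axis=0), 1.0, rtol=1e-12)
        assert (model.pos_freq >= 0).all() and (model.pos_freq <= 1).all()

    def test_smoothing_removes_exact_zeros(self):
        pos = [SequenceRecord("p", "AAAA", POSITIVE)]
        neg = [SequenceRecord("n", "TTTT", NEGATIVE)]
        model = fit_bpb(pos, neg, alpha=1.0)
        assert (model.pos_freq > 0).all()
        np.testing.assert_allclose(model.pos_freq.sum(axis=0), 1.0)


class TestEncodeBpb:
    def test_toy_lookup(self, toy_bpb_records):
        pos, neg = toy_bpb_records
        model = fit_bpb(pos, neg)
        vec = encode_bpb(model, pos[0])  # ACG
        np.testing.assert_allclose(vec, [1.0, 2 / 3, 1.0, 0.0, 0.0, 0.0])

    def test_200bp_input_yields_400_features(self, rng):
        pos = random_records(rng, 4, 200, POSITIVE)
        neg = random_records(rng, 4, 200, NEGATIVE)
        model = fit_bpb(pos, neg)
        assert encode_bpb(model, pos[0]).shape == (400,)

    def test_training_member_first_half_positive(self, rng):
        pos = random_records(rng, 6, 25, POSITIVE)
        neg = random_records(rng, 6, 25, NEGATIVE)
        model = fit_bpb(pos, neg)
        for rec in pos:
            assert (encode_bpb(model, rec)[:25] > 0).all()

    def test_length_mismatch_rejected(self, toy_bpb_records):
        pos, neg = toy_bpb_records
        model = fit_bpb(pos, neg)
        with pytest.raises(ValueError, match="length"):
            encode_bpb(model, SequenceRecord("q", "ACGT", POSITIVE))

    def test_masked_position_looks_up_uniform(self, toy_bpb_records):
        pos, neg = toy_bpb_records
        model = fit_bpb(pos, neg)
        vec = encode_bpb(model, SequenceRecord("q", "ANG", POSITIVE))
        assert vec[1] == 0.25 and vec[4] == 0.25


class TestCompositionEncoders:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", [1, 0, 0, 0]),
            ("ACGT", [0.25, 0.25, 0.25, 0.25]),
            ("GGGG", [0, 0, 1, 0]),
        ],
    )
    def test_nc_examples(self, seq, expected):
        np.testing.assert_allclose(encode_nc(seq), expected)

    def test_nc_empty_rejected(self):
        with pytest.raises(ValueError):
            encode_nc("")

    def test_psenc_single_trimer_type(self):
        vec = encode_psenc("AAAA")
        assert vec[0] == 1.0 and vec.sum() == 1.0

    def test_psenc_three_windows(self):
        vec = encode_psenc("ACGTA")
        nonzero = {i: v for i, v in enumerate(vec) if v > 0}
        # ACG, CGT, GTA each once over 3 windows
        assert len(nonzero) == 3
        assert all(v == pytest.approx(1 / 3) for v in nonzero.values())

    def test_psenc_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than 3"):
            encode_psenc("AC")

    @given(dna)
    @settings(deadline=None, max_examples=60)
    def test_composition_vectors_sum_to_one(self, seq):
        assert encode_nc(seq).sum() == pytest.approx(1.0)
        vec = encode_psenc(seq)
        assert vec.shape == (64,)
        assert vec.sum() == pytest.approx(1.0)

    def test_masked_windows_excluded(self):
        # N kills the windows it touches; remaining windows renormalise
        vec = encode_psenc("AANAAA")
        assert vec[0] == 1.0  # only AAA windows remain
        nc = encode_nc("AANA")
        np.testing.assert_allclose(nc, [1, 0, 0, 0])


class TestOracleEquivalence:
    """All three encoders agree with naive character-scanning references."""

    def test_random_short_sequences(self, rng):
        for _ in range(25):
            length = int(rng.integers(3, 13))
            pos = random_records(rng, int(rng.integers(1, 6)), length, POSITIVE)
            neg = random_records(rng, int(rng.integers(1, 6)), length, NEGATIVE)
            model = fit_bpb(pos, neg)
            ref_pos, ref_neg = naive_bpb_profiles(
                [r.seq for r in pos], [r.seq for r in neg]
            )
            np.testing.assert_allclose(model.pos_freq, ref_pos, rtol=1e-12)
            np.testing.assert_allclose(model.neg_freq, ref_neg, rtol=1e-12)
            probe = random_records(rng, 1, length, POSITIVE)[0]
            np.testing.assert_allclose(
                encode_bpb(model, probe),
                naive_bpb_encode(ref_pos, ref_neg, probe.seq),
                rtol=1e-12,
            )
            np.testing.assert_allclose(
                encode_nc(probe), naive_nc(probe.seq), rtol=1e-12
            )
            np.testing.assert_allclose(
                encode_psenc(probe), naive_psenc(probe.seq), rtol=1e-12
            )


class TestEncodeDataset:
    def make_dataset(self, rng, n=200):
        recs = random_records(rng, 5, n, POSITIVE) + random_records(
            rng, 5, n, NEGATIVE
        )
        return validate_dataset(recs)

    def test_all_families_200bp_gives_468_columns(self, rng):
        ds = self.make_dataset(rng)
        recs, y = ds.layer1()
        pos = [r for r, v in zip(recs, y) if v > 0]
        neg = [r for r, v in zip(recs, y) if v < 0]
        matrix = encode_dataset(ds, bpb=fit_bpb(pos, neg))
        assert matrix.n_features == 400 + 4 + 64
        assert len(set(matrix.feature_names)) == 468

    def test_nc_only_columns(self, rng):
        ds = self.make_dataset(rng, n=20)
        matrix = encode_dataset(ds, families=["NC"])
        assert matrix.feature_names == ["NC_A", "NC_T", "NC_G", "NC_C"]

    def test_empty_family_set_rejected(self, rng):
        ds = self.make_dataset(rng, n=20)
        with pytest.raises(ValueError, match="at least one"):
            encode_dataset(ds, families=[])

    def test_bpb_without_model_rejected(self, rng):
        ds = self.make_dataset(rng, n=20)
        with pytest.raises(ValueError, match="BPBModel"):
            encode_dataset(ds, families=["BPB"])

    def test_permutation_equivariance(self, rng):
        ds = self.make_dataset(rng, n=30)
        perm = rng.permutation(len(ds.records))
        shuffled = validate_dataset([ds.records[i] for i in perm])
        m1 = encode_dataset(ds, families=["NC", "PseNC"])
        m2 = encode_dataset(shuffled, families=["NC", "PseNC"])
        np.testing.assert_allclose(m1.values[perm], m2.values)
        assert [m1.sample_ids[i] for i in perm] == m2.sample_ids


class TestSerialisation:
    def test_feature_matrix_tsv_round_trip(self, tmp_path, rng):
        values = rng.random((3, 4))
        m = FeatureMatrix(values, NC_FEATURE_NAMES, ["a", "b", "c"])
        m.to_tsv(tmp_path / "m.tsv")
        back = FeatureMatrix.from_tsv(tmp_path / "m.tsv")
        np.testing.assert_allclose(back.values, m.values)
        assert back.feature_names == m.feature_names
        assert back.sample_ids == m.sample_ids

    def test_bpb_model_tsv_round_trip(self, tmp_path, toy_bpb_records):
        pos, neg = toy_bpb_records
        model = fit_bpb(pos, neg)
        model.to_tsv(tmp_path / "bpb.tsv")
        back = BPBModel.from_tsv(tmp_path / "bpb.tsv")
        np.testing.assert_allclose(back.pos_freq, model.pos_freq)
        np.testing.assert_allclose(back.neg_freq, model.neg_freq)

    def test_feature_names_map_to_unique_origin(self):
        names = bpb_feature_names(3)
        assert names == [
            "BPB_pos_1",
            "BPB_pos_2",
            "BPB_pos_3",
            "BPB_neg_1",
            "BPB_neg_2",
            "BPB_neg_3",
        ]
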