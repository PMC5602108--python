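"""False-positive filter: labeling, sequence encoding, MTD model, forest."""

import math

import numpy as np
import pytest

from meripeak.fpfilter import (
    ALPHABET,
    MTDModel,
    PEAK_SEQ_CENTER,
    PEAK_SEQ_LEN,
    PeakSequence,
    encode_peak_sequence,
    extract_features,
    feature_names,
    label_training_peaks,
    mtd_loglik,
    mtd_train,
    score_peaks,
    train_classifier,
)
from meripeak.peakcall import PeakCall


def _peak(summit=5000, enrichment=4.0, chrom="chr1"):
    return PeakCall(chrom=chrom, summit=summit, region_start=summit - 100,
                    region_end=summit + 100, ip_count=40, input_count=5,
                    ip_total=1000, input_total=1000, enrichment=enrichment)


class TestLabeling:
    def test_unmatched_control_peak_is_tp(self):
        labeled = label_training_peaks([_peak(1000)], [_peak(9000)], 50)
        assert labeled == [(labeled[0][0], "TP")]

    def test_stable_matched_peak_is_fp(self):
        ctrl = _peak(1000, enrichment=4.0)
        kd = _peak(1010, enrichment=4.8)  # relative change 0.2
        labeled = label_training_peaks([ctrl], [kd], 50)
        assert labeled[0][1] == "FP"

    def test_large_change_is_unlabeled(self):
        ctrl = _peak(1000, enrichment=4.0)
        kd = _peak(1010, enrichment=0.8)  # relative change 0.8
        assert label_training_peaks([ctrl], [kd], 50) == []

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            label_training_peaks([], [_peak()], 50)


class TestEncodeSequence:
    def _fasta(self, seq):
        return {"chr1": seq}

    def test_window_arithmetic(self):
        seq = "".join("ACGT"[(i // 7) % 4] for i in range(10_000))
        ps = encode_peak_sequence(_peak(5000), self._fasta(seq))
        assert len(ps.symbols) == PEAK_SEQ_LEN
        assert ps.symbols[PEAK_SEQ_CENTER] == "M"
        assert ps.symbols[:PEAK_SEQ_CENTER] == seq[4900:5000]
        assert ps.symbols[PEAK_SEQ_CENTER + 1:] == seq[5001:5100]

    def test_planted_motif_flanks_m(self):
        seq = "C" * 4998 + "GGACT" + "C" * 4997
        ps = encode_peak_sequence(_peak(5000), self._fasta(seq))  # A of GGACT at 5000
        assert ps.symbols[98:103] == "GGMCT"

    def test_minus_strand_is_reverse_complement(self):
        rng = np.random.default_rng(14)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        fwd = encode_peak_sequence(_peak(5000), self._fasta(seq), strand="+")
        rev = encode_peak_sequence(_peak(5000), self._fasta(seq), strand="-")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "M": "M"}
        manual = "".join(comp[c] for c in fwd.symbols[::-1])
        # forward window is [4900,5100); reverse uses [4901,5101): one-base shift
        assert rev.symbols[PEAK_SEQ_CENTER] == "M"
        assert manual[99] == "M"
        assert rev.symbols[1:] == manual[:-1]

    def test_contig_edge_padded_with_n(self):
        ps = encode_peak_sequence(
            PeakCall(chrom="chr1", summit=10, region_start=0, region_end=20,
                     ip_count=5, input_count=1, ip_total=10, input_total=10,
                     enrichment=2.0),
            self._fasta("ACGT" * 100),
        )
        assert ps.symbols.startswith("N" * 90)


class TestMTD:
    def test_uniform_sequences_give_uniform_rows(self):
        rng = np.random.default_rng(15)
        seqs = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(100)]
        m = mtd_train(seqs, order=1, min_sequences=10)
        # rows for observed symbols approach uniform over ACGT (M unseen)
        np.testing.assert_allclose(m.Q[:4, :4], 0.25, atol=0.02)

    def test_deterministic_chain_loglik_zero(self):
        # A->C->G->T->A ... : one-hot transitions, log-likelihood log(1)=0
        seqs = ["ACGT" * 100 for _ in range(60)]
        m = mtd_train(seqs, order=1, min_sequences=10)
        assert mtd_loglik(m, "ACGT" * 25) == pytest.approx(0.0, abs=1e-3)

    def test_loglik_matches_direct_sum_on_toy_sequence(self):
        lam = np.array([0.6, 0.4])
        Q = np.full((5, 5), 0.2)
        Q[0] = [0.5, 0.2, 0.1, 0.1, 0.1]
        m = MTDModel(order=2, lag_weights=lam, Q=Q)
        seq = "ACGATCGATA"
        idx = [ALPHABET.index(c) for c in seq]
        expected = sum(
            math.log(lam[0] * Q[idx[t - 1], idx[t]] + lam[1] * Q[idx[t - 2], idx[t]])
            for t in range(2, len(idx))
        )
        assert mtd_loglik(m, seq) == pytest.approx(expected, rel=1e-12)

    def test_training_loglik_uniform_closed_form(self):
        rng = np.random.default_rng(16)
        seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(100)]
        m = mtd_train(seqs, order=3, min_sequences=10)
        s = "".join(rng.choice(list("ACGT"), size=103))
        assert mtd_loglik(m, s) == pytest.approx(100 * math.log(0.25), rel=0.02)

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="invalid symbols"):
            mtd_train(["ACGTX" * 50] * 60, order=1, min_sequences=10)

    def test_n_positions_skipped(self):
        m = mtd_train(["ACGT" * 100] * 60, order=1, min_sequences=10)
        with_n = mtd_loglik(m, "ACGTN" + "ACGT")
        assert np.isfinite(with_n)


class TestFeatures:
    def _models(self):
        rng = np.random.default_rng(17)
        seqs = []
        for _ in range(60):
            s = "".join(rng.choice(list("ACGT"), size=PEAK_SEQ_LEN))
            seqs.append(PeakSequence(s[:100] + "M" + s[101:]))
        m = mtd_train(seqs, order=2, min_sequences=10)
        return m, m

    def test_mono_counts_conserve_window(self):
        tp, fp = self._models()
        rng = np.random.default_rng(18)
        s = "".join(rng.choice(list("ACGT"), size=PEAK_SEQ_LEN))
        ps = PeakSequence(s[:100] + "M" + s[101:])
        vec = extract_features(_peak(), ps, None, tp, fp)
        names = feature_names()
        mono = sum(vec[names.index(f"kmer_{b}")] for b in "ACGT")
        mono += vec[names.index("m_count")]
        assert mono == PEAK_SEQ_LEN

    def test_all_a_window_convention(self):
        tp, fp = self._models()
        ps = PeakSequence("A" * 100 + "M" + "A" * 99)
        vec = extract_features(_peak(), ps, None, tp, fp)
        names = feature_names()
        assert vec[names.index("kmer_A")] == 199  # M counted separately
        assert vec[names.index("m_count")] == 1

    def test_identical_peaks_identical_vectors(self):
        tp, fp = self._models()
        ps = PeakSequence("C" * 100 + "M" + "C" * 99)
        v1 = extract_features(_peak(), ps, None, tp, fp)
        v2 = extract_features(_peak(), ps, None, tp, fp)
        np.testing.assert_array_equal(v1, v2)

    def test_schema_length_matches_names(self):
        tp, fp = self._models()
        ps = PeakSequence("C" * 100 + "M" + "C" * 99)
        vec = extract_features(_peak(), ps, None, tp, fp)
        assert len(vec) == len(feature_names())


def _separable_data(n=400, d=8, seed=19):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, size=(n // 2, d))
    X1 = rng.normal(1.5, 1, size=(n // 2, d))
    X = np.vstack([X0, X1])
    y = ["FP"] * (n // 2) + ["TP"] * (n // 2)
    schema = [f"f{i}" for i in range(d)]
    return X, y, schema


class TestClassifier:
    def test_separable_data_high_oob_accuracy(self):
        X, y, schema = _separable_data()
        model = train_classifier(X, y, n_trees=100, seed=1, feature_schema=schema)
        assert model.oob_error < 0.15

    def test_same_seed_identical_scores(self):
        X, y, schema = _separable_data()
        peaks1 = [_peak(s) for s in range(1000, 1000 + len(X))]
        peaks2 = [_peak(s) for s in range(1000, 1000 + len(X))]
        m1 = train_classifier(X, y, n_trees=60, seed=5, feature_schema=schema)
        m2 = train_classifier(X, y, n_trees=60, seed=5, feature_schema=schema)
        s1 = score_peaks(m1, peaks1, X, feature_schema=schema)
        s2 = score_peaks(m2, peaks2, X, feature_schema=schema)
        assert [a.score for a in s1] == [a.score for a in s2]

    def test_single_class_raises(self):
        X, _, schema = _separable_data()
        with pytest.raises(ValueError, match="both TP and FP"):
            train_classifier(X, ["TP"] * len(X), n_trees=10, feature_schema=schema)

    def test_threshold_zero_all_tp(self):
        X, y, schema = _separable_data(n=100)
        model = train_classifier(X, y, n_trees=30, seed=2, feature_schema=schema)
        scores = score_peaks(model, [_peak(s) for s in range(1000, 1100)], X,
                             threshold=0.0, feature_schema=schema)
        assert all(s.label == "TP" for s in scores)

    def test_raising_threshold_never_increases_recall(self):
        X, y, schema = _separable_data(n=200)
        model = train_classifier(X, y, n_trees=50, seed=3, feature_schema=schema)
        recalls = []
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            peaks = [_peak(s) for s in range(1000, 1000 + len(X))]
            scores = score_peaks(model, peaks, X, threshold=thr, feature_schema=schema)
            tp_calls = [s.label == "TP" for s, lab in zip(scores, y) if lab == "TP"]
            recalls.append(np.mean(tp_calls))
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_schema_mismatch_fatal(self):
        X, y, schema = _separable_data(n=100)
        model = train_classifier(X, y, n_trees=10, seed=4, feature_schema=schema)
        with pytest.raises(ValueError, match="schema mismatch"):
            score_peaks(model, [_peak()], X[:1],
                        feature_schema=["other"] * len(schema))

    def test_model_roundtrip(self, tmp_path):
        from meripeak.fpfilter import PeakClassifier

        X, y, schema = _separable_data(n=100)
        model = train_classifier(X, y, n_trees=20, seed=6, feature_schema=schema)
        path = str(tmp_path / "model.joblib")
        model.save(path)
        loaded = PeakClassifier.load(path)
        np.testing.assert_array_equal(loaded.vote_fraction(X), model.vote_fraction(X))
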