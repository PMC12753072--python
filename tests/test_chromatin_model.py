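"""Sequence model: encoding, training-set geometry, AUROC, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromrisk import chromatin_model as cm
from chromrisk.data_io import GenomeSequences, IntervalSet


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def auroc_bruteforce(scores, labels):
    """All-pairs oracle: wins + half-ties over pos x neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def kmer_counts(seqs, k=6):
    lut = {"".join(p): i for i, p in
           enumerate(itertools.product("ACGT", repeat=k))}
    X = np.zeros((len(seqs), len(lut)))
    for r, s in enumerate(seqs):
        for i in range(len(s) - k + 1):
            j = lut.get(s[i:i + k])
            if j is not None:
                X[r, j] += 1
    return X


def planted_motif_dataset(n_per_class, L, motif, seed):
    rng = np.random.default_rng(seed)
    def draw(n):
        return ["".join(row) for row in rng.choice(list("ACGT"), size=(n, L))]
    pos = []
    for s in draw(n_per_class):
        i = int(rng.integers(0, L - len(motif)))
        pos.append(s[:i] + motif + s[i + len(motif):])
    neg = draw(n_per_class)
    seqs = pos + neg
    labels = np.array([1.0] * n_per_class + [0.0] * n_per_class)
    return cm.TrainingSet(seqs, labels, np.arange(len(seqs)), L)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

class TestOneHot:
    def test_unit_vectors_in_acgt_order(self):
        np.testing.assert_array_equal(cm.one_hot_encode("ACGT"), np.eye(4))

    def test_n_row_all_zero(self):
        np.testing.assert_array_equal(cm.one_hot_encode("N"),
                                      np.zeros((1, 4)))

    def test_case_insensitive(self):
        np.testing.assert_array_equal(cm.one_hot_encode("acgt"),
                                      cm.one_hot_encode("ACGT"))

    def test_illegal_character_position_reported(self):
        with pytest.raises(ValueError, match="position 2"):
            cm.one_hot_encode("ACXT")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=50))
    def test_row_sums_one_except_n(self, seq):
        enc = cm.one_hot_encode(seq)
        expected = np.array([0.0 if c == "N" else 1.0 for c in seq])
        np.testing.assert_array_equal(enc.sum(axis=1), expected)


# ---------------------------------------------------------------------------
# Training-set construction
# ---------------------------------------------------------------------------

class TestBuildTrainingSet:
    @pytest.fixture(scope="class")
    def landscape(self):
        rng = np.random.default_rng(42)
        seqs = {c: "".join(rng.choice(list("ACGT"), size=20_000))
                for c in ("chr1", "chr2")}
        genome = GenomeSequences(seqs)
        peaks = IntervalSet(pd.DataFrame(
            [("chr1", s, s + 200) for s in range(1000, 16000, 1500)]
            + [("chr2", s, s + 200) for s in range(1000, 16000, 1500)],
            columns=["chrom", "start", "end"]))
        return genome, peaks

    def test_positive_window_centered_on_midpoint(self, landscape):
        genome, _ = landscape
        peaks = IntervalSet(pd.DataFrame([("chr1", 1000, 1200)],
                                         columns=["chrom", "start", "end"]))
        ts = cm.build_training_set(genome, peaks, L=500, neg_ratio=0, seed=0)
        row = ts.coords.iloc[0]
        assert (row["start"], row["end"]) == (850, 1350)

    def test_excluded_chromosome_absent(self, landscape):
        genome, peaks = landscape
        ts = cm.build_training_set(genome, peaks, L=200,
                                   excluded_chrom="chr2", seed=0)
        assert (ts.coords["chrom"] != "chr2").all()

    def test_neg_ratio_counts(self, landscape):
        genome, peaks = landscape
        ts = cm.build_training_set(genome, peaks, L=200, neg_ratio=1, seed=0)
        assert (1 - ts.labels).sum() == ts.labels.sum() == len(peaks)

    def test_negatives_avoid_peaks_and_match_gc(self, landscape):
        genome, peaks = landscape
        tol = 0.05
        ts = cm.build_training_set(genome, peaks, L=200, gc_tolerance=tol,
                                   seed=0)
        pos_gc = [cm.gc_fraction(s) for s, l in
                  zip(ts.sequences, ts.labels) if l]
        for seq, label, (_, row) in zip(ts.sequences, ts.labels,
                                        ts.coords.iterrows()):
            if label:
                continue
            for _, pk in peaks.df.iterrows():
                assert not (row["chrom"] == pk["chrom"]
                            and row["start"] < pk["end"]
                            and pk["start"] < row["end"])
            assert min(abs(cm.gc_fraction(seq) - g) for g in pos_gc) <= tol

    def test_unknown_excluded_chrom_rejected(self, landscape):
        genome, peaks = landscape
        with pytest.raises(ValueError, match="chr9"):
            cm.build_training_set(genome, peaks, L=200,
                                  excluded_chrom="chr9", seed=0)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

class TestAuroc:
    def test_perfect_separation(self):
        assert cm.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_swapped_classes(self):
        assert cm.auroc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_interleaved_hand_value(self):
        # pairs: (.9>.8), (.9>.6), (.7<.8), (.7>.6) -> 3/4
        assert cm.auroc([0.9, 0.7, 0.8, 0.6], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            cm.auroc([0.5, 0.6], [1, 1])

    def test_matches_bruteforce_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert cm.auroc(scores, labels) == pytest.approx(
                auroc_bruteforce(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

class TestTrainModel:
    @pytest.fixture(scope="class")
    def motif_data(self):
        return planted_motif_dataset(150, 200, "TGACTCAC", seed=1)

    @pytest.fixture(scope="class")
    def trained(self, motif_data):
        config = cm.ModelConfig.small(cv_folds=5, seed=1)
        return cm.train_model(config, motif_data)

    def test_cv_auroc_recovers_planted_motif(self, trained, motif_data):
        """The network separates motif windows nearly perfectly and does not
        trail a 6-mer logistic oracle on the same folds by more than 0.02."""
        from sklearn.linear_model import LogisticRegression
        from chromrisk.chromatin_model import _group_folds

        model, report = trained
        assert report.cv_auroc_mean >= 0.95

        X = kmer_counts(motif_data.sequences)
        y = motif_data.labels
        folds = _group_folds(motif_data.groups, 5, seed=1)
        oracle_aucs = []
        for val in folds:
            tr = np.setdiff1d(np.arange(len(y)), val)
            clf = LogisticRegression(max_iter=2000).fit(X[tr], y[tr])
            oracle_aucs.append(cm.auroc(clf.predict_proba(X[val])[:, 1],
                                        y[val]))
        assert report.cv_auroc_mean >= np.mean(oracle_aucs) - 0.02

    def test_shuffled_labels_give_chance_cv(self, motif_data):
        rng = np.random.default_rng(3)
        shuffled = cm.TrainingSet(motif_data.sequences,
                                  rng.permutation(motif_data.labels),
                                  motif_data.groups, motif_data.window_length)
        config = cm.ModelConfig.small(cv_folds=5, seed=2, epochs=6)
        _, report = cm.train_model(config, shuffled)
        assert 0.4 <= report.cv_auroc_mean <= 0.6

    def test_too_many_folds_rejected(self):
        data = planted_motif_dataset(60, 100, "TGACTCAC", seed=2)
        with pytest.raises(ValueError, match="folds"):
            cm.train_model(cm.ModelConfig.small(window_length=100,
                                                cv_folds=80, seed=0), data)

    def test_class_minimum_enforced(self):
        data = planted_motif_dataset(20, 100, "TGACTCAC", seed=2)
        with pytest.raises(ValueError, match="50"):
            cm.train_model(cm.ModelConfig.small(window_length=100,
                                                cv_folds=0, seed=0), data)

    def test_window_length_mismatch_rejected(self, motif_data):
        with pytest.raises(ValueError, match="mismatch"):
            cm.train_model(cm.ModelConfig.small(window_length=100,
                                                cv_folds=0), motif_data)


class TestPredict:
    def test_empty_input_empty_output(self, trained_model):
        assert cm.predict_accessibility(trained_model, []).shape == (0,)

    def test_duplicate_windows_identical_scores(self, trained_model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        s = cm.predict_accessibility(trained_model, [seq, seq])
        assert s[0] == s[1]

    def test_batching_invisible(self, trained_model, rng):
        seqs = ["".join(row) for row in rng.choice(list("ACGT"),
                                                   size=(300, 200))]
        full = cm.predict_accessibility(trained_model, seqs)
        # results must agree for any batch slicing (up to BLAS summation
        # order, which perturbs the last float bit)
        parts = np.concatenate([
            cm.predict_accessibility(trained_model, seqs[i:i + 7])
            for i in range(0, 300, 7)])
        np.testing.assert_allclose(full, parts, atol=1e-12, rtol=0)

    def test_scores_bounded(self, trained_model, rng):
        seqs = ["".join(row) for row in rng.choice(list("ACGTN"),
                                                   size=(500, 200))]
        s = cm.predict_accessibility(trained_model, seqs)
        assert ((s >= 0) & (s <= 1)).all()

    def test_length_mismatch_reports_index(self, trained_model):
        with pytest.raises(ValueError, match="window 1"):
            cm.predict_accessibility(trained_model, ["A" * 200, "A" * 199])


class TestPersistence:
    def test_save_load_round_trip_predictions(self, trained_model, tmp_path,
                                              rng):
        cm.save_model(trained_model, tmp_path / "model")
        back = cm.load_model(tmp_path / "model")
        assert back.fingerprint == trained_model.fingerprint
        seqs = ["".join(row) for row in rng.choice(list("ACGT"),
                                                   size=(20, 200))]
        np.testing.assert_array_equal(
            cm.predict_accessibility(trained_model, seqs),
            cm.predict_accessibility(back, seqs))


def test_training_reproducible_for_fixed_seed():
    data = planted_motif_dataset(60, 100, "TGACTCAC", seed=4)
    config = cm.ModelConfig.small(window_length=100, cv_folds=0, seed=5,
                                  epochs=3)
    m1, _ = cm.train_model(config, data)
    m2, _ = cm.train_model(config, data)
    probe = planted_motif_dataset(10, 100, "TGACTCAC", seed=6).sequences
    np.testing.assert_allclose(cm.predict_accessibility(m1, probe),
                               cm.predict_accessibility(m2, probe),
                               atol=1e-5)
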