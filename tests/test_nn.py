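"""Feature normalisation, backprop training, scoring and the six-run protocol."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import decoynet.nn as nn_mod
from decoynet.nn import (
    PROTOCOL_RUNS,
    NetworkModel,
    PSMNetClassifier,
    TrainingConfig,
    normalize_features,
    run_protocol,
    score,
    train_network,
    train_scorer,
)
from decoynet.psm import FIVE_FEATURES
from decoynet.synth import GeneratorConfig, generate_stratum

from conftest import make_record


class TestNormalizeFeatures:
    def test_constant_column_maps_to_zeros(self):
        records = [make_record(0, xcorr=2.0) for _ in range(5)]
        X, params = normalize_features(records, ("xcorr",))
        assert np.all(X == 0.0)

    def test_two_value_column_standardizes_to_unit(self):
        records = [make_record(i, xcorr=v) for i, v in enumerate([0.0, 2.0])]
        X, _ = normalize_features(records, ("xcorr",))
        assert np.allclose(X[:, 0], [-1.0, 1.0])

    def test_moments_on_random_matrix(self, rng):
        records = [
            make_record(
                i,
                xcorr=float(rng.uniform(0, 5)),
                delta_cn=float(rng.uniform(0, 1)),
                delta_mass_ppm=float(rng.normal(0, 3)),
                sp_rank=int(rng.integers(1, 100)),
                perc_ions=float(rng.uniform(0, 1)),
                rt_pvalue=float(rng.uniform(0.01, 1)),
            )
            for i in range(200)
        ]
        X, params = normalize_features(records, tuple(FIVE_FEATURES) + ("rt_pvalue",))
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(X.std(axis=0), 1.0, atol=1e-10)
        # applying stored params reproduces the matrix
        assert np.allclose(params.apply(records), X)

    def test_sp_rank_is_log_transformed(self):
        records = [make_record(i, sp_rank=r) for i, r in enumerate([1, 9])]
        X, params = normalize_features(records, ("sp_rank",))
        raw = np.log1p([1, 9])
        expect = (raw - raw.mean()) / raw.std()
        assert np.allclose(X[:, 0], expect)

    def test_absent_feature_names_record(self):
        records = [make_record(0, rt_pvalue=None)]
        with pytest.raises(ValueError, match="scan00000"):
            normalize_features(records, ("rt_pvalue",))


def _two_clouds(n=100, sep=2.0, sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(-sep, sd, size=(half, 2)),
            rng.normal(sep, sd, size=(n - half, 2)),
        ]
    )
    y = np.array([0] * half + [1] * (n - half))
    return X, y


def _xor_clusters(n=200, sd=0.2, seed=0):
    rng = np.random.default_rng(seed)
    centers = [(-1, -1, 0), (1, 1, 0), (-1, 1, 1), (1, -1, 1)]
    X, y = [], []
    for cx, cy, label in centers:
        X.append(rng.normal((cx, cy), sd, size=(n // 4, 2)))
        y += [label] * (n // 4)
    return np.vstack(X), np.array(y)


class TestTraining:
    def test_separable_clouds_reach_near_perfect_accuracy(self):
        X, y = _two_clouds()
        clf = PSMNetClassifier(n_hidden=3, learning_rate=0.2, epochs=200,
                               random_state=1).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_xor_pattern_requires_and_gets_nonlinear_boundary(self):
        X, y = _xor_clusters()
        clf = PSMNetClassifier(n_hidden=5, learning_rate=0.2, epochs=2000,
                               random_state=1).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_training_is_deterministic(self):
        X, y = _two_clouds(n=60)
        a = PSMNetClassifier(epochs=50, random_state=7).fit(X, y)
        b = PSMNetClassifier(epochs=50, random_state=7).fit(X, y)
        for wa, wb in zip(a.coefs_ + a.intercepts_, b.coefs_ + b.intercepts_):
            assert np.array_equal(wa, wb)

    def test_different_seed_changes_weights(self):
        X, y = _two_clouds(n=60)
        a = PSMNetClassifier(epochs=50, random_state=7).fit(X, y)
        b = PSMNetClassifier(epochs=50, random_state=8).fit(X, y)
        assert not np.array_equal(a.coefs_[0], b.coefs_[0])

    def test_loss_decreases(self):
        X, y = _two_clouds(n=80)
        clf = PSMNetClassifier(epochs=100, random_state=3).fit(X, y)
        assert clf.loss_final_ < clf.loss_initial_

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single-class"):
            PSMNetClassifier().fit(X, np.zeros(10, dtype=int))

    def test_pure_python_fallback_trains(self, monkeypatch):
        monkeypatch.setattr(nn_mod, "_ACTIVE_TRAIN_LOOP", [nn_mod._train_loop])
        X, y = _two_clouds(n=60)
        clf = PSMNetClassifier(n_hidden=3, epochs=50, random_state=1).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        assert clf.loss_final_ < clf.loss_initial_


class TestScoring:
    def test_probability_is_normalized_activation_pair(self):
        # hand-crafted weights: zero hidden layer, output biases chosen so
        # the two sigmoid activations are known exactly
        cfg = TrainingConfig(feature_list=("xcorr",), n_hidden=1, epochs=1)
        logit = lambda p: float(np.log(p / (1 - p)))
        model = NetworkModel(
            config=cfg,
            w_hidden=np.zeros((1, 1)),
            b_hidden=np.zeros(1),
            w_output=np.zeros((1, 2)),
            b_output=np.array([logit(0.1), logit(0.9)]),
        )
        probs = model.probabilities(np.zeros((1, 1)))
        assert np.allclose(probs, 0.9 / (0.9 + 0.1))

        symmetric = NetworkModel(
            config=cfg,
            w_hidden=np.zeros((1, 1)),
            b_hidden=np.zeros(1),
            w_output=np.zeros((1, 2)),
            b_output=np.array([logit(0.5), logit(0.5)]),
        )
        assert np.allclose(symmetric.probabilities(np.zeros((1, 1))), 0.5)

    def test_decoys_score_below_targets_on_signal(self, small_stratum):
        records, _ = small_stratum
        cfg = TrainingConfig(feature_list=FIVE_FEATURES, n_hidden=4,
                             learning_rate=0.1, epochs=200, seed=2)
        model = train_scorer(records, cfg)
        scored = score(model, records)
        p = np.array([s.probability for s in scored])
        decoy = np.array([s.record.is_decoy for s in scored])
        assert p[decoy].mean() < p[~decoy].mean()
        assert np.all((p >= 0) & (p <= 1))
        assert [s.record.spectrum_id for s in scored] == [
            r.spectrum_id for r in records
        ]

    def test_model_json_roundtrip(self, small_stratum):
        records, _ = small_stratum
        cfg = TrainingConfig(feature_list=FIVE_FEATURES, n_hidden=3,
                             learning_rate=0.2, epochs=20, seed=9)
        model = train_scorer(records, cfg)
        back = NetworkModel.from_json(model.to_json())
        assert np.allclose(back.w_hidden, model.w_hidden)
        assert back.normalization == model.normalization
        s1 = score(model, records[:10])
        s2 = score(back, records[:10])
        assert [a.probability for a in s1] == pytest.approx(
            [b.probability for b in s2]
        )

    def test_no_signal_gives_chance_level_auc_on_fresh_draws(self):
        """Feature noise must not become class signal beyond the training set.

        Scored on held-out records from the same null population: a scorer
        trained on pure noise must rank fresh decoys and targets at chance.
        (On its own training records the fitted labels leak — decoy-vs-target
        AUC rises above 0.5 by memorisation — which is exactly the
        anti-conservative self-scoring bias documented in the methods note.)
        """
        aucs = []
        for seed in range(20):
            cfg = GeneratorConfig(n_per_stratum=1000, correct_fraction=0.0,
                                  rt_signal=False, seed=seed)
            train_records, _ = generate_stratum(cfg, False, 2)
            fresh_records, _ = generate_stratum(cfg, False, 3)  # disjoint draw
            tc = TrainingConfig(feature_list=FIVE_FEATURES, n_hidden=4,
                                learning_rate=0.1, epochs=500, seed=seed)
            model = train_scorer(train_records, tc)
            scored = score(model, fresh_records)
            y = [0 if s.record.is_decoy else 1 for s in scored]
            aucs.append(roc_auc_score(y, [s.probability for s in scored]))
        assert abs(np.mean(aucs) - 0.5) <= 0.05


class TestProtocol:
    def test_six_runs_cover_every_record(self, small_stratum):
        records, _ = small_stratum
        runs = run_protocol(records[:120], FIVE_FEATURES, base_seed=3)
        assert len(runs) == 6
        for scored in runs:
            assert len(scored) == 120

    def test_run_configurations(self):
        assert PROTOCOL_RUNS[0] == (4, 0.1, 1000)
        assert PROTOCOL_RUNS[5] == (5, 0.3, 2000)
        assert len(PROTOCOL_RUNS) == 6

    def test_protocol_determinism(self, small_stratum):
        records, _ = small_stratum
        a = run_protocol(records[:80], FIVE_FEATURES, base_seed=5)
        b = run_protocol(records[:80], FIVE_FEATURES, base_seed=5)
        assert [
            [s.probability for s in run] for run in a
        ] == [[s.probability for s in run] for run in b]
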