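import dataclasses

import numpy as np
import pytest

from emats import models
from emats.models import (
    default_spec,
    predict_sequence,
    reduced_spec,
    train_regressor,
    untrained_model,
)


def _toy_spec(kind, in_dim, out_dim, **kw):
    base = reduced_spec(kind, **{"hidden": 12, "depth": 1, "max_epochs": 8,
                                 "learning_rate": 3e-3, **kw})
    return dataclasses.replace(base, input_dim=in_dim, output_dim=out_dim)


def _linear_task(rng, n_pairs, T, in_dim, out_dim):
    A = rng.normal(size=(in_dim, out_dim)) * 0.4
    pairs = []
    for _ in range(n_pairs):
        x = rng.normal(size=(T, in_dim))
        pairs.append((x, x @ A))
    return pairs


class TestTraining:
    def test_published_topologies(self):
        sd, si, vc = default_spec("ats_sd"), default_spec("ats_si"), default_spec("vc")
        assert (sd.input_dim, sd.output_dim, sd.hidden, sd.depth) == (54, 80, 256, 3)
        assert not sd.bidirectional and not si.bidirectional and vc.bidirectional
        assert (sd.learning_rate, si.learning_rate, vc.learning_rate) == (3e-4, 1e-5, 5e-5)
        assert (sd.max_epochs, si.max_epochs, vc.max_epochs) == (50, 30, 30)
        assert (vc.input_dim, vc.output_dim, vc.hidden) == (80, 80, 128)

    def test_validation_loss_improves_on_smoke_task(self):
        rng = np.random.default_rng(0)
        pairs = _linear_task(rng, 24, 30, 6, 4)
        model = train_regressor(_toy_spec("ats_si", 6, 4), pairs[:20], pairs[20:], seed=1)
        assert model.train_log[-1]["val_loss"] < model.train_log[0]["val_loss"]

    def test_loss_non_increasing_on_linear_toy(self):
        rng = np.random.default_rng(1)
        pairs = _linear_task(rng, 16, 25, 4, 3)
        spec = _toy_spec("ats_si", 4, 3, max_epochs=20)
        model = train_regressor(spec, pairs[:12], pairs[12:], seed=2)
        losses = [e["val_loss"] for e in model.train_log]
        # allow tiny upticks from stochastic sentence order, but trend must fall
        assert losses[-1] < 0.5 * losses[0]
        assert min(losses) == losses[model.selected_epoch]

    def test_selected_epoch_is_argmin_validation(self):
        rng = np.random.default_rng(2)
        pairs = _linear_task(rng, 10, 20, 3, 2)
        model = train_regressor(_toy_spec("vc", 3, 2), pairs[:8], pairs[8:], seed=3)
        val = [e["val_loss"] for e in model.train_log]
        assert model.selected_epoch == int(np.argmin(val))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pairs = _linear_task(rng, 8, 15, 3, 2)
        m1 = train_regressor(_toy_spec("ats_si", 3, 2, max_epochs=3), pairs[:6], pairs[6:], seed=7)
        m2 = train_regressor(_toy_spec("ats_si", 3, 2, max_epochs=3), pairs[:6], pairs[6:], seed=7)
        assert [e["train_loss"] for e in m1.train_log] == [e["train_loss"] for e in m2.train_log]

    def test_dim_mismatch_and_empty_rejected(self):
        spec = _toy_spec("ats_si", 3, 2)
        x, y = np.zeros((5, 3)), np.zeros((5, 2))
        with pytest.raises(ValueError, match="dims"):
            train_regressor(spec, [(np.zeros((5, 4)), y)], [(x, y)])
        with pytest.raises(ValueError, match="empty"):
            train_regressor(spec, [], [(x, y)])
        with pytest.raises(ValueError, match="length"):
            train_regressor(spec, [(np.zeros((4, 3)), y)], [(x, y)])


class TestPrediction:
    def test_output_shape_frame_synchronous(self):
        model = untrained_model(_toy_spec("ats_si", 5, 3), seed=0)
        out = predict_sequence(model, np.zeros((17, 5)))
        assert out.shape == (17, 3)

    def test_unidirectional_model_is_causal(self):
        model = untrained_model(_toy_spec("ats_si", 5, 3, depth=2), seed=1)
        x = np.random.default_rng(5).normal(size=(40, 5))
        full = predict_sequence(model, x)
        for cut in (1, 7, 25):
            np.testing.assert_allclose(predict_sequence(model, x[:cut]), full[:cut], atol=1e-12)

    def test_bidirectional_model_uses_future_context(self):
        model = untrained_model(_toy_spec("vc", 5, 3), seed=2)
        x = np.random.default_rng(6).normal(size=(40, 5))
        full = predict_sequence(model, x)
        prefix = predict_sequence(model, x[:10])
        assert not np.allclose(full[:10], prefix)

    def test_input_dim_checked(self):
        model = untrained_model(_toy_spec("ats_si", 5, 3), seed=0)
        with pytest.raises(ValueError):
            predict_sequence(model, np.zeros((4, 7)))


def test_vc_model_recovers_planted_coloration():
    """A BLSTM trained on shift+gain-coloured pairs moves sequences toward the
    target coloration: post-conversion cepstral distortion must drop."""
    from emats import evaluation, features

    rng = np.random.default_rng(8)
    gain = 1.0 + 0.1 * np.sin(np.arange(80) / 9.0)
    shift = 0.8 * np.cos(np.arange(80) / 11.0)
    t = np.linspace(0, 1, 30)[:, None]
    b = np.arange(80)[None, :]

    def source_mel(phase):
        return -6 + 2 * np.tanh(np.sin(2 * np.pi * 2 * t + b / 10 + phase))

    pairs = [(m, gain * m + shift)
             for m in (source_mel(p) for p in rng.uniform(0, 6, size=14))]
    in_stats = features.zscore_fit([x for x, _ in pairs])
    out_stats = features.zscore_fit([y for _, y in pairs])
    norm = [(features.zscore_apply(x, in_stats), features.zscore_apply(y, out_stats))
            for x, y in pairs]
    spec = _toy_spec("vc", 80, 80, hidden=24, max_epochs=15)
    model = train_regressor(spec, norm[:11], norm[11:], seed=9)

    test = source_mel(1.234)
    target = gain * test + shift
    converted = features.zscore_invert(
        predict_sequence(model, features.zscore_apply(test, in_stats)), out_stats)
    ref = features.mfcc_from_mel(target)
    before = evaluation.mcd(ref, features.mfcc_from_mel(test))
    after = evaluation.mcd(ref, features.mfcc_from_mel(converted))
    assert after < before
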