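"""Model forward dynamics: noise, architectural reductions, depression gating."""

import numpy as np
import pytest

from stpnet.models import (
    ModelConfig,
    ModelKind,
    apply_noise,
    forward_step,
    init_model,
    load_checkpoint,
    run_sequence,
    save_checkpoint,
)
from stpnet.stp_dynamics import STPParams, run_depression
from stpnet.synthetic_data import EmbeddingMatrix, StimulusSequence, generate_session


def _noise_off(kind, **kw):
    return ModelConfig(kind=kind, noise_sd=0.0, **kw)


def _one_hot_embeddings(n_images=8, n_features=64, unit=0, image=0, amp=3.0):
    vals = np.full((n_images, n_features), 1e-12)
    vals[image, unit] = amp
    return EmbeddingMatrix(values=vals)


class TestApplyNoise:
    def test_zero_sd_is_identity(self, rng):
        a = rng.random(10)
        assert np.array_equal(apply_noise(a, 0.0, rng), a)

    def test_zero_activity_stays_zero(self, rng):
        out = apply_noise(np.zeros(1000), 0.5, rng)
        assert np.all(out == 0)

    def test_rectification_bias_is_small(self, rng):
        """E[max(0, a(1+eps))] stays within 5% of a at sd=0.5."""
        a = np.ones(200_000)
        out = apply_noise(a, 0.5, rng)
        assert abs(out.mean() - 1.0) < 0.05
        assert np.all(out >= 0)


class TestForwardStep:
    def test_zero_input_zero_hidden_rnn_gives_bias_logit(self):
        config = _noise_off(ModelKind.RNN)
        state = init_model(config, seed=0)
        state.b_h = np.minimum(state.b_h, 0.0)  # silence the hidden bias drive
        logit, hidden = forward_step(state, config, np.zeros(64), np.random.default_rng(0))
        assert np.all(hidden == 0)
        assert logit == pytest.approx(state.b_out)

    def test_depression_disabled_reduces_to_static_feedforward(self, rng):
        """With U -> 0 the STPNet pass equals a plain two-layer network."""
        config = _noise_off(ModelKind.STPNET, stp=STPParams(U=1e-12))
        state = init_model(config, seed=1)
        r = rng.random(64) * 3
        logit, hidden = forward_step(state, config, r, np.random.default_rng(0))
        expected_hidden = np.maximum(state.W_in @ r + state.b_h, 0)
        assert np.allclose(hidden, expected_hidden, atol=1e-8)
        assert logit == pytest.approx(float(state.W_out @ expected_hidden + state.b_out), abs=1e-7)

    def test_repeated_presentations_follow_depression_oracle(self):
        """Hidden drive of a single-image unit scales as the standalone x(k)."""
        config = _noise_off(ModelKind.STPNET)
        state = init_model(config, seed=2)
        emb = _one_hot_embeddings(amp=3.0)
        seq = _manual_sequence([0] * 6)
        rec = run_sequence(state, config, seq, emb, np.random.default_rng(0))
        pres = np.flatnonzero(seq.is_presentation)
        gated = rec.input_gated[pres, 0]
        rates = np.zeros((seq.n_steps, 1))
        rates[pres, 0] = 3.0
        x_oracle = run_depression(rates, config.stp)[pres, 0]
        assert np.allclose(gated, 3.0 * x_oracle, rtol=1e-9)

    def test_input_shape_checked(self):
        config = _noise_off(ModelKind.STPNET)
        state = init_model(config, seed=0)
        with pytest.raises(ValueError):
            forward_step(state, config, np.zeros(10), np.random.default_rng(0))


def _manual_sequence(images, omit=(), change=(), sham=()):
    """Build a sequence of presentations (1 image + 2 gray frames each)."""
    n = len(images)
    T = n * 3
    frame_kind = np.ones(T, dtype=np.int8)  # GRAY
    image_id = np.full(T, -1)
    is_change = np.zeros(T, dtype=bool)
    is_sham = np.zeros(T, dtype=bool)
    repeat = np.zeros(T, dtype=int)
    trial = np.zeros(T, dtype=int)
    for p, img in enumerate(images):
        t = 3 * p
        frame_kind[t] = 2 if p in omit else 0
        image_id[t] = img
        is_change[t] = p in change
        is_sham[t] = p in sham
        repeat[t] = 1
    return StimulusSequence(frame_kind, image_id, is_change, is_sham, repeat, trial)


class TestArchitecturalReductions:
    def _run_all(self, state, kind, seq, emb, n_hidden=16):
        config = _noise_off(kind)
        return run_sequence(state, config, seq, emb, np.random.default_rng(0))

    def test_stprnn_with_zero_adapting_weights_equals_rnn(self, embeddings):
        seq = generate_session(n_trials=20, seed=5)
        rnn_cfg = _noise_off(ModelKind.RNN)
        rnn = init_model(rnn_cfg, seed=3)
        stprnn_cfg = _noise_off(ModelKind.STPRNN)
        stprnn = init_model(stprnn_cfg, seed=4)
        stprnn.W_in = np.zeros_like(stprnn.W_in)  # adapting block off
        stprnn.W_plain = rnn.W_in.copy()
        stprnn.W_rec = rnn.W_rec.copy()
        stprnn.b_h = rnn.b_h.copy()
        stprnn.W_out = rnn.W_out.copy()
        stprnn.b_out = rnn.b_out
        out_rnn = run_sequence(rnn, rnn_cfg, seq, embeddings, np.random.default_rng(0))
        out_sr = run_sequence(stprnn, stprnn_cfg, seq, embeddings, np.random.default_rng(0))
        assert np.allclose(out_rnn.logits, out_sr.logits, atol=1e-10)

    def test_stprnn_with_zero_plain_and_recurrent_equals_stpnet(self, embeddings):
        seq = generate_session(n_trials=20, seed=6)
        stp_cfg = _noise_off(ModelKind.STPNET)
        stp = init_model(stp_cfg, seed=3)
        stprnn_cfg = _noise_off(ModelKind.STPRNN)
        stprnn = init_model(stprnn_cfg, seed=4)
        stprnn.W_plain = np.zeros_like(stprnn.W_plain)
        stprnn.W_rec = np.zeros_like(stprnn.W_rec)
        stprnn.W_in = stp.W_in.copy()
        stprnn.b_h = stp.b_h.copy()
        stprnn.W_out = stp.W_out.copy()
        stprnn.b_out = stp.b_out
        out_stp = run_sequence(stp, stp_cfg, seq, embeddings, np.random.default_rng(0))
        out_sr = run_sequence(stprnn, stprnn_cfg, seq, embeddings, np.random.default_rng(0))
        assert np.allclose(out_stp.logits, out_sr.logits, atol=1e-10)


class TestRunSequence:
    def test_empty_sequence_gives_empty_outputs(self, embeddings):
        seq = _manual_sequence([])
        config = _noise_off(ModelKind.RNN)
        state = init_model(config, seed=0)
        rec = run_sequence(state, config, seq, embeddings, np.random.default_rng(0))
        assert rec.logits.shape == (0,)
        assert rec.hidden.shape == (0, 16)

    def test_hidden_activity_is_non_negative(self, embeddings):
        seq = generate_session(n_trials=30, p_omit=0.05, seed=7)
        for kind in ModelKind:
            config = ModelConfig(kind=kind, noise_sd=0.5)
            state = init_model(config, seed=1)
            rec = run_sequence(state, config, seq, embeddings, np.random.default_rng(2))
            assert np.all(rec.hidden >= 0)
            if rec.resources is not None:
                assert np.all((rec.resources > 0) & (rec.resources <= 1))

    def test_rnn_persists_through_omission_stpnet_evoked_is_zero(self, embeddings):
        """During an omitted frame the recurrent model keeps stimulus-evoked
        activity while the feedforward depressing model falls back exactly to
        its gray-screen baseline relu(b_h)."""
        seq = _manual_sequence([0, 0, 0, 0], omit=(2,))
        om_step = 6
        rnn_cfg = _noise_off(ModelKind.RNN)
        rnn = init_model(rnn_cfg, seed=8)
        rnn.W_rec = np.abs(rnn.W_rec)  # guarantee persistence
        rec = run_sequence(rnn, rnn_cfg, seq, embeddings, np.random.default_rng(0))
        baseline = np.maximum(rnn.b_h, 0)
        assert rec.hidden[om_step].sum() > baseline.sum()

        stp_cfg = _noise_off(ModelKind.STPNET)
        stp = init_model(stp_cfg, seed=8)
        rec2 = run_sequence(stp, stp_cfg, seq, embeddings, np.random.default_rng(0))
        evoked = rec2.hidden[om_step] - np.maximum(stp.b_h, 0)
        assert np.all(evoked == 0)

    def test_forward_step_agrees_with_run_sequence_under_shared_noise(self, embeddings):
        seq = generate_session(n_trials=10, seed=9)
        config = ModelConfig(kind=ModelKind.STPRNN, noise_sd=0.5)
        state_a = init_model(config, seed=10)
        state_b = init_model(config, seed=10)
        rec = run_sequence(state_a, config, seq, embeddings, np.random.default_rng(5))
        rng = np.random.default_rng(5)
        state_b.reset_dynamic(config)
        logits = []
        zero = np.zeros(64)
        for t in range(seq.n_steps):
            feats = embeddings.values[seq.image_id[t]] if seq.is_presentation[t] else zero
            logit, _ = forward_step(state_b, config, feats, rng)
            logits.append(logit)
        assert np.allclose(rec.logits, logits, atol=1e-12)

    def test_mismatched_embedding_raises(self):
        seq = generate_session(n_trials=5, seed=0)
        config = _noise_off(ModelKind.RNN)
        state = init_model(config, seed=0)
        small = EmbeddingMatrix(values=np.ones((8, 32)))
        with pytest.raises(ValueError):
            run_sequence(state, config, seq, small, np.random.default_rng(0))


class TestCheckpoints:
    @pytest.mark.parametrize("kind", list(ModelKind))
    def test_round_trip_is_bit_exact(self, tmp_path, kind):
        config = ModelConfig(kind=kind)
        state = init_model(config, seed=11)
        path = tmp_path / "model.h5"
        save_checkpoint(path, state, config, seed=11)
        loaded, loaded_cfg = load_checkpoint(path)
        assert loaded_cfg.kind == kind
        for key, val in state.parameters().items():
            assert np.array_equal(val, loaded.parameters()[key])
        if state.synapse is not None:
            assert np.array_equal(state.synapse.x, loaded.synapse.x)
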