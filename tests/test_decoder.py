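"""Decoder stage wiring, ablation flags, config round-trips, gradient flow."""

import numpy as np
import pytest
import yaml

from mhanet import ModelConfig, ablation_configs, assemble_mhanet, shape_trace
from mhanet.decoder import DecoderStageConfig, MHAStage
from mhanet.nn import autograd as ag
from mhanet.nn.autograd import Tensor
from mhanet.train import TrainConfig, train


def test_stage_config_sum_requires_channel_match():
    with pytest.raises(ValueError, match="out_channels"):
        DecoderStageConfig(in_channels=64, skip_channels=32, out_channels=16, use_sum=True)


def test_stage_forward_shapes():
    cfg = DecoderStageConfig(in_channels=32, skip_channels=16, out_channels=16, se_reduction=4)
    stage = MHAStage(cfg, np.random.default_rng(0)).eval()
    rng = np.random.default_rng(1)
    deep = Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    skip = Tensor(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
    trace = []
    out = stage(deep, skip, trace=trace)
    assert out.shape == (1, 16, 16, 16)
    assert dict(trace)["concat"] == (1, 48, 16, 16)


def test_zero_skip_sum_equals_no_sum():
    """Adding an all-zero skip is a no-op, so use_sum on/off must agree."""
    mk = lambda use_sum: MHAStage(
        DecoderStageConfig(
            in_channels=32, skip_channels=16, out_channels=16, use_sum=use_sum, se_reduction=4
        ),
        np.random.default_rng(42),
    ).eval()
    deep = Tensor(np.random.default_rng(2).normal(size=(1, 32, 4, 4)).astype(np.float32))
    zero_skip = Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32))
    with ag.no_grad():
        a = mk(True)(deep, zero_skip).numpy()
        b = mk(False)(deep, zero_skip).numpy()
    np.testing.assert_array_equal(a, b)


def test_model_config_chain_validation():
    stages = ModelConfig(width_scale=0.25).resolve().stages
    bad = (stages[0],) + (
        DecoderStageConfig(in_channels=99, skip_channels=32, out_channels=32),
    ) + stages[2:]
    with pytest.raises(ValueError, match="stage 2"):
        ModelConfig(width_scale=0.25, stages=bad).validate()


def test_ablation_flag_triples():
    cfgs = ablation_configs(width_scale=0.25)
    assert set(cfgs) == {"baseline", "baseline+PSA", "baseline+SE", "full"}
    assert not cfgs["baseline"].use_psa and not cfgs["baseline"].use_se
    assert cfgs["full"].use_psa and cfgs["full"].use_se and cfgs["full"].use_sum


def test_ablation_parameter_ordering_quarter_scale():
    counts = {n: assemble_mhanet(c).num_params() for n, c in ablation_configs(0.25).items()}
    assert counts["baseline"] < counts["baseline+SE"] < counts["full"]
    assert counts["baseline"] < counts["baseline+PSA"] < counts["full"]


def test_config_roundtrips_through_yaml():
    cfg = ModelConfig(width_scale=0.25, use_se=False, seed=9).resolve()
    restored = ModelConfig.from_dict(yaml.safe_load(yaml.safe_dump(cfg.to_dict())))
    assert restored == cfg


def test_forward_output_contract():
    model = assemble_mhanet(ModelConfig(width_scale=0.25, seed=3)).eval()
    x = np.random.default_rng(4).random((2, 3, 64, 64)).astype(np.float32)
    prob = model.predict_proba(x)
    assert prob.shape == (2, 1, 64, 64)
    assert (prob > 0).all() and (prob < 1).all()
    np.testing.assert_array_equal(prob, model.predict_proba(x))  # eval determinism


def test_resolution_generalization():
    """One weight set runs at multiple divisible input sizes."""
    model = assemble_mhanet(ModelConfig(width_scale=0.25, seed=5)).eval()
    for hw in ((64, 64), (96, 64)):
        tr = shape_trace(model, hw)
        assert tr["output"] == (1, 1, *hw)
        assert tr["bottleneck"][2:] == (hw[0] // 32, hw[1] // 32)


def test_every_parameter_receives_gradient():
    """One optimization step leaves no dead branch.

    se_reduction=4 keeps the SE hidden layers a few units wide at quarter
    width; with a 1-unit hidden layer a ReLU that is off for the whole toy
    batch would zero that branch's gradient by construction, which is an
    initialization accident rather than a wiring defect.
    """
    model = assemble_mhanet(ModelConfig(width_scale=0.25, se_reduction=4, seed=6))
    rng = np.random.default_rng(7)
    x = rng.random((2, 3, 32, 32)).astype(np.float32)
    t = (rng.random((2, 1, 32, 32)) > 0.5).astype(np.float32)
    loss = ag.bce_with_logits(model(Tensor(x)), t)
    loss.backward()
    dead = [
        n
        for n, p in model.named_parameters()
        if p.grad is None or not np.isfinite(p.grad).all() or not np.any(p.grad)
    ]
    assert dead == []


def test_nonempty_train_set_required():
    model = assemble_mhanet(ModelConfig(width_scale=0.25, seed=0))
    with pytest.raises(ValueError, match="empty"):
        train(model, [], [], TrainConfig(epochs=1))
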