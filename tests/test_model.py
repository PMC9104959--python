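"""Architecture accounting, receptive fields and forward-pass contracts."""

import numpy as np
import pytest

from lighteyes.config import NetworkConfig
from lighteyes.model import LightEyesModel, build_model, receptive_field

from oracles import make_positive_model, receptive_field_bruteforce


@pytest.mark.parametrize(
    "variant,expected",
    [("full", 35551), ("A1", 28369), ("A2", 33625), ("A3", 35377)],
)
def test_variant_parameter_counts(variant, expected):
    model, summary = build_model(NetworkConfig(variant=variant))
    assert model.count_parameters() == expected
    assert summary.total_params == expected


def test_default_topology_per_layer(default_model):
    """Layer-by-layer widths and parameter counts of the default network."""
    rows = {r.name: r for r in default_model.summary().rows}
    assert (rows["conv1"].in_channels, rows["conv1"].out_channels) == (3, 16)
    assert rows["conv1"].n_params == 448
    for i in range(2, 13):
        assert rows[f"conv{i}"].n_params == 2320
    assert rows["conv13"].n_params == 1160
    for i in range(14, 25):
        assert rows[f"conv{i}"].n_params == 584
    for j in range(1, 4):
        assert rows[f"branch3_conv{j}"].n_params == 584
    for head in ("aux1_head", "aux2_head", "aux3_head"):
        assert rows[head].n_params == 73
    assert rows["fusion"].n_params == 28  # (9*3 + 1) * 1
    assert default_model.summary().total_filters == 316


def test_variant_nesting_in_parameter_count():
    counts = {
        v: build_model(NetworkConfig(variant=v))[0].count_parameters()
        for v in ("A1", "A2", "full")
    }
    assert counts["A1"] < counts["A2"] < counts["full"]
    assert (counts["A1"], counts["A2"], counts["full"]) == (28369, 33625, 35551)


def test_minimal_single_conv_count():
    """One 3x3 conv from 3 channels to 1 filter has (9*3+1)*1 = 28 params."""
    cfg = NetworkConfig(nc=1, nl=2, narrow_width=1)
    model, _ = build_model(cfg)
    conv1 = model._layers["conv1"]
    assert conv1.n_params() == 28


def test_closed_form_matches_enumeration_for_random_configs():
    """The (k^2*Cin+1)*Cout closed form summed over the summary equals an
    exhaustive enumeration of learnable scalars, for 20 random configs."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        cfg = NetworkConfig(
            nc=int(rng.integers(2, 33)),
            nl=int(rng.integers(4, 31)),
            narrow_width=int(rng.integers(1, 9)),
            variant=str(rng.choice(["full", "A1", "A2", "A3"])),
        )
        model = LightEyesModel(cfg)
        enumerated = sum(int(a.size) for a in model.parameters().values())
        assert model.summary().total_params == enumerated


@pytest.mark.parametrize(
    "tap,expected",
    [
        ("conv24", 49),
        ("aux1", 33),
        ("aux2", 51),
        ("aux3", 66),
        ("conv30", 33),
        ("conv29", 51),
        ("conv28", 66),
        ("conv1", 3),
    ],
)
def test_receptive_field_recursion(tap, expected):
    assert receptive_field(NetworkConfig(), tap) == expected


def test_receptive_field_unknown_tap():
    with pytest.raises(KeyError):
        receptive_field(NetworkConfig(), "conv99")


def test_receptive_field_matches_perturbation_oracle_small_net():
    """Recursion vs the forward-perturbation support oracle on a small
    network covering every structural element (pool, upsample, fusion)."""
    cfg = NetworkConfig(nc=4, nl=6, narrow_width=3)
    model = make_positive_model(cfg)
    for tap in ("conv6", "aux1_head", "aux2_head", "aux3_head", "fusion"):
        expected = model.receptive_field(tap)
        measured = receptive_field_bruteforce(model, tap, size=48)
        assert measured == expected, tap


def test_forward_output_contract(default_model, rng):
    img = rng.random((64, 64, 3))
    maps = default_model.forward(img)
    for arr in (maps.fused, maps.aux1, maps.aux2, maps.aux3):
        assert arr.shape == (64, 64)
        assert arr.min() >= 0.0 and arr.max() <= 1.0
    maps2 = default_model.forward(img)
    assert np.array_equal(maps.fused, maps2.fused)


def test_forward_rejects_bad_inputs(default_model):
    with pytest.raises(ValueError, match="odd"):
        default_model.forward(np.zeros((63, 64, 3)))
    with pytest.raises(ValueError):
        default_model.forward(np.zeros((64, 64, 4)))


def test_encoder_preserves_resolution_layer_by_layer(default_model, rng):
    """No hidden striding: every encoder feature map is exactly H x W."""
    img = rng.random((32, 48, 3))
    default_model.forward(img, keep_cache=True)
    for i in range(1, 25):
        assert default_model.activation(f"conv{i}").shape[1:] == (32, 48)
    assert default_model.activation("pool").shape[1:] == (16, 24)
    assert default_model.activation("aux3_up").shape[1:] == (32, 48)
    default_model._cache = None


def test_variant_heads_present():
    img = np.random.default_rng(0).random((16, 16, 3))
    for variant, head in (("A1", "aux1"), ("A2", "aux2"), ("A3", "aux3")):
        model, _ = build_model(NetworkConfig(variant=variant), seed=0)
        maps = model.forward(img)
        assert set(maps.logits) == {head}
        assert maps.fused.shape == (16, 16)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        NetworkConfig(nc=0)
    with pytest.raises(ValueError):
        NetworkConfig(narrow_width=0)
    with pytest.raises(ValueError):
        NetworkConfig(variant="A4")
    with pytest.raises(ValueError):
        NetworkConfig(kernel_size=4)


def test_backward_matches_directional_finite_difference(rng):
    """Full-network analytic gradient vs central finite differences along a
    random parameter direction (class-balanced loss, fixed everything)."""
    from lighteyes.config import DropLossConfig, TrainConfig
    from lighteyes.pipeline import step_loss

    cfg = NetworkConfig(nc=4, nl=4, narrow_width=3)
    model = LightEyesModel(cfg)
    model.init_weights(0)
    img = rng.random((8, 8, 3))
    gt = (rng.random((8, 8)) < 0.3).astype(np.uint8)
    tc = TrainConfig(loss=DropLossConfig(kind="class_balanced"))

    def total_loss():
        maps = model.forward(img, keep_cache=True)
        total, _, hg = step_loss(model, maps, gt, tc, np.random.default_rng(0))
        return total, hg

    total, hg = total_loss()
    model.zero_grads()
    model.backward(hg)
    grads = {k: v.copy() for k, v in model.gradients().items()}
    params = model.parameters()
    direction = {k: rng.normal(size=v.shape) for k, v in params.items()}
    eps = 1e-6
    for k in params:
        params[k] += eps * direction[k]
    lp, _ = total_loss()
    for k in params:
        params[k] -= 2 * eps * direction[k]
    lm, _ = total_loss()
    for k in params:
        params[k] += eps * direction[k]
    fd = (lp - lm) / (2 * eps)
    analytic = sum((grads[k] * direction[k]).sum() for k in params)
    assert abs(fd - analytic) <= 1e-6 * max(1.0, abs(fd))


def test_save_load_roundtrip_bitwise(tmp_path, rng):
    model, _ = build_model(NetworkConfig(nc=4, nl=4, narrow_width=3), seed=3)
    img = rng.random((16, 16, 3))
    before = model.forward(img).fused
    path = tmp_path / "weights.npz"
    model.save(path)
    restored = LightEyesModel.load(path)
    after = restored.forward(img).fused
    assert np.array_equal(before, after)
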