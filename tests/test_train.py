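"""Augmentation, training loop, evaluation report, manual-vs-auto fit."""

import numpy as np
import pytest

from choroidseg import (
    NetworkConfig, TrainConfig, augment, build_network, compare_manual_auto,
    dice_score, evaluate, generate_phantom, train, PhantomSpec,
)
from choroidseg.nn.autograd import Tensor
from choroidseg.nn.layers import Module
from choroidseg.phantom import BAND_INTENSITIES


@pytest.fixture(scope="module")
def small_dataset():
    out = []
    for seed in range(8):
        spec = PhantomSpec.tiny(seed=seed, pit_shift=(seed % 5) - 2,
                                choroid_px=12 + seed % 5)
        out.append(generate_phantom(spec))
    return out


class OracleModel(Module):
    """Returns a stored ground-truth mask as its probability map."""

    def __init__(self, masks):
        super().__init__()
        self.masks = {m.tobytes(): m for m in masks}
        self.queue = list(masks)
        self.cfg = NetworkConfig.tiny()

    def forward(self, x: Tensor) -> Tensor:
        mask = self.queue.pop(0)
        self.queue.append(mask)
        return Tensor(mask[None, None].astype(float))


# ---------------------------------------------------------------------- #
# augmentation


def test_augment_identity_when_disabled(tiny_phantom):
    bscan, mask = tiny_phantom
    b2, m2 = augment(bscan, mask, seed=0, rotation_deg=0.0, flip_prob=0.0,
                     jitter_strength=0.0)
    np.testing.assert_array_equal(b2.pixels, bscan.pixels)
    np.testing.assert_array_equal(m2, mask)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_augment_mask_stays_binary_and_photometric_spares_mask(
        seed, tiny_phantom):
    bscan, mask = tiny_phantom
    b2, m2 = augment(bscan, mask, seed=seed)
    assert set(np.unique(m2)) <= {0, 1}
    # photometric-only jitter never alters the mask
    b3, m3 = augment(bscan, mask, seed=seed, rotation_deg=0.0, flip_prob=0.0,
                     jitter_strength=0.2)
    np.testing.assert_array_equal(m3, mask)


def test_augment_flip_moves_image_and_mask_together():
    spec = PhantomSpec.tiny(pit_shift=6, speckle_sigma=0.0,
                            lacunae_density=0.0)
    bscan, mask = generate_phantom(spec)
    b2, m2 = augment(bscan, mask, seed=0, rotation_deg=0.0,
                     flip_prob=1.0, jitter_strength=0.0)
    np.testing.assert_array_equal(m2, mask[:, ::-1])
    # the mask still overlays the choroid band of the flipped image
    choroid_vals = b2.pixels[m2 == 1]
    assert np.isclose(choroid_vals, BAND_INTENSITIES["choroid"]).all()


# ---------------------------------------------------------------------- #
# training


def test_zero_learning_rate_leaves_weights_unchanged(small_dataset):
    model = build_network(NetworkConfig.tiny(seed=0))
    before = [p.data.copy() for p in model.parameters()]
    # full-batch so batch statistics are identical every epoch: with a
    # zero learning rate the loss history must be exactly flat
    cfg = TrainConfig(epochs=3, learning_rate=0.0, seed=0, augment=False,
                      batch_size=len(small_dataset))
    _, history = train(model, small_dataset, cfg)
    for p, b in zip(model.parameters(), before):
        np.testing.assert_array_equal(p.data, b)
    # flat up to float summation order (samples are shuffled per epoch)
    assert history == pytest.approx([history[0]] * len(history), abs=1e-12)


def test_training_is_reproducible(small_dataset):
    histories = []
    for _ in range(2):
        model = build_network(NetworkConfig.tiny(seed=1))
        _, h = train(model, small_dataset,
                     TrainConfig(epochs=2, seed=9))
        histories.append(h)
    assert histories[0] == histories[1]


def test_training_reduces_dice_loss(small_dataset):
    model = build_network(NetworkConfig.tiny(seed=2))
    _, history = train(model, small_dataset,
                       TrainConfig(epochs=5, seed=2, augment=False))
    assert history[-1] < history[0]


def test_training_rejects_empty_dataset():
    model = build_network(NetworkConfig.tiny())
    with pytest.raises(ValueError, match="empty"):
        train(model, [], TrainConfig())


# ---------------------------------------------------------------------- #
# evaluation


def test_oracle_model_scores_perfectly(small_dataset):
    masks = [m for _, m in small_dataset]
    report = evaluate(OracleModel(masks), small_dataset)
    assert report.dsc_mean == 1.0
    assert report.assd_mean == 0.0


def test_single_image_report_statistics(small_dataset):
    masks = [small_dataset[0][1]]
    report = evaluate(OracleModel(masks), small_dataset[:1])
    assert report.dsc_sd == 0.0
    assert report.dsc_max == report.dsc_mean


def test_fused_identical_models_match_single(small_dataset):
    model = build_network(NetworkConfig.tiny(seed=4))
    single = evaluate(model, small_dataset[:4])
    fused = evaluate([model, model], small_dataset[:4])
    assert single.per_image == fused.per_image


# ---------------------------------------------------------------------- #
# manual vs automated comparison


def test_compare_manual_auto_perfect_agreement(rng):
    manual = rng.uniform(150, 400, 20)
    slope, intercept, r = compare_manual_auto(np.c_[manual, manual])
    assert (slope, intercept, r) == pytest.approx((1.0, 0.0, 1.0))
    slope, intercept, r = compare_manual_auto(np.c_[manual, -manual + 5])
    assert r == pytest.approx(-1.0)


def test_compare_manual_auto_matches_direct_formula():
    pairs = [(1, 2), (2, 3), (3, 5)]
    x = np.array([1.0, 2, 3])
    y = np.array([2.0, 3, 5])
    r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum()
                          * ((y - y.mean()) ** 2).sum()))
    _, _, r = compare_manual_auto(pairs)
    assert r == pytest.approx(r_oracle)


def test_compare_manual_auto_rejects_degenerate_input():
    with pytest.raises(ValueError, match="3"):
        compare_manual_auto([(1, 1), (2, 2)])
    with pytest.raises(ValueError, match="variance"):
        compare_manual_auto([(1, 1), (1, 2), (1, 3)])
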