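"""cGAN losses, architecture contracts, and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edgegan.cgan import (
    ClassModel,
    DiscriminatorSpec,
    GeneratorSpec,
    TrainingConfig,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generator_loss,
    train_class_model,
)
from edgegan.edges import EdgeParams
from edgegan.errors import InvalidArgumentError
from edgegan.synthetic import STROMALIKE, TUMORLIKE, generate_tiles
from edgegan.tiles import Tile

from conftest import TINY_DSPEC, TINY_GSPEC


class TestDiscriminatorLoss:
    def test_perfect_discriminator_limit(self):
        assert discriminator_loss(1.0, 0.0) == pytest.approx(0.0, abs=1e-5)

    def test_coin_flip_value(self):
        assert discriminator_loss(0.5, 0.5) == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_hand_arithmetic(self):
        # -ln 0.9 - ln 0.9
        assert discriminator_loss(0.9, 0.1) == pytest.approx(-2 * np.log(0.9), rel=1e-9)

    @pytest.mark.parametrize("d_real,d_fake", [(-0.1, 0.5), (0.5, 1.2), (2.0, 2.0)])
    def test_out_of_range_rejected(self, d_real, d_fake):
        with pytest.raises(InvalidArgumentError):
            discriminator_loss(d_real, d_fake)

    def test_monotone_in_probabilities(self):
        """Loss decreases exactly when the discriminator improves."""
        grid = np.linspace(0.05, 0.95, 10)
        for d_fake in grid:
            losses = [discriminator_loss(d_real, d_fake) for d_real in grid]
            assert all(a > b for a, b in zip(losses, losses[1:]))
        for d_real in grid:
            losses = [discriminator_loss(d_real, d_fake) for d_fake in grid]
            assert all(a < b for a, b in zip(losses, losses[1:]))


class TestGeneratorLoss:
    def test_perfect_reconstruction_coin_flip(self):
        img = np.zeros((4, 4, 3))
        b = generator_loss(0.5, img, img, TrainingConfig())
        assert b.g_adv == pytest.approx(np.log(2), rel=1e-9)
        assert b.g_mse == 0.0

    def test_hand_arithmetic_total(self):
        cfg = TrainingConfig(lambda_mse=100.0, lambda_adv=1.0)
        rec = np.zeros((4, 4, 3))
        b = generator_loss(0.5, rec, rec + 0.1, cfg)
        assert b.g_mse == pytest.approx(0.01, rel=1e-9)
        assert b.g_total == pytest.approx(np.log(2) + 1.0, rel=1e-9)

    def test_generator_wins_limit(self):
        img = np.zeros((4, 4, 3))
        b = generator_loss(1.0, img, img, TrainingConfig())
        assert b.g_total == pytest.approx(0.0, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generator_loss(0.5, np.zeros((4, 4, 3)), np.zeros((5, 5, 3)), TrainingConfig())

    def test_adv_term_decreases_as_d_fake_increases(self):
        vals = [generator_loss(p, np.zeros(3), np.zeros(3), TrainingConfig()).g_adv
                for p in np.linspace(0.05, 0.95, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.01, 0.99), st.floats(0.0, 1000.0), st.floats(0.0, 10.0),
           st.integers(0, 2**31 - 1))
    def test_total_is_exact_weighted_sum(self, d_fake, lam_mse, lam_adv, seed):
        if lam_mse + lam_adv == 0:
            lam_adv = 1.0
        cfg = TrainingConfig(lambda_mse=lam_mse, lambda_adv=lam_adv)
        rng = np.random.default_rng(seed)
        rec = rng.standard_normal((3, 3, 3))
        tgt = rng.standard_normal((3, 3, 3))
        b = generator_loss(d_fake, rec, tgt, cfg)
        assert b.g_total == pytest.approx(lam_adv * b.g_adv + lam_mse * b.g_mse,
                                          abs=1e-12, rel=1e-12)


class TestBuilders:
    def test_generator_forward_contract(self):
        gen = build_generator(GeneratorSpec(depth=2, base_filters=8), 64, seed=0)
        y = gen.forward(np.zeros((1, 3, 64, 64), dtype=np.float32), train=False)
        assert y.shape == (1, 3, 64, 64)
        assert np.isfinite(y).all() and (np.abs(y) <= 1).all()

    def test_build_determinism(self):
        a = build_generator(TINY_GSPEC, 32, seed=9)
        b = build_generator(TINY_GSPEC, 32, seed=9)
        for pa, pb in zip(a.param_arrays(), b.param_arrays()):
            np.testing.assert_array_equal(pa, pb)
        da = build_discriminator(TINY_DSPEC, 32, seed=9)
        db = build_discriminator(TINY_DSPEC, 32, seed=9)
        for pa, pb in zip(da.param_arrays(), db.param_arrays()):
            np.testing.assert_array_equal(pa, pb)

    def test_indivisible_tile_size_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_generator(GeneratorSpec(depth=3, base_filters=8), 36)

    def test_generator_parameter_count_hand_derived(self):
        """depth 2, base 8: layer-by-layer sum of kernel*in*out + out.

        enc0 Conv 3->8:    4*4*3*8  + 8  = 392
        enc1 Conv 8->16:   4*4*8*16 + 16 = 2064
        dec0 ConvT 16->8:  4*4*16*8 + 8  = 2056
        dec1 ConvT 16->3:  4*4*16*3 + 3  = 771   (input is concat(8, skip 8))
        total                            = 5283
        """
        gen = build_generator(GeneratorSpec(depth=2, base_filters=8), 32)
        assert gen.n_params() == 392 + 2064 + 2056 + 771

    def test_discriminator_parameter_count_hand_derived(self):
        """in 6, stages 2, base 8, tile 32:

        conv0 6->8:  4*4*6*8  + 8  = 776
        conv1 8->16: 4*4*8*16 + 16 = 2064
        dense (16*8*8)->2: 1024*2+2 = 2050
        total                       = 4890
        """
        disc = build_discriminator(DiscriminatorSpec(conv_stages=2, base_filters=8), 32)
        assert disc.n_params() == 776 + 2064 + 2050

    def test_discriminator_probabilities_normalised(self):
        disc = build_discriminator(TINY_DSPEC, 32, seed=0)
        p = disc.predict_proba(np.random.default_rng(0)
                               .standard_normal((3, 6, 32, 32)).astype(np.float32))
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestTraining:
    def test_overfits_single_tile(self):
        """200 steps on one repeated tile must reduce reconstruction MSE."""
        tile = generate_tiles(TUMORLIKE, 1, 32)[0]
        tiles = [Tile(pixels=tile.pixels.copy(), label=tile.label) for _ in range(8)]
        cfg = TrainingConfig(epochs=25, batch_size=8, learning_rate=1e-3, seed=3)
        model = train_class_model(tiles, EdgeParams(sigma=2.0),
                                  TINY_GSPEC, TINY_DSPEC, cfg)
        assert model.training_log[-1].g_mse < model.training_log[0].g_mse

    def test_bit_reproducible(self):
        tiles = generate_tiles(STROMALIKE, 8, 32)
        cfg = TrainingConfig(epochs=1, batch_size=4, seed=11)
        m1 = train_class_model(tiles, EdgeParams(), TINY_GSPEC, TINY_DSPEC, cfg)
        m2 = train_class_model(tiles, EdgeParams(), TINY_GSPEC, TINY_DSPEC, cfg)
        assert m1.fingerprint == m2.fingerprint

    def test_mixed_labels_rejected(self):
        tiles = generate_tiles(TUMORLIKE, 2, 32) + generate_tiles(STROMALIKE, 2, 32)
        with pytest.raises(InvalidArgumentError):
            train_class_model(tiles, EdgeParams(), TINY_GSPEC, TINY_DSPEC,
                              TrainingConfig(epochs=1))

    def test_training_isolated_from_other_class_data(self, tmp_path):
        """Training a class model is invariant to other classes' data being
        present on disk — each network learns a single class."""
        from edgegan.tiling import write_tileset

        tiles = generate_tiles(TUMORLIKE, 6, 32)
        cfg = TrainingConfig(epochs=1, batch_size=4, seed=13)
        m_before = train_class_model(tiles, EdgeParams(), TINY_GSPEC, TINY_DSPEC, cfg)
        write_tileset(generate_tiles(STROMALIKE, 6, 32), tmp_path / "other_class")
        m_after = train_class_model(tiles, EdgeParams(), TINY_GSPEC, TINY_DSPEC, cfg)
        assert m_before.fingerprint == m_after.fingerprint

    def test_loss_log_terms_finite_and_nonnegative(self):
        tiles = generate_tiles(TUMORLIKE, 8, 32)
        cfg = TrainingConfig(epochs=2, batch_size=4, seed=5)
        model = train_class_model(tiles, EdgeParams(), TINY_GSPEC, TINY_DSPEC, cfg)
        assert len(model.training_log) == 2
        for rec in model.training_log:
            for term in (rec.d_loss, rec.g_adv, rec.g_mse, rec.g_total):
                assert np.isfinite(term) and term >= 0


class TestReconstruct:
    def test_shape_range_and_determinism(self, tiny_trained_registry):
        model = next(iter(tiny_trained_registry))
        tile = generate_tiles(TUMORLIKE, 1, 32)[0].pixels
        r1 = model.reconstruct(tile)
        r2 = model.reconstruct(tile)
        assert r1.shape == tile.shape and r1.dtype == np.uint8
        np.testing.assert_array_equal(r1, r2)

    def test_size_mismatch_rejected(self, tiny_trained_registry):
        model = next(iter(tiny_trained_registry))
        with pytest.raises(InvalidArgumentError):
            model.reconstruct(np.zeros((64, 64, 3), dtype=np.uint8))

    def test_same_class_error_below_cross_class(self, tiny_trained_registry):
        """The framework's core premise on held-out tiles: each generator
        reconstructs its own class better than the other class."""
        from edgegan.classify import dissimilarity
        from edgegan.tiles import stack_pixels

        for spec in (TUMORLIKE, STROMALIKE):
            held_out = generate_tiles(spec, 50, 32)[40:]
            px = stack_pixels(held_out)
            errs = {}
            for model in tiny_trained_registry:
                recon = model.reconstruct_batch(px)
                errs[model.label] = np.mean([
                    dissimilarity("mse", px[i], recon[i]) for i in range(len(px))
                ])
            same = errs[spec.name]
            cross = min(v for k, v in errs.items() if k != spec.name)
            assert same < cross
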