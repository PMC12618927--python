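import numpy as np
import pytest

from wavecal.codec import (Bitstream, CodecConfig, CodecModel, EarlyStopper,
                           TrainConfig, compress, decompress, rd_curve, train)
from wavecal.errors import ConfigurationError, FormatError, UsageError
from wavecal.phantoms import PhantomSpec, generate_dataset, make_split
from wavecal.vae import LossWeights

TINY_CODEC = CodecConfig(image_hw=(32, 32), channels=(8, 16), latent_dim=32,
                         dense_hidden=64, heads=4, embed_dim=16, dropout=0.0)
FAST_TRAIN = TrainConfig(learning_rate=1e-2, epochs=3, batch_size=16, seed=0,
                         loss_weights=LossWeights(1.0, 0.01, 1e-4))


@pytest.fixture(scope="module")
def trained_setup():
    imgs = np.stack([g.pixels for g in generate_dataset(
        24, PhantomSpec(height=32, width=32), seed=2)])
    split = make_split(24, seed=2)
    model, log = train(imgs, split, FAST_TRAIN, codec_config=TINY_CODEC)
    return imgs, split, model, log


class TestBitstreamContainer:
    def test_header_round_trip_is_exact(self):
        bs = Bitstream(height=64, width=48, wavelet_id=0, levels=1,
                       qstep=0.125, clip_range=127,
                       model_hash=b"\x01\x02\x03\x04\x05\x06\x07\x08",
                       n_symbols=32, payload=b"\xde\xad\xbe\xef")
        back = Bitstream.from_bytes(bs.to_bytes())
        for f in ("height", "width", "wavelet_id", "levels", "qstep",
                  "clip_range", "model_hash", "n_symbols", "payload"):
            assert getattr(back, f) == getattr(bs, f)

    def test_bpp_accounts_for_header_and_payload_bits(self):
        bs = Bitstream(height=10, width=10, wavelet_id=0, levels=1, qstep=0.1,
                       clip_range=127, model_hash=b"\x00" * 8, n_symbols=4,
                       payload=b"abc")
        assert bs.bpp == len(bs.to_bytes()) * 8 / 100

    def test_every_single_byte_corruption_is_detected(self):
        bs = Bitstream(height=4, width=4, wavelet_id=0, levels=1, qstep=0.1,
                       clip_range=3, model_hash=b"\x00" * 8, n_symbols=3,
                       payload=b"\x12\x34\x56")
        blob = bytearray(bs.to_bytes())
        start = len(blob) - len(bs.payload)
        for i in range(start, len(blob)):
            corrupted = bytearray(blob)
            corrupted[i] ^= 0xFF
            with pytest.raises(FormatError):
                Bitstream.from_bytes(bytes(corrupted))

    def test_bad_magic_rejected(self):
        with pytest.raises(FormatError):
            Bitstream.from_bytes(b"NOPE" + b"\x00" * 40)


class TestEarlyStopper:
    def test_halts_patience_epochs_after_plateau(self):
        # val loss improves until epoch 3 then plateaus: stop at 3 + patience
        stopper = EarlyStopper(patience=4)
        losses = [1.0, 0.8, 0.6, 0.5] + [0.5] * 20
        stopped_at = None
        for epoch, loss in enumerate(losses):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 3
        assert stopped_at == 3 + 4

    def test_first_occurrence_kept_on_ties(self):
        stopper = EarlyStopper(patience=10)
        for loss in [1.0, 0.4, 0.4, 0.4]:
            stopper.update(loss)
        assert stopper.best_epoch == 1


class TestCompressDecompress:
    def test_bitstreams_are_byte_identical_across_runs(self, trained_setup):
        imgs, _, model, _ = trained_setup
        a = compress(imgs[0], model).to_bytes()
        b = compress(imgs[0], model).to_bytes()
        assert a == b

    def test_reconstruction_shape_range_and_determinism(self, trained_setup):
        imgs, _, model, _ = trained_setup
        bs = compress(imgs[1], model)
        r1 = decompress(bs, model).pixels
        r2 = decompress(Bitstream.from_bytes(bs.to_bytes()), model).pixels
        assert r1.shape == imgs[1].shape
        assert r1.min() >= 0.0 and r1.max() <= 1.0
        assert np.array_equal(r1, r2)

    def test_model_hash_mismatch_refused(self, trained_setup):
        imgs, _, model, _ = trained_setup
        bs = compress(imgs[0], model)
        other = CodecModel(TINY_CODEC, seed=99)
        other.trained = True
        with pytest.raises(UsageError):
            decompress(bs, other)

    def test_untrained_model_refused(self, trained_setup):
        imgs, _, _, _ = trained_setup
        with pytest.raises(UsageError):
            compress(imgs[0], CodecModel(TINY_CODEC, seed=0))

    def test_attached_filter_changes_and_stays_in_range(self, trained_setup):
        from wavecal.spatial_filter import FilterKernel

        imgs, _, model, _ = trained_setup
        bs = compress(imgs[0], model)
        plain = decompress(bs, model).pixels
        model.filter = FilterKernel(np.full((3, 3), 1 / 9))
        try:
            smoothed = decompress(bs, model).pixels
        finally:
            model.filter = None
        assert not np.array_equal(plain, smoothed)
        assert smoothed.min() >= 0.0 and smoothed.max() <= 1.0

    def test_save_load_preserves_hash_and_reconstruction(self, trained_setup,
                                                         tmp_path):
        imgs, _, model, _ = trained_setup
        p = tmp_path / "model.npz"
        model.save(p)
        loaded = CodecModel.load(p)
        assert loaded.model_hash == model.model_hash
        bs = compress(imgs[2], model)
        assert np.array_equal(decompress(bs, model).pixels,
                              decompress(bs, loaded).pixels)


class TestTraining:
    def test_same_config_and_seed_give_identical_checkpoints(self):
        imgs = np.stack([g.pixels for g in generate_dataset(
            16, PhantomSpec(height=32, width=32), seed=4)])
        split = make_split(16, seed=4)
        cfg = TrainConfig(learning_rate=1e-2, epochs=2, batch_size=8, seed=1,
                          loss_weights=LossWeights(1.0, 0.0, 1e-4))
        m1, _ = train(imgs, split, cfg, codec_config=TINY_CODEC)
        m2, _ = train(imgs, split, cfg, codec_config=TINY_CODEC)
        assert m1.model_hash == m2.model_hash

    def test_training_reduces_validation_loss(self, trained_setup):
        _, _, _, log = trained_setup
        assert min(log.val_recon_mse[1:]) < log.val_recon_mse[0]

    def test_cross_validation_covers_each_image_once(self):
        from wavecal.codec import cross_validate

        imgs = np.stack([g.pixels for g in generate_dataset(
            12, PhantomSpec(height=32, width=32), seed=6)])
        cfg = TrainConfig(learning_rate=1e-2, epochs=1, batch_size=8, seed=0,
                          loss_weights=LossWeights(1.0, 0.0, 1e-4))
        out = cross_validate(imgs, cfg, k=3, codec_config=TINY_CODEC)
        assert len(out["fold_val_mse"]) == 3
        assert out["mean_val_mse"] == pytest.approx(
            np.mean(out["fold_val_mse"]))
        assert out["sd_val_mse"] >= 0.0

    def test_empty_split_rejected(self):
        imgs = np.zeros((12, 32, 32))
        from wavecal.phantoms import DatasetSplit

        bad = DatasetSplit(train_ids=(), val_ids=(1,), test_ids=(2,))
        with pytest.raises(UsageError):
            train(imgs, bad, FAST_TRAIN, codec_config=TINY_CODEC)


class TestRdCurve:
    def test_one_record_per_image_and_qstep(self, trained_setup):
        imgs, _, model, _ = trained_setup
        recs = rd_curve(imgs[:2], model, (0.5, 2.0))
        assert len(recs) == 4

    def test_identical_qsteps_give_identical_records(self, trained_setup):
        imgs, _, model, _ = trained_setup
        recs = rd_curve(imgs[:1], model, (0.2, 0.2))
        assert recs[0].bpp == recs[1].bpp
        assert recs[0].psnr_db == recs[1].psnr_db

    def test_rate_strictly_drops_for_4x_coarser_quantization(self,
                                                             trained_setup):
        imgs, _, model, _ = trained_setup
        recs = rd_curve(imgs[:4], model, (0.05, 0.2, 0.8))
        bpp = [np.mean([r.bpp for r in recs[i * 4 : (i + 1) * 4]])
               for i in range(3)]
        assert bpp[0] > bpp[1] > bpp[2]

    def test_single_qstep_rejected(self, trained_setup):
        imgs, _, model, _ = trained_setup
        with pytest.raises(ConfigurationError):
            rd_curve(imgs[:1], model, (0.5,))


class TestCodecConfig:
    def test_unknown_wavelet_and_multi_level_rejected(self):
        with pytest.raises(ConfigurationError):
            CodecConfig(wavelet="nope")
        with pytest.raises(ConfigurationError):
            CodecConfig(levels=2)
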