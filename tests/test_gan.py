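import numpy as np
import pytest

import spherogen as sg
from spherogen.volumes import LabelVolume


def batch_at(p_real=0.5, p_fake=0.5, n=3):
    rng = np.random.default_rng(0)
    y = rng.random((n, 4, 4, 4))
    return sg.GanBatch(
        y=y, y_hat=y.copy(),
        d_real=np.full(n, p_real), d_fake=np.full(n, p_fake),
        dseg_real=np.full(n, p_real), dseg_fake=np.full(n, p_fake),
    )


class TestSplitOutput:
    def test_two_channels_split_unchanged(self):
        rng = np.random.default_rng(1)
        stack = rng.random((2, 3, 4, 5))
        y, v = sg.split_generator_output(stack)
        assert np.array_equal(y.data, stack[0])
        assert np.array_equal(v.data, stack[1])
        assert y.shape == v.shape

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            sg.split_generator_output(np.zeros((3, 2, 2, 2)))


class TestLosses:
    def test_uninformed_discriminator_gives_two_log_half(self):
        b = batch_at(0.5, 0.5)
        assert sg.loss_cgan(b) == pytest.approx(2 * np.log(0.5), abs=1e-9)
        assert sg.loss_sgan(b) == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_perfect_discriminator_clamped_limit_near_zero(self):
        eps = 1e-7
        b = batch_at(1.0, 0.0)
        assert sg.loss_cgan(b, eps) == pytest.approx(0.0, abs=1e-5)
        assert sg.loss_sgan(b, eps) == pytest.approx(0.0, abs=1e-5)

    def test_batch_mean_invariance(self):
        one = sg.GanBatch(d_real=np.array([0.7]), d_fake=np.array([0.4]))
        two = sg.GanBatch(d_real=np.array([0.7, 0.7]), d_fake=np.array([0.4, 0.4]))
        assert sg.loss_cgan(one) == pytest.approx(sg.loss_cgan(two))

    def test_l1_examples(self):
        assert sg.loss_l1(np.array([[[1.0, 0.0]]]), np.array([[[0.0, 1.0]]])) == 1.0
        y = np.random.default_rng(0).random((3, 3, 3))
        assert sg.loss_l1(y, y) == 0.0
        assert sg.loss_l1(3 * y, np.zeros_like(y)) == pytest.approx(3 * sg.loss_l1(y, np.zeros_like(y)))

    def test_l1_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sg.loss_l1(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_sgan_ignores_images_entirely(self):
        rng = np.random.default_rng(2)
        b1 = batch_at(0.6, 0.3)
        b2 = batch_at(0.6, 0.3)
        b2.y = rng.random(b2.y.shape)
        b2.y_hat = rng.random(b2.y.shape)
        b2.x = rng.random(b2.y.shape)
        assert sg.loss_sgan(b1) == sg.loss_sgan(b2)


class TestObjectives:
    def test_cgan_combination_arithmetic(self):
        # components (-1.0, -0.5, 0.2) with lambda_L1 = 100 -> total 18.5
        b = batch_at()
        b.d_real = np.array([np.exp(-1.0)])
        b.d_fake = np.array([1.0 - 1.0 + 1e-12])  # log(1 - ~0) ~ 0
        b.dseg_real = np.array([np.exp(-0.5)])
        b.dseg_fake = np.array([1e-12])
        b.y = np.full((1, 2, 2, 2), 0.2)
        b.y_hat = np.zeros((1, 2, 2, 2))
        total, comp = sg.objective_cgan(b, sg.LossWeights(lambda_L1=100.0))
        assert comp["cgan"] == pytest.approx(-1.0, abs=1e-5)
        assert comp["sgan"] == pytest.approx(-0.5, abs=1e-5)
        assert comp["l1"] == pytest.approx(0.2)
        assert total == pytest.approx(comp["cgan"] + comp["sgan"] + 100 * comp["l1"])
        assert total == pytest.approx(18.5, abs=1e-3)

    def test_lambda_zero_drops_l1(self):
        b = batch_at(0.5, 0.5)
        total, comp = sg.objective_cgan(b, sg.LossWeights(lambda_L1=0.0))
        assert total == pytest.approx(comp["cgan"] + comp["sgan"])

    def test_cyclegan_all_half_discriminators(self):
        rng = np.random.default_rng(3)
        vol = rng.random((2, 4, 4, 4))
        b = sg.GanBatch(
            y=vol, y_hat=vol.copy(), x=vol, x_tilde=vol.copy(), y_tilde=vol.copy(),
            d_real=np.full(2, 0.5), d_fake=np.full(2, 0.5),
            dseg_real=np.full(2, 0.5), dseg_fake=np.full(2, 0.5),
            da_real=np.full(2, 0.5), da_fake=np.full(2, 0.5),
            db_real=np.full(2, 0.5), db_fake=np.full(2, 0.5),
        )
        total, comp = sg.objective_cyclegan(b, sg.LossWeights(lambda_cyc=10.0))
        assert comp["cyc"] == 0.0  # perfect cycle
        for key in ("gan_a", "gan_b", "gan_s"):
            assert comp[key] == pytest.approx(2 * np.log(0.5), abs=1e-9)
        assert total == pytest.approx(6 * np.log(0.5), abs=1e-9)

    def test_cycle_weight_scales_linearly(self):
        rng = np.random.default_rng(4)
        vol = rng.random((2, 3, 3, 3))
        b = sg.GanBatch(
            y=vol, y_hat=vol, x=vol, x_tilde=vol + 0.1, y_tilde=vol,
            d_real=np.full(2, 0.5), d_fake=np.full(2, 0.5),
            dseg_real=np.full(2, 0.5), dseg_fake=np.full(2, 0.5),
            da_real=np.full(2, 0.5), da_fake=np.full(2, 0.5),
            db_real=np.full(2, 0.5), db_fake=np.full(2, 0.5),
        )
        t1, c1 = sg.objective_cyclegan(b, sg.LossWeights(lambda_cyc=1.0))
        t2, c2 = sg.objective_cyclegan(b, sg.LossWeights(lambda_cyc=2.0))
        assert t2 - t1 == pytest.approx(c1["cyc"])


class TestPostprocess:
    def make_two_cell_volume(self):
        """Two cells split by a 1-voxel membrane plane at x = 5."""
        cells = np.zeros((7, 9, 11), dtype=np.int64)
        cells[:, :, :6] = 1
        cells[:, :, 6:] = 2
        membrane = np.zeros_like(cells)
        membrane[:, :, 5:7] = 1  # boundary voxels of both cells
        return LabelVolume(cells), LabelVolume(membrane)

    def test_touching_nuclei_split_into_cell_labels(self):
        cells, membrane = self.make_two_cell_volume()
        v_hat = np.zeros(cells.shape)
        v_hat[1:6, 2:7, 2:10] = 1.0  # one blob spanning the membrane
        out = sg.postprocess_instance_labels(v_hat, membrane, cells,
                                             threshold=0.5, opening_radius=1)
        labels = set(np.unique(out.data)) - {0}
        assert labels == {1, 2}
        assert np.all(cells.data[out.data == 1] == 1)
        assert np.all(cells.data[out.data == 2] == 2)

    def test_blob_in_medium_removed(self):
        cells, membrane = self.make_two_cell_volume()
        cells.data[:, :, 9:] = 0  # open medium region
        v_hat = np.zeros(cells.shape)
        v_hat[2:5, 2:5, 2:5] = 1.0
        v_hat[1:6, 1:6, 9:] = 1.0  # artifact entirely in medium
        out = sg.postprocess_instance_labels(v_hat, membrane, cells)
        assert np.all(out.data[:, :, 9:] == 0)
        assert 1 in np.unique(out.data)

    def test_output_subsets(self):
        cells, membrane = self.make_two_cell_volume()
        rng = np.random.default_rng(0)
        v_hat = rng.random(cells.shape)
        out = sg.postprocess_instance_labels(v_hat, membrane, cells)
        fg = out.data > 0
        assert np.all(v_hat[fg] >= 0.5)           # foreground within threshold set
        assert np.all(cells.data[fg] == out.data[fg])  # labels from cells
        assert not np.any(membrane.data[fg] > 0)  # membrane subtracted

    def test_idempotent_on_own_output(self):
        cells, membrane = self.make_two_cell_volume()
        v_hat = np.zeros(cells.shape)
        v_hat[1:6, 2:7, 2:5] = 1.0
        out1 = sg.postprocess_instance_labels(v_hat, membrane, cells)
        out2 = sg.postprocess_instance_labels(
            (out1.data > 0).astype(float), LabelVolume(np.zeros_like(membrane.data)),
            cells
        )
        assert np.array_equal(out1.data, out2.data)


class TestSmokeHarness:
    def test_trajectory_finite_and_complete(self):
        traj = sg.smoke_train_harness(iters=10, seed=0)
        assert len(traj) == 10
        for entry in traj:
            assert set(entry) == {"total", "cgan", "sgan", "l1"}
            assert all(np.isfinite(v) for v in entry.values())

    def test_deterministic_given_seed(self):
        a = sg.smoke_train_harness(iters=5, seed=3)
        b = sg.smoke_train_harness(iters=5, seed=3)
        assert a == b

    def test_l1_component_reported_with_zero_weight(self):
        traj = sg.smoke_train_harness(iters=3, weights=sg.LossWeights(lambda_L1=0.0))
        assert all("l1" in e for e in traj)

    def test_missing_backend_raises(self):
        with pytest.raises(NotImplementedError):
            sg.smoke_train_harness(iters=1, backend="torch")
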