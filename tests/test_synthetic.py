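"""Generator contracts: trace model, population structure, volumes, skeletons."""

import numpy as np
import pytest

from olivemap.protocol import generate_protocol
from olivemap.synthetic import (PopulationSpec, Skeleton, TuningParams,
                                expected_drive, expected_response,
                                generate_population, generate_skeletons,
                                generate_voxel_volume, simulate_trace)
from olivemap.overlap import skeleton_endpoints


@pytest.fixture(scope="module")
def epochs():
    p = generate_protocol(monocular_blocks=True, include_conv_div=True, seed=0)
    by_label = {}
    for e in p.epochs:
        if not e.discard:
            by_label[(e.eye, e.label())] = e
    return by_label


def plateau(trace, epoch, baseline_F):
    """Mean dF/F0 over the last third of the moving phase (kernel settled)."""
    dff = trace / baseline_F - 1.0
    hi = epoch.n_frames_pre + epoch.n_frames_move
    lo = hi - epoch.n_frames_move // 3
    return dff[lo:hi].mean()


class TestSimulateTrace:
    def test_zero_drive_is_flat_baseline(self, epochs):
        tp = TuningParams(noise_sd=0.0, amplitude=0.0, rot_gain_cw=0.0)
        tr = simulate_trace(tp, epochs[("both", "T000")], 1, seed=0)[0]
        assert np.allclose(tr, tp.baseline_F)

    def test_uniform_tuning_plateaus_at_amplitude(self, epochs):
        """kappa = 0 with eye weights summing to 1: every direction
        plateaus at the configured amplitude."""
        tp = TuningParams(noise_sd=0.0, amplitude=0.6, kappa=0.0,
                          w_contra=0.5, w_ipsi=0.5)
        for d in range(0, 360, 45):
            e = epochs[("both", f"T{d:03d}")]
            tr = simulate_trace(tp, e, 1, seed=0)[0]
            assert plateau(tr, e, tp.baseline_F) == pytest.approx(0.6, rel=1e-3)

    def test_von_mises_attenuation_ratio(self, epochs):
        """kappa = 4, PD = 0: the 180-degree response is exp(-8) of the
        preferred one (closed form of the drive)."""
        tp = TuningParams(noise_sd=0.0, amplitude=0.5, kappa=4.0, pd_deg=0.0)
        r0 = expected_response(tp, epochs[("both", "T000")])
        r180 = expected_response(tp, epochs[("both", "T180")])
        assert r180 / r0 == pytest.approx(np.exp(-8.0), rel=1e-9)

    def test_linearity_in_amplitude(self, epochs):
        e = epochs[("both", "T000")]
        r1 = expected_response(TuningParams(noise_sd=0.0, amplitude=0.3), e)
        r2 = expected_response(TuningParams(noise_sd=0.0, amplitude=0.6), e)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_zero_ipsi_weight_silences_ipsilateral_eye(self, epochs):
        tp = TuningParams(noise_sd=0.0, amplitude=0.5, w_contra=1.0,
                          w_ipsi=0.0)
        # neuron on the left: its ipsilateral eye is the left one
        e = epochs[("left", "T000")]
        tr = simulate_trace(tp, e, 1, seed=0, side="left")[0]
        assert np.allclose(tr, tp.baseline_F)
        tr_contra = simulate_trace(tp, e, 1, seed=0, side="right")[0]
        assert plateau(tr_contra, e, tp.baseline_F) > 0.4

    def test_rotation_gain_drives_rotation_epochs(self, epochs):
        tp = TuningParams(noise_sd=0.0, amplitude=0.0, rot_gain_cw=0.5,
                          w_contra=0.5, w_ipsi=0.5)
        assert expected_drive(tp, epochs[("both", "CW")]) == pytest.approx(0.5)
        assert expected_drive(tp, epochs[("both", "CCW")]) == 0.0

    def test_deterministic_given_seed(self, epochs):
        tp = TuningParams(noise_sd=2.0)
        e = epochs[("both", "T090")]
        a = simulate_trace(tp, e, 3, seed=5)
        b = simulate_trace(tp, e, 3, seed=5)
        assert np.array_equal(a, b)

    def test_repetition_count_guard(self, epochs):
        with pytest.raises(ValueError):
            simulate_trace(TuningParams(), epochs[("both", "T000")], 0)


class TestGeneratePopulation:
    def test_forward_only_class_has_forward_pds(self):
        spec = PopulationSpec(seed=1)
        for name in spec.classes:
            spec.classes[name].n = 0
        spec.classes["forward"].n = 30
        ds = generate_population(spec)
        cos = np.cos(np.deg2rad(ds.ground_truth["pd_deg"]))
        assert (cos > 0).all()

    def test_determinism(self):
        a = generate_population(PopulationSpec(seed=9))
        b = generate_population(PopulationSpec(seed=9))
        assert a.ground_truth.equals(b.ground_truth)
        assert a.anatomy.equals(b.anatomy)
        ta = a.neurons[0].traces[(0, 0)]
        tb = b.neurons[0].traces[(0, 0)]
        assert np.array_equal(ta, tb)

    def test_forward_rostral_backward_caudal_offset(self, small_dataset):
        gt = small_dataset.ground_truth
        fwd = gt[gt["class_label"] == "forward"]["rc_um"].mean()
        bwd = gt[gt["class_label"] == "backward"]["rc_um"].mean()
        assert fwd < bwd  # rostral pole at low rc

    def test_rotation_classes_lateralized(self, small_dataset):
        gt = small_dataset.ground_truth
        cw = gt[gt["class_label"] == "cw_rotation"]["lr_um"].mean()
        ccw = gt[gt["class_label"] == "ccw_rotation"]["lr_um"].mean()
        assert cw > 0 > ccw  # CW on the right, CCW on the left

    def test_every_neuron_has_traces_for_every_stimulus(self, small_dataset):
        small_dataset.validate()

    def test_zero_neurons_rejected(self):
        spec = PopulationSpec(seed=0)
        for name in spec.classes:
            spec.classes[name].n = 0
        with pytest.raises(ValueError):
            generate_population(spec)


@pytest.fixture(scope="module")
def one_neuron_volume():
    spec = PopulationSpec(seed=3, noise_sd=0.0)
    for name in spec.classes:
        spec.classes[name].n = 0
    spec.classes["forward"].n = 1
    spec.classes["forward"].pd_sd_deg = 1.0
    ds = generate_population(spec)
    vol = generate_voxel_volume(ds, seed=0, noise_sd=0.0,
                                brightness_noise_sd=0.0)
    return ds, vol


class TestGenerateVoxelVolume:

    def test_brightness_peaks_at_centroid(self, one_neuron_volume):
        ds, vol = one_neuron_volume
        peak = np.unravel_index(np.argmax(vol.brightness),
                                vol.brightness.shape)
        assert peak == vol.voxel_index(ds.neurons[0].centroid_um)

    def test_forward_neuron_prefers_forward_stimuli(self, one_neuron_volume):
        ds, vol = one_neuron_volume
        idx = vol.voxel_index(ds.neurons[0].centroid_um)
        mean = vol.responses.mean(axis=1)
        fwd = [i for i, e in enumerate(vol.epochs)
               if e.kind == "translation" and e.direction_deg % 360 in
               (315, 0, 45)]
        bwd = [i for i, e in enumerate(vol.epochs)
               if e.kind == "translation" and e.direction_deg % 360 in
               (135, 180, 225)]
        assert mean[fwd][(slice(None),) + idx].mean() > \
            mean[bwd][(slice(None),) + idx].mean()

    def test_blob_center_matches_expected_response(self, one_neuron_volume):
        """At zero noise the voxel at the centroid reproduces the
        generator's closed-form window-mean response."""
        from olivemap.synthetic import TuningParams
        ds, vol = one_neuron_volume
        row = ds.ground_truth.iloc[0]
        params = TuningParams(amplitude=row["amplitude"], pd_deg=row["pd_deg"],
                              kappa=row["kappa"], noise_sd=0.0)
        idx = vol.voxel_index(ds.neurons[0].centroid_um)
        mean = vol.responses.mean(axis=1)
        for i, e in enumerate(vol.epochs):
            if e.kind != "translation":
                continue
            expected = expected_response(params, e, side=ds.neurons[0].side)
            # the rendered blob is sampled at the nearest voxel center
            assert mean[i][idx] == pytest.approx(expected, abs=0.1 * max(
                expected, 0.05))

    def test_empty_dataset_rejected(self, small_dataset):
        import dataclasses
        empty = dataclasses.replace(small_dataset, neurons=[])
        with pytest.raises(ValueError):
            generate_voxel_volume(empty)


class TestSkeletons:
    def test_straight_polyline_has_two_endpoints(self):
        nodes = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        sk = Skeleton(nodes_um=nodes, parents=np.array([-1, 0, 1]))
        mask = sk.rasterize(axes=(0, 1), scale_um=1.0)
        assert len(skeleton_endpoints(mask)) == 2

    def test_leaves_at_requested_terminals(self):
        terms = np.array([[20.0, 5.0, 0.0], [20.0, -5.0, 0.0],
                          [25.0, 0.0, 3.0]])
        [sk] = generate_skeletons([terms], np.array([[0.0, 0.0, 0.0]]),
                                  seed=1)
        leaf_coords = sk.nodes_um[sk.leaves()]
        for t in terms:
            assert np.any(np.all(np.isclose(leaf_coords, t), axis=1))

    def test_three_leaf_tree_has_four_raster_endpoints(self):
        """Root plus three leaves; verified against brute-force neighbor
        counting on the rasterized mask."""
        terms = np.array([[30.0, 10.0, 0.0], [30.0, -10.0, 0.0],
                          [35.0, 0.0, 0.0]])
        [sk] = generate_skeletons([terms], np.array([[0.0, 0.0, 0.0]]),
                                  seed=2, jitter_um=0.0)
        mask = sk.rasterize(axes=(0, 1), scale_um=1.0)
        eps = skeleton_endpoints(mask)
        brute = []
        for r, c in np.argwhere(mask):
            n = mask[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2].sum() - 1
            if n <= 1:
                brute.append((r, c))
        assert sorted(map(tuple, eps)) == sorted(brute)
        assert len(eps) == 4

    def test_empty_terminal_list_rejected(self):
        with pytest.raises(ValueError):
            generate_skeletons([np.empty((0, 3))],
                               np.array([[0.0, 0.0, 0.0]]), seed=0)

    def test_tree_validation(self):
        with pytest.raises(ValueError):  # two roots
            Skeleton(nodes_um=np.zeros((2, 3)), parents=np.array([-1, -1]))
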