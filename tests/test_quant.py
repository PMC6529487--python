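"""SUV quantification: decay correction, VoI erosion, SUVmean/SUVpeak,
fraction of dose — each checked against brute-force oracles."""

import dataclasses

import numpy as np
import pytest

from albupet.quant import (
    EmptyVoIError,
    decay_correct,
    extract_voi,
    fraction_of_dose,
    quantify_organ,
    quantify_phantom,
    suv_image,
    suv_mean,
    suv_peak,
)
from albupet.simulate import Ellipsoid, PhantomGeometry, VoxelPhantom, build_phantom


def make_phantom(activity, labels, names, spacing=(6.0, 6.0, 6.0), t_scan=0.0,
                 body_weight=75000.0, injected=14e6):
    return VoxelPhantom(
        voxel_spacing=spacing,
        activity_map=activity,
        label_map=labels,
        label_names=names,
        body_weight=body_weight,
        injected_activity=injected,
        t_scan=t_scan,
    )


@pytest.fixture()
def box_phantom(rng):
    """A 20^3 phantom with a 10^3 cubic organ and random activity."""
    labels = np.ones((20, 20, 20), dtype=np.uint16)
    labels[5:15, 5:15, 5:15] = 2
    activity = rng.uniform(10.0, 100.0, size=(20, 20, 20))
    return make_phantom(activity, labels, {"body": 1, "organ": 2})


class TestDecayCorrect:
    def test_one_half_life_doubles(self):
        assert decay_correct(50.0, 78.41, 78.41) == pytest.approx(100.0, rel=1e-12)

    def test_time_zero_identity(self):
        assert decay_correct(7.5, 0.0, 78.41) == 7.5

    def test_closed_form_exponent(self):
        # independent evaluation of the exponent
        assert decay_correct(1.0, 168.0, 78.41) == pytest.approx(
            np.exp(np.log(2.0) * 168.0 / 78.41), rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(1.0, -5.0, 78.41)


class TestExtractVoi:
    def test_erosion_zero_returns_full_mask(self, box_phantom):
        voi = extract_voi(box_phantom, "organ", margin=0)
        assert voi.sum() == 1000

    def test_eroded_voxels_never_touch_other_labels(self, box_phantom):
        """Brute-force 26-neighbourhood check of the erosion contract."""
        voi = extract_voi(box_phantom, "organ", margin=1)
        assert 0 < voi.sum() < 1000
        organ = box_phantom.label_map == 2
        idx = np.argwhere(voi)
        for z, y, x in idx:
            neigh = organ[
                max(z - 1, 0) : z + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2
            ]
            assert neigh.all()

    def test_single_voxel_organ_fully_erodes(self):
        labels = np.ones((5, 5, 5), dtype=np.uint16)
        labels[2, 2, 2] = 2
        phantom = make_phantom(np.ones((5, 5, 5)), labels, {"body": 1, "dot": 2})
        with pytest.raises(EmptyVoIError):
            extract_voi(phantom, "dot", margin=1)

    def test_unknown_label_raises(self, box_phantom):
        with pytest.raises(EmptyVoIError):
            extract_voi(box_phantom, "no-such-organ")


class TestSuvMean:
    def test_matches_per_voxel_hand_computation(self, box_phantom):
        voi = extract_voi(box_phantom, "organ", margin=1)
        got = suv_mean(box_phantom, voi, half_life=78.41)
        conc = box_phantom.activity_map[voi].mean()  # t_scan = 0, no decay
        expected = conc / (box_phantom.injected_activity / box_phantom.body_weight)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_quantification_commutes_with_decay_correction(self, box_phantom):
        """Correcting the mean equals averaging corrected voxels."""
        phantom_late = dataclasses.replace(box_phantom, t_scan=120.0)
        voi = extract_voi(phantom_late, "organ", margin=0)
        a = suv_mean(phantom_late, voi, 78.41)
        per_voxel = suv_image(phantom_late, 78.41)[voi].mean()
        assert a == pytest.approx(per_voxel, rel=1e-12)


class TestSuvPeak:
    def test_uniform_voi_peak_equals_mean(self, config):
        labels = np.ones((16, 16, 16), dtype=np.uint16)
        labels[2:14, 2:14, 2:14] = 2
        activity = np.where(labels == 2, 40.0, 7.0)
        phantom = make_phantom(activity, labels, {"body": 1, "organ": 2})
        voi = extract_voi(phantom, "organ", margin=0)
        peak, fallback = suv_peak(phantom, voi, 78.41)
        assert not fallback
        assert peak == pytest.approx(suv_mean(phantom, voi, 78.41), rel=1e-12)

    def test_single_hot_voxel_is_diluted(self):
        labels = np.ones((16, 16, 16), dtype=np.uint16)
        labels[2:14, 2:14, 2:14] = 2
        activity = np.full((16, 16, 16), 1.0)
        activity[8, 8, 8] = 1000.0
        phantom = make_phantom(activity, labels, {"body": 1, "organ": 2})
        voi = extract_voi(phantom, "organ", margin=0)
        peak, _ = suv_peak(phantom, voi, 78.41)
        hot_suv = suv_image(phantom, 78.41)[8, 8, 8]
        assert peak < hot_suv

    def test_matches_exhaustive_all_centers_search(self, rng):
        """Random field: the implementation must equal a brute-force scan
        over every candidate center."""
        labels = np.ones((14, 14, 14), dtype=np.uint16)
        labels[2:12, 2:12, 2:12] = 2
        activity = rng.uniform(0.0, 50.0, size=(14, 14, 14))
        phantom = make_phantom(activity, labels, {"body": 1, "organ": 2})
        voi = extract_voi(phantom, "organ", margin=0)
        peak, fallback = suv_peak(phantom, voi, 78.41)
        assert not fallback

        # brute force: for every voxel whose full sphere lies in the VoI,
        # average SUV over voxels whose centers are within the 1 cm^3 radius
        suv = suv_image(phantom, 78.41)
        spacing = np.array(phantom.voxel_spacing)
        radius = (3.0 * 1000.0 / (4 * np.pi)) ** (1 / 3)
        offs = [
            (dz, dy, dx)
            for dz in range(-3, 4)
            for dy in range(-3, 4)
            for dx in range(-3, 4)
            if np.linalg.norm(np.array([dz, dy, dx]) * spacing) <= radius
        ]
        best = -np.inf
        for z, y, x in np.argwhere(voi):
            coords = [(z + dz, y + dy, x + dx) for dz, dy, dx in offs]
            if any(
                not (0 <= a < 14 and 0 <= b < 14 and 0 <= c < 14) or not voi[a, b, c]
                for a, b, c in coords
            ):
                continue
            best = max(best, np.mean([suv[a, b, c] for a, b, c in coords]))
        assert peak == pytest.approx(best, rel=1e-12)

    def test_small_voi_falls_back_to_mean_with_flag(self):
        labels = np.ones((8, 8, 8), dtype=np.uint16)
        labels[3:5, 3:5, 3:5] = 2
        phantom = make_phantom(np.full((8, 8, 8), 2.0), labels, {"body": 1, "organ": 2})
        voi = extract_voi(phantom, "organ", margin=0)
        peak, fallback = suv_peak(phantom, voi, 78.41)
        assert fallback
        assert peak == pytest.approx(suv_mean(phantom, voi, 78.41))


class TestFractionOfDose:
    @pytest.mark.parametrize(
        "suv, mf, expected",
        [(9.0, 0.01, 9.0), (1.0, 1.0, 100.0), (0.5, 0.02, 1.0)],
    )
    def test_direct_product(self, suv, mf, expected):
        assert fraction_of_dose(suv, mf) == pytest.approx(expected, rel=1e-12)

    def test_partition_of_phantom_sums_to_hundred_percent(self, config):
        """Quantifying every region of a phantom without erosion and using
        phantom-derived mass fractions conserves the administered dose."""
        geo = PhantomGeometry(
            shape=(24, 24, 24),
            spacing=(5.0, 5.0, 5.0),
            body=Ellipsoid((60.0, 60.0, 60.0), (58.0, 58.0, 58.0)),
            organs={
                "a": Ellipsoid((40.0, 60.0, 60.0), (18.0, 18.0, 18.0)),
                "b": Ellipsoid((85.0, 60.0, 60.0), (14.0, 14.0, 14.0)),
            },
        )
        body = geo.body.mask(geo.shape, geo.spacing)
        voxel_mL = np.prod(geo.spacing) / 1000.0
        body_mass = body.sum() * voxel_mL  # grams at density 1
        cfg = dataclasses.replace(config, body_weight=float(body_mass))
        # place concentrations so total phantom activity == injected activity
        concs = {"a": 900.0, "b": 300.0}
        masks = {n: geo.organs[n].mask(geo.shape, geo.spacing) for n in concs}
        organ_activity = sum(concs[n] * masks[n].sum() * voxel_mL for n in concs)
        n_bg = body.sum() - sum(m.sum() for m in masks.values())
        bg = (cfg.dose_activity - organ_activity) / (n_bg * voxel_mL)
        phantom = build_phantom(cfg, concs, t_scan=0.0, geometry=geo, background_conc=bg)

        total = 0.0
        for region in ("a", "b", "body"):
            voi = extract_voi(phantom, region, margin=0)
            suv = suv_mean(phantom, voi, cfg.isotope_half_life)
            mf = voi.sum() * voxel_mL / body_mass
            total += fraction_of_dose(suv, mf)
        assert total == pytest.approx(100.0, abs=0.5)


def test_quantify_phantom_table(config, rng):
    labels = np.ones((16, 16, 16), dtype=np.uint16)
    labels[3:13, 3:13, 3:13] = 2
    activity = rng.uniform(5, 10, size=(16, 16, 16))
    phantom = make_phantom(activity, labels, {"body": 1, "organ": 2})
    df = quantify_phantom(phantom, 78.41, peak_organs=("organ",))
    assert list(df["organ"]) == ["organ"]
    assert df.loc[0, "suv_peak"] is not None
    m = quantify_organ(phantom, "organ", 78.41)
    assert df.loc[0, "suv_mean"] == pytest.approx(m.suv_mean)
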