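"""Threshold calibration and morphological labelling against generator truth."""

import numpy as np
import pytest

import lvtrab as lt
from lvtrab.frames import ED, ES, GrayFrame, Label
from lvtrab.segmentation import (
    AnnulusHint,
    ThresholdLock,
    calibrate_threshold,
    label_frame,
    segment_study,
)

from conftest import REGION4, dice_per_region


def _hint_from_truth(study, frame):
    lab = [f for f in study.label_frames
           if f.phase == frame.phase and f.slice_index == frame.slice_index][0].labels
    ann = np.isin(lab, (int(Label.TRABECULATION), int(Label.RECESS)))
    pap = lab == int(Label.PAPILLARY)
    return AnnulusHint(annulus=ann, papillary=pap if pap.any() else None)


def _ed_frame(study, k=0):
    return [f for f in study.gray_frames if f.phase == ED and
            (f.slice_index in (None, k))][0]


class TestCalibration:
    def test_threshold_between_intensities_and_fraction_recovered(
            self, noiseless_sa_small):
        frame = _ed_frame(noiseless_sa_small)
        lock = calibrate_threshold(frame, _hint_from_truth(noiseless_sa_small, frame))
        assert 300 < lock.threshold < 1000
        assert lock.achieved_fraction == pytest.approx(
            noiseless_sa_small.spec.trabecular_tissue_fraction, abs=0.02)
        assert lock.papillary_tissue_rate == 1.0

    def test_agrees_with_exhaustive_scan_oracle(self, noisy_sa_small):
        # oracle: scan candidate thresholds in 1-unit steps over the intensity
        # range and take the best achievable |fraction - 0.5|
        frame = _ed_frame(noisy_sa_small)
        hint = _hint_from_truth(noisy_sa_small, frame)
        lock = calibrate_threshold(frame, hint)
        vals = frame.pixels[hint.annulus]
        grid = np.arange(np.floor(vals.min()), np.ceil(vals.max()) + 1.0, 1.0)
        fracs = np.array([(vals <= t).mean() for t in grid])
        best = np.abs(fracs - 0.5).min()
        achieved = np.abs((vals <= lock.threshold).mean() - 0.5)
        assert achieved <= best + 1e-12

    def test_all_blood_annulus_is_an_error(self, noiseless_sa_small):
        frame = _ed_frame(noiseless_sa_small)
        lab = noiseless_sa_small.frames(ED, gray=False)[0].labels
        hint = AnnulusHint(annulus=lab == int(Label.CENTRAL_CAVITY))
        with pytest.raises(ValueError, match="degenerate|blood"):
            calibrate_threshold(frame, hint)

    def test_empty_annulus_is_an_error(self, noiseless_sa_small):
        frame = _ed_frame(noiseless_sa_small)
        with pytest.raises(ValueError, match="empty"):
            calibrate_threshold(frame, AnnulusHint(np.zeros_like(frame.pixels, bool)))

    def test_repeated_calibration_is_deterministic(self, noisy_sa_small):
        frame = _ed_frame(noisy_sa_small)
        hint = _hint_from_truth(noisy_sa_small, frame)
        assert (calibrate_threshold(frame, hint).threshold
                == calibrate_threshold(frame, hint).threshold)

    def test_es_reference_rejected(self, noiseless_sa_small):
        frame = [f for f in noiseless_sa_small.gray_frames if f.phase == ES][0]
        with pytest.raises(ValueError, match="ED"):
            calibrate_threshold(frame, _hint_from_truth(noiseless_sa_small, frame))


def test_threshold_monotonicity_of_tissue_count(noisy_sa_small):
    img = _ed_frame(noisy_sa_small).pixels
    counts = [np.sum(img <= t) for t in np.linspace(img.min(), img.max(), 50)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


@pytest.mark.parametrize("view", ["short_axis", "four_chamber"])
@pytest.mark.parametrize("phase", [ED, ES])
def test_noiseless_dice_per_region(
        view, phase, noiseless_sa_study, noiseless_4ch_study):
    """An ED-calibrated lock labels both phases at Dice >= 0.95 per region."""
    study = noiseless_sa_study if view == "short_axis" else noiseless_4ch_study
    seg = lt.ThresholdSegmenter().fit(_ed_frame(study, k=study.spec.n_slices // 2))
    labels = seg.predict(list(study.gray_frames))
    scores = dice_per_region(study, labels, phase)
    for lbl in REGION4:
        assert scores[lbl] >= 0.95, f"{lbl.name}: Dice {scores[lbl]:.3f}"


def test_plain_annulus_without_trabeculae():
    """A trabeculation-free ring yields empty trabeculation/recess labels and
    a cavity covering all enclosed blood."""
    n, px = 96, 1.0
    c = (n - 1) / 2
    yy, xx = np.meshgrid(*(np.arange(n) - c,) * 2, indexing="ij")
    r = np.hypot(xx, yy) * px
    img = np.zeros((n, n))
    img[r < 44] = 1000.0
    img[(r >= 30) & (r < 44)] = 300.0
    frame = GrayFrame(pixels=img, pixel_spacing=px, slice_thickness=8.0, phase=ED)
    lock = ThresholdLock(threshold=650.0, reference_frame="t", achieved_fraction=0.0)
    lab = label_frame(frame, lock)
    assert lab.count(Label.TRABECULATION) == 0
    assert lab.count(Label.RECESS) == 0
    assert lab.count(Label.CENTRAL_CAVITY) == np.sum(r < 30)


def test_segment_study_uses_one_lock_and_reports_partial_failures(
        noiseless_sa_small):
    frames = list(noiseless_sa_small.gray_frames)
    # a frame with no anatomy at all cannot be labelled
    corrupt = GrayFrame(
        pixels=np.full_like(frames[0].pixels, 10.0) + np.eye(frames[0].pixels.shape[0]),
        pixel_spacing=frames[0].pixel_spacing,
        slice_thickness=frames[0].slice_thickness,
        phase=ES, slice_index=99,
    )
    seg = lt.ThresholdSegmenter().fit(_ed_frame(noiseless_sa_small))
    result = segment_study(frames + [corrupt], seg.lock_)
    assert len(result.labels) == len(frames)
    assert len(result.failures) == 1
    assert "99" in result.failures[0][0]
    assert result.summary == f"{len(frames)}/{len(frames) + 1} frames labelled"
    thresholds = {lf.diagnostics["threshold"] for lf in result.labels}
    assert thresholds == {seg.threshold_}


def test_labels_are_exhaustive_inside_the_lv(noiseless_sa_small):
    seg = lt.ThresholdSegmenter().fit(_ed_frame(noiseless_sa_small))
    lab = seg.predict(noiseless_sa_small.gray_frames[0]).labels
    gt = noiseless_sa_small.frames(ED, gray=False)[0].labels
    in_lv = gt > 0
    assert (lab[in_lv] > 0).all()


def test_noisy_monte_carlo_volume_recovery():
    """At 5% (of the intensity gap) noise, per-region volumes stay within 10%
    relative error of the generated truth (envelope over 20 seeds)."""
    worst = {}
    for seed in range(20):
        spec = lt.default_short_axis_spec(n_slices=2, seed=seed)
        assert spec.noise_sd == pytest.approx(
            0.05 * (spec.intensity_blood - spec.intensity_myocardium))
        study = lt.generate_short_axis_phantom(spec)
        q, _ = lt.analyze_frames(list(study.gray_frames))
        for lbl in REGION4:
            for phase in (ED, ES):
                rel = abs(q.get(lbl, phase) - study.truth.get(lbl, phase))
                rel /= study.truth.get(lbl, phase)
                worst[(lbl, phase)] = max(worst.get((lbl, phase), 0.0), rel)
    for key, err in worst.items():
        assert err <= 0.10, f"{key}: {err:.3f}"


class TestSklearnSurface:
    def test_get_set_params_roundtrip(self):
        seg = lt.ThresholdSegmenter(r_open_mm=3.5)
        params = seg.get_params()
        assert params["r_open_mm"] == 3.5
        seg.set_params(r_close_mm=7.0)
        assert seg.r_close_mm == 7.0

    def test_clone_preserves_params(self):
        from sklearn.base import clone

        seg = clone(lt.ThresholdSegmenter(target_fraction=0.45))
        assert seg.target_fraction == 0.45
        assert not hasattr(seg, "lock_")

    def test_predict_before_fit_raises(self, noiseless_sa_small):
        with pytest.raises(RuntimeError, match="not fitted"):
            lt.ThresholdSegmenter().predict(noiseless_sa_small.gray_frames[0])

    def test_fitted_attributes(self, noiseless_sa_small):
        seg = lt.ThresholdSegmenter().fit(_ed_frame(noiseless_sa_small))
        assert seg.threshold_ == seg.lock_.threshold
        assert 0 <= seg.achieved_fraction_ <= 1
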