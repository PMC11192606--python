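"""Region quantities, EF conventions, trabecular mass, longitudinal metrics,
and the mislabeling sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lvtrab as lt
from lvtrab.frames import ED, ES, Label, LabelFrame
from lvtrab.metrics import (
    CONVENTIONS,
    LongitudinalLandmarks,
    RegionQuantities,
    mislabel_sensitivity,
)

from conftest import ef_of


def _quantities(cc=(70, 28), ir=(45, 18), trab=(30, 30), compact=(0, 0),
                pap=(5, 5), kind="volume"):
    return RegionQuantities(
        kind=kind,
        values={
            Label.CENTRAL_CAVITY: {ED: cc[0], ES: cc[1]},
            Label.RECESS: {ED: ir[0], ES: ir[1]},
            Label.TRABECULATION: {ED: trab[0], ES: trab[1]},
            Label.COMPACT: {ED: compact[0], ES: compact[1]},
            Label.PAPILLARY: {ED: pap[0], ES: pap[1]},
        },
    )


class TestQuantitiesFromLabels:
    def test_single_slice_volume_arithmetic(self):
        lab = np.zeros((20, 20), dtype=np.uint8)
        lab[:10, :10] = int(Label.CENTRAL_CAVITY)  # 100 px of 1 mm², 10 mm thick
        frames = [
            LabelFrame(labels=lab, pixel_spacing=1.0, slice_thickness=10.0, phase=p)
            for p in (ED, ES)
        ]
        q = lt.quantities_from_labels(frames)
        assert q.get(Label.CENTRAL_CAVITY, ED) == pytest.approx(1.0)

    def test_phantom_truth_matches_analytic(self, noiseless_sa_small):
        q = lt.quantities_from_labels(noiseless_sa_small.label_frames)
        a = noiseless_sa_small.analytic
        for lbl in (Label.CENTRAL_CAVITY, Label.RECESS, Label.TRABECULATION):
            assert q.get(lbl, ED) == pytest.approx(a.get(lbl, ED), rel=0.03)

    def test_empty_label_is_zero_not_an_error(self):
        lab = np.zeros((8, 8), dtype=np.uint8)
        frames = [LabelFrame(labels=lab, pixel_spacing=1.0, slice_thickness=8.0,
                             phase=p) for p in (ED, ES)]
        q = lt.quantities_from_labels(frames)
        assert q.get(Label.RECESS, ED) == 0.0

    def test_mixed_views_rejected(self, noiseless_sa_small, noiseless_4ch_study):
        with pytest.raises(ValueError, match="mixed views"):
            lt.quantities_from_labels(
                list(noiseless_sa_small.label_frames)
                + list(noiseless_4ch_study.label_frames))

    def test_additivity_under_label_splitting(self, noiseless_sa_small):
        """Relabelling half of one region's pixels as another region leaves
        the total unchanged."""
        q0 = lt.quantities_from_labels(noiseless_sa_small.label_frames)
        split = []
        for f in noiseless_sa_small.label_frames:
            lab = f.labels.copy()
            rec = np.argwhere(lab == int(Label.RECESS))
            for (i, j) in rec[: len(rec) // 2]:
                lab[i, j] = int(Label.CENTRAL_CAVITY)
            split.append(LabelFrame(
                labels=lab, pixel_spacing=f.pixel_spacing,
                slice_thickness=f.slice_thickness, phase=f.phase,
                slice_index=f.slice_index))
        q1 = lt.quantities_from_labels(split)
        for phase in (ED, ES):
            assert q1.total(phase) == pytest.approx(q0.total(phase), abs=1e-9)


class TestFractionalChangeAndEF:
    def test_recess_sfvc_on_excessive_baseline(self, table2_excessive_quantities):
        assert lt.fractional_change(
            table2_excessive_quantities, Label.RECESS) == pytest.approx(0.40)

    def test_no_change_is_unity(self):
        q = _quantities(ir=(45, 45))
        assert lt.fractional_change(q, Label.RECESS) == 1.0

    def test_zero_ed_flagged_not_computed(self):
        q = _quantities(ir=(0, 0))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(lt.fractional_change(q, Label.RECESS))

    @pytest.mark.parametrize("edv, esv, expected", [
        (120.0, 48.0, 0.60),
        (115.0, 46.0, 0.60),
        (37.5, 37.5, 0.0),
    ])
    def test_ef_worked_examples(self, edv, esv, expected):
        assert lt.ef(edv, esv) == pytest.approx(expected, abs=1e-12)

    def test_ef_negative_with_warning_when_esv_exceeds_edv(self):
        with pytest.warns(UserWarning, match="mislabeling"):
            assert lt.ef(50.0, 60.0) == pytest.approx(-0.2)

    def test_ef_rejects_nonpositive_edv(self):
        with pytest.raises(ValueError):
            lt.ef(0.0, 0.0)


class TestCavityConventions:
    @pytest.mark.parametrize("conv, edv, esv, ef_expected", [
        ("contour", 115.0, 46.0, 0.60),
        ("guidelines", 145.0, 76.0, 69.0 / 145.0),
        ("jacquier", 70.0, 28.0, 0.60),
    ])
    def test_excessive_baseline_pools(self, table2_excessive_quantities,
                                      conv, edv, esv, ef_expected):
        rep = lt.cavity_report(table2_excessive_quantities, conv)
        assert (rep.edv, rep.esv) == (edv, esv)
        assert rep.sv == edv - esv
        assert rep.ef == pytest.approx(ef_expected, abs=1e-12)

    def test_area_kind_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            lt.cavity_report(_quantities(kind="area"), "contour")


class TestTrabecularMass:
    @pytest.mark.parametrize("trab, compact, frac, positive", [
        ((36, 36), (64, 64), 0.36, True),
        ((10, 10), (90, 90), 0.10, False),
    ])
    def test_fraction_and_jacquier_flag(self, trab, compact, frac, positive):
        out = lt.trabecular_mass(_quantities(trab=trab, compact=compact, pap=(0, 0)))
        assert out["fraction_of_lv_mass"] == pytest.approx(frac)
        assert out["jacquier_positive"] is positive

    def test_mass_is_the_phase_mean(self):
        out = lt.trabecular_mass(_quantities(trab=(30, 32), compact=(60, 58)))
        assert out["mass_volume"] == pytest.approx(31.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            lt.trabecular_mass(_quantities(trab=(0, 0), compact=(0, 0)))


class TestLongitudinal:
    def _landmarks(self, shorten=15.0):
        pts = {}
        for view in ("two_chamber", "three_chamber", "four_chamber"):
            pts[view] = {
                ED: {"apex": (0.0, -100.0), "annulus": ((-30.0, 0.0), (30.0, 0.0))},
                ES: {"apex": (0.0, -(100.0 - shorten)),
                     "annulus": ((-30.0, 0.0), (30.0, 0.0))},
            }
        return LongitudinalLandmarks(points=pts)

    def test_gl_shortening_formula(self):
        out = lt.longitudinal_metrics(self._landmarks(shorten=15.0))
        assert out["gl_shortening"] == pytest.approx(0.15)

    def test_global_mapse_averages_six_walls(self):
        out = lt.longitudinal_metrics(self._landmarks(shorten=12.0))
        assert len(out["mapse_per_wall"]) == 6
        # all six apex-annulus walls shorten by the same apex displacement
        expected = np.hypot(30.0, 100.0) - np.hypot(30.0, 88.0)
        assert out["global_mapse"] == pytest.approx(expected)

    def test_phantom_landmarks_recover_prescribed_shortening(self):
        spec = lt.default_four_chamber_spec(
            noise_sd=0.0, blur_sigma=0.0, target_gl_shortening=0.10)
        study = lt.generate_four_chamber_phantom(spec)
        out = lt.longitudinal_metrics(study.landmarks)
        assert out["gl_shortening"] == pytest.approx(0.10, abs=0.005)
        assert out["global_mapse"] > 0

    def test_missing_phase_is_an_error(self):
        pts = {"four_chamber": {ED: {"apex": (0, -90),
                                     "annulus": ((-25, 0), (25, 0))}}}
        with pytest.raises(ValueError, match="missing landmarks"):
            lt.longitudinal_metrics(LongitudinalLandmarks(points=pts))


@pytest.mark.parametrize("value, category", [
    (0.35, "below_40"),
    (0.40, "40_to_50"),
    (0.50, "40_to_50"),
    (0.505, "above_50"),
    (0.61, "above_50"),
])
def test_ef_category_boundaries(value, category):
    assert lt.ef_category(value) == category


class TestMislabelSensitivity:
    def test_zero_transfer_is_identity(self, table2_excessive_quantities):
        out = mislabel_sensitivity(table2_excessive_quantities, 0.0, 0.0)
        assert out["ef_ir"] == pytest.approx(0.60)
        assert out["ef_cc"] == pytest.approx(0.60)

    def test_es_only_transfer_worked_example(self, table2_excessive_quantities):
        # moving 10% of the ES central cavity into the recesses: 18 + 2.8 mL
        out = mislabel_sensitivity(table2_excessive_quantities, 0.0, 0.10)
        assert out["ef_ir"] == pytest.approx((45 - 20.8) / 45)

    def test_symmetric_transfer_never_crosses(self):
        # recess EF above CC EF: the symmetric perturbation is a mediant and
        # stays between the two originals — brute-force over the grid
        q = _quantities(cc=(70, 39.2), ir=(45, 18))  # EF_cc=0.44, EF_ir=0.60
        for s in np.arange(0.0, 1.0, 0.01):
            out = mislabel_sensitivity(q, s, s)
            assert out["ef_ir"] >= out["ef_cc"] - 1e-12
        assert mislabel_sensitivity(q, 0.3, 0.3)["symmetric_crossing"] is None

    def test_es_only_crossing_exists_and_solves_equality(self):
        q = _quantities(cc=(70, 39.2), ir=(45, 18))
        s = mislabel_sensitivity(q, 0.0, 0.0)["crossing_transfer"]
        assert s is not None and 0 < s < 1
        out = mislabel_sensitivity(q, 0.0, s)
        assert out["ef_ir"] == pytest.approx(out["ef_cc"], abs=1e-9)

    def test_transfer_fraction_bounds(self, table2_excessive_quantities):
        with pytest.raises(ValueError):
            mislabel_sensitivity(table2_excessive_quantities, 1.0, 0.0)


# ---------------------------------------------------------------------------
# algebraic identities on random inputs
# ---------------------------------------------------------------------------

volumes = st.floats(min_value=1.0, max_value=500.0)


@settings(max_examples=100, derandomize=True)
@given(cc_ed=volumes, ir_ed=volumes, trab=volumes,
       ef_cc=st.floats(0.02, 0.98), ef_ir=st.floats(0.02, 0.98))
def test_sfvc_plus_ef_is_one_for_blood_labels(cc_ed, ir_ed, trab, ef_cc, ef_ir):
    q = _quantities(cc=(cc_ed, (1 - ef_cc) * cc_ed),
                    ir=(ir_ed, (1 - ef_ir) * ir_ed), trab=(trab, trab))
    for lbl in (Label.CENTRAL_CAVITY, Label.RECESS):
        sfvc = lt.fractional_change(q, lbl)
        assert sfvc + ef_of(q, lbl) == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(cc_ed=volumes, ir_ed=volumes, trab=volumes,
       ef_cc=st.floats(0.02, 0.98), ef_ir=st.floats(0.02, 0.98))
def test_convention_identities_on_random_tables(cc_ed, ir_ed, trab, ef_cc, ef_ir):
    q = _quantities(cc=(cc_ed, (1 - ef_cc) * cc_ed),
                    ir=(ir_ed, (1 - ef_ir) * ir_ed), trab=(trab, trab))
    reps = {c: lt.cavity_report(q, c) for c in CONVENTIONS}
    # phase-equal tissue: SV identical under guidelines and contour
    assert reps["guidelines"].sv == pytest.approx(reps["contour"].sv, abs=1e-9)
    # Jacquier EF is the CC EF
    assert reps["jacquier"].ef == pytest.approx(ef_of(q, Label.CENTRAL_CAVITY))
    # adding non-ejecting tissue to both phases lowers EF
    if reps["contour"].sv > 0:
        assert reps["contour"].ef > reps["guidelines"].ef


@settings(max_examples=50, derandomize=True)
@given(cc_ed=volumes, ir_ed=volumes, trab_ed=volumes, dtrab=st.floats(-20.0, 20.0),
       ef_cc=st.floats(0.02, 0.98), ef_ir=st.floats(0.02, 0.98))
def test_sv_difference_equals_tissue_measurement_mismatch(
        cc_ed, ir_ed, trab_ed, dtrab, ef_cc, ef_ir):
    trab_es = max(trab_ed + dtrab, 0.0)
    q = _quantities(cc=(cc_ed, (1 - ef_cc) * cc_ed),
                    ir=(ir_ed, (1 - ef_ir) * ir_ed), trab=(trab_ed, trab_es))
    sv_g = lt.cavity_report(q, "guidelines").sv
    sv_c = lt.cavity_report(q, "contour").sv
    assert sv_g - sv_c == pytest.approx(trab_ed - trab_es, abs=1e-9)
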