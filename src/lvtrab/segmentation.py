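"""Threshold-locked four-region labelling of cine frames.

The measurement protocol mirrors clinical practice on bright-blood cine CMR:

1. **Calibrate** one intensity threshold per study on a reference ED frame
   (mid-ventricular short-axis, or the four-chamber frame) such that the
   trabecular layer splits into approximately equal parts trabecular tissue
   and intertrabecular recesses, while the papillary muscles classify as
   myocardium.
2. **Lock** that threshold and apply it unchanged to every other ED and ES
   frame of the study — never recalibrating per frame or per phase.
3. **Partition** each binarized frame into compact wall, trabeculations,
   recesses, central cavity and papillary muscles with morphological
   operations whose scales are physical (mm), not pixel counts:

   * the compact wall is the largest connected tissue component surviving an
     opening of radius ``r_open_mm`` (which removes the thin trabecular
     spokes);
   * wall-connected tissue inside the wall is trabecular; detached tissue is
     papillary;
   * the cavity-side boundary of the trabecular layer is the inner edge of a
     morphological closing (radius ``r_close_mm``) of the wall-connected
     tissue, papillary discs excluded so they cannot bridge to the spokes;
   * enclosed blood inside that boundary is the central cavity; enclosed
     blood outside it is recess.

The calibration itself is exposed in scikit-learn form:
:class:`ThresholdSegmenter` with ``fit`` (calibrate on the reference frame,
fitted attributes ``threshold_``, ``lock_``) and ``predict`` (label frames
with the locked threshold); :func:`calibrate_threshold`, :func:`label_frame`
and :func:`segment_study` are thin functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from sklearn.base import BaseEstimator

from .frames import GrayFrame, Label, LabelFrame

__all__ = [
    "AnnulusHint",
    "ThresholdLock",
    "MorphologyParams",
    "SegmentationError",
    "SegmentationResult",
    "ThresholdSegmenter",
    "calibrate_threshold",
    "estimate_annulus",
    "label_frame",
    "segment_study",
]

_CONN8 = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Labelling failed on a frame; the message names the frame and cause."""


def _disk(radius_px: float) -> np.ndarray:
    r = max(1, int(math.floor(radius_px)))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(yy, xx) <= radius_px + 1e-9).astype(bool)


@dataclass(frozen=True)
class AnnulusHint:
    """Geometric hint for calibration: a mask delimiting the trabecular layer
    of the reference frame and, optionally, a papillary-muscle mask."""

    annulus: np.ndarray
    papillary: np.ndarray | None = None


@dataclass(frozen=True)
class ThresholdLock:
    """A calibrated, study-wide intensity threshold.

    ``achieved_fraction`` is the tissue fraction realized inside the
    calibration annulus; ``papillary_tissue_rate`` the fraction of hinted
    papillary pixels classifying as tissue at the locked threshold (``None``
    when no papillary hint was given).  ``warning`` records a calibration that
    could not reach a tissue fraction in [0.3, 0.7] — recorded, not fatal.
    """

    threshold: float
    reference_frame: str
    achieved_fraction: float
    papillary_tissue_rate: float | None = None
    warning: str | None = None


@dataclass(frozen=True)
class MorphologyParams:
    """Physical scales of the morphological partition.

    ``r_open_mm`` must exceed half the widest expected trabecular spoke
    (spokes widen angularly at ES); ``r_close_mm`` half the widest recess
    mouth.  ``background_cutoff`` separates air/background from myocardium
    among the sub-threshold intensities; ``None`` derives it per frame by
    Otsu on the sub-threshold histogram.
    """

    r_open_mm: float = 4.0
    r_close_mm: float = 6.0
    r_endo_mm: float = 9.0
    background_cutoff: float | None = None


def calibrate_threshold(
    reference: GrayFrame,
    annulus_hint: AnnulusHint,
    target_fraction: float = 0.5,
) -> ThresholdLock:
    """Calibrate the study threshold on an ED reference frame.

    Returns the threshold whose tissue fraction inside the annulus is closest
    to ``target_fraction``.  The tissue-fraction-vs-threshold curve is a
    monotone step function of the sorted annulus intensities, so the optimum
    is found exactly by order-statistic inversion (the converged limit of a
    bisection on that curve); the returned threshold is the midpoint of the
    optimal plateau, strictly inside the frame's intensity range.
    """
    if reference.phase != "ED":
        raise ValueError("calibration reference must be an ED frame")
    ann = np.asarray(annulus_hint.annulus, dtype=bool)
    if ann.shape != reference.pixels.shape:
        raise ValueError("annulus hint shape does not match the reference frame")
    vals = np.sort(reference.pixels[ann])
    if vals.size == 0:
        raise ValueError("annulus hint is empty")
    n = vals.size
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size < 2:
        raise ValueError("annulus is degenerate: a single intensity value "
                         "(e.g. all blood) admits no threshold")
    cum = np.cumsum(counts)
    fracs = cum / n  # tissue fraction when thresholding in [uniq[j], uniq[j+1])
    j = int(np.argmin(np.abs(fracs[:-1] - target_fraction)))
    threshold = 0.5 * (uniq[j] + uniq[j + 1])
    achieved = float(fracs[j])

    lo, hi = float(reference.pixels.min()), float(reference.pixels.max())
    threshold = float(np.clip(threshold, np.nextafter(lo, hi), np.nextafter(hi, lo)))

    pap_rate = None
    if annulus_hint.papillary is not None:
        pap = np.asarray(annulus_hint.papillary, dtype=bool)
        if pap.any():
            pap_rate = float(np.mean(reference.pixels[pap] <= threshold))
    warning = None
    if not 0.3 <= achieved <= 0.7:
        warning = (
            f"no threshold reaches an annulus tissue fraction in [0.3, 0.7]; "
            f"best achievable is {achieved:.3f}"
        )
    if pap_rate is not None and pap_rate < 0.9:
        note = f"only {pap_rate:.0%} of papillary pixels classify as tissue"
        warning = f"{warning}; {note}" if warning else note
    return ThresholdLock(
        threshold=threshold,
        reference_frame=f"{reference.study_id}/{reference.view}"
        f"/{reference.slice_index}/{reference.phase}",
        achieved_fraction=achieved,
        papillary_tissue_rate=pap_rate,
        warning=warning,
    )


def _binarize(frame: GrayFrame, threshold: float, background_cutoff: float | None):
    """Tissue / enclosed-blood masks of one frame.

    Sub-threshold intensities contain both myocardium and background (air);
    they are separated at ``background_cutoff`` (Otsu on the sub-threshold
    histogram when not given).  The LV interior is the hole-filled tissue
    mask; enclosed blood is the supra-threshold interior.
    """
    img = frame.pixels
    non_blood = img <= threshold
    if not non_blood.any() or non_blood.all():
        raise SegmentationError("threshold outside the frame's intensity range")
    if background_cutoff is None:
        sub = img[non_blood]
        if sub.max() - sub.min() < 1e-12:
            background_cutoff = -np.inf
        else:
            background_cutoff = float(threshold_otsu(sub))
    tissue = non_blood & (img > background_cutoff)
    interior = ndimage.binary_fill_holes(tissue)
    blood = interior & ~tissue
    return tissue, blood


def _frame_id(frame) -> str:
    return f"{frame.view}/slice={frame.slice_index}/{frame.phase}"


def label_frame(
    frame: GrayFrame, lock: ThresholdLock, params: MorphologyParams | None = None
) -> LabelFrame:
    """Partition one frame into the four LV regions plus papillary.

    Raises :class:`SegmentationError` when no closed compact ring enclosing a
    blood pool is found.  When more than one opened tissue component encloses
    blood, the one enclosing the largest pool is taken and the ambiguity is
    logged in the frame diagnostics.
    """
    params = params or MorphologyParams()
    px = frame.pixel_spacing
    tissue, blood = _binarize(frame, lock.threshold, params.background_cutoff)

    r_open_px = params.r_open_mm / px
    opened = ndimage.binary_opening(tissue, structure=_disk(r_open_px))
    comp_lab, n_comp = ndimage.label(opened, structure=_CONN8)
    if n_comp == 0:
        raise SegmentationError(
            f"{_frame_id(frame)}: no compact ring survives the opening"
        )
    # candidate ring = opened component enclosing the most blood
    enclosed_counts = []
    for i in range(1, n_comp + 1):
        comp = comp_lab == i
        inner = ndimage.binary_fill_holes(comp) & ~comp
        enclosed_counts.append(int(np.count_nonzero(inner & blood)))
    order = np.argsort(enclosed_counts)[::-1]
    best = int(order[0])
    diagnostics: dict = {"threshold": lock.threshold}
    if enclosed_counts[best] == 0:
        raise SegmentationError(
            f"{_frame_id(frame)}: no closed compact ring encloses a blood pool "
            "(open myocardium after binarization)"
        )
    if n_comp > 1 and enclosed_counts[int(order[1])] > 0:
        diagnostics["ring_ambiguity"] = (
            f"{n_comp} opened components enclose blood; kept the one with the "
            f"largest pool ({enclosed_counts[best]} px)"
        )
    ring = comp_lab == best + 1
    inner_region = ndimage.binary_fill_holes(ring) & ~ring
    # regularize the endocardial boundary: spoke roots survive the opening as
    # shallow intrusions of the ring into the enclosed region; closing the
    # region fills those notches so the roots count as trabecular, not wall
    inner_region = ndimage.binary_closing(inner_region, structure=_disk(params.r_endo_mm / px))

    # wall pixels shaved off by the opening (outer/inner edge, high curvature)
    shell = ndimage.binary_dilation(ring, structure=_disk(r_open_px + 1))
    compact = (ring | (tissue & shell)) & ~inner_region

    # wall-connected tissue inside the ring = trabecular; detached = papillary
    tissue_inside = tissue & inner_region
    in_lab, n_in = ndimage.label(tissue_inside, structure=_CONN8)
    touching = ndimage.binary_dilation(compact, structure=_CONN8)
    trab = np.zeros_like(tissue)
    papillary = np.zeros_like(tissue)
    for i in range(1, n_in + 1):
        comp = in_lab == i
        if (comp & touching).any():
            trab |= comp
        else:
            papillary |= comp

    # cavity-side boundary of the trabecular layer: inner edge of the closing
    # of the wall-connected myocardium (papillary excluded so it cannot
    # bridge to the spoke tips)
    closed = ndimage.binary_closing(
        compact | trab, structure=_disk(params.r_close_mm / px)
    )
    blood_inside = blood & inner_region
    cav_candidates = blood_inside & ~closed
    cav_lab, n_cav = ndimage.label(cav_candidates, structure=_CONN8)
    if n_cav == 0:
        raise SegmentationError(f"{_frame_id(frame)}: no central cavity found")
    sizes = ndimage.sum_labels(np.ones_like(cav_lab), cav_lab, range(1, n_cav + 1))
    cavity = cav_lab == (int(np.argmax(sizes)) + 1)
    recess = blood_inside & ~cavity

    out = np.zeros(frame.pixels.shape, dtype=np.uint8)
    out[compact] = int(Label.COMPACT)
    out[trab] = int(Label.TRABECULATION)
    out[recess] = int(Label.RECESS)
    out[cavity] = int(Label.CENTRAL_CAVITY)
    out[papillary] = int(Label.PAPILLARY)
    return LabelFrame(
        labels=out,
        pixel_spacing=frame.pixel_spacing,
        slice_thickness=frame.slice_thickness,
        phase=frame.phase,
        view=frame.view,
        slice_index=frame.slice_index,
        study_id=frame.study_id,
        diagnostics=diagnostics,
    )


@dataclass
class SegmentationResult:
    """Labels and per-frame diagnostics of one study segmentation."""

    labels: list[LabelFrame] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.labels) + len(self.failures)

    @property
    def summary(self) -> str:
        return f"{len(self.labels)}/{self.n_total} frames labelled"


def segment_study(
    frames,
    lock: ThresholdLock,
    params: MorphologyParams | None = None,
) -> SegmentationResult:
    """Apply one locked threshold to every frame of a study.

    Never recalibrates per frame.  Frames that fail keep the study going: the
    result lists per-frame failures with the frame identity attached.
    """
    result = SegmentationResult()
    for frame in frames:
        try:
            result.labels.append(label_frame(frame, lock, params))
        except SegmentationError as exc:
            result.failures.append((_frame_id(frame), str(exc)))
    return result


def estimate_annulus(
    frame: GrayFrame, params: MorphologyParams | None = None
) -> AnnulusHint:
    """Coarse trabecular-layer hint from the frame itself.

    A provisional myocardium/blood threshold from a three-class Otsu split
    (background, myocardium, blood) drives one pass of the morphological
    partition; its trabeculation + recess region is the annulus hint and its
    papillary label the papillary hint.  Used when no ground-truth or manual
    hint is available.
    """
    img = frame.pixels
    t_bg, t_blood = threshold_multiotsu(img, classes=3)
    # multiotsu returns bin centres (the threshold bin belongs to the lower
    # class); shift by half a bin before digitizing, then move each threshold
    # to the midpoint of the gap between its classes so exact two-level
    # images binarize correctly
    half_bin = (img.max() - img.min()) / 256 / 2
    cls = np.digitize(img, [t_bg + half_bin, t_blood + half_bin])
    if (cls == 1).any() and (cls == 2).any():
        t_blood = 0.5 * (img[cls == 1].max() + img[cls == 2].min())
    if (cls == 0).any() and (cls == 1).any():
        t_bg = 0.5 * (img[cls == 0].max() + img[cls == 1].min())
    provisional = ThresholdLock(
        threshold=float(t_blood), reference_frame="provisional", achieved_fraction=np.nan
    )
    p = params or MorphologyParams()
    coarse = label_frame(frame, provisional, MorphologyParams(
        r_open_mm=p.r_open_mm, r_close_mm=p.r_close_mm, r_endo_mm=p.r_endo_mm,
        background_cutoff=float(t_bg),
    ))
    ann = np.isin(coarse.labels, (int(Label.TRABECULATION), int(Label.RECESS)))
    pap = coarse.labels == int(Label.PAPILLARY)
    return AnnulusHint(annulus=ann, papillary=pap if pap.any() else None)


class ThresholdSegmenter(BaseEstimator):
    """Scikit-learn-style calibrate-then-lock segmenter.

    ``fit(reference, annulus_hint=None)`` calibrates the study threshold on a
    reference ED frame (hint estimated from the frame when not given) and
    sets the fitted attributes ``threshold_``, ``lock_`` and
    ``achieved_fraction_``; ``predict(frames)`` labels frames with the locked
    threshold.  Parameters follow :class:`MorphologyParams` plus the
    calibration target fraction.
    """

    def __init__(
        self,
        target_fraction: float = 0.5,
        r_open_mm: float = 4.0,
        r_close_mm: float = 6.0,
        r_endo_mm: float = 9.0,
        background_cutoff: float | None = None,
    ):
        self.target_fraction = target_fraction
        self.r_open_mm = r_open_mm
        self.r_close_mm = r_close_mm
        self.r_endo_mm = r_endo_mm
        self.background_cutoff = background_cutoff

    def _params(self) -> MorphologyParams:
        return MorphologyParams(
            r_open_mm=self.r_open_mm,
            r_close_mm=self.r_close_mm,
            r_endo_mm=self.r_endo_mm,
            background_cutoff=self.background_cutoff,
        )

    def fit(self, reference: GrayFrame, annulus_hint: AnnulusHint | None = None):
        if annulus_hint is None:
            annulus_hint = estimate_annulus(reference, self._params())
        self.lock_ = calibrate_threshold(reference, annulus_hint, self.target_fraction)
        self.threshold_ = self.lock_.threshold
        self.achieved_fraction_ = self.lock_.achieved_fraction
        return self

    def predict(self, frames) -> list[LabelFrame] | LabelFrame:
        if not hasattr(self, "lock_"):
            raise RuntimeError("ThresholdSegmenter is not fitted; call fit() first")
        if isinstance(frames, GrayFrame):
            return label_frame(frames, self.lock_, self._params())
        result = segment_study(frames, self.lock_, self._params())
        if result.failures:
            raise SegmentationError(
                "; ".join(f"{fid}: {msg}" for fid, msg in result.failures)
            )
        return result.labels

    def transform(self, frames):
        return self.predict(frames)
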