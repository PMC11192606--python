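"""Per-region and whole-LV quantities.

Everything downstream of the label maps is arithmetic on a small table of
per-phase region volumes (short-axis stacks, Simpson slice summation, mL) or
areas (four-chamber views, cm²):

* systolic fractional volume/area change (SFVC/SFAC) — the ES value divided by
  the ED value of a label; for a blood pool this is exactly ``1 − EF``;
* ejection fraction ``EF = (EDV − ESV)/EDV`` of the central cavity, the
  intertrabecular recesses, and the pooled total cavity;
* the pooled total cavity under three conventions:

  - ``guidelines`` — trabecular tissue is counted inside the blood pool
    (cavity = CC + recesses + trabeculations, per echo/CMR guidelines);
  - ``jacquier``  — the recesses are counted as trabecular myocardium
    (cavity = CC only);
  - ``contour``   — trabeculations contoured out, recesses kept as blood
    (cavity = CC + recesses; the reference convention);

* trabecular mass (mean of ED and ES tissue volumes), its fraction of LV mass,
  and the Jacquier criterion (fraction > 20%);
* MAPSE and global longitudinal shortening from apex/annulus landmarks;
* a mislabeling sensitivity analysis that moves central-cavity blood into the
  recess label and recomputes both EFs.

Fractions are stored as fractions throughout; rendering as percentages happens
only in the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .frames import ED, ES, Label, LabelFrame, Phase

__all__ = [
    "Convention",
    "CONVENTIONS",
    "RegionQuantities",
    "CavityReport",
    "LongitudinalLandmarks",
    "quantities_from_labels",
    "fractional_change",
    "ef",
    "cavity_report",
    "trabecular_mass",
    "longitudinal_metrics",
    "ef_category",
    "mislabel_sensitivity",
]

Convention = str
CONVENTIONS: tuple[Convention, ...] = ("guidelines", "jacquier", "contour")

#: Jacquier criterion: excessive trabeculation ⇔ trabecular myocardium > 20% of LV mass.
JACQUIER_MASS_FRACTION = 0.20

_QUANT_LABELS = (
    Label.COMPACT,
    Label.TRABECULATION,
    Label.RECESS,
    Label.CENTRAL_CAVITY,
    Label.PAPILLARY,
)


@dataclass(frozen=True)
class RegionQuantities:
    """Per-phase volume (mL) or area (cm²) of each region of one study/view.

    ``values[label][phase]`` holds the measurement; ``kind`` is ``"volume"``
    (short-axis stacks) or ``"area"`` (four-chamber views).
    """

    kind: str
    values: Mapping[Label, Mapping[Phase, float]]
    view: str = "short_axis"
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("volume", "area"):
            raise ValueError(f"kind must be 'volume' or 'area', got {self.kind!r}")
        vals = {
            Label(lbl): {ED: float(v[ED]), ES: float(v[ES])}
            for lbl, v in self.values.items()
        }
        for lbl, v in vals.items():
            for phase, x in v.items():
                if x < 0:
                    raise ValueError(f"negative {self.kind} for {lbl.name} at {phase}")
        for lbl in _QUANT_LABELS:
            vals.setdefault(lbl, {ED: 0.0, ES: 0.0})
        object.__setattr__(self, "values", vals)

    def get(self, label: Label, phase: Phase) -> float:
        return self.values[label][phase]

    def total(self, phase: Phase) -> float:
        """Sum of all region values at one phase (exact sum of the parts)."""
        return sum(self.values[lbl][phase] for lbl in _QUANT_LABELS)

    def myocardium(self, phase: Phase, include_papillary: bool = True) -> float:
        m = self.get(Label.COMPACT, phase) + self.get(Label.TRABECULATION, phase)
        if include_papillary:
            m += self.get(Label.PAPILLARY, phase)
        return m


@dataclass(frozen=True)
class CavityReport:
    """EDV/ESV/SV/EF of the pooled total cavity under one convention.

    Volumes in mL; EF as a fraction.  ``sv = edv − esv`` exactly.
    """

    convention: Convention
    edv: float
    esv: float
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.edv < 0 or self.esv < 0:
            raise ValueError("volumes must be non-negative")

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return ef(self.edv, self.esv)


def quantities_from_labels(frames: Iterable[LabelFrame]) -> RegionQuantities:
    """Region quantities of one study/view from its label frames.

    Short-axis stacks yield volumes by Simpson slice summation
    (Σ slices: pixel count × pixel area × slice thickness); four-chamber
    views yield areas (pixel count × pixel area).  Both phases must be present
    and all frames must share view and spacing metadata.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no label frames given")
    views = {f.view for f in frames}
    if len(views) > 1:
        raise ValueError(f"mixed views in one call: {sorted(views)}")
    view = views.pop()
    spacings = {round(f.pixel_spacing, 9) for f in frames}
    if len(spacings) > 1:
        raise ValueError("inconsistent pixel spacing across frames")
    kind = "area" if frames[0].slice_thickness is None else "volume"
    study_id = frames[0].study_id

    values: dict[Label, dict[Phase, float]] = {
        lbl: {ED: 0.0, ES: 0.0} for lbl in _QUANT_LABELS
    }
    seen = {ED: 0, ES: 0}
    for f in frames:
        seen[f.phase] += 1
        for lbl in _QUANT_LABELS:
            if kind == "volume":
                values[lbl][f.phase] += f.volume_ml(lbl)
            else:
                values[lbl][f.phase] += f.area_cm2(lbl)
    if seen[ED] == 0 or seen[ES] == 0:
        raise ValueError(f"both phases required, got ED×{seen[ED]}, ES×{seen[ES]}")
    return RegionQuantities(kind=kind, values=values, view=view, study_id=study_id)


def fractional_change(q: RegionQuantities, label: Label) -> float:
    """Systolic fractional change of one label: ES value / ED value.

    SFVC for volume-kind quantities, SFAC for area-kind.  For any blood label
    this equals ``1 − EF`` identically.  An ED value of zero leaves the ratio
    undefined: NaN is returned with a warning (flagged, not computed).
    """
    ed = q.get(label, ED)
    es = q.get(label, ES)
    if ed <= 0:
        warnings.warn(
            f"fractional change of {Label(label).name} undefined: ED value is 0",
            stacklevel=2,
        )
        return float("nan")
    return es / ed


def ef(edv: float, esv: float) -> float:
    """Ejection fraction ``(EDV − ESV)/EDV``.

    ``esv > edv`` yields a negative EF with a warning (possible mislabeling)
    rather than an error; ``edv ≤ 0`` is an error.
    """
    if edv <= 0:
        raise ValueError(f"EDV must be positive, got {edv}")
    if esv < 0:
        raise ValueError(f"ESV must be non-negative, got {esv}")
    if esv > edv:
        warnings.warn(
            f"ESV ({esv:g}) exceeds EDV ({edv:g}): negative EF — possible mislabeling",
            stacklevel=2,
        )
    return (edv - esv) / edv


def _pooled(q: RegionQuantities, convention: Convention, phase: Phase) -> float:
    cc = q.get(Label.CENTRAL_CAVITY, phase)
    ir = q.get(Label.RECESS, phase)
    if convention == "jacquier":
        return cc
    if convention == "contour":
        return cc + ir
    if convention == "guidelines":
        # Trabecular tissue enters the blood pool at its measured per-phase
        # value, so an ED/ES measurement mismatch propagates into SV.
        return cc + ir + q.get(Label.TRABECULATION, phase)
    raise ValueError(f"unknown convention {convention!r}")


def cavity_report(q: RegionQuantities, convention: Convention) -> CavityReport:
    """Total-cavity EDV/ESV/SV/EF under one cavity convention (volume-kind only)."""
    if q.kind != "volume":
        raise ValueError("cavity conventions are defined on volumes, not areas")
    return CavityReport(
        convention=convention,
        edv=_pooled(q, convention, ED),
        esv=_pooled(q, convention, ES),
        study_id=q.study_id,
    )


def trabecular_mass(
    q: RegionQuantities, include_papillary: bool = False
) -> dict[str, float | bool]:
    """Trabecular mass and the Jacquier criterion.

    Tissue volumes are the mean of the ED and ES measurements.  LV mass is
    mean-phase compact + trabecular tissue, optionally + papillary (the
    roll-up is configurable because conventions differ on whether papillary
    volume belongs to the mass denominator; both are reported upstream).

    Returns ``mass_volume`` (mL), ``fraction_of_lv_mass`` (fraction),
    ``jacquier_positive`` (fraction > 20%) and ``fraction_of_layer``
    (trabecular tissue / (tissue + recess) at ED).
    """
    if q.kind != "volume":
        raise ValueError("trabecular mass is defined on volumes")
    trab = 0.5 * (q.get(Label.TRABECULATION, ED) + q.get(Label.TRABECULATION, ES))
    compact = 0.5 * (q.get(Label.COMPACT, ED) + q.get(Label.COMPACT, ES))
    pap = 0.5 * (q.get(Label.PAPILLARY, ED) + q.get(Label.PAPILLARY, ES))
    lv_mass = compact + trab + (pap if include_papillary else 0.0)
    if lv_mass <= 0:
        raise ValueError("zero LV mass")
    layer_ed = q.get(Label.TRABECULATION, ED) + q.get(Label.RECESS, ED)
    fraction = trab / lv_mass
    return {
        "mass_volume": trab,
        "fraction_of_lv_mass": fraction,
        "jacquier_positive": bool(fraction > JACQUIER_MASS_FRACTION),
        "fraction_of_layer": (
            q.get(Label.TRABECULATION, ED) / layer_ed if layer_ed > 0 else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# Longitudinal function (MAPSE, GL-shortening)
# ---------------------------------------------------------------------------

_LONG_AXIS_VIEWS = ("two_chamber", "three_chamber", "four_chamber")


@dataclass(frozen=True)
class LongitudinalLandmarks:
    """Apex and mitral-annulus landmarks of the long-axis views, in mm.

    ``points[view][phase]`` is a mapping with ``"apex"`` (a 2-vector, the
    epicardial apex) and ``"annulus"`` (two 2-vectors, the origins of the
    mitral leaflets).  Each view contributes two wall lengths (apex to each
    annulus origin) and one LV length (apex to the annulus midpoint).
    """

    points: Mapping[str, Mapping[Phase, Mapping[str, object]]]
    study_id: str = ""

    def views(self) -> list[str]:
        return [v for v in _LONG_AXIS_VIEWS if v in self.points]

    def _entry(self, view: str, phase: Phase) -> Mapping[str, object]:
        try:
            return self.points[view][phase]
        except KeyError as exc:
            raise ValueError(f"missing landmarks: view {view!r}, phase {phase!r}") from exc

    def wall_lengths(self, view: str, phase: Phase) -> tuple[float, float]:
        entry = self._entry(view, phase)
        apex = np.asarray(entry["apex"], dtype=float)
        ann = [np.asarray(p, dtype=float) for p in entry["annulus"]]
        if len(ann) != 2:
            raise ValueError("each view needs exactly two mitral-annulus origins")
        lengths = tuple(float(np.linalg.norm(apex - p)) for p in ann)
        if min(lengths) <= 0:
            raise ValueError("wall lengths must be positive")
        return lengths

    def lv_length(self, view: str, phase: Phase) -> float:
        entry = self._entry(view, phase)
        apex = np.asarray(entry["apex"], dtype=float)
        ann = [np.asarray(p, dtype=float) for p in entry["annulus"]]
        mid = 0.5 * (ann[0] + ann[1])
        length = float(np.linalg.norm(apex - mid))
        if length <= 0:
            raise ValueError("LV length must be positive")
        return length


def longitudinal_metrics(lm: LongitudinalLandmarks) -> dict[str, object]:
    """MAPSE per wall, global MAPSE, and global longitudinal shortening.

    Per-wall MAPSE = wall length at ED − wall length at ES.  Global MAPSE is
    the mean over the available walls (six when all three long-axis views are
    present).  GL-shortening = 100 × (LV length ED − LV length ES)/LV length
    ED, computed from the global (view-averaged) LV lengths and returned as a
    fraction here.
    """
    views = lm.views()
    if not views:
        raise ValueError("no long-axis views with landmarks")
    mapse: dict[str, float] = {}
    lv_ed, lv_es = [], []
    for view in views:
        ed_walls = lm.wall_lengths(view, ED)
        es_walls = lm.wall_lengths(view, ES)
        for i, (a, b) in enumerate(zip(ed_walls, es_walls)):
            mapse[f"{view}_wall{i + 1}"] = a - b
        lv_ed.append(lm.lv_length(view, ED))
        lv_es.append(lm.lv_length(view, ES))
    global_ed = float(np.mean(lv_ed))
    global_es = float(np.mean(lv_es))
    return {
        "mapse_per_wall": mapse,
        "global_mapse": float(np.mean(list(mapse.values()))),
        "gl_shortening": (global_ed - global_es) / global_ed,
        "lv_length_ed": global_ed,
        "lv_length_es": global_es,
    }


def ef_category(value: float) -> str:
    """EF category: ``below_40`` (<40%), ``40_to_50`` (40–50%, boundaries
    inclusive), ``above_50`` (>50%).  ``value`` is a fraction."""
    if not np.isfinite(value):
        raise ValueError("EF must be finite")
    if value < 0.40:
        return "below_40"
    if value <= 0.50:
        return "40_to_50"
    return "above_50"


def mislabel_sensitivity(
    q: RegionQuantities, transfer_ed: float, transfer_es: float
) -> dict[str, float | None]:
    """EF of CC and recesses after deliberately mislabeling cavity blood.

    Moves ``transfer_ed`` of the central-cavity ED volume and ``transfer_es``
    of its ES volume from the central-cavity label to the recess label
    (deflating the CC, inflating the recesses) and recomputes both EFs.  The
    exact perturbation scheme of the source analysis is not published; the two
    schemes here — symmetric (equal ED and ES fractions) and ES-only — are
    declared reconstructions.

    Under the symmetric scheme the perturbed recess EF is a mediant of the two
    original EFs and therefore can never cross below the CC EF when it starts
    above it: ``symmetric_crossing`` is ``None`` in that case.  The ES-only
    scheme does admit a crossing; ``crossing_transfer`` is the ES transfer
    fraction solving EF(IR) = EF(CC), or ``None`` when it falls outside
    ``[0, 1)``.
    """
    if not (0 <= transfer_ed < 1 and 0 <= transfer_es < 1):
        raise ValueError("transfer fractions must lie in [0, 1)")
    cc_ed = q.get(Label.CENTRAL_CAVITY, ED)
    cc_es = q.get(Label.CENTRAL_CAVITY, ES)
    ir_ed = q.get(Label.RECESS, ED)
    ir_es = q.get(Label.RECESS, ES)

    new_cc_ed = (1 - transfer_ed) * cc_ed
    new_cc_es = (1 - transfer_es) * cc_es
    new_ir_ed = ir_ed + transfer_ed * cc_ed
    new_ir_es = ir_es + transfer_es * cc_es

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ef_cc_new = ef(new_cc_ed, new_cc_es) if new_cc_ed > 0 else float("nan")
        ef_ir_new = ef(new_ir_ed, new_ir_es) if new_ir_ed > 0 else float("nan")

    # ES-only crossing: (ir_ed − ir_es − s·cc_es)/ir_ed = (cc_ed − (1−s)·cc_es)/cc_ed
    denom = cc_es * (cc_ed + ir_ed)
    crossing: float | None = None
    if denom > 0:
        s = (cc_ed * (ir_ed - ir_es) - ir_ed * (cc_ed - cc_es)) / denom
        if 0 <= s < 1:
            crossing = float(s)

    symmetric_crossing: float | None = None  # mediant property: no crossing exists
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cc_ed > 0 and ir_ed > 0 and np.isclose(ef(cc_ed, cc_es), ef(ir_ed, ir_es)):
            symmetric_crossing = 0.0  # already equal; any transfer preserves equality

    return {
        "ef_ir": ef_ir_new,
        "ef_cc": ef_cc_new,
        "crossing_transfer": crossing,
        "symmetric_crossing": symmetric_crossing,
    }
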