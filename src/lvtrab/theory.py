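"""Clamped-volume theoretical ventricle and its parameter sweeps.

A schematic LV whose total content — papillary muscles, central cavity (CC),
trabecular tissue, and intertrabecular recesses (IR) at end-diastole — is
clamped to 150 mL.  Two baselines are built in:

==================  =======  ==========
component (ED, mL)  normal   excessive
==================  =======  ==========
papillary               5        5
central cavity        120       70
trabeculations         10       30
recesses               15       45
==================  =======  ==========

with both blood pools operating at EF 60%.  Three one-parameter sweeps probe
how trabecular-layer characteristics distort the measured total EF:

* ``sweep_trab_volume`` — grow the trabecular tissue volume (the recess volume
  scales with it, ratio 1.5 as in both baselines) with both pool EFs held;
  under the guidelines convention the measured EF falls, under the contour
  convention it is invariant.
* ``sweep_layer_ef`` — vary the recess EF (layer compliance) from stiff to
  highly contractile while the CC EF stays at 60%.
* ``sweep_ed_mismatch`` — mis-measure the trabecular tissue volume at ED while
  the ES measurement stays at truth; the mismatch perturbs recess EF and, via
  the per-phase guidelines/contour pooling, EDV, SV and total EF.

All arithmetic is closed-form on the analytic volumes; rounding happens only
in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .frames import ED, ES, Label
from .metrics import CONVENTIONS, CavityReport, Convention, RegionQuantities, cavity_report

__all__ = [
    "ModelLV",
    "SweepResult",
    "baseline",
    "convention_ef",
    "sweep_trab_volume",
    "sweep_layer_ef",
    "sweep_ed_mismatch",
    "CLAMP_TOTAL_ML",
    "RECESS_TO_TRAB_RATIO",
]

CLAMP_TOTAL_ML = 150.0
#: Recess-to-trabeculation ED volume ratio shared by both baselines (15/10 = 45/30).
RECESS_TO_TRAB_RATIO = 1.5


@dataclass(frozen=True)
class ModelLV:
    """The theoretical ventricle: ED volumes (mL) plus the two pool EFs.

    The ED content (papillary + CC + trabeculations + recesses) must equal
    ``clamp_total`` exactly.  ES blood volumes are derived from the EFs;
    tissue volumes are phase-equal unless a sweep perturbs the measurement.
    """

    papillary: float
    cc_ed: float
    trab: float
    ir_ed: float
    ef_cc: float
    ef_ir: float
    clamp_total: float = CLAMP_TOTAL_ML

    def __post_init__(self) -> None:
        for name in ("papillary", "cc_ed", "trab", "ir_ed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("ef_cc", "ef_ir"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = self.papillary + self.cc_ed + self.trab + self.ir_ed
        if not np.isclose(total, self.clamp_total, rtol=0, atol=1e-9):
            raise ValueError(
                f"clamp violated: components sum to {total} mL, expected {self.clamp_total}"
            )

    @property
    def cc_es(self) -> float:
        return (1 - self.ef_cc) * self.cc_ed

    @property
    def ir_es(self) -> float:
        return (1 - self.ef_ir) * self.ir_ed

    def to_quantities(self, trab_ed: float | None = None) -> RegionQuantities:
        """The model as volume-kind :class:`RegionQuantities`.

        ``trab_ed`` overrides the ED trabecular *measurement* (the ES
        measurement and the truth stay at ``self.trab``); the corresponding
        measured recess ED is the layer total minus the measured tissue, so
        the layer sum is preserved.
        """
        t_ed = self.trab if trab_ed is None else float(trab_ed)
        layer_ed = self.trab + self.ir_ed
        if not 0 <= t_ed <= layer_ed:
            raise ValueError("measured ED trabecular volume outside the layer total")
        return RegionQuantities(
            kind="volume",
            values={
                Label.COMPACT: {ED: 0.0, ES: 0.0},
                Label.PAPILLARY: {ED: self.papillary, ES: self.papillary},
                Label.TRABECULATION: {ED: t_ed, ES: self.trab},
                Label.RECESS: {ED: layer_ed - t_ed, ES: self.ir_es},
                Label.CENTRAL_CAVITY: {ED: self.cc_ed, ES: self.cc_es},
            },
            study_id="theoretical",
        )


_BASELINES = {
    "normal": dict(papillary=5.0, cc_ed=120.0, trab=10.0, ir_ed=15.0),
    "excessive": dict(papillary=5.0, cc_ed=70.0, trab=30.0, ir_ed=45.0),
}


def baseline(kind: str = "excessive") -> ModelLV:
    """The built-in baseline ventricles (both pools at EF 60%)."""
    try:
        vols = _BASELINES[kind]
    except KeyError as exc:
        raise ValueError(f"kind must be one of {sorted(_BASELINES)}, got {kind!r}") from exc
    return ModelLV(ef_cc=0.60, ef_ir=0.60, **vols)


def convention_ef(m: ModelLV, convention: Convention) -> CavityReport:
    """Total-cavity EDV/ESV/SV/EF of the model under one cavity convention."""
    return cavity_report(m.to_quantities(), convention)


@dataclass(frozen=True)
class SweepResult:
    """One parameter sweep: the swept name, its grid, and a tidy table with
    per-point component volumes and the EF under every convention."""

    parameter: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        grid = self.table[self.parameter].to_numpy()
        if len(grid) == 0:
            raise ValueError("empty sweep")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("sweep grid must be strictly increasing")

    @property
    def grid(self) -> np.ndarray:
        return self.table[self.parameter].to_numpy()

    def ef(self, convention: Convention) -> np.ndarray:
        return self.table[f"ef_{convention}"].to_numpy()

    def sv(self, convention: Convention) -> np.ndarray:
        return self.table[f"sv_{convention}"].to_numpy()


def _sweep_rows(param: str, value: float, m: ModelLV, trab_ed: float | None = None) -> dict:
    q = m.to_quantities(trab_ed=trab_ed)
    row = {
        param: value,
        "papillary": m.papillary,
        "cc_ed": m.cc_ed,
        "cc_es": m.cc_es,
        "trab_ed": q.get(Label.TRABECULATION, ED),
        "trab_es": q.get(Label.TRABECULATION, ES),
        "ir_ed": q.get(Label.RECESS, ED),
        "ir_es": q.get(Label.RECESS, ES),
        "ef_ir": (
            (q.get(Label.RECESS, ED) - q.get(Label.RECESS, ES)) / q.get(Label.RECESS, ED)
            if q.get(Label.RECESS, ED) > 0
            else np.nan
        ),
    }
    for conv in CONVENTIONS:
        rep = cavity_report(q, conv)
        row[f"edv_{conv}"] = rep.edv
        row[f"esv_{conv}"] = rep.esv
        row[f"sv_{conv}"] = rep.sv
        row[f"ef_{conv}"] = rep.ef
    return row


def sweep_trab_volume(
    kind: str = "excessive",
    trab_grid=None,
    recess_ratio: float = RECESS_TO_TRAB_RATIO,
) -> SweepResult:
    """Sweep the trabecular tissue volume with both pool EFs held.

    For each tissue volume T the recess ED volume is tied to it as
    ``ir_ed = recess_ratio × T`` (the ratio 1.5 is shared by both baselines;
    the redistribution rule is an inference, exposed here as a parameter) and
    the CC absorbs the remainder of the clamp.  Infeasible points (CC ED
    volume < 0) are dropped with a warning.
    """
    base = baseline(kind)
    if trab_grid is None:
        trab_grid = np.arange(0.0, 50.0 + 1e-9, 2.5)
    rows = []
    for t in np.asarray(trab_grid, dtype=float):
        ir = recess_ratio * t
        cc = base.clamp_total - base.papillary - t - ir
        if cc < 0:
            warnings.warn(f"trabecular volume {t:g} mL infeasible (CC would be negative)")
            continue
        m = replace(base, cc_ed=cc, trab=t, ir_ed=ir)
        rows.append(_sweep_rows("trab_volume", float(t), m))
    return SweepResult("trab_volume", pd.DataFrame(rows))


def sweep_layer_ef(kind: str = "excessive", ef_ir_grid=None) -> SweepResult:
    """Sweep the recess (trabecular-layer) EF with all volumes fixed at the
    baseline and the CC EF held at 60%."""
    base = baseline(kind)
    if ef_ir_grid is None:
        ef_ir_grid = np.arange(0.10, 0.90 + 1e-9, 0.05)
    rows = []
    for e in np.asarray(ef_ir_grid, dtype=float):
        if not 0 <= e <= 1:
            raise ValueError("recess EF grid must lie in [0, 1]")
        rows.append(_sweep_rows("ef_ir", float(e), replace(base, ef_ir=e)))
    return SweepResult("ef_ir", pd.DataFrame(rows))


def sweep_ed_mismatch(kind: str = "excessive", measured_trab_ed_grid=None) -> SweepResult:
    """Sweep the *measured* ED trabecular tissue volume.

    The ES measurement stays at the baseline truth; the measured ED recess is
    the layer total minus the measured ED tissue.  Underestimating the tissue
    at ED inflates the measured recess ED, hence the recess EF, and (under the
    per-phase guidelines/contour pooling) EDV, SV and total EF.  Points at or
    beyond the layer total are dropped with a warning.
    """
    base = baseline(kind)
    layer = base.trab + base.ir_ed
    if measured_trab_ed_grid is None:
        measured_trab_ed_grid = np.arange(10.0, 50.0 + 1e-9, 2.5)
    rows = []
    for m_ed in np.asarray(measured_trab_ed_grid, dtype=float):
        if m_ed <= 0 or m_ed >= layer:
            warnings.warn(
                f"measured ED trabecular volume {m_ed:g} mL outside (0, {layer:g}); dropped"
            )
            continue
        rows.append(_sweep_rows("measured_trab_ed", float(m_ed), base, trab_ed=m_ed))
    return SweepResult("measured_trab_ed", pd.DataFrame(rows))
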