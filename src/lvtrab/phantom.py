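"""Synthetic cine phantoms with known ground truth.

Bright-blood (SSFP-like) cine frames of a schematic left ventricle at
end-diastole and end-systole, together with the exact label maps they were
rendered from, so that every downstream stage — threshold calibration,
four-region labelling, volumetry, EF — can be validated without patient data.

Short-axis geometry (per slice)
-------------------------------
Concentric at ED: an annular compact wall (outer radius ``R``, thickness
``compact_thickness``), a trabecular annulus of ``n_trabeculae`` radial tissue
spokes occupying ``trabecular_tissue_fraction`` of the annulus, a circular
central cavity, and papillary discs detached from the wall inside the cavity.

The ES geometry is solved in closed form from the analytic disc/annulus areas
so that the central-cavity volume shrinks to ``(1 − target_ef_cc)`` of its ED
value and the recess volume to ``(1 − target_ef_ir)`` of its ED value while
every tissue volume is conserved exactly: the cavity radius follows from the
cavity target, the layer outer radius from tissue conservation (the spokes
thicken angularly to absorb the conserved tissue), and the epicardial radius
from compact-wall conservation (the wall thickens inward).

Four-chamber geometry
---------------------
A single long-axis slice: a bullet-shaped (half-ellipse) LV with semi-axes
``epicardial_radius`` × ``long_axis_length``, a trabeculated apical/lateral
band, papillary discs, and a thin schematic tissue cap closing the base so the
blood pool is enclosed.  Ground truth is area-based (cm²); apex and
mitral-annulus landmarks are emitted per phase, with the long axis shortening
by ``target_gl_shortening`` at ES.

Rendering
---------
Labels are rasterized first (these are the ground truth, emitted pre-blur);
intensities are assigned per tissue/blood, blurred by ``blur_sigma`` and
degraded with additive Gaussian noise of sd ``noise_sd`` from the spec's seed.
Identical spec + seed reproduce the frames bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import ED, ES, GrayFrame, Label, LabelFrame, Phase
from .metrics import LongitudinalLandmarks, RegionQuantities, quantities_from_labels

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "PhantomGeometryError",
    "generate_short_axis_phantom",
    "generate_four_chamber_phantom",
    "default_short_axis_spec",
    "default_four_chamber_spec",
]


class PhantomGeometryError(ValueError):
    """Requested phantom geometry is infeasible; the message names the
    violated constraint."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom study.

    Lengths in mm, intensities in arbitrary units, fractions in (0, 1).
    ``epicardial_radius`` may be a scalar (cylindrical stack) or a per-slice
    profile (monotone apex-to-base tapering); the default stack is cylindrical
    so that apical slices stay resolvable at the default grid.
    """

    n_slices: int = 8
    grid_size: int = 128
    pixel_spacing: float = 0.8
    slice_thickness: float = 8.0
    epicardial_radius: float | Sequence[float] = 42.0
    compact_thickness: float = 10.0
    trabecular_layer_thickness: float = 13.0
    n_trabeculae: int = 20
    trabecular_tissue_fraction: float = 0.5
    target_ef_cc: float = 0.438
    target_ef_ir: float = 0.610
    papillary_count: int = 2
    papillary_radius: float = 4.0
    intensity_blood: float = 1000.0
    intensity_myocardium: float = 300.0
    noise_sd: float = 35.0
    blur_sigma: float = 0.8
    seed: int = 0
    # four-chamber only
    long_axis_length: float = 80.0
    target_gl_shortening: float = 0.15
    base_cap_thickness: float = 10.0
    #: half-angle (degrees) at each end of the base excluded from the
    #: trabeculated band — the band is apical/lateral, not peri-annular
    band_margin_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.grid_size < 16:
            raise PhantomGeometryError("need at least one slice and a 16-pixel grid")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise PhantomGeometryError("spacing and slice thickness must be positive")
        layer = self.compact_thickness + self.trabecular_layer_thickness
        if self.compact_thickness <= 0 or self.trabecular_layer_thickness <= 0:
            raise PhantomGeometryError("wall and layer thickness must be positive")
        for r in self.radius_profile():
            if r <= layer:
                raise PhantomGeometryError(
                    "epicardial_radius must exceed compact + trabecular layer thickness"
                )
        for name in ("trabecular_tissue_fraction", "target_ef_cc", "target_ef_ir",
                     "target_gl_shortening"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise PhantomGeometryError(f"{name} must lie strictly in (0, 1)")
        if self.intensity_blood <= self.intensity_myocardium:
            raise PhantomGeometryError(
                "bright-blood convention requires intensity_blood > intensity_myocardium"
            )
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise PhantomGeometryError("noise_sd and blur_sigma must be non-negative")
        if self.n_trabeculae < 1:
            raise PhantomGeometryError("need at least one trabecula")
        if self.papillary_count < 0 or self.papillary_radius <= 0:
            raise PhantomGeometryError("invalid papillary parameters")
        half_field = self.grid_size * self.pixel_spacing / 2
        if max(self.radius_profile()) > half_field - 2 * self.pixel_spacing:
            raise PhantomGeometryError(
                "grid too small: LV must fit with a background margin of >= 2 pixels"
            )

    def radius_profile(self) -> tuple[float, ...]:
        r = self.epicardial_radius
        if np.isscalar(r):
            return (float(r),) * self.n_slices
        prof = tuple(float(x) for x in r)  # type: ignore[arg-type]
        if len(prof) != self.n_slices:
            raise PhantomGeometryError("epicardial_radius profile length != n_slices")
        return prof


@dataclass(frozen=True)
class PhantomStudy:
    """A generated study: gray and ground-truth label frames per slice per
    phase, the counted ground-truth quantities, landmarks (four-chamber), and
    the generating spec."""

    spec: PhantomSpec
    view: str
    gray_frames: tuple[GrayFrame, ...]
    label_frames: tuple[LabelFrame, ...]
    truth: RegionQuantities
    analytic: RegionQuantities
    landmarks: LongitudinalLandmarks | None = None
    study_id: str = ""

    def frames(self, phase: Phase | None = None, gray: bool = True):
        pool = self.gray_frames if gray else self.label_frames
        return [f for f in pool if phase is None or f.phase == phase]


# ---------------------------------------------------------------------------
# Short-axis geometry
# ---------------------------------------------------------------------------

#: papillary disc centres sit at this fraction of the cavity radius
_PAP_CENTER_FRAC = 0.5
#: minimum clearance (mm) between a papillary disc and the cavity boundary
_PAP_CLEARANCE = 1.5


@dataclass(frozen=True)
class _SliceGeometry:
    """Analytic radii/fractions of one short-axis slice at one phase."""

    r_epi: float
    r_layer_outer: float
    r_cavity: float
    tissue_fraction: float
    pap_center_r: float

    def areas(self, n_pap: int, r_pap: float) -> dict[Label, float]:
        a_pap = n_pap * math.pi * r_pap**2
        a_ann = math.pi * (self.r_layer_outer**2 - self.r_cavity**2)
        return {
            Label.COMPACT: math.pi * (self.r_epi**2 - self.r_layer_outer**2),
            Label.TRABECULATION: a_ann * self.tissue_fraction,
            Label.RECESS: a_ann * (1 - self.tissue_fraction),
            Label.CENTRAL_CAVITY: math.pi * self.r_cavity**2 - a_pap,
            Label.PAPILLARY: a_pap,
        }


def _solve_slice(spec: PhantomSpec, r_epi: float) -> dict[Phase, _SliceGeometry]:
    """ED geometry from the spec, ES geometry from the closed-form inversion
    of the analytic disc/annulus areas under the EF targets and exact tissue
    conservation."""
    px = spec.pixel_spacing
    r_to = r_epi - spec.compact_thickness
    r_cc = r_to - spec.trabecular_layer_thickness
    a_pap = spec.papillary_count * math.pi * spec.papillary_radius**2
    pap_c = _PAP_CENTER_FRAC * r_cc
    if spec.papillary_count:
        if pap_c + spec.papillary_radius > r_cc - _PAP_CLEARANCE:
            raise PhantomGeometryError(
                "papillary discs would touch the cavity boundary at ED"
            )
        if pap_c - spec.papillary_radius < 0:
            raise PhantomGeometryError("papillary discs overlap the cavity centre")
    ed = _SliceGeometry(r_epi, r_to, r_cc, spec.trabecular_tissue_fraction, pap_c)
    a = ed.areas(spec.papillary_count, spec.papillary_radius)

    # ES: cavity radius from the CC target, layer outer radius from tissue
    # conservation, spoke fraction from the recess target, epicardium from
    # compact conservation.
    a_cc_es = (1 - spec.target_ef_cc) * a[Label.CENTRAL_CAVITY]
    r_cc_es = math.sqrt((a_cc_es + a_pap) / math.pi)
    if r_cc_es < px:
        raise PhantomGeometryError(
            f"target_ef_cc={spec.target_ef_cc} drives the ES cavity radius "
            f"({r_cc_es:.2f} mm) below one pixel"
        )
    layer_es = a[Label.TRABECULATION] + (1 - spec.target_ef_ir) * a[Label.RECESS]
    r_to_es = math.sqrt(r_cc_es**2 + layer_es / math.pi)
    f_es = a[Label.TRABECULATION] / layer_es
    if not 0 < f_es < 1:
        raise PhantomGeometryError("ES spoke fraction left (0, 1); infeasible targets")
    r_epi_es = math.sqrt(r_to_es**2 + a[Label.COMPACT] / math.pi)
    pap_c_es = pap_c * (r_cc_es / r_cc)
    if spec.papillary_count and pap_c_es + spec.papillary_radius > r_cc_es - px:
        raise PhantomGeometryError(
            "papillary discs would touch the cavity boundary at ES"
        )
    es = _SliceGeometry(r_epi_es, r_to_es, r_cc_es, f_es, pap_c_es)
    return {ED: ed, ES: es}


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.grid_size
    c = (n - 1) / 2.0
    idx = (np.arange(n) - c) * spec.pixel_spacing
    y, x = np.meshgrid(idx, idx, indexing="ij")
    return x, y


def _spoke_mask(theta: np.ndarray, n_spokes: int, tissue_fraction: float) -> np.ndarray:
    """True where the angle falls inside a tissue spoke (spokes evenly spaced,
    widened symmetrically about their centres)."""
    period = 2 * math.pi / n_spokes
    half_width = period * tissue_fraction / 2
    d = np.abs((theta % period) - period / 2)  # distance to nearest spoke centre
    return d <= half_width


def _rasterize_short_axis(spec: PhantomSpec, geom: _SliceGeometry) -> np.ndarray:
    x, y = _grid_coords(spec)
    r = np.hypot(x, y)
    # spoke centres at period/2 + k·period in theta
    theta = np.arctan2(y, x) % (2 * math.pi)
    lab = np.zeros(r.shape, dtype=np.uint8)
    lab[(r >= geom.r_layer_outer) & (r < geom.r_epi)] = int(Label.COMPACT)
    ann = (r >= geom.r_cavity) & (r < geom.r_layer_outer)
    spokes = _spoke_mask(theta, spec.n_trabeculae, geom.tissue_fraction)
    lab[ann & spokes] = int(Label.TRABECULATION)
    lab[ann & ~spokes] = int(Label.RECESS)
    cav = r < geom.r_cavity
    lab[cav] = int(Label.CENTRAL_CAVITY)
    for k in range(spec.papillary_count):
        ang = 2 * math.pi * k / spec.papillary_count + math.pi / 2
        cx = geom.pap_center_r * math.cos(ang)
        cy = geom.pap_center_r * math.sin(ang)
        pap = np.hypot(x - cx, y - cy) <= spec.papillary_radius
        lab[pap & cav] = int(Label.PAPILLARY)
    return lab


def _render_gray(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    tissue = np.isin(labels, (int(Label.COMPACT), int(Label.TRABECULATION), int(Label.PAPILLARY)))
    blood = np.isin(labels, (int(Label.RECESS), int(Label.CENTRAL_CAVITY)))
    img = np.zeros(labels.shape, dtype=float)
    img[tissue] = spec.intensity_myocardium
    img[blood] = spec.intensity_blood
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def generate_short_axis_phantom(spec: PhantomSpec, study_id: str = "phantom") -> PhantomStudy:
    """Generate a short-axis stack phantom (ED + ES frames per slice)."""
    rng = np.random.default_rng(spec.seed)
    gray: list[GrayFrame] = []
    labels: list[LabelFrame] = []
    analytic_vals = {lbl: {ED: 0.0, ES: 0.0} for lbl in
                     (Label.COMPACT, Label.TRABECULATION, Label.RECESS,
                      Label.CENTRAL_CAVITY, Label.PAPILLARY)}
    geoms = [_solve_slice(spec, r) for r in spec.radius_profile()]
    for phase in (ED, ES):
        for k, g in enumerate(geoms):
            geom = g[phase]
            lab = _rasterize_short_axis(spec, geom)
            img = _render_gray(spec, lab, rng)
            meta = dict(
                pixel_spacing=spec.pixel_spacing,
                slice_thickness=spec.slice_thickness,
                phase=phase,
                view="short_axis",
                slice_index=k,
                study_id=study_id,
            )
            labels.append(LabelFrame(labels=lab, **meta))
            gray.append(GrayFrame(pixels=img, **meta))
            for lbl, area in geom.areas(spec.papillary_count, spec.papillary_radius).items():
                analytic_vals[lbl][phase] += area * spec.slice_thickness / 1000.0
    analytic = RegionQuantities("volume", analytic_vals, view="short_axis", study_id=study_id)
    truth = quantities_from_labels(labels)
    return PhantomStudy(
        spec=spec, view="short_axis", gray_frames=tuple(gray),
        label_frames=tuple(labels), truth=truth, analytic=analytic, study_id=study_id,
    )


# ---------------------------------------------------------------------------
# Four-chamber geometry
# ---------------------------------------------------------------------------

_PAP_RHO_4CH = 0.25


@dataclass(frozen=True)
class _LongAxisGeometry:
    """Half-ellipse long-axis geometry at one phase (lengths in mm; rho are
    elliptical fractions of the epicardial boundary)."""

    semi_minor: float  # R, mm
    semi_major: float  # L, mm (apex depth below the base plane)
    rho_layer_outer: float
    rho_cavity: float
    tissue_fraction: float
    pap_rho: float

    def areas(self, spec: PhantomSpec) -> dict[Label, float]:
        beta = 1 - 2 * spec.band_margin_deg / 180.0
        s = self.semi_minor * self.semi_major
        a_half = math.pi / 2 * s
        a_pap = spec.papillary_count * math.pi * spec.papillary_radius**2
        a_ann = a_half * (self.rho_layer_outer**2 - self.rho_cavity**2)
        cap = 2 * self.semi_minor * spec.base_cap_thickness
        return {
            Label.COMPACT: a_half * (1 - self.rho_layer_outer**2) + cap,
            Label.TRABECULATION: a_ann * beta * self.tissue_fraction,
            Label.RECESS: a_ann * beta * (1 - self.tissue_fraction),
            Label.CENTRAL_CAVITY: (
                a_half * self.rho_cavity**2 + a_ann * (1 - beta) - a_pap
            ),
            Label.PAPILLARY: a_pap,
        }


def _solve_long_axis(spec: PhantomSpec) -> dict[Phase, _LongAxisGeometry]:
    R, L, h = float(spec.epicardial_radius), spec.long_axis_length, spec.base_cap_thickness
    if not np.isscalar(spec.epicardial_radius):
        raise PhantomGeometryError("four-chamber view takes a scalar epicardial_radius")
    field = spec.grid_size * spec.pixel_spacing
    if L + h > field - 4 * spec.pixel_spacing or 2 * R > field - 4 * spec.pixel_spacing:
        raise PhantomGeometryError(
            "grid too small: long-axis view must fit with a background margin of >= 2 pixels"
        )
    rho_to = 1 - spec.compact_thickness / R
    rho_cc = rho_to - spec.trabecular_layer_thickness / R
    if rho_cc <= 0:
        raise PhantomGeometryError("layer thicker than the epicardial radius")
    if spec.papillary_count and (
        _PAP_RHO_4CH + spec.papillary_radius / min(R, L) > rho_cc - _PAP_CLEARANCE / min(R, L)
    ):
        raise PhantomGeometryError("papillary discs would touch the cavity boundary at ED")
    ed = _LongAxisGeometry(R, L, rho_to, rho_cc, spec.trabecular_tissue_fraction, _PAP_RHO_4CH)
    a = ed.areas(spec)

    beta = 1 - 2 * spec.band_margin_deg / 180.0
    L_es = L * (1 - spec.target_gl_shortening)
    a_cav_es = (1 - spec.target_ef_cc) * a[Label.CENTRAL_CAVITY]
    a_layer_es = a[Label.TRABECULATION] + (1 - spec.target_ef_ir) * a[Label.RECESS]
    a_pap = a[Label.PAPILLARY]
    a_total_es = a_cav_es + a_layer_es + a[Label.COMPACT] + a_pap
    # (π/2)·R_es·L_es + 2h·R_es = total ES area → R_es (linear in R_es)
    R_es = a_total_es / (math.pi / 2 * L_es + 2 * h)
    s_es = R_es * L_es
    a_half_es = math.pi / 2 * s_es
    shell_es = a[Label.COMPACT] - 2 * R_es * h  # elliptical shell after the cap
    if shell_es <= 0:
        raise PhantomGeometryError("compact shell vanishes at ES; infeasible targets")
    rho_to_es_sq = 1 - shell_es / a_half_es
    if not 0 < rho_to_es_sq < 1:
        raise PhantomGeometryError("ES epicardial geometry infeasible")
    rho_to_es = math.sqrt(rho_to_es_sq)
    # trabecular band: tissue conserved + recess target fixes the layer span;
    # the remaining (1−β) arc of the annulus belongs to the cavity
    layer_band_es = a_layer_es  # = a_half_es·β·(ρ_to²−ρ_cc²)
    rho_cc_es_sq = (rho_to_es_sq * a_half_es * beta - layer_band_es) / (a_half_es * beta)
    if rho_cc_es_sq <= 0:
        raise PhantomGeometryError(
            "targets drive the ES cavity below zero (cavity radius < one pixel)"
        )
    rho_cc_es = math.sqrt(rho_cc_es_sq)
    if rho_cc_es * min(R_es, L_es) < spec.pixel_spacing:
        raise PhantomGeometryError("ES cavity smaller than one pixel")
    f_es = a[Label.TRABECULATION] / a_layer_es
    pap_rho_es = _PAP_RHO_4CH * (rho_cc_es / rho_cc)
    if spec.papillary_count and (
        pap_rho_es + spec.papillary_radius / min(R_es, L_es) > rho_cc_es
    ):
        raise PhantomGeometryError("papillary discs would touch the cavity boundary at ES")
    es = _LongAxisGeometry(R_es, L_es, rho_to_es, rho_cc_es, f_es, pap_rho_es)
    return {ED: ed, ES: es}


def _rasterize_long_axis(spec: PhantomSpec, geom: _LongAxisGeometry) -> np.ndarray:
    x, y0 = _grid_coords(spec)
    # shift so the shape (y ∈ [−L, cap]) is vertically centred on the grid
    y = y0 - (geom.semi_major - spec.base_cap_thickness) / 2
    lab = np.zeros(x.shape, dtype=np.uint8)
    # schematic base cap
    cap = (y >= 0) & (y < spec.base_cap_thickness) & (np.abs(x) <= geom.semi_minor)
    lab[cap] = int(Label.COMPACT)
    u = x / geom.semi_minor
    v = y / geom.semi_major
    below = y < 0
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)  # ∈ (−π, 0) below the base
    inside = below & (rho < 1)
    lab[inside & (rho >= geom.rho_layer_outer)] = int(Label.COMPACT)
    ann = inside & (rho >= geom.rho_cavity) & (rho < geom.rho_layer_outer)
    margin = math.radians(spec.band_margin_deg)
    band = (theta <= -margin) & (theta >= -(math.pi - margin))
    band_span = math.pi - 2 * margin
    # spokes evenly spaced inside the band, widened about their centres
    n = spec.n_trabeculae
    period = band_span / n
    pos = (-theta - margin) % period
    spokes = np.abs(pos - period / 2) <= period * geom.tissue_fraction / 2
    lab[ann & band & spokes] = int(Label.TRABECULATION)
    lab[ann & band & ~spokes] = int(Label.RECESS)
    lab[ann & ~band] = int(Label.CENTRAL_CAVITY)
    cav = inside & (rho < geom.rho_cavity)
    lab[cav] = int(Label.CENTRAL_CAVITY)
    for k in range(spec.papillary_count):
        ang = -(math.pi / 3) - k * (math.pi / 3)
        cx = geom.pap_rho * math.cos(ang) * geom.semi_minor
        cy = geom.pap_rho * math.sin(ang) * geom.semi_major
        pap = np.hypot(x - cx, y - cy) <= spec.papillary_radius
        lab[pap & cav] = int(Label.PAPILLARY)
    return lab


def generate_four_chamber_phantom(spec: PhantomSpec, study_id: str = "phantom") -> PhantomStudy:
    """Generate a single-slice four-chamber phantom with landmarks.

    Ground truth is area-based (cm²).  Landmark coordinates are in mm in the
    image plane, origin at the mitral-annulus midpoint (base-plane centre),
    the long axis pointing to negative y.
    """
    rng = np.random.default_rng(spec.seed)
    geoms = _solve_long_axis(spec)
    gray: list[GrayFrame] = []
    labels: list[LabelFrame] = []
    analytic_vals = {lbl: {} for lbl in (Label.COMPACT, Label.TRABECULATION, Label.RECESS,
                                         Label.CENTRAL_CAVITY, Label.PAPILLARY)}
    points: dict[str, dict[Phase, dict]] = {"four_chamber": {}}
    for phase in (ED, ES):
        geom = geoms[phase]
        lab = _rasterize_long_axis(spec, geom)
        img = _render_gray(spec, lab, rng)
        meta = dict(
            pixel_spacing=spec.pixel_spacing, slice_thickness=None, phase=phase,
            view="four_chamber", slice_index=None, study_id=study_id,
        )
        labels.append(LabelFrame(labels=lab, **meta))
        gray.append(GrayFrame(pixels=img, **meta))
        for lbl, area in geom.areas(spec).items():
            analytic_vals[lbl][phase] = area / 100.0  # mm² → cm²
        points["four_chamber"][phase] = {
            "apex": (0.0, -geom.semi_major),
            "annulus": ((-geom.semi_minor, 0.0), (geom.semi_minor, 0.0)),
        }
    analytic = RegionQuantities("area", analytic_vals, view="four_chamber", study_id=study_id)
    truth = quantities_from_labels(labels)
    lm = LongitudinalLandmarks(points=points, study_id=study_id)
    return PhantomStudy(
        spec=spec, view="four_chamber", gray_frames=tuple(gray),
        label_frames=tuple(labels), truth=truth, analytic=analytic,
        landmarks=lm, study_id=study_id,
    )


def default_short_axis_spec(**overrides) -> PhantomSpec:
    """The default short-axis phantom: an excessively trabeculated LV with the
    cohort-mean EF targets (CC 43.8%, recesses 61.0%)."""
    return PhantomSpec(**overrides)


def default_four_chamber_spec(**overrides) -> PhantomSpec:
    """The default four-chamber phantom: area-change targets at the cohort
    means (cavity SFAC 72% → area EF 28%; recess SFAC 37% → area EF 63%)."""
    params = dict(
        n_slices=1,
        epicardial_radius=38.0,
        long_axis_length=80.0,
        n_trabeculae=12,
        target_ef_cc=0.28,
        target_ef_ir=0.63,
        papillary_radius=3.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)
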