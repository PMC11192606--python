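"""Standard-format I/O: NIfTI frames, YAML manifests/specs, JSON landmarks.

A *study* on disk is a YAML manifest pointing at one gray NIfTI per phase
(short-axis slices stacked on the third axis; four-chamber as a single
slice), optional label NIfTI files with a JSON sidecar documenting the
integer code table, and an optional landmarks JSON.  Spacing lives both in
the manifest and the NIfTI headers and is cross-checked on read (mismatch
beyond 1% is an error).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .frames import ED, ES, GrayFrame, Label, LabelFrame
from .metrics import LongitudinalLandmarks
from .phantom import PhantomStudy

__all__ = [
    "StudyBundle",
    "ManifestError",
    "write_study",
    "read_study",
    "write_landmarks",
    "read_landmarks",
    "config_hash",
]

_PHASES = (ED, ES)


class ManifestError(ValueError):
    """A study manifest is invalid; the message names the schema violation."""


@dataclass(frozen=True)
class StudyBundle:
    """A validated on-disk study: frames loaded, metadata cross-checked."""

    study_id: str
    view: str
    pixel_spacing: float
    slice_thickness: float | None
    gray_frames: tuple[GrayFrame, ...]
    label_frames: tuple[LabelFrame, ...]
    landmarks: LongitudinalLandmarks | None
    provenance: str
    manifest_path: Path


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _affine(pixel_spacing: float, slice_thickness: float | None) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness or 1.0, 1.0])


def _stack(frames) -> np.ndarray:
    frames = sorted(frames, key=lambda f: f.slice_index or 0)
    arrays = [f.pixels if isinstance(f, GrayFrame) else f.labels for f in frames]
    return np.stack(arrays, axis=-1)


def write_landmarks(lm: LongitudinalLandmarks, path: Path) -> None:
    payload = {
        view: {
            phase: {
                "apex": list(map(float, entry["apex"])),
                "annulus": [list(map(float, p)) for p in entry["annulus"]],
            }
            for phase, entry in phases.items()
        }
        for view, phases in lm.points.items()
    }
    path.write_text(json.dumps(payload, indent=2))


def read_landmarks(path: Path, study_id: str = "") -> LongitudinalLandmarks:
    raw = json.loads(Path(path).read_text())
    return LongitudinalLandmarks(points=raw, study_id=study_id)


def write_study(study: PhantomStudy, out_dir: Path, with_labels: bool = True) -> Path:
    """Write a phantom study as NIfTI + manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = study.spec
    thickness = spec.slice_thickness if study.view == "short_axis" else None
    manifest: dict = {
        "study_id": study.study_id,
        "view": study.view,
        "pixel_spacing_mm": spec.pixel_spacing,
        "slice_thickness_mm": thickness,
        "provenance": f"phantom:{config_hash(spec)}",
        "gray": {},
    }
    for phase in _PHASES:
        arr = _stack(study.frames(phase, gray=True)).astype(np.float32)
        name = f"{study.study_id}_{study.view}_{phase}.nii"
        nib.save(nib.Nifti1Image(arr, _affine(spec.pixel_spacing, thickness)),
                 out_dir / name)
        manifest["gray"][phase] = name
    if with_labels:
        manifest["labels"] = {}
        for phase in _PHASES:
            arr = _stack(study.frames(phase, gray=False)).astype(np.uint8)
            name = f"{study.study_id}_{study.view}_{phase}_labels.nii"
            nib.save(nib.Nifti1Image(arr, _affine(spec.pixel_spacing, thickness)),
                     out_dir / name)
            manifest["labels"][phase] = name
        code_table = {int(code): name for code, name in
                      ((c, c.name.lower()) for c in Label)}
        (out_dir / f"{study.study_id}_label_codes.json").write_text(
            json.dumps(code_table, indent=2)
        )
    if study.landmarks is not None:
        lm_name = f"{study.study_id}_landmarks.json"
        write_landmarks(study.landmarks, out_dir / lm_name)
        manifest["landmarks"] = lm_name
    spec_name = f"{study.study_id}_spec.yaml"
    (out_dir / spec_name).write_text(yaml.safe_dump(dataclasses.asdict(spec)))
    manifest["spec"] = spec_name
    manifest_path = out_dir / f"{study.study_id}_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def _load_nifti(path: Path, expected_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise ManifestError(f"unreadable NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    if abs(zooms[0] - expected_spacing) > 0.01 * expected_spacing:
        raise ManifestError(
            f"{path}: header spacing {zooms[0]:.4f} mm disagrees with the "
            f"manifest ({expected_spacing:.4f} mm) by more than 1%"
        )
    if data.ndim == 2:
        data = data[..., None]
    return data, np.asarray(zooms)


def read_study(manifest_path: Path) -> StudyBundle:
    """Load and validate a study manifest.

    Errors name the missing phase, the unreadable file, or the spacing
    mismatch.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = yaml.safe_load(manifest_path.read_text())
    except Exception as exc:
        raise ManifestError(f"cannot parse manifest {manifest_path}: {exc}") from exc
    for key in ("study_id", "view", "pixel_spacing_mm", "gray"):
        if key not in manifest:
            raise ManifestError(f"manifest lacks required key {key!r}")
    view = manifest["view"]
    spacing = float(manifest["pixel_spacing_mm"])
    thickness = manifest.get("slice_thickness_mm")
    thickness = float(thickness) if thickness else None
    if spacing <= 0:
        raise ManifestError("pixel spacing must be positive")
    if view == "short_axis" and thickness is None:
        raise ManifestError("short-axis studies need slice_thickness_mm")
    study_id = str(manifest["study_id"])
    base = manifest_path.parent

    def load_frames(section: dict, as_labels: bool):
        frames = []
        for phase in _PHASES:
            if phase not in section:
                raise ManifestError(f"manifest lacks the {phase} phase")
            data, _ = _load_nifti(base / section[phase], spacing)
            for k in range(data.shape[-1]):
                meta = dict(
                    pixel_spacing=spacing,
                    slice_thickness=thickness,
                    phase=phase,
                    view=view,
                    slice_index=k if view == "short_axis" else None,
                    study_id=study_id,
                )
                if as_labels:
                    frames.append(LabelFrame(labels=data[..., k].astype(np.uint8), **meta))
                else:
                    frames.append(GrayFrame(pixels=data[..., k].astype(float), **meta))
        return tuple(frames)

    gray = load_frames(manifest["gray"], as_labels=False)
    labels: tuple[LabelFrame, ...] = ()
    if "labels" in manifest:
        labels = load_frames(manifest["labels"], as_labels=True)
    landmarks = None
    if manifest.get("landmarks"):
        landmarks = read_landmarks(base / manifest["landmarks"], study_id=study_id)
    return StudyBundle(
        study_id=study_id,
        view=view,
        pixel_spacing=spacing,
        slice_thickness=thickness,
        gray_frames=gray,
        label_frames=labels,
        landmarks=landmarks,
        provenance=str(manifest.get("provenance", "external")),
        manifest_path=manifest_path,
    )
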