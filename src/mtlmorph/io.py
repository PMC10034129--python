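"""Standard-format I/O: PLY meshes, NIfTI volumes, TIFF sections with JSON
sidecars, CSV tables.

Conventions: world = origin + index * spacing with 0-based indices and
axis-aligned spacing; meshes in world mm.
"""

from __future__ import annotations

import json
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import trimesh

from .surface import TriSurface
from .projective import SectionImage, SectionStack


def write_ply(surface: TriSurface, path) -> Path:
    path = Path(path)
    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    mesh.export(path, file_type="ply", encoding="ascii")
    return path


def read_ply(path) -> TriSurface:
    mesh = trimesh.load_mesh(str(path), process=False)
    return TriSurface(np.asarray(mesh.vertices, float), np.asarray(mesh.faces))


def write_nifti(volume: np.ndarray, spacing, path, origin=(0.0, 0.0, 0.0)) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(np.asarray(volume), affine)
    nib.save(img, str(path))
    return path


def read_nifti(path):
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    return vol, spacing, origin


def write_section(section: SectionImage, path) -> Path:
    """16-bit TIFF plus a JSON sidecar {pixel_size_mm, z_mm, stack_id}."""
    path = Path(path)
    img = section.image
    lo, hi = float(img.min()), float(img.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(path, ((img - lo) * scale).astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_size_mm": section.pixel_size, "z_mm": section.z_mm,
        "stack_id": section.stack_id, "intensity_offset": lo,
        "intensity_scale": scale}))
    return path


def read_section(path) -> SectionImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = tifffile.imread(path).astype(float)
    img = raw / meta.get("intensity_scale", 1.0) + meta.get("intensity_offset", 0.0)
    return SectionImage(img, meta["pixel_size_mm"], meta["z_mm"],
                        meta.get("stack_id", ""))


def write_stack(stack: SectionStack, directory, prefix: str = "section"):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(stack):
        paths.append(write_section(s, directory / f"{prefix}_{i:03d}.tiff"))
    return paths


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
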