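"""NIfTI-1 volume/mask I/O and report serialization.

Volumes are stored one per NIfTI file with a diagonal affine (the package's
fixed axis convention); spacing comes from the affine diagonal and the
origin from its translation.  A compartment set is stored as one mask file
per VOI plus a JSON manifest recording roles and tumor-to-LPT assignment.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import CompartmentSet, Grid, VOIMask, VoxelImage

__all__ = ["read_volume", "write_volume", "read_masks", "write_masks", "write_report"]

MANIFEST_NAME = "masks.json"
SCHEMA_VERSION = 1


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> Grid:
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.abs(off).max() > 1e-6:
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError("affine must have positive diagonal spacing")
    return Grid(tuple(int(n) for n in shape[:3]), spacing, tuple(float(x) for x in aff[:3, 3]))


def write_volume(image: VoxelImage, path) -> None:
    img = nib.Nifti1Image(image.values.astype(np.float64), _affine(image.grid))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = image.quantity.encode()[:79]
    nib.save(img, str(path))


def read_volume(path, quantity: str | None = None) -> VoxelImage:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        grid = _grid_from_affine(img.affine, data.shape)
    except Exception as exc:  # noqa: BLE001 - annotate the offending file
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if quantity is None:
        quantity = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "activity"
    return VoxelImage(grid, data, quantity)


def write_masks(comp: CompartmentSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": SCHEMA_VERSION, "liver": "liver.nii.gz",
                "lpts": [], "tumors": []}

    def save(mask: VOIMask, fname: str) -> None:
        img = nib.Nifti1Image(mask.membership.astype(np.uint8), _affine(mask.grid))
        nib.save(img, str(directory / fname))

    save(comp.liver, "liver.nii.gz")
    for i, lpt in enumerate(comp.lpts):
        fname = f"lpt-{i}.nii.gz"
        save(lpt, fname)
        manifest["lpts"].append({"file": fname, "label": lpt.label})
    for i, (t, k) in enumerate(zip(comp.tumors, comp.tumor_lpt)):
        fname = f"tumor-{i}.nii.gz"
        save(t, fname)
        manifest["tumors"].append({"file": fname, "label": t.label, "lpt": int(k)})
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))


def _read_mask(path, label: str) -> VOIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return VOIMask(_grid_from_affine(img.affine, data.shape), data > 0, label)


def read_masks(directory) -> CompartmentSet:
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    liver = _read_mask(directory / manifest["liver"], "liver")
    lpts = [_read_mask(directory / e["file"], e["label"]) for e in manifest["lpts"]]
    tumors = [_read_mask(directory / e["file"], e["label"]) for e in manifest["tumors"]]
    return CompartmentSet.assemble(liver, lpts, tumors, warn_uncovered=False)


def write_report(obj, path) -> None:
    """Serialize a (possibly nested) report structure to JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
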