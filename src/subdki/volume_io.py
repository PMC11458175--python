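"""NIfTI readers/writers, dataset assembly and direction downsampling.

File conventions: 4-D diffusion volumes as NIfTI-1, FSL-style ``.bval`` /
``.bvec`` sidecars, and a CSV timing sidecar mapping every volume index to
its (Delta, delta) pair in milliseconds — bval/bvec carry no diffusion-time
information, so the sidecar is required for multi-diffusion-time data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .models import AcquisitionScheme, read_scheme, write_scheme

__all__ = [
    "DWIDataset",
    "DirectionSubset",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "downsample_directions",
]


@dataclass
class DWIDataset:
    """A diffusion-weighted acquisition: 4-D data plus its scheme and geometry."""

    data: np.ndarray                 # (x, y, z, volume)
    scheme: AcquisitionScheme
    affine: np.ndarray               # 4x4
    mask: np.ndarray | None = None   # (x, y, z) bool
    labels: np.ndarray | None = None  # (x, y, z) int region map

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, volume)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"{self.data.shape[3]} volumes vs {len(self.scheme)} scheme rows")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or not np.isfinite(
                np.linalg.det(self.affine)) or np.linalg.det(self.affine) == 0:
            raise ValueError("affine must be an invertible 4x4 matrix")
        grid = self.data.shape[:3]
        for name in ("mask", "labels"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != grid:
                raise ValueError(f"{name} grid does not match data grid")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)


def read_dwi(nifti_path, bval_path, bvec_path, timing_path,
             mask_path=None, labels_path=None) -> DWIDataset:
    """Load and cross-validate a DWI dataset from its file quartet."""
    img = nib.load(str(nifti_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4-D volume, got {data.ndim}-D")
    scheme = read_scheme(bval_path, bvec_path, timing_path)
    if len(scheme) != data.shape[3]:
        raise ValueError(
            f"volume count mismatch: image has {data.shape[3]} volumes, "
            f"sidecars describe {len(scheme)}")
    mask = labels = None
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if labels_path is not None:
        labels = np.asanyarray(nib.load(str(labels_path)).dataobj).astype(int)
    return DWIDataset(data=data, scheme=scheme, affine=img.affine,
                      mask=mask, labels=labels)


def write_dwi(ds: DWIDataset, stem: str | Path) -> dict:
    """Write ``<stem>.nii`` plus bval/bvec/timing sidecars; returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = write_scheme(ds.scheme, stem)
    img = nib.Nifti1Image(ds.data.astype(np.float32), ds.affine)
    nii = stem.with_suffix(".nii")
    nib.save(img, str(nii))
    paths["nifti"] = nii
    if ds.labels is not None:
        lab = stem.parent / (stem.name + "_labels.nii")
        nib.save(nib.Nifti1Image(ds.labels.astype(np.int16), ds.affine),
                 str(lab))
        paths["labels"] = lab
    if ds.mask is not None:
        mk = stem.parent / (stem.name + "_mask.nii")
        nib.save(nib.Nifti1Image(ds.mask.astype(np.uint8), ds.affine),
                 str(mk))
        paths["mask"] = mk
    return paths


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_maps(maps: dict[str, np.ndarray], affine, out_dir,
               config: dict | None = None) -> dict:
    """One NIfTI per metric map plus a provenance JSON.

    The provenance file records the package version, a hash of the supplied
    config, and per-map shapes, so a result directory is self-describing.
    Output bytes are deterministic for fixed inputs (uncompressed .nii).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.asarray(affine, dtype=float)
    paths = {}
    shapes = {}
    for name, arr in maps.items():
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise ValueError(f"map {name!r} must be 3-D, got shape {arr.shape}")
        if shapes and arr.shape != next(iter(shapes.values())):
            raise ValueError("all maps must share one grid")
        shapes[name] = arr.shape
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(p))
        paths[name] = p
    prov = {
        "package": "subdki",
        "version": __version__,
        "config_hash": _config_hash(config or {}),
        "config": config or {},
        "maps": {k: list(v) for k, v in shapes.items()},
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True,
                                    default=str))
    paths["provenance"] = prov_path
    return paths


@dataclass
class DirectionSubset:
    """Downsampling result for one shell: kept volumes and antipodal pairing."""

    shell_id: int
    kept_indices: list[int]          # volume indices into the scheme
    pairing: dict[int, int]          # volume index -> antipodal mate (-1 if none)


def _unique_axes(vecs: np.ndarray, tol: float = 1e-6):
    """Collapse a direction set into antipodal axes: (axis reps, mate map)."""
    n = vecs.shape[1]
    rep = [-1] * n
    mate = [-1] * n
    axes = []
    for i in range(n):
        if rep[i] >= 0:
            continue
        rep[i] = i
        for j in range(i + 1, n):
            if rep[j] < 0 and np.linalg.norm(vecs[:, j] + vecs[:, i]) < tol:
                rep[j] = i
                mate[i] = j
                mate[j] = i
                break
        axes.append(i)
    return axes, mate


def downsample_directions(scheme: AcquisitionScheme,
                          target: int) -> list[DirectionSubset]:
    """Greedy maximal-angular-spread selection of ``target`` axes per shell.

    Directions are first collapsed into antipodal axes; a deterministic
    greedy pass then keeps the ``target`` axes maximising the minimum
    pairwise angle (both polarities of a kept axis are retained, so the
    measurement count per shell is twice the target where mates exist).
    SNR bookkeeping consequence: halving the measurement count scales the
    powder-average noise SD by sqrt(2).
    """
    if scheme.bvecs is None:
        raise ValueError("scheme has no direction vectors")
    out = []
    ids = scheme.shell_ids()
    for sid in range(ids.max() + 1):
        rows = np.nonzero(ids == sid)[0]
        if scheme.is_b0[rows[0]]:
            continue
        vecs = scheme.bvecs[:, rows]
        norms = np.linalg.norm(vecs, axis=0)
        vecs = vecs / np.where(norms > 0, norms, 1.0)
        axes, mate = _unique_axes(vecs)
        if target > len(axes):
            raise ValueError(
                f"shell {sid}: requested {target} axes but only "
                f"{len(axes)} available")
        if target == len(axes):
            chosen = list(range(len(axes)))
        else:
            # start from the first axis; repeatedly add the axis with the
            # largest minimum angle to everything already chosen, breaking
            # ties by lowest index (deterministic)
            cosabs = np.abs(vecs[:, axes].T @ vecs[:, axes])
            np.clip(cosabs, 0.0, 1.0, out=cosabs)
            chosen = [0]
            while len(chosen) < target:
                remaining = [a for a in range(len(axes)) if a not in chosen]
                best, best_min = remaining[0], -1.0
                for a in remaining:
                    min_ang = np.min(np.arccos(cosabs[a, chosen]))
                    if min_ang > best_min + 1e-12:
                        best, best_min = a, min_ang
                chosen.append(best)
        kept = []
        pairing = {}
        for a in sorted(chosen):
            i = axes[a]
            vol_i = int(rows[i])
            kept.append(vol_i)
            if mate[i] >= 0:
                vol_j = int(rows[mate[i]])
                kept.append(vol_j)
                pairing[vol_i] = vol_j
                pairing[vol_j] = vol_i
            else:
                pairing[vol_i] = -1
        out.append(DirectionSubset(shell_id=int(sid),
                                   kept_indices=sorted(kept),
                                   pairing=pairing))
    return out
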