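"""Labelled voxel volumes and their on-disk representation.

A :class:`LabelVolume` is a 3-D integer array with isotropic spacing.  The
array is indexed ``[ix, iy, iz]``; the breast axis is +y (chest wall at
low y, nipple at high y) and "axial" slices are x-z planes.  World
coordinates are attached to voxel centers.

Label legend (breast phantoms): 0 air, 1 adipose, 2 skin, 3 glandular,
4 Cooper's-ligament membrane (connective tissue).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AIR, ADIPOSE, SKIN, GLANDULAR, LIGAMENT = 0, 1, 2, 3, 4

#: default mapping of breast labels to physics_data material names
BREAST_LEGEND = {
    ADIPOSE: "adipose",
    SKIN: "skin",
    GLANDULAR: "glandular",
    LIGAMENT: "connective",
}


@dataclass
class LabelVolume:
    """3-D integer label array with isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    legend: dict[int, str] = field(default_factory=lambda: dict(BREAST_LEGEND))

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + self.voxel_mm * np.arange(self.shape[axis])

    def center_mm(self) -> np.ndarray:
        return self.origin_mm + self.voxel_mm * (np.array(self.shape) - 1) / 2.0

    def label_counts(self) -> dict[int, int]:
        counts = np.bincount(self.data.ravel(), minlength=5)
        return {i: int(c) for i, c in enumerate(counts)}

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.voxel_mm,
                           self.origin_mm.copy(), dict(self.legend))

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path, nifti: bool = False) -> Path:
        """Write MetaImage (.mhd + .raw) or NIfTI plus a JSON label sidecar."""
        import SimpleITK as sitk

        path = Path(path)
        if nifti and "".join(path.suffixes) not in (".nii", ".nii.gz"):
            path = path.with_suffix(".nii.gz")
        elif not nifti:
            path = path.with_suffix(".mhd")
        img = sitk.GetImageFromArray(np.transpose(self.data, (2, 1, 0)))
        img.SetSpacing((self.voxel_mm,) * 3)
        img.SetOrigin(tuple(self.origin_mm))
        sitk.WriteImage(img, str(path))
        sidecar = path.parent / (path.name.split(".")[0] + ".labels.json")
        sidecar.write_text(json.dumps(
            {"legend": {str(k): v for k, v in self.legend.items()},
             "voxel_mm": self.voxel_mm}, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        import SimpleITK as sitk

        path = Path(path)
        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        legend = dict(BREAST_LEGEND)
        sidecar = path.parent / (path.name.split(".")[0] + ".labels.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            legend = {int(k): v for k, v in meta["legend"].items()}
        return cls(data, float(img.GetSpacing()[0]),
                   np.array(img.GetOrigin()), legend)
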