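"""Labelled image domains: segmented 2D/3D gut masks with physical spacing.

A :class:`LabelledDomain` is an integer raster (2D) or voxel (3D) array in
which 0 is background and each positive label is one region sub-domain of the
gut (e.g. the sigmoid colon's part of an anatomogram).  Physical coordinates
are cell-centre coordinates: world = index * spacing, in mm.

2D domains are stored as label PNGs with a JSON sidecar carrying spacing,
the label-to-region map, connectivity and any adjacency overrides (used for
anatomogram cut-domains that overlap in the drawing but are anatomically
adjacent).  3D domains are integer-label NIfTI volumes (spacing from the
header) with the same sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .jsonio import dump_json, load_json


class DomainError(ValueError):
    pass


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    full = {2: 8, 3: 26}[ndim]
    if connectivity == full:
        return np.ones((3,) * ndim, dtype=bool)
    if connectivity in (4, 6):
        return ndimage.generate_binary_structure(ndim, 1)
    raise DomainError(f"unsupported connectivity {connectivity} for {ndim}D")


@dataclass
class LabelledDomain:
    domain_id: str
    label_grid: np.ndarray
    spacing: tuple[float, ...]
    region_label_map: dict[int, str]
    connectivity: int | None = None  # 8 (2D) / 26 (3D) by default
    adjacency_overrides: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim not in (2, 3):
            raise DomainError("label_grid must be 2D or 3D")
        if len(self.spacing) != self.label_grid.ndim:
            raise DomainError("spacing length must match grid dimensionality")
        if self.connectivity is None:
            self.connectivity = {2: 8, 3: 26}[self.label_grid.ndim]

    @property
    def ndim(self) -> int:
        return self.label_grid.ndim

    @property
    def foreground(self) -> np.ndarray:
        return self.label_grid > 0

    @property
    def structure(self) -> np.ndarray:
        return _structure(self.ndim, self.connectivity)

    def region_of_index(self, idx) -> str:
        lab = int(self.label_grid[tuple(int(i) for i in idx)])
        if lab == 0:
            raise DomainError(f"index {tuple(idx)} is background")
        return self.region_label_map[lab]

    def world_to_index(self, point_mm) -> tuple[int, ...]:
        """Nearest grid cell for a physical point (cell centres at index*spacing)."""
        idx = np.round(np.asarray(point_mm, float) / np.asarray(self.spacing)).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.label_grid.shape):
            raise DomainError(f"point {tuple(point_mm)} mm lies outside the grid")
        return tuple(int(i) for i in idx)

    def validate(self) -> list[str]:
        errs: list[str] = []
        fg = self.foreground
        if not fg.any():
            errs.append("domain has empty foreground")
            return errs
        _, ncomp = ndimage.label(fg, structure=self.structure)
        if ncomp != 1:
            errs.append(
                f"foreground has {ncomp} connected components under "
                f"{self.connectivity}-connectivity (expected 1)"
            )
        labels = set(np.unique(self.label_grid)) - {0}
        mapped = set(self.region_label_map)
        if labels - mapped:
            errs.append(f"labels without a region mapping: {sorted(labels - mapped)}")
        if len(set(self.region_label_map.values())) != len(self.region_label_map):
            errs.append("region_label_map maps two labels to the same region id")
        return errs

    def check_valid(self) -> "LabelledDomain":
        errs = self.validate()
        if errs:
            raise DomainError("; ".join(errs))
        return self


# ---------------------------------------------------------------------------
# I/O


def _sidecar_dict(domain: LabelledDomain) -> dict:
    return {
        "domain_id": domain.domain_id,
        "spacing_mm": list(domain.spacing),
        "region_label_map": {str(k): v for k, v in domain.region_label_map.items()},
        "connectivity": domain.connectivity,
        "adjacency_overrides": [list(p) for p in domain.adjacency_overrides],
    }


def _from_sidecar(doc: dict, grid: np.ndarray, spacing=None) -> LabelledDomain:
    return LabelledDomain(
        domain_id=doc.get("domain_id", "domain"),
        label_grid=grid,
        spacing=tuple(spacing if spacing is not None else doc["spacing_mm"]),
        region_label_map={int(k): v for k, v in doc["region_label_map"].items()},
        connectivity=doc.get("connectivity"),
        adjacency_overrides=[tuple(p) for p in doc.get("adjacency_overrides", [])],
    )


def sidecar_path_for(image_path: str | Path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii", ".png"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def save_domain(domain: LabelledDomain, image_path: str | Path) -> None:
    """Write a label PNG (2D) or NIfTI (3D) plus its JSON sidecar."""
    image_path = Path(image_path)
    if domain.ndim == 2:
        from PIL import Image

        arr = domain.label_grid
        if arr.min() < 0 or arr.max() > 65535:
            raise DomainError("label values must fit a 16-bit PNG")
        Image.fromarray(arr.astype(np.uint16)).save(image_path)
    else:
        import nibabel as nib

        affine = np.diag(list(domain.spacing) + [1.0])
        img = nib.Nifti1Image(domain.label_grid.astype(np.int16), affine)
        img.header.set_zooms(domain.spacing)
        nib.save(img, str(image_path))
    dump_json(_sidecar_dict(domain), sidecar_path_for(image_path))


def load_domain(image_path: str | Path) -> LabelledDomain:
    image_path = Path(image_path)
    doc = load_json(sidecar_path_for(image_path))
    name = image_path.name
    if name.endswith(".png"):
        from PIL import Image

        grid = np.asarray(Image.open(image_path), dtype=np.int32)
        return _from_sidecar(doc, grid).check_valid()
    import nibabel as nib

    img = nib.load(str(image_path))
    grid = np.asarray(img.dataobj).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return _from_sidecar(doc, grid, spacing=spacing).check_valid()
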