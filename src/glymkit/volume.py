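"""In-memory carriers for 3-D scalar images and region label maps.

A :class:`Volume` is a plain scalar lattice plus its voxel geometry (per-axis
spacing in mm and a 4x4 voxel-to-world affine).  All pipeline stages assume
their inputs already live on a common grid; spatial registration is upstream
of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume", "LabelMap"]


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class Volume:
    """A 3-D scalar image with voxel geometry.

    Parameters
    ----------
    data
        3-D array of finite scalars (arbitrary units).
    spacing
        Per-axis voxel size in mm, strictly positive.
    affine
        4x4 voxel-index to world-mm map.  If omitted, a diagonal affine is
        built from ``spacing``.
    space_tag
        Free-text label for the coordinate space (e.g. ``"phantom-std"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume payload must be 3-D, got {self.data.ndim}-D")
        if 0 in self.data.shape:
            raise ValueError(f"Volume has a zero-length axis: shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
                raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new payload (must keep the grid shape)."""
        if np.asarray(data).shape != self.data.shape:
            raise ValueError("with_data requires an identically shaped payload")
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


# Canonical region legend shared by the phantom generators and the ePVS /
# ALPS pipelines.  Any nonzero label present in a LabelMap must be covered
# by its legend.
DEFAULT_LEGEND = {0: "background", 1: "WM", 2: "GM", 3: "BG", 4: "CSF"}


@dataclass
class LabelMap:
    """Integer region labels on the same grid as a companion :class:`Volume`."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("LabelMap payload must be integer-valued")
            self.labels = lab.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover labels {sorted(missing)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of every label whose legend entry equals ``name``."""
        ids = [k for k, v in self.legend.items() if v == name]
        if not ids:
            raise KeyError(f"region {name!r} not in legend {self.legend}")
        return np.isin(self.labels, ids)
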