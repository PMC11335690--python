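"""DTI-ALPS: ROI placement and index computation.

The ALPS (Analysis aLong the Perivascular Space) index samples diffusivity
along the medullary-vein axis (X, left-right) in two white-matter systems at
the level of the lateral-ventricle body: the projection fibers (principal
axis Z, inferior-superior) and the association fibers (principal axis Y,
anterior-posterior).  With bilateral square ROIs in each system,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where each term is first averaged over the left and right ROIs.  An
isotropic medium gives ALPS = 1 for any ROI placement; values well above 1
indicate preserved diffusion along the perivascular axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume

__all__ = ["AlpsRoiSet", "AlpsResult", "make_alps_rois", "compute_alps_index"]

ROI_NAMES = ("projection_left", "projection_right", "association_left", "association_right")


@dataclass
class AlpsRoiSet:
    """Four axial square ROIs: bilateral projection- and association-fiber sites."""

    masks: dict[str, np.ndarray]
    area_mm2: float
    slab_slices: int
    centers_vox: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ROI_NAMES) - set(self.masks)
        if missing:
            raise ValueError(f"missing ROIs: {sorted(missing)}")
        sizes = {k: int(m.sum()) for k, m in self.masks.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(f"ROI voxel counts differ: {sizes}")
        stacked = np.stack([self.masks[k] for k in ROI_NAMES]).astype(int)
        if stacked.sum(axis=0).max() > 1:
            raise ValueError("ROIs overlap")


def make_alps_rois(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centers: dict[str, tuple[float, float, float]],
    area_mm2: float = 16.0,
    slab_slices: int = 1,
) -> AlpsRoiSet:
    """Build four axial square ROIs of ``area_mm2`` (default 16 mm^2).

    ``centers`` maps each ROI name to world-mm coordinates (diagonal
    phantom-space affine assumed: world = index * spacing).  The square side
    is rounded to the nearest achievable multiple of the in-plane spacing;
    left/right pairs are mirrored about the mid-sagittal (X) plane by
    construction of their centers.  A center outside the grid is an error.
    """
    side_mm = float(np.sqrt(area_mm2))
    masks: dict[str, np.ndarray] = {}
    centers_vox: dict[str, tuple[int, int, int]] = {}
    for name in ROI_NAMES:
        if name not in centers:
            raise ValueError(f"no center given for ROI {name!r}")
        cw = np.asarray(centers[name], dtype=float)
        cv = cw / np.asarray(spacing)
        if np.any(cv < 0) or np.any(cv >= np.asarray(shape)):
            raise ValueError(f"ROI {name!r} center {tuple(cw)} falls outside the grid")
        nx = max(1, int(round(side_mm / spacing[0])))
        ny = max(1, int(round(side_mm / spacing[1])))
        ci = np.floor(cv).astype(int)
        x0 = int(np.clip(ci[0] - nx // 2, 0, shape[0] - nx))
        y0 = int(np.clip(ci[1] - ny // 2, 0, shape[1] - ny))
        z0 = int(np.clip(ci[2] - slab_slices // 2, 0, shape[2] - slab_slices))
        m = np.zeros(shape, dtype=bool)
        m[x0 : x0 + nx, y0 : y0 + ny, z0 : z0 + slab_slices] = True
        masks[name] = m
        centers_vox[name] = (int(ci[0]), int(ci[1]), int(ci[2]))
    return AlpsRoiSet(masks=masks, area_mm2=area_mm2, slab_slices=slab_slices, centers_vox=centers_vox)


@dataclass
class AlpsResult:
    """Bilateral ROI means of Dxx/Dyy/Dzz and the ALPS index they imply."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    alps_index: float
    roi_means: dict[str, dict[str, float]]
    fit_method: str = ""

    def recompute_index(self) -> float:
        num = 0.5 * (self.dxx_proj + self.dxx_assoc)
        den = 0.5 * (self.dyy_proj + self.dzz_assoc)
        return num / den


def _roi_mean(vol: Volume, mask: np.ndarray, fit_mask: np.ndarray | None) -> float:
    m = mask if fit_mask is None else (mask & fit_mask)
    if not m.any():
        raise ValueError("ROI does not intersect the fitted mask")
    return float(vol.data[m].mean())


def compute_alps_index(
    dxx: Volume,
    dyy: Volume,
    dzz: Volume,
    rois: AlpsRoiSet,
    fit_mask: np.ndarray | None = None,
    fit_method: str = "",
    per_side_ratio: bool = False,
) -> AlpsResult:
    """ALPS index from diffusivity maps and a four-ROI set.

    Default behaviour averages each term over the left and right ROIs before
    forming the single ratio (average-then-ratio).  ``per_side_ratio=True``
    instead forms the ratio per hemisphere and averages the two ratios; the
    two conventions agree exactly for left-right symmetric fields.
    """
    means: dict[str, dict[str, float]] = {}
    for name, m in rois.masks.items():
        means[name] = {
            "dxx": _roi_mean(dxx, m, fit_mask),
            "dyy": _roi_mean(dyy, m, fit_mask),
            "dzz": _roi_mean(dzz, m, fit_mask),
        }
    if per_side_ratio:
        ratios = []
        for side in ("left", "right"):
            num = 0.5 * (means[f"projection_{side}"]["dxx"] + means[f"association_{side}"]["dxx"])
            den = 0.5 * (means[f"projection_{side}"]["dyy"] + means[f"association_{side}"]["dzz"])
            if den <= 0:
                raise ValueError(f"non-positive ALPS denominator on {side} side")
            ratios.append(num / den)
        alps = float(np.mean(ratios))
        dxx_proj = 0.5 * (means["projection_left"]["dxx"] + means["projection_right"]["dxx"])
        dxx_assoc = 0.5 * (means["association_left"]["dxx"] + means["association_right"]["dxx"])
        dyy_proj = 0.5 * (means["projection_left"]["dyy"] + means["projection_right"]["dyy"])
        dzz_assoc = 0.5 * (means["association_left"]["dzz"] + means["association_right"]["dzz"])
    else:
        dxx_proj = 0.5 * (means["projection_left"]["dxx"] + means["projection_right"]["dxx"])
        dxx_assoc = 0.5 * (means["association_left"]["dxx"] + means["association_right"]["dxx"])
        dyy_proj = 0.5 * (means["projection_left"]["dyy"] + means["projection_right"]["dyy"])
        dzz_assoc = 0.5 * (means["association_left"]["dzz"] + means["association_right"]["dzz"])
        den = 0.5 * (dyy_proj + dzz_assoc)
        if den <= 0:
            raise ValueError("non-positive ALPS denominator")
        alps = 0.5 * (dxx_proj + dxx_assoc) / den
    return AlpsResult(
        dxx_proj=dxx_proj,
        dxx_assoc=dxx_assoc,
        dyy_proj=dyy_proj,
        dzz_assoc=dzz_assoc,
        alps_index=float(alps),
        roi_means=means,
        fit_method=fit_method,
    )
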