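"""Enlarged-perivascular-space (ePVS) segmentation and burden.

Pipeline (all stages on a common working grid, default 0.7 mm isotropic):

1. intensity-normalize T1w and T2w to the white-matter signal;
2. form the enhanced perivascular contrast (EPC) image as the T1w/T2w
   ratio — PVS voxels (dark T1w, bright T2w) have strictly lower EPC than
   surrounding white matter;
3. multiscale Frangi vesselness of the EPC image with dark-tube polarity;
4. threshold at ``h``, 26-connected components, drop clusters smaller than
   ``min_cluster_voxels`` (default 9 voxels, ~3 mm^3 at 0.7 mm);
5. burden = 100 % x (ePVS voxels in region) / (region voxels).

Absolute vesselness scale is implementation-dependent, so besides fixed-``h``
defaults the module ships a quantile threshold mode and a calibration
routine that fits ``h`` on a noise-free phantom with known burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import RunManifest
from .io import resample_labels, resample_volume
from .volume import LabelMap, Volume

logger = logging.getLogger("glymkit")

__all__ = [
    "EpcParams",
    "FrangiParams",
    "SegmentationParams",
    "EpvsResult",
    "normalize_intensity",
    "compute_epc",
    "frangi_vesselness",
    "fit_structureness_c",
    "region_fill",
    "region_vesselness",
    "segment_epvs",
    "compute_burden",
    "calibrate_threshold",
    "run_epvs",
]


@dataclass
class EpcParams:
    epsilon: float = 1e-6  # guard for the T1w/T2w division
    normalization_stat: str = "median"  # median | mean over the WM mask

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.normalization_stat not in ("median", "mean"):
            raise ValueError("normalization_stat must be median|mean")


@dataclass
class FrangiParams:
    """Multiscale Hessian vesselness settings (scales in mm)."""

    scales_mm: tuple[float, ...] = (0.35, 0.7, 1.05)
    alpha: float = 0.5  # plate vs line discrimination
    beta: float = 0.5  # blob discrimination
    c: float | str = "auto"  # structureness; auto = half max Frobenius norm
    polarity: str = "dark_tubes"  # dark_tubes | bright_tubes
    strict_isotropic: bool = True

    def __post_init__(self) -> None:
        if not self.scales_mm or any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive")
        if list(self.scales_mm) != sorted(self.scales_mm):
            raise ValueError("scales must be sorted ascending")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.polarity not in ("dark_tubes", "bright_tubes"):
            raise ValueError("polarity must be dark_tubes|bright_tubes")


@dataclass
class SegmentationParams:
    h: float = 2e-7  # vesselness threshold (white matter default)
    min_cluster_voxels: int = 9  # ~3 mm^3 at the 0.7 mm working grid
    connectivity: int = 26  # 6 | 18 | 26
    working_spacing_mm: float = 0.7
    threshold_mode: str = "absolute"  # absolute | quantile (h = upper quantile)
    # optional guard: restrict detection to the region eroded by this many
    # voxels (burden stays normalized by the FULL region volume); the
    # pipeline's region-conditioned filtering makes 0 a safe default
    erode_voxels: int = 0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.threshold_mode not in ("absolute", "quantile"):
            raise ValueError("threshold_mode must be absolute|quantile")


# Basal-ganglia default threshold is slightly higher than the white-matter one.
WM_SEGMENTATION_DEFAULTS = SegmentationParams(h=2e-7)
BG_SEGMENTATION_DEFAULTS = SegmentationParams(h=3e-7)


@dataclass
class EpvsResult:
    mask: np.ndarray
    cluster_labels: np.ndarray
    cluster_sizes: np.ndarray
    burden_pct: float
    region: str
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_clusters = int(self.cluster_sizes.size)
        if not (0.0 <= self.burden_pct <= 100.0):
            raise ValueError(f"burden out of range: {self.burden_pct}")


def normalize_intensity(v: Volume, wm_mask: np.ndarray, stat: str = "median") -> Volume:
    """Divide the image by its white-matter median (or mean).

    The WM statistic of the output is 1 by construction; the median is the
    default because PVS inclusions inside the mask barely move it.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    ref = float(np.median(v.data[wm_mask]) if stat == "median" else v.data[wm_mask].mean())
    if ref <= 0:
        raise ValueError(f"non-positive WM reference statistic ({ref})")
    return v.with_data(v.data / ref)


def compute_epc(t1w_norm: Volume, t2w_norm: Volume, p: EpcParams | None = None) -> Volume:
    """Enhanced perivascular contrast: T1w / max(T2w, epsilon).

    On WM-normalized inputs, WM sits near 1 while PVS voxels (low T1w, high
    T2w) drop well below it, which is what the dark-tube vesselness filter
    keys on.
    """
    p = p or EpcParams()
    if not t1w_norm.same_grid(t2w_norm):
        raise ValueError("T1w and T2w are not on the same grid")
    epc = t1w_norm.data / np.maximum(t2w_norm.data, p.epsilon)
    return t1w_norm.with_data(epc)


def _hessian_scale(img: np.ndarray, sigma_vox: float, sigma_mm: float, spacing: float) -> np.ndarray:
    """sigma^2-normalized Hessian (mm units) at one Gaussian scale; (..., 3, 3)."""
    H = np.empty(img.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = ndimage.gaussian_filter(img, sigma=sigma_vox, order=order, mode="nearest")
            d = d / spacing**2  # voxel-index derivatives -> per-mm^2
            H[..., i, j] = d
            H[..., j, i] = d
    return H * sigma_mm**2  # gamma = 2 scale normalization


def frangi_vesselness(v: Volume, p: FrangiParams | None = None,
                      region_mask: np.ndarray | None = None) -> Volume:
    """Multiscale Frangi tubularity of a 3-D image.

    At each scale, with Hessian eigenvalues ordered |l1| <= |l2| <= |l3|,

        V = (1 - exp(-Ra^2 / 2 a^2)) * exp(-Rb^2 / 2 b^2) * (1 - exp(-S^2 / 2 c^2))

    with Ra = |l2|/|l3| (plate suppression), Rb = |l1|/sqrt(|l2 l3|) (blob
    suppression) and S the Hessian Frobenius norm; V = 0 wherever the
    polarity condition (l2, l3 > 0 for dark tubes) fails, and the output is
    the maximum over scales.  ``c="auto"`` uses half the maximum S over the
    region (or whole image) per scale; a scalar or per-scale sequence fixes
    it — vesselness values (and thresholds) are only comparable across
    images with a fixed c, see :func:`fit_structureness_c`.
    """
    p = p or FrangiParams()
    sp = v.spacing
    if p.strict_isotropic and (max(sp) - min(sp)) > 1e-6 * max(sp):
        raise ValueError(
            f"anisotropic spacing {sp}: resample to an isotropic grid first "
            "(or set strict_isotropic=False)"
        )
    spacing = float(sp[0])
    img = np.asarray(v.data, dtype=float)
    if p.polarity == "dark_tubes":
        img = -img  # dark ridges become bright ridges
    out = np.zeros(img.shape)
    for k, sigma_mm in enumerate(p.scales_mm):
        sigma_vox = sigma_mm / spacing
        H = _hessian_scale(img, sigma_vox, sigma_mm, spacing)
        evals = np.linalg.eigvalsh(H)
        order = np.argsort(np.abs(evals), axis=-1)
        evals = np.take_along_axis(evals, order, axis=-1)
        l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]
        # bright-ridge condition on the (possibly negated) image
        valid = (l2 < 0) & (l3 < 0)
        a2 = np.abs(l2)
        a3 = np.abs(l3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ra2 = np.where(a3 > 0, (a2 / a3) ** 2, 0.0)
            rb2 = np.where(a2 * a3 > 0, np.abs(l1) ** 2 / (a2 * a3), 0.0)
        s2 = (evals**2).sum(axis=-1)
        if isinstance(p.c, str) and p.c == "auto":
            ref = s2[region_mask] if region_mask is not None else s2
            smax = float(np.sqrt(ref.max())) if ref.size else 0.0
            c = 0.5 * smax if smax > 0 else 1.0
        elif isinstance(p.c, (tuple, list, np.ndarray)):
            c = float(p.c[k])
        else:
            c = float(p.c)
        vness = (
            (1.0 - np.exp(-ra2 / (2.0 * p.alpha**2)))
            * np.exp(-rb2 / (2.0 * p.beta**2))
            * (1.0 - np.exp(-s2 / (2.0 * c**2)))
        )
        vness = np.where(valid, vness, 0.0)
        out = np.maximum(out, vness)
    return v.with_data(out)


def fit_structureness_c(
    v: Volume, p: FrangiParams | None = None, region_mask: np.ndarray | None = None
) -> tuple[float, ...]:
    """Per-scale ``c`` values (half the max Hessian Frobenius norm) for an
    image, to be frozen into :class:`FrangiParams` when vesselness values or
    thresholds must be comparable across images (e.g. calibration on one
    phantom, application on another)."""
    p = p or FrangiParams()
    spacing = float(v.spacing[0])
    img = np.asarray(v.data, dtype=float)
    if p.polarity == "dark_tubes":
        img = -img
    out = []
    for sigma_mm in p.scales_mm:
        H = _hessian_scale(img, sigma_mm / spacing, sigma_mm, spacing)
        s2 = (H**2).sum(axis=(-2, -1))
        ref = s2[region_mask] if region_mask is not None else s2
        smax = float(np.sqrt(ref.max())) if ref.size else 0.0
        out.append(0.5 * smax if smax > 0 else 1.0)
    return tuple(out)


def region_vesselness(
    epc: Volume, region_mask: np.ndarray, p: FrangiParams | None = None
) -> Volume:
    """Region-conditioned vesselness: voxels outside the region are replaced
    by the region's median intensity before filtering.

    Tissue-boundary edges are themselves ridge-like and would otherwise fire
    the tubularity filter throughout a neighbourhood the size of the Gaussian
    support; conditioning on the region removes that contrast at the source
    while tubes near the boundary keep their own (internal) contrast.
    """
    conditioned = region_fill(epc, region_mask)
    return frangi_vesselness(conditioned, p, region_mask=np.asarray(region_mask, bool))


def region_fill(epc: Volume, region_mask: np.ndarray, pv_guard_voxels: int = 2) -> Volume:
    """Replace voxels outside the region *core* by the core's median intensity.

    The core is the region eroded by ``pv_guard_voxels`` (L-inf), which
    strips the partial-volume ring that resampling blends across tissue
    boundaries; without this the ring itself carries boundary contrast into
    the filter.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    core = region_mask
    if pv_guard_voxels > 0:
        core = ndimage.binary_erosion(
            region_mask,
            structure=ndimage.generate_binary_structure(3, 3),
            iterations=pv_guard_voxels,
            border_value=1,
        )
        if not core.any():
            raise ValueError("region core empty after partial-volume guard")
    fill = float(np.median(epc.data[core]))
    return epc.with_data(np.where(core, epc.data, fill))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def segment_epvs(
    vesselness: Volume,
    region_mask: np.ndarray,
    p: SegmentationParams | None = None,
    region: str = "WM",
) -> EpvsResult:
    """Threshold + connected-component segmentation inside a region mask.

    Voxels with vesselness >= h (inside the region) are grouped at the
    requested connectivity; components smaller than ``min_cluster_voxels``
    are removed.  In quantile mode ``h`` is interpreted as the upper-tail
    fraction of region voxels to keep (e.g. 0.005 keeps the top 0.5 %).
    """
    p = p or SegmentationParams()
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    if p.erode_voxels > 0:
        # L-inf erosion matches the box support of the separable Gaussian
        detect = ndimage.binary_erosion(
            region_mask,
            structure=ndimage.generate_binary_structure(3, 3),
            iterations=p.erode_voxels,
            border_value=1,
        )
        if not detect.any():
            raise ValueError("region mask is empty after boundary erosion")
    else:
        detect = region_mask
    vmap = np.asarray(vesselness.data)
    if p.threshold_mode == "quantile":
        h = float(np.quantile(vmap[detect], 1.0 - p.h))
    else:
        h = p.h
    supra = (vmap >= h) & detect
    labels, n = ndimage.label(supra, structure=_connectivity_structure(p.connectivity))
    if n == 0:
        return EpvsResult(
            mask=np.zeros_like(region_mask),
            cluster_labels=labels,
            cluster_sizes=np.array([], dtype=int),
            burden_pct=0.0,
            region=region,
        )
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.where(sizes >= p.min_cluster_voxels)[0] + 1
    mask = np.isin(labels, keep)
    # relabel retained clusters 1..K for a dense labeling
    out_labels, k = ndimage.label(mask, structure=_connectivity_structure(p.connectivity))
    kept_sizes = np.bincount(out_labels.ravel())[1:] if k else np.array([], dtype=int)
    burden = compute_burden(mask, region_mask)
    return EpvsResult(
        mask=mask,
        cluster_labels=out_labels,
        cluster_sizes=np.sort(kept_sizes)[::-1],
        burden_pct=burden,
        region=region,
    )


def compute_burden(epvs_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Region-normalized burden: 100 x |mask ∩ region| / |region| (voxel
    volume cancels, so the ratio is grid-independent)."""
    region_mask = np.asarray(region_mask, dtype=bool)
    epvs_mask = np.asarray(epvs_mask, dtype=bool)
    if epvs_mask.shape != region_mask.shape:
        raise ValueError("masks are not on the same grid")
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError("region mask is empty")
    return 100.0 * float((epvs_mask & region_mask).sum()) / n_region


def calibrate_threshold(
    vesselness: Volume,
    region_mask: np.ndarray,
    target_burden_pct: float,
    p: SegmentationParams | None = None,
    n_iter: int = 40,
) -> float:
    """Fit the absolute threshold ``h`` so the segmented burden matches a
    known target (e.g. a noise-free phantom's true burden), by bisection.

    Burden is monotone non-increasing in ``h``; the returned ``h`` is the
    bisection midpoint after ``n_iter`` halvings.
    """
    p = p or SegmentationParams()
    region_mask = np.asarray(region_mask, dtype=bool)
    if target_burden_pct <= 0:
        raise ValueError("target burden must be > 0 for calibration")
    lo, hi = 0.0, float(np.asarray(vesselness.data)[region_mask].max())
    if hi <= 0:
        raise ValueError("vesselness is zero everywhere in the region")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        q = SegmentationParams(
            h=mid,
            min_cluster_voxels=p.min_cluster_voxels,
            connectivity=p.connectivity,
            working_spacing_mm=p.working_spacing_mm,
            erode_voxels=p.erode_voxels,
        )
        b = segment_epvs(vesselness, region_mask, q).burden_pct
        if b > target_burden_pct:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def run_epvs(
    t1w: Volume,
    t2w: Volume,
    labels: LabelMap,
    wm_params: SegmentationParams | None = None,
    bg_params: SegmentationParams | None = None,
    epc_params: EpcParams | None = None,
    frangi_params: FrangiParams | None = None,
    manifest: RunManifest | None = None,
) -> dict[str, EpvsResult]:
    """End-to-end ePVS pipeline for the WM and BG regions.

    resample (0.7 mm) -> WM normalization -> EPC -> Frangi -> per-region
    threshold/cluster segmentation -> burden.
    """
    wm_params = wm_params or SegmentationParams(h=WM_SEGMENTATION_DEFAULTS.h)
    bg_params = bg_params or SegmentationParams(h=BG_SEGMENTATION_DEFAULTS.h)
    epc_params = epc_params or EpcParams()
    frangi_params = frangi_params or FrangiParams()
    if manifest is None:
        manifest = RunManifest()
    if not t1w.same_grid(t2w):
        raise ValueError("T1w and T2w are not co-registered on a common grid")

    ws = wm_params.working_spacing_mm
    target = (ws, ws, ws)
    t1r = resample_volume(t1w, target, mode="linear")
    t2r = resample_volume(t2w, target, mode="linear")
    labr = resample_labels(labels, target)
    manifest.log_stage(
        "resample", {"target_spacing_mm": ws}, {"t1w": t1w.data, "t2w": t2w.data}
    )

    wm_mask = labr.region_mask("WM")
    t1n = normalize_intensity(t1r, wm_mask, epc_params.normalization_stat)
    t2n = normalize_intensity(t2r, wm_mask, epc_params.normalization_stat)
    epc = compute_epc(t1n, t2n, epc_params)
    manifest.log_stage("epc", vars(epc_params), {"epc": epc.data})

    results: dict[str, EpvsResult] = {}
    for region, params in (("WM", wm_params), ("BG", bg_params)):
        rmask = labr.region_mask(region)
        vness = region_vesselness(epc, rmask, frangi_params)
        res = segment_epvs(vness, rmask, params, region=region)
        manifest.log_stage(
            f"segment_{region.lower()}",
            vars(params),
            {"vesselness": vness.data},
        )
        results[region] = res
    return results
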