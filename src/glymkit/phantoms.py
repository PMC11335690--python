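"""Synthetic MRI phantoms with analytic ground truth.

Two families:

* **Structural phantoms** — co-registered T1w/T2w volumes over a blocky
  tissue layout (WM, GM, BG, CSF) containing straight cylindrical
  perivascular-space inclusions rendered CSF-like (dark on T1w, bright on
  T2w) with partial volume via 3x supersampling.  The true per-region PVS
  burden is computed from the supersampled analytic volume, so segmentation
  accuracy can be scored exactly.

* **DWI phantoms** — 4-D diffusion series generated from per-region
  diffusion (and optional kurtosis) tensors through the exact forward model
  of :mod:`glymkit.dki`, optionally corrupted with Rician or Gaussian noise.
  :func:`make_alps_tensor_field` lays out bilateral projection (Z-principal)
  and association (Y-principal) fiber blocks with a known analytic ALPS
  index and matching ROI centers.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dki import TensorField, signal_forward_model
from .io import GradientTable
from .volume import DEFAULT_LEGEND, LabelMap, Volume

__all__ = [
    "StructuralPhantomSpec",
    "StructuralPhantom",
    "make_structural_phantom",
    "DwiPhantomSpec",
    "make_dwi_phantom",
    "make_alps_tensor_field",
    "default_gradient_table",
    "diag_tensor",
    "isotropic_kurtosis",
]

# (T1w, T2w) tissue intensities, arbitrary units.  PVS inclusions take the
# CSF intensity pair, giving the dark-T1w / bright-T2w tube appearance.
DEFAULT_TISSUE_TABLE = {
    "WM": (1.00, 0.45),
    "GM": (0.70, 0.70),
    "BG": (0.78, 0.62),
    "CSF": (0.15, 1.00),
    "background": (0.0, 0.0),
}

LABEL_IDS = {v: k for k, v in DEFAULT_LEGEND.items()}


# ---------------------------------------------------------------------------
# structural phantom


@dataclass
class StructuralPhantomSpec:
    """Geometry, contrast and PVS content of a structural phantom."""

    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: float = 1.0  # mm, isotropic (structural protocol: 1 mm^3)
    tissue_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TABLE)
    )
    pvs_count: dict[str, int] = field(default_factory=lambda: {"WM": 12, "BG": 3})
    pvs_radius_mm: tuple[float, float] = (0.4, 0.8)
    pvs_length_mm: tuple[float, float] = (3.0, 8.0)
    orientation: str = "isotropic"  # or "z" for axis-aligned tubes
    noise_sigma: tuple[float, float] = (0.02, 0.02)  # (T1w, T2w)
    supersample: int = 6  # subvoxel grid per axis; 6 keeps cylinder-volume
    # discretization error under ~2% for mm-scale radii
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pvs_radius_mm[0] <= 0 or self.pvs_length_mm[0] <= 0:
            raise ValueError("PVS radii and lengths must be positive")
        if any(n < 0 for n in self.pvs_count.values()):
            raise ValueError("pvs_count must be >= 0")
        if any(s < 0 for s in self.noise_sigma):
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class StructuralPhantom:
    t1w: Volume
    t2w: Volume
    labels: LabelMap
    pvs_truth: np.ndarray  # binary (any analytic occupancy)
    pvs_fraction: np.ndarray  # supersampled occupancy in [0, 1]
    true_burden: dict[str, float]  # percent per region
    cylinders: list[dict] = field(default_factory=list)


def _default_label_layout(shape: tuple[int, int, int]) -> np.ndarray:
    """Nested-box tissue layout: GM shell > WM block > BG and CSF blocks."""
    nx, ny, nz = shape
    lab = np.zeros(shape, dtype=np.int16)

    def box(f0, f1):
        return tuple(
            slice(int(round(f0 * n)), int(round(f1 * n))) for n in (nx, ny, nz)
        )

    lab[box(0.05, 0.95)] = LABEL_IDS["GM"]
    lab[box(0.15, 0.85)] = LABEL_IDS["WM"]
    # basal ganglia: a block in the lower-central WM, sized so a usable
    # interior remains inside the segmentation's boundary guard
    lab[
        slice(int(0.25 * nx), int(0.62 * nx)),
        slice(int(0.25 * ny), int(0.62 * ny)),
        slice(int(0.20 * nz), int(0.55 * nz)),
    ] = LABEL_IDS["BG"]
    # ventricle-like CSF block, above the BG block
    lab[
        slice(int(0.44 * nx), int(0.56 * nx)),
        slice(int(0.44 * ny), int(0.56 * ny)),
        slice(int(0.60 * nz), int(0.78 * nz)),
    ] = LABEL_IDS["CSF"]
    return lab


def _sample_cylinder(rng, region_idx, spec, region_mask):
    """Draw one cylinder (center mm, axis, radius, length) inside a region."""
    shape = np.asarray(spec.shape)
    sp = spec.spacing
    for _ in range(200):
        k = rng.integers(0, region_idx.shape[0])
        center = (region_idx[k] + 0.5) * sp  # mm
        if spec.orientation == "z":
            axis = np.array([0.0, 0.0, 1.0])
        else:
            v = rng.normal(size=3)
            axis = v / np.linalg.norm(v)
        radius = rng.uniform(*spec.pvs_radius_mm)
        length = rng.uniform(*spec.pvs_length_mm)
        # accept if both end caps (plus radius margin) stay inside the region
        ok = True
        for t in (-0.5, -0.25, 0.0, 0.25, 0.5):
            p = center + t * length * axis
            iv = np.floor(p / sp).astype(int)
            if np.any(iv < 0) or np.any(iv >= shape) or not region_mask[tuple(iv)]:
                ok = False
                break
        if ok:
            return {"center": center, "axis": axis, "radius": radius, "length": length}
    raise RuntimeError(
        "could not place a PVS tube after 200 attempts (region too small "
        "for the requested radius/length range)"
    )


def _render_cylinders(cylinders, shape, spacing, ss) -> np.ndarray:
    """Fractional voxel occupancy of the union of cylinders, via ss^3 subsampling."""
    frac = np.zeros(shape)
    offs = (np.arange(ss) + 0.5) / ss  # subvoxel centers in voxel units
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    for cyl in cylinders:
        c, u, r, L = cyl["center"], cyl["axis"], cyl["radius"], cyl["length"]
        half = L / 2.0
        pad = r + half  # bounding box half-extent along each axis (loose)
        lo = np.maximum(np.floor((c - pad) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + pad) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ix = np.arange(lo[0], hi[0])
        iy = np.arange(lo[1], hi[1])
        iz = np.arange(lo[2], hi[2])
        vox = np.stack(np.meshgrid(ix, iy, iz, indexing="ij"), axis=-1).reshape(-1, 3)
        # (Nvox, ss^3, 3) subvoxel centers in mm
        pts = (vox[:, None, :] + sub[None, :, :]) * spacing
        d = pts - c
        t = d @ u
        rad2 = (d**2).sum(-1) - t**2
        inside = (np.abs(t) <= half) & (rad2 <= r**2)
        f = inside.mean(axis=1).reshape(len(ix), len(iy), len(iz))
        # union of tubes: occupancy saturates at 1
        frac[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = np.maximum(
            frac[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]], f
        )
    return frac


def make_structural_phantom(spec: StructuralPhantomSpec) -> StructuralPhantom:
    """Generate a T1w/T2w phantom with known PVS content.

    Deterministic given ``spec.seed``.  ``true_burden`` is the supersampled
    analytic PVS volume fraction per region, in percent, recorded before
    noise is applied.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _default_label_layout(spec.shape)
    cylinders: list[dict] = []
    region_of: list[str] = []
    for region in ("WM", "BG"):
        n = spec.pvs_count.get(region, 0)
        if n == 0:
            continue
        mask = labels == LABEL_IDS[region]
        idx = np.argwhere(mask)
        if idx.size == 0:
            raise RuntimeError(f"region {region} empty in layout")
        for _ in range(n):
            cylinders.append(_sample_cylinder(rng, idx, spec, mask))
            region_of.append(region)

    frac = _render_cylinders(cylinders, spec.shape, spec.spacing, spec.supersample)
    # PVS only counts inside WM or BG support
    support = (labels == LABEL_IDS["WM"]) | (labels == LABEL_IDS["BG"])
    frac = np.where(support, frac, 0.0)

    true_burden = {}
    for region in ("WM", "BG"):
        rmask = labels == LABEL_IDS[region]
        true_burden[region] = float(100.0 * frac[rmask].sum() / rmask.sum())

    t1 = np.zeros(spec.shape)
    t2 = np.zeros(spec.shape)
    legend_names = {k: v for k, v in DEFAULT_LEGEND.items()}
    for lab_id, name in legend_names.items():
        i1, i2 = spec.tissue_table[name]
        m = labels == lab_id
        t1[m] = i1
        t2[m] = i2
    csf1, csf2 = spec.tissue_table["CSF"]
    t1 = (1.0 - frac) * t1 + frac * csf1
    t2 = (1.0 - frac) * t2 + frac * csf2
    if spec.noise_sigma[0] > 0:
        t1 = t1 + rng.normal(0.0, spec.noise_sigma[0], size=spec.shape)
    if spec.noise_sigma[1] > 0:
        t2 = t2 + rng.normal(0.0, spec.noise_sigma[1], size=spec.shape)

    sp3 = (spec.spacing,) * 3
    return StructuralPhantom(
        t1w=Volume(t1, spacing=sp3, space_tag="phantom-std"),
        t2w=Volume(t2, spacing=sp3, space_tag="phantom-std"),
        labels=LabelMap(labels, spacing=sp3),
        pvs_truth=frac > 0,
        pvs_fraction=frac,
        true_burden=true_burden,
        cylinders=cylinders,
    )


# ---------------------------------------------------------------------------
# diffusion phantom


def diag_tensor(dx: float, dy: float, dz: float) -> np.ndarray:
    """Diagonal diffusion tensor (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s."""
    return np.array([dx, dy, dz, 0.0, 0.0, 0.0])


def isotropic_kurtosis(K: float) -> np.ndarray:
    """Fully isotropic kurtosis tensor with directional kurtosis K on every axis."""
    w = np.zeros(15)
    w[0] = w[1] = w[2] = K
    w[9] = w[10] = w[11] = K / 3.0
    return w


def _check_spd(d6: np.ndarray, where: str) -> None:
    m = np.array(
        [
            [d6[0], d6[3], d6[4]],
            [d6[3], d6[1], d6[5]],
            [d6[4], d6[5], d6[2]],
        ]
    )
    if np.linalg.eigvalsh(m).min() <= 0:
        raise ValueError(f"diffusion tensor for {where} is not positive-definite")


def _fibonacci_sphere(n: int, offset: int = 0) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (Fibonacci spiral)."""
    i = np.arange(n) + 0.5 + offset
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (np.arange(n) + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def default_gradient_table() -> GradientTable:
    """The two-shell acquisition emulated by the phantoms: 2 x b=0, 45
    directions at b=1000 s/mm^2 and 90 at b=2500 s/mm^2."""
    bvals = np.concatenate([[0.0, 0.0], np.full(45, 1000.0), np.full(90, 2500.0)])
    bvecs = np.concatenate(
        [np.zeros((2, 3)), _fibonacci_sphere(45), _fibonacci_sphere(90, offset=17)]
    )
    return GradientTable(bvals=bvals, bvecs=bvecs)


@dataclass
class DwiPhantomSpec:
    """Per-region tensors + acquisition scheme for a DWI phantom."""

    shape: tuple[int, int, int] = (24, 24, 12)
    spacing: float = 2.0  # mm (DWI protocol: 2 mm isotropic)
    labels: np.ndarray | None = None  # int array, 0 = no signal
    region_params: dict[int, dict] = field(default_factory=dict)
    # each entry: {"D": (6,), "W": (15,) or None, "S0": float}
    gtab: GradientTable | None = None
    snr: float = 30.0
    noise_model: str = "none"  # rician | gaussian | none
    seed: int = 0
    alps_truth: float | None = None
    roi_centers: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise ValueError("snr must be > 0 when noise is enabled")
        if self.gtab is None:
            self.gtab = default_gradient_table()
        if self.labels is None:
            self.labels = np.ones(self.shape, dtype=np.int16)
            if 1 not in self.region_params:
                self.region_params[1] = {
                    "D": diag_tensor(1.0e-3, 1.0e-3, 1.0e-3),
                    "W": None,
                    "S0": 1.0,
                }
        for lab, p in self.region_params.items():
            _check_spd(np.asarray(p["D"], dtype=float), f"region {lab}")


def make_dwi_phantom(spec: DwiPhantomSpec) -> tuple[np.ndarray, TensorField]:
    """4-D DWI series + ground-truth tensor field.

    Noiseless mode reproduces the forward model to machine precision.
    Rician mode draws two independent Gaussian channels of sd (mean
    foreground S0)/snr and takes the magnitude.
    """
    gtab = spec.gtab
    labels = spec.labels
    shape = labels.shape
    n = len(gtab)
    dwi = np.zeros(shape + (n,))
    S0 = np.zeros(shape)
    D = np.zeros(shape + (6,))
    W = np.zeros(shape + (15,))
    any_w = any(p.get("W") is not None for p in spec.region_params.values())
    for lab, p in spec.region_params.items():
        m = labels == lab
        if not m.any():
            continue
        d6 = np.asarray(p["D"], dtype=float)
        w15 = None if p.get("W") is None else np.asarray(p["W"], dtype=float)
        s0 = float(p.get("S0", 1.0))
        sig = signal_forward_model(gtab, np.asarray(s0), d6, w15)  # (N,)
        if np.any(sig > s0 * (1.0 + 1e-9)):
            raise ValueError(
                f"region {lab}: kurtosis term too large for the b-range "
                "(predicted signal exceeds S0)"
            )
        dwi[m] = sig
        S0[m] = s0
        D[m] = d6
        if w15 is not None:
            W[m] = w15

    if spec.noise_model != "none":
        rng = np.random.default_rng(spec.seed)
        fg = labels > 0
        sigma = float(S0[fg].mean()) / spec.snr if fg.any() else 1.0 / spec.snr
        n1 = rng.normal(0.0, sigma, size=dwi.shape)
        if spec.noise_model == "gaussian":
            dwi = dwi + n1
        else:
            n2 = rng.normal(0.0, sigma, size=dwi.shape)
            dwi = np.sqrt((dwi + n1) ** 2 + n2**2)

    sp3 = (spec.spacing,) * 3
    truth = TensorField(
        S0=S0,
        D=D,
        W=W if any_w else None,
        mask=labels > 0,
        spacing=sp3,
        fit_method="ground-truth",
    )
    return dwi, truth


def make_alps_tensor_field(
    dxx_proj: float,
    dyy_proj: float,
    dzz_proj: float,
    dxx_assoc: float,
    dyy_assoc: float,
    dzz_assoc: float,
    shape: tuple[int, int, int] = (24, 24, 12),
    spacing: float = 2.0,
    S0: float = 1.0,
    kurtosis: float | None = 1.0,
    snr: float = 30.0,
    noise_model: str = "none",
    seed: int = 0,
) -> DwiPhantomSpec:
    """DWI phantom spec with bilateral projection/association fiber blocks.

    The projection blocks carry a diagonal tensor with principal axis Z
    (inferior-superior), the association blocks with principal axis Y
    (anterior-posterior); the surrounding medium is mildly isotropic.  The
    analytic ground-truth ALPS index

        ((dxx_proj + dxx_assoc)/2) / ((dyy_proj + dzz_assoc)/2)

    and matching 16 mm^2 ROI centers are attached to the returned spec.

    ``kurtosis`` defaults to 1.0 (typical cerebral white matter): brain
    tissue is not mono-exponential, and on a b=2500 s/mm^2 shell the
    kurtosis term is what keeps signals above the noise floor, as in vivo.
    Pass ``kurtosis=None`` for a pure-tensor (K=0) phantom for analytic
    DTI checks.
    """
    for v, name in [
        (dxx_proj, "dxx_proj"), (dyy_proj, "dyy_proj"), (dzz_proj, "dzz_proj"),
        (dxx_assoc, "dxx_assoc"), (dyy_assoc, "dyy_assoc"), (dzz_assoc, "dzz_assoc"),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive (got {v})")
    nx, ny, nz = shape
    labels = np.ones(shape, dtype=np.int16)  # 1 = background medium
    # bilateral blocks, mirror-symmetric about the mid-sagittal plane
    xl = slice(int(0.12 * nx), int(0.40 * nx))
    xr = slice(nx - int(0.40 * nx), nx - int(0.12 * nx))
    yp = slice(int(0.20 * ny), int(0.45 * ny))  # projection rows
    ya = slice(int(0.55 * ny), int(0.80 * ny))  # association rows
    zc = slice(int(0.25 * nz), int(0.75 * nz))
    labels[xl, yp, zc] = 2  # projection left
    labels[xr, yp, zc] = 3  # projection right
    labels[xl, ya, zc] = 4  # association left
    labels[xr, ya, zc] = 5  # association right

    region_params = {
        1: {"D": diag_tensor(0.8e-3, 0.8e-3, 0.8e-3), "W": None, "S0": S0},
        2: {"D": diag_tensor(dxx_proj, dyy_proj, dzz_proj), "W": None, "S0": S0},
        3: {"D": diag_tensor(dxx_proj, dyy_proj, dzz_proj), "W": None, "S0": S0},
        4: {"D": diag_tensor(dxx_assoc, dyy_assoc, dzz_assoc), "W": None, "S0": S0},
        5: {"D": diag_tensor(dxx_assoc, dyy_assoc, dzz_assoc), "W": None, "S0": S0},
    }
    if kurtosis is not None:
        for p in region_params.values():
            p["W"] = isotropic_kurtosis(kurtosis)

    def block_center(xs: slice, ys: slice) -> tuple[float, float, float]:
        cx = 0.5 * (xs.start + xs.stop) * spacing
        cy = 0.5 * (ys.start + ys.stop) * spacing
        cz = 0.5 * (zc.start + zc.stop) * spacing
        return (cx, cy, cz)

    roi_centers = {
        "projection_left": block_center(xl, yp),
        "projection_right": block_center(xr, yp),
        "association_left": block_center(xl, ya),
        "association_right": block_center(xr, ya),
    }
    alps_truth = ((dxx_proj + dxx_assoc) / 2.0) / ((dyy_proj + dzz_assoc) / 2.0)
    return DwiPhantomSpec(
        shape=shape,
        spacing=spacing,
        labels=labels,
        region_params=region_params,
        snr=snr,
        noise_model=noise_model,
        seed=seed,
        alps_truth=alps_truth,
        roi_centers=roi_centers,
    )
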