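"""Diffusion tensor and diffusion-kurtosis fitting on log-signals.

Model
-----
For a unit gradient direction ``g`` and b-value ``b`` (s/mm^2) the
kurtosis-extended signal model is

    ln S(b, g) = ln S0 - b * ADC(g) + (1/6) * b^2 * ADC(g)^2 * K(g)

with ``ADC(g) = g^T D g`` (mm^2/s) and the directional kurtosis
``K(g) = (MD / ADC(g))^2 * W(g)`` where ``W(g)`` contracts the fully
symmetric fourth-order kurtosis tensor W with g four times and
``MD = tr(D)/3``.  Substituting K(g) makes the exponent *linear* in the 6
unique components of D and the 15 unique components of ``V = MD^2 * W``:
that is the design used by the linear fits below.  W is recovered from V by
dividing by ``MD^2`` of the fitted tensor.

Two estimators are provided:

* :func:`fit_dti_wls` — tensor-only weighted least squares (weights =
  squared predicted signal, one reweighting pass after an OLS start), the
  standard log-linear DTI estimator.
* :func:`fit_dki_lls` — joint 22-parameter linear least squares for
  ``(ln S0, D, V)`` on two or more shells; the D reported by this fit is
  what feeds the ALPS index when multi-shell data are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GradientTable
from .volume import Volume

logger = logging.getLogger("glymkit")

__all__ = [
    "TensorField",
    "dti_design_matrix",
    "dki_design_matrix",
    "signal_forward_model",
    "fit_dti_wls",
    "fit_dki_lls",
    "extract_diffusivity_maps",
    "KT_INDICES",
    "KT_MULTIPLICITY",
]

# unique components of the symmetric diffusion tensor, in storage order
DT_INDICES = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
DT_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)

# unique components of the fully symmetric kurtosis tensor, in storage order
KT_INDICES = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
KT_MULTIPLICITY = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

_MIN_SIGNAL = 1e-10


@dataclass
class TensorField:
    """Per-voxel fit results on a 3-D grid.

    ``D`` holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s; ``W`` (optional)
    holds the 15 unique kurtosis components (unitless) in :data:`KT_INDICES`
    order.  Voxels outside ``mask`` are zero-filled and flagged, never
    silently dropped.
    """

    S0: np.ndarray
    D: np.ndarray  # (..., 6)
    mask: np.ndarray
    W: np.ndarray | None = None  # (..., 15)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    fit_method: str = ""
    n_clipped_signals: int = 0
    n_negative_eigs: int = 0
    failed_mask: np.ndarray | None = None

    def tensor_matrices(self) -> np.ndarray:
        """Full 3x3 symmetric tensors, shape (..., 3, 3)."""
        out = np.zeros(self.D.shape[:-1] + (3, 3))
        for c, (i, j) in enumerate(DT_INDICES):
            out[..., i, j] = self.D[..., c]
            out[..., j, i] = self.D[..., c]
        return out

    def eigenvalues(self, clamp: bool = False) -> np.ndarray:
        evals = np.linalg.eigvalsh(self.tensor_matrices())
        if clamp:
            evals = np.clip(evals, 0.0, None)
        return evals

    def mean_diffusivity(self) -> np.ndarray:
        return self.D[..., :3].mean(axis=-1)

    def mean_kurtosis_tensor(self) -> np.ndarray:
        """MKT = mean of W(g) over the sphere = (W_xxxx+W_yyyy+W_zzzz+2(W_xxyy+W_xxzz+W_yyzz))/5."""
        if self.W is None:
            raise ValueError("no kurtosis tensor fitted")
        w = self.W
        return (w[..., 0] + w[..., 1] + w[..., 2] + 2.0 * (w[..., 9] + w[..., 10] + w[..., 11])) / 5.0


def dti_design_matrix(gtab: GradientTable) -> np.ndarray:
    """(N, 7) design for ln S = X @ [ln S0, D6]."""
    g = gtab.bvecs
    b = gtab.bvals
    cols = [np.ones_like(b)]
    for m, (i, j) in zip(DT_MULTIPLICITY, DT_INDICES):
        cols.append(-b * m * g[:, i] * g[:, j])
    return np.stack(cols, axis=1)


def dki_design_matrix(gtab: GradientTable) -> np.ndarray:
    """(N, 22) design for ln S = X @ [ln S0, D6, V15] with V = MD^2 * W."""
    g = gtab.bvecs
    b = gtab.bvals
    X = np.empty((len(gtab), 22))
    X[:, :7] = dti_design_matrix(gtab)
    for c, (m, idx) in enumerate(zip(KT_MULTIPLICITY, KT_INDICES)):
        prod = np.ones_like(b)
        for ax in idx:
            prod = prod * g[:, ax]
        X[:, 7 + c] = (b**2 / 6.0) * m * prod
    return X


def signal_forward_model(
    gtab: GradientTable,
    S0: np.ndarray | float,
    D: np.ndarray,
    W: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless signals for tensors D (..., 6) and optional kurtosis W (..., 15).

    Returns an array of shape ``D.shape[:-1] + (len(gtab),)``.  This is the
    exact model inverted by the linear fits, so fit(model(x)) == x in the
    noiseless case.
    """
    D = np.asarray(D, dtype=float)
    base = D.shape[:-1]
    Xd = dti_design_matrix(gtab)  # (N, 7)
    params = np.concatenate(
        [np.zeros(base + (1,)), D.reshape(base + (6,))], axis=-1
    )
    log_s = params @ Xd.T  # (..., N), without the ln S0 column contribution
    if W is not None:
        W = np.asarray(W, dtype=float)
        md = D[..., :3].mean(axis=-1)
        V = W * (md**2)[..., None]
        Xk = dki_design_matrix(gtab)[:, 7:]  # (N, 15)
        log_s = log_s + V @ Xk.T
    s0 = np.asarray(S0, dtype=float)
    return np.exp(log_s) * s0[..., None] if s0.ndim else np.exp(log_s) * s0


def _prepare_signals(dwi: np.ndarray, gtab: GradientTable, mask: np.ndarray):
    if dwi.shape[-1] != len(gtab):
        raise ValueError(
            f"DWI has {dwi.shape[-1]} volumes but gradient table has {len(gtab)}"
        )
    mask = np.asarray(mask, dtype=bool)
    sig = np.asarray(dwi, dtype=float)[mask]  # (M, N)
    n_clipped = int(np.sum(sig <= 0))
    if n_clipped:
        logger.warning("clipped %d non-positive signals to %g", n_clipped, _MIN_SIGNAL)
    sig = np.clip(sig, _MIN_SIGNAL, None)
    return sig, mask, n_clipped


def _check_dti_feasible(gtab: GradientTable) -> None:
    nz = gtab.bvals > 0
    dirs = np.unique(np.round(gtab.bvecs[nz], 6), axis=0)
    if dirs.shape[0] < 6:
        raise ValueError(f"need >= 6 unique diffusion directions, got {dirs.shape[0]}")
    if not np.any(~nz):
        raise ValueError("need at least one b=0 volume")


def _finish(field_shape, mask, S0_flat, D_flat, W_flat, spacing, affine, method, n_clipped):
    S0 = np.zeros(field_shape)
    D = np.zeros(field_shape + (6,))
    S0[mask] = S0_flat
    D[mask] = D_flat
    W = None
    if W_flat is not None:
        W = np.zeros(field_shape + (15,))
        W[mask] = W_flat
    tf = TensorField(
        S0=S0, D=D, W=W, mask=mask, spacing=spacing, affine=affine,
        fit_method=method, n_clipped_signals=n_clipped,
    )
    evals = np.linalg.eigvalsh(tf.tensor_matrices()[mask])
    tf.n_negative_eigs = int(np.sum(np.any(evals < 0, axis=-1)))
    bad = ~np.isfinite(D_flat).all(axis=-1)
    if bad.any():
        failed = np.zeros(field_shape, dtype=bool)
        failed[mask] = bad
        tf.failed_mask = failed
        logger.warning("%d voxel fits failed (non-finite parameters)", int(bad.sum()))
    return tf


def fit_dti_wls(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> TensorField:
    """Weighted least-squares diffusion tensor fit.

    OLS on the log-signal initializes the fit; one reweighting pass with
    weights equal to the squared predicted signals gives the standard WLS
    estimator.  Noiseless data are recovered exactly (the OLS solution
    already interpolates).
    """
    _check_dti_feasible(gtab)
    if mask is None:
        mask = np.ones(dwi.shape[:-1], dtype=bool)
    sig, mask, n_clipped = _prepare_signals(dwi, gtab, mask)
    X = dti_design_matrix(gtab)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient DTI design (collinear directions)")
    y = np.log(sig)  # (M, N)
    beta = y @ np.linalg.pinv(X).T  # OLS, (M, 7)
    # one WLS pass: w_i = predicted_signal_i^2
    w = np.exp(2.0 * (beta @ X.T))  # (M, N)
    Xw = np.einsum("mn,np->mnp", w, X)  # (M, N, 7)
    lhs = np.einsum("mnp,nq->mpq", Xw, X)  # (M, 7, 7)
    rhs = np.einsum("mnp,mn->mp", Xw, y)  # (M, 7)
    beta = np.linalg.solve(lhs, rhs[..., None])[..., 0]
    S0_flat = np.exp(beta[:, 0])
    D_flat = beta[:, 1:7]
    return _finish(dwi.shape[:-1], mask, S0_flat, D_flat, None, spacing, affine, "dti-wls", n_clipped)


def fit_dki_lls(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> TensorField:
    """Joint linear least-squares fit of diffusion + kurtosis tensors.

    Requires at least two nonzero shells (e.g. b = 1000 and 2500 s/mm^2) and
    >= 15 unique directions on the outer shell; single-shell data cannot
    separate D from the kurtosis term — use :func:`fit_dti_wls` there.
    """
    shells = gtab.shells
    if shells.size < 2:
        raise ValueError(
            "kurtosis fitting needs >= 2 nonzero b-shells; "
            "for single-shell data use fit_dti_wls"
        )
    outer = gtab.bvals == shells.max()
    n_outer = np.unique(np.round(gtab.bvecs[outer], 6), axis=0).shape[0]
    if n_outer < 15:
        raise ValueError(f"need >= 15 unique outer-shell directions, got {n_outer}")
    _check_dti_feasible(gtab)
    if mask is None:
        mask = np.ones(dwi.shape[:-1], dtype=bool)
    sig, mask, n_clipped = _prepare_signals(dwi, gtab, mask)
    X = dki_design_matrix(gtab)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient DKI design for this gradient scheme")
    beta = np.log(sig) @ np.linalg.pinv(X).T  # (M, 22)
    S0_flat = np.exp(beta[:, 0])
    D_flat = beta[:, 1:7]
    V_flat = beta[:, 7:22]
    md = D_flat[:, :3].mean(axis=1)
    md2 = np.where(np.abs(md) > 1e-12, md**2, np.inf)  # W undefined where MD ~ 0
    W_flat = V_flat / md2[:, None]
    return _finish(dwi.shape[:-1], mask, S0_flat, D_flat, W_flat, spacing, affine, "dki-lls", n_clipped)


def extract_diffusivity_maps(tf: TensorField) -> tuple[Volume, Volume, Volume]:
    """Dxx, Dyy, Dzz maps: diagonal tensor components in the volume axis
    frame (not eigenvalues), per the ALPS convention X=L-R, Y=A-P, Z=I-S."""
    vols = []
    for c in range(3):
        vols.append(
            Volume(
                data=tf.D[..., c],
                spacing=tf.spacing,
                affine=tf.affine,
                space_tag="diffusivity",
            )
        )
    return tuple(vols)  # type: ignore[return-value]
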