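"""Volumetric searchlight mapping of hypothesis-matrix evidence.

A sphere of fixed world-space radius is moved over every in-mask voxel; for
each sphere the data block is reduced to second-order features, the
variational model with a single (seed-derived) hypothesis component plus an
IID noise component is fitted, and the evidence for that component is scored
by Bayesian model reduction against the null prior N(-16, 1/128).  The
output is a log-Bayes-factor map (full vs component-suppressed model) and
the corresponding posterior-probability map (its logistic), conventionally
thresholded at 0.95.

Spheres are independent, so the maps are invariant to processing order and
the loop parallelises trivially; expensive whole-volume quantities (condition
parameter estimates and model residuals) are computed once up front.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .bmr import PRECISE_PRIOR_VAR, bayesian_model_reduction, _switched_off_prior
from .components import ComponentSet, HypothesisMatrix
from .second_order import GLMData, SecondOrderData, _pinv, spatial_dof
from .vl import GaussianDensity, default_hyperprior, fit_vl

__all__ = ["SearchlightSpec", "EvidenceMap", "extract_sphere", "run_searchlight",
           "evidence_map_to_nifti", "load_volume"]

log = logging.getLogger(__name__)


@dataclass
class SearchlightSpec:
    radius_mm: float = 8.0
    mask: np.ndarray = None            #: 3-D binary volume
    affine: np.ndarray = None          #: 4x4 voxel-to-world transform
    min_voxels: int = 10
    component: HypothesisMatrix = None  #: seed hypothesis matrix
    threshold_prob: float = 0.95

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.ndim != 3 or not self.mask.any():
                raise ValueError("mask must be a nonempty 3-D binary volume")
        if self.affine is None:
            self.affine = np.eye(4)
        if not 0.0 < self.threshold_prob < 1.0:
            raise ValueError("threshold_prob must lie in (0, 1)")


@dataclass
class EvidenceMap:
    logBF: np.ndarray                  #: 3-D, NaN outside mask / skipped
    posterior_prob: np.ndarray
    n_fitted: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    threshold_prob: float = 0.95

    def thresholded(self) -> np.ndarray:
        """Binary map of voxels whose posterior probability exceeds the
        threshold."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.posterior_prob, nan=0.0) > self.threshold_prob

    def summary(self) -> dict:
        finite = np.isfinite(self.logBF)
        out = {"n_fitted": int(self.n_fitted),
               "n_suprathreshold": int(self.thresholded().sum()),
               "threshold_prob": float(self.threshold_prob)}
        if finite.any():
            peak = np.unravel_index(np.nanargmax(np.where(finite, self.logBF, -np.inf)),
                                    self.logBF.shape)
            world = (self.affine @ np.array([*peak, 1.0]))[:3]
            out["peak_logBF"] = float(self.logBF[peak])
            out["peak_mm"] = [float(x) for x in world]
        return out


def _world_coords(index_array: np.ndarray, affine: np.ndarray) -> np.ndarray:
    homo = np.hstack([index_array, np.ones((index_array.shape[0], 1))])
    return (homo @ affine.T)[:, :3]


def extract_sphere(center_voxel, spec: SearchlightSpec, data: np.ndarray,
                   Z: np.ndarray, X: np.ndarray | None = None) -> GLMData | None:
    """Timeseries of all in-mask voxels within ``radius_mm`` (inclusive) of a
    centre voxel, measured between voxel centres in world space.

    Returns None (and logs) when fewer than ``min_voxels`` voxels fall inside
    the sphere.
    """
    mask_idx = np.argwhere(spec.mask)
    if not spec.mask[tuple(center_voxel)]:
        raise ValueError(f"centre {tuple(center_voxel)} lies outside the mask")
    coords = _world_coords(mask_idx, spec.affine)
    center = _world_coords(np.atleast_2d(center_voxel), spec.affine)[0]
    dist = np.linalg.norm(coords - center, axis=1)
    inside = mask_idx[dist <= spec.radius_mm + 1e-9]
    if inside.shape[0] < spec.min_voxels:
        log.info("sphere at %s skipped: %d < %d voxels",
                 tuple(center_voxel), inside.shape[0], spec.min_voxels)
        return None
    Y = data[inside[:, 0], inside[:, 1], inside[:, 2], :].T
    return GLMData(Y=Y, Z=Z, X=X)


def run_searchlight(data: np.ndarray, Z: np.ndarray, X: np.ndarray | None,
                    spec: SearchlightSpec,
                    prior: GaussianDensity | None = None, *,
                    precise_variance: float = PRECISE_PRIOR_VAR,
                    n_jobs: int = 1) -> EvidenceMap:
    """Fit the seed-component model in every searchlight and map the evidence.

    ``data`` is a 4-D array (x, y, z, time); its time dimension must match the
    rows of ``Z``.  Per sphere the rows are mean-centred over the sphere's
    voxels, the model {seed component, noise} is fitted by variational
    Laplace, and the log Bayes factor against the component-suppressed prior
    is recorded.  Sphere failures are logged and left as NaN.
    """
    if spec.component is None:
        raise ValueError("spec.component (the seed hypothesis matrix) is required")
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, time)")
    m = data.shape[3]
    if Z.shape[0] != m:
        raise ValueError(f"time dimension {m} does not match design rows {Z.shape[0]}")
    k = Z.shape[1]
    if spec.component.n_conditions != k:
        raise ValueError("seed component dimension does not match the design")
    if prior is None:
        prior = default_hyperprior(2)

    mask_idx = np.argwhere(spec.mask)
    coords = _world_coords(mask_idx, spec.affine)
    tree = cKDTree(coords)
    neighbour_lists = tree.query_ball_point(coords, spec.radius_mm + 1e-9)

    Y = data[spec.mask].T                     # m x V, in-mask voxels
    Zp = _pinv(Z)
    if X is None:
        R = np.eye(k)
        ZX = Z
    else:
        A = Zp @ X
        R = np.eye(k) - A @ _pinv(A)
        ZX = np.hstack([Z, X])
    ZY = Zp @ Y                               # k x V condition estimates
    RES = Y - ZX @ (_pinv(ZX) @ Y)            # m x V model residuals
    residual_dof = m - np.linalg.matrix_rank(ZX)
    Ce = R @ (Zp @ Zp.T) @ R
    w, V = np.linalg.eigh(0.5 * (R + R.T))
    E = V[:, w > 0.5]
    comps = ComponentSet([spec.component]).with_noise(Ce)

    def fit_one(i: int):
        idx = np.asarray(sorted(neighbour_lists[i]), dtype=int)
        if idx.size < spec.min_voxels:
            return None
        blk = ZY[:, idx]
        blk = blk - (Zp @ Y[:, idx].mean(axis=1))[:, None]  # row-centring
        Uhat = R @ blk
        S = Uhat @ Uhat.T
        res = RES[:, idx]
        res = res - res.mean(axis=1, keepdims=True)
        if not np.any(res):
            return None
        upsilon = spatial_dof(res, residual_dof=residual_dof)
        so = SecondOrderData(S=0.5 * (S + S.T), Ce=Ce, R=R, upsilon=upsilon,
                             n_voxels=idx.size, basis=E)
        try:
            fit = fit_vl(so, comps, prior)
            rm = bayesian_model_reduction(
                fit.posterior, prior,
                _switched_off_prior(prior, [0], precise_variance))
        except (ValueError, FloatingPointError) as err:
            log.warning("sphere %d failed: %s", i, err)
            return None
        return float(rm.delta_F)

    n_centres = mask_idx.shape[0]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(fit_one)(i)
                                          for i in range(n_centres))
    else:
        results = [fit_one(i) for i in range(n_centres)]

    logBF = np.full(spec.mask.shape, np.nan)
    n_fitted = 0
    for (ix, iy, iz), val in zip(mask_idx, results):
        if val is not None:
            logBF[ix, iy, iz] = val
            n_fitted += 1
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-logBF))
    return EvidenceMap(logBF=logBF, posterior_prob=prob, n_fitted=n_fitted,
                       affine=spec.affine, threshold_prob=spec.threshold_prob)


def load_volume(data_path: str | Path, mask_path: str | Path):
    """Read a 4-D NIfTI and its 3-D mask; returns (data, mask, affine)."""
    import nibabel as nib

    img = nib.load(str(data_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0.5
    return data, mask, img.affine


def evidence_map_to_nifti(emap: EvidenceMap, out_prefix: str | Path) -> dict[str, str]:
    """Write logBF and posterior-probability NIfTI volumes plus a JSON
    summary; returns the paths written."""
    import nibabel as nib

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("logBF", emap.logBF), ("pp", emap.posterior_prob)):
        p = out_prefix.parent / f"{out_prefix.name}_{name}.nii"
        nib.Nifti1Image(vol.astype(np.float32), emap.affine).to_filename(str(p))
        paths[name] = str(p)
    p = out_prefix.parent / f"{out_prefix.name}_summary.json"
    p.write_text(json.dumps(emap.summary(), indent=2))
    paths["summary"] = str(p)
    return paths
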