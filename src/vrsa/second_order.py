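"""Reduction of the multivariate GLM Y = Z U + X B + e to second-order features.

The variational machinery never sees the raw data: it consumes the second
moment ``S`` of the (confound-orthogonalised) condition parameter estimates
``Uhat = R Z^- Y``, the corresponding error component ``Ce``, and the
effective spatial degrees of freedom ``upsilon`` that play the role of the
Wishart degrees of freedom under spatially correlated noise.

Confounds are removed in condition space with the idempotent residual-forming
matrix ``R = I - (Z^- X)(Z^- X)^-``.  When a constant confound is present, R
is a centering projector and the second-order quantities live in the
(conditions-1)-dimensional range of R; an orthonormal basis of that range is
stored so downstream log-determinants are taken over the informative subspace
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GLMData", "SecondOrderData", "reduce_to_second_order", "spatial_dof",
           "read_glm_data", "write_glm_data", "read_table"]

#: relative singular-value cutoff for pseudo-inverses
PINV_RCOND = 1e-10


@dataclass
class GLMData:
    """One subject's data block: measurements x voxels data ``Y``, the
    condition design ``Z`` and confounds ``X`` (may be empty)."""

    Y: np.ndarray
    Z: np.ndarray
    X: np.ndarray | None = None
    row_centred: bool = False

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.X is not None:
            X = np.asarray(self.X, dtype=float)
            self.X = X.reshape(X.shape[0], -1) if X.size else None
        rows = {self.Y.shape[0], self.Z.shape[0]}
        if self.X is not None:
            rows.add(self.X.shape[0])
        if len(rows) != 1:
            raise ValueError(f"row counts of Y, Z, X disagree: {sorted(rows)}")

    @property
    def n_conditions(self) -> int:
        return self.Z.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.Y.shape[1]


@dataclass
class SecondOrderData:
    """Second-order features consumed by the variational engine."""

    S: np.ndarray            #: conditions x conditions second moment of Uhat
    Ce: np.ndarray           #: error covariance component R Z^- Z^-' R
    R: np.ndarray            #: idempotent confound-removing projector
    upsilon: float           #: effective spatial degrees of freedom
    n_voxels: int
    basis: np.ndarray = field(default=None)  # orthonormal basis of range(R)

    def __post_init__(self) -> None:
        if self.basis is None:
            self.basis = np.eye(self.S.shape[0])
        if np.abs(self.R @ self.R - self.R).max() > 1e-8:
            raise ValueError("R is not idempotent")

    @property
    def n_conditions(self) -> int:
        return self.S.shape[0]

    @property
    def S_bar(self) -> np.ndarray:
        """Per-effective-voxel second moment S / upsilon; its entries are on
        the scale of per-voxel (co)variances."""
        return self.S / self.upsilon

    def project(self, M: np.ndarray) -> np.ndarray:
        """Express a conditions-space matrix in the informative subspace."""
        E = self.basis
        return E.T @ M @ E

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("S", "Ce", "R", "basis"):
            np.savetxt(directory / f"{name}.tsv", getattr(self, name), delimiter="\t")
        meta = {"upsilon": float(self.upsilon), "n_voxels": int(self.n_voxels)}
        (directory / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "SecondOrderData":
        directory = Path(directory)
        mats = {name: np.atleast_2d(np.loadtxt(directory / f"{name}.tsv", delimiter="\t"))
                for name in ("S", "Ce", "R", "basis")}
        meta = json.loads((directory / "meta.json").read_text())
        return cls(mats["S"], mats["Ce"], mats["R"], meta["upsilon"],
                   meta["n_voxels"], mats["basis"])


def _pinv(A: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(A, rcond=PINV_RCOND)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV/whitespace-delimited table with a header row.

    Inspects the header line directly; ``sep=None`` sniffing invents phantom
    columns on single-column files.
    """
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = r"\s+"
    return pd.read_csv(path, sep=sep)


def _check_full_rank(Z: np.ndarray) -> None:
    k = Z.shape[1]
    if np.linalg.matrix_rank(Z, tol=PINV_RCOND * max(np.linalg.norm(Z), 1.0)) < k:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, Rq, piv = qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rq))
        bad = sorted(piv[i] for i in range(k) if diag[i] < 1e-10 * max(diag.max(), 1.0))
        raise ValueError(f"design matrix Z is rank deficient; offending columns: {bad}")


def spatial_dof(residuals: np.ndarray, residual_dof: float | None = None) -> float:
    """Effective spatial degrees of freedom of a residual matrix.

    upsilon = tr(Y)^2 / tr(Y Y) with Y = r'r, the voxel-by-voxel second
    moment of the residuals.  Identical columns give 1; mutually orthogonal
    equal-norm columns give the number of voxels.  Invariant to overall
    scaling of the residuals.

    When ``residual_dof`` (the temporal degrees of freedom m' left after
    model fitting) is supplied, the plug-in ratio is replaced by the ratio of
    Wishart-unbiased estimates of tr(V)^2 and tr(VV),

        upsilon = ((m'+1) t1^2 - 2 t2) / (m' t2 - t1^2),
        t1 = tr(Y), t2 = tr(Y Y),

    which removes the finite-sample spectral spread of Y (the plug-in ratio
    approaches p/(1 + p/m') rather than p for white noise).  The result is
    clipped to [1, voxels].
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    p = r.shape[1]
    if p < 1:
        raise ValueError("need at least one voxel")
    G = r.T @ r
    t1 = np.trace(G)
    if t1 <= 0:
        raise ValueError("residuals are identically zero; spatial DOF undefined")
    t2 = np.sum(G * G)
    if residual_dof is not None and residual_dof > 2:
        mp = float(residual_dof)
        denom = mp * t2 - t1 * t1
        if denom > 0:
            ups = ((mp + 1.0) * t1 * t1 - 2.0 * t2) / denom
            return float(np.clip(ups, 1.0, p))
    return float(np.clip(t1 * t1 / t2, 1.0, p))


def reduce_to_second_order(d: GLMData, centre_rows: bool = False) -> SecondOrderData:
    """Reduce a GLM data block to the second-order features (S, Ce, R, upsilon).

    If ``centre_rows``, each row of Y is mean-centred over voxels first (so the
    second moment becomes a spatial covariance and hypothesis matrices read as
    covariance components).
    """
    Y, Z, X = d.Y, d.Z, d.X
    _check_full_rank(Z)
    if centre_rows and not d.row_centred:
        Y = Y - Y.mean(axis=1, keepdims=True)
    k = Z.shape[1]
    Zp = _pinv(Z)
    if X is None:
        R = np.eye(k)
    else:
        A = Zp @ X
        R = np.eye(k) - A @ _pinv(A)
        if np.abs(R).max() < 1e-10:
            raise ValueError("confounds X span the condition design entirely; "
                             "no estimable condition effects remain")
    Uhat = R @ (Zp @ Y)
    S = Uhat @ Uhat.T
    Ce = R @ (Zp @ Zp.T) @ R

    ZX = Z if X is None else np.hstack([Z, X])
    residuals = Y - ZX @ (_pinv(ZX) @ Y)
    residual_dof = Y.shape[0] - np.linalg.matrix_rank(ZX)
    if np.abs(residuals).max() <= 1e-12 * max(np.abs(Y).max(), 1.0):
        # noiseless data fit the model exactly: no evidence of spatial
        # correlation, so every voxel counts
        upsilon = float(d.n_voxels)
    else:
        upsilon = spatial_dof(residuals, residual_dof=residual_dof)

    # orthonormal basis of range(R): the subspace in which S and Ce are full
    # rank once confound directions are projected out
    w, V = np.linalg.eigh(0.5 * (R + R.T))
    E = V[:, w > 0.5]  # eigenvalues of an idempotent matrix are 0 or 1

    S = 0.5 * (S + S.T)
    Ce = 0.5 * (Ce + Ce.T)
    return SecondOrderData(S=S, Ce=Ce, R=R, upsilon=upsilon,
                           n_voxels=d.n_voxels, basis=E)


def read_glm_data(y_path: str | Path, z_path: str | Path,
                  x_path: str | Path | None = None) -> GLMData:
    """Assemble a GLMData block from delimited text files (header rows)."""
    Y = read_table(y_path).to_numpy(float)
    Z = read_table(z_path).to_numpy(float)
    X = None
    if x_path is not None:
        X = read_table(x_path).to_numpy(float)
    return GLMData(Y=Y, Z=Z, X=X)


def write_glm_data(d: GLMData, directory: str | Path, prefix: str = "") -> dict[str, str]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, M in (("Y", d.Y), ("Z", d.Z), ("X", d.X)):
        if M is None:
            continue
        fname = f"{prefix}{name}.tsv"
        cols = [f"{name.lower()}{i+1}" for i in range(M.shape[1])]
        pd.DataFrame(M, columns=cols).to_csv(directory / fname, sep="\t", index=False)
        paths[name] = fname
    return paths
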