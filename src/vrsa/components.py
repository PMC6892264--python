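"""Hypothesis matrices (covariance components), contrasts and (dis)similarity maps.

A hypothesis about condition-specific responses is encoded as a symmetric
positive semi-definite conditions-by-conditions matrix ``C``.  A rank-one
hypothesis is the outer product of a contrast vector with itself and plays
the role of a t-contrast; higher-rank matrices (e.g. an empirical second
moment from another region) play the role of F-contrasts and can be
decomposed into orthogonal rank-one hypotheses by eigendecomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Contrast",
    "HypothesisMatrix",
    "ComponentSet",
    "contrast_to_component",
    "orthonormalise_contrasts",
    "decompose_component",
    "similarity_to_dissimilarity",
    "read_contrast",
    "write_contrast",
    "read_component",
    "write_component",
    "read_component_set",
    "write_component_set",
]

#: relative tolerance below which eigenvalues do not count towards the rank
RANK_TOL = 1e-10
#: relative tolerance for accepting slightly indefinite matrices as PSD
PSD_TOL = 1e-8


@dataclass
class Contrast:
    """A vector over experimental conditions; the 'square root' of a rank-one
    hypothesis matrix.  Not implicitly normalised."""

    values: np.ndarray
    label: str = "contrast"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("contrast must have at least one entry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"contrast {self.label!r} has non-finite entries")

    @property
    def n_conditions(self) -> int:
        return self.values.size

    def normalised(self) -> "Contrast":
        """Return a unit-norm copy."""
        nrm = np.linalg.norm(self.values)
        if nrm == 0:
            raise ValueError(f"cannot normalise the zero contrast {self.label!r}")
        return Contrast(self.values / nrm, self.label)


@dataclass
class HypothesisMatrix:
    """A symmetric PSD conditions-by-conditions covariance component."""

    matrix: np.ndarray
    label: str = "component"
    origin: Literal["contrast", "full_rank", "empirical"] = "full_rank"
    rank: int = field(init=False)

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"component {self.label!r} must be square, got {C.shape}")
        scale = max(np.abs(C).max(), 1.0)
        if np.abs(C - C.T).max() > 1e-10 * scale:
            raise ValueError(f"component {self.label!r} is not symmetric")
        C = 0.5 * (C + C.T)
        w = np.linalg.eigvalsh(C)
        wmax = max(w[-1], 0.0)
        if w[0] < -PSD_TOL * max(wmax, 1e-30):
            raise ValueError(
                f"component {self.label!r} is not positive semi-definite "
                f"(min eigenvalue {w[0]:.3e})"
            )
        self.matrix = C
        self.rank = int(np.sum(w > RANK_TOL * max(wmax, 1e-30)))

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def unit_trace(self) -> "HypothesisMatrix":
        """Rescale to unit trace (optional pre-scaling for full-rank hypotheses)."""
        tr = np.trace(self.matrix)
        if tr <= 0:
            raise ValueError(f"component {self.label!r} has non-positive trace")
        return HypothesisMatrix(self.matrix / tr, self.label, self.origin)


@dataclass
class ComponentSet:
    """An ordered collection of hypothesis matrices entering the mixture
    G = v1*C1 + v2*C2 + ...; ``includes_noise`` marks a trailing error
    component."""

    components: list[HypothesisMatrix]
    includes_noise: bool = False

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("component set is empty")
        dims = {c.n_conditions for c in self.components}
        if len(dims) != 1:
            raise ValueError(f"components have mismatched dimensions: {sorted(dims)}")
        labels = [c.label for c in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError(f"component labels are not unique: {labels}")

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    @property
    def n_conditions(self) -> int:
        return self.components[0].n_conditions

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    @property
    def effect_indices(self) -> list[int]:
        """Indices of the non-noise (effect) components."""
        n = len(self.components)
        return list(range(n - 1 if self.includes_noise else n))

    def matrices(self) -> list[np.ndarray]:
        return [c.matrix for c in self.components]

    def with_noise(self, Ce: np.ndarray, label: str = "noise") -> "ComponentSet":
        """Return a new set with an error component appended."""
        if self.includes_noise:
            raise ValueError("component set already includes a noise component")
        noise = HypothesisMatrix(Ce, label=label, origin="full_rank")
        return ComponentSet(self.components + [noise], includes_noise=True)


def contrast_to_component(c: Contrast, normalise: bool = False) -> HypothesisMatrix:
    """Build the rank-one hypothesis matrix C = c c' from a contrast.

    If ``normalise``, the contrast is scaled to unit norm first so that the
    associated hyperparameter is interpretable as a per-voxel variance.
    """
    v = c.normalised().values if normalise else c.values
    if np.all(v == 0):
        raise ValueError(f"contrast {c.label!r} is identically zero")
    return HypothesisMatrix(np.outer(v, v), label=c.label, origin="contrast")


def orthonormalise_contrasts(contrasts: Sequence[Contrast]) -> list[Contrast]:
    """Gram-Schmidt orthonormalisation, in the order supplied.

    Makes the hyperparameters of the ensuing rank-one components comparable
    across components.  Raises if a contrast is (numerically) in the span of
    its predecessors.
    """
    out: list[Contrast] = []
    basis: list[np.ndarray] = []
    for c in contrasts:
        v = c.values.astype(float).copy()
        for b in basis:
            v -= (b @ v) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-10 * max(np.linalg.norm(c.values), 1.0):
            raise ValueError(
                f"contrast {c.label!r} is linearly dependent on earlier contrasts"
            )
        v /= nrm
        basis.append(v)
        out.append(Contrast(v, c.label))
    return out


def decompose_component(C: HypothesisMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a hypothesis matrix into orthonormal patterns.

    Returns ``(vectors, values)`` with eigenvalues sorted descending and
    clipped at zero; ``vectors[:, i]`` is the i-th pattern.  The sign of each
    vector is fixed by making its largest-magnitude element positive (first
    index on ties), so decompositions are reproducible.
    """
    w, V = np.linalg.eigh(C.matrix)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    for i in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] = -V[:, i]
    return V, w


def similarity_to_dissimilarity(
    M: HypothesisMatrix | np.ndarray, mode: Literal["correlation", "covariance"]
) -> np.ndarray:
    """Map a similarity matrix to its representational dissimilarity matrix.

    correlation mode: D2_ij = 2 - 2*C_ij (requires unit diagonal);
    covariance mode:  D*_ij = G_ii + G_jj - 2*G_ij.
    The two agree when the covariance happens to be a correlation matrix.
    """
    G = M.matrix if isinstance(M, HypothesisMatrix) else np.asarray(M, dtype=float)
    d = np.diag(G)
    if mode == "correlation":
        if np.abs(d - 1.0).max() > 1e-8:
            raise ValueError("correlation mode requires a unit diagonal")
        D = 2.0 - 2.0 * G
    elif mode == "covariance":
        D = d[:, None] + d[None, :] - 2.0 * G
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


# ---------------------------------------------------------------------------
# delimited-text / manifest IO

def read_contrast(path: str | Path, label: str | None = None) -> Contrast:
    from .second_order import read_table

    df = read_table(path)
    return Contrast(df.iloc[:, -1].to_numpy(float), label or Path(path).stem)


def write_contrast(c: Contrast, path: str | Path, condition_labels=None) -> None:
    labels = condition_labels or [f"cond{i+1}" for i in range(c.n_conditions)]
    pd.DataFrame({"condition": labels, c.label: c.values}).to_csv(path, sep="\t", index=False)


def read_component(path: str | Path, label: str | None = None,
                   origin: str = "full_rank") -> HypothesisMatrix:
    from .second_order import read_table

    df = read_table(path)
    return HypothesisMatrix(df.to_numpy(float), label or Path(path).stem, origin)


def write_component(C: HypothesisMatrix, path: str | Path, condition_labels=None) -> None:
    labels = condition_labels or [f"cond{i+1}" for i in range(C.n_conditions)]
    pd.DataFrame(C.matrix, columns=labels).to_csv(path, sep="\t", index=False)


def write_component_set(cs: ComponentSet, directory: str | Path) -> None:
    """Write each matrix as TSV plus a JSON manifest of labels and origins."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, comp in enumerate(cs.components):
        fname = f"component_{i:02d}.tsv"
        write_component(comp, directory / fname)
        entries.append({"file": fname, "label": comp.label, "origin": comp.origin})
    manifest = {"components": entries, "includes_noise": cs.includes_noise}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_component_set(directory: str | Path) -> ComponentSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    comps = [
        read_component(directory / e["file"], e["label"], e.get("origin", "full_rank"))
        for e in manifest["components"]
    ]
    return ComponentSet(comps, includes_noise=manifest.get("includes_noise", False))
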