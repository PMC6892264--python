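"""Synthetic multi-subject datasets with a two-factor representational design.

Emulates the study conditions used throughout the package's tests: 16 stimuli
crossing a parametric factor (8 equally spaced levels) with a categorical
factor (2 levels), 8 subjects, 24 presentations of each stimulus, and
Gaussian measurement noise that may be spatially smoothed.  The response
carries both main effects (per-voxel variance 1 each by default) and no
interaction; the baseline noise standard deviation is half the main-effect
standard deviation.

The spatial layout is a 1-D line of voxels; smoothing is a Gaussian kernel
with reflecting boundaries, after which the noise is rescaled so its
(expected) per-voxel standard deviation equals ``noise_sd`` — smoothing
changes spatial correlation, not marginal variance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .components import ComponentSet, Contrast, contrast_to_component
from .second_order import GLMData, write_glm_data

__all__ = ["SimulationConfig", "make_study_design", "design_components",
           "simulate_dataset", "write_dataset", "dataset_to_nifti"]


@dataclass
class SimulationConfig:
    n_subjects: int = 8
    n_conditions: int = 16
    n_reps: int = 24
    n_voxels: int = 64
    #: true per-voxel variances for (parametric, categorical, interaction)
    effect_scales: tuple[float, ...] = (1.0, 1.0, 0.0)
    #: per-voxel noise standard deviation; default half the main-effect sd
    noise_sd: float = 0.5
    #: spatial smoothing kernel sd, in voxels
    smooth_sd_voxels: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_conditions", "n_reps", "n_voxels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_conditions % 2:
            raise ValueError("n_conditions must be even (two categorical levels)")
        if self.noise_sd < 0 or self.smooth_sd_voxels < 0:
            raise ValueError("noise_sd and smooth_sd_voxels must be nonnegative")
        self.effect_scales = tuple(float(s) for s in self.effect_scales)
        if len(self.effect_scales) != 3 or any(s < 0 for s in self.effect_scales):
            raise ValueError("effect_scales must be three nonnegative variances")


def make_study_design(n_conditions: int = 16) -> tuple[np.ndarray, list[Contrast]]:
    """The two-factor design template and its three contrasts.

    Conditions are ordered category-major: the first half of the stimuli are
    category +, the second half category -, with the parametric levels
    equally spaced within each half.  Returns the identity condition template
    (one row per condition) and unit-norm contrasts for the parametric main
    effect, the categorical main effect and their interaction (the
    elementwise product of the parametric contrast with the +/-1 categorical
    sign pattern, which keeps it unit-norm and orthogonal to both).
    """
    if n_conditions % 2:
        raise ValueError("n_conditions must be even")
    n_levels = n_conditions // 2
    levels = np.linspace(-1.0, 1.0, n_levels)
    parametric = np.tile(levels, 2)
    parametric = parametric - parametric.mean()
    parametric = parametric / np.linalg.norm(parametric)
    sign = np.repeat([1.0, -1.0], n_levels)
    categorical = sign / np.linalg.norm(sign)
    interaction = parametric * sign          # unit-norm by construction
    contrasts = [Contrast(parametric, "parametric"),
                 Contrast(categorical, "categorical"),
                 Contrast(interaction, "interaction")]
    return np.eye(n_conditions), contrasts


def design_components(n_conditions: int = 16) -> ComponentSet:
    """Rank-one hypothesis matrices for the three design contrasts."""
    _, contrasts = make_study_design(n_conditions)
    return ComponentSet([contrast_to_component(c) for c in contrasts])


def _smooth_rows(noise: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian smoothing along the voxel axis with reflecting boundaries,
    rescaled so the expected per-voxel variance is preserved."""
    if sd <= 0:
        return noise
    radius = max(int(np.ceil(4.0 * sd)), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sd) ** 2)
    kernel /= kernel.sum()
    p = noise.shape[1]
    padded = np.pad(noise, ((0, 0), (radius, radius)), mode="reflect")
    out = np.empty_like(noise)
    for j in range(p):
        out[:, j] = padded[:, j:j + 2 * radius + 1] @ kernel
    # interior variance after smoothing is ||kernel||^2; undo it
    return out / np.sqrt(np.sum(kernel ** 2))


def simulate_dataset(cfg: SimulationConfig) -> list[GLMData]:
    """Per-subject GLM data blocks Y = Z U + X B + e.

    Z stacks ``n_reps`` seeded random permutations of the conditions (one-hot
    rows); each active contrast contributes a voxel pattern drawn i.i.d. with
    its configured per-voxel variance; X is a constant confound with a
    per-voxel baseline.  Bitwise reproducible from ``cfg.seed``.
    """
    _, contrasts = make_study_design(cfg.n_conditions)
    k, p = cfg.n_conditions, cfg.n_voxels
    m = k * cfg.n_reps
    datasets = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, s]))
        order = np.concatenate([rng.permutation(k) for _ in range(cfg.n_reps)])
        Z = np.zeros((m, k))
        Z[np.arange(m), order] = 1.0
        U = np.zeros((k, p))
        for c, scale in zip(contrasts, cfg.effect_scales):
            pattern = rng.standard_normal(p) * np.sqrt(scale)
            U += np.outer(c.values, pattern)
        X = np.ones((m, 1))
        B = rng.standard_normal((1, p))
        noise = rng.standard_normal((m, p))
        noise = _smooth_rows(noise, cfg.smooth_sd_voxels) * cfg.noise_sd
        Y = Z @ U + X @ B + noise
        datasets.append(GLMData(Y=Y, Z=Z, X=X))
    return datasets


def write_dataset(cfg: SimulationConfig, directory: str | Path) -> Path:
    """Write per-subject Y/Z/X delimited files plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "subjects": []}
    for s, d in enumerate(simulate_dataset(cfg)):
        paths = write_glm_data(d, directory, prefix=f"sub-{s+1:02d}_")
        manifest["subjects"].append(paths)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def dataset_to_nifti(d: GLMData, shape: tuple[int, int, int],
                     voxel_size_mm: float = 2.0):
    """Pack one subject's voxels into a 4-D NIfTI image (time last) plus a
    mask, for exercising the searchlight pipeline.  Voxels fill the grid in
    C order; unused grid positions are masked out."""
    import nibabel as nib

    m, p = d.Y.shape
    n_grid = int(np.prod(shape))
    if p > n_grid:
        raise ValueError(f"{p} voxels do not fit into grid {shape}")
    vol = np.zeros((n_grid, m))
    vol[:p] = d.Y.T
    mask = np.zeros(n_grid)
    mask[:p] = 1.0
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol.reshape(*shape, m), affine)
    mask_img = nib.Nifti1Image(mask.reshape(shape), affine)
    return img, mask_img
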