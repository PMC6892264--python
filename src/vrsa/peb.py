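"""Parametric empirical Bayes (PEB) over subject-level hyperparameters.

The between-subject model is a second-level GLM on the log-scale
hyperparameters, lambda_s = D_s lambda2 + r_s, with D a subjects-by-regressors
design whose first column of ones carries the group average, and r_s additive
between-subject variability with diagonal covariance Gamma.

The key computational device is Bayesian model reduction: swapping a
subject's original shrinkage prior for a candidate empirical prior
N(D_s lambda2, Gamma) changes that subject's log evidence by an analytic
amount that is *exactly quadratic* in lambda2.  Summing over subjects, the
group free energy is therefore a Gaussian form in lambda2 — its posterior is
closed-form given Gamma — and only the between-subject log-variances gamma
need iterative (Newton, step-halved) optimisation.  No subject data are
re-inverted.

Between-subject covariance parameterisation: Gamma_jj = exp(gamma_j) * b_j,
where b_j is the mean first-level posterior variance of component j, with
hyperprior gamma_j ~ N(0, 1) — wide enough that the random-effect variance is
determined by the subjects rather than pinned at its baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bmr import (EvidenceTable, PRECISE_PRIOR_VAR, bayesian_model_reduction,
                  softmax_probabilities)
from .vl import FitResult, GaussianDensity, PRIOR_LOG_MEAN, PRIOR_LOG_VAR

__all__ = ["GroupModel", "fit_peb", "group_component_evidence",
           "default_level2_prior"]

#: hyperprior variance on the log between-subject variance scalings; loose
#: enough that the data, not the prior, determine the random-effect variance
GAMMA_PRIOR_VAR = 1.0
#: bounds on gamma, keeping the between-subject variance computable
GAMMA_FLOOR = -8.0
GAMMA_CEIL = 8.0


@dataclass
class GroupModel:
    design: np.ndarray
    level2_posterior: GaussianDensity      #: over vec(lambda2), regressor-major
    level2_prior: GaussianDensity
    between_variance: np.ndarray           #: Gamma diagonal, one per component
    updated_subject_posteriors: list[GaussianDensity]
    free_energy: float
    n_components: int
    labels: list[str] = field(default_factory=list)
    trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def n_regressors(self) -> int:
        return self.design.shape[1]

    def group_mean(self) -> GaussianDensity:
        """Marginal posterior over the group-average (first-regressor)
        hyperparameters."""
        n = self.n_components
        return GaussianDensity(self.level2_posterior.mean[:n],
                               self.level2_posterior.cov[:n, :n])

    def to_dict(self) -> dict:
        return {
            "design": self.design.tolist(),
            "level2_posterior": self.level2_posterior.to_dict(),
            "level2_prior": self.level2_prior.to_dict(),
            "between_variance": self.between_variance.tolist(),
            "updated_subject_posteriors": [q.to_dict()
                                           for q in self.updated_subject_posteriors],
            "free_energy": float(self.free_energy),
            "n_components": int(self.n_components),
            "labels": list(self.labels),
        }


def default_level2_prior(n_components: int, n_regressors: int) -> GaussianDensity:
    """Level-2 prior on vec(lambda2): the group-mean column inherits the
    first-level shrinkage prior N(-16, 128); additional covariate columns get
    N(0, 128)."""
    mean = np.zeros(n_regressors * n_components)
    mean[:n_components] = PRIOR_LOG_MEAN
    return GaussianDensity(mean, PRIOR_LOG_VAR * np.eye(n_regressors * n_components))


def _subject_quadratics(posteriors, Pi, eta, Gamma):
    """Coefficients of each subject's evidence change as a function of the
    empirical prior mean m: E_s(m) = const_s + g_s' m - 1/2 m' K_s m."""
    Gi = np.diag(1.0 / np.diag(Gamma))
    consts, gs, Ks = [], [], []
    for q in posteriors:
        P = np.linalg.inv(q.cov)
        Pr = P - Pi + Gi
        w = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
        if w.min() <= 0:
            return None  # inadmissible Gamma for this subject
        Pr_inv = np.linalg.inv(Pr)
        c = P @ q.mean - Pi @ eta
        # log-det and data terms of the BMR evidence change at m = 0
        ld = (np.linalg.slogdet(Gi)[1] + np.linalg.slogdet(P)[1]
              - np.linalg.slogdet(Pi)[1] - np.linalg.slogdet(Pr)[1])
        quad0 = q.mean @ P @ q.mean - eta @ Pi @ eta - c @ Pr_inv @ c
        consts.append(0.5 * ld - 0.5 * quad0)
        gs.append(Gi @ (Pr_inv @ c))
        Ks.append(Gi - Gi @ Pr_inv @ Gi)
    return consts, gs, Ks


def _profiled_fit(D, posteriors, Pi, eta, Gamma, l2_prior):
    """Closed-form level-2 posterior and group free energy for a given Gamma."""
    out = _subject_quadratics(posteriors, Pi, eta, Gamma)
    if out is None:
        return None
    consts, gs, Ks = out
    s, r = D.shape
    n = posteriors[0].dim
    q = r * n
    Sigma2_inv = np.linalg.inv(l2_prior.cov)
    Lam = Sigma2_inv.copy()
    rhs = Sigma2_inv @ l2_prior.mean
    Ts = [np.kron(D[i:i + 1, :], np.eye(n)) for i in range(s)]
    for i in range(s):
        Lam += Ts[i].T @ Ks[i] @ Ts[i]
        rhs += Ts[i].T @ gs[i]
    Omega2 = np.linalg.inv(Lam)
    Omega2 = 0.5 * (Omega2 + Omega2.T)
    beta = Omega2 @ rhs
    # group free energy at the optimum (relative; subject base evidences and
    # the gamma prior penalty are added by the caller)
    F = sum(consts)
    for i in range(s):
        m = Ts[i] @ beta
        F += gs[i] @ m - 0.5 * m @ Ks[i] @ m
    db = beta - l2_prior.mean
    F -= 0.5 * db @ Sigma2_inv @ db
    F += 0.5 * (np.linalg.slogdet(Omega2)[1] - np.linalg.slogdet(l2_prior.cov)[1])
    return float(F), beta, Omega2


def fit_peb(subject_fits: list[FitResult], subject_prior: GaussianDensity,
            D: np.ndarray | None = None,
            level2_prior: GaussianDensity | None = None, *,
            mean_centre_covariates: bool = True, max_iter: int = 128,
            tol: float = 1e-3) -> GroupModel:
    """Fit the between-subject model over first-level posteriors.

    Returns the posterior over the second-level effects, the estimated
    between-subject variances, and each subject's posterior re-evaluated
    under the empirical prior from the group (via Bayesian model reduction).
    """
    if not subject_fits:
        raise ValueError("no subject fits supplied")
    posteriors = [f.posterior for f in subject_fits]
    n = posteriors[0].dim
    if any(q.dim != n for q in posteriors):
        raise ValueError("subject posteriors have mismatched dimensions")
    if subject_prior.dim != n:
        raise ValueError("subject prior dimension does not match fits")
    s = len(posteriors)
    if s < 2:
        warnings.warn("PEB with a single subject: the group posterior simply "
                      "mirrors that subject", RuntimeWarning, stacklevel=2)

    if D is None:
        D = np.ones((s, 1))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.shape[0] != s:
        raise ValueError(f"design has {D.shape[0]} rows for {s} subjects")
    if not np.allclose(D[:, 0], 1.0):
        raise ValueError("first column of the between-subject design must be ones")
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("between-subject design is rank deficient")
    if mean_centre_covariates and D.shape[1] > 1:
        D = D.copy()
        D[:, 1:] -= D[:, 1:].mean(axis=0)

    r = D.shape[1]
    if level2_prior is None:
        level2_prior = default_level2_prior(n, r)
    if level2_prior.dim != r * n:
        raise ValueError("level-2 prior dimension must be regressors x components")

    eta, Pi = subject_prior.mean, subject_prior.precision()
    b = np.array([np.mean([q.cov[j, j] for q in posteriors]) for j in range(n)])

    def objective(gamma):
        Gamma = np.diag(np.exp(np.clip(gamma, GAMMA_FLOOR, GAMMA_CEIL)) * b)
        res = _profiled_fit(D, posteriors, Pi, eta, Gamma, level2_prior)
        if res is None:
            return None
        F, beta, Omega2 = res
        F -= 0.5 * gamma @ gamma / GAMMA_PRIOR_VAR
        return F, beta, Omega2, Gamma

    gamma = np.zeros(n)
    res = objective(gamma)
    if res is None:
        raise ValueError("between-subject model inadmissible at the initial "
                         "variance scaling")
    F, beta, Omega2, Gamma = res
    trajectory = [F]
    converged = False
    n_small = 0
    h = 1e-4
    for _ in range(max_iter):
        # numeric gradient and Hessian of the profiled objective over gamma
        grad = np.zeros(n)
        hess = np.zeros((n, n))
        f0 = F
        fp, fm = np.zeros(n), np.zeros(n)
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            rp, rm = objective(gamma + e), objective(gamma - e)
            fp[j] = rp[0] if rp else -np.inf
            fm[j] = rm[0] if rm else -np.inf
            grad[j] = (fp[j] - fm[j]) / (2 * h)
            hess[j, j] = (fp[j] - 2 * f0 + fm[j]) / h**2
        for j in range(n):
            for k in range(j + 1, n):
                e = np.zeros(n)
                e[j], e[k] = h, h
                rpp = objective(gamma + e)
                fjk = rpp[0] if rpp else -np.inf
                hess[j, k] = hess[k, j] = (
                    (fjk - fp[j] - fp[k] + f0) / h**2 - 0.5 * (hess[j, j] + hess[k, k]))
        w = np.linalg.eigvalsh(0.5 * (hess + hess.T))
        if w.max() < 0:  # concave: Newton step
            step = np.linalg.solve(-hess, grad)
        else:
            step = grad * GAMMA_PRIOR_VAR  # preconditioned ascent fallback
        accepted = False
        for _ in range(9):
            cand = np.clip(gamma + step, GAMMA_FLOOR, GAMMA_CEIL)
            res = objective(cand)
            if res is not None and res[0] >= F:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        delta = res[0] - F
        gamma, (F, beta, Omega2, Gamma) = cand, res
        trajectory.append(F)
        if abs(delta) < tol:
            n_small += 1
            if n_small >= 2:
                converged = True
                break
        else:
            n_small = 0
    if not converged:
        warnings.warn("PEB did not converge within the iteration limit",
                      RuntimeWarning, stacklevel=2)

    # re-evaluate each subject under the empirical prior from the group
    B = beta.reshape(r, n)
    updated = []
    for i, q in enumerate(posteriors):
        emp_prior = GaussianDensity(B.T @ D[i], Gamma)
        rm = bayesian_model_reduction(q, subject_prior, emp_prior)
        updated.append(rm.reduced_posterior)

    labels = list(subject_fits[0].labels) or [f"component_{j+1}" for j in range(n)]
    return GroupModel(design=D, level2_posterior=GaussianDensity(beta, Omega2),
                      level2_prior=level2_prior,
                      between_variance=np.diag(Gamma).copy(),
                      updated_subject_posteriors=updated, free_energy=float(F),
                      n_components=n, labels=labels,
                      trajectory=np.asarray(trajectory), converged=converged)


def group_component_evidence(g: GroupModel,
                             precise_variance: float = PRECISE_PRIOR_VAR,
                             noise_is_last: bool = True) -> EvidenceTable:
    """Score each component's group-average effect by Bayesian model
    reduction on the level-2 posterior, shrinking the group-mean entry to the
    precise prior N(-16, 1/128)."""
    n = g.n_components
    idx = list(range(n - 1 if noise_is_last else n))
    labels, dFs = [], []
    for j in idx:
        cov = g.level2_prior.cov.copy()
        mean = g.level2_prior.mean.copy()
        cov[j, :] = 0.0
        cov[:, j] = 0.0
        cov[j, j] = precise_variance
        mean[j] = PRIOR_LOG_MEAN
        rm = bayesian_model_reduction(g.level2_posterior, g.level2_prior,
                                      GaussianDensity(mean, cov),
                                      label=g.labels[j] if j < len(g.labels) else "")
        labels.append(g.labels[j] if j < len(g.labels) else f"component_{j+1}")
        dFs.append(rm.delta_F)
    dFs = np.asarray(dFs)
    probs = np.array([softmax_probabilities([f, 0.0])[0] for f in dFs])
    return EvidenceTable(labels, dFs, probs, kind="per_component")
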