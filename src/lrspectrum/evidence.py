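"""Is there *any* learning-rate information in a voxel?

The 99 trial-level value traces are compressed by SVD; their first three
left singular vectors capture essentially all learning-rate-related variance
(the traces form a smooth one-parameter family).  Per voxel and subject, a
base GLM is compared with a GLM that adds the three SVD components
(HRF-convolved, demeaned, high-pass filtered) via the Akaike Information
Criterion, and -AIC/2 enters random-effects Bayesian model selection across
subjects (variational Dirichlet scheme) yielding, per voxel, the protected
exceedance probability (PXP) of the learning-rate model:

    PXP_k = EP_k * (1 - BOR) + BOR / K

where EP is the exceedance probability (the probability that model k is the
most frequent in the population) and BOR the Bayes omnibus risk (posterior
probability that all model frequencies are equal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp
from scipy.stats import beta as beta_dist

from .glm import GLMResult, prewhiten, fit_glm
from .regressors import DesignMatrix, RegressorBank, hrf_convolve, highpass_filter
from .value import ValueTraces

__all__ = [
    "SVDResult",
    "BMSResult",
    "svd_components",
    "component_regressors",
    "aic_score",
    "rfx_bms",
    "exceedance_probability",
    "evidence_map",
]


@dataclass(frozen=True)
class SVDResult:
    components: np.ndarray        # (n_trials, m) left singular vectors
    variance_fraction: np.ndarray  # all singular values' variance fractions

    @property
    def top_fraction(self) -> float:
        """Cumulative variance fraction of the retained components."""
        m = self.components.shape[1]
        return float(self.variance_fraction[:m].sum())


@dataclass(frozen=True)
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    EP: np.ndarray
    BOR: float
    PXP: np.ndarray


def svd_components(trace_matrix: np.ndarray, m: int = 3) -> SVDResult:
    """SVD of the (trial x LR) value-trace matrix after column demeaning."""
    M = np.asarray(trace_matrix, dtype=float)
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(M.shape) * np.finfo(float).eps)) if s[0] > 0 else 0
    if m > rank:
        raise ValueError(f"requested {m} components but matrix rank is {rank}")
    frac = s ** 2 / np.sum(s ** 2)
    return SVDResult(components=U[:, :m], variance_fraction=frac)


def component_regressors(svd: SVDResult, session, TR: float,
                         volumes: slice | None = None,
                         trials: np.ndarray | None = None,
                         cutoff: float = 100.0) -> np.ndarray:
    """Turn trial-level SVD components into GLM columns.

    Each component modulates the decision-phase boxcar, is convolved with
    the HRF, demeaned and high-pass filtered like any other regressor.
    """
    vol = volumes if volumes is not None else slice(0, session.n_volumes)
    v0 = vol.start or 0
    v1 = vol.stop if vol.stop is not None else session.n_volumes
    idx = trials if trials is not None else np.arange(session.n_trials)
    onsets = session.decision_onset[idx]
    durations = session.response_time[idx] - session.decision_onset[idx]
    cols = []
    for j in range(svd.components.shape[1]):
        h = svd.components[idx, j]
        h = h - h.mean()
        raw = hrf_convolve(onsets, durations, h, TR, session.n_volumes)[v0:v1]
        cols.append(highpass_filter(raw, TR, cutoff))
    return np.column_stack(cols)


def aic_score(result: GLMResult) -> float:
    """Gaussian AIC: n*ln(RSS/n) + 2*(k+1) (the +1 counts the noise variance)."""
    if result.n <= result.k:
        raise ValueError("AIC needs n > k")
    rss = result.RSS
    if rss <= 0:
        import warnings
        warnings.warn("RSS is zero; AIC floored")
        rss = np.finfo(float).tiny * result.n
    return float(result.n * np.log(rss / result.n) + 2 * (result.k + 1))


def exceedance_probability(alpha: np.ndarray,
                           n_samples: int = 200_000,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """P(model k has the largest frequency) under Dirichlet(alpha).

    Analytic (regularized incomplete beta) for K = 2; Monte-Carlo otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    K = len(alpha)
    if K == 2:
        p1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = rng or np.random.default_rng(0)
    samples = rng.dirichlet(alpha, size=n_samples)
    wins = np.bincount(np.argmax(samples, axis=1), minlength=K)
    return wins / n_samples


def _rfx_variational(lme: np.ndarray, alpha0: np.ndarray,
                     tol: float = 1e-4, max_iter: int = 500):
    """Variational Dirichlet updates for group model frequencies.

    Returns (alpha, g, F) where g are posterior assignment probabilities and
    F the variational free energy of the random-effects model.
    """
    N, K = lme.shape
    alpha = alpha0.copy()
    for _ in range(max_iter):
        Elogr = digamma(alpha) - digamma(alpha.sum())
        log_u = lme + Elogr
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    Elogr = digamma(alpha) - digamma(alpha.sum())
    log_u = lme + Elogr
    g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))

    # free energy: E[log joint] + entropies
    ELJ = (gammaln(alpha0.sum()) - gammaln(alpha0).sum()
           + ((alpha0 - 1) * Elogr).sum()
           + (g * (Elogr + lme)).sum())
    Sqf = (gammaln(alpha).sum() - gammaln(alpha.sum())
           - ((alpha - 1) * Elogr).sum())
    Sqm = -np.sum(g[g > 0] * np.log(g[g > 0]))
    return alpha, g, ELJ + Sqf + Sqm


def rfx_bms(log_evidence: np.ndarray, alpha0: float = 1.0,
            tol: float = 1e-4) -> BMSResult:
    """Random-effects Bayesian model selection across subjects.

    Parameters
    ----------
    log_evidence:
        (n_subjects, K) log model evidences (here -AIC/2).

    Returns the posterior Dirichlet parameters, expected model frequencies,
    exceedance probabilities, Bayes omnibus risk and protected exceedance
    probabilities.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2:
        raise ValueError("need a (subjects x models) matrix with >= 2 subjects")
    if not np.isfinite(lme).all():
        raise ValueError("log evidences must be finite")
    N, K = lme.shape
    lme = lme - lme.mean(axis=1, keepdims=True)  # per-subject offset is arbitrary

    a0 = np.full(K, float(alpha0))
    alpha, _, F1 = _rfx_variational(lme, a0, tol=tol)
    ef = alpha / alpha.sum()
    ep = exceedance_probability(alpha)

    # null model: equal frequencies 1/K for every subject
    F0 = float(np.sum(logsumexp(lme - np.log(K), axis=1)))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(dirichlet_alpha=alpha, expected_frequency=ef, EP=ep,
                     BOR=bor, PXP=pxp)


def evidence_map(subject_data: list[dict],
                 whiten: bool = True) -> dict:
    """Per-voxel group PXP for the learning-rate-component model.

    Parameters
    ----------
    subject_data:
        One dict per subject with keys ``Y`` (V x n volumes), ``base``
        (DesignMatrix) and ``components`` (n x 3 convolved SVD component
        columns).  All subjects must share the voxel count.

    Returns a dict with ``pxp`` (V,), ``bor`` (V,), ``delta_aic``
    (subjects x V, AIC0 - AIC1) and ``lme`` (subjects x V x 2).
    """
    n_sub = len(subject_data)
    V = np.atleast_2d(subject_data[0]["Y"]).shape[0]
    lme = np.empty((n_sub, V, 2))
    for s, sub in enumerate(subject_data):
        Y = np.atleast_2d(np.asarray(sub["Y"], dtype=float))
        X0 = sub["base"].values
        X1 = np.column_stack([X0, sub["components"]])
        for v in range(Y.shape[0]):
            y = Y[v]
            if whiten:
                yw, X0w, phi = prewhiten(y, X0)
                from .glm import _quasi_difference
                X1w = _quasi_difference(X1, phi)
            else:
                yw, X0w, X1w = y, X0, X1
            aic0 = aic_score(fit_glm(yw, X0w))
            aic1 = aic_score(fit_glm(yw, X1w))
            lme[s, v] = [-aic0 / 2.0, -aic1 / 2.0]

    pxp = np.empty(V)
    bor = np.empty(V)
    for v in range(V):
        res = rfx_bms(lme[:, v, :])
        pxp[v] = res.PXP[1]
        bor[v] = res.BOR
    delta_aic = -2.0 * (lme[:, :, 0] - lme[:, :, 1])
    return dict(pxp=pxp, bor=bor, delta_aic=delta_aic, lme=lme)
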