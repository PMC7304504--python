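"""Maximum-likelihood exploratory factor analysis of the subjective traits.

The measurement model is ``T = Lambda F + eps`` with ``var(T) = Lambda Phi
Lambda' + Psi``; under orthogonal factors (``Phi = I``) phenotype vectors are
iid ``N(0, Sigma)`` with ``Sigma = Lambda Lambda' + Psi`` and the model is fit
by maximizing the Gaussian log-likelihood

    l(Lambda, Psi) = -(n/2) [ t log 2*pi + log det Sigma + tr(Sigma^{-1} S) ],

where ``S`` is the sample covariance of the standardized traits (their
correlation matrix).  Fitting runs expectation-maximization followed by a
quasi-Newton polish of the profile likelihood over the uniquenesses (the
classic Lawley–Maxwell reduction).  The orthogonal ML solution is then rotated
— oblimin (quartimin, oblique) by default, varimax optionally — and the
cross-loading-free structure for the confirmatory stage is read off by
assigning each trait to the factor with the largest absolute loading.

The number of factors is chosen by Horn's parallel analysis: leading
eigenvalues of the observed correlation matrix are retained while they exceed
the chosen percentile of the matching eigenvalue from simulated independent
normal data of the same shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import as_rng

PSI_FLOOR = 1e-6


class EFAError(RuntimeError):
    pass


class ConvergenceError(EFAError):
    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


def standardize(T: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait (column); drops rows with any missing value."""
    T = T.dropna()
    sd = T.std(ddof=1)
    if (sd == 0).any():
        raise EFAError(f"constant traits cannot be standardized: "
                       f"{list(sd.index[sd == 0])}")
    return (T - T.mean()) / sd


@dataclass
class FactorModel:
    """Fitted factor-analysis model.

    ``Lambda`` holds the (possibly rotated) loadings, ``Phi`` the factor
    correlation matrix (identity for orthogonal solutions), ``psi`` the
    diagonal specific variances.  ``Lambda_unrotated`` keeps the raw ML
    solution whose likelihood ``loglik`` was maximized.
    """

    Lambda: np.ndarray
    psi: np.ndarray
    trait_names: list[str]
    Phi: np.ndarray | None = None
    Lambda_unrotated: np.ndarray | None = None
    loglik: float = np.nan
    n_obs: int = 0
    converged: bool = True
    n_iter: int = 0
    rotation: str = "none"
    F: np.ndarray | None = None  # q x n factor scores, filled by the CFA stage

    def __post_init__(self) -> None:
        if self.Phi is None:
            self.Phi = np.eye(self.q)
        if self.Lambda_unrotated is None:
            self.Lambda_unrotated = self.Lambda.copy()

    @property
    def q(self) -> int:
        return self.Lambda.shape[1]

    @property
    def Psi(self) -> np.ndarray:
        return np.diag(self.psi)

    @property
    def Sigma_implied(self) -> np.ndarray:
        return self.Lambda @ self.Phi @ self.Lambda.T + self.Psi

    @property
    def communalities(self) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", self.Lambda, self.Phi, self.Lambda)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"factor{j + 1}" for j in range(self.q)]
        return pd.DataFrame(self.Lambda, index=self.trait_names, columns=cols)


@dataclass
class FactorStructure:
    """Cross-loading-free trait -> factor assignment with sign anchors."""

    assignment: dict[str, str]
    factor_labels: list[str]
    anchor_traits: dict[str, str]

    def __post_init__(self) -> None:
        for label in self.factor_labels:
            traits = self.traits_for(label)
            if len(traits) < 2:
                raise EFAError(f"factor {label!r} has {len(traits)} trait(s); "
                               f"each factor needs at least 2")
        for label, anchor in self.anchor_traits.items():
            if self.assignment.get(anchor) != label:
                raise EFAError(f"anchor trait {anchor!r} is not assigned to "
                               f"factor {label!r}")

    def traits_for(self, label: str) -> list[str]:
        return [t for t, f in self.assignment.items() if f == label]

    @property
    def trait_names(self) -> list[str]:
        return list(self.assignment)


def efa_loglik(Lambda: np.ndarray, psi: np.ndarray, T) -> float:
    """Gaussian factor-analysis log-likelihood at (Lambda, Psi) for data T.

    ``T`` is an (n, t) array/DataFrame of (standardized) observations; the
    implied covariance is ``Sigma = Lambda Lambda' + diag(psi)`` and the value
    is ``-(n/2) [ t log 2 pi + log det Sigma + tr(Sigma^{-1} S) ]`` with ``S``
    the ML (divisor n) sample covariance about the sample mean.
    """
    X = np.asarray(T, dtype=float)
    n, t = X.shape
    S = np.cov(X, rowvar=False, ddof=0)
    Lambda = np.atleast_2d(np.asarray(Lambda, dtype=float))
    if Lambda.size == 0:
        Lambda = np.zeros((t, 0))
    Sigma = Lambda @ Lambda.T + np.diag(np.asarray(psi, dtype=float))
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise EFAError("implied covariance is singular or not positive definite")
    return -0.5 * n * (t * np.log(2 * np.pi) + logdet
                       + float(np.trace(np.linalg.solve(Sigma, S))))


def _profile_objective(log_psi: np.ndarray, S: np.ndarray, q: int) -> float:
    """Negative profile log-likelihood (up to constants) over uniquenesses."""
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    theta = np.linalg.eigvalsh(d[:, None] * S * d[None, :])[::-1]
    theta = np.maximum(theta[q:], 1e-12)
    return float(np.sum(theta - np.log(theta)) - (len(psi) - q))


def _loadings_from_psi(psi: np.ndarray, S: np.ndarray, q: int) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    vals, vecs = np.linalg.eigh(d[:, None] * S * d[None, :])
    vals, vecs = vals[::-1], vecs[:, ::-1]
    top = np.maximum(vals[:q] - 1.0, 0.0)
    return np.sqrt(psi)[:, None] * vecs[:, :q] * np.sqrt(top)[None, :]


def fit_efa(T: pd.DataFrame, q: int, rotation: str = "oblimin",
            tol: float = 1e-8, max_iter: int = 1000) -> FactorModel:
    """ML exploratory factor analysis with q factors on standardized traits.

    EM iterations (Rubin–Thayer) until the log-likelihood changes by less
    than ``tol``, then an L-BFGS polish of the profile likelihood over the
    uniquenesses; the solution is rotated afterwards ("oblimin", "varimax" or
    "none").  Heywood cases (communality -> 1) are floored at
    ``PSI_FLOOR`` and warned about.
    """
    T = standardize(pd.DataFrame(T))
    names = list(T.columns)
    X = np.asarray(T, dtype=float)
    n, t = X.shape
    if not 0 <= q < t:
        raise EFAError(f"q must be in [0, {t})")
    S = np.cov(X, rowvar=False, ddof=0)
    if np.linalg.eigvalsh(S).min() <= 1e-10:
        raise EFAError("sample correlation matrix is not positive definite")
    if q == 0:
        psi = np.diag(S).copy()
        return FactorModel(np.zeros((t, 0)), psi, names,
                           loglik=efa_loglik(np.zeros((t, 0)), psi, X),
                           n_obs=n, rotation="none")

    # EM start: principal-axis-style initialization
    psi = np.maximum(1.0 / np.diag(np.linalg.inv(S)), PSI_FLOOR)
    Lam = _loadings_from_psi(psi, S, q)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Sigma = Lam @ Lam.T + np.diag(psi)
        SinvL = np.linalg.solve(Sigma, Lam)                 # t x q
        Eff = np.eye(q) - Lam.T @ SinvL + SinvL.T @ S @ SinvL
        Cxz = S @ SinvL
        Lam = Cxz @ np.linalg.inv(Eff)
        psi = np.maximum(np.diag(S - Lam @ Cxz.T), PSI_FLOOR)
        ll = efa_loglik(Lam, psi, X)
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll

    # quasi-Newton polish on the profile likelihood
    res = optimize.minimize(
        _profile_objective, np.log(psi), args=(S, q), method="L-BFGS-B",
        bounds=[(np.log(PSI_FLOOR), 0.0)] * t,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    psi_opt = np.exp(res.x)
    Lam_opt = _loadings_from_psi(psi_opt, S, q)
    if efa_loglik(Lam_opt, psi_opt, X) >= trace[-1] - 1e-9:
        Lam, psi = Lam_opt, psi_opt
        converged = True
    if not converged:
        raise ConvergenceError(
            f"EFA did not converge in {max_iter} EM iterations", trace)
    if np.any(psi <= PSI_FLOOR * (1 + 1e-9)):
        warnings.warn("Heywood case: specific variance at its lower bound",
                      RuntimeWarning, stacklevel=2)

    ll = efa_loglik(Lam, psi, X)
    if rotation == "none":
        L_rot, Phi = Lam, np.eye(q)
    elif rotation == "varimax":
        L_rot, _ = varimax(Lam)
        Phi = np.eye(q)
    elif rotation == "oblimin":
        L_rot, Phi, _ = oblimin(Lam)
    else:
        raise EFAError(f"unknown rotation {rotation!r}")
    return FactorModel(L_rot, psi, names, Phi=Phi, Lambda_unrotated=Lam,
                       loglik=ll, n_obs=n, converged=converged, n_iter=it,
                       rotation=rotation)


# ---------------------------------------------------------------------------
# rotations


def varimax(Lambda: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """Orthogonal varimax rotation; returns (rotated loadings, rotation R)."""
    L = np.asarray(Lambda, dtype=float).copy()
    t, q = L.shape
    R = np.eye(q)
    if q < 2:
        return L, R
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR ** 3 - LR @ np.diag(np.sum(LR ** 2, axis=0)) / t)
        )
        R = u @ vt
        new = s.sum()
        if new - var < tol * max(var, 1.0):
            break
        var = new
    return L @ R, R


def _quartimin(L: np.ndarray):
    L2 = L ** 2
    N = 1.0 - np.eye(L.shape[1])
    M = L2 @ N
    return float(np.sum(L2 * M)) / 4.0, L * M


def oblimin(Lambda: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """Oblique quartimin rotation by gradient projection.

    Returns (rotated loadings, factor correlation Phi, rotation T) with
    ``Lambda_rot = Lambda T'^{-1}`` and ``Phi = T'T``.
    """
    A = np.asarray(Lambda, dtype=float)
    q = A.shape[1]
    Tm = np.eye(q)
    if q < 2:
        return A.copy(), np.eye(q), Tm
    al = 1.0
    L = A @ np.linalg.inv(Tm).T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ np.linalg.inv(Tm)).T
    for _ in range(max_iter):
        Gp = G - Tm * np.sum(Tm * G, axis=0, keepdims=True)
        s = np.sqrt(np.sum(Gp ** 2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = Tm - al * Gp
            Tt = X / np.sqrt(np.sum(X ** 2, axis=0, keepdims=True))
            L = A @ np.linalg.inv(Tt).T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        Tm, f = Tt, ft
        G = -(L.T @ Gq @ np.linalg.inv(Tm)).T
    Phi = Tm.T @ Tm
    return A @ np.linalg.inv(Tm).T, Phi, Tm


# ---------------------------------------------------------------------------
# factor retention and structure


def parallel_analysis(T: pd.DataFrame, n_sims: int = 1000,
                      percentile: float = 95.0, seed=0) -> int:
    """Horn's parallel analysis: number of factors to retain.

    Leading eigenvalues of the observed correlation matrix are retained while
    each exceeds the given percentile of the corresponding (rank-matched)
    eigenvalue from ``n_sims`` simulated datasets of independent standard
    normals with the observed n and t; retention stops at the first
    non-exceedance.  Deterministic given the seed.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    X = np.asarray(standardize(pd.DataFrame(T)), dtype=float)
    n, t = X.shape
    obs = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))[::-1]
    rng = as_rng(seed)
    null = np.empty((n_sims, t))
    for b in range(n_sims):
        Z = rng.standard_normal((n, t))
        null[b] = np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False))[::-1]
    thresh = np.percentile(null, percentile, axis=0)
    q = 0
    for lam_obs, lam_null in zip(obs, thresh):
        if lam_obs > lam_null:
            q += 1
        else:
            break
    return q


def derive_structure(model: FactorModel,
                     labels: tuple[str, str] = ("difficult", "easy"),
                     anchor_traits: dict[str, str] | None = None
                     ) -> FactorStructure:
    """Read the cross-loading-free structure off a fitted two-factor model.

    Each trait joins the factor with the largest absolute loading (exact ties
    are an error — no silent tie-break).  Factors are labeled by which one
    carries each anchor trait (defaults: the temperament score anchors
    *difficult*, the "calm" attribute anchors *easy*), matching the convention
    that the *difficult* factor loads on the negative-behavior traits.
    """
    if anchor_traits is None:
        anchor_traits = {"difficult": "ts", "easy": "calm"}
        anchor_traits = {k: v for k, v in anchor_traits.items() if k in labels}
    L = np.abs(model.Lambda)
    if L.shape[1] != len(labels):
        raise EFAError(f"model has {L.shape[1]} factors; {len(labels)} labels given")
    col = np.argmax(L, axis=1)
    sorted_rows = np.sort(L, axis=1)
    ties = np.isclose(sorted_rows[:, -1], sorted_rows[:, -2]) if L.shape[1] > 1 else \
        np.zeros(L.shape[0], bool)
    if ties.any():
        tied = [model.trait_names[i] for i in np.flatnonzero(ties)]
        raise EFAError(f"tied absolute loadings for {tied}; assign manually")
    # map factor column -> label via the anchors
    col_label: dict[int, str] = {}
    for label, anchor in anchor_traits.items():
        if anchor not in model.trait_names:
            raise EFAError(f"anchor trait {anchor!r} not among the model's traits")
        c = int(col[model.trait_names.index(anchor)])
        if c in col_label:
            raise EFAError(
                f"anchors {col_label[c]!r} and {label!r} land on the same factor")
        col_label[c] = label
    if len(col_label) != len(labels):
        missing = [l for l in labels if l not in col_label.values()]
        raise EFAError(f"no anchor identifies factor(s) {missing}")
    assignment = {t: col_label[int(c)] for t, c in zip(model.trait_names, col)}
    return FactorStructure(assignment, list(labels),
                           {l: a for l, a in anchor_traits.items()})
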