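"""Bayesian confirmatory factor analysis by Gibbs sampling.

The confirmatory model keeps the cross-loading-free structure found in the
exploratory stage: each standardized subjective trait loads on exactly one of
the two latent factors (*difficult*, *easy*).  Factor scores are sampled by
data augmentation — treating the per-animal scores ``f_i`` as missing data
with the conditional

    f_i | theta, t_i ~ N( M Lambda' Psi^{-1} t_i , M ),
    M = (Lambda' Psi^{-1} Lambda + Phi^{-1})^{-1},

after which every parameter block has a conjugate update: free loadings by
normal regression on their factor's scores, specific variances by
inverse-gamma, and the factor covariance by inverse-Wishart.

Identification uses the marker method: the anchor trait of each factor has its
raw loading fixed at 1 while the factor covariance ``Phi`` is free.
Standardized loadings (the quantity conventionally reported) are computed per
draw as ``lambda * sd(factor) / sd(trait)`` with the model-implied trait SD,
so they are bounded by 1 in magnitude.  Because the marker loading is fixed
positive, factor sign and label switching cannot occur between draws.

Default priors (weakly informative): free loadings normal with mean 0 and
variance 100 (a stated precision of 0.01 — a variance of 0.01 would crush the
loadings reported for these traits toward zero), ``Phi ~ IW(I_q, 3)``,
``psi_j ~ IG(1, 0.5)``.  Default run length: 3 chains of 6,000 iterations with
the first 3,000 discarded.  Convergence is judged by the potential scale
reduction factor (PSRF < 1.2) over the monitored parameters: free loadings,
``Phi`` entries and specific variances (not the n x q factor scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efa import FactorStructure, standardize
from .mcmc import PosteriorSamples, inv_wishart_rvs, psrf, psrf_table
from .synthetic import as_rng, as_seed_sequence

__all__ = [
    "CFAPriors", "fit_bayesian_cfa", "extract_factor_scores",
    "standardize_loadings", "psrf", "psrf_table", "PosteriorSamples",
]

PSRF_THRESHOLD = 1.2


@dataclass(frozen=True)
class CFAPriors:
    """Priors of the Bayesian CFA.

    loading_variance : variance of the N(0, v) prior on free raw loadings
        (default 100, i.e. precision 0.01).
    phi_scale_identity, phi_df : inverse-Wishart prior IW(c I_q, df) on Phi.
    psi_shape, psi_scale : IG(shape, scale) prior on each specific variance.
    """

    loading_variance: float = 100.0
    phi_scale_identity: float = 1.0
    phi_df: float = 3.0
    psi_shape: float = 1.0
    psi_scale: float = 0.5

    def __post_init__(self) -> None:
        if min(self.loading_variance, self.phi_scale_identity,
               self.psi_shape, self.psi_scale) <= 0:
            raise ValueError("prior hyperparameters must be positive")


def _layout(structure: FactorStructure, trait_names: list[str]):
    """Factor column per trait, marker rows, and free-loading rows."""
    factors = list(structure.factor_labels)
    fcol = np.array([factors.index(structure.assignment[t]) for t in trait_names])
    markers = {f: structure.anchor_traits[f] for f in factors}
    marker_rows = {factors.index(f): trait_names.index(t) for f, t in markers.items()}
    free_rows = [j for j in range(len(trait_names)) if j not in marker_rows.values()]
    return factors, fcol, marker_rows, free_rows


def fit_bayesian_cfa(
    T: pd.DataFrame,
    structure: FactorStructure,
    priors: CFAPriors | None = None,
    n_chains: int = 3,
    n_iter: int = 6000,
    n_burnin: int = 3000,
    seed=0,
    store_factor_scores: bool = True,
) -> PosteriorSamples:
    """Gibbs sampler for the marker-identified confirmatory factor model.

    ``T`` is an (n, traits) table; it is standardized internally.  Each chain
    starts from overdispersed values drawn from its own substream.  Retained
    draws hold the free raw loadings, the ``Phi`` entries and the specific
    variances; running means of the factor scores are accumulated per chain
    (``extra["factor_score_mean"]``) instead of storing the n x q draws.
    """
    priors = priors or CFAPriors()
    if n_burnin >= n_iter:
        raise ValueError("n_burnin must be smaller than n_iter")
    T = standardize(pd.DataFrame(T)[list(structure.trait_names)])
    names = list(T.columns)
    X = np.asarray(T, dtype=float)
    n, t = X.shape
    factors, fcol, marker_rows, free_rows = _layout(structure, names)
    q = len(factors)
    onehot = np.zeros((t, q))
    onehot[np.arange(t), fcol] = 1.0

    param_names = (
        [f"lambda[{names[j]}]" for j in free_rows]
        + [f"phi[{factors[a]},{factors[b]}]" for a in range(q) for b in range(a, q)]
        + [f"psi[{names[j]}]" for j in range(t)]
    )
    phi_idx = [(a, b) for a in range(q) for b in range(a, q)]
    n_kept = n_iter - n_burnin
    draws = np.zeros((n_chains, n_kept, len(param_names)))
    fs_sum = np.zeros((n, q))

    root = as_seed_sequence(seed)
    for chain, ss in enumerate(root.spawn(n_chains)):
        rng = as_rng(ss)
        lam = np.ones(t)                       # raw loadings; markers stay 1
        lam[free_rows] = rng.normal(0.5, 0.5, size=len(free_rows))
        psi = rng.uniform(0.2, 1.0, size=t)
        Phi = np.eye(q)
        Lambda = onehot * lam[:, None]
        for it in range(n_iter):
            # (1) factor scores by data augmentation
            PsiInvL = Lambda / psi[:, None]                     # t x q
            M = np.linalg.inv(Lambda.T @ PsiInvL + np.linalg.inv(Phi))
            mean_F = X @ PsiInvL @ M.T
            F = mean_F + rng.standard_normal((n, q)) @ np.linalg.cholesky(M).T
            # (2) free loadings: scalar conjugate regression per trait
            ss_f = np.einsum("ij,ij->j", F, F)                  # per-factor f'f
            proj = X.T @ F                                       # t x q
            for j in free_rows:
                k = fcol[j]
                prec = ss_f[k] / psi[j] + 1.0 / priors.loading_variance
                mu = (proj[j, k] / psi[j]) / prec
                lam[j] = mu + rng.standard_normal() / np.sqrt(prec)
            Lambda = onehot * lam[:, None]
            # (3) specific variances
            resid = X - F[:, fcol] * lam[None, :]
            sse = np.einsum("ij,ij->j", resid, resid)
            psi = 1.0 / rng.gamma(priors.psi_shape + 0.5 * n,
                                  1.0 / (priors.psi_scale + 0.5 * sse))
            # (4) factor covariance
            Phi = inv_wishart_rvs(priors.phi_df + n,
                                  priors.phi_scale_identity * np.eye(q) + F.T @ F,
                                  rng)
            if it >= n_burnin:
                row = ([lam[j] for j in free_rows]
                       + [Phi[a, b] for a, b in phi_idx]
                       + list(psi))
                draws[chain, it - n_burnin] = row
                if store_factor_scores:
                    fs_sum += F

    extra = {
        "trait_names": names,
        "factors": factors,
        "factor_column": fcol,
        "free_rows": free_rows,
        "marker_rows": marker_rows,
        "structure": structure,
        "n_obs": n,
        "animal_index": list(T.index),
    }
    if store_factor_scores:
        extra["factor_score_mean"] = fs_sum / (n_kept * n_chains)
    return PosteriorSamples(draws, param_names, n_burnin, thin=1,
                            seed=seed if isinstance(seed, int) else None,
                            extra=extra)


def extract_factor_scores(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior-mean factor scores per animal, as new phenotypes.

    Averages the augmented-data draws of ``F`` over retained iterations and
    chains.  Columns are the factor labels (*difficult*, *easy*); the row
    index carries the animal identifiers of the input table.
    """
    if "factor_score_mean" not in samples.extra:
        raise ValueError("samples were run without store_factor_scores")
    return pd.DataFrame(samples.extra["factor_score_mean"],
                        columns=samples.extra["factors"],
                        index=samples.extra["animal_index"])


def standardize_loadings(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior table of standardized loadings, one row per (factor, trait).

    Per draw, the standardized loading of trait j on its factor k is
    ``lambda_j * sd(F_k) / sd(T_j)`` with ``sd(F_k) = sqrt(Phi_kk)`` and the
    model-implied ``sd(T_j) = sqrt(lambda_j^2 Phi_kk + psi_j)``; the table
    reports the posterior mean and SD.  Marker traits (raw loading 1) are
    included.
    """
    names = samples.extra["trait_names"]
    factors = samples.extra["factors"]
    fcol = samples.extra["factor_column"]
    free_rows = set(samples.extra["free_rows"])
    pooled = samples.draws.reshape(-1, samples.draws.shape[2])
    col = {p: i for i, p in enumerate(samples.parameter_names)}
    rows = []
    for j, trait in enumerate(names):
        k = fcol[j]
        lam = (pooled[:, col[f"lambda[{trait}]"]] if j in free_rows
               else np.ones(pooled.shape[0]))
        phi_kk = pooled[:, col[f"phi[{factors[k]},{factors[k]}]"]]
        psi_j = pooled[:, col[f"psi[{trait}]"]]
        std = lam * np.sqrt(phi_kk) / np.sqrt(lam ** 2 * phi_kk + psi_j)
        rows.append({"factor": factors[k], "trait": trait,
                     "loading": float(std.mean()),
                     "posterior_sd": float(std.std(ddof=1))})
    return pd.DataFrame(rows)


def monitored_psrf(samples: PosteriorSamples) -> pd.Series:
    """PSRF for every monitored parameter (loadings, Phi, Psi)."""
    return psrf_table(samples)
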