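"""Shared MCMC machinery: draw container, convergence and interval summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with chain structure.

    ``draws`` has shape (n_chains, n_kept, n_parameters); burn-in is already
    excluded and thinning already applied, so every summary runs on retained
    draws only.  ``extra`` carries sampler-specific side products (e.g. running
    posterior means of latent quantities too large to store per draw).
    """

    draws: np.ndarray
    parameter_names: list[str]
    n_burnin: int
    thin: int = 1
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names length mismatch")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """(chains, iterations) draws of one parameter."""
        return self.draws[:, :, self.parameter_names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.parameter(name).reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior mean and SD per parameter over all chains."""
        pooled = self.draws.reshape(-1, self.draws.shape[2])
        return pd.DataFrame(
            {"mean": pooled.mean(axis=0), "sd": pooled.std(axis=0, ddof=1)},
            index=self.parameter_names,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat (chain, iteration, parameters...) table of the retained draws."""
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.parameter_names)
            df.insert(0, "iteration", np.arange(self.n_kept))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def psrf(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """Potential scale reduction factor (Gelman–Rubin, Brooks–Gelman form).

    With m chains of n retained draws, W the mean within-chain variance and
    B/n the variance of the chain means, the statistic is
    ``sqrt((n-1)/n + B/(n W))``.  Values near 1 indicate the chains sample the
    same distribution; the conventional acceptance threshold here is 1.2.
    """
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required with a PosteriorSamples input")
        chains = samples.parameter(parameter)
    else:
        chains = np.asarray(samples, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected a (chains, iterations) array")
    m, n = chains.shape
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    if n < 2:
        raise ValueError("PSRF requires at least 2 retained draws per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return float(np.sqrt((n - 1) / n)) if B_over_n == 0.0 else np.inf
    return float(np.sqrt((n - 1) / n + B_over_n / W))


def psrf_table(samples: PosteriorSamples,
               parameters: list[str] | None = None) -> pd.Series:
    """PSRF per monitored parameter."""
    names = parameters if parameters is not None else samples.parameter_names
    return pd.Series({p: psrf(samples, p) for p in names}, name="psrf")


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` posterior mass (sorted-window).

    Sorts the draws and slides a window of ``ceil(prob * n)`` draws, returning
    the shortest.  A fixed effect is called significant when this interval
    excludes zero.
    """
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    k = int(np.ceil(prob * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def inv_wishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from the inverse-Wishart IW(scale, df) via Bartlett decomposition.

    If ``W ~ Wishart(df, scale^{-1})`` then ``W^{-1} ~ IW(scale, df)``.
    Requires ``df >= dim``.
    """
    scale = np.atleast_2d(scale)
    p = scale.shape[0]
    if df < p:
        raise ValueError("inverse-Wishart degrees of freedom must be >= dimension")
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    idx = np.tril_indices(p, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    LA = L @ A
    W = LA @ LA.T
    out = np.linalg.inv(W)
    return 0.5 * (out + out.T)
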