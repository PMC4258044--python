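"""Noninformative-Bayes posterior and HPD interval for ICC_b.

The model is the same additive two-way random-effects likelihood used by the
frequentist methods.  The prior is flat on the location ``mu`` and flat on
the three standard deviations (an improper prior, proportional to 1 on
``sigma_b, sigma_l, sigma_e > 0``).  Among common noninformative choices
this prior does not concentrate the induced ICC prior at {0, 1} and leaves
the ICC posterior invariant to rescaling the data.

Sampling is by Gibbs with conjugate blocks: subject effects, rater effects
and ``mu`` have normal full conditionals; under the flat-on-sigma prior each
variance has an inverse-gamma full conditional with shape (n - 1)/2 and rate
S/2 for ``n`` effects with sum of squares ``S``.  The sampler runs many
chains simultaneously as stacked arrays, which the simulation harness uses
to fit thousands of datasets in one pass.

With only 2 levels of a factor the variance conditional has shape 1/2 and
the posterior is barely proper; a warning is emitted for fewer than 3 rater
levels (small-group caution for flat priors on group-level scales).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .design import DataGrid
from .results import IntervalResult

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "fit_posterior",
    "hpd_interval",
    "sample_rho_chains",
]

_ESS_FLOOR = 100.0


@dataclass(frozen=True)
class PriorSpec:
    """Prior family tag; only the uniform-on-standard-deviations prior is supported."""

    family: str = "uniform_sd"

    def __post_init__(self) -> None:
        if self.family != "uniform_sd":
            raise ValueError(f"unsupported prior family: {self.family!r}")


@dataclass
class PosteriorSample:
    """Retained posterior draws for (mu, sigma_b, sigma_l, sigma_e) and rho_b."""

    mu: np.ndarray
    sigma_b: np.ndarray
    sigma_l: np.ndarray
    sigma_e: np.ndarray
    rho_b: np.ndarray
    n_iter: int
    burnin: int
    thin: int
    seed: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rho_b) < 1000:
            raise ValueError("fewer than 1000 retained draws")
        if np.any(self.sigma_b <= 0) or np.any(self.sigma_l <= 0) or np.any(self.sigma_e <= 0):
            raise ValueError("non-positive sigma draw retained")
        if np.any((self.rho_b <= 0) | (self.rho_b >= 1)):
            raise ValueError("rho_b draw outside (0, 1)")


def sample_rho_chains(
    y_stack: np.ndarray,
    n_iter: int,
    burnin: int,
    thin: int,
    rng: np.random.Generator,
    keep_params: bool = False,
) -> dict[str, np.ndarray]:
    """Gibbs-sample ICC_b posteriors for a stack of datasets.

    ``y_stack`` has shape (n_chains, b0, l0, r0); one independent chain per
    dataset, all advanced together with vectorized conditional updates.
    Returns retained draws of shape (n_chains, n_kept) for ``rho`` and, when
    ``keep_params`` is set, for the model parameters as well.
    """
    y = np.asarray(y_stack, dtype=float)
    if y.ndim == 3:
        y = y[..., None]
    n_chains, b0, l0, r0 = y.shape
    n_obs = b0 * l0 * r0
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")

    mu = y.mean(axis=(1, 2, 3)).reshape(-1, 1, 1, 1)
    b_eff = np.zeros((n_chains, b0, 1, 1))
    l_eff = np.zeros((n_chains, 1, l0, 1))
    s2b = np.ones((n_chains, 1, 1, 1))
    s2l = np.ones((n_chains, 1, 1, 1))
    s2e = np.ones((n_chains, 1, 1, 1))

    kept_rho: list[np.ndarray] = []
    kept_params: list[np.ndarray] = []
    for it in range(n_iter):
        resid = y - mu - l_eff
        prec = 1.0 / s2b + (l0 * r0) / s2e
        mean = (resid.sum(axis=(2, 3), keepdims=True) / s2e) / prec
        b_eff = mean + rng.standard_normal((n_chains, b0, 1, 1)) / np.sqrt(prec)

        resid = y - mu - b_eff
        prec = 1.0 / s2l + (b0 * r0) / s2e
        mean = (resid.sum(axis=(1, 3), keepdims=True) / s2e) / prec
        l_eff = mean + rng.standard_normal((n_chains, 1, l0, 1)) / np.sqrt(prec)

        centered = y - b_eff - l_eff
        mu = centered.mean(axis=(1, 2, 3)).reshape(-1, 1, 1, 1) + rng.standard_normal(
            (n_chains, 1, 1, 1)
        ) * np.sqrt(s2e / n_obs)

        ss = np.sum(b_eff**2, axis=1, keepdims=True)
        s2b = 0.5 * ss / rng.gamma((b0 - 1) / 2.0, 1.0, (n_chains, 1, 1, 1))
        ss = np.sum(l_eff**2, axis=2, keepdims=True)
        s2l = 0.5 * ss / rng.gamma((l0 - 1) / 2.0, 1.0, (n_chains, 1, 1, 1))
        ss = np.sum((centered - mu) ** 2, axis=(1, 2, 3)).reshape(-1, 1, 1, 1)
        s2e = 0.5 * ss / rng.gamma((n_obs - 1) / 2.0, 1.0, (n_chains, 1, 1, 1))

        if it >= burnin and (it - burnin) % thin == 0:
            rho = s2b / (s2b + s2l + s2e)
            kept_rho.append(rho.reshape(n_chains).copy())
            if keep_params:
                kept_params.append(
                    np.stack(
                        [
                            mu.reshape(n_chains),
                            np.sqrt(s2b).reshape(n_chains),
                            np.sqrt(s2l).reshape(n_chains),
                            np.sqrt(s2e).reshape(n_chains),
                        ],
                        axis=1,
                    )
                )

    out = {"rho": np.array(kept_rho).T}
    if keep_params:
        params = np.array(kept_params)  # (n_kept, n_chains, 4)
        out["mu"] = params[:, :, 0].T
        out["sigma_b"] = params[:, :, 1].T
        out["sigma_l"] = params[:, :, 2].T
        out["sigma_e"] = params[:, :, 3].T
    return out


def fit_posterior(
    grid: DataGrid,
    prior: PriorSpec | None = None,
    n_iter: int = 100_000,
    burnin: int = 10_000,
    thin: int = 10,
    seed: int = 0,
) -> PosteriorSample:
    """Posterior sample of (mu, sigma_b, sigma_l, sigma_e, rho_b) for one grid.

    Defaults (100k iterations, 10k burn-in, thin 10) suit a single-dataset
    analysis; the simulation harness uses a shorter schedule.  The effective
    sample size of the rho chain is estimated and a convergence warning is
    recorded in ``meta`` (and emitted) when it falls below 100.
    """
    prior = prior or PriorSpec()
    if grid.design.l0 < 3:
        warnings.warn(
            "fewer than 3 rater/lab levels: the flat-on-sigma posterior is "
            "barely proper and rater-variance inference is unreliable",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = sample_rho_chains(
        grid.values[None, ...], n_iter, burnin, thin, rng, keep_params=True
    )
    rho = draws["rho"][0]
    if not np.all(np.isfinite(rho)):
        raise FloatingPointError("non-finite values in posterior chain")
    meta: dict[str, Any] = {"prior": prior.family}
    try:
        import arviz

        ess = float(arviz.ess(np.asarray(rho)[None, :]))
    except Exception:  # pragma: no cover - ess estimation is advisory
        ess = float(len(rho))
    meta["ess_rho"] = ess
    if ess < _ESS_FLOOR:
        meta["convergence_warning"] = f"rho effective sample size {ess:.0f} < {_ESS_FLOOR:.0f}"
        warnings.warn(meta["convergence_warning"], UserWarning, stacklevel=2)
    return PosteriorSample(
        mu=draws["mu"][0],
        sigma_b=draws["sigma_b"][0],
        sigma_l=draws["sigma_l"][0],
        sigma_e=draws["sigma_e"][0],
        rho_b=rho,
        n_iter=n_iter,
        burnin=burnin,
        thin=thin,
        seed=seed,
        meta=meta,
    )


def hpd_from_draws(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest window containing ceil(level * n) sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(level * n))
    k = max(1, min(k, n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def hpd_interval(
    sample: PosteriorSample | np.ndarray,
    level: float = 0.95,
    allow_small: bool = False,
) -> IntervalResult:
    """Highest-posterior-density interval for rho_b from posterior draws.

    The HPD window is never wider than the equal-tailed interval on the same
    draws.  ``allow_small`` overrides the 1000-draw floor (useful for tests
    on tiny hand-built samples).
    """
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must be in (0, 1], got {level}")
    if isinstance(sample, PosteriorSample):
        draws = sample.rho_b
        meta: dict[str, Any] = {
            "n_iter": sample.n_iter,
            "burnin": sample.burnin,
            "thin": sample.thin,
            "seed": sample.seed,
        }
    else:
        draws = np.asarray(sample, dtype=float)
        meta = {}
    if len(draws) == 0:
        raise ValueError("empty sample")
    if len(draws) < 1000 and not allow_small:
        raise ValueError("fewer than 1000 draws; pass allow_small=True to override")
    lo, hi = hpd_from_draws(draws, level)
    return IntervalResult(
        method="bayes",
        level=level,
        lower=max(0.0, lo),
        upper=min(1.0, hi),
        meta=meta,
    )


def equal_tailed_interval(
    sample: PosteriorSample | np.ndarray, level: float = 0.95
) -> IntervalResult:
    """Equal-tailed credible interval on the same draws (offered for comparison)."""
    draws = sample.rho_b if isinstance(sample, PosteriorSample) else np.asarray(sample)
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2, 1.0 - alpha / 2])
    return IntervalResult(
        method="bayes",
        level=level,
        lower=float(max(0.0, lo)),
        upper=float(min(1.0, hi)),
        meta={"flavor": "equal_tailed"},
    )
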