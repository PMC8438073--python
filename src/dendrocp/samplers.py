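"""Shared MCMC machinery.

The change-point models are sampled with an affine-invariant ensemble sampler
(emcee) on an unconstrained-or-bounded parameter vector; variance parameters
ride on the log scale with the Jacobian folded into the log-posterior.
Convergence is summarized with rank-normalized split R-hat treating walkers
as chains (arviz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnsembleResult", "run_ensemble", "rhat_from_walkers", "dic"]


@dataclass
class EnsembleResult:
    """Posterior draws from one ensemble run.

    chain has shape (n_kept_steps, n_walkers, ndim); ``flat`` flattens the
    first two axes. log_prob matches chain's leading axes.
    """

    chain: np.ndarray
    log_prob: np.ndarray
    acceptance: float
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    @property
    def flat_log_prob(self) -> np.ndarray:
        return self.log_prob.reshape(-1)


def run_ensemble(
    log_prob,
    p0: np.ndarray,
    *,
    n_steps: int,
    n_burn: int,
    thin: int = 1,
    seed: int | None = None,
    vectorize: bool = False,
    param_names: list[str] | None = None,
) -> EnsembleResult:
    """Run emcee from initial walker positions ``p0`` (n_walkers, ndim).

    All walkers must start at finite log-probability. Draw order is fully
    deterministic given ``seed``.
    """
    import emcee

    p0 = np.asarray(p0, dtype=float)
    n_walkers, ndim = p0.shape
    lp0 = (
        log_prob(p0)
        if vectorize
        else np.array([log_prob(p) for p in p0])
    )
    if not np.all(np.isfinite(lp0)):
        bad = int(np.sum(~np.isfinite(lp0)))
        raise ValueError(f"{bad} walker(s) start at non-finite log-probability")

    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob, vectorize=vectorize, moves=moves
    )
    rng_state = np.random.RandomState(seed if seed is not None else 0).get_state()
    sampler.random_state = rng_state
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sampler.run_mcmc(p0, n_burn + n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, thin=thin)  # (steps, walkers, ndim)
    log_p = sampler.get_log_prob(discard=n_burn, thin=thin)
    result = EnsembleResult(
        chain=chain,
        log_prob=log_p,
        acceptance=float(np.mean(sampler.acceptance_fraction)),
    )
    if param_names is not None:
        result.rhat = rhat_from_walkers(chain, param_names)
    return result


def rhat_from_walkers(chain: np.ndarray, names: list[str]) -> dict[str, float]:
    """Rank-normalized split R-hat per parameter, walkers treated as chains."""
    import arviz as az

    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            arr = chain[:, :, j].T  # (chains, draws)
            out[name] = float(az.rhat(arr.copy()))
    return out


def split_rhat_single_chain(draws: np.ndarray, n_splits: int = 4) -> float:
    """Split R-hat for a single chain of draws (1-D), via arviz."""
    import arviz as az

    n = (len(draws) // n_splits) * n_splits
    arr = draws[:n].reshape(n_splits, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr.copy()))


def dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """Deviance information criterion.

    DIC = Dbar + pD with the classic effective-parameter count
    pD = Dbar - D(posterior mean). Returns (DIC, pD).
    """
    dbar = float(np.mean(deviance_draws))
    p_d = dbar - float(deviance_at_mean)
    return dbar + p_d, p_d
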