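"""Posterior sampling and model-comparison machinery shared by all model modules.

The sampler is an adaptive random-walk Metropolis algorithm run as several
independent chains (vectorised across chains).  Proposal scale and covariance
adapt during burn-in (Haario-style) and are frozen afterwards, so retained
draws come from a fixed Markov kernel.  Models with Bernoulli inclusion
indicators (variable selection) add Metropolis flip moves for the indicator
block after each continuous update.

Convergence diagnostics (split R-hat, effective sample size) and PSIS-LOO
model comparison are delegated to :mod:`arviz`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "LooResult",
    "retained_draws",
    "sample",
    "rhat",
    "ess",
    "psis_loo",
    "compare_loo",
    "posterior_mass_above",
    "bayes_factor_from_indicator",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative description of a posterior for :func:`sample`.

    Parameters are a flat unconstrained vector of length ``n_params``;
    ``names`` maps slices of that vector to named blocks (e.g. variance
    parameters are sampled on the log scale and the model's ``transform``
    is responsible for mapping back).

    Attributes
    ----------
    log_post:
        Vectorised log posterior density: maps an array of shape
        ``(m, n_params)`` to ``(m,)``.  Must return ``-inf`` (not raise)
        for invalid states.
    names:
        Mapping block name -> (start, stop) slice into the vector.
    init:
        Callable ``rng -> (n_params,)`` initial vector.
    pointwise_loglik:
        Optional vectorised map ``(m, n_params) -> (m, n_obs)`` of
        per-observation log likelihood, recorded for PSIS-LOO.
    indicator_slice:
        Optional (start, stop) marking components that are 0/1 inclusion
        indicators, updated by flip moves instead of the random walk.
    heredity_parents:
        For each indicator (local index), the local indices of the parent
        indicators that must all be 1 before it may switch on.  Empty list
        for main effects.
    """

    log_post: Callable[[np.ndarray], np.ndarray]
    n_params: int
    names: dict[str, tuple[int, int]]
    init: Callable[[np.random.Generator], np.ndarray]
    pointwise_loglik: Callable[[np.ndarray], np.ndarray] | None = None
    indicator_slice: tuple[int, int] | None = None
    heredity_parents: dict[int, list[int]] = field(default_factory=dict)


class PosteriorDraws:
    """MCMC output: named parameter arrays indexed ``(chain, draw)``.

    ``params[name]`` has shape ``(n_chains, n_draws)`` for scalar blocks and
    ``(n_chains, n_draws, k)`` for vector blocks.  ``pointwise_loglik``, when
    present, has shape ``(n_chains, n_draws, n_obs)``.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        pointwise_loglik: np.ndarray | None = None,
        accept_rate: float | None = None,
        meta: dict | None = None,
    ):
        self.meta = meta or {}
        shapes = {k: v.shape[:2] for k, v in params.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"inconsistent (chain, draw) shapes: {shapes}")
        self.params = params
        self.n_chains, self.n_draws = first
        self.pointwise_loglik = pointwise_loglik
        self.accept_rate = accept_rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def flat(self, name: str) -> np.ndarray:
        """Draws of ``name`` pooled over chains: shape (chain*draw, ...)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def n_retained(self) -> int:
        return self.n_chains * self.n_draws

    def to_frame(self):
        """One row per chain x draw, columns per scalar component (CSV persistence)."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {}
        ch, dr = np.meshgrid(
            np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij"
        )
        cols["chain"], cols["draw"] = ch.ravel(), dr.ravel()
        for name, v in self.params.items():
            if v.ndim == 2:
                cols[name] = v.reshape(-1)
            else:
                for k in range(v.shape[2]):
                    cols[f"{name}[{k}]"] = v[:, :, k].reshape(-1)
        return pd.DataFrame(cols)


@dataclass
class LooResult:
    """PSIS-LOO summary: ``looic = -2 * elpd``."""

    looic: float
    elpd: float
    se: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.looic, -2.0 * self.elpd):
            raise ValueError("looic must equal -2 * elpd")


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def retained_draws(chains: int, iters: int, burn_in: int, thin: int) -> int:
    """Total retained posterior draws for a chains/iters/burn-in/thin schedule."""
    if not (iters > burn_in >= 0):
        raise ValueError("require iters > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return chains * ((iters - burn_in) // thin)


def sample(
    model_spec: ModelSpec,
    chains: int = 3,
    iters: int = 50_000,
    burn_in: int = 40_000,
    thin: int = 10,
    seed: int = 0,
    target_accept: float = 0.25,
) -> PosteriorDraws:
    """Draw from a posterior with adaptive random-walk Metropolis chains.

    Retains ``chains * (iters - burn_in) // thin`` draws.  All chains are
    advanced together (vectorised), each with its own adapted scale; the
    proposal covariance is estimated from burn-in history and frozen at the
    end of burn-in.

    Raises
    ------
    ValueError
        If the schedule is invalid or the log posterior is non-finite at
        initialisation (the offending chain is named).
    """
    kept_per_chain = retained_draws(1, iters, burn_in, thin)
    rng = np.random.default_rng(seed)
    d = model_spec.n_params

    x = np.stack([model_spec.init(rng) for _ in range(chains)])  # (C, d)
    lp = model_spec.log_post(x)
    if not np.all(np.isfinite(lp)):
        bad = int(np.flatnonzero(~np.isfinite(lp))[0])
        raise ValueError(
            f"non-finite log posterior at initialisation of chain {bad}; "
            f"check data validity and initial values"
        )

    ind = model_spec.indicator_slice
    if ind is not None:
        i0, i1 = ind
        cont_idx = np.r_[np.arange(0, i0), np.arange(i1, d)]
        n_ind = i1 - i0
    else:
        cont_idx = np.arange(d)
        n_ind = 0
    dc = len(cont_idx)

    log_scale = np.full(chains, np.log(2.38 / np.sqrt(max(dc, 1))))
    chol = np.eye(dc)
    # burn-in history for covariance adaptation (refreshed periodically,
    # pooled across chains; frozen at the end of burn-in)
    hist = np.empty((chains, burn_in, dc)) if burn_in > 0 and dc > 0 else None
    adapt_every = max(200, burn_in // 8)

    keep = np.empty((chains, kept_per_chain, d))
    n_acc = 0
    n_prop = 0
    kidx = 0

    for t in range(iters):
        if dc > 0:
            z = rng.standard_normal((chains, dc))
            step = (z @ chol.T) * np.exp(log_scale)[:, None]
            xp = x.copy()
            xp[:, cont_idx] += step
            lpp = model_spec.log_post(xp)
            log_u = np.log(rng.random(chains))
            acc = log_u < (lpp - lp)
            x[acc] = xp[acc]
            lp[acc] = lpp[acc]
            n_acc += int(acc.sum())
            n_prop += chains
            if t < burn_in:
                # Robbins-Monro on the log step size toward target acceptance
                g = max(t + 1, 10) ** -0.6
                log_scale += g * (acc.astype(float) - target_accept)
                if hist is not None:
                    hist[:, t] = x[:, cont_idx]
                    if (t + 1) % adapt_every == 0 and t + 1 >= 400:
                        h = hist[:, (t + 1) // 2 : t + 1].reshape(-1, dc)
                        cov = np.atleast_2d(np.cov(h.T)) + 1e-9 * np.eye(dc)
                        try:
                            chol = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass

        if n_ind > 0:
            x, lp = _flip_indicators(model_spec, x, lp, rng)

        if t >= burn_in and (t - burn_in) % thin == 0:
            keep[:, kidx] = x
            kidx += 1

    params = {
        name: _squeeze_block(keep[:, :, a:b]) for name, (a, b) in model_spec.names.items()
    }
    pw = None
    if model_spec.pointwise_loglik is not None:
        flat = keep.reshape(chains * kept_per_chain, d)
        pw = model_spec.pointwise_loglik(flat).reshape(chains, kept_per_chain, -1)
    return PosteriorDraws(params, pw, accept_rate=n_acc / max(n_prop, 1))


def _squeeze_block(arr: np.ndarray) -> np.ndarray:
    return arr[:, :, 0] if arr.shape[2] == 1 else arr


def _flip_indicators(
    spec: ModelSpec, x: np.ndarray, lp: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One Metropolis flip sweep over the indicator block.

    Only heredity-valid flips are proposed: an indicator with parents may
    switch on only when all parents are 1, and a parent may switch off only
    when none of its children are 1.  The move set is symmetric, so plain
    Metropolis acceptance applies.
    """
    i0, i1 = spec.indicator_slice
    n_ind = i1 - i0
    children: dict[int, list[int]] = {}
    for child, parents in spec.heredity_parents.items():
        for p in parents:
            children.setdefault(p, []).append(child)

    for j in rng.permutation(n_ind):
        cur = x[:, i0 + j]
        proposed_on = cur < 0.5
        ok = np.ones(x.shape[0], dtype=bool)
        parents = spec.heredity_parents.get(int(j), [])
        if parents:
            par_on = np.all(x[:, [i0 + p for p in parents]] > 0.5, axis=1)
            ok &= np.where(proposed_on, par_on, True)
        for c in children.get(int(j), []):
            ok &= np.where(~proposed_on, x[:, i0 + c] < 0.5, True)
        if not ok.any():
            continue
        xp = x.copy()
        xp[:, i0 + j] = 1.0 - cur
        lpp = spec.log_post(xp)
        acc = ok & (np.log(rng.random(x.shape[0])) < (lpp - lp))
        x[acc] = xp[acc]
        lp[acc] = lpp[acc]
    return x, lp


# --------------------------------------------------------------------------
# diagnostics & comparison
# --------------------------------------------------------------------------


def _to_idata(draws: PosteriorDraws, include_loglik: bool = False):
    import arviz as az

    post = {k: v for k, v in draws.params.items()}
    kwargs = {}
    if include_loglik:
        if draws.pointwise_loglik is None:
            raise ValueError("PosteriorDraws has no pointwise log likelihood")
        kwargs["log_likelihood"] = {"obs": draws.pointwise_loglik}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.from_dict(posterior=post, **kwargs)


def rhat(draws: PosteriorDraws, flag_threshold: float = 1.1) -> dict[str, float]:
    """Split R-hat per parameter block (max over vector components).

    Emits a warning naming every block whose R-hat exceeds ``flag_threshold``.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(_to_idata(draws))
    out = {k: float(np.max(rh[k].values)) for k in draws.params}
    bad = {k: v for k, v in out.items() if v > flag_threshold}
    if bad:
        warnings.warn(f"R-hat above {flag_threshold}: {bad}", stacklevel=2)
    return out


def ess(draws: PosteriorDraws) -> dict[str, float]:
    """Bulk effective sample size per parameter block (min over components)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        e = az.ess(_to_idata(draws))
    return {k: float(np.min(e[k].values)) for k in draws.params}


def psis_loo(draws: PosteriorDraws) -> LooResult:
    """PSIS-LOO expected log predictive density and LOOIC.

    Requires the pointwise log likelihood recorded at sampling time.
    """
    import arviz as az

    if draws.pointwise_loglik is None:
        raise ValueError(
            "pointwise log likelihood missing; refit with a model_spec that "
            "declares observations"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.loo(_to_idata(draws, include_loglik=True), pointwise=True)
    elpd = float(r.elpd_loo)
    return LooResult(
        looic=-2.0 * elpd,
        elpd=elpd,
        se=float(r.se),
        pointwise_elpd=np.asarray(r.loo_i),
        pareto_k=np.asarray(r.pareto_k),
    )


def compare_loo(results: dict, tie_break: Sequence | None = None):
    """Rank models by LOOIC ascending; ties go to the earliest key in
    ``tie_break`` order (or insertion order).  Returns (best_key, table)."""
    import pandas as pd

    if not results:
        raise ValueError("no models to compare")
    order = list(tie_break) if tie_break is not None else list(results)
    rows = [
        {"model": k, "looic": results[k].looic, "elpd": results[k].elpd, "se": results[k].se}
        for k in order
    ]
    tab = pd.DataFrame(rows).sort_values("looic", kind="stable").reset_index(drop=True)
    return tab.loc[0, "model"], tab


def posterior_mass_above(draws: np.ndarray, threshold: float) -> float:
    """Fraction of draws strictly above ``threshold`` (one-sided evidence mass)."""
    arr = np.asarray(draws).ravel()
    if arr.size == 0:
        raise ValueError("empty draws")
    return float(np.mean(arr > threshold))


def bayes_factor_from_indicator(posterior_inclusion: float, prior_inclusion: float) -> float:
    """Bayes factor for a term from its posterior vs prior inclusion probability.

    BF = (posterior odds) / (prior odds).  Probabilities of exactly 0 or 1
    give infinite odds; report a bound from the Monte-Carlo resolution
    (e.g. inclusion > 1 - 1/n_draws) instead of calling this.
    """
    for name, p in (("posterior", posterior_inclusion), ("prior", prior_inclusion)):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"{name} inclusion probability must lie strictly in (0, 1); "
                f"got {p}. For saturated indicators report a bound such as "
                f"BF > odds(1 - 1/n_draws)/odds(prior)."
            )
    post_odds = posterior_inclusion / (1.0 - posterior_inclusion)
    prior_odds = prior_inclusion / (1.0 - prior_inclusion)
    return post_odds / prior_odds
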