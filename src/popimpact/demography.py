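"""Two-stage (control -> impact) Bayesian vital-rate models.

The centrepiece is a shared-frailty discrete-interval survival model.  At
control sites the unit hazard for age ``a``, site ``i``, year ``j`` and
interval ``k`` is

    UH = exp(sum_c beta_c X_c + psi_a + Z_k + Gamma_i + Lambda_j)

with per-interval baseline log hazards ``Z_k``, an age offset ``psi``
(adult is the reference class), and zero-centred site and year varying
effects whose standard deviations are estimated.  At impact (development)
sites, a predicted log unit hazard is built from the *concurrently sampled*
control-stage parameters and the covariates measured at the impact sites —
excluding the site effect, whose mean is zero at control sites — and the
impact covariates enter on top of it:

    LUH_P = sum_c beta_c X_c* + psi_a* + Z_k* + Lambda_j*
    UH_G  = exp(LUH_P + sum_g delta_g X_g + Omega_i)

Both likelihoods are evaluated inside one posterior, so the full
uncertainty in the confounder effects propagates into ``delta``.  An event
in interval ``k`` contributes ``1 - exp(-UH_k)``; every interval survived
(including censored tails) contributes ``exp(-UH_k)``; cumulative hazard
and the survival function follow as ``CH = sum UH`` and ``S = exp(-CH)``.

The same two-stage pattern, on the logit scale, covers the binary vital
rates (renest propensity: Bernoulli; hatchability and chick survival:
Binomial), and a single-likelihood Poisson log-link model covers clutch
size.  Nest survival uses the hazard machinery at daily intervals with a
hen frailty integrated out by Gauss-Hermite quadrature.  Unobserved life
stages are supplied as informative prior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mcmc
from .mcmc import ModelSpec, PosteriorDraws
from .selection import SelectionPrior

__all__ = [
    "SurvivalCurve",
    "survival_curve",
    "validate_histories",
    "fit_control_survival",
    "fit_impact_survival",
    "fit_binary_vital",
    "fit_clutch_size",
    "fit_nest_survival",
    "informative_prior_stage",
    "annual_survival_draws",
    "predicted_probability",
]

_OMEGA_SD = 2.5     # weakly-informative prior sd for impact-site constants
_CONF_SD = 10.0     # "non-informative" prior sd for confounder coefficients
_SD_HN = 2.0        # half-Normal scale for varying-effect sd priors


# --------------------------------------------------------------------------
# survival curves
# --------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Cumulative hazard and survival probability by interval."""

    ch: np.ndarray
    s: np.ndarray


def survival_curve(unit_hazards: np.ndarray) -> SurvivalCurve:
    """``CH_k = sum(UH_1..k)`` and ``S_k = exp(-CH_k)`` along the last axis."""
    uh = np.asarray(unit_hazards, dtype=float)
    if np.any(uh < 0):
        raise ValueError("unit hazards must be nonnegative")
    ch = np.cumsum(uh, axis=-1)
    return SurvivalCurve(ch=ch, s=np.exp(-ch))


# --------------------------------------------------------------------------
# encounter-history preparation
# --------------------------------------------------------------------------


def validate_histories(df: pd.DataFrame) -> None:
    required = {"individual_id", "site_id", "year", "interval", "age_class", "status",
                "is_control_site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"encounter histories missing columns: {sorted(missing)}")
    bad = set(df["status"].unique()) - {"alive", "dead", "censored"}
    if bad:
        raise ValueError(f"unknown status values: {bad}")
    cov = [c for c in df.columns if c.startswith(("x_c", "x_g"))]
    if cov and not np.all(np.isfinite(df[cov].to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")
    for ind, grp in df.groupby("individual_id", sort=False):
        ks = grp["interval"].to_numpy()
        if not np.array_equal(ks, np.arange(ks[0], ks[0] + len(ks))):
            raise ValueError(f"intervals not contiguous for {ind!r}")
        terminal = grp["status"].isin(["dead", "censored"])
        if terminal.sum() != 1 or not terminal.iloc[-1]:
            raise ValueError(f"{ind!r} must end in exactly one dead/censored state")


@dataclass
class _SurvDesign:
    """Row-level design for the joint hazard likelihood (rows sorted by
    individual, so pointwise terms aggregate with reduceat)."""

    event: np.ndarray
    X_main: np.ndarray          # all non-selection columns
    X_delta: np.ndarray         # impact covariate columns (zero on control rows)
    blocks: dict[str, tuple[int, int]]   # block name -> slice into theta
    col_blocks: dict[str, tuple[int, int]]  # block name -> slice into X_main cols
    ind_starts: np.ndarray
    n_ind: int
    n_delta: int
    meta: dict


def _build_survival_design(
    df: pd.DataFrame,
    include_impact: bool,
    match_year_effects: bool = True,
    baseline: str = "per_interval",
) -> _SurvDesign:
    df = df.sort_values(["individual_id", "interval"], kind="stable").reset_index(drop=True)
    n = len(df)
    event = (df["status"] == "dead").to_numpy(dtype=float)
    control = df["is_control_site"].to_numpy(dtype=bool)
    if include_impact and control.all():
        raise ValueError("no impact-site records present")
    if not control.any():
        raise ValueError("control-stage fit requires control-site records")
    if event[control].sum() == 0:
        warnings.warn("no events at control sites; baseline hazard unidentified", stacklevel=3)

    xc_cols = sorted(c for c in df.columns if c.startswith("x_c"))
    xg_cols = sorted(c for c in df.columns if c.startswith("x_g"))
    Xc = df[xc_cols].to_numpy(dtype=float) if xc_cols else np.zeros((n, 0))
    Xg = df[xg_cols].to_numpy(dtype=float) if xg_cols else np.zeros((n, 0))
    Xg = np.where(control[:, None], 0.0, Xg)

    yearling = (df["age_class"] == "yearling").to_numpy(dtype=float)
    intervals = np.sort(df["interval"].unique())
    k_idx = np.searchsorted(intervals, df["interval"].to_numpy())
    K = len(intervals) if baseline == "per_interval" else 1
    years = np.sort(df["year"].unique())
    j_idx = np.searchsorted(years, df["year"].to_numpy())
    csites = np.sort(df.loc[control, "site_id"].unique())
    gsites = np.sort(df.loc[~control, "site_id"].unique()) if include_impact else np.array([])

    cols: list[np.ndarray] = []
    col_blocks: dict[str, tuple[int, int]] = {}

    def add(name, mat):
        a = sum(c.shape[1] for c in cols)
        cols.append(mat)
        col_blocks[name] = (a, a + mat.shape[1])

    if xc_cols:
        add("beta_c", Xc)
    add("psi", yearling[:, None])
    Zmat = np.zeros((n, K))
    Zmat[np.arange(n), k_idx if K > 1 else 0] = 1.0
    add("z", Zmat)
    Gmat = np.zeros((n, len(csites)))
    crow = np.flatnonzero(control)
    Gmat[crow, np.searchsorted(csites, df.loc[control, "site_id"])] = 1.0
    add("gamma", Gmat)  # impact rows: excluded (mean control-site effect is zero)
    Jmat = np.zeros((n, len(years)))
    Jmat[np.arange(n), j_idx] = 1.0
    if not match_year_effects:
        Jmat[~control] = 0.0
    add("lam", Jmat)
    if include_impact and len(gsites):
        Omat = np.zeros((n, len(gsites)))
        grow = np.flatnonzero(~control)
        Omat[grow, np.searchsorted(gsites, df.loc[~control, "site_id"])] = 1.0
        add("omega", Omat)

    X_main = np.concatenate(cols, axis=1)
    n_delta = Xg.shape[1] if include_impact else 0
    X_delta = Xg[:, :n_delta] if n_delta else np.zeros((n, 0))

    # theta layout: X_main blocks, then the two log-sd hypers, then delta
    blocks = dict(col_blocks)
    d = X_main.shape[1]
    blocks["log_sigma_gamma"] = (d, d + 1)
    blocks["log_sigma_lambda"] = (d + 1, d + 2)
    if n_delta:
        blocks["delta"] = (d + 2, d + 2 + n_delta)

    ids = df["individual_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    return _SurvDesign(
        event=event, X_main=X_main, X_delta=X_delta, blocks=blocks,
        col_blocks=col_blocks, ind_starts=starts, n_ind=len(starts),
        n_delta=n_delta,
        meta={"intervals": intervals, "years": years, "control_sites": csites,
              "impact_sites": gsites, "xc_cols": xc_cols, "xg_cols": xg_cols,
              "individuals": ids[starts]},
    )


def _hazard_rows_loglik(lp: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Row log likelihood from log unit hazard: events 1-exp(-UH), survived
    intervals exp(-UH)."""
    uh = np.exp(np.clip(lp, -500, 30))
    with np.errstate(divide="ignore"):
        log_pdie = np.log(-np.expm1(-uh))
    return np.where(event > 0.5, log_pdie, -uh)


def _make_survival_spec(des: _SurvDesign, selection: SelectionPrior | None) -> ModelSpec:
    d_main = des.X_main.shape[1]
    d = d_main + 2 + des.n_delta
    use_ind = selection is not None and selection.mode == "indicator" and des.n_delta > 0
    n_ind = des.n_delta if use_ind else 0
    d_tot = d + n_ind
    cb = des.col_blocks
    blocks = dict(des.blocks)
    if use_ind:
        blocks["inclusion"] = (d, d + n_ind)

    g0, g1 = cb["gamma"]
    l0, l1 = cb["lam"]
    dl0 = d_main + 2
    has_bc = "beta_c" in cb

    def log_post(theta):
        theta = np.atleast_2d(theta)
        main = theta[:, :d_main]
        lp = main @ des.X_main.T
        if des.n_delta:
            delta = theta[:, dl0 : dl0 + des.n_delta]
            if use_ind:
                delta = delta * theta[:, d : d + n_ind]
            lp = lp + delta @ des.X_delta.T
        ll = _hazard_rows_loglik(lp, des.event).sum(axis=1)
        return ll + _survival_log_prior(theta, des, selection, use_ind)

    def pointwise(theta):
        theta = np.atleast_2d(theta)
        main = theta[:, :d_main]
        lp = main @ des.X_main.T
        if des.n_delta:
            delta = theta[:, dl0 : dl0 + des.n_delta]
            if use_ind:
                delta = delta * theta[:, d : d + n_ind]
            lp = lp + delta @ des.X_delta.T
        rows = _hazard_rows_loglik(lp, des.event)
        return np.add.reduceat(rows, des.ind_starts, axis=1)

    def init(rng):
        x = np.zeros(d_tot)
        z0, z1 = cb["z"]
        x[z0:z1] = np.log(0.02) + rng.normal(0, 0.2, z1 - z0)
        if has_bc:
            b0, b1 = cb["beta_c"]
            x[b0:b1] = rng.normal(0, 0.1, b1 - b0)
        x[d_main] = x[d_main + 1] = np.log(0.2) + rng.normal(0, 0.2)
        if use_ind:
            x[d : d + n_ind] = 1.0
        return x

    def heredity():
        if not use_ind or selection.heredity != "strong" or selection.terms is None:
            return {}
        return selection.terms.parent_map()

    return ModelSpec(
        log_post=log_post, n_params=d_tot, names=blocks, init=init,
        pointwise_loglik=pointwise,
        indicator_slice=(d, d + n_ind) if use_ind else None,
        heredity_parents=heredity(),
    )


def _survival_log_prior(theta, des: _SurvDesign, selection, use_ind) -> np.ndarray:
    cb = des.col_blocks
    d_main = des.X_main.shape[1]
    lp = np.zeros(theta.shape[0])
    if "beta_c" in cb:
        a, b = cb["beta_c"]
        lp += -0.5 * np.sum(theta[:, a:b] ** 2, axis=1) / _CONF_SD**2
    for name in ("psi", "z"):
        a, b = cb[name]
        lp += -0.5 * np.sum(theta[:, a:b] ** 2, axis=1) / _CONF_SD**2
    for name, hyper in (("gamma", d_main), ("lam", d_main + 1)):
        a, b = cb[name]
        log_sd = theta[:, hyper]
        sd = np.exp(log_sd)
        lp += -0.5 * np.sum(theta[:, a:b] ** 2, axis=1) / np.maximum(sd**2, 1e-300)
        lp += -(b - a) * log_sd
        lp += -0.5 * (sd / _SD_HN) ** 2 + log_sd  # half-Normal + Jacobian
    if "omega" in cb:
        a, b = cb["omega"]
        lp += -0.5 * np.sum(theta[:, a:b] ** 2, axis=1) / _OMEGA_SD**2
    if des.n_delta:
        a = d_main + 2
        delta = theta[:, a : a + des.n_delta]
        if selection is None:
            lp += -0.5 * np.sum(delta**2, axis=1) / _CONF_SD**2
        elif selection.mode == "indicator":
            lp += -0.5 * np.sum(delta**2, axis=1) / selection.slab_sd**2
            if use_ind:
                ind = theta[:, a + des.n_delta : a + 2 * des.n_delta]
                lp += selection.indicator_log_prior(ind)
        elif selection.mode == "lasso":
            # Laplace(0, tau) with tau ~ Uniform(0, 10), tau marginalised on a grid
            lp += selection.lasso_log_prior(delta)
    return lp


def fit_control_survival(
    histories: pd.DataFrame,
    chains: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
    interval_scale: str = "month",
    baseline: str = "per_interval",
) -> PosteriorDraws:
    """Stage-1 shared-frailty survival fit on control-site records only.

    Requires records from at least 2 control sites and 2 years.  Flags a
    dataset with no events (hazard unidentified).  ``interval_scale`` is
    documentation of the interval unit; the likelihood is per-interval
    either way.
    """
    validate_histories(histories)
    ctrl = histories[histories["is_control_site"]].copy()
    if ctrl["site_id"].nunique() < 2 or ctrl["year"].nunique() < 2:
        raise ValueError("control stage needs >= 2 sites and >= 2 years")
    des = _build_survival_design(ctrl, include_impact=False, baseline=baseline)
    spec = _make_survival_spec(des, selection=None)
    draws = mcmc.sample(spec, chains=chains, iters=iters, burn_in=burn_in, thin=thin, seed=seed)
    draws.meta = des.meta
    return draws


def fit_impact_survival(
    histories: pd.DataFrame,
    chains: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
    selection: SelectionPrior | None = None,
    fixed_control: dict[str, np.ndarray] | None = None,
    match_year_effects: bool = True,
    baseline: str = "per_interval",
) -> PosteriorDraws:
    """Joint two-stage survival fit: control and impact likelihoods sampled
    concurrently, so confounder uncertainty propagates into ``delta``.

    ``selection`` applies a Bayesian Lasso or indicator-selection prior to
    the impact coefficients.  ``fixed_control`` (block name -> values)
    freezes the control-stage parameters at given values instead of
    sampling them — used to quantify the uncertainty the two-stage scheme
    propagates; it is not the recommended analysis path.

    Warns when impact-site confounder covariates fall outside the observed
    control-site range (extrapolation of the baseline prediction).
    """
    validate_histories(histories)
    control = histories["is_control_site"]
    xc_cols = sorted(c for c in histories.columns if c.startswith("x_c"))
    for c in xc_cols:
        lo, hi = histories.loc[control, c].min(), histories.loc[control, c].max()
        out = ((histories.loc[~control, c] < lo) | (histories.loc[~control, c] > hi)).mean()
        if out > 0.0005:
            warnings.warn(
                f"{out:.2%} of impact-site values of {c!r} outside the control range; "
                f"baseline predictions extrapolate", stacklevel=2,
            )
    des = _build_survival_design(
        histories, include_impact=True,
        match_year_effects=match_year_effects, baseline=baseline,
    )
    spec = _make_survival_spec(des, selection)
    if fixed_control is not None:
        spec = _freeze_blocks(spec, des, fixed_control)
    draws = mcmc.sample(spec, chains=chains, iters=iters, burn_in=burn_in, thin=thin, seed=seed)
    draws.meta = des.meta
    return draws


def _freeze_blocks(spec: ModelSpec, des: _SurvDesign, fixed: dict[str, np.ndarray]) -> ModelSpec:
    """Wrap a spec so the named blocks stay constant (plug-in control fit)."""
    const = np.zeros(spec.n_params)
    frozen = np.zeros(spec.n_params, dtype=bool)
    for name, vals in fixed.items():
        a, b = spec.names[name]
        const[a:b] = np.asarray(vals, dtype=float).ravel()
        frozen[a:b] = True
    free = np.flatnonzero(~frozen)
    remap = {}
    pos = 0
    for name, (a, b) in spec.names.items():
        if frozen[a]:
            continue
        remap[name] = (pos, pos + (b - a))
        pos += b - a

    def embed(theta):
        theta = np.atleast_2d(theta)
        full = np.tile(const, (theta.shape[0], 1))
        full[:, free] = theta
        return full

    ind = None
    if spec.indicator_slice is not None:
        i0, i1 = spec.indicator_slice
        if not frozen[i0]:
            j0 = int(np.searchsorted(free, i0))
            ind = (j0, j0 + (i1 - i0))

    return ModelSpec(
        log_post=lambda th: spec.log_post(embed(th)),
        n_params=len(free),
        names=remap,
        init=lambda rng: spec.init(rng)[free],
        pointwise_loglik=(
            (lambda th: spec.pointwise_loglik(embed(th)))
            if spec.pointwise_loglik else None
        ),
        indicator_slice=ind,
        heredity_parents=spec.heredity_parents,
    )


# --------------------------------------------------------------------------
# binary vital rates (renest, hatchability, chick survival)
# --------------------------------------------------------------------------


def fit_binary_vital(
    records: pd.DataFrame,
    family: str = "bernoulli",
    chains: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
    selection: SelectionPrior | None = None,
) -> PosteriorDraws:
    """Two-stage logit model for a binary vital rate.

    ``records`` needs columns ``y`` (successes; 0/1 for bernoulli),
    ``n`` (trials; binomial only), confounders ``x_c*``, impact covariates
    ``x_g*`` and ``is_control_site``/``site_id``.  The control stage is an
    intercept + confounder GLM; at impact sites the per-record baseline
    logit ``P`` (control parameters at local covariates) is combined with
    the impact terms: ``logit p = P + delta . X_g + Omega_i``.
    """
    if family not in ("bernoulli", "binomial"):
        raise ValueError("family must be 'bernoulli' or 'binomial'")
    df = records.reset_index(drop=True)
    y = df["y"].to_numpy(dtype=float)
    if family == "binomial":
        ntr = df["n"].to_numpy(dtype=float)
        if np.any(y > ntr) or np.any(y < 0):
            raise ValueError("need 0 <= y <= n")
    else:
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("bernoulli y must be 0/1")
        ntr = np.ones_like(y)

    control = df["is_control_site"].to_numpy(dtype=bool)
    xc_cols = sorted(c for c in df.columns if c.startswith("x_c"))
    xg_cols = sorted(c for c in df.columns if c.startswith("x_g"))
    Xc = df[xc_cols].to_numpy(dtype=float) if xc_cols else np.zeros((len(df), 0))
    Xg = df[xg_cols].to_numpy(dtype=float) if xg_cols else np.zeros((len(df), 0))
    Xg = np.where(control[:, None], 0.0, Xg)
    gsites = np.sort(df.loc[~control, "site_id"].unique()) if (~control).any() else np.array([])
    Omat = np.zeros((len(df), len(gsites)))
    if len(gsites):
        grow = np.flatnonzero(~control)
        Omat[grow, np.searchsorted(gsites, df.loc[~control, "site_id"])] = 1.0

    X_main = np.concatenate([np.ones((len(df), 1)), Xc, Omat], axis=1)
    nC, nG, nO = Xc.shape[1], Xg.shape[1], Omat.shape[1]
    d_main = X_main.shape[1]
    use_ind = selection is not None and selection.mode == "indicator" and nG > 0
    d = d_main + nG + (nG if use_ind else 0)

    def _lp(theta):
        theta = np.atleast_2d(theta)
        lp = theta[:, :d_main] @ X_main.T
        if nG:
            delta = theta[:, d_main : d_main + nG]
            if use_ind:
                delta = delta * theta[:, d_main + nG : d_main + 2 * nG]
            lp = lp + delta @ Xg.T
        return lp

    def _rows(theta):
        lp = _lp(theta)
        return y * lp - ntr * np.log1p(np.exp(np.clip(lp, -500, 500)))

    def log_post(theta):
        theta = np.atleast_2d(theta)
        ll = _rows(theta).sum(axis=1)
        prior = -0.5 * theta[:, 0] ** 2 / _CONF_SD**2
        if nC:
            prior += -0.5 * np.sum(theta[:, 1 : 1 + nC] ** 2, axis=1) / _CONF_SD**2
        if nO:
            prior += -0.5 * np.sum(theta[:, 1 + nC : d_main] ** 2, axis=1) / _OMEGA_SD**2
        if nG:
            delta = theta[:, d_main : d_main + nG]
            if selection is None:
                prior += -0.5 * np.sum(delta**2, axis=1) / _CONF_SD**2
            elif selection.mode == "indicator":
                prior += -0.5 * np.sum(delta**2, axis=1) / selection.slab_sd**2
                if use_ind:
                    prior += selection.indicator_log_prior(
                        theta[:, d_main + nG : d_main + 2 * nG]
                    )
            else:
                prior += selection.lasso_log_prior(delta)
        return ll + prior

    names = {"intercept": (0, 1)}
    if nC:
        names["beta_c"] = (1, 1 + nC)
    if nO:
        names["omega"] = (1 + nC, d_main)
    if nG:
        names["delta"] = (d_main, d_main + nG)
    if use_ind:
        names["inclusion"] = (d_main + nG, d)

    def init(rng):
        x = rng.normal(0, 0.3, size=d)
        if use_ind:
            x[d_main + nG :] = 1.0
        return x

    spec = ModelSpec(
        log_post=log_post, n_params=d, names=names, init=init,
        pointwise_loglik=_rows,
        indicator_slice=(d_main + nG, d) if use_ind else None,
        heredity_parents=(
            selection.terms.parent_map()
            if use_ind and selection.heredity == "strong" and selection.terms
            else {}
        ),
    )
    draws = mcmc.sample(spec, chains=chains, iters=iters, burn_in=burn_in, thin=thin, seed=seed)
    draws.meta = {"xc_cols": xc_cols, "xg_cols": xg_cols, "impact_sites": gsites}
    return draws


def predicted_probability(draws: PosteriorDraws, x_c=None, x_g=None, site: int | None = None):
    """Per-draw success probability at given covariates (zeros by default);
    ``logit p = intercept + beta_c.x_c [+ delta.x_g + omega_site]``."""
    lp = draws.flat("intercept").copy()
    if "beta_c" in draws and x_c is not None:
        lp = lp + draws.flat("beta_c") @ np.asarray(x_c, dtype=float)
    if "delta" in draws and x_g is not None:
        delta = draws.flat("delta")
        if delta.ndim == 1:
            delta = delta[:, None]
        if "inclusion" in draws:
            inc = draws.flat("inclusion")
            delta = delta * (inc if inc.ndim == 2 else inc[:, None])
        lp = lp + delta @ np.asarray(x_g, dtype=float)
    if "omega" in draws and site is not None:
        om = draws.flat("omega")
        lp = lp + (om[:, site] if om.ndim == 2 else om)
    return 1.0 / (1.0 + np.exp(-lp))


# --------------------------------------------------------------------------
# clutch size (single likelihood, Poisson log link)
# --------------------------------------------------------------------------


def fit_clutch_size(
    clutch_records: pd.DataFrame,
    chains: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
) -> PosteriorDraws:
    """Poisson log-link model of clutch size with age and nest-attempt
    effects: ``log N_cs = psi_age + T_attempt`` (first attempt is the
    reference for T).  Needs columns clutch_size, age_class, attempt.

    All-zero counts are fitted (posterior near zero) and flagged.
    """
    y = clutch_records["clutch_size"].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("clutch sizes must be nonnegative")
    if y.sum() == 0:
        warnings.warn("all clutch sizes are zero; expected clutch near 0", stacklevel=2)
    adult = (clutch_records["age_class"] == "adult").to_numpy(dtype=float)
    second = (clutch_records["attempt"].to_numpy(dtype=int) >= 2).astype(float)
    X = np.column_stack([1.0 - adult, adult, second])  # psi_yearling, psi_adult, T2

    def log_post(theta):
        theta = np.atleast_2d(theta)
        lp = theta @ X.T
        ll = np.sum(y * lp - np.exp(np.clip(lp, -500, 30)), axis=1)
        return ll + (-0.5 * np.sum(theta**2, axis=1) / _CONF_SD**2)

    def pointwise(theta):
        theta = np.atleast_2d(theta)
        lp = theta @ X.T
        from scipy.special import gammaln

        return y * lp - np.exp(np.clip(lp, -500, 30)) - gammaln(y + 1.0)

    spec = ModelSpec(
        log_post=log_post, n_params=3,
        names={"clutch_psi": (0, 2), "clutch_t2": (2, 3)},
        init=lambda rng: np.r_[np.log(y.mean() + 0.5) + rng.normal(0, 0.1, 2),
                               rng.normal(0, 0.1)],
        pointwise_loglik=pointwise,
    )
    return mcmc.sample(spec, chains=chains, iters=iters, burn_in=burn_in, thin=thin, seed=seed)


def expected_clutch(draws: PosteriorDraws, age: str, attempt: int) -> np.ndarray:
    """Per-draw expected clutch size ``exp(psi_age + T_attempt)``."""
    psi = draws.flat("clutch_psi")
    t2 = draws.flat("clutch_t2")
    lp = psi[:, 1 if age == "adult" else 0] + (t2 if attempt >= 2 else 0.0)
    return np.exp(lp)


# --------------------------------------------------------------------------
# nest survival (daily intervals, hen frailty by quadrature)
# --------------------------------------------------------------------------


def fit_nest_survival(
    nests: pd.DataFrame,
    nest_days: int,
    chains: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
    n_quad: int = 15,
) -> PosteriorDraws:
    """Daily-interval nest survival with a hen frailty.

    Constant daily baseline log hazard plus a nest-attempt effect and
    optional ``x_c*``/``x_g*`` covariate columns; the hen-level Normal
    frailty is integrated out with Gauss-Hermite quadrature, so hens
    monitored at several nests share one random effect.  Columns required:
    nest_id, hen_id, attempt, exposure_days, fate {hatched, failed}.
    """
    df = nests.sort_values(["hen_id", "nest_id"], kind="stable").reset_index(drop=True)
    failed = (df["fate"] == "failed").to_numpy(dtype=float)
    expo = df["exposure_days"].to_numpy(dtype=float)
    if np.any(expo < 1) or np.any(expo > nest_days):
        raise ValueError("exposure_days must lie in [1, nest_days]")
    second = (df["attempt"].to_numpy(dtype=int) >= 2).astype(float)
    xc_cols = sorted(c for c in df.columns if c.startswith("x_c"))
    Xc = df[xc_cols].to_numpy(dtype=float) if xc_cols else np.zeros((len(df), 0))
    X = np.column_stack([np.ones(len(df)), second, Xc])
    dX = X.shape[1]
    d = dX + 1  # + log sigma_hen

    hens = df["hen_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, hens[1:] != hens[:-1]])
    # probabilists' Gauss-Hermite: weights sum to sqrt(2*pi), normalise
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(wts / wts.sum())

    def _hen_loglik(theta):
        theta = np.atleast_2d(theta)
        m = theta.shape[0]
        lp = theta[:, :dX] @ X.T  # (m, n)
        sd = np.exp(theta[:, dX])[:, None, None]
        z = lp[:, :, None] + sd * nodes[None, None, :]  # (m, n, Q)
        uh = np.exp(np.clip(z, -500, 30))
        with np.errstate(divide="ignore"):
            ll_nest = np.where(
                failed[None, :, None] > 0.5,
                -(expo[None, :, None] - 1.0) * uh + np.log(-np.expm1(-uh)),
                -expo[None, :, None] * uh,
            )
        per_hen = np.add.reduceat(ll_nest, starts, axis=1)  # (m, H, Q)
        from scipy.special import logsumexp

        return logsumexp(per_hen + log_w[None, None, :], axis=2)  # (m, H)

    def log_post(theta):
        theta = np.atleast_2d(theta)
        ll = _hen_loglik(theta).sum(axis=1)
        prior = -0.5 * np.sum(theta[:, :dX] ** 2, axis=1) / _CONF_SD**2
        sd = np.exp(theta[:, dX])
        prior += -0.5 * (sd / _SD_HN) ** 2 + theta[:, dX]
        return ll + prior

    spec = ModelSpec(
        log_post=log_post, n_params=d,
        names={"nest_lp": (0, dX), "log_sigma_hen": (dX, d)},
        init=lambda rng: np.r_[np.log(0.02) + rng.normal(0, 0.2),
                               rng.normal(0, 0.1, dX - 1),
                               np.log(0.2) + rng.normal(0, 0.2)],
        pointwise_loglik=_hen_loglik,
    )
    draws = mcmc.sample(spec, chains=chains, iters=iters, burn_in=burn_in, thin=thin, seed=seed)
    draws.meta = {"nest_days": nest_days, "lp_cols": ["intercept", "attempt2", *xc_cols]}
    return draws


def nest_survival_draws(draws: PosteriorDraws, attempt: int = 1) -> np.ndarray:
    """Per-draw probability a nest survives the full laying+incubation span."""
    lp = draws.flat("nest_lp")
    nd = draws.meta["nest_days"]
    z = lp[:, 0] + (lp[:, 1] if attempt >= 2 else 0.0)
    return np.exp(-nd * np.exp(z))


# --------------------------------------------------------------------------
# unobserved life stages, derived quantities
# --------------------------------------------------------------------------


def informative_prior_stage(
    name: str, prior_spec: dict, n_draws: int, seed: int = 0
) -> np.ndarray:
    """Independent draws for a life stage specified by an informative prior.

    ``prior_spec``: {"family": "beta"|"point"|"uniform"|"normal", ...}.
    Probability-type stages must have support within [0, 1]; draw counts are
    matched to the other posteriors so the stages compose in the matrix
    model.
    """
    rng = np.random.default_rng(seed)
    fam = prior_spec["family"]
    is_prob = prior_spec.get("is_probability", True)
    if fam == "beta":
        out = rng.beta(prior_spec["a"], prior_spec["b"], size=n_draws)
    elif fam == "point":
        v = float(prior_spec["value"])
        if is_prob and not 0.0 <= v <= 1.0:
            raise ValueError(f"point prior for probability stage {name!r} outside [0,1]")
        out = np.full(n_draws, v)
    elif fam == "uniform":
        lo, hi = prior_spec["low"], prior_spec["high"]
        if is_prob and (lo < 0 or hi > 1):
            raise ValueError(f"uniform prior for probability stage {name!r} outside [0,1]")
        out = rng.uniform(lo, hi, size=n_draws)
    elif fam == "normal":
        if is_prob:
            raise ValueError(
                f"unbounded normal prior invalid for probability stage {name!r}; "
                f"use beta or a truncated spec"
            )
        out = rng.normal(prior_spec["mu"], prior_spec["sd"], size=n_draws)
    else:
        raise ValueError(f"unknown prior family {fam!r}")
    return out


def annual_survival_draws(
    draws: PosteriorDraws,
    age: str = "adult",
    x_c=None,
    extra_lp: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Per-draw annual survival from a fitted hazard model: the unit hazards
    over all intervals at the given covariates are accumulated and
    ``S = exp(-CH)``.  ``extra_lp`` adds impact terms (delta.x_g + omega)
    on the log-hazard scale."""
    z = draws.flat("z")
    if z.ndim == 1:
        z = z[:, None]
    lp = z.copy()
    if age == "yearling":
        lp = lp + draws.flat("psi").reshape(-1, 1)
    if x_c is not None and "beta_c" in draws:
        lp = lp + (draws.flat("beta_c") @ np.asarray(x_c, dtype=float))[:, None]
    lp = lp + np.asarray(extra_lp, dtype=float).reshape(-1, 1) if np.ndim(extra_lp) else lp + extra_lp
    uh = np.exp(lp)
    return np.exp(-uh.sum(axis=1))
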