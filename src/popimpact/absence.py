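"""BACI analysis of population-node absence rates.

Counts are subset to the final two years of the before and after periods;
a node is scored absent within a period iff both retained years have a zero
count (the second year confirms the first — any second-year activity scores
presence).  Absence probability ``A`` is then estimated per BACI cell with
a Bernoulli GLM (logit link, cell-means parameterisation), and the same
BACI ratio / CI statistics used for growth rates are applied to ``A``.

Because an increased absence rate after impact drives the ratio in the
opposite direction from a decreased growth rate, the ratio is exposed
exactly as defined and both one-sided posterior masses are reported; see
the package methods note for a worked direction example.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import mcmc
from .growth import CELLS, BACIStatistics, ZoneAssignment, baci_ratio, validate_lek_table
from .mcmc import ModelSpec, PosteriorDraws

__all__ = [
    "subset_final_two_years",
    "score_absence",
    "fit_absence_glm",
    "baci_ratio_absence",
]


def subset_final_two_years(
    table: pd.DataFrame,
    before_years: tuple[int, int],
    after_years: tuple[int, int],
) -> pd.DataFrame:
    """Retain only the four specified years (two per period).

    Leks lacking any data in a period after subsetting are flagged with a
    warning (they are dropped later by :func:`score_absence`).
    """
    validate_lek_table(table)
    for pair, period in ((before_years, "before"), (after_years, "after")):
        if len(pair) != 2:
            raise ValueError(f"{period}_years must be a pair")
        in_period = set(table.loc[table["period"] == period, "year"])
        if not set(pair) <= in_period:
            raise ValueError(f"{period}_years {pair} not within the {period} period")
    keep = set(before_years) | set(after_years)
    out = table[table["year"].isin(keep)].copy()
    for lek, grp in out.groupby("lek_id"):
        for period in ("before", "after"):
            if (grp["period"] == period).sum() == 0:
                warnings.warn(f"lek {lek!r} has no retained {period}-period data", stacklevel=2)
    return out


def score_absence(subset: pd.DataFrame, zone: ZoneAssignment) -> pd.DataFrame:
    """Binary absence per lek-period, joined with the zone into BACI cells.

    absent = 1 iff both retained years in the period have count 0.  Leks
    missing one of the two years in a period are excluded from that period
    with a warning.  Returns columns: lek_id, group (BACI cell), absent.
    """
    rows = []
    for (lek, period), grp in subset.groupby(["lek_id", "period"]):
        if len(grp) != 2:
            warnings.warn(
                f"lek {lek!r} lacks both retained years in the {period} period; excluded",
                stacklevel=2,
            )
            continue
        if lek not in zone.groups:
            raise ValueError(f"lek {lek!r} missing from zone assignment")
        absent = int((grp["max_count"] == 0).all())
        cell = f"{period}_{zone.groups[lek]}"
        rows.append({"lek_id": lek, "group": cell, "absent": absent})
    return pd.DataFrame(rows, columns=["lek_id", "group", "absent"]).sort_values(
        ["group", "lek_id"], ignore_index=True
    )


def fit_absence_glm(
    table: pd.DataFrame,
    chains: int = 3,
    iters: int = 4000,
    burn_in: int = 2000,
    thin: int = 1,
    seed: int = 0,
    prior_sd: float = 1.5,
) -> PosteriorDraws:
    """Cell-means Bayesian logistic model of absence.

    One logit-scale intercept per BACI cell with a Normal(0, prior_sd^2)
    prior; ``A_cell = logit^-1(intercept)`` is recorded per draw, along
    with the pointwise Bernoulli log likelihood for PSIS-LOO.  Cells where
    every outcome is identical are fitted under the prior regularisation
    and flagged.
    """
    if table.empty:
        raise ValueError("empty absence table")
    bad = set(table["group"].unique()) - set(CELLS)
    if bad:
        raise ValueError(f"unknown BACI cells: {bad}")
    for cell in CELLS:
        sub = table.loc[table["group"] == cell, "absent"]
        if sub.empty:
            raise ValueError(f"BACI cell {cell!r} has no leks")
        if sub.nunique() == 1:
            warnings.warn(
                f"cell {cell!r} has all-identical outcomes ({sub.iloc[0]}); "
                f"estimate relies on the prior",
                stacklevel=2,
            )

    cell_idx = np.array([CELLS.index(g) for g in table["group"]])
    y = table["absent"].to_numpy(dtype=float)

    def log_post(theta):
        theta = np.atleast_2d(theta)
        lp = theta[:, cell_idx]  # (m, n)
        ll = np.sum(y * lp - np.log1p(np.exp(lp)), axis=1)
        prior = -0.5 * np.sum(theta**2, axis=1) / prior_sd**2
        return ll + prior

    def pointwise(theta):
        theta = np.atleast_2d(theta)
        lp = theta[:, cell_idx]
        return y * lp - np.log1p(np.exp(lp))

    spec = ModelSpec(
        log_post=log_post,
        n_params=4,
        names={"logit_A": (0, 4)},
        init=lambda rng: rng.normal(0.0, 0.5, size=4),
        pointwise_loglik=pointwise,
    )
    return mcmc.sample(spec, chains=chains, iters=iters, burn_in=burn_in, thin=thin, seed=seed)


def absence_probabilities(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Per-draw absence probability A per BACI cell."""
    logit = draws.flat("logit_A")
    return {cell: 1.0 / (1.0 + np.exp(-logit[:, k])) for k, cell in enumerate(CELLS)}


def baci_ratio_absence(a: dict[str, np.ndarray]) -> tuple[BACIStatistics, float]:
    """BACI statistics on absence probability A.

    Returns the statistics (ratio defined exactly as for growth) together
    with the opposite-side posterior mass ``P(R < 1)``, since the direction
    evidencing impact depends on which side of 1 increased absence drives
    the ratio to.
    """
    stats = baci_ratio(a)
    mass_below = mcmc.posterior_mass_above(-stats.r_baci, -1.0)
    return stats, mass_below
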