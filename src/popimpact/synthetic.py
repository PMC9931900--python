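"""Synthetic study-system generators.

Every input the analysis pipeline consumes can be produced here with known
ground-truth parameters: annual maximum lek counts around an energy
development (state-space generative model), individual encounter histories
(piecewise-constant hazards with site/year frailties and impact covariates),
reproduction records (renest propensity, clutch size, hatchability, chick
counts, daily nest survival), a synthetic landscape (DEM, abundance index,
infrastructure and candidate points), and binned point-count predator
surveys with half-normal detection.

All generators are deterministic under ``SimConfig.seed``; each uses an
independent substream so adding one output never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import PointSet, RasterGrid

__all__ = [
    "SimConfig",
    "simulate_lek_counts",
    "simulate_encounter_histories",
    "simulate_reproduction",
    "simulate_landscape",
    "simulate_raven_surveys",
]


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic study system.

    The defaults mirror the study design the framework targets: 14 years of
    lek surveys split 7 before / 7 after the onset of development, leks
    spread over a 60-km universe around the infrastructure, monthly survival
    intervals over a biological year, and point-count surveys truncated at
    1.125 km with five distance bins.
    """

    seed: int = 0

    # --- lek-count state-space truth (growth-rate analysis) ---
    n_leks: int = 103
    n_years_before: int = 7
    n_years_after: int = 7
    # mean growth by BACI cell: (before-control, before-impact, after-control, after-impact)
    true_beta_tp: tuple[float, float, float, float] = (0.0, 0.0, 0.0, -0.2)
    sigma_obs: float = 0.2
    sigma_r: float = 0.1
    sigma_alpha: float = 0.05   # lek-level variation in mean growth
    sigma_eta: float = 0.05     # year-level variation in mean growth
    true_impact_km: float = 10.0
    max_distance_km: float = 60.0
    log_n0_mean: float = float(np.log(25.0))
    log_n0_sd: float = 0.5

    # --- survival truth (demographic analysis) ---
    n_individuals: int = 400
    n_control_sites: int = 6
    n_impact_sites: int = 2
    n_demog_years: int = 4
    n_intervals: int = 12                      # monthly intervals per year
    true_beta_C: tuple[float, ...] = (0.5, -0.5)
    true_delta_G: tuple[float, ...] = (-0.6,)  # effect on log hazard of the impact covariate
    true_omega: float = 0.0                    # impact-site constant effect
    baseline_hazards: tuple[float, ...] = (0.04,) * 12  # ~0.62 annual survival
    true_psi_age: tuple[float, float] = (0.2, 0.0)  # yearling, adult log-hazard offsets
    sigma_site: float = 0.2
    sigma_year: float = 0.15
    censor_rate: float = 0.02                  # per-interval random right-censoring

    # --- reproduction truth ---
    n_hens: int = 300
    renest_logit: float = -0.4                 # propensity to renest after a failed first nest
    clutch_log_mean: tuple[float, float] = (float(np.log(8.0)), float(np.log(6.5)))
    clutch_age_effect: float = 0.05            # adult minus yearling on the log scale
    hatch_p: float = 0.9
    chick_p: float = 0.35
    nest_days: int = 38
    nest_daily_hazard: float = 0.02

    # --- landscape truth ---
    # 1000 x 1000 cells at 30 m = a 30 x 30 km window, so the 4-km candidate
    # clustering and 2/5/10-km ranking buffers operate at their real scales
    raster_shape: tuple[int, int] = (1000, 1000)
    cell_size_m: float = 30.0
    dem_plane: tuple[float, float, float] = (1500.0, 0.02, -0.01)  # base, d/dx, d/dy
    dem_bumps: tuple[tuple[float, float, float, float], ...] = (
        (300.0, 400.0, 120.0, 80.0),  # (row, col, amplitude_m, width_cells)
    )
    n_candidates: int = 25
    candidate_cluster_km: float = 1.0

    # --- predator-survey truth ---
    detection_sigma0: float = 400.0            # half-normal scale, metres
    raven_density: float = 2.0                 # birds per km^2
    n_surveys: int = 500
    survey_radius_m: float = 1125.0
    bin_cuts_m: tuple[float, ...] = (225.0, 450.0, 675.0, 900.0, 1125.0)
    detection_covariate_effects: tuple[float, ...] = (0.0, 0.0)  # on log sigma

    def __post_init__(self):
        positive = {
            "sigma_obs": self.sigma_obs,
            "sigma_r": self.sigma_r,
            "detection_sigma0": self.detection_sigma0,
            "cell_size_m": self.cell_size_m,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.detection_sigma0 <= 0 or self.cell_size_m <= 0:
            raise ValueError("detection_sigma0 and cell_size_m must be positive")
        if self.n_years_before < 2 or self.n_years_after < 2:
            raise ValueError("need at least 2 years in each period")
        if min(self.raster_shape) < 1:
            raise ValueError("raster_shape must be positive")
        for arr_name in ("true_beta_tp", "true_beta_C", "true_delta_G", "baseline_hazards"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{arr_name} must be finite")
        if len(self.true_beta_tp) != 4:
            raise ValueError("true_beta_tp must have 4 entries (BACI cells)")
        if np.any(np.asarray(self.baseline_hazards) < 0):
            raise ValueError("baseline hazards must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# --------------------------------------------------------------------------
# lek counts
# --------------------------------------------------------------------------


def simulate_lek_counts(cfg: SimConfig) -> pd.DataFrame:
    """Annual maximum counts per lek under the state-space generative model.

    Latent log abundance evolves by ``log N[j+1] = log N[j] + r[j]`` with
    ``r ~ Normal(alpha_l + beta_tp + eta_j, sigma_r^2)``; observed log counts
    add ``Normal(0, sigma_obs^2)`` noise, are exponentiated and rounded to
    nonnegative integers.  Each lek carries a fixed Euclidean distance to
    the nearest infrastructure, uniform over ``[0, max_distance_km]``; the
    transition into year ``j+1`` inherits that year's period, and a lek's
    generative treatment is "impact" iff its distance is within
    ``true_impact_km``.

    Returns a tidy frame: lek_id, year, max_count, distance_km, period.
    """
    rng = cfg.rng(1)
    n_years = cfg.n_years_before + cfg.n_years_after
    L, J = cfg.n_leks, n_years

    distance = rng.uniform(0.0, cfg.max_distance_km, size=L)
    impact = distance <= cfg.true_impact_km
    alpha = rng.normal(0.0, cfg.sigma_alpha, size=L)
    eta = rng.normal(0.0, cfg.sigma_eta, size=J - 1)
    beta = np.asarray(cfg.true_beta_tp, dtype=float)

    log_n = np.empty((L, J))
    log_n[:, 0] = rng.normal(cfg.log_n0_mean, cfg.log_n0_sd, size=L)
    for j in range(J - 1):
        after = (j + 1) >= cfg.n_years_before  # year j+1 falls in the after period
        cell = np.where(impact, 3 if after else 1, 2 if after else 0)
        mu = alpha + beta[cell] + eta[j]
        r = rng.normal(mu, cfg.sigma_r)
        log_n[:, j + 1] = log_n[:, j] + r

    log_y = log_n + rng.normal(0.0, cfg.sigma_obs, size=(L, J))
    counts = np.maximum(np.rint(np.exp(log_y)), 0).astype(int)

    lek_ids = [f"lek{i:03d}" for i in range(L)]
    years = np.arange(1, J + 1)
    period = np.where(years <= cfg.n_years_before, "before", "after")
    rows = pd.DataFrame(
        {
            "lek_id": np.repeat(lek_ids, J),
            "year": np.tile(years, L),
            "max_count": counts.ravel(),
            "distance_km": np.repeat(distance, J),
            "period": np.tile(period, L),
        }
    )
    return rows


# --------------------------------------------------------------------------
# encounter histories
# --------------------------------------------------------------------------


def simulate_encounter_histories(cfg: SimConfig) -> pd.DataFrame:
    """Individual survival histories at discrete intervals.

    Per individual-interval, the unit hazard is
    ``UH = exp(Z_k + psi_age + beta_C . X_C + Gamma_site + Lambda_year
    [+ delta_G . X_G + omega at impact sites])`` and death occurs in the
    interval with probability ``1 - exp(-UH)``.  Independent per-interval
    right-censoring is applied at ``censor_rate``; every individual's last
    row is dead or censored (survivors of the final interval are censored by
    study end).

    One row per individual-interval actually at risk, long format, with the
    confounder covariates (x_c0, x_c1, ...), the impact covariate(s)
    (x_g0, ...; zero at control sites), and status in
    {"alive", "dead", "censored"}.
    """
    rng = cfg.rng(2)
    n = cfg.n_individuals
    n_sites = cfg.n_control_sites + cfg.n_impact_sites
    site_ids = np.array(
        [f"C{i}" for i in range(cfg.n_control_sites)]
        + [f"G{i}" for i in range(cfg.n_impact_sites)]
    )
    is_control = np.array([True] * cfg.n_control_sites + [False] * cfg.n_impact_sites)

    gamma = rng.normal(0.0, cfg.sigma_site, size=n_sites)
    lam = rng.normal(0.0, cfg.sigma_year, size=cfg.n_demog_years)
    beta_c = np.asarray(cfg.true_beta_C, dtype=float)
    delta_g = np.asarray(cfg.true_delta_G, dtype=float)
    z_k = np.log(np.maximum(np.asarray(cfg.baseline_hazards, dtype=float), 1e-300))
    psi = np.asarray(cfg.true_psi_age, dtype=float)

    site_idx = rng.integers(0, n_sites, size=n)
    year_idx = rng.integers(0, cfg.n_demog_years, size=n)
    age_idx = (rng.random(n) < 0.7).astype(int)  # 0 yearling, 1 adult
    x_c = rng.normal(0.0, 1.0, size=(n, len(beta_c)))
    # impact covariate: exponential-decay distance to infrastructure (only
    # meaningful at impact sites; identically zero at control sites)
    x_g = np.where(
        is_control[site_idx][:, None],
        0.0,
        rng.uniform(0.0, 1.0, size=(n, len(delta_g))),
    )

    rows = []
    K = cfg.n_intervals
    for i in range(n):
        lp0 = (
            psi[age_idx[i]]
            + float(beta_c @ x_c[i])
            + gamma[site_idx[i]]
            + lam[year_idx[i]]
        )
        if not is_control[site_idx[i]]:
            lp0 += float(delta_g @ x_g[i]) + cfg.true_omega
        for k in range(K):
            uh = np.exp(z_k[k] + lp0)
            died = rng.random() < -np.expm1(-uh)
            if died:
                status = "dead"
            elif rng.random() < cfg.censor_rate or k == K - 1:
                status = "censored"
            else:
                status = "alive"
            rows.append(
                (
                    f"ind{i:04d}",
                    site_ids[site_idx[i]],
                    year_idx[i] + 1,
                    k + 1,
                    "adult" if age_idx[i] else "yearling",
                    status,
                    *x_c[i],
                    *x_g[i],
                    bool(is_control[site_idx[i]]),
                )
            )
            if status != "alive":
                break

    cols = (
        ["individual_id", "site_id", "year", "interval", "age_class", "status"]
        + [f"x_c{j}" for j in range(len(beta_c))]
        + [f"x_g{j}" for j in range(len(delta_g))]
        + ["is_control_site"]
    )
    return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------
# reproduction
# --------------------------------------------------------------------------


def simulate_reproduction(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Nest, clutch and brood records for the reproduction models.

    Nest fate follows daily-interval survival at ``nest_daily_hazard`` over
    ``nest_days``; hens whose first nest fails renest with probability
    ``logit^-1(renest_logit)``.  Clutch size is Poisson with log mean
    ``clutch_log_mean[attempt] + clutch_age_effect * adult``; hatched eggs
    are Binomial(clutch, hatch_p) at successful nests and chicks alive at
    day 50 are Binomial(hatched, chick_p).

    Returns (nests, clutches, broods):
      nests    — nest_id, hen_id, site_id, year, attempt, age_class,
                 exposure_days, fate {hatched, failed}
      clutches — nest_id + clutch_size, eggs_hatched (successful nests)
      broods   — nest_id + chicks_day50
    """
    rng = cfg.rng(3)
    p_daily = -np.expm1(-cfg.nest_daily_hazard)  # per-day failure probability
    p_renest = 1.0 / (1.0 + np.exp(-cfg.renest_logit))

    nests, clutches, broods = [], [], []
    n_sites = cfg.n_control_sites + cfg.n_impact_sites
    for h in range(cfg.n_hens):
        hen = f"hen{h:04d}"
        site = f"S{rng.integers(0, n_sites)}"
        year = int(rng.integers(1, cfg.n_demog_years + 1))
        adult = int(rng.random() < 0.7)
        for attempt in (1, 2):
            nest_id = f"{hen}_n{attempt}"
            days_survived = int(rng.geometric(p_daily)) if p_daily > 0 else cfg.nest_days + 1
            hatched_nest = days_survived > cfg.nest_days
            exposure = min(days_survived, cfg.nest_days)
            nests.append(
                (
                    nest_id, hen, site, year, attempt,
                    "adult" if adult else "yearling",
                    exposure, "hatched" if hatched_nest else "failed",
                )
            )
            log_mu = cfg.clutch_log_mean[attempt - 1] + cfg.clutch_age_effect * adult
            clutch = int(rng.poisson(np.exp(log_mu)))
            eggs = int(rng.binomial(clutch, cfg.hatch_p)) if hatched_nest else 0
            clutches.append((nest_id, clutch, eggs))
            if hatched_nest and eggs > 0:
                broods.append((nest_id, int(rng.binomial(eggs, cfg.chick_p))))
            if hatched_nest or rng.random() >= p_renest:
                break

    nests_df = pd.DataFrame(
        nests,
        columns=[
            "nest_id", "hen_id", "site_id", "year", "attempt",
            "age_class", "exposure_days", "fate",
        ],
    )
    clutch_df = pd.DataFrame(clutches, columns=["nest_id", "clutch_size", "eggs_hatched"])
    brood_df = pd.DataFrame(broods, columns=["nest_id", "chicks_day50"])
    return nests_df, clutch_df, brood_df


# --------------------------------------------------------------------------
# landscape
# --------------------------------------------------------------------------


def simulate_landscape(
    cfg: SimConfig,
) -> tuple[RasterGrid, RasterGrid, PointSet, PointSet]:
    """Synthetic terrain, abundance index, infrastructure and candidate sites.

    The DEM is a planar trend plus Gaussian bumps at configured cells; the
    abundance/space-use index (AUI) is a smooth field squashed into [0, 1];
    infrastructure is a small set of points near the grid centre; candidate
    development sites are a clustered scatter (cluster parents + offspring
    within ``candidate_cluster_km``).
    """
    rng = cfg.rng(4)
    nr, nc = cfg.raster_shape
    cell = cfg.cell_size_m
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")

    base, dzdx, dzdy = cfg.dem_plane
    dem = base + dzdx * cc * cell + dzdy * rr * cell
    for br, bc, amp, width in cfg.dem_bumps:
        dem = dem + amp * np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2.0 * width**2))
    dem_grid = RasterGrid(dem, origin=(0.0, 0.0), cell_size=cell)

    # AUI: smooth random field -> logistic squash into [0, 1]
    field_ = rng.normal(0.0, 1.0, size=(nr, nc))
    from scipy.ndimage import gaussian_filter

    smooth = gaussian_filter(field_, sigma=6.0)
    smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    aui_grid = RasterGrid(1.0 / (1.0 + np.exp(-1.5 * smooth)), origin=(0.0, 0.0), cell_size=cell)

    cx, cy = dem_grid.center_of(nr // 2, nc // 2)
    infra_xy = np.column_stack(
        [
            cx + rng.normal(0.0, 5 * cell, size=3),
            cy + rng.normal(0.0, 5 * cell, size=3),
        ]
    )
    infrastructure = PointSet(
        [f"infra{i}" for i in range(len(infra_xy))],
        infra_xy,
        {"infrastructure_class": np.array(["plant", "well", "pipeline"])},
    )

    extent_x, extent_y = nc * cell, nr * cell
    n_parents = max(1, cfg.n_candidates // 3)
    parents = np.column_stack(
        [rng.uniform(0, extent_x, n_parents), rng.uniform(-extent_y, 0, n_parents)]
    )
    idx = rng.integers(0, n_parents, size=cfg.n_candidates)
    cand_xy = parents[idx] + rng.normal(
        0.0, cfg.candidate_cluster_km * 1000.0, size=(cfg.n_candidates, 2)
    )
    candidates = PointSet(
        [f"cand{i:03d}" for i in range(cfg.n_candidates)],
        cand_xy,
        {"mwh": rng.uniform(5.0, 150.0, size=cfg.n_candidates)},
    )
    return dem_grid, aui_grid, infrastructure, candidates


# --------------------------------------------------------------------------
# predator point-count surveys
# --------------------------------------------------------------------------


def simulate_raven_surveys(cfg: SimConfig) -> pd.DataFrame:
    """Binned point-count surveys with half-normal distance detection.

    Birds are placed uniformly over the survey disc of radius
    ``survey_radius_m`` at intensity ``raven_density`` (per km^2), detected
    with probability ``exp(-r^2 / (2 sigma^2))`` where
    ``log sigma = log detection_sigma0 + effects . z``, and detected
    distances are binned at the configured cut-points.

    Returns one row per survey: survey_id, x, y, year, detection covariates
    (z_viewshed, z_forest), and per-bin counts n_bin1..n_bin5.
    """
    if cfg.detection_sigma0 <= 0:
        raise ValueError("detection_sigma0 must be positive")
    rng = cfg.rng(5)
    w = cfg.survey_radius_m
    cuts = np.asarray(cfg.bin_cuts_m, dtype=float)
    area_km2 = np.pi * (w / 1000.0) ** 2
    effects = np.asarray(cfg.detection_covariate_effects, dtype=float)

    n = cfg.n_surveys
    xy = rng.uniform(0.0, 50_000.0, size=(n, 2))
    years = rng.integers(1, cfg.n_demog_years + 1, size=n)
    z = rng.normal(0.0, 1.0, size=(n, len(effects)))
    sigma = cfg.detection_sigma0 * np.exp(z @ effects)

    bin_counts = np.zeros((n, len(cuts)), dtype=int)
    for s in range(n):
        m = rng.poisson(cfg.raven_density * area_km2)
        if m == 0:
            continue
        r = w * np.sqrt(rng.random(m))  # uniform over the disc
        detected = rng.random(m) < np.exp(-(r**2) / (2.0 * sigma[s] ** 2))
        if detected.any():
            b = np.searchsorted(cuts, r[detected], side="left")
            b = np.minimum(b, len(cuts) - 1)
            np.add.at(bin_counts[s], b, 1)

    out = pd.DataFrame(
        {
            "survey_id": [f"srv{i:04d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "year": years,
        }
    )
    for j in range(len(effects)):
        out[f"z{j}"] = z[:, j]
    for b in range(len(cuts)):
        out[f"n_bin{b + 1}"] = bin_counts[:, b]
    return out
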