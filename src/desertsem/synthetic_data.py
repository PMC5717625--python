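"""Synthetic desert food-web datasets with known ground truth.

The generator emulates the long-term study design: nine trapping sites
with 2-12 one-hectare pitfall grids each (36 traps per grid, open 2-6
nights per trip), quarterly trapping trips, automatic weather stations
recording daily rainfall at every site, per-grid years-since-wildfire,
grid-level spinifex cover (%) and seed index (0-5), and a two-year
camera-trap window with monthly pooled photograph counts of dingo, feral
cat and red fox per site.

Responses are drawn from exactly the model families the fitter assumes:
Poisson counts with a log-effort offset and a trip-level normal random
intercept, and binomial-logit scores with denominators 100 (cover) and 5
(seed).  The rodent <-> predator feedback is broken causally in time —
predator counts in month *m* respond to the most recent rodent trapping
rate before *m*, while rodent counts at a trip respond to that month's
realised predator photo rates — so every node's local model is correctly
specified given the covariates its analysis frame carries, and ground
truth slopes are recoverable by the fitting engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import cli_io
from .model_graph import ModelGraph, canonical_graph

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "generate_design",
    "trip_calendar",
    "simulate_daily_rain",
    "simulate_dataset",
    "default_ground_truth",
    "parameter_recovery",
]

_START = pd.Timestamp("1995-01-15")
_LOOKBACK_MONTHS = 24
_BASELINE_ROD100 = 5.0  # prey availability before the first trapping trip


@dataclass
class StudyDesign:
    """Dimensions of the monitoring programme."""

    n_sites: int
    grids_per_site: list[int]
    n_trips: int = 20
    trap_nights_per_grid_trip: int = 108  # 36 traps x 3 nights
    camera_months: int = 24
    cameras_per_site: int = 3

    def __post_init__(self):
        if self.n_sites < 0 or (self.n_sites and self.n_trips <= 0):
            raise ValueError("design counts must be positive")
        if any(not (2 <= g <= 12) for g in self.grids_per_site):
            raise ValueError("grids per site must lie in [2, 12]")
        if self.n_sites and not (72 <= self.trap_nights_per_grid_trip <= 216):
            raise ValueError("trap nights per grid per trip must lie in [72, 216]")

    @property
    def sites(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    """True link-scale coefficients and trip-level random-intercept SDs.

    Coefficient keys match the design-matrix column names the engine
    builds ('(Intercept)', predictor columns, 'site[S2]' dummies,
    'phase:dingo_per_cn' for the interaction).
    """

    coefficients: dict[str, dict[str, float]]
    random_sd: dict[str, float]
    denominators: dict[str, int] = field(
        default_factory=lambda: {"spinifex_cover": 100, "spinifex_seed": 5}
    )

    def __post_init__(self):
        if any(sd < 0 for sd in self.random_sd.values()):
            raise ValueError("random-intercept SDs must be non-negative")

    def validate_arity(self, graph: ModelGraph) -> None:
        for spec in graph.nodes:
            coefs = self.coefficients.get(spec.name)
            if coefs is None:
                raise ValueError(f"ground truth missing node {spec.name!r}")
            for term in spec.predictors:
                if term in spec.categorical:
                    continue
                if term not in coefs:
                    raise ValueError(
                        f"ground truth for {spec.name!r} missing term {term!r}"
                    )

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "random_sd": self.random_sd,
            "denominators": self.denominators,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


def generate_design(n_sites: int, seed: int, n_trips: int = 20) -> StudyDesign:
    """Draw a study design: ``n_sites`` sites with 2-12 grids each.

    The default of 20 quarterly trips yields pooled sample sizes per node
    (roughly 1100-1300 grid-trip rows for the long-term models, ~500 for
    the two-year rodent submodel, ~200 site-months of camera data)
    matching the order of magnitude of the field study.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    grids = rng.integers(2, 13, size=n_sites).tolist()
    nights = int(36 * rng.integers(2, 7))
    return StudyDesign(
        n_sites=n_sites,
        grids_per_site=grids,
        n_trips=n_trips,
        trap_nights_per_grid_trip=nights,
    )


def trip_calendar(design: StudyDesign) -> pd.DataFrame:
    """Quarterly trip dates shared across sites (trip 1 = Jan 1995)."""
    dates = [_START + pd.DateOffset(months=3 * t) for t in range(design.n_trips)]
    return pd.DataFrame({"trip": np.arange(1, design.n_trips + 1), "date": dates})


def simulate_daily_rain(
    design: StudyDesign,
    mean_event: float = 6.0,
    overdispersion: float = 0.75,
    seed: int = 0,
    p_wet: float = 0.12,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Two-part daily rainfall per site: a Bernoulli wet-day indicator and
    a gamma-distributed event size on wet days.

    ``overdispersion`` is the gamma shape: event-size variance equals
    mean_event**2 / overdispersion, so small values give the heavy-tailed,
    zero-inflated totals characteristic of arid rainfall and the law
    tightens to its degenerate light-tailed limit as the shape grows.
    """
    if mean_event <= 0 or overdispersion <= 0 or not (0 < p_wet <= 1):
        raise ValueError("rain parameters must be positive (and p_wet <= 1)")
    if design.n_sites == 0:
        return pd.DataFrame(columns=["site", "date", "rainfall_mm"])
    if start is None or end is None:
        cal = trip_calendar(design)
        if start is None:
            start = (cal["date"].min() - pd.DateOffset(months=_LOOKBACK_MONTHS)).normalize()
        if end is None:
            end = (cal["date"].max() + pd.offsets.MonthEnd(1)).normalize()
    dates = pd.date_range(start, end, freq="D")
    rng = np.random.default_rng(seed)
    frames = []
    for site in design.sites:
        wet = rng.random(len(dates)) < p_wet
        amounts = np.zeros(len(dates))
        n_wet = int(wet.sum())
        if n_wet:
            amounts[wet] = rng.gamma(
                shape=overdispersion, scale=mean_event / overdispersion, size=n_wet
            )
        frames.append(
            pd.DataFrame({"site": site, "date": dates, "rainfall_mm": amounts})
        )
    return pd.concat(frames, ignore_index=True)


def default_ground_truth(n_sites: int = 9) -> GroundTruth:
    """Reference coefficients reproducing the qualitative structure of the
    fitted desert food web: vegetation driven up by rainfall and fire age,
    seed driven by cover, rodents boosted by seed and dingo activity but
    suppressed by the introduced cat and fox, mesopredators checked by the
    dingo most strongly in the decline/bust prey phases."""
    site_effects = {}
    offsets = [0.2, -0.2, 0.1, -0.1, 0.3, -0.3, 0.15, -0.15]
    for i in range(1, n_sites):
        site_effects[f"site[S{i + 1}]"] = offsets[(i - 1) % len(offsets)]
    coefficients = {
        "dasyurids": {
            "(Intercept)": -2.0,
            **site_effects,
            "mean_event_size_lag2": 0.02,
            "mulgara_per_100tn": -0.05,
        },
        "spinifex_cover": {
            "(Intercept)": -1.85,
            "years_since_fire": 0.04,
            "rain_8mo": 0.001,
        },
        "spinifex_seed": {
            "(Intercept)": -1.8,
            "spinifex_cover": 0.03,
            "rain_8mo": 0.0005,
        },
        "rodents": {
            "(Intercept)": -2.8,
            "seed_index": 0.5,
            "cat_per_cn": -3.0,
            "fox_per_cn": -3.0,
            "dingo_per_cn": 2.0,
        },
        "mulgara": {
            "(Intercept)": -4.0,
            "rodents_per_100tn": 0.01,
            "spinifex_cover": 0.02,
            "years_since_fire": -0.005,
        },
        "cat": {
            "(Intercept)": -2.2,
            "rodents_per_100tn": 0.02,
            "dingo_per_cn": 1.0,
            "phase": 0.05,
            "phase:dingo_per_cn": -0.8,
        },
        "fox": {
            "(Intercept)": -2.6,
            "rodents_per_100tn": 0.005,
            "dingo_per_cn": 0.3,
            "phase": -0.3,
            "phase:dingo_per_cn": -0.5,
        },
        "dingo": {"(Intercept)": -2.5, "rodents_per_100tn": 0.02},
        "reptiles": {
            "(Intercept)": -1.2,
            "years_since_fire": -0.02,
            "spinifex_cover": 0.005,
            "rain_days": 0.05,
        },
    }
    random_sd = {
        "dasyurids": 0.3,
        "spinifex_cover": 0.25,
        "spinifex_seed": 0.25,
        "rodents": 0.3,
        "mulgara": 0.3,
        "cat": 0.3,
        "fox": 0.3,
        "dingo": 0.25,
        "reptiles": 0.3,
    }
    return GroundTruth(coefficients=coefficients, random_sd=random_sd)


def _phase_sequence(monthly_rain8: pd.Series, force_pulse_at: int | None = None) -> pd.Series:
    """Boom(1) -> decline(2) -> bust(3) blocks triggered by rainfall
    pulses: a pulse (8-month total above its 75th percentile) starts six
    months of boom, then six of decline, then bust until the next pulse.

    ``force_pulse_at`` marks one month as a pulse regardless of the
    threshold; the camera deployment in the emulated study was timed to
    span a resource pulse and the subsequent bust, so the generator
    guarantees one inside the camera window.
    """
    thresh = monthly_rain8.quantile(0.75)
    phase = np.full(len(monthly_rain8), 3, dtype=int)
    countdown = 0
    for i, val in enumerate(monthly_rain8.to_numpy()):
        if (val >= thresh or i == force_pulse_at) and countdown <= 6:
            countdown = 12
        if countdown > 6:
            phase[i] = 1
        elif countdown > 0:
            phase[i] = 2
        countdown = max(countdown - 1, 0)
    return pd.Series(phase, index=monthly_rain8.index)


def simulate_dataset(design: StudyDesign, truth: GroundTruth, seed: int) -> dict:
    """Generate the full table bundle for one synthetic realisation.

    Returns a dict with keys 'captures', 'cameras', 'vegetation',
    'covariates', 'fire', 'rain_daily' — the same delimited long formats
    the readers validate.
    """
    graph = canonical_graph()
    truth.validate_arity(graph)
    rng = np.random.default_rng(seed)
    cal = trip_calendar(design)
    sites = design.sites
    n_trips = design.n_trips

    rain_daily = simulate_daily_rain(design, seed=int(rng.integers(2**31)))
    cov = cli_io.derive_rain_covariates(rain_daily, cal)

    # fill the (missing-by-construction) first two event-size lags with the
    # site mean for simulation only; fitted frames keep the NaN and drop rows
    cov_sim = cov.copy()
    cov_sim["mean_event_size_lag2"] = cov_sim.groupby("site")[
        "mean_event_size_lag2"
    ].transform(lambda s: s.fillna(s.mean()))

    # --- wildfire ages per grid (continuous years, occasional reset) -----
    fire_rows = []
    for si, site in enumerate(sites):
        for g in range(design.grids_per_site[si]):
            age = float(rng.uniform(2, 30))
            for t in range(1, n_trips + 1):
                fire_rows.append(
                    {"site": site, "grid": f"{site}G{g + 1}", "trip": t,
                     "years_since_fire": round(age, 2)}
                )
                age += 0.25
                if rng.random() < 0.02:
                    age = 0.25
    fire = pd.DataFrame(fire_rows)

    # --- vegetation (binomial-logit, trip random intercepts) -------------
    tc = truth.coefficients
    sd = truth.random_sd
    u = {
        node: rng.normal(0.0, sd[node], size=n_trips)
        for node in ("spinifex_cover", "spinifex_seed", "rodents",
                     "mulgara", "dasyurids", "reptiles")
    }
    master = fire.merge(cov_sim[["site", "trip", "rain_8mo", "rain_days",
                                 "mean_event_size_lag2"]], on=["site", "trip"])
    master = master.merge(cal, on="trip")
    t_idx = master["trip"].to_numpy() - 1

    c = tc["spinifex_cover"]
    eta = (c["(Intercept)"] + c["years_since_fire"] * master["years_since_fire"]
           + c["rain_8mo"] * master["rain_8mo"] + u["spinifex_cover"][t_idx])
    master["spinifex_cover"] = rng.binomial(100, expit(eta.to_numpy()))

    c = tc["spinifex_seed"]
    eta = (c["(Intercept)"] + c["spinifex_cover"] * master["spinifex_cover"]
           + c["rain_8mo"] * master["rain_8mo"] + u["spinifex_seed"][t_idx])
    master["seed_index"] = rng.binomial(5, expit(eta.to_numpy()))

    # --- monthly predator loop and per-trip rodent realisation -----------
    months = pd.period_range(cal["date"].min(), cal["date"].max(), freq="M")
    window_start = months[-1] - (design.camera_months - 1)

    # regional phase from site-mean 8-month rainfall totals per month
    monthly_tot = (
        rain_daily.assign(month=pd.to_datetime(rain_daily["date"]).dt.to_period("M"))
        .groupby("month")["rainfall_mm"].sum()
        / max(design.n_sites, 1)
    )
    rain8_monthly = monthly_tot.rolling(8).sum().reindex(months)
    rain8_filled = rain8_monthly.fillna(rain8_monthly.mean())
    # guarantee a pulse early in the camera window (boom -> decline -> bust)
    win_idx = np.flatnonzero(months >= window_start)
    early = win_idx[: max(len(win_idx) // 2, 1)]
    force_at = int(early[np.argmax(rain8_filled.to_numpy()[early])])
    phase_by_month = _phase_sequence(rain8_filled, force_pulse_at=force_at)

    u_cam = {
        node: rng.normal(0.0, sd[node], size=len(months))
        for node in ("cat", "fox", "dingo")
    }
    master["month"] = master["date"].dt.to_period("M")
    master["trap_nights"] = design.trap_nights_per_grid_trip
    site_rate = {s: np.nan for s in sites}  # latest observed rodent rate
    cam_rows = []
    rod_counts = np.full(len(master), -1, dtype=int)
    for mi, m in enumerate(months):
        days = m.days_in_month
        cn = design.cameras_per_site * days
        phase = int(phase_by_month.iloc[mi])
        for site in sites:
            rod_prev = site_rate[site]
            rod_cov = _BASELINE_ROD100 if np.isnan(rod_prev) else rod_prev
            c = tc["dingo"]
            eta_d = (c["(Intercept)"] + c["rodents_per_100tn"] * rod_cov
                     + np.log(cn) + u_cam["dingo"][mi])
            n_dingo = rng.poisson(np.exp(eta_d))
            dingo_rate = n_dingo / cn
            counts = {"dingo": n_dingo}
            for pred in ("cat", "fox"):
                c = tc[pred]
                eta_p = (c["(Intercept)"] + c["rodents_per_100tn"] * rod_cov
                         + c["dingo_per_cn"] * dingo_rate + c["phase"] * phase
                         + c["phase:dingo_per_cn"] * phase * dingo_rate
                         + np.log(cn) + u_cam[pred][mi])
                counts[pred] = rng.poisson(np.exp(eta_p))
            if m >= window_start:
                cam_rows.append(
                    {"site": site, "month": str(m), "camera_nights": cn,
                     "cat": counts["cat"], "fox": counts["fox"],
                     "dingo": counts["dingo"], "phase": phase,
                     "rodents_per_100tn": rod_prev}
                )
            # rodent counts for this site's grids trapped this month
            mask = (master["month"] == m) & (master["site"] == site)
            if mask.any():
                idx = np.where(mask.to_numpy())[0]
                c = tc["rodents"]
                eta_r = (
                    c["(Intercept)"]
                    + c["seed_index"] * master["seed_index"].to_numpy()[idx]
                    + c["cat_per_cn"] * counts["cat"] / cn
                    + c["fox_per_cn"] * counts["fox"] / cn
                    + c["dingo_per_cn"] * dingo_rate
                    + np.log(design.trap_nights_per_grid_trip)
                    + u["rodents"][master["trip"].to_numpy()[idx] - 1]
                )
                rod_counts[idx] = rng.poisson(np.exp(eta_r))
                site_rate[site] = float(
                    rod_counts[idx].sum()
                    / (len(idx) * design.trap_nights_per_grid_trip) * 100.0
                )
    master["rodents"] = rod_counts
    cameras = pd.DataFrame(cam_rows)

    # --- remaining capture nodes -----------------------------------------
    tn = design.trap_nights_per_grid_trip
    rod100 = master["rodents"].to_numpy() / tn * 100.0

    c = tc["mulgara"]
    eta = (c["(Intercept)"] + c["rodents_per_100tn"] * rod100
           + c["spinifex_cover"] * master["spinifex_cover"].to_numpy()
           + c["years_since_fire"] * master["years_since_fire"].to_numpy()
           + np.log(tn) + u["mulgara"][t_idx])
    master["mulgara"] = rng.poisson(np.exp(eta))
    mul100 = master["mulgara"].to_numpy() / tn * 100.0

    c = tc["dasyurids"]
    site_eff = np.array(
        [c.get(f"site[{s}]", 0.0) for s in master["site"]]
    )
    eta = (c["(Intercept)"] + site_eff
           + c["mean_event_size_lag2"] * master["mean_event_size_lag2"].to_numpy()
           + c["mulgara_per_100tn"] * mul100
           + np.log(tn) + u["dasyurids"][t_idx])
    master["dasyurids"] = rng.poisson(np.exp(eta))

    c = tc["reptiles"]
    eta = (c["(Intercept)"]
           + c["years_since_fire"] * master["years_since_fire"].to_numpy()
           + c["spinifex_cover"] * master["spinifex_cover"].to_numpy()
           + c["rain_days"] * master["rain_days"].to_numpy()
           + np.log(tn) + u["reptiles"][t_idx])
    master["reptiles"] = rng.poisson(np.exp(eta))

    captures = master[["site", "grid", "trip", "date", "trap_nights",
                       "dasyurids", "rodents", "mulgara", "reptiles"]].copy()
    captures["date"] = captures["date"].dt.strftime("%Y-%m-%d")
    vegetation = master[["site", "grid", "trip", "spinifex_cover", "seed_index"]].copy()
    rain_out = rain_daily.copy()
    rain_out["date"] = pd.to_datetime(rain_out["date"]).dt.strftime("%Y-%m-%d")

    return {
        "captures": captures,
        "cameras": cameras,
        "vegetation": vegetation,
        "covariates": cov,
        "fire": fire,
        "rain_daily": rain_out,
    }


def parameter_recovery(
    n_reps: int = 100,
    seed: int = 0,
    design: StudyDesign | None = None,
    truth: GroundTruth | None = None,
    nodes: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit harness: for each replicate, fit every node to a
    fresh synthetic dataset and record whether each true slope lies within
    two estimated standard errors of its estimate.

    Red-fox fits are made on the z-transformed scale; estimates and
    standard errors are converted back to raw units with the recorded
    per-column standard deviations before comparison.
    """
    from .glmm_engine import fit_node

    graph = canonical_graph()
    if design is None:
        design = generate_design(9, seed=seed)
    if truth is None:
        truth = default_ground_truth(design.n_sites)
    specs = [s for s in graph.nodes if nodes is None or s.name in nodes]
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_reps)]
    records: dict[tuple[str, str], list[bool]] = {}
    for rep_seed in rep_seeds:
        tables = simulate_dataset(design, truth, seed=rep_seed)
        frames = cli_io.build_node_frames(tables, graph)
        for spec in specs:
            fit = fit_node(spec, frames[spec.name])
            for term in spec.predictors:
                if term in spec.categorical:
                    continue
                est = fit.coef(term)
                se = fit.std_errors[fit.columns.index(term)]
                if fit.z_scale and term in fit.z_scale:
                    _, sd_x = fit.z_scale[term]
                    est, se = est / sd_x, se / sd_x
                true = truth.coefficients[spec.name][term]
                records.setdefault((spec.name, term), []).append(
                    bool(abs(est - true) <= 2.0 * se)
                )
    rows = [
        {"node": node, "term": term, "n_reps": len(ok),
         "n_within_2se": int(sum(ok)), "coverage": sum(ok) / len(ok)}
        for (node, term), ok in records.items()
    ]
    return pd.DataFrame(rows)
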