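"""Synthetic hospitals, skilled nursing facilities, and discharge cohorts.

The generator emulates the structure of a national post-acute-care
referral dataset with a *known* ground truth, so that every downstream
stage — cohort filters, choice-set construction, preferred-network
classification, matching, weighting, and the discrete-choice models —
can be tested against the process that produced the data:

* geography: states are rectangular tiles; hospitals scatter uniformly
  within a tile; SNFs cluster around hospitals with exponential radial
  decay (a long-tailed mixture), so that in some markets the 22 km
  radius binds and in others the 15-nearest rule does;
* patients: age, sex, race/ethnicity, dual eligibility, Medicare
  Advantage, ESRD entitlement, urbanicity, and a comorbidity index are
  drawn marginally; opioid use disorder (OUD) status follows a logistic
  model on those covariates whose intercept is calibrated to the target
  prevalence (default 1.2%), with younger age and dual eligibility
  raising OUD risk;
* placement: each discharge's SNF is drawn from a McFadden conditional
  logit over the hospital's choice set (same-state SNFs within the
  radius, unioned with the k nearest), with utilities x'beta for
  patients without OUD and x'(beta + delta) for patients with OUD;
* preferred status is dynamic: the first calendar year is a burn-in
  with no preferred facilities, and each later year classifies the
  highest-volume SNFs covering a cumulative 50% of the hospital's
  realized prior-year discharges as preferred — the same rule the
  analysis pipeline applies, so truth and reconstruction coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import ATTRIBUTES, GeneratorConfig
from .geo import cross_distance_km

KM_PER_DEG_LAT = 111.195
BASE_LAT = 38.0

RACE_LEVELS = (
    "non_hispanic_white",
    "black",
    "hispanic",
    "asian_pacific_islander",
    "unknown",
    "other",
    "american_indian_alaska_native",
)
RACE_PROBS = (0.797, 0.108, 0.059, 0.020, 0.006, 0.006, 0.004)

RUCA_LEVELS = ("metropolitan", "micropolitan", "small town", "rural")
RUCA_PROBS = (0.832, 0.098, 0.042, 0.028)

STAR_PROBS = (0.08, 0.14, 0.22, 0.31, 0.25)  # 1..5 stars
NEUTRAL_STAR = 3.0  # utility placeholder when a rating is missing


@dataclass
class GroundTruth:
    """The generating process, returned alongside the data for oracles."""

    beta: Dict[str, float]
    delta: Dict[str, float]
    propensity_coefs: Dict[str, float]  # includes the calibrated "intercept"
    choice_sets: Dict[str, List[str]]  # hospital_id -> ordered facility ids
    networks: Dict[int, Dict[str, List[str]]]  # year -> hospital -> preferred
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "beta": self.beta,
            "delta": self.delta,
            "propensity_coefs": self.propensity_coefs,
            "choice_sets": self.choice_sets,
            "networks": {str(y): m for y, m in self.networks.items()},
            "seed": self.seed,
        }


@dataclass
class SyntheticPopulation:
    facilities: pd.DataFrame
    hospitals: pd.DataFrame
    discharges: pd.DataFrame
    truth: GroundTruth

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "facilities": self.facilities,
            "hospitals": self.hospitals,
            "discharges": self.discharges,
        }


def _km_to_deg_lon(km: np.ndarray, lat: np.ndarray) -> np.ndarray:
    return km / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))


def _make_geography(cfg: GeneratorConfig, rng: np.random.Generator):
    """States as longitude tiles; hospitals uniform; SNFs clustered."""
    tile_km = cfg.spatial_extent_km
    tile_deg_lat = tile_km / KM_PER_DEG_LAT
    tile_deg_lon = tile_km / (KM_PER_DEG_LAT * np.cos(np.radians(BASE_LAT)))

    state_ids = [f"ST{s+1}" for s in range(cfg.n_states)]

    h_state = np.arange(cfg.n_hospitals) % cfg.n_states
    h_lat = BASE_LAT + rng.uniform(0.1, 0.9, cfg.n_hospitals) * tile_deg_lat
    h_lon = (h_state + rng.uniform(0.1, 0.9, cfg.n_hospitals)) * tile_deg_lon
    hospitals = pd.DataFrame(
        {
            "hospital_id": [f"H{i+1:03d}" for i in range(cfg.n_hospitals)],
            "state_id": [state_ids[s] for s in h_state],
            "latitude": h_lat,
            "longitude": h_lon,
        }
    )

    f_state = np.arange(cfg.n_snfs) % cfg.n_states
    anchor = np.empty(cfg.n_snfs, dtype=int)
    for s in range(cfg.n_states):
        pool = np.flatnonzero(h_state == s)
        mask = f_state == s
        anchor[mask] = rng.choice(pool, size=int(mask.sum()))
    # long-tailed radial scatter: most SNFs near an anchor hospital,
    # a minority far out so the 15-nearest rule binds in thin markets
    far = rng.random(cfg.n_snfs) < 0.2
    radius = rng.exponential(cfg.snf_scatter_km, cfg.n_snfs)
    radius[far] = rng.exponential(4.0 * cfg.snf_scatter_km, int(far.sum()))
    bearing = rng.uniform(0.0, 2.0 * np.pi, cfg.n_snfs)
    f_lat = h_lat[anchor] + (radius * np.cos(bearing)) / KM_PER_DEG_LAT
    f_lon = h_lon[anchor] + _km_to_deg_lon(radius * np.sin(bearing), h_lat[anchor])
    f_lat = np.clip(f_lat, -90.0, 90.0)

    stars = rng.choice(np.arange(1, 6), size=cfg.n_snfs, p=STAR_PROBS).astype(float)
    stars[rng.random(cfg.n_snfs) < cfg.star_missing_rate] = np.nan
    facilities = pd.DataFrame(
        {
            "facility_id": [f"S{i+1:04d}" for i in range(cfg.n_snfs)],
            "state_id": [state_ids[s] for s in f_state],
            "latitude": f_lat,
            "longitude": f_lon,
            "star_rating": stars,
            "for_profit": rng.random(cfg.n_snfs) < 0.70,
            "chain": rng.random(cfg.n_snfs) < 0.60,
            "hospital_affiliated": rng.random(cfg.n_snfs) < 0.05,
            "beds": np.clip(rng.lognormal(np.log(115.0), 0.5, cfg.n_snfs), 20, 500).round().astype(int),
            "occupancy_pct": np.clip(rng.normal(80.0, 15.0, cfg.n_snfs), 5.0, 100.0).round(1),
            "pct_medicaid": np.clip(rng.normal(48.0, 25.0, cfg.n_snfs), 0.0, 100.0).round(1),
        }
    )
    return facilities, hospitals


def _make_patients(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_discharges
    disabled = rng.random(n) < 0.075  # Medicare entitlement before 65
    age = np.where(
        disabled,
        rng.uniform(18.0, 65.0, n),
        np.clip(rng.normal(79.0, 9.0, n), 65.0, 100.0),
    )
    female = rng.random(n) < 0.60
    race = rng.choice(np.array(RACE_LEVELS, dtype=object), size=n, p=RACE_PROBS)
    dual = rng.random(n) < np.where(age < 65.0, 0.70, 0.20)
    ma = rng.random(n) < 0.37
    esrd = rng.random(n) < 0.026
    ruca = rng.choice(np.array(RUCA_LEVELS, dtype=object), size=n, p=RUCA_PROBS)
    elix = np.minimum(rng.poisson(5.0, n), 15)

    start = np.datetime64(f"{cfg.year_start}-01-01")
    end = np.datetime64(f"{cfg.year_end}-12-31")
    span = int((end - start) / np.timedelta64(1, "D")) + 1
    dates = start + rng.integers(0, span, n).astype("timedelta64[D]")

    return pd.DataFrame(
        {
            "discharge_id": [f"D{i+1:06d}" for i in range(n)],
            "patient_id": [f"P{i+1:06d}" for i in range(n)],
            "discharge_date": dates,
            "snf_admission_lag_days": (rng.random(n) < 0.30).astype(int),
            "had_prior_year_snf": np.zeros(n, dtype=bool),
            "age": np.round(age, 1),
            "sex": np.where(female, "female", "male"),
            "race_ethnicity": race,
            "dual_eligible": dual,
            "medicare_advantage": ma,
            "esrd_eligibility": esrd,
            "ruca": ruca,
            "elixhauser": elix,
        }
    )


def _draw_oud(
    patients: pd.DataFrame, cfg: GeneratorConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, Dict[str, float]]:
    """OUD via a logistic model; intercept solved to hit the prevalence."""
    c = cfg.propensity_coefs
    eta = (
        c.get("age_per_decade", 0.0) * (patients["age"].to_numpy() - 75.0) / 10.0
        + c.get("dual_eligible", 0.0) * patients["dual_eligible"].to_numpy()
        + c.get("female", 0.0) * (patients["sex"].to_numpy() == "female")
        + c.get("elixhauser", 0.0) * (patients["elixhauser"].to_numpy() - 5.0)
        + c.get("medicare_advantage", 0.0) * patients["medicare_advantage"].to_numpy()
    )
    a0 = brentq(lambda a: expit(a + eta).mean() - cfg.oud_prevalence, -20.0, 10.0)
    p = expit(a0 + eta)
    oud = rng.random(len(p)) < p
    coefs = dict(c)
    coefs["intercept"] = float(a0)
    return oud, coefs


def _hospital_choice_sets(
    facilities: pd.DataFrame, hospitals: pd.DataFrame, cfg: GeneratorConfig
) -> Dict[str, List[str]]:
    """Per hospital: same-state SNFs within the radius, union k nearest.

    Ordered by ascending hospital distance with facility_id tie-break.
    """
    sets: Dict[str, List[str]] = {}
    for state, hosp_grp in hospitals.groupby("state_id", sort=True):
        fac = facilities[facilities["state_id"] == state].reset_index(drop=True)
        if fac.empty:
            raise ValueError(f"state {state} has zero SNFs; choice sets undefined")
        d = cross_distance_km(
            hosp_grp["latitude"], hosp_grp["longitude"], fac["latitude"], fac["longitude"]
        )
        for row, (_, h) in zip(d, hosp_grp.iterrows()):
            order = np.lexsort((fac["facility_id"].to_numpy(), row))
            keep = set(np.flatnonzero(row <= cfg.radius_km))
            keep.update(order[: cfg.k_nearest])
            members = sorted(keep, key=lambda i: (row[i], fac["facility_id"].iat[i]))
            sets[h["hospital_id"]] = [fac["facility_id"].iat[i] for i in members]
    return sets


def classify_cumulative(volumes: Mapping[str, int], threshold: float) -> List[str]:
    """Highest-volume facilities covering a cumulative share >= threshold.

    Inclusive crossing: the facility whose addition first attains the
    threshold is included.  Ties in volume break by ascending id.
    Zero total volume yields an empty set.
    """
    total = float(sum(volumes.values()))
    if total <= 0:
        return []
    ranked = sorted(volumes.items(), key=lambda kv: (-kv[1], kv[0]))
    out: List[str] = []
    cum = 0.0
    for fid, v in ranked:
        if cum >= threshold * total - 1e-12:
            break
        out.append(fid)
        cum += v
    return out


def _facility_attr_matrix(fac: pd.DataFrame) -> Dict[str, np.ndarray]:
    star = fac["star_rating"].to_numpy(dtype=float)
    star = np.where(np.isnan(star), NEUTRAL_STAR, star)
    return {
        "star_rating": star,
        "for_profit": fac["for_profit"].to_numpy(dtype=float),
        "chain": fac["chain"].to_numpy(dtype=float),
        "hospital_affiliated": fac["hospital_affiliated"].to_numpy(dtype=float),
        "beds": fac["beds"].to_numpy(dtype=float),
        "occupancy_pct": fac["occupancy_pct"].to_numpy(dtype=float),
        "pct_medicaid": fac["pct_medicaid"].to_numpy(dtype=float),
    }


def generate_population(config: GeneratorConfig) -> SyntheticPopulation:
    """Generate facilities, hospitals, and discharges with known truth.

    Deterministic given ``config`` (all randomness flows from
    ``config.seed`` through named substreams).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geo, rng_pat, rng_oud, rng_choice = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    facilities, hospitals = _make_geography(config, rng_geo)
    discharges = _make_patients(config, rng_pat)
    oud, prop_coefs = _draw_oud(discharges, config, rng_oud)
    discharges["oud"] = oud

    # hospital assignment: uniform, independent of patient covariates
    hosp_idx = rng_pat.integers(0, config.n_hospitals, config.n_discharges)
    discharges["hospital_id"] = hospitals["hospital_id"].to_numpy()[hosp_idx]
    h_lat = hospitals["latitude"].to_numpy()[hosp_idx]
    h_lon = hospitals["longitude"].to_numpy()[hosp_idx]
    # homes scatter around the discharging hospital
    home_dx = rng_pat.normal(0.0, 8.0, config.n_discharges)
    home_dy = rng_pat.normal(0.0, 8.0, config.n_discharges)
    discharges["home_latitude"] = h_lat + home_dy / KM_PER_DEG_LAT
    discharges["home_longitude"] = h_lon + _km_to_deg_lon(home_dx, h_lat)

    choice_sets = _hospital_choice_sets(facilities, hospitals, config)
    fac_indexed = facilities.set_index("facility_id")
    attr_by_fac = {k: dict(zip(facilities["facility_id"], v)) for k, v in _facility_attr_matrix(facilities).items()}

    beta, delta = config.true_beta, config.true_delta
    years = discharges["discharge_date"].dt.year.to_numpy()
    chosen = np.empty(config.n_discharges, dtype=object)
    networks: Dict[int, Dict[str, List[str]]] = {}
    prev_vol: Dict[str, Dict[str, int]] = {}

    for year in range(config.year_start, config.year_end + 1):
        networks[year] = {
            h: classify_cumulative(prev_vol.get(h, {}), 0.50) for h in choice_sets
        }
        vol_this: Dict[str, Dict[str, int]] = {}
        in_year = np.flatnonzero(years == year)
        for h, idx in pd.Series(in_year).groupby(
            discharges["hospital_id"].to_numpy()[in_year]
        ):
            members = choice_sets[h]
            pref = np.array(
                [1.0 if f in networks[year][h] else 0.0 for f in members]
            )
            f_lat = fac_indexed.loc[members, "latitude"].to_numpy()
            f_lon = fac_indexed.loc[members, "longitude"].to_numpy()
            hosp = hospitals.loc[hospitals["hospital_id"] == h].iloc[0]
            d_hosp = cross_distance_km(
                [hosp["latitude"]], [hosp["longitude"]], f_lat, f_lon
            )[0]

            static = {a: np.array([attr_by_fac[a][f] for f in members]) for a in attr_by_fac}
            static["preferred"] = pref
            static["dist_hosp_km"] = d_hosp

            base_v = sum(beta[a] * static[a] for a in static)
            base_d = sum(delta[a] * static[a] for a in static)

            rows = idx.to_numpy()
            d_home = cross_distance_km(
                discharges["home_latitude"].to_numpy()[rows],
                discharges["home_longitude"].to_numpy()[rows],
                f_lat,
                f_lon,
            )
            is_oud = discharges["oud"].to_numpy()[rows].astype(float)[:, None]
            v = (
                base_v[None, :]
                + beta["dist_home_km"] * d_home
                + is_oud * (base_d[None, :] + delta["dist_home_km"] * d_home)
            )
            gumbel = rng_choice.gumbel(size=v.shape)
            pick = np.argmax(v + gumbel, axis=1)
            for r, p_i in zip(rows, pick):
                chosen[r] = members[p_i]
            counts = pd.Series([members[p_i] for p_i in pick]).value_counts()
            vol_this[h] = counts.to_dict()
        prev_vol = vol_this

    discharges["chosen_facility_id"] = chosen
    col_order = [
        "discharge_id",
        "patient_id",
        "hospital_id",
        "discharge_date",
        "chosen_facility_id",
        "snf_admission_lag_days",
        "had_prior_year_snf",
        "oud",
        "age",
        "sex",
        "race_ethnicity",
        "dual_eligible",
        "medicare_advantage",
        "esrd_eligibility",
        "ruca",
        "elixhauser",
        "home_latitude",
        "home_longitude",
    ]
    discharges = discharges[col_order]

    truth = GroundTruth(
        beta=dict(beta),
        delta=dict(delta),
        propensity_coefs=prop_coefs,
        choice_sets=choice_sets,
        networks=networks,
        seed=config.seed,
    )
    return SyntheticPopulation(facilities, hospitals, discharges, truth)


# ---------------------------------------------------------------------------
# direct simulators for oracle-style tests


def simulate_choice_data(
    n_sets: int,
    n_alts: int,
    beta: Mapping[str, float],
    delta: Optional[Mapping[str, float]] = None,
    oud_share: float = 0.5,
    n_clusters: int = 20,
    seed: int = 0,
    weights: bool = False,
) -> pd.DataFrame:
    """Long-format choice data drawn directly from known (beta, delta).

    One row per (choice set, alternative); attribute columns are the
    keys of ``beta``; ``choice`` marks the drawn alternative, ``oud``
    the set-level exposure, ``state_id`` the cluster label.  Used for
    parameter-recovery and test-calibration oracles, bypassing the
    geographic population machinery.
    """
    rng = np.random.default_rng(seed)
    attrs = list(beta)
    n = n_sets * n_alts
    cols: Dict[str, np.ndarray] = {}
    for a in attrs:
        if a == "preferred":
            cols[a] = (rng.random(n) < 0.3).astype(float)
        elif a == "star_rating":
            cols[a] = rng.integers(1, 6, n).astype(float)
        elif a in ("dist_home_km", "dist_hosp_km"):
            cols[a] = rng.exponential(8.0, n)
        elif a in ("for_profit", "chain", "hospital_affiliated"):
            cols[a] = (rng.random(n) < 0.5).astype(float)
        elif a == "beds":
            cols[a] = np.clip(rng.normal(130.0, 75.0, n), 20.0, None)
        elif a == "occupancy_pct":
            cols[a] = np.clip(rng.normal(80.0, 15.0, n), 5.0, 100.0)
        elif a == "pct_medicaid":
            cols[a] = rng.uniform(0.0, 100.0, n)
        else:
            cols[a] = rng.normal(0.0, 1.0, n)

    oud_set = (rng.random(n_sets) < oud_share).astype(int)
    state_set = rng.integers(0, n_clusters, n_sets)
    set_id = np.repeat(np.arange(n_sets), n_alts)
    oud = oud_set[set_id]

    v = np.zeros(n)
    for a in attrs:
        v += beta[a] * cols[a]
        if delta is not None and a in delta:
            v += delta[a] * oud * cols[a]
    v = v.reshape(n_sets, n_alts)
    pick = np.argmax(v + rng.gumbel(size=v.shape), axis=1)
    choice = np.zeros(n, dtype=int)
    choice[np.arange(n_sets) * n_alts + pick] = 1

    df = pd.DataFrame(
        {
            "discharge_id": set_id,
            "state_id": state_set[set_id],
            "oud": oud,
            "choice": choice,
            **cols,
        }
    )
    if "dist_home_km" in cols:
        d = cols["dist_home_km"].reshape(n_sets, n_alts)
        closest = np.zeros(n, dtype=int)
        closest[np.arange(n_sets) * n_alts + np.argmin(d, axis=1)] = 1
        df["closest"] = closest
    if weights:
        df["weight"] = np.repeat(rng.uniform(0.5, 1.5, n_sets), n_alts)
    return df


def simulate_lpm_outcome(
    n: int,
    n_hospitals: int,
    oud_gap: float,
    oud_share: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary outcome with an injected within-hospital OUD gap.

    Hospital base rates vary; OUD shifts the success probability by
    exactly ``oud_gap`` within hospital, so a fixed-effects linear
    probability model has a known truth to recover.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.35, 0.70, n_hospitals)
    hosp = rng.integers(0, n_hospitals, n)
    oud = (rng.random(n) < oud_share).astype(int)
    female = (rng.random(n) < 0.6).astype(int)
    p = base[hosp] + oud_gap * oud + 0.02 * female
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "hospital_id": [f"H{i:03d}" for i in hosp],
            "oud": oud,
            "female": female,
            "y": y,
        }
    )


def inject_edge_cases(
    tables: Dict[str, pd.DataFrame], spec: Mapping[str, int]
) -> Dict[str, pd.DataFrame]:
    """Deterministically append records violating the cohort filters.

    ``spec`` maps rule names to counts: ``lag2`` (admission lag of 2
    days), ``prior_year_snf``, ``out_of_state`` (chosen SNF in a
    different state than the hospital), ``missing_coords``, ``underage``
    (age < 18).  An empty spec returns the tables unchanged.
    """
    known = {"lag2", "prior_year_snf", "out_of_state", "missing_coords", "underage"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown edge-case keys: {sorted(unknown)}")
    if not spec or all(v == 0 for v in spec.values()):
        return tables

    discharges = tables["discharges"]
    facilities = tables["facilities"]
    hospitals = tables["hospitals"].set_index("hospital_id")
    new_rows = []
    counter = 0
    for rule, count in spec.items():
        for _ in range(int(count)):
            row = discharges.iloc[counter % len(discharges)].copy()
            counter += 1
            row["discharge_id"] = f"E{counter:05d}"
            row["patient_id"] = f"PE{counter:05d}"
            if rule == "lag2":
                row["snf_admission_lag_days"] = 2
            elif rule == "prior_year_snf":
                row["had_prior_year_snf"] = True
            elif rule == "out_of_state":
                h_state = hospitals.loc[row["hospital_id"], "state_id"]
                other = facilities[facilities["state_id"] != h_state]
                if other.empty:
                    raise ValueError("cannot build out-of-state case: single state")
                row["chosen_facility_id"] = other["facility_id"].iloc[0]
            elif rule == "missing_coords":
                row["home_latitude"] = np.nan
            elif rule == "underage":
                row["age"] = 17.0
            new_rows.append(row)

    out = dict(tables)
    out["discharges"] = pd.concat(
        [discharges, pd.DataFrame(new_rows)], ignore_index=True
    )
    return out
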