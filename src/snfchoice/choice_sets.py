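"""Cohort filters, hospital-year choice sets, and preferred networks.

A discharge's *choice set* is the set of skilled nursing facilities a
patient leaving a given hospital in a given year could plausibly have
entered: the union of (a) every same-state SNF that received at least
one discharge from that hospital that year, (b) every SNF within a
radius (default 22 km) of the hospital, and (c) the k nearest SNFs
(default 15).  Category (a) guarantees the admitted SNF belongs to its
own set; (b) and (c) keep sets sensible in dense and thin markets
respectively.

A hospital-year's *preferred network* is the smallest set of
highest-volume SNFs that received a cumulative threshold share
(default 50%) of the hospital's prior-calendar-year SNF discharges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .geo import cross_distance_km
from .synthetic import classify_cumulative

logger = logging.getLogger(__name__)

#: Cohort rules in application order; the exclusion log follows this order.
FILTER_ORDER = (
    "age_under_18",
    "snf_admission_lag_over_1_day",
    "prior_year_snf_stay",
    "out_of_state_snf",
    "missing_geocoding",
)


@dataclass
class PreferredNetwork:
    """Preferred SNFs of one hospital-year."""

    hospital_id: str
    year: int
    ranked_facilities: List[str]
    preferred_set: List[str]
    cumulative_share_achieved: float
    threshold: float


def apply_cohort_filters(
    discharges: pd.DataFrame,
    facilities: pd.DataFrame,
    hospitals: pd.DataFrame,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the inclusion rules in order; return kept rows and a log.

    Rules, in order: adults only (age >= 18); SNF admission within one
    day of discharge; no SNF stay in the prior year; chosen SNF in the
    hospital's state; complete geocoding.  The log counts removals per
    rule as applied sequentially, so counts sum to input minus output.
    """
    fac_state = facilities.set_index("facility_id")["state_id"]
    hosp_state = hospitals.set_index("hospital_id")["state_id"]
    unknown_fac = set(discharges["chosen_facility_id"].dropna()) - set(fac_state.index)
    if unknown_fac:
        raise ValueError(f"discharges reference unknown facilities: {sorted(unknown_fac)[:5]}")
    unknown_hosp = set(discharges["hospital_id"]) - set(hosp_state.index)
    if unknown_hosp:
        raise ValueError(f"discharges reference unknown hospitals: {sorted(unknown_hosp)[:5]}")

    kept = discharges
    log: Dict[str, int] = {}
    for rule in FILTER_ORDER:
        if rule == "age_under_18":
            ok = kept["age"] >= 18.0
        elif rule == "snf_admission_lag_over_1_day":
            ok = kept["snf_admission_lag_days"] <= 1
        elif rule == "prior_year_snf_stay":
            ok = ~kept["had_prior_year_snf"].astype(bool)
        elif rule == "out_of_state_snf":
            ok = (
                kept["chosen_facility_id"].map(fac_state).to_numpy()
                == kept["hospital_id"].map(hosp_state).to_numpy()
            )
        elif rule == "missing_geocoding":
            ok = (
                kept["home_latitude"].notna()
                & kept["home_longitude"].notna()
                & kept["chosen_facility_id"].map(facilities.set_index("facility_id")["latitude"]).notna()
            )
        log[rule] = int((~ok).sum())
        kept = kept[ok]
    logger.info("cohort filters: kept %d of %d discharges (%s)", len(kept), len(discharges), log)
    return kept.reset_index(drop=True), log


def build_choice_set(
    hospital: pd.Series,
    year: int,
    facilities: pd.DataFrame,
    year_discharges: pd.DataFrame,
    radius_km: float = 22.0,
    k_nearest: int = 15,
) -> List[str]:
    """Union of discharge-linked, within-radius, and k-nearest SNFs.

    ``facilities`` must already be restricted to the hospital's state.
    Ordering is deterministic: descending shared volume this year, then
    ascending hospital distance, then facility_id.
    """
    if facilities.empty:
        raise ValueError(f"hospital {hospital['hospital_id']} has no same-state SNFs")
    fac_ids = facilities["facility_id"].to_numpy()
    dist = cross_distance_km(
        [hospital["latitude"]],
        [hospital["longitude"]],
        facilities["latitude"],
        facilities["longitude"],
    )[0]

    linked = year_discharges.loc[
        year_discharges["hospital_id"] == hospital["hospital_id"], "chosen_facility_id"
    ]
    volume = linked.value_counts().to_dict()

    members = set(np.flatnonzero(dist <= radius_km))
    members.update(np.lexsort((fac_ids, dist))[:k_nearest])
    members.update(i for i, f in enumerate(fac_ids) if f in volume)

    ordered = sorted(
        members, key=lambda i: (-volume.get(fac_ids[i], 0), dist[i], fac_ids[i])
    )
    return [fac_ids[i] for i in ordered]


def classify_preferred(
    prior_year_volumes: Mapping[str, int],
    threshold: float = 0.50,
    hospital_id: str = "",
    year: int = 0,
) -> PreferredNetwork:
    """Classify the cumulative-volume preferred network.

    Walks the descending-volume ranking (ties broken by ascending
    facility id) accumulating shares, and includes facilities up to and
    including the one whose addition first attains the threshold.
    A hospital with zero prior-year volume gets an empty preferred set.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    total = float(sum(prior_year_volumes.values()))
    ranked = [
        f for f, _ in sorted(prior_year_volumes.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    preferred = classify_cumulative(prior_year_volumes, threshold)
    if total <= 0:
        logger.warning(
            "hospital %s year %d: no prior-year SNF discharges; empty preferred set",
            hospital_id,
            year,
        )
        share = 0.0
    else:
        share = sum(prior_year_volumes[f] for f in preferred) / total
    return PreferredNetwork(
        hospital_id=hospital_id,
        year=year,
        ranked_facilities=ranked,
        preferred_set=preferred,
        cumulative_share_achieved=share,
        threshold=threshold,
    )


def prior_year_volumes(
    all_discharges: pd.DataFrame, hospital_id: str, year: int
) -> Dict[str, int]:
    """Shared discharge volume per SNF for the prior calendar year.

    Counts every SNF-bound discharge from the hospital (before cohort
    exclusions) — referral relationships reflect total flow.
    """
    years = pd.to_datetime(all_discharges["discharge_date"]).dt.year
    rows = all_discharges[
        (all_discharges["hospital_id"] == hospital_id) & (years == year - 1)
    ]
    return rows["chosen_facility_id"].value_counts().to_dict()


def build_networks(
    all_discharges: pd.DataFrame,
    hospital_ids: List[str],
    years: List[int],
    threshold: float = 0.50,
) -> Dict[Tuple[str, int], PreferredNetwork]:
    """Preferred networks for every (hospital, year) combination."""
    d = all_discharges.copy()
    d["_year"] = pd.to_datetime(d["discharge_date"]).dt.year
    grouped = d.groupby(["hospital_id", "_year"])["chosen_facility_id"]
    vol_map = {k: v.value_counts().to_dict() for k, v in grouped}
    out = {}
    for h in hospital_ids:
        for y in years:
            out[(h, y)] = classify_preferred(
                vol_map.get((h, y - 1), {}), threshold, hospital_id=h, year=y
            )
    return out


def assemble_choice_data(
    kept_discharges: pd.DataFrame,
    facilities: pd.DataFrame,
    hospitals: pd.DataFrame,
    networks: Mapping[Tuple[str, int], PreferredNetwork],
    radius_km: float = 22.0,
    k_nearest: int = 15,
) -> pd.DataFrame:
    """Long-format choice table: one row per (discharge, alternative).

    Columns: ids, ``choice`` indicator, ``closest`` indicator (minimum
    home distance, facility_id tie-break), ``oud``, cluster ``state_id``,
    the SNF attribute vector, and a ``weight`` placeholder (1.0).
    Row count equals the summed choice-set sizes.  A discharge whose
    chosen SNF is missing from its set is an upstream bug and raises.
    """
    d = kept_discharges.copy()
    d["_year"] = pd.to_datetime(d["discharge_date"]).dt.year
    fac = facilities.set_index("facility_id")
    hosp = hospitals.set_index("hospital_id")

    blocks: List[pd.DataFrame] = []
    for (h_id, year), grp in d.groupby(["hospital_id", "_year"], sort=True):
        hospital = hosp.loc[h_id]
        hospital = pd.concat([hospital, pd.Series({"hospital_id": h_id})])
        state_fac = facilities[facilities["state_id"] == hospital["state_id"]]
        members = build_choice_set(
            hospital, year, state_fac, d[d["_year"] == year], radius_km, k_nearest
        )
        f = fac.loc[members]
        d_hosp = cross_distance_km(
            [hospital["latitude"]], [hospital["longitude"]], f["latitude"], f["longitude"]
        )[0]
        net = networks[(h_id, year)]
        pref = np.array([1 if m in net.preferred_set else 0 for m in members])

        n_alt = len(members)
        d_home = cross_distance_km(
            grp["home_latitude"], grp["home_longitude"], f["latitude"], f["longitude"]
        )
        chosen_pos = pd.Index(members).get_indexer(grp["chosen_facility_id"])
        if np.any(chosen_pos < 0):
            bad = grp.loc[chosen_pos < 0, "discharge_id"].iloc[0]
            raise RuntimeError(
                f"discharge {bad}: chosen SNF absent from its choice set (upstream bug)"
            )
        # closest: min home distance; scanning columns in facility_id order
        # makes argmin's first-minimum rule the id tie-break
        perm = np.argsort(np.array(members, dtype=object))
        closest_pos = perm[np.argmin(d_home[:, perm], axis=1)]

        n_rows = len(grp) * n_alt
        block = pd.DataFrame(
            {
                "discharge_id": np.repeat(grp["discharge_id"].to_numpy(), n_alt),
                "hospital_id": h_id,
                "year": year,
                "state_id": hospital["state_id"],
                "facility_id": np.tile(np.array(members, dtype=object), len(grp)),
                "choice": 0,
                "closest": 0,
                "oud": np.repeat(grp["oud"].to_numpy().astype(int), n_alt),
                "preferred": np.tile(pref, len(grp)),
                "star_rating": np.tile(f["star_rating"].to_numpy(dtype=float), len(grp)),
                "dist_home_km": d_home.ravel(),
                "dist_hosp_km": np.tile(d_hosp, len(grp)),
                "for_profit": np.tile(f["for_profit"].to_numpy(dtype=float), len(grp)),
                "chain": np.tile(f["chain"].to_numpy(dtype=float), len(grp)),
                "hospital_affiliated": np.tile(
                    f["hospital_affiliated"].to_numpy(dtype=float), len(grp)
                ),
                "beds": np.tile(f["beds"].to_numpy(dtype=float), len(grp)),
                "occupancy_pct": np.tile(f["occupancy_pct"].to_numpy(dtype=float), len(grp)),
                "pct_medicaid": np.tile(f["pct_medicaid"].to_numpy(dtype=float), len(grp)),
                "weight": 1.0,
            }
        )
        flat = np.arange(len(grp)) * n_alt
        block.iloc[flat + chosen_pos, block.columns.get_loc("choice")] = 1
        block.iloc[flat + closest_pos, block.columns.get_loc("closest")] = 1
        blocks.append(block)

    out = pd.concat(blocks, ignore_index=True)
    out = out.sort_values(["discharge_id", "facility_id"], kind="mergesort").reset_index(
        drop=True
    )
    logger.info(
        "choice table: %d alternatives among %d discharges",
        len(out),
        out["discharge_id"].nunique(),
    )
    return out
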