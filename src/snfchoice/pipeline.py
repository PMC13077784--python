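"""Pipeline orchestration: simulate -> filter -> build -> match ->
weight -> fit-lpm -> fit-clogit -> margins -> iia, with resumable
stages, CSV + JSON-sidecar table I/O, and report assembly (covariate
balance, quintile placement shares, preferred-threshold sensitivity).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import choice_sets as cs
from . import cohort as ch
from . import lpm as lp
from . import margins as mg
from .clogit import ConditionalLogit, fit_by_quintile
from .config import PipelineConfig
from .synthetic import generate_population

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "build",
    "match",
    "weight",
    "fit-lpm",
    "fit-clogit",
    "margins",
    "iia",
)

STAGE_OUTPUTS: Dict[str, Tuple[str, ...]] = {
    "simulate": ("facilities.csv", "hospitals.csv", "discharges.csv", "ground_truth.json"),
    "filter": ("cohort.csv", "exclusion_log.json"),
    "build": ("networks.csv", "choice_long.csv", "cohort_outcomes.csv"),
    "match": ("matched.csv",),
    "weight": ("weights.csv",),
    "fit-lpm": ("lpm_results.csv",),
    "fit-clogit": ("clogit_results.csv",),
    "margins": ("margins.csv",),
    "iia": ("iia_results.csv",),
}


# ---------------------------------------------------------------------------
# table I/O: CSV with a JSON sidecar recording column kinds


def _kind(dtype, col: pd.Series) -> str:
    if pd.api.types.is_bool_dtype(dtype):
        return "bool"
    if pd.api.types.is_datetime64_any_dtype(dtype):
        return "date"
    if pd.api.types.is_integer_dtype(dtype):
        return "int"
    if pd.api.types.is_float_dtype(dtype):
        return "float"
    return "str"


def write_table(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    schema = {c: _kind(df[c].dtype, df[c]) for c in df.columns}
    out = df.copy()
    for c, k in schema.items():
        if k == "bool":
            out[c] = out[c].astype(int)
        elif k == "date":
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=1)
    )


def read_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    if sidecar.exists():
        schema = json.loads(sidecar.read_text())
        for c, k in schema.items():
            if c not in df.columns:
                continue
            if k == "bool":
                df[c] = df[c].astype(bool)
            elif k == "date":
                df[c] = pd.to_datetime(df[c])
    return df


def _stage_seed(seed: int, k: int) -> int:
    """Named substream: deterministic child seed per stage index."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(
    config: PipelineConfig,
    through: str = "iia",
    force: bool = False,
) -> Dict[str, object]:
    """Execute the stages in order up to ``through``.

    Stages whose outputs already exist are skipped until a stage has to
    (re)run, after which every later stage also reruns — deleting one
    intermediate re-executes only it and its downstream.  The resolved
    configuration is written next to the outputs.  Returns a dict of
    in-memory results for the stages that executed.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.json").write_text(config.model_dump_json(indent=1))

    results: Dict[str, object] = {"out_dir": out}
    run_log: Dict[str, Dict[str, int]] = {}
    dirty = force
    for stage in STAGES[: STAGES.index(through) + 1]:
        have = all((out / f).exists() for f in STAGE_OUTPUTS[stage])
        if have and not dirty:
            logger.info("stage %s: outputs present, skipped", stage)
            continue
        dirty = True
        logger.info("stage %s: running", stage)
        counts = _STAGE_FN[stage](config, out, results)
        run_log[stage] = counts
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return results


def _load(out: Path, name: str, results: Dict[str, object]):
    key = name.replace(".csv", "")
    if key not in results:
        results[key] = read_table(out / name)
    return results[key]


def _stage_simulate(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    gen_cfg = cfg.generator.model_copy(update={"seed": _stage_seed(cfg.seed, 0)})
    pop = generate_population(gen_cfg)
    write_table(pop.facilities, out / "facilities.csv")
    write_table(pop.hospitals, out / "hospitals.csv")
    write_table(pop.discharges, out / "discharges.csv")
    (out / "ground_truth.json").write_text(json.dumps(pop.truth.to_json_dict(), indent=1))
    results.update(
        facilities=pop.facilities, hospitals=pop.hospitals, discharges=pop.discharges,
        truth=pop.truth,
    )
    return {
        "facilities": len(pop.facilities),
        "hospitals": len(pop.hospitals),
        "discharges": len(pop.discharges),
    }


def _stage_filter(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    discharges = _load(out, "discharges.csv", results)
    facilities = _load(out, "facilities.csv", results)
    hospitals = _load(out, "hospitals.csv", results)
    kept, log = cs.apply_cohort_filters(discharges, facilities, hospitals)
    write_table(kept, out / "cohort.csv")
    (out / "exclusion_log.json").write_text(json.dumps(log, indent=1))
    results["cohort"] = kept
    results["exclusion_log"] = log
    return {"input": len(discharges), "kept": len(kept), **log}


def _stage_build(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    cohort = _load(out, "cohort.csv", results)
    discharges = _load(out, "discharges.csv", results)
    facilities = _load(out, "facilities.csv", results)
    hospitals = _load(out, "hospitals.csv", results)

    years = sorted(pd.to_datetime(cohort["discharge_date"]).dt.year.unique())
    networks = cs.build_networks(
        discharges, list(hospitals["hospital_id"]), years, cfg.preferred_threshold
    )
    net_rows = [
        {
            "hospital_id": n.hospital_id,
            "year": n.year,
            "preferred_set": ";".join(n.preferred_set),
            "cumulative_share": n.cumulative_share_achieved,
            "threshold": n.threshold,
        }
        for n in networks.values()
    ]
    write_table(pd.DataFrame(net_rows), out / "networks.csv")

    table = cs.assemble_choice_data(
        cohort, facilities, hospitals, networks, cfg.radius_km, cfg.k_nearest
    )
    write_table(table, out / "choice_long.csv")

    outcomes = lp.make_outcomes(cohort, facilities, networks, cfg.high_quality_stars)
    write_table(outcomes, out / "cohort_outcomes.csv")
    results.update(networks=networks, choice_long=table, cohort_outcomes=outcomes)
    return {
        "alternatives": len(table),
        "choice_sets": int(table["discharge_id"].nunique()),
        "networks": len(net_rows),
    }


def _stage_match(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    cohort = _load(out, "cohort_outcomes.csv", results)
    matched = ch.match(
        cohort, cfg.match_ratio, cfg.match_window_days, seed=_stage_seed(cfg.seed, 3)
    )
    rows = []
    for i, (case, controls) in enumerate(matched.pairs):
        rows.append({"pair_id": i, "discharge_id": case, "role": "case"})
        rows.extend(
            {"pair_id": i, "discharge_id": c, "role": "control"} for c in controls
        )
    matched_df = pd.DataFrame(rows)
    write_table(matched_df, out / "matched.csv")
    results["matched"] = matched_df
    results["matched_cohort"] = matched
    return {"pairs": len(matched.pairs), "unmatched_oud": matched.unmatched_oud}


def _stage_weight(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    cohort = _load(out, "cohort_outcomes.csv", results)
    matched_tbl = _load(out, "matched.csv", results)
    sample = cohort[cohort["discharge_id"].isin(set(matched_tbl["discharge_id"]))]
    fit = ch.fit_propensity(sample, knot_age=cfg.knot_age)
    weights = ch.compute_ipw(
        fit, sample.set_index("discharge_id")["oud"], cfg.trim_bounds
    )
    weights["quintile"] = ch.assign_quintiles(weights)
    wdf = weights.reset_index(names="discharge_id")
    write_table(wdf, out / "weights.csv")
    results["propensity_fit"] = fit
    results["weights"] = wdf
    return {"weighted": len(wdf), "trimmed": len(sample) - len(wdf)}


def _stage_lpm(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    outcomes = _load(out, "cohort_outcomes.csv", results)
    fits = {}
    rows = []
    for oc in ("preferred_entry", "high_quality_entry", "hq_given_preferred"):
        res = lp.FixedEffectsLPM.from_dataframe(outcomes, oc).fit()
        fits[oc] = res
        tab = res.summary().reset_index(names="term")
        tab.insert(0, "outcome", oc)
        tab["n_used"] = res.n_used
        tab["n_singletons_dropped"] = res.n_singletons_dropped
        rows.append(tab)
    write_table(pd.concat(rows, ignore_index=True), out / "lpm_results.csv")
    results["lpm_fits"] = fits
    return {"models": len(fits)}


def _matched_choice_table(out: Path, results: Dict) -> pd.DataFrame:
    table = _load(out, "choice_long.csv", results)
    matched_tbl = _load(out, "matched.csv", results)
    wdf = _load(out, "weights.csv", results)
    ids = set(matched_tbl["discharge_id"])
    sub = table[table["discharge_id"].isin(ids)].copy()
    wmap = wdf.set_index("discharge_id")["weight"]
    qmap = wdf.set_index("discharge_id")["quintile"]
    sub["weight"] = sub["discharge_id"].map(wmap)
    sub["quintile"] = sub["discharge_id"].map(qmap)
    # discharges trimmed out of the weighted sample keep weight 1 for the
    # unweighted fit and are excluded from weighted/quintile fits
    sub["trimmed"] = sub["weight"].isna()
    sub["weight"] = sub["weight"].fillna(1.0)
    return sub


def _stage_clogit(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    sub = _matched_choice_table(out, results)
    unweighted = ConditionalLogit.from_choice_table(sub).fit()
    wsub = sub[~sub["trimmed"]]
    weighted = ConditionalLogit.from_choice_table(wsub, weight_col="weight").fit()
    quintiles = fit_by_quintile(
        wsub,
        wsub.drop_duplicates("discharge_id").set_index("discharge_id")["quintile"],
        min_choice_sets=cfg.min_quintile_choice_sets,
    )
    fits = {"overall": unweighted, "ipw": weighted}
    fits.update({f"quintile_{q}": f for q, f in quintiles.items()})
    rows = []
    for name, f in fits.items():
        tab = f.summary().reset_index(names="term")
        tab.insert(0, "stratum", name)
        rows.append(tab)
    write_table(pd.concat(rows, ignore_index=True), out / "clogit_results.csv")
    results["clogit_fits"] = fits
    results["matched_choice_table"] = sub
    return {
        "strata": len(fits),
        "choice_sets": unweighted.n_choice_sets,
        "alternatives": unweighted.n_alternatives,
    }


def _stage_margins(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    if "clogit_fits" not in results:
        _stage_clogit(cfg, out, results)
    sub = results["matched_choice_table"]
    fits = results["clogit_fits"]
    effects: List[mg.MarginalEffect] = []
    for attr in ("preferred", "star_rating"):
        effects.append(mg.closest_snf_margin(fits["overall"], sub, attr, "overall"))
        effects.append(
            mg.closest_snf_margin(
                fits["ipw"], sub[~sub["trimmed"]], attr, "ipw"
            )
        )
        for name, f in fits.items():
            if not name.startswith("quintile_"):
                continue
            q = int(name.split("_")[1])
            qsub = sub[(~sub["trimmed"]) & (sub["quintile"] == q)]
            effects.append(mg.closest_snf_margin(f, qsub, attr, name))
    tab = pd.DataFrame([e.as_dict() for e in effects])
    write_table(tab, out / "margins.csv")
    results["margins"] = effects
    return {"rows": len(tab)}


def _stage_iia(cfg: PipelineConfig, out: Path, results: Dict) -> Dict[str, int]:
    if "clogit_fits" not in results:
        _stage_clogit(cfg, out, results)
    sub = results["matched_choice_table"]
    full = results["clogit_fits"]["overall"]
    rows = []
    for i, frac in enumerate(cfg.iia_drop_fractions):
        cmp = mg.iia_thinning_check(
            sub, frac, seed=_stage_seed(cfg.seed, 100 + i), full_fit=full
        )
        cmp = cmp.reset_index(names="term")
        cmp.insert(0, "drop_fraction", frac)
        rows.append(cmp)
    tab = pd.concat(rows, ignore_index=True)
    write_table(tab, out / "iia_results.csv")
    results["iia"] = tab
    return {"rows": len(tab)}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "build": _stage_build,
    "match": _stage_match,
    "weight": _stage_weight,
    "fit-lpm": _stage_lpm,
    "fit-clogit": _stage_clogit,
    "margins": _stage_margins,
    "iia": _stage_iia,
}


# ---------------------------------------------------------------------------
# reporting


def summarize_balance(
    cohort: pd.DataFrame,
    matched_ids: Optional[Sequence[str]] = None,
    weights: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Covariate means by exposure group across the three samples.

    Panels mirror the descriptive layout of the study: full sample,
    matched sample, and matched sample with inverse probability
    weights; each panel carries group means and the standardized mean
    difference.  An empty exposure group yields a missing panel with a
    warning rather than a failure.
    """
    import warnings as _warnings

    panels = {"full": (cohort, None)}
    if matched_ids is not None:
        matched = cohort[cohort["discharge_id"].isin(set(matched_ids))]
        panels["matched"] = (matched, None)
        if weights is not None:
            wmap = weights.set_index("discharge_id")["weight"]
            wsample = matched[matched["discharge_id"].isin(wmap.index)]
            panels["matched_ipw"] = (wsample, wsample["discharge_id"].map(wmap))

    blocks = []
    for name, (sample, w) in panels.items():
        oud = sample["oud"].astype(bool)
        if oud.sum() == 0 or (~oud).sum() == 0:
            _warnings.warn(f"balance panel {name!r}: an exposure group is empty; panel omitted")
            continue
        X = ch.propensity_design(sample)
        wv = np.ones(len(sample)) if w is None else np.asarray(w, dtype=float)
        mean1 = {
            c: np.average(X[c].to_numpy(dtype=float)[oud], weights=wv[oud]) for c in X.columns
        }
        mean0 = {
            c: np.average(X[c].to_numpy(dtype=float)[~oud], weights=wv[~oud]) for c in X.columns
        }
        smd = ch.standardized_mean_differences(sample, X, wv)
        block = pd.DataFrame(
            {"covariate": list(X.columns), "sample": name,
             "mean_oud": [mean1[c] for c in X.columns],
             "mean_non_oud": [mean0[c] for c in X.columns],
             "smd": [smd[c] for c in X.columns]}
        )
        blocks.append(block)
    if not blocks:
        return pd.DataFrame(
            columns=["covariate", "sample", "mean_oud", "mean_non_oud", "smd"]
        )
    return pd.concat(blocks, ignore_index=True)


def plot_quintile_shares(
    outcomes: pd.DataFrame, weights: pd.DataFrame, path: Optional[Path] = None
):
    """Placement shares by propensity quintile and exposure group.

    Grouped bars of the share entering preferred and high-quality SNFs
    (and high-quality among preferred entries) per quintile, for the
    matched sample.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = outcomes.merge(weights[["discharge_id", "quintile"]], on="discharge_id")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharey=True)
    panels = (
        ("preferred_entry", "Preferred SNF"),
        ("high_quality_entry", "High-quality SNF"),
        ("hq_given_preferred", "High-quality | preferred"),
    )
    width = 0.38
    for ax, (col, title) in zip(axes, panels):
        shares = merged.groupby(["quintile", "oud"])[col].mean().unstack("oud") * 100
        q = shares.index.to_numpy(dtype=float)
        ax.bar(q - width / 2, shares.get(False, shares.iloc[:, 0]), width, label="non-OUD")
        ax.bar(q + width / 2, shares.get(True, shares.iloc[:, -1]), width, label="OUD")
        ax.set_title(title)
        ax.set_xlabel("propensity quintile")
    axes[0].set_ylabel("% of discharges")
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def preferred_threshold_sensitivity(
    discharges: pd.DataFrame,
    cohort: pd.DataFrame,
    facilities: pd.DataFrame,
    hospitals: pd.DataFrame,
    matched_table: pd.DataFrame,
    grid: Sequence[float],
    radius_km: float = 22.0,
    k_nearest: int = 15,
) -> pd.DataFrame:
    """Re-run preferred classification and the choice model on a
    threshold grid; reports the preferred coefficient, its OUD
    interaction, and the closest-SNF preferred margins per threshold.
    """
    years = sorted(pd.to_datetime(cohort["discharge_date"]).dt.year.unique())
    rows = []
    for thr in grid:
        networks = cs.build_networks(
            discharges, list(hospitals["hospital_id"]), years, thr
        )
        sub = matched_table.copy()
        pref = {
            (h, y): set(n.preferred_set) for (h, y), n in networks.items()
        }
        sub["preferred"] = [
            1.0 if f in pref[(h, y)] else 0.0
            for f, h, y in zip(sub["facility_id"], sub["hospital_id"], sub["year"])
        ]
        fit = ConditionalLogit.from_choice_table(sub).fit()
        eff = mg.closest_snf_margin(fit, sub, "preferred", stratum=f"thr={thr:.2f}")
        rows.append(
            {
                "threshold": thr,
                "beta_preferred": fit.params["preferred"],
                "delta_preferred": fit.params["oud_x_preferred"],
                "interaction_p": eff.p_value,
                "margin_non_oud_pp": eff.margin_non_oud_pp,
                "margin_oud_pp": eff.margin_oud_pp,
                "difference_pp": eff.difference_pp,
            }
        )
    return pd.DataFrame(rows)
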