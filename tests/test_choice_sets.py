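"""Cohort filters, choice-set union rule, preferred classification,
and long-table assembly, each against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from snfchoice.choice_sets import (
    apply_cohort_filters,
    assemble_choice_data,
    build_choice_set,
    build_networks,
    classify_preferred,
)
from snfchoice.config import GeneratorConfig
from snfchoice.geo import EARTH_RADIUS_KM
from snfchoice.synthetic import generate_population, inject_edge_cases


def law_of_cosines_km(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(np.asarray(lon2) - lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return EARTH_RADIUS_KM * np.arccos(np.clip(c, -1.0, 1.0))


@pytest.fixture(scope="module")
def tiny_pop():
    return generate_population(
        GeneratorConfig(seed=17, n_discharges=400, n_hospitals=8, n_snfs=50, n_states=2)
    )


class TestCohortFilters:
    def test_clean_tables_pass_unchanged(self, tiny_pop):
        kept, log = apply_cohort_filters(
            tiny_pop.discharges, tiny_pop.facilities, tiny_pop.hospitals
        )
        assert len(kept) == len(tiny_pop.discharges)
        assert all(v == 0 for v in log.values())

    def test_each_rule_excludes_its_violations(self, tiny_pop):
        spec = {
            "lag2": 3,
            "prior_year_snf": 2,
            "out_of_state": 4,
            "missing_coords": 1,
            "underage": 2,
        }
        tables = inject_edge_cases(tiny_pop.tables(), spec)
        kept, log = apply_cohort_filters(
            tables["discharges"], tables["facilities"], tables["hospitals"]
        )
        assert len(kept) == len(tiny_pop.discharges)
        assert log["snf_admission_lag_over_1_day"] == 3
        assert log["prior_year_snf_stay"] == 2
        assert log["out_of_state_snf"] == 4
        assert log["missing_geocoding"] == 1
        assert log["age_under_18"] == 2
        assert sum(log.values()) == len(tables["discharges"]) - len(kept)

    def test_unlinkable_ids_raise(self, tiny_pop):
        bad = tiny_pop.discharges.copy()
        bad.loc[bad.index[0], "chosen_facility_id"] = "S9999"
        with pytest.raises(ValueError, match="unknown facilities"):
            apply_cohort_filters(bad, tiny_pop.facilities, tiny_pop.hospitals)


class TestBuildChoiceSet:
    def _market(self, seed, n_snf, far=False):
        rng = np.random.default_rng(seed)
        hospital = pd.Series(
            {"hospital_id": "H1", "latitude": 40.0, "longitude": -75.0, "state_id": "ST1"}
        )
        spread = 3.0 if far else 0.5
        fac = pd.DataFrame(
            {
                "facility_id": [f"S{i:03d}" for i in range(n_snf)],
                "state_id": "ST1",
                "latitude": 40.0 + rng.uniform(-spread, spread, n_snf),
                "longitude": -75.0 + rng.uniform(-spread, spread, n_snf),
            }
        )
        return hospital, fac

    def test_small_remote_market_truncates_to_all(self):
        hospital, fac = self._market(1, 3, far=True)
        empty = pd.DataFrame(columns=["hospital_id", "chosen_facility_id"])
        got = build_choice_set(hospital, 2018, fac, empty)
        assert sorted(got) == sorted(fac["facility_id"])

    def test_union_matches_brute_force_oracle(self):
        """40-SNF market; one discharge to a far SNF; the returned set
        must equal an independently computed three-category union."""
        hospital, fac = self._market(2, 40)
        d = law_of_cosines_km(
            hospital["latitude"], hospital["longitude"], fac["latitude"], fac["longitude"]
        )
        far_id = fac["facility_id"].iloc[int(np.argsort(d)[30])]
        discharges = pd.DataFrame(
            {"hospital_id": ["H1"], "chosen_facility_id": [far_id]}
        )
        got = build_choice_set(hospital, 2018, fac, discharges)
        oracle = (
            set(fac["facility_id"][d <= 22.0])
            | set(fac["facility_id"].iloc[np.argsort(d)[:15]])
            | {far_id}
        )
        assert set(got) == oracle
        assert far_id in got  # category (a) guarantees chosen membership

    def test_empty_market_raises(self):
        hospital, fac = self._market(3, 5)
        with pytest.raises(ValueError, match="no same-state SNFs"):
            build_choice_set(hospital, 2018, fac.iloc[:0], fac.iloc[:0])

    def test_ordering_is_deterministic(self):
        hospital, fac = self._market(4, 25)
        discharges = pd.DataFrame(
            {
                "hospital_id": ["H1"] * 4,
                "chosen_facility_id": [fac["facility_id"].iloc[i] for i in (5, 5, 5, 9)],
            }
        )
        a = build_choice_set(hospital, 2018, fac, discharges)
        b = build_choice_set(hospital, 2018, fac.sample(frac=1, random_state=0), discharges)
        assert a == b
        assert a[0] == fac["facility_id"].iloc[5]  # highest shared volume first


def brute_force_preferred(volumes, threshold):
    """All-prefixes oracle: shortest descending-volume prefix with
    cumulative share >= threshold."""
    ranked = sorted(volumes, key=lambda f: (-volumes[f], f))
    total = sum(volumes.values())
    for k in range(len(ranked) + 1):
        if sum(volumes[f] for f in ranked[:k]) >= threshold * total:
            return ranked[:k]
    return ranked


class TestClassifyPreferred:
    def test_exact_threshold_crossing_is_inclusive(self):
        net = classify_preferred({"A": 50, "B": 30, "C": 20}, 0.50)
        assert net.preferred_set == ["A"]
        assert net.cumulative_share_achieved == pytest.approx(0.50)

    def test_crossing_facility_included(self):
        net = classify_preferred({"A": 40, "B": 35, "C": 25}, 0.50)
        assert net.preferred_set == ["A", "B"]
        assert net.cumulative_share_achieved == pytest.approx(0.75)

    def test_zero_volume_gives_empty_set(self):
        net = classify_preferred({}, 0.50, hospital_id="H9", year=2020)
        assert net.preferred_set == []
        assert net.cumulative_share_achieved == 0.0

    def test_random_volumes_match_prefix_oracle_and_minimality(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 12)
            vols = {f"S{i}": int(v) for i, v in enumerate(rng.integers(0, 50, n))}
            if sum(vols.values()) == 0:
                vols["S0"] = 1
            thr = float(rng.uniform(0.05, 0.95))
            got = classify_preferred(vols, thr).preferred_set
            assert got == brute_force_preferred(vols, thr)
            total = sum(vols.values())
            share = sum(vols[f] for f in got) / total
            assert share >= thr - 1e-12
            if got:  # minimality: dropping the last member falls below
                assert (share - vols[got[-1]] / total) < thr

    def test_preferred_set_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        vols = {f"S{i}": int(v) for i, v in enumerate(rng.integers(1, 40, 9))}
        sizes = [
            len(classify_preferred(vols, t).preferred_set)
            for t in (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80)
        ]
        assert sizes == sorted(sizes)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_preferred({"A": 1}, 1.0)


class TestAssemble:
    def test_row_counts_and_choice_indicators(self, tiny_pop):
        kept, _ = apply_cohort_filters(
            tiny_pop.discharges, tiny_pop.facilities, tiny_pop.hospitals
        )
        years = sorted(pd.to_datetime(kept["discharge_date"]).dt.year.unique())
        networks = build_networks(
            tiny_pop.discharges, list(tiny_pop.hospitals["hospital_id"]), years
        )
        table = assemble_choice_data(kept, tiny_pop.facilities, tiny_pop.hospitals, networks)
        sizes = table.groupby("discharge_id").size()
        assert len(table) == sizes.sum()
        assert (table.groupby("discharge_id")["choice"].sum() == 1).all()
        assert (table.groupby("discharge_id")["closest"].sum() == 1).all()
        # every chosen row's facility is the discharge's actual SNF
        chosen = table[table["choice"] == 1].set_index("discharge_id")["facility_id"]
        expect = kept.set_index("discharge_id")["chosen_facility_id"]
        assert chosen.sort_index().equals(expect.sort_index())

    def test_permuted_input_gives_identical_table(self, tiny_pop):
        kept, _ = apply_cohort_filters(
            tiny_pop.discharges, tiny_pop.facilities, tiny_pop.hospitals
        )
        years = sorted(pd.to_datetime(kept["discharge_date"]).dt.year.unique())
        networks = build_networks(
            tiny_pop.discharges, list(tiny_pop.hospitals["hospital_id"]), years
        )
        a = assemble_choice_data(kept, tiny_pop.facilities, tiny_pop.hospitals, networks)
        shuffled = kept.sample(frac=1, random_state=4).reset_index(drop=True)
        b = assemble_choice_data(shuffled, tiny_pop.facilities, tiny_pop.hospitals, networks)
        pd.testing.assert_frame_equal(a, b)

    def test_generator_networks_reproduced_exactly(self, tiny_pop):
        """Pipeline classification equals the generator's dynamic truth."""
        years = list(range(2016, 2020))
        networks = build_networks(
            tiny_pop.discharges, list(tiny_pop.hospitals["hospital_id"]), years
        )
        for (h, y), net in networks.items():
            assert net.preferred_set == tiny_pop.truth.networks[y][h]
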