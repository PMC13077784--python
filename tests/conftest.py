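"""Shared fixtures: small synthetic populations and a pipeline run."""

import numpy as np
import pandas as pd
import pytest

from snfchoice.config import GeneratorConfig, PipelineConfig
from snfchoice.synthetic import generate_population


@pytest.fixture(scope="session")
def small_population():
    """Compact multi-state population with default confounding."""
    cfg = GeneratorConfig(
        seed=11,
        n_states=3,
        n_hospitals=15,
        n_snfs=90,
        n_discharges=12_000,
        oud_prevalence=0.05,  # boosted so the matched subsample is exercisable at this n
        year_start=2016,
        year_end=2019,
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline execution shared across integration tests."""
    from snfchoice.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        seed=5,
        out_dir=str(out),
        generator=GeneratorConfig(
            seed=5,
            n_states=3,
            n_hospitals=15,
            n_snfs=90,
            n_discharges=8_000,
            oud_prevalence=0.06,
            year_start=2016,
            year_end=2019,
        ),
    )
    results = run_pipeline(cfg)
    return cfg, results


def make_choice_table(sets, oud=None, state=None, extra_cols=None):
    """Hand-built long-format choice table.

    ``sets`` is a list of (attribute_matrix, chosen_index); attribute
    columns are named x0, x1, ...  ``oud``/``state`` give one value per
    set.
    """
    rows = []
    for g, (X, chosen) in enumerate(sets):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for j in range(X.shape[0]):
            row = {
                "discharge_id": f"d{g}",
                "choice": 1 if j == chosen else 0,
                "oud": 0 if oud is None else int(oud[g]),
                "state_id": "s0" if state is None else state[g],
            }
            for k in range(X.shape[1]):
                row[f"x{k}"] = X[j, k]
            rows.append(row)
    df = pd.DataFrame(rows)
    if extra_cols:
        for c, v in extra_cols.items():
            df[c] = v
    return df
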