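"""Shared fixtures: the canonical study-condition fixture is expensive to
generate (~3k patients, ~160k enrollment rows), so it is built once per
session and every test reads from it."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from bonemet.cohort import apply_inclusion_exclusion
from bonemet.io import claims_by_patient
from bonemet.phenotype import classify_cohort
from bonemet.simulate import (
    CrossTabSpec,
    Fixture,
    FixtureSpec,
    canonical_spec,
    generate_fixture,
)
from bonemet.stats import CrossTab2x2, concordance, crosstab


@dataclass
class PipelineRun:
    spec: FixtureSpec
    fixture: Fixture
    cohort: list
    log: pd.DataFrame
    status: pd.DataFrame
    crosstabs: dict[str, CrossTab2x2]
    concordance: dict


def run_pipeline_in_memory(spec: FixtureSpec) -> PipelineRun:
    fixture = generate_fixture(spec)
    cohort, log = apply_inclusion_exclusion(fixture.registry, fixture.enrollment)
    dx_months = {m.patient_id: m.dx_month for m in cohort}
    status = classify_cohort(dx_months, claims_by_patient(fixture.claims))
    registry_flags = {m.patient_id: m.registry_bm for m in cohort}
    tabs, results = {}, {}
    for name in ("a1", "a2", "a3", "a3_expanded"):
        flags = dict(zip(status["patient_id"], status[name].astype(bool)))
        tabs[name] = crosstab(registry_flags, flags)
        results[name] = concordance(tabs[name])
    return PipelineRun(spec, fixture, cohort, log, status, tabs, results)


@pytest.fixture(scope="session")
def canonical_run() -> PipelineRun:
    return run_pipeline_in_memory(canonical_spec(seed=20140102))


def small_spec(
    n_pos: int = 20,
    n_neg: int = 16,
    cells: dict[str, tuple[int, int]] | None = None,
    **overrides,
) -> FixtureSpec:
    """A tiny internally-consistent fixture spec for fast tests.

    ``cells`` maps approach -> (tp, fp); defaults exercise every recipe.
    """
    cells = cells or {"a1": (12, 9), "a2": (10, 7), "a3": (7, 4)}
    crosstabs = {
        name: CrossTabSpec(name, tp, fp, n_pos - tp, n_neg - fp)
        for name, (tp, fp) in cells.items()
    }
    defaults = dict(
        crosstabs=crosstabs,
        n_total=n_pos + n_neg,
        n_registry_bm=n_pos,
        n_expanded_extra_tp=3,
        n_expanded_extra_fp=2,
        n_decoys_by_reason={},
        seed=11,
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


def random_consistent_spec(rng: np.random.Generator) -> FixtureSpec:
    """Draw a random fixture spec satisfying the margin/nesting invariants."""
    n_pos = int(rng.integers(6, 25))
    n_neg = int(rng.integers(6, 25))
    tps = sorted(int(rng.integers(0, n_pos + 1)) for _ in range(3))
    fps = sorted(int(rng.integers(0, n_neg + 1)) for _ in range(3))
    cells = {
        "a1": (tps[2], fps[2]),
        "a2": (tps[1], fps[1]),
        "a3": (tps[0], fps[0]),
    }
    extra_tp = int(rng.integers(0, n_pos - tps[2] + 1))
    extra_fp = int(rng.integers(0, n_neg - fps[2] + 1))
    return small_spec(
        n_pos,
        n_neg,
        cells,
        n_expanded_extra_tp=extra_tp,
        n_expanded_extra_fp=extra_fp,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
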