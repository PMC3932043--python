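"""Stage orchestration: simulate -> select -> phenotype -> evaluate.

Every stage reads and writes plain CSV so any stage can be re-run in
isolation from the intermediates of a previous run; ``run_all`` chains the
four stages and records a manifest (seed, row counts, SHA-256 digests of
every emitted table) so a run is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .codes import DEFAULT_CODESET, CodeSet
from .cohort import CohortMember, apply_inclusion_exclusion, exclusion_counts
from .datamodel import Claim
from .errors import StageError
from .io import claims_by_patient, read_claims, read_tables
from .phenotype import classify_cohort
from .simulate import FixtureSpec, canonical_spec, generate_fixture
from .stats import (
    SUPPRESSION_THRESHOLD,
    concordance,
    crosstab,
    render_utilization,
    round_half_up,
    utilization_table,
)
from .timeutil import parse_month

logger = logging.getLogger(__name__)

UTILIZATION_CATEGORIES_POST = (
    "bmd_test",
    "psa_test",
    "oncologist_visit",
    "bone_biopsy",
    "bone_joint_imaging",
    "radiation",
    "radiopharmaceutical",
    "iv_bisphosphonate",
)
UTILIZATION_CATEGORIES_WINDOW = ("psa_test", "bone_biopsy", "bone_joint_imaging")


@dataclass
class RunConfig:
    """One-stop configuration for an end-to-end run."""

    out_dir: Path
    seed: int = 20140102
    spec: FixtureSpec | None = None  # None -> canonical study-condition spec
    codeset: CodeSet = DEFAULT_CODESET
    ci_method: str = "wald"
    suppress_threshold: int = SUPPRESSION_THRESHOLD
    approaches: tuple[str, ...] = ("a1", "a2", "a3", "a3_expanded")
    study_end: str = "2009-12"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise StageError(stage, f"required input file not found: {path}")
    return Path(path)


def stage_simulate(config: RunConfig) -> Path:
    raw_dir = config.out_dir / "raw"
    spec = config.spec if config.spec is not None else canonical_spec(seed=config.seed)
    generate_fixture(spec, out_dir=raw_dir)
    return raw_dir


def stage_select(
    raw_dir: Path, out_dir: Path, study_end: str = "2009-12"
) -> tuple[list[CohortMember], pd.DataFrame]:
    for name in ("registry.csv", "claims.csv", "enrollment.csv"):
        _require(Path(raw_dir) / name, "select")
    registry, _, enrollment = read_tables(raw_dir)
    cohort, log = apply_inclusion_exclusion(
        registry, enrollment, study_end=parse_month(study_end)
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out_dir / "cohort.csv")
    log.to_csv(out_dir / "exclusions.csv", index=False)
    counts = exclusion_counts(log)
    logger.info("exclusion cascade:\n%s", counts.to_string())
    return cohort, log


def write_cohort(cohort: list[CohortMember], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "dx_month": str(m.dx_month),
                "censor_month": str(m.censor_month),
                "registry_bm": "true" if m.registry_bm else "false",
            }
            for m in cohort
        ],
        columns=["patient_id", "dx_month", "censor_month", "registry_bm"],
    ).to_csv(path, index=False)


def read_cohort(path: Path) -> list[CohortMember]:
    frame = pd.read_csv(_require(path, "read_cohort"), dtype=str)
    return [
        CohortMember(
            patient_id=row.patient_id,
            dx_month=parse_month(row.dx_month),
            censor_month=parse_month(row.censor_month),
            registry_bm=row.registry_bm == "true",
        )
        for row in frame.itertuples(index=False)
    ]


def stage_phenotype(
    cohort: list[CohortMember],
    claims: list[Claim],
    out_path: Path,
    codeset: CodeSet = DEFAULT_CODESET,
) -> pd.DataFrame:
    dx_months = {m.patient_id: m.dx_month for m in cohort}
    status = classify_cohort(dx_months, claims_by_patient(claims), codeset)
    out = status.copy()
    for col in ("a1", "a2", "a3", "a3_expanded", "bm_ever"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(out_path, index=False)
    return status


def stage_evaluate(
    cohort: list[CohortMember],
    status: pd.DataFrame,
    claims: list[Claim],
    out_dir: Path,
    registry_frame: pd.DataFrame | None = None,
    ci_method: str = "wald",
    suppress_threshold: int = SUPPRESSION_THRESHOLD,
    approaches: tuple[str, ...] = ("a1", "a2", "a3", "a3_expanded"),
) -> dict:
    """Concordance per approach plus the stratified utilization tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry_flags = {m.patient_id: m.registry_bm for m in cohort}
    flags_by_approach = {
        name: dict(zip(status["patient_id"], status[name].astype(bool)))
        for name in approaches
    }

    results = {}
    table2_rows = {stat: {} for stat in ("sensitivity", "specificity", "ppv")}
    for name in approaches:
        ct = crosstab(registry_flags, flags_by_approach[name])
        result = concordance(ct, ci_method=ci_method)
        results[name] = {"crosstab": ct, "concordance": result}
        for stat, ci in (
            ("sensitivity", result.sensitivity_ci),
            ("specificity", result.specificity_ci),
            ("ppv", result.ppv_ci),
        ):
            point = getattr(result, stat)
            table2_rows[stat][name] = (
                f"{round_half_up(point, 3):.3f} "
                f"({round_half_up(ci[0], 3):.3f} - {round_half_up(ci[1], 3):.3f})"
                if point is not None
                else "undefined"
            )

    pd.DataFrame(
        [{"statistic": stat, **by_approach} for stat, by_approach in table2_rows.items()]
    ).to_csv(out_dir / "table2.csv", index=False)

    _write_table1(cohort, flags_by_approach, registry_frame, out_dir / "table1.csv")

    claims_map = claims_by_patient(claims)
    a3_strata = {
        pid: ("concurrent_bm" if flag else "no_concurrent_bm")
        for pid, flag in flags_by_approach["a3"].items()
    }
    seer_strata = {
        pid: ("seer_bm" if flag else "no_seer_bm") for pid, flag in registry_flags.items()
    }
    _write_utilization(
        cohort, claims_map, a3_strata, seer_strata, out_dir / "table3.csv", suppress_threshold
    )
    m1b_cohort = [m for m in cohort if m.registry_bm]
    m1b_strata = {pid: a3_strata[pid] for pid in (m.patient_id for m in m1b_cohort)}
    _write_utilization(
        cohort=m1b_cohort,
        claims_map=claims_map,
        primary=m1b_strata,
        secondary=None,
        path=out_dir / "table4.csv",
        threshold=suppress_threshold,
    )
    return results


def _write_table1(cohort, flags_by_approach, registry_frame, path: Path) -> None:
    n = len(cohort)
    rows = [{"variable": "cohort_size", "n": n, "pct": ""}]
    n_bm = sum(m.registry_bm for m in cohort)
    rows.append(
        {"variable": "seer_bm_m1b", "n": n_bm, "pct": round_half_up(100 * n_bm / n, 1)}
    )
    for name, flags in flags_by_approach.items():
        k = sum(flags.values())
        rows.append(
            {
                "variable": f"claims_bm_concurrent_{name}",
                "n": k,
                "pct": round_half_up(100 * k / n, 1),
            }
        )
    if registry_frame is not None:
        kept = registry_frame[
            registry_frame["patient_id"].isin({m.patient_id for m in cohort})
        ]
        for column in ("race", "comorbidity_class"):
            for value, count in kept[column].value_counts().items():
                rows.append(
                    {
                        "variable": f"{column}_{value}",
                        "n": int(count),
                        "pct": round_half_up(100 * count / n, 1),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_utilization(cohort, claims_map, primary, secondary, path, threshold) -> None:
    blocks = []
    for strata in (primary, secondary):
        if strata is None:
            continue
        labels = list(dict.fromkeys(strata.values()))
        rows = []
        for period, categories in (
            ("post", UTILIZATION_CATEGORIES_POST),
            ("window", UTILIZATION_CATEGORIES_WINDOW),
        ):
            rows.extend(
                utilization_table(
                    cohort, claims_map, strata, categories, period, threshold
                )
            )
        rendered = render_utilization(rows, labels, threshold)
        blocks.append(rendered.set_index(["category", "period"]))
    combined = pd.concat(blocks, axis=1).reset_index()
    combined.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all four stages; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        raw_dir = stage_simulate(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    try:
        cohort, log = stage_select(raw_dir, out_dir, study_end=config.study_end)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("select", str(exc)) from exc
    try:
        claims = read_claims(raw_dir / "claims.csv")
        status = stage_phenotype(
            cohort, claims, out_dir / "bm_status.csv", config.codeset
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("phenotype", str(exc)) from exc
    try:
        registry_frame = pd.read_csv(raw_dir / "registry.csv", dtype=str)
        report_dir = out_dir / "report"
        results = stage_evaluate(
            cohort,
            status,
            claims,
            report_dir,
            registry_frame=registry_frame,
            ci_method=config.ci_method,
            suppress_threshold=config.suppress_threshold,
            approaches=config.approaches,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    emitted = sorted(
        str(p.relative_to(out_dir))
        for p in out_dir.rglob("*.csv")
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "ci_method": config.ci_method,
        "suppress_threshold": config.suppress_threshold,
        "counts": {
            "registry_in": int(len(log)),
            "retained": len(cohort),
            "excluded": int((log["exclusion_reason"] != "").sum()),
            "flagged": {
                name: int(res["crosstab"].n_flagged) for name, res in results.items()
            },
        },
        "files": {name: _sha256(out_dir / name) for name in emitted},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
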