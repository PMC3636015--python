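"""End-to-end analysis: records in, machine-readable report out.

The pipeline runs classification → valuation → extrapolation → costs →
cost-effectiveness → sensitivity → effect sizes on a participant dataset
(a CSV, or the published-summary reconstruction when no input is given)
and emits a JSON report in which every rounded display value sits next to
its unrounded counterpart, plus CSV matrices for human diffing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

from . import __version__
from ._rounding import round_half_up
from .cea import break_even_persons, ce_table, return_multiple
from .costs import amortize, cost_ratio
from .extrapolation import (
    change_factor,
    extrapolate_delta_h,
    persons_per_qaly,
    qaly_gain,
)
from .reference import (
    COST_SCHEDULES,
    PERSONS_TREATED_GRID,
    QALY_VALUES_K_EUR,
    REFERENCE_OUTCOMES,
    reference_records,
)
from .scales import (
    CategoryScheme,
    DEFAULT_SCHEME,
    DistressSource,
    ParticipantRecord,
    read_participants,
)
from .sensitivity import run_scenarios, scenarios_frame
from .stats import change_contrast, hedges_g
from .valuation import (
    DeltaH,
    ValuationMatrix,
    between_groups_delta_h,
    build_descriptive_matrix,
    delta_h,
    load_valuation_matrix,
    total_qol,
)

logger = logging.getLogger("rossercea")

__all__ = ["PipelineConfig", "run_pipeline", "validate_report", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one pipeline run.

    With all defaults the run reproduces the published analysis from the
    printed summary tables.
    """

    input_path: Optional[str] = None
    valuation_path: Optional[str] = None
    scheme: CategoryScheme = DEFAULT_SCHEME
    distress_source: DistressSource = DistressSource.PER_TIMEPOINT
    horizon_years: float = 1.0
    scenarios: Sequence[int] = (1, 2, 3, 4, 5)
    qaly_values: Mapping[str, float] = field(default_factory=lambda: dict(QALY_VALUES_K_EUR))
    persons_treated: Sequence[int] = PERSONS_TREATED_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(f"input file not found: {self.input_path}")
        if self.valuation_path is not None and not Path(self.valuation_path).exists():
            raise FileNotFoundError(f"valuation file not found: {self.valuation_path}")

    def digest(self) -> str:
        payload = {
            "input_path": self.input_path,
            "valuation_path": self.valuation_path,
            "scheme": {
                "cesd_disability_edges": list(self.scheme.cesd_disability_edges),
                "cesd_subgroup_edges": list(self.scheme.cesd_subgroup_edges),
                "k10_distress_edges": list(self.scheme.k10_distress_edges),
            },
            "distress_source": self.distress_source.value,
            "horizon_years": self.horizon_years,
            "scenarios": list(self.scenarios),
            "qaly_values": dict(self.qaly_values),
            "persons_treated": list(self.persons_treated),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in (
            "input_path", "valuation_path", "horizon_years", "scenarios",
            "qaly_values", "persons_treated", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "distress_source" in raw:
            kwargs["distress_source"] = DistressSource(raw["distress_source"])
        if "scheme" in raw:
            kwargs["scheme"] = CategoryScheme.from_dict(raw["scheme"])
        return cls(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the analysis report as a plain dict."""
    records = _load_records(config)
    valuation = _load_valuation(config)
    qol = _qol_stage(records, valuation, config)
    extrap = _extrapolation_stage(qol, config)
    costs = _cost_stage()
    ce = _ce_stage(extrap, costs, config)
    sens = _sensitivity_stage(records, valuation, config)
    effect = _stats_stage(records)
    report = {
        "provenance": {
            "package_version": __version__,
            "config_sha256": config.digest(),
            "seed": config.seed,
            "n_records": len(records),
        },
        "descriptive_matrices": qol["matrices_grid"],
        "qol": qol["summary"],
        "extrapolation": extrap,
        "costs": costs,
        "cost_effectiveness": ce,
        "sensitivity": sens,
        "effect_sizes": effect,
    }
    problems = validate_report(report)
    if problems:  # defensive: indicates an internal error, not bad user input
        raise RuntimeError("report failed schema validation: " + "; ".join(problems))
    return report


@_stage("load_records")
def _load_records(config: PipelineConfig) -> list[ParticipantRecord]:
    if config.input_path is None:
        return reference_records()
    return read_participants(config.input_path)


@_stage("load_valuation")
def _load_valuation(config: PipelineConfig) -> ValuationMatrix:
    return load_valuation_matrix(config.valuation_path)


@_stage("qol_valuation")
def _qol_stage(records, valuation, config) -> dict[str, Any]:
    matrices, summary, grids = {}, {}, {}
    dh: dict[str, DeltaH] = {}
    for arm in ("intervention", "control"):
        per_tp = {}
        for tp in ("pre", "post"):
            m = build_descriptive_matrix(
                records, arm, tp, config.scheme, config.distress_source
            )
            matrices[(arm, tp)] = m
            grids[f"{arm}_{tp}"] = m.to_frame().to_dict(orient="index")
            q = total_qol(m, valuation)
            per_tp[tp] = q
        dh[arm] = delta_h(per_tp["pre"], per_tp["post"])
        summary[arm] = {
            "n": per_tp["pre"].n,
            "total_pre": per_tp["pre"].total,
            "total_post": per_tp["post"].total,
            "mean_pre": per_tp["pre"].mean,
            "mean_post": per_tp["post"].mean,
            "total_pre_display": round_half_up(per_tp["pre"].total, 2),
            "total_post_display": round_half_up(per_tp["post"].total, 2),
            "delta_h": dh[arm].value,
            "delta_h_display": round_half_up(dh[arm].value, 3),
        }
    between = between_groups_delta_h(dh["intervention"], dh["control"])
    summary["between_groups"] = {
        "delta_h": between.value,
        "delta_h_display": round_half_up(between.value, 3),
    }
    return {"matrices": matrices, "matrices_grid": grids, "summary": summary, "dh": dh, "between": between}


@_stage("extrapolation")
def _extrapolation_stage(qol, config) -> dict[str, Any]:
    factors = {arm: change_factor(REFERENCE_OUTCOMES[arm]) for arm in ("intervention", "control")}
    ext = {
        arm: extrapolate_delta_h(qol["dh"][arm], factors[arm])
        for arm in ("intervention", "control")
    }
    between_ext = between_groups_delta_h(ext["intervention"], ext["control"])
    gain = qaly_gain(between_ext, config.horizon_years)
    out: dict[str, Any] = {
        "change_factors": factors,
        "delta_h_extrapolated": {arm: ext[arm].value for arm in ext},
        "between_groups_extrapolated": between_ext.value,
        "qaly_gain": gain.value,
        "horizon_years": config.horizon_years,
    }
    out["persons_per_qaly"] = persons_per_qaly(gain) if gain.value > 0 else None
    return out


@_stage("cost_model")
def _cost_stage() -> dict[str, Any]:
    amortized = {name: amortize(sched) for name, sched in COST_SCHEDULES.items()}
    return {
        "schedules": {
            name: {
                "per_year_totals": list(a.per_year_totals),
                "mean_annual": a.mean_annual,
                "mean_annual_display": round_half_up(a.mean_annual, 1),
            }
            for name, a in amortized.items()
        },
        "translation_vs_development_pct": cost_ratio(
            amortized["translation_norway"], amortized["development_australia"]
        ),
        "raw_development_pct": 100.0
        * COST_SCHEDULES["translation_norway"].development
        / COST_SCHEDULES["development_australia"].development,
    }


@_stage("cost_effectiveness")
def _ce_stage(extrap, costs, config) -> dict[str, Any]:
    ppq = extrap["persons_per_qaly"]
    if ppq is None:
        return {"note": "no positive QALY gain; CE table not computed", "table": []}
    # The CE grid consumes whole-€1000 annual costs (half-even at the .5);
    # published CERs derive from these whole-number cost figures.
    sched_costs = {
        name: float(round(s["mean_annual"])) for name, s in costs["schedules"].items()
    }
    table = ce_table(config.qaly_values, sched_costs, config.persons_treated, ppq)
    be = {
        name: {
            est: break_even_persons(v, ppq, cost)
            for est, v in config.qaly_values.items()
        }
        for name, cost in sched_costs.items()
    }
    rm = {}
    for _, row in table.iterrows():
        rm[f"{row['project']}:{row['estimate']}:{row['persons_treated']}"] = return_multiple(
            row["total_savings"], row["annual_cost"]
        )
    return {
        "persons_per_qaly": ppq,
        "table": table.to_dict(orient="records"),
        "break_even_persons": be,
        "return_multiples": rm,
    }


@_stage("sensitivity")
def _sensitivity_stage(records, valuation, config) -> list[dict[str, Any]]:
    results = run_scenarios(
        records, config.scenarios, valuation, config.scheme, config.distress_source
    )
    return scenarios_frame(results).to_dict(orient="records")


@_stage("trial_stats")
def _stats_stage(records) -> dict[str, Any]:
    contrasts = {}
    for arm in ("intervention", "control"):
        pre = [r.cesd_pre for r in records if r.arm == arm and r.completer]
        post = [r.cesd_post for r in records if r.arm == arm and r.completer]
        contrasts[arm] = change_contrast(pre, post)
    try:
        es = hedges_g(contrasts["intervention"], contrasts["control"])
        effect = {"g": es.g, "se": es.se}
    except ValueError:
        effect = {"g": None, "se": None}
    return {
        "contrasts": {
            arm: {"mean": c.mean, "sd": c.sd, "n": c.n} for arm, c in contrasts.items()
        },
        "hedges_g": effect,
    }


_REQUIRED_KEYS = {
    "provenance": dict,
    "descriptive_matrices": dict,
    "qol": dict,
    "extrapolation": dict,
    "costs": dict,
    "cost_effectiveness": dict,
    "sensitivity": list,
    "effect_sizes": dict,
}


def validate_report(report: Mapping[str, Any]) -> list[str]:
    """Check the report against the published schema; return problem list."""
    problems = []
    for key, typ in _REQUIRED_KEYS.items():
        if key not in report:
            problems.append(f"missing section {key!r}")
        elif not isinstance(report[key], typ):
            problems.append(f"section {key!r} should be {typ.__name__}")
    if not problems:
        for arm in ("intervention", "control"):
            if arm not in report["qol"]:
                problems.append(f"qol section missing arm {arm!r}")
        for field_ in ("package_version", "config_sha256", "seed"):
            if field_ not in report["provenance"]:
                problems.append(f"provenance missing {field_!r}")
    return problems


def write_report(report: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write report.json plus per-matrix CSVs; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    for name, grid in report["descriptive_matrices"].items():
        pd.DataFrame.from_dict(grid, orient="index").to_csv(out / f"matrix_{name}.csv")
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return path
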