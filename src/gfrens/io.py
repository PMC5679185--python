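"""Cohort file I/O, report serialisation and run configuration.

The cohort file is delimited text (comma by default) with a header row and
columns ``id,age,sex,scr,scr_unit,mgfr``; ``sex`` accepts F/M/female/male
case-insensitively, ``scr_unit`` is ``mg_per_dl`` (default) or
``umol_per_l``, and ``mgfr`` may be empty.  Rows failing validation are
collected into a reject report rather than silently dropped; ``strict``
promotes them to an error.

Evaluation reports serialise losslessly to JSON and render to TSV or
Markdown tables (metrics at one decimal, p-values at three, with a dagger
marking comparisons significant at p < 0.05).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from .equations import DomainError, PatientRecord, Sex, convert_creatinine
from .validation import (
    ALPHA,
    ComparisonResult,
    EvaluationReport,
    MetricEstimate,
    PerformanceSummary,
)

__all__ = [
    "SchemaError",
    "CohortReadResult",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "report_to_dict",
    "report_from_dict",
    "write_report",
    "render_report_table",
]

REQUIRED_COLUMNS = ("id", "age", "sex", "scr")
SEX_ALIASES = {"f": Sex.FEMALE, "female": Sex.FEMALE, "m": Sex.MALE, "male": Sex.MALE}


class SchemaError(ValueError):
    """The input file lacks required structure."""


@dataclass
class CohortReadResult:
    """Validated records, the canonical cohort frame, and rejected rows."""

    records: list[PatientRecord]
    frame: pd.DataFrame
    rejects: pd.DataFrame  # columns: row, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


@dataclass
class RunConfig:
    """Shared run options for the command-line workflows."""

    seed: int = 0
    bootstrap: int = 2000
    subgroup_edges: tuple[float, ...] = (30.0, 60.0)
    difference_direction: str = "mgfr_minus_egfr"
    strict: bool = False
    ann: dict[str, Any] = field(default_factory=dict)
    svm: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bootstrap < 100:
            raise ValueError("bootstrap draws must be >= 100")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        if "subgroup_edges" in known:
            known["subgroup_edges"] = tuple(known["subgroup_edges"])
        return cls(**known)


def read_cohort(
    path: str | Path, delimiter: str = ",", strict: bool = False
) -> CohortReadResult:
    """Read and validate a cohort file; invalid rows go to the reject
    report (or raise under ``strict``)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns: {missing}")

    records: list[PatientRecord] = []
    kept_rows: list[int] = []
    rejects: list[tuple[int, str]] = []
    for i, row in raw.iterrows():
        try:
            records.append(_parse_row(row))
            kept_rows.append(i)
        except (DomainError, ValueError) as exc:
            rejects.append((int(i), str(exc)))
    if strict and rejects:
        raise DomainError(
            f"{len(rejects)} invalid rows in {path}; first: row {rejects[0][0]}: {rejects[0][1]}"
        )
    if not records:
        logging.getLogger("gfrens.io").warning("%s contains no valid records", path)
    from .equations import records_to_frame

    frame = records_to_frame(records)
    frame.index = pd.Index(kept_rows)
    return CohortReadResult(
        records=records,
        frame=frame,
        rejects=pd.DataFrame(rejects, columns=["row", "reason"]),
    )


def _parse_row(row: pd.Series) -> PatientRecord:
    sex_raw = str(row["sex"]).strip().lower()
    if sex_raw not in SEX_ALIASES:
        raise ValueError(f"unrecognised sex {row['sex']!r}")
    unit = str(row.get("scr_unit", "") or "mg_per_dl").strip().lower() or "mg_per_dl"
    scr = convert_creatinine(_parse_float(row["scr"], "scr"), unit)
    mgfr_raw = str(row.get("mgfr", "") or "").strip()
    mgfr = _parse_float(mgfr_raw, "mgfr") if mgfr_raw else None
    return PatientRecord(
        id=str(row["id"]),
        age=_parse_float(row["age"], "age"),
        sex=SEX_ALIASES[sex_raw],
        scr=scr,
        mgfr=mgfr,
    )


def _parse_float(value, name: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric {name}: {value!r}") from exc
    if not math.isfinite(out):
        raise ValueError(f"non-finite {name}: {value!r}")
    return out


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------


def _metric_to_dict(m: Optional[MetricEstimate]):
    return None if m is None else {"value": m.value, "ci": [m.ci_low, m.ci_high]}


def _metric_from_dict(d) -> Optional[MetricEstimate]:
    if d is None:
        return None
    lo, hi = d["ci"]
    return MetricEstimate(value=d["value"], ci_low=lo, ci_high=hi)


def report_to_dict(report: EvaluationReport) -> dict[str, Any]:
    return {
        "benchmark": report.benchmark,
        "subgroups": list(report.subgroups),
        "meta": report.meta,
        "summaries": {
            model: {
                group: {
                    "n": s.n,
                    "bias": _metric_to_dict(s.bias),
                    "precision": _metric_to_dict(s.precision),
                    "accuracy_p30": _metric_to_dict(s.accuracy_p30),
                }
                for group, s in groups.items()
            }
            for model, groups in report.summaries.items()
        },
        "comparisons": {
            model: {
                group: {
                    "benchmark": c.benchmark,
                    "candidate": c.candidate,
                    "p_bias": c.p_bias,
                    "p_precision": c.p_precision,
                    "p_accuracy": c.p_accuracy,
                }
                for group, c in groups.items()
            }
            for model, groups in report.comparisons.items()
        },
    }


def report_from_dict(d: Mapping[str, Any]) -> EvaluationReport:
    summaries = {
        model: {
            group: PerformanceSummary(
                n=s["n"],
                bias=_metric_from_dict(s["bias"]),
                precision=_metric_from_dict(s["precision"]),
                accuracy_p30=_metric_from_dict(s["accuracy_p30"]),
            )
            for group, s in groups.items()
        }
        for model, groups in d["summaries"].items()
    }
    comparisons = {
        model: {
            group: ComparisonResult(
                benchmark=c["benchmark"],
                candidate=c["candidate"],
                p_bias=c["p_bias"],
                p_precision=c["p_precision"],
                p_accuracy=c["p_accuracy"],
            )
            for group, c in groups.items()
        }
        for model, groups in d["comparisons"].items()
    }
    return EvaluationReport(
        benchmark=d["benchmark"],
        subgroups=tuple(d["subgroups"]),
        summaries=summaries,
        comparisons=comparisons,
        meta=dict(d["meta"]),
    )


def write_report(report: EvaluationReport, path: str | Path, format: str = "json") -> None:
    """Serialise a report as JSON (lossless) or render it as TSV/Markdown."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=1, sort_keys=True) + "\n")
    elif format in ("tsv", "markdown"):
        path.write_text(render_report_table(report, format=format))
    else:
        raise ValueError(f"unknown report format {format!r}")


def _fmt_metric(m: Optional[MetricEstimate]) -> str:
    if m is None:
        return "-"
    if m.ci_low is None:
        return f"{m.value:.1f}"
    return f"{m.value:.1f} ({m.ci_low:.1f} to {m.ci_high:.1f})"


def render_report_table(report: EvaluationReport, format: str = "markdown") -> str:
    """Render per-model metric rows with one column per subgroup; a dagger
    marks candidates significantly different from the benchmark (p < 0.05)."""
    groups = list(report.subgroups)
    header = ["Metric / model", *groups]
    rows: list[list[str]] = []
    metric_defs = [
        ("Bias = median difference (95% CI)", "bias", "p_bias"),
        ("Precision = IQR of the difference (95% CI)", "precision", "p_precision"),
        ("Accuracy = P30 (95% CI)", "accuracy_p30", "p_accuracy"),
    ]
    for title, attr, pattr in metric_defs:
        rows.append([title] + [""] * len(groups))
        for model in report.summaries:
            cells = [f"  {model}"]
            for g in groups:
                s = report.summaries[model][g]
                m = getattr(s, attr)
                if attr == "accuracy_p30" and m is not None:
                    m = MetricEstimate(
                        m.value * 100,
                        None if m.ci_low is None else m.ci_low * 100,
                        None if m.ci_high is None else m.ci_high * 100,
                    )
                cell = _fmt_metric(m)
                comp = report.comparisons.get(model, {}).get(g)
                if comp is not None:
                    p = getattr(comp, pattr)
                    if p is not None:
                        cell += f" [p={p:.3f}]"
                        if p < ALPHA:
                            cell += " ‡"
                cells.append(cell)
            rows.append(cells)
    if format == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    widths = [max(len(h), *(len(r[i]) for r in rows)) for i, h in enumerate(header)]
    def md_row(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [md_row(header), md_row(["-" * w for w in widths])]
    lines += [md_row(r) for r in rows]
    return "\n".join(lines) + "\n"
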