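"""Equation-validation framework: bias, precision, P30 accuracy.

For each model on a (sub)cohort with measured GFR the framework reports

* bias — the median of per-patient differences (measured − estimated GFR, so
  positive bias means underestimation; the direction is configurable),
* precision — the interquartile range of those differences,
* P30 accuracy — the fraction of patients whose estimate lies within ±30%
  of the measured value (boundary inclusive),

each with a 95% percentile-bootstrap confidence interval (patients resampled
with replacement, default 2000 draws).  Candidate models are compared with a
benchmark by paired tests: Wilcoxon signed-rank on the per-patient
differences for bias, a paired-bootstrap test on the IQR difference for
precision, and McNemar's test on the P30 hit indicators for accuracy.
Subgroup summaries stratify patients by measured GFR into half-open bins
(by default <30, [30, 60), ≥60 ml/min/1.73 m²).

Quantiles use linear interpolation of order statistics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "DifferenceVector",
    "MetricEstimate",
    "PerformanceSummary",
    "ComparisonResult",
    "SubgroupSpec",
    "EvaluationReport",
    "differences",
    "median_bias",
    "iqr_precision",
    "p30_accuracy",
    "p30_hits",
    "bootstrap_ci",
    "compare_bias_wilcoxon",
    "compare_precision_bootstrap",
    "compare_accuracy_mcnemar",
    "stratified_summary",
    "evaluate_models",
    "ALPHA",
]

#: Two-sided significance level used to flag comparisons.
ALPHA = 0.05

#: How many discordant pairs switch McNemar from exact binomial to the
#: continuity-corrected chi-square, and how many Wilcoxon pairs switch from
#: the exact null to the normal approximation.
MCNEMAR_EXACT_LIMIT = 25
WILCOXON_EXACT_LIMIT = 25


@dataclass(frozen=True)
class DifferenceVector:
    """Per-patient measured-minus-estimated GFR values with aligned ids."""

    values: np.ndarray
    paired_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "paired_ids", tuple(map(str, self.paired_ids)))
        if len(values) != len(self.paired_ids):
            raise ValueError("values and ids must align")
        if len(set(self.paired_ids)) != len(self.paired_ids):
            raise ValueError("patient ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("differences must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MetricEstimate:
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class PerformanceSummary:
    """Bias / precision / P30 of one model on one (sub)cohort."""

    n: int
    bias: Optional[MetricEstimate]
    precision: Optional[MetricEstimate]
    accuracy_p30: Optional[MetricEstimate]


@dataclass(frozen=True)
class ComparisonResult:
    """Paired p-values of a candidate model against the benchmark."""

    benchmark: str
    candidate: str
    p_bias: Optional[float]
    p_precision: Optional[float]
    p_accuracy: Optional[float]


@dataclass(frozen=True)
class SubgroupSpec:
    """Measured-GFR strata: half-open bins [lo, hi) from inner edges."""

    edges: tuple[float, ...] = (30.0, 60.0)

    def __post_init__(self) -> None:
        if list(self.edges) != sorted(set(self.edges)) or any(
            e <= 0 for e in self.edges
        ):
            raise ValueError("edges must be positive, sorted and distinct")

    @classmethod
    def ckd_stages(cls) -> "SubgroupSpec":
        return cls(edges=(15.0, 30.0, 60.0, 90.0))

    @property
    def labels(self) -> tuple[str, ...]:
        edges = self.edges
        out = [f"<{edges[0]:g}"]
        out += [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        out.append(f">={edges[-1]:g}")
        return tuple(out)

    def assign(self, mgfr: np.ndarray) -> np.ndarray:
        """Bin index per patient under the [lo, hi) convention."""
        return np.searchsorted(np.asarray(self.edges), np.asarray(mgfr), side="right")


def _check_pairing(cohort: pd.DataFrame, egfr: np.ndarray) -> np.ndarray:
    egfr = np.asarray(egfr, dtype=float)
    if len(cohort) != len(egfr):
        raise ValueError(
            f"cohort ({len(cohort)}) and predictions ({len(egfr)}) differ in length"
        )
    if "mgfr" not in cohort.columns or cohort["mgfr"].isna().any():
        raise ValueError("every record needs a measured GFR")
    return egfr


def differences(
    cohort: pd.DataFrame, egfr: np.ndarray, direction: str = "mgfr_minus_egfr"
) -> DifferenceVector:
    """Per-patient paired differences between measured and estimated GFR."""
    egfr = _check_pairing(cohort, egfr)
    mgfr = np.asarray(cohort["mgfr"], dtype=float)
    if direction == "mgfr_minus_egfr":
        vals = mgfr - egfr
    elif direction == "egfr_minus_mgfr":
        vals = egfr - mgfr
    else:
        raise ValueError(f"unknown difference direction {direction!r}")
    ids = cohort["id"].astype(str) if "id" in cohort.columns else cohort.index.astype(str)
    return DifferenceVector(values=vals, paired_ids=tuple(ids))


def _as_values(d) -> np.ndarray:
    return np.asarray(d.values if isinstance(d, DifferenceVector) else d, dtype=float)


def median_bias(d: DifferenceVector | np.ndarray) -> float:
    """Sample median of the differences (bias; positive = underestimation)."""
    vals = _as_values(d)
    if len(vals) == 0:
        raise ValueError("median of an empty difference vector")
    return float(np.median(vals))


def iqr_precision(d: DifferenceVector | np.ndarray) -> float:
    """Interquartile range Q3 − Q1 of the differences (precision)."""
    vals = _as_values(d)
    if len(vals) < 2:
        raise ValueError("IQR needs at least two differences")
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
    return float(q3 - q1)


def p30_hits(mgfr: np.ndarray, egfr: np.ndarray) -> np.ndarray:
    """0/1 indicator per patient of |eGFR − mGFR| ≤ 0.30 × mGFR (inclusive)."""
    mgfr = np.asarray(mgfr, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    if np.any(mgfr <= 0):
        raise ValueError("measured GFR must be positive for P30")
    return (np.abs(egfr - mgfr) <= 0.30 * mgfr).astype(int)


def p30_accuracy(cohort: pd.DataFrame, egfr: np.ndarray) -> float:
    """Fraction of patients whose estimate is within ±30% of measured GFR."""
    egfr = _check_pairing(cohort, egfr)
    hits = p30_hits(np.asarray(cohort["mgfr"], dtype=float), egfr)
    return float(hits.mean())


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------


def _resample_indices(rng: np.random.Generator, B: int, n: int) -> np.ndarray:
    return rng.integers(0, n, size=(B, n))


def bootstrap_ci(
    statistic: Callable[..., float],
    data: np.ndarray | Sequence[np.ndarray],
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for ``statistic``.

    ``data`` is one array or a tuple of aligned arrays; patients are
    resampled with replacement jointly across the arrays.  ``statistic``
    receives the resampled array(s); if it accepts an ``axis`` keyword the
    B × n resample matrix is evaluated in one vectorised call.
    """
    arrays = (data,) if isinstance(data, np.ndarray) else tuple(data)
    arrays = tuple(np.asarray(a, dtype=float) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("data arrays must be aligned")
    if n < 2:
        raise ValueError("bootstrap needs at least two patients")
    if B < 100:
        raise ValueError("need at least 100 bootstrap draws")
    rng = np.random.default_rng(seed)
    idx = _resample_indices(rng, B, n)
    try:
        vals = np.asarray(statistic(*(a[idx] for a in arrays), axis=1), dtype=float)
        if vals.shape != (B,):
            raise TypeError
    except TypeError:
        vals = np.array(
            [statistic(*(a[row] for a in arrays)) for row in idx], dtype=float
        )
    lo, hi = np.quantile(vals, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def _median_stat(x, axis=None):
    return np.median(x, axis=axis)


def _iqr_stat(x, axis=None):
    q1, q3 = np.quantile(x, [0.25, 0.75], axis=axis)
    return q3 - q1


def _p30_stat(mgfr, egfr, axis=None):
    return (np.abs(egfr - mgfr) <= 0.30 * mgfr).mean(axis=axis)


# ---------------------------------------------------------------------------
# Paired comparisons against the benchmark
# ---------------------------------------------------------------------------


def _check_same_patients(dA: DifferenceVector, dB: DifferenceVector) -> None:
    if dA.paired_ids != dB.paired_ids:
        raise ValueError("difference vectors must cover the same patients in order")


def compare_bias_wilcoxon(dA: DifferenceVector, dB: DifferenceVector) -> float:
    """Two-sided Wilcoxon signed-rank p-value on the paired per-patient
    values dA − dB.  Zero differences are dropped; the exact null is used
    for ≤ 25 untied pairs, otherwise the normal approximation with tie
    correction."""
    _check_same_patients(dA, dB)
    z = dA.values - dB.values
    z = z[z != 0.0]
    if len(z) == 0:
        return 1.0
    ties = len(np.unique(np.abs(z))) < len(z)
    method = "exact" if (len(z) <= WILCOXON_EXACT_LIMIT and not ties) else "approx"
    res = stats.wilcoxon(z, zero_method="wilcox", correction=True, method=method)
    return float(min(res.pvalue, 1.0))


def compare_precision_bootstrap(
    dA: DifferenceVector,
    dB: DifferenceVector,
    B: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Paired-bootstrap achieved significance level for H0: IQR(A) = IQR(B).

    Each draw resamples patient indices once (jointly for both models) and
    evaluates Δ* = IQR(A*) − IQR(B*); p = 2 × min(P(Δ* ≤ 0), P(Δ* ≥ 0)).
    """
    _check_same_patients(dA, dB)
    if B < 100:
        raise ValueError("need at least 100 bootstrap draws")
    n = len(dA)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(rng, B, n)
    delta = _iqr_stat(dA.values[idx], axis=1) - _iqr_stat(dB.values[idx], axis=1)
    p = 2.0 * min(float(np.mean(delta <= 0.0)), float(np.mean(delta >= 0.0)))
    return min(p, 1.0)


def compare_accuracy_mcnemar(hitsA: np.ndarray, hitsB: np.ndarray) -> float:
    """Two-sided McNemar p-value from the discordant P30 hit counts; exact
    binomial when b + c < 25, continuity-corrected chi-square otherwise."""
    hitsA = np.asarray(hitsA)
    hitsB = np.asarray(hitsB)
    if hitsA.shape != hitsB.shape:
        raise ValueError("hit vectors must align")
    for h in (hitsA, hitsB):
        if not np.isin(h, (0, 1)).all():
            raise ValueError("hit vectors must be 0/1")
    b = int(np.sum((hitsA == 1) & (hitsB == 0)))
    c = int(np.sum((hitsA == 0) & (hitsB == 1)))
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=(b + c < MCNEMAR_EXACT_LIMIT), correction=True)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Table-shaped reports
# ---------------------------------------------------------------------------

OVERALL = "overall"


def _summary_for(
    cohort: pd.DataFrame,
    egfr: np.ndarray,
    B: int,
    seeds: Mapping[str, np.random.SeedSequence],
    direction: str,
) -> PerformanceSummary:
    n = len(cohort)
    if n == 0:
        return PerformanceSummary(n=0, bias=None, precision=None, accuracy_p30=None)
    mgfr = np.asarray(cohort["mgfr"], dtype=float)
    d = mgfr - egfr if direction == "mgfr_minus_egfr" else egfr - mgfr
    bias = MetricEstimate(float(np.median(d)))
    precision = None
    acc = MetricEstimate(float(p30_hits(mgfr, egfr).mean()))
    if n >= 2:
        bias = MetricEstimate(bias.value, *bootstrap_ci(_median_stat, d, B=B, seed=seeds["bias"]))
        precision = MetricEstimate(
            _iqr_stat(d), *bootstrap_ci(_iqr_stat, d, B=B, seed=seeds["precision"])
        )
        acc = MetricEstimate(
            acc.value,
            *bootstrap_ci(_p30_stat, (mgfr, egfr), B=B, seed=seeds["accuracy"]),
        )
    return PerformanceSummary(n=n, bias=bias, precision=precision, accuracy_p30=acc)


def _spawn_seeds(seed: int) -> np.random.SeedSequence:
    return (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )


def stratified_summary(
    cohort: pd.DataFrame,
    predictions: Mapping[str, np.ndarray],
    spec: SubgroupSpec = SubgroupSpec(),
    B: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    direction: str = "mgfr_minus_egfr",
) -> dict[str, dict[str, PerformanceSummary]]:
    """Per-model PerformanceSummary overall and per measured-GFR stratum.

    Bins are assigned on measured GFR with the half-open [lo, hi)
    convention; an empty stratum yields a summary with n = 0 and absent
    metrics.  One child seed stream is spawned per (model, stratum, metric)
    in a fixed order, so results are reproducible for a fixed top seed.
    """
    preds = {k: _check_pairing(cohort, v) for k, v in predictions.items()}
    mgfr = np.asarray(cohort["mgfr"], dtype=float)
    bins = spec.assign(mgfr)
    groups: dict[str, np.ndarray] = {OVERALL: np.ones(len(cohort), dtype=bool)}
    for i, label in enumerate(spec.labels):
        groups[label] = bins == i
    root = _spawn_seeds(seed)
    out: dict[str, dict[str, PerformanceSummary]] = {}
    for label in sorted(preds):
        out[label] = {}
        for gname, mask in groups.items():
            seeds = dict(zip(("bias", "precision", "accuracy"), root.spawn(3)))
            out[label][gname] = _summary_for(
                cohort.loc[mask], preds[label][mask], B, seeds, direction
            )
    return out


@dataclass
class EvaluationReport:
    """Full evaluation: per-model per-stratum summaries plus paired
    comparisons of each candidate against the benchmark."""

    benchmark: str
    subgroups: tuple[str, ...]
    summaries: dict[str, dict[str, PerformanceSummary]]
    comparisons: dict[str, dict[str, ComparisonResult]]
    meta: dict[str, Any] = field(default_factory=dict)

    def significant(self, candidate: str, group: str = OVERALL) -> dict[str, bool]:
        c = self.comparisons[candidate][group]
        return {
            m: (p is not None and p < ALPHA)
            for m, p in (
                ("bias", c.p_bias),
                ("precision", c.p_precision),
                ("accuracy", c.p_accuracy),
            )
        }


def evaluate_models(
    cohort: pd.DataFrame,
    predictions: Mapping[str, np.ndarray],
    benchmark: str,
    spec: SubgroupSpec = SubgroupSpec(),
    B: int = 2000,
    seed: int = 0,
    direction: str = "mgfr_minus_egfr",
) -> EvaluationReport:
    """Evaluate all models against the benchmark, overall and per stratum."""
    if benchmark not in predictions:
        raise ValueError(f"benchmark {benchmark!r} missing from predictions")
    preds = {k: _check_pairing(cohort, v) for k, v in predictions.items()}
    root = _spawn_seeds(seed)
    summary_seed, comparison_seed = root.spawn(2)
    summaries = stratified_summary(
        cohort, preds, spec=spec, B=B, seed=summary_seed, direction=direction
    )
    mgfr = np.asarray(cohort["mgfr"], dtype=float)
    bins = spec.assign(mgfr)
    groups: dict[str, np.ndarray] = {OVERALL: np.ones(len(cohort), dtype=bool)}
    for i, label in enumerate(spec.labels):
        groups[label] = bins == i

    comparisons: dict[str, dict[str, ComparisonResult]] = {}
    for label in sorted(preds):
        if label == benchmark:
            continue
        comparisons[label] = {}
        for gname, mask in groups.items():
            (prec_seed,) = comparison_seed.spawn(1)
            sub = cohort.loc[mask]
            if mask.sum() < 2:
                comparisons[label][gname] = ComparisonResult(
                    benchmark, label, None, None, None
                )
                continue
            dB = differences(sub, preds[benchmark][mask], direction)
            dA = differences(sub, preds[label][mask], direction)
            sub_mgfr = mgfr[mask]
            comparisons[label][gname] = ComparisonResult(
                benchmark=benchmark,
                candidate=label,
                p_bias=compare_bias_wilcoxon(dA, dB),
                p_precision=compare_precision_bootstrap(dA, dB, B=B, seed=prec_seed),
                p_accuracy=compare_accuracy_mcnemar(
                    p30_hits(sub_mgfr, preds[label][mask]),
                    p30_hits(sub_mgfr, preds[benchmark][mask]),
                ),
            )
    return EvaluationReport(
        benchmark=benchmark,
        subgroups=(OVERALL,) + spec.labels,
        summaries=summaries,
        comparisons=comparisons,
        meta={"B": B, "n": len(cohort), "direction": direction},
    )
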