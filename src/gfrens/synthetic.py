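"""Synthetic chronic-kidney-disease cohorts for exercising the pipeline.

The generator emulates the joint structure of a referral CKD cohort:

1. measured GFR is drawn from a mixture over the conventional staging bins
   (<15, [15,30), [30,60), [60,90), ≥90 ml/min/1.73 m²), uniform within a
   bin;
2. age is truncated-normal and sex Bernoulli, independent of GFR;
3. serum creatinine is obtained by inverting the piecewise power-law
   estimating equation for the drawn GFR and multiplying log-normal noise
   exp(ε), ε ~ N(0, noise_sigma²) — so at noise_sigma = 0 the estimating
   equation recovers the generated GFR exactly.

By default the age term of the equation is *omitted* from the creatinine
model (the age effect is folded into the per-sex scale), so the estimating
equation carries a realistic age-driven systematic error on generated data;
set ``age_coupled=True`` to include the age term in generation, in which
case the equation inverts the generator exactly at zero noise for every
record and any age.

The female branches leave measured GFR in [79·s, 92·s) unreachable (s is the
age factor, 1 when uncoupled) and the male branches overlap on
[98·s_b, 105·s_a); generation draws uniformly on bin ∩ attainable-set and
prefers the at-or-below branch in the overlap, so stage proportions are
respected exactly and noiseless inversion holds record-by-record.

Two presets parameterise the generator to the marginals of the development
(n = 1002-scale) and external-validation (n = 417-scale) cohorts the model
suite is meant to be exercised against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .equations import BRANCHES, EquationBranch, Sex, Side

__all__ = [
    "CohortSpec",
    "STAGE_EDGES",
    "development_spec",
    "validation_spec",
    "simulate_cohort",
    "simulate_single_branch",
    "recover_coefficients",
]

#: Inner edges of the CKD staging bins on measured GFR.
STAGE_EDGES = (15.0, 30.0, 60.0, 90.0)


def _branch(sex: Sex, side: Side) -> EquationBranch:
    return next(b for b in BRANCHES if b.sex is sex and b.side is side)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of the synthetic cohort generator."""

    n: int
    stage_proportions: tuple[float, float, float, float, float]
    age_mean: float
    age_sd: float
    age_range: tuple[float, float] = (18.0, 90.0)
    male_fraction: float = 0.5
    diabetes_fraction: float = 0.3
    noise_sigma: float = 0.2  # sd of multiplicative log-normal creatinine noise
    seed: int = 0
    age_coupled: bool = False
    within_stage: str = "uniform"
    gfr_range: tuple[float, float] = (10.0, 175.0)  # support of measured GFR
    scr_floor: float = 0.1  # mg/dl

    def __post_init__(self) -> None:
        p = np.asarray(self.stage_proportions, dtype=float)
        if p.shape != (5,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stage proportions must be 5 nonnegative weights summing to 1")
        if self.n < 0 or self.noise_sigma < 0 or not self.age_sd > 0:
            raise ValueError("invalid cohort spec")
        if self.within_stage != "uniform":
            raise ValueError("only the uniform within-stage family is implemented")
        if not 0 <= self.male_fraction <= 1 or not 0 <= self.diabetes_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")


def development_spec(n: int = 1002, seed: int = 0, **overrides) -> CohortSpec:
    """Preset matching the development cohort's marginals (stage counts
    10/99/275/345/273, age 55.7 ± 15.0, 56.9% male, 49.9% diabetic)."""
    counts = np.array([10, 99, 275, 345, 273], dtype=float)
    spec = CohortSpec(
        n=n,
        stage_proportions=tuple(counts / counts.sum()),
        age_mean=55.7,
        age_sd=15.0,
        male_fraction=570 / 1002,
        diabetes_fraction=500 / 1002,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def validation_spec(n: int = 417, seed: int = 0, **overrides) -> CohortSpec:
    """Preset matching the external-validation cohort's marginals (stage
    counts 9/94/149/123/42, age 51.3 ± 16.0, 62.8% male, 23.2% diabetic)."""
    counts = np.array([9, 94, 149, 123, 42], dtype=float)
    spec = CohortSpec(
        n=n,
        stage_proportions=tuple(counts / counts.sum()),
        age_mean=51.3,
        age_sd=16.0,
        male_fraction=262 / 417,
        diabetes_fraction=97 / 417,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _stage_bounds(spec: CohortSpec) -> np.ndarray:
    lo, hi = spec.gfr_range
    edges = [lo, *STAGE_EDGES, hi]
    return np.array(list(zip(edges[:-1], edges[1:])))


def simulate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a cohort frame (id, age, sex, scr, mgfr, diabetes) from ``spec``.

    Reproducible for a fixed spec (``seed`` overrides ``spec.seed``).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed if seed is None else seed))
    n = spec.n
    if n == 0:
        return pd.DataFrame(columns=["id", "age", "sex", "scr", "mgfr", "diabetes"])

    stage = rng.choice(5, size=n, p=np.asarray(spec.stage_proportions))
    male = rng.random(n) < spec.male_fraction
    a, b = [(x - spec.age_mean) / spec.age_sd for x in spec.age_range]
    age = truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng)
    diabetes = rng.random(n) < spec.diabetes_fraction

    bounds = _stage_bounds(spec)
    lo, hi = bounds[stage, 0], bounds[stage, 1]
    mgfr, below = _draw_mgfr(rng, lo, hi, male, age if spec.age_coupled else None)
    scr = _invert_creatinine(mgfr, below, male, age if spec.age_coupled else None)
    if spec.noise_sigma > 0:
        scr = scr * np.exp(rng.normal(0.0, spec.noise_sigma, size=n))
    scr = np.maximum(scr, spec.scr_floor)

    return pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": np.where(male, Sex.MALE.value, Sex.FEMALE.value),
            "scr": scr,
            "mgfr": mgfr,
            "diabetes": diabetes.astype(int),
        }
    )


def _effective_scales(male: np.ndarray, age: Optional[np.ndarray]):
    """Per-record effective scales k·a^age (a^age = 1 when age is None) for
    the at-or-below and above branches of each record's sex."""
    k_below = np.empty(len(male))
    k_above = np.empty(len(male))
    for is_male, sex in ((True, Sex.MALE), (False, Sex.FEMALE)):
        mask = male == is_male
        bb = _branch(sex, Side.AT_OR_BELOW)
        ba = _branch(sex, Side.ABOVE)
        fb = bb.age_base ** age[mask] if age is not None else 1.0
        fa = ba.age_base ** age[mask] if age is not None else 1.0
        k_below[mask] = bb.scale * fb
        k_above[mask] = ba.scale * fa
    return k_below, k_above


def _draw_mgfr(rng, lo, hi, male, age):
    """Uniform draw on [lo, hi) ∩ attainable-set; returns (mgfr, below-branch
    mask).  The at-or-below branch is preferred where the branches overlap."""
    cut_b, cut_a = _effective_scales(male, age)
    gap = cut_a < cut_b  # unreachable interval [cut_a, cut_b)
    seg1_len = np.where(gap, np.clip(np.minimum(hi, cut_a) - lo, 0.0, None), hi - lo)
    seg2_start = np.maximum(lo, cut_b)
    seg2_len = np.where(gap, np.clip(hi - seg2_start, 0.0, None), 0.0)
    total = seg1_len + seg2_len
    degenerate = total <= 0  # bin swallowed by the gap: fall back to full bin
    seg1_len = np.where(degenerate, hi - lo, seg1_len)
    total = np.where(degenerate, hi - lo, total)
    u = rng.random(len(lo)) * total
    mgfr = np.where(u < seg1_len, lo + u, seg2_start + (u - seg1_len))
    return mgfr, mgfr >= cut_b


def _invert_creatinine(mgfr, below, male, age):
    """Creatinine (mg/dl) such that the selected branch maps it back to
    ``mgfr`` exactly (with the age term included only when ``age`` given)."""
    scr = np.empty(len(mgfr))
    for is_male, sex in ((True, Sex.MALE), (False, Sex.FEMALE)):
        for side, mask_side in ((Side.AT_OR_BELOW, below), (Side.ABOVE, ~below)):
            br = _branch(sex, side)
            mask = (male == is_male) & mask_side
            k_eff = br.scale * (br.age_base ** age[mask] if age is not None else 1.0)
            scr[mask] = br.threshold * (mgfr[mask] / k_eff) ** (
                1.0 / br.creatinine_exponent
            )
    return scr


def simulate_single_branch(
    branch: EquationBranch,
    n: int,
    seed: int = 0,
    noise_sigma: float = 0.0,
    age_mean: float = 55.0,
    age_sd: float = 15.0,
    age_range: tuple[float, float] = (18.0, 90.0),
    mgfr_range: Optional[tuple[float, float]] = None,
    margin: float = 1.3,
) -> pd.DataFrame:
    """Cohort confined to one equation branch (age term always included),
    for parameter-recovery experiments.

    Measured GFR is drawn uniformly on a range consistent with the branch at
    every generated age; ``margin`` keeps it a multiplicative factor away
    from the branch boundary so that creatinine noise almost never pushes a
    record across the threshold into the sibling branch."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a, b = [(x - age_mean) / age_sd for x in age_range]
    age = truncnorm.rvs(a, b, loc=age_mean, scale=age_sd, size=n, random_state=rng)
    k_eff = branch.scale * branch.age_base ** age
    if mgfr_range is None:
        # below branch needs g >= k_eff (max over ages); above needs g < k_eff (min)
        if branch.side is Side.AT_OR_BELOW:
            mgfr_range = (
                float(margin * branch.scale * branch.age_base ** age_range[0]),
                175.0,
            )
        else:
            mgfr_range = (
                10.0,
                float(branch.scale * branch.age_base ** age_range[1] / margin),
            )
    mgfr = rng.uniform(*mgfr_range, size=n)
    scr = branch.threshold * (mgfr / k_eff) ** (1.0 / branch.creatinine_exponent)
    if noise_sigma > 0:
        scr = scr * np.exp(rng.normal(0.0, noise_sigma, size=n))
    return pd.DataFrame(
        {
            "id": [f"B{i:06d}" for i in range(n)],
            "age": age,
            "sex": branch.sex.value,
            "scr": np.maximum(scr, 0.1),
            "mgfr": mgfr,
            "diabetes": 0,
        }
    )


def recover_coefficients(
    cohort: pd.DataFrame, min_per_branch: int = 30
) -> dict[tuple[str, str], Optional[dict[str, float]]]:
    """Refit the piecewise power law per branch by ordinary least squares.

    The power law mGFR = k·(SC/τ)^c·a^age is log-linear.  Because the
    stochastic variation sits in creatinine given GFR (biological and
    assay variation of the filtration marker — exactly how the synthetic
    generator is built), least squares is run in the direction that puts
    that noise in the residual: ln(SC/τ) regressed on ln(mGFR) and age,

        ln(SC/τ) = b0 + b1·ln(mGFR) + b2·age + ε,

    and the branch coefficients are recovered as c = 1/b1, ln k = −b0/b1,
    ln a = −b2/b1.  Regressing ln(mGFR) on ln(SC) instead would attenuate
    the exponent (regression dilution) whenever the branch's GFR range is
    narrow.  Each (sex, threshold-side) branch is fitted on its own
    records; branches with fewer than ``min_per_branch`` records are
    reported as None (unfitted) rather than raising.
    """
    if "mgfr" not in cohort.columns or cohort["mgfr"].isna().any():
        raise ValueError("every record needs a measured GFR")
    from .equations import _male_indicator

    male = _male_indicator(cohort["sex"])
    scr = np.asarray(cohort["scr"], dtype=float)
    age = np.asarray(cohort["age"], dtype=float)
    g = np.asarray(cohort["mgfr"], dtype=float)
    out: dict[tuple[str, str], Optional[dict[str, float]]] = {}
    for br in BRANCHES:
        mask = male == (br.sex is Sex.MALE)
        if br.side is Side.AT_OR_BELOW:
            mask &= scr <= br.threshold
        else:
            mask &= scr > br.threshold
        key = (br.sex.value, br.side.value)
        if mask.sum() < min_per_branch:
            out[key] = None
            continue
        X = np.column_stack([np.ones(mask.sum()), np.log(g[mask]), age[mask]])
        beta, *_ = np.linalg.lstsq(X, np.log(scr[mask] / br.threshold), rcond=None)
        b0, b1, b2 = beta
        out[key] = {
            "scale": float(np.exp(-b0 / b1)),
            "creatinine_exponent": float(1.0 / b1),
            "age_base": float(np.exp(-b2 / b1)),
        }
    return out
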