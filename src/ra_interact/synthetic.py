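"""Synthetic mixed-type cohort generator with a known logistic ground truth.

Emulates a cross-sectional risk-factor survey cohort: continuous measurements
(age, BMI, depression score, sleep hours, income-to-poverty ratio, systolic
blood pressure), binary risk factors (sex, gout, diabetes, smoking), a
five-level ethnicity factor, and a binary disease outcome drawn from a
logistic model that may include second- and third-order interaction effects.

Continuous marginals are normal with bounds enforced either by rejection
(``truncate``) or by clipping (``clip``).  Clipping emulates the top-/bottom-
coding used by survey instruments (age 80+, income-to-poverty ratio capped at
5, sleep capped at 12 h, questionnaire floor at 0) and — unlike truncation —
can reproduce dispersions close to the interval's uniform bound.  The parent
(mu, sigma) of each bounded normal is solved numerically so that the
*post*-bound moments equal the schema's stated mean/sd.

Ground-truth effects are log-odds per standard deviation of the term column
(interaction columns standardized after the product is formed, binary columns
included), matching how the downstream analysis reports effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .prep import InteractionTerm

__all__ = [
    "ContinuousVar",
    "BinaryVar",
    "CategoricalVar",
    "CohortSchema",
    "GroundTruth",
    "Cohort",
    "SchemaError",
    "default_schema",
    "default_truth",
    "generate_cohort",
    "true_probability",
    "split_cohort",
]


class SchemaError(ValueError):
    """Invalid cohort schema (probabilities, bounds or moments unattainable)."""


@dataclass(frozen=True)
class ContinuousVar:
    name: str
    mean: float
    sd: float
    lower: float
    upper: float
    #: "truncate" = rejection sampling inside the bounds;
    #: "clip" = censor at the bounds (top-/bottom-coding).
    bound_mode: str = "truncate"

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise SchemaError(f"{self.name}: sd must be > 0, got {self.sd}")
        if not self.lower < self.upper:
            raise SchemaError(f"{self.name}: lower must be < upper")
        if self.bound_mode not in ("truncate", "clip"):
            raise SchemaError(f"{self.name}: unknown bound_mode {self.bound_mode!r}")


@dataclass(frozen=True)
class BinaryVar:
    name: str
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise SchemaError(
                f"{self.name}: prevalence must be in (0,1), got {self.prevalence}"
            )


@dataclass(frozen=True)
class CategoricalVar:
    name: str
    levels: tuple[str, ...]
    probabilities: tuple[float, ...]
    #: level treated as the reference (no dummy column emitted for it)
    reference: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probabilities):
            raise SchemaError(f"{self.name}: levels/probabilities length mismatch")
        if any(p < 0 or p > 1 for p in self.probabilities):
            raise SchemaError(f"{self.name}: probabilities outside [0,1]")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise SchemaError(f"{self.name}: probabilities must sum to 1")
        if self.reference is not None and self.reference not in self.levels:
            raise SchemaError(f"{self.name}: reference {self.reference!r} not a level")

    @property
    def dummy_names(self) -> tuple[str, ...]:
        return tuple(
            f"{self.name}_{lv}" for lv in self.levels if lv != self.reference
        )


@dataclass(frozen=True)
class CohortSchema:
    continuous_vars: tuple[ContinuousVar, ...]
    binary_vars: tuple[BinaryVar, ...]
    categorical_vars: tuple[CategoricalVar, ...]
    outcome_name: str = "ra"

    @property
    def column_names(self) -> list[str]:
        """Analysis columns in order: continuous, binary, categorical dummies."""
        names = [v.name for v in self.continuous_vars]
        names += [v.name for v in self.binary_vars]
        for v in self.categorical_vars:
            names += list(v.dummy_names)
        return names

    def to_yaml(self) -> str:
        doc = {
            "continuous": [vars(v).copy() for v in self.continuous_vars],
            "binary": [vars(v).copy() for v in self.binary_vars],
            "categorical": [
                {
                    "name": v.name,
                    "levels": list(v.levels),
                    "probabilities": list(v.probabilities),
                    "reference": v.reference,
                }
                for v in self.categorical_vars
            ],
            "outcome": self.outcome_name,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSchema":
        doc = yaml.safe_load(text)
        return cls(
            continuous_vars=tuple(ContinuousVar(**d) for d in doc.get("continuous", [])),
            binary_vars=tuple(BinaryVar(**d) for d in doc.get("binary", [])),
            categorical_vars=tuple(
                CategoricalVar(
                    name=d["name"],
                    levels=tuple(d["levels"]),
                    probabilities=tuple(d["probabilities"]),
                    reference=d.get("reference"),
                )
                for d in doc.get("categorical", [])
            ),
            outcome_name=doc.get("outcome", "ra"),
        )


@dataclass(frozen=True)
class GroundTruth:
    """True logistic model: intercept + per-SD log-odds effects on term columns."""

    intercept: float
    effects: Mapping[InteractionTerm, float] = field(default_factory=dict)

    def variable_names(self) -> set[str]:
        out: set[str] = set()
        for term in self.effects:
            out.update(term.factors)
        return out


@dataclass
class Cohort:
    """Participant table (analysis columns + outcome), plus generator truth."""

    frame: pd.DataFrame
    outcome_name: str = "ra"
    #: per-row true outcome probability when generated synthetically
    true_prob: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, outcome_name: str = "ra") -> "Cohort":
        return cls(pd.read_csv(path), outcome_name=outcome_name)


# ---------------------------------------------------------------------------
# default study conditions: the "All" marginals of the training breakdown
# ---------------------------------------------------------------------------

def default_schema() -> CohortSchema:
    """Schema matching the study population's printed marginal moments."""
    return CohortSchema(
        continuous_vars=(
            ContinuousVar("age", 45.6, 16.9, 18.0, 80.0, "clip"),
            ContinuousVar("bmi", 28.7, 6.65, 14.0, 70.0, "truncate"),
            ContinuousVar("phq", 2.89, 4.03, 0.0, 27.0, "clip"),
            ContinuousVar("sleep", 7.01, 1.44, 1.0, 12.0, "clip"),
            ContinuousVar("ipr", 2.50, 1.64, 0.0, 5.0, "clip"),
            ContinuousVar("bp", 123.0, 17.9, 80.0, 230.0, "truncate"),
        ),
        binary_vars=(
            BinaryVar("male", 0.523),
            BinaryVar("gout", 0.030),
            BinaryVar("diabetes", 0.106),
            BinaryVar("smoked", 0.428),
        ),
        categorical_vars=(
            CategoricalVar(
                "eth",
                levels=("ma", "oh", "black", "white", "onh"),
                probabilities=(0.163, 0.105, 0.208, 0.410, 0.114),
                reference="white",
            ),
        ),
        outcome_name="ra",
    )


def default_truth() -> GroundTruth:
    """A sparse truth with one main effect and two interactions.

    Effects are log-odds per SD; the intercept targets the study's ~6.6%
    outcome prevalence.
    """
    return GroundTruth(
        intercept=float(np.log(1143 / (17366 - 1143))),
        effects={
            InteractionTerm(("age",)): 0.5,
            InteractionTerm(("age", "bmi")): 0.4,
            InteractionTerm(("eth_onh", "male")): -0.4,
        },
    )


# ---------------------------------------------------------------------------
# bounded-normal moment matching
# ---------------------------------------------------------------------------

def _truncated_moments(mu: float, sigma: float, lo: float, hi: float):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _censored_moments(mu: float, sigma: float, lo: float, hi: float):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    p_lo = stats.norm.cdf(a)
    p_hi = stats.norm.sf(b)
    p_mid = max(1.0 - p_lo - p_hi, 0.0)
    if p_mid <= 0:
        mid_m, mid_v = 0.5 * (lo + hi), 0.0
    else:
        mid_m, mid_v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    m1 = lo * p_lo + hi * p_hi + p_mid * mid_m
    m2 = lo**2 * p_lo + hi**2 * p_hi + p_mid * (mid_v + mid_m**2)
    var = max(m2 - m1**2, 0.0)
    return float(m1), float(np.sqrt(var))


def _solve_parent_params(var: ContinuousVar) -> tuple[float, float]:
    """Parent (mu, sigma) whose bounded distribution has the schema moments."""
    moments = _truncated_moments if var.bound_mode == "truncate" else _censored_moments

    def residual(x):
        mu, log_sigma = x
        m, s = moments(mu, float(np.exp(log_sigma)), var.lower, var.upper)
        return [m - var.mean, s - var.sd]

    sol = optimize.root(residual, x0=[var.mean, np.log(var.sd)], method="hybr")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    m, s = moments(mu, sigma, var.lower, var.upper)
    if abs(m - var.mean) > 1e-6 * max(1.0, abs(var.mean)) or abs(s - var.sd) > 1e-6 * var.sd:
        raise SchemaError(
            f"{var.name}: stated moments mean={var.mean}, sd={var.sd} are not "
            f"attainable on [{var.lower}, {var.upper}] with bound_mode="
            f"{var.bound_mode!r} (best fit mean={m:.4g}, sd={s:.4g})"
        )
    return mu, sigma


_PARENT_CACHE: dict[ContinuousVar, tuple[float, float]] = {}


def _parent_params(var: ContinuousVar) -> tuple[float, float]:
    if var not in _PARENT_CACHE:
        _PARENT_CACHE[var] = _solve_parent_params(var)
    return _PARENT_CACHE[var]


def _sample_continuous(var: ContinuousVar, u: np.ndarray) -> np.ndarray:
    """Transform standard-normal draws into the bounded marginal."""
    mu, sigma = _parent_params(var)
    if var.bound_mode == "clip":
        return np.clip(mu + sigma * u, var.lower, var.upper)
    # rejection == inverse-cdf of the truncated normal applied to the copula uniform
    a, b = (var.lower - mu) / sigma, (var.upper - mu) / sigma
    return stats.truncnorm.ppf(stats.norm.cdf(u), a, b, loc=mu, scale=sigma)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _standardized_term_columns(
    frame: pd.DataFrame, terms: Sequence[InteractionTerm]
) -> pd.DataFrame:
    """Per-SD standardized term columns (products formed first)."""
    out = {}
    for term in terms:
        col = np.ones(len(frame))
        for f in term.factors:
            if f not in frame.columns:
                raise KeyError(f"ground truth references unknown variable {f!r}")
            col = col * frame[f].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise SchemaError(f"term {term.name} is constant in the generated cohort")
        out[term.name] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=frame.index)


def true_probability(
    truth: GroundTruth, standardized_row: Mapping[str, float]
) -> float:
    """Logistic outcome probability for one (already standardized) row."""
    eta = truth.intercept
    for term, beta in truth.effects.items():
        if term.name not in standardized_row:
            raise KeyError(f"row is missing standardized term {term.name!r}")
        eta += beta * standardized_row[term.name]
    return float(1.0 / (1.0 + np.exp(-eta)))


def generate_cohort(
    schema: CohortSchema,
    truth: GroundTruth,
    n: int,
    seed: int,
    correlation: np.ndarray | None = None,
    missing_rate: float = 0.0,
) -> Cohort:
    """Draw an analysis-ready cohort of ``n`` participants.

    Parameters
    ----------
    correlation : optional Gaussian-copula correlation matrix over the
        continuous variables followed by the binary variables (latent
        thresholds); the ethnicity factor stays independent.  ``None`` means
        independent risk factors.
    missing_rate : optional uniform missingness switch; entries are set to
        NaN at this rate (outcome never blanked).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cont = schema.continuous_vars
    binv = schema.binary_vars
    d_latent = len(cont) + len(binv)

    columns: dict[str, np.ndarray] = {}
    if n > 0:
        if correlation is None:
            z = rng.standard_normal((n, d_latent))
        else:
            correlation = np.asarray(correlation, dtype=float)
            if correlation.shape != (d_latent, d_latent):
                raise SchemaError(
                    f"correlation must be {d_latent}x{d_latent} "
                    "(continuous then binary variables)"
                )
            chol = np.linalg.cholesky(correlation)
            z = rng.standard_normal((n, d_latent)) @ chol.T
        for j, var in enumerate(cont):
            columns[var.name] = _sample_continuous(var, z[:, j])
        for j, var in enumerate(binv):
            thresh = stats.norm.ppf(1.0 - var.prevalence)
            columns[var.name] = (z[:, len(cont) + j] > thresh).astype(np.int64)
        for var in schema.categorical_vars:
            draws = rng.choice(len(var.levels), size=n, p=var.probabilities)
            for k, lv in enumerate(var.levels):
                if lv == var.reference:
                    continue
                columns[f"{var.name}_{lv}"] = (draws == k).astype(np.int64)
    else:
        for name in schema.column_names:
            columns[name] = np.array([], dtype=float)

    frame = pd.DataFrame(columns, columns=schema.column_names)

    if n > 0:
        std_terms = _standardized_term_columns(frame, list(truth.effects))
        eta = truth.intercept + sum(
            beta * std_terms[t.name].to_numpy() for t, beta in truth.effects.items()
        )
        eta = np.asarray(eta, dtype=float) + np.zeros(n)
        prob = 1.0 / (1.0 + np.exp(-eta))
        frame[schema.outcome_name] = (rng.random(n) < prob).astype(np.int64)
    else:
        prob = np.array([], dtype=float)
        frame[schema.outcome_name] = np.array([], dtype=np.int64)

    if missing_rate > 0 and n > 0:
        mask = rng.random((n, len(schema.column_names))) < missing_rate
        vals = frame[schema.column_names].to_numpy(dtype=float)
        vals[mask] = np.nan
        frame[schema.column_names] = vals

    return Cohort(frame, outcome_name=schema.outcome_name, true_prob=prob)


def split_cohort(
    cohort: Cohort, fractions: tuple[float, ...], seed: int
) -> tuple[Cohort, ...]:
    """Random disjoint partition with largest-remainder size rounding."""
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    n = cohort.n
    sizes = largest_remainder_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = []
    start = 0
    for size in sizes:
        idx = np.sort(perm[start : start + size])
        start += size
        tp = cohort.true_prob[idx] if cohort.true_prob is not None else None
        parts.append(
            Cohort(
                cohort.frame.iloc[idx].reset_index(drop=True),
                outcome_name=cohort.outcome_name,
                true_prob=tp,
            )
        )
    return tuple(parts)


def largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    shortfall = n - sum(sizes)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in remainders[:shortfall]:
        sizes[i] += 1
    return sizes
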