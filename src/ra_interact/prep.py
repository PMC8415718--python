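"""Variable derivation, interaction expansion, design matrix and summaries.

Analysis variables for the cohort are six continuous measurements, four free
binary indicators, and four mutually exclusive ethnicity dummies (reference
level dropped).  Second- and third-order interaction terms are all multisets
of variable names of size 2-3, minus terms that square a binary variable and
minus products of two mutually exclusive binaries (both are degenerate:
b^2 = b, and dummies of one factor never co-occur).

Standardization is applied to the *interacted* columns (products formed
first, then centered/scaled on training rows), so every reported effect is
per one standard deviation of the column itself.  Pure products of binaries
remain on {0,1} and are treated as qualitative downstream.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "InteractionTerm",
    "DesignMatrix",
    "ValidationError",
    "DegenerateColumnError",
    "default_variable_specs",
    "derive_variables",
    "expand_interactions",
    "build_design",
    "standardize",
    "summarize_groups",
]


class ValidationError(ValueError):
    pass


class DegenerateColumnError(ValueError):
    pass


@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str  # "continuous" | "binary"
    exclusivity_group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"{self.name}: kind must be continuous or binary")
        if self.exclusivity_group is not None and self.kind != "binary":
            raise ValidationError(f"{self.name}: only binaries join exclusivity groups")


@dataclass(frozen=True, order=True)
class InteractionTerm:
    """A multiset of 1-3 variable names, canonically sorted."""

    factors: tuple[str, ...]

    def __init__(self, factors: Iterable[str]):
        object.__setattr__(self, "factors", tuple(sorted(factors)))
        if not 1 <= len(self.factors) <= 3:
            raise ValidationError(f"term order must be 1-3, got {len(self.factors)}")

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def name(self) -> str:
        return "*".join(self.factors)

    @classmethod
    def from_name(cls, name: str) -> "InteractionTerm":
        return cls(name.split("*"))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"InteractionTerm({self.name!r})"


def default_variable_specs() -> list[VariableSpec]:
    """The study's 14 first-order variables."""
    cont = ["age", "bmi", "phq", "sleep", "ipr", "bp"]
    free_bin = ["male", "gout", "diabetes", "smoked"]
    eth = ["eth_ma", "eth_oh", "eth_black", "eth_onh"]
    specs = [VariableSpec(v, "continuous") for v in cont]
    specs += [VariableSpec(v, "binary") for v in free_bin]
    specs += [VariableSpec(v, "binary", exclusivity_group="eth") for v in eth]
    return specs


def _term_allowed(counts: Counter, specs_by_name: dict[str, VariableSpec]) -> bool:
    groups_seen: dict[str, str] = {}
    for name, mult in counts.items():
        spec = specs_by_name[name]
        if spec.kind == "binary" and mult >= 2:
            return False  # squaring a binary is the binary itself
        g = spec.exclusivity_group
        if g is not None:
            if g in groups_seen and groups_seen[g] != name:
                return False  # product of mutually exclusive binaries is 0
            groups_seen[g] = name
    return True


def expand_interactions(specs: Sequence[VariableSpec]) -> list[InteractionTerm]:
    """All pruned order-2 and order-3 multisets, in canonical sorted order."""
    names = sorted({s.name for s in specs})
    if len(names) != len(specs):
        raise ValidationError("variable names must be unique")
    by_name = {s.name: s for s in specs}
    terms: list[InteractionTerm] = []
    for order in (2, 3):
        for combo in itertools.combinations_with_replacement(names, order):
            if _term_allowed(Counter(combo), by_name):
                terms.append(InteractionTerm(combo))
    return terms


# ---------------------------------------------------------------------------
# raw-table derivation
# ---------------------------------------------------------------------------

def derive_variables(
    raw: pd.DataFrame,
    phq_items: Sequence[str] = tuple(f"phq{i}" for i in range(1, 10)),
    bp_readings: Sequence[str] = ("bp1", "bp2", "bp3", "bp4"),
    ethnicity_col: str = "eth",
    ethnicity_levels: Sequence[str] = ("ma", "oh", "black", "white", "onh"),
    ethnicity_reference: str = "white",
    age_col: str = "age",
    sleep_col: str = "sleep",
    sleep_cap: float = 12.0,
    log: list | None = None,
):
    """Derive analysis variables from a raw survey-style table.

    Depression score = sum of the nine questionnaire items (each 0-3); blood
    pressure = mean of the four readings; participants aged 17 or younger and
    rows with any missing field are excluded (complete-case); ethnicity is
    expanded to dummies against the reference level; sleep is capped.

    Returns the derived table; appends exclusion counts to ``log`` if given.
    """
    from .synthetic import Cohort  # local import to avoid a cycle

    raw = raw.copy()
    items = raw[list(phq_items)]
    bad = ~(items.isna() | ((items >= 0) & (items <= 3)))
    if bad.to_numpy().any():
        raise ValidationError("PHQ items must lie in 0-3")
    raw["phq"] = items.sum(axis=1, skipna=False)
    raw["bp"] = raw[list(bp_readings)].mean(axis=1, skipna=False)

    known = set(ethnicity_levels)
    observed = set(raw[ethnicity_col].dropna().unique())
    if not observed <= known:
        raise ValidationError(f"unknown ethnicity levels: {sorted(observed - known)}")
    for lv in ethnicity_levels:
        if lv == ethnicity_reference:
            continue
        raw[f"{ethnicity_col}_{lv}"] = (raw[ethnicity_col] == lv).astype(np.int64)
    raw.loc[raw[ethnicity_col].isna(), [
        f"{ethnicity_col}_{lv}" for lv in ethnicity_levels if lv != ethnicity_reference
    ]] = np.nan

    if sleep_col in raw.columns:
        raw[sleep_col] = raw[sleep_col].clip(upper=sleep_cap)

    n0 = len(raw)
    raw = raw[raw[age_col] > 17]
    n_age = n0 - len(raw)

    keep = [c for c in raw.columns if c not in (*phq_items, *bp_readings, ethnicity_col)]
    out = raw[keep]
    n1 = len(out)
    out = out.dropna()
    n_missing = n1 - len(out)
    if log is not None:
        log.append({"excluded_age": n_age, "excluded_missing": n_missing})
    return Cohort(out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """n x K table of term columns with per-column standardization state."""

    terms: list[InteractionTerm]
    values: pd.DataFrame
    #: terms whose column involves at least one continuous base variable
    quantitative: list[bool]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    training_rows: np.ndarray | None = field(default=None, repr=False)

    @property
    def column_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def standardized(self) -> bool:
        return self.center is not None

    def destandardize(self) -> pd.DataFrame:
        """Exact round-trip back to the raw product columns."""
        if not self.standardized:
            return self.values.copy()
        raw = self.values.to_numpy() * self.scale + self.center
        return pd.DataFrame(raw, columns=self.column_names, index=self.values.index)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)


def build_design(
    cohort, specs: Sequence[VariableSpec], terms: Sequence[InteractionTerm] | None = None
) -> DesignMatrix:
    """Assemble first-order + interaction columns (first-order first).

    ``cohort`` may be a Cohort or a plain DataFrame covering every factor name.
    """
    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    if terms is None:
        terms = expand_interactions(specs)
    by_name = {s.name: s for s in specs}
    all_terms = [InteractionTerm((s.name,)) for s in specs] + list(terms)

    cols = {}
    quant = []
    for term in all_terms:
        col = np.ones(len(frame))
        is_quant = False
        for f in term.factors:
            if f not in frame.columns:
                raise KeyError(f"design factor {f!r} not found in cohort")
            col = col * frame[f].to_numpy(dtype=float)
            if by_name[f].kind == "continuous":
                is_quant = True
        cols[term.name] = col
        quant.append(is_quant)
    values = pd.DataFrame(cols, index=frame.index)
    return DesignMatrix(terms=all_terms, values=values, quantitative=quant)


def drop_degenerate(
    design: DesignMatrix, training_rows: Sequence[int]
) -> tuple[DesignMatrix, list[str]]:
    """Remove columns constant on the training rows (e.g. empty rare-binary
    products in a small cohort); returns the reduced design and the names."""
    training_rows = np.asarray(training_rows)
    train = design.values.to_numpy(dtype=float)[training_rows]
    keep, dropped = [], []
    for j in range(train.shape[1]):
        if train[:, j].std(ddof=0) == 0:
            dropped.append(design.column_names[j])
        else:
            keep.append(j)
    if not dropped:
        return design, []
    return (
        DesignMatrix(
            terms=[design.terms[j] for j in keep],
            values=design.values.iloc[:, keep],
            quantitative=[design.quantitative[j] for j in keep],
        ),
        dropped,
    )


def standardize(design: DesignMatrix, training_rows: Sequence[int]) -> DesignMatrix:
    """Center/scale quantitative columns with training statistics.

    Pure-binary columns are left on {0,1}.  Validation/test rows are
    transformed with the *training* mean and sd.
    """
    training_rows = np.asarray(training_rows)
    if training_rows.size == 0:
        raise ValidationError("training rows must be nonempty")
    vals = design.values.to_numpy(dtype=float).copy()
    center = np.zeros(vals.shape[1])
    scale = np.ones(vals.shape[1])
    train = vals[training_rows]
    for j, is_quant in enumerate(design.quantitative):
        if not is_quant:
            continue
        m = train[:, j].mean()
        s = train[:, j].std(ddof=0)
        if s == 0:
            raise DegenerateColumnError(
                f"column {design.column_names[j]!r} is constant on training rows"
            )
        center[j], scale[j] = m, s
        vals[:, j] = (vals[:, j] - m) / s
    return DesignMatrix(
        terms=design.terms,
        values=pd.DataFrame(vals, columns=design.column_names, index=design.values.index),
        quantitative=design.quantitative,
        center=center,
        scale=scale,
        training_rows=training_rows,
    )


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def summarize_groups(
    cohort,
    outcome: str | None = None,
    binary_vars: Sequence[str] | None = None,
    continuous_vars: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-outcome-group counts/percentages (binaries) and mean/sd (continuous).

    Percentages are computed within each outcome group.  An empty group is
    flagged in the ``note`` column rather than silently producing NaN.
    """
    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    if outcome is None:
        outcome = getattr(cohort, "outcome_name", "ra")
    y = frame[outcome]
    if not set(pd.unique(y.dropna())) <= {0, 1}:
        raise ValidationError("outcome must be binary 0/1")

    if binary_vars is None or continuous_vars is None:
        others = [c for c in frame.columns if c != outcome]
        auto_bin = [c for c in others if set(pd.unique(frame[c].dropna())) <= {0, 1}]
        binary_vars = binary_vars if binary_vars is not None else auto_bin
        continuous_vars = (
            continuous_vars
            if continuous_vars is not None
            else [c for c in others if c not in auto_bin]
        )

    rows = []
    for group, label in ((1, "case"), (0, "control")):
        sub = frame[y == group]
        empty = len(sub) == 0
        for v in binary_vars:
            count = int(sub[v].sum()) if not empty else 0
            pct = 100.0 * count / len(sub) if not empty else np.nan
            rows.append(
                {
                    "group": label,
                    "variable": v,
                    "statistic": "count_pct",
                    "count": count,
                    "percent": pct,
                    "mean": np.nan,
                    "sd": np.nan,
                    "note": "empty group" if empty else "",
                }
            )
        for v in continuous_vars:
            rows.append(
                {
                    "group": label,
                    "variable": v,
                    "statistic": "mean_sd",
                    "count": len(sub),
                    "percent": np.nan,
                    "mean": sub[v].mean() if not empty else np.nan,
                    "sd": sub[v].std(ddof=1) if len(sub) > 1 else (0.0 if len(sub) == 1 else np.nan),
                    "note": "empty group" if empty else "",
                }
            )
    return pd.DataFrame(rows)
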