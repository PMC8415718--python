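"""Posterior coefficient reconstruction and HDI ranking.

The final logistic model is fitted on a GA-selected subset of FAMD synthetic
variables.  Stacking its posterior draws into a matrix A (draws x retained
components, zero columns for unselected components), the induced posterior
over the FAMD *active columns* is B = A V', where V holds the right singular
vectors: per draw, the linear predictor computed in synthetic space equals
the one computed in (weighted, centered) active-column space.

Active-column coefficients are then mapped back to interpretable per-variable
effects: quantitative columns are standardized, so their coefficient is
already a log-odds change per SD; a binary variable coded as an indicator
pair contributes b_on/w_on - b_off/w_off per 0/1 flip (w = sqrt(state
proportion), the FAMD column weight), which is multiplied by the column's
sample sd so that every reported effect is per one standard deviation of the
variable.  Effects are exponentiated to odds multipliers, summarized by
highest-density intervals, and ranked by the posterior probability that the
odds multiplier lies on its median's side of 1 (ties broken by |log median|,
then name).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .famd import FAMDResults
from .prep import InteractionTerm

__all__ = [
    "ReconstructedPosterior",
    "reconstruct",
    "binary_effect",
    "hdi",
    "rank_variables",
    "interaction_report",
]


@dataclass
class ReconstructedPosterior:
    """Draws x active-columns posterior of log-odds coefficients.

    ``B`` is on the scale of the weighted, centered FAMD columns;
    ``deweighted()`` returns per-original-scale coefficients (per SD for
    quantitative columns, per weighted-indicator unit removed for
    indicators).  Columns exist only for FAMD-active columns.
    """

    B: np.ndarray
    column_names: list[str]
    kinds: list[str]
    weights: np.ndarray
    intercept: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.B.shape[0]

    def deweighted(self) -> pd.DataFrame:
        """Indicator coefficients divided by sqrt(state proportion)."""
        W = np.where(np.array(self.kinds) == "indicator", self.weights, 1.0)
        return pd.DataFrame(self.B / W, columns=self.column_names)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.column_names.index(name)
        except ValueError as exc:
            raise KeyError(f"no reconstructed column {name!r}") from exc
        return self.B[:, j]


def reconstruct(
    A: np.ndarray,
    model: FAMDResults,
    selected: np.ndarray | None = None,
    intercept: np.ndarray | None = None,
) -> ReconstructedPosterior:
    """Map synthetic-variable posterior draws back to active columns (B = A V').

    Parameters
    ----------
    A : draws x m matrix of posterior draws, one column per *retained*
        synthetic variable in order (columns of unselected variables may be
        present — they are zeroed — or A may have one column per selected
        variable, expanded here).
    selected : optional bit vector over the m retained variables marking the
        GA-chosen subset.  Unselected columns are set to zero.
    """
    A = np.asarray(A, dtype=float)
    m = model.n_retained
    if selected is not None:
        selected = np.asarray(selected).astype(bool)
        if selected.size != m:
            raise ValueError(f"selected has {selected.size} bits, model retains {m}")
        if A.shape[1] == int(selected.sum()):
            full = np.zeros((A.shape[0], m))
            full[:, np.flatnonzero(selected)] = A
            A = full
        elif A.shape[1] == m:
            A = A.copy()
            A[:, ~selected] = 0.0
        else:
            raise ValueError(
                f"A has {A.shape[1]} columns; expected {m} or {int(selected.sum())}"
            )
    elif A.shape[1] != m:
        raise ValueError(f"A has {A.shape[1]} columns; model retains {m}")

    V_r = model.V[:, model.retained]  # K x m
    B = A @ V_r.T
    return ReconstructedPosterior(
        B=B,
        column_names=list(model.column_names),
        kinds=list(model.kinds),
        weights=np.asarray(model.weights, dtype=float),
        intercept=intercept,
    )


def binary_effect(recon: ReconstructedPosterior, on_name: str, off_name: str) -> np.ndarray:
    """Per-draw log-odds effect of flipping a binary: c_on - c_off.

    ``c`` are the de-weighted indicator coefficients, so the difference is the
    change in linear predictor between the two states of the variable.
    """
    names = recon.column_names
    for nm in (on_name, off_name):
        if nm not in names:
            raise KeyError(f"indicator {nm!r} missing from reconstruction")
    dw = recon.deweighted()
    return dw[on_name].to_numpy() - dw[off_name].to_numpy()


def hdi(samples, mass: float) -> tuple[float, float]:
    """Highest-density interval: the shortest window of sorted draws holding
    ceil(mass * S) draws."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0,1)")
    if x.size == 1:
        return float(x[0]), float(x[0])
    w = min(int(np.ceil(mass * x.size)), x.size)
    widths = x[w - 1 :] - x[: x.size - w + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + w - 1])


def _direction_probability(odds_draws: np.ndarray) -> tuple[float, float]:
    med = float(np.median(odds_draws))
    if med >= 1.0:
        p = float(np.mean(odds_draws > 1.0))
    else:
        p = float(np.mean(odds_draws < 1.0))
    return med, min(max(p, 0.5), 1.0)


def rank_variables(effect_draws: pd.DataFrame | dict) -> pd.DataFrame:
    """Ranked HDI summary of per-variable log-odds effect draws.

    ``effect_draws`` maps variable name -> per-draw log-odds effects (per SD).
    Draws are exponentiated to odds multipliers; variables sort by descending
    direction probability, then |log median|, then name.
    """
    if isinstance(effect_draws, dict):
        effect_draws = pd.DataFrame(effect_draws)
    rows = []
    for name in effect_draws.columns:
        odds = np.exp(effect_draws[name].to_numpy(dtype=float))
        med, p = _direction_probability(odds)
        lo50, hi50 = hdi(odds, 0.50)
        lo99, hi99 = hdi(odds, 0.99)
        rows.append(
            {
                "variable": name,
                "order": InteractionTerm.from_name(name).order,
                "median_or": med,
                "hdi50_lower": lo50,
                "hdi50_upper": hi50,
                "hdi99_lower": lo99,
                "hdi99_upper": hi99,
                "direction_prob": p,
            }
        )
    out = pd.DataFrame(rows)
    out["_tiebreak"] = np.abs(np.log(out["median_or"]))
    out = out.sort_values(
        ["direction_prob", "_tiebreak", "variable"], ascending=[False, False, True]
    ).drop(columns="_tiebreak")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def interaction_report(summaries: pd.DataFrame, order: int, top_k: int | None = None) -> pd.DataFrame:
    """Top-ranked variables of one interaction order, names as factor products."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    sub = summaries[summaries["order"] == order].sort_values("rank")
    if top_k is not None:
        sub = sub.head(top_k)
    sub = sub.copy()
    sub["display"] = [
        "·".join(InteractionTerm.from_name(v).factors) for v in sub["variable"]
    ]
    return sub.reset_index(drop=True)
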