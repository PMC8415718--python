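"""Factor analysis of mixed data (FAMD) by weighted SVD.

Quantitative columns enter standardized (as in PCA); each qualitative column
is expanded into one 0/1 indicator per state, and each indicator is divided
by the square root of its state proportion and centered (as in multiple
correspondence analysis).  The SVD of the resulting matrix M = U S V' yields
decorrelated synthetic variables: row scores M V have variances equal to the
eigenvalues S^2 / n, and each synthetic variable maximizes the summed squared
correlation with quantitative columns plus the correlation ratio with
qualitative columns, subject to orthogonality with earlier ones.

Components with variance at or below a threshold (default 1, the average
inertia per independent axis) are conventionally dropped before downstream
modelling; held-out data are projected with the training centers/weights.

The component sign is fixed so that the largest-magnitude entry of each right
singular vector is positive, making results reproducible across linear
algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAMD",
    "FAMDResults",
    "DegenerateColumnError",
    "EmptyRetentionError",
    "ProjectionError",
    "disjunctive_code",
]


class DegenerateColumnError(ValueError):
    pass


class EmptyRetentionError(ValueError):
    pass


class ProjectionError(KeyError):
    pass


def disjunctive_code(qualitative: pd.DataFrame) -> pd.DataFrame:
    """Complete disjunctive coding: one 0/1 indicator per observed state.

    A binary column ``b`` yields the pair (b, 1-b).  Raises on a column with a
    single observed state (its indicator would be constant).
    """
    out = {}
    for col in qualitative.columns:
        states = _ordered_states(qualitative[col])
        if len(states) < 2:
            raise DegenerateColumnError(
                f"qualitative column {col!r} has a single observed state"
            )
        for s in states:
            out[_indicator_name(col, s)] = (
                (qualitative[col] == s).to_numpy().astype(np.int64)
            )
    return pd.DataFrame(out, index=qualitative.index)


def _ordered_states(series: pd.Series) -> list:
    states = pd.unique(series.dropna())
    # binary 0/1 columns list the "on" state first so the (b, 1-b) pair reads naturally
    if set(states) <= {0, 1}:
        return [s for s in (1, 0) if s in set(states)]
    return sorted(states, key=str)


def _indicator_name(col: str, state) -> str:
    return f"{col}={state}"


class FAMD:
    """Model object; ``fit()`` returns a :class:`FAMDResults`.

    Parameters
    ----------
    quantitative : DataFrame of numeric active columns (may be empty).
    qualitative : DataFrame of categorical active columns (may be empty).
    """

    def __init__(
        self,
        quantitative: pd.DataFrame | None = None,
        qualitative: pd.DataFrame | None = None,
    ):
        n_rows = None
        for f in (quantitative, qualitative):
            if f is not None and len(f.columns):
                n_rows = len(f)
        self.quantitative = (
            quantitative if quantitative is not None else pd.DataFrame(index=range(n_rows or 0))
        )
        self.qualitative = (
            qualitative if qualitative is not None else pd.DataFrame(index=range(n_rows or 0))
        )
        if len(self.quantitative.columns) + len(self.qualitative.columns) < 2:
            raise ValueError("FAMD needs at least 2 active columns")

    def fit(self) -> "FAMDResults":
        n = max(len(self.quantitative), len(self.qualitative))
        blocks, names, centers, weights, kinds, state_of = [], [], [], [], [], []

        for col in self.quantitative.columns:
            x = self.quantitative[col].to_numpy(dtype=float)
            m, s = x.mean(), x.std(ddof=0)
            if s == 0:
                raise DegenerateColumnError(f"quantitative column {col!r} is constant")
            blocks.append((x - m) / s)
            names.append(col)
            centers.append(m)
            weights.append(s)  # stored as the divisor applied after centering
            kinds.append("quant")
            state_of.append(None)

        qual_states: dict[str, list] = {}
        for col in self.qualitative.columns:
            states = _ordered_states(self.qualitative[col])
            if len(states) < 2:
                raise DegenerateColumnError(
                    f"qualitative column {col!r} has a single observed state"
                )
            qual_states[col] = states
            for s in states:
                ind = (self.qualitative[col] == s).to_numpy().astype(float)
                p = ind.mean()
                # indicator scaled by 1/sqrt(p) then centered
                blocks.append((ind - p) / np.sqrt(p))
                names.append(_indicator_name(col, s))
                centers.append(p)
                weights.append(np.sqrt(p))
                kinds.append("indicator")
                state_of.append((col, s))

        M = np.column_stack(blocks)
        U, sv, Vt = np.linalg.svd(M, full_matrices=False)
        V = Vt.T
        # sign convention: largest-|entry| of each right singular vector positive
        flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
        flip[flip == 0] = 1.0
        V = V * flip
        U = U * flip
        eigenvalues = sv**2 / n

        return FAMDResults(
            column_names=names,
            centers=np.array(centers),
            weights=np.array(weights),
            kinds=kinds,
            state_of=state_of,
            qual_states=qual_states,
            V=V,
            singular_values=sv,
            eigenvalues=eigenvalues,
            n_rows=n,
            retained=np.ones(len(sv), dtype=bool),
            _M=M,
            _scores=M @ V,
        )


@dataclass
class FAMDResults:
    """Fitted FAMD: centers/weights, right singular vectors, eigenvalues."""

    column_names: list[str]
    centers: np.ndarray
    weights: np.ndarray
    kinds: list[str]
    state_of: list
    qual_states: dict[str, list]
    V: np.ndarray
    singular_values: np.ndarray
    eigenvalues: np.ndarray
    n_rows: int
    retained: np.ndarray
    _M: np.ndarray = field(repr=False)
    _scores: np.ndarray = field(repr=False)

    # -- retention ----------------------------------------------------------
    def retain(self, threshold: float = 1.0) -> "FAMDResults":
        """Keep components with eigenvalue strictly greater than ``threshold``."""
        mask = self.eigenvalues > threshold
        if not mask.any():
            raise EmptyRetentionError(
                f"no component has variance > {threshold} "
                f"(largest eigenvalue {self.eigenvalues.max():.4g})"
            )
        out = FAMDResults(**{**self.__dict__})
        out.retained = mask
        return out

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_variance_share(self) -> float:
        return float(self.eigenvalues[self.retained].sum() / self.eigenvalues.sum())

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    # -- projection ---------------------------------------------------------
    def _assemble(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        j = 0
        while j < len(self.column_names):
            kind = self.kinds[j]
            if kind == "quant":
                name = self.column_names[j]
                if name not in table.columns:
                    raise ProjectionError(f"missing quantitative column {name!r}")
                x = table[name].to_numpy(dtype=float)
                cols.append((x - self.centers[j]) / self.weights[j])
                j += 1
            else:
                col, _state = self.state_of[j]
                if col not in table.columns:
                    raise ProjectionError(f"missing qualitative column {col!r}")
                observed = set(pd.unique(table[col].dropna()))
                known = set(self.qual_states[col])
                if not observed <= known:
                    raise ProjectionError(
                        f"unseen state(s) {sorted(observed - known, key=str)} "
                        f"in qualitative column {col!r}"
                    )
                while j < len(self.column_names) and self.kinds[j] == "indicator" and self.state_of[j][0] == col:
                    _, s = self.state_of[j]
                    ind = (table[col] == s).to_numpy().astype(float)
                    p = self.centers[j]
                    cols.append((ind - p) / np.sqrt(p))
                    j += 1
        return np.column_stack(cols)

    def project(self, table: pd.DataFrame) -> pd.DataFrame:
        """Factor scores of ``table`` on the retained synthetic variables."""
        M = self._assemble(table)
        scores = M @ self.V[:, self.retained]
        return pd.DataFrame(
            scores,
            index=table.index,
            columns=[f"sv{i + 1}" for i in np.flatnonzero(self.retained)],
        )

    def training_scores(self) -> pd.DataFrame:
        scores = self._scores[:, self.retained]
        return pd.DataFrame(
            scores, columns=[f"sv{i + 1}" for i in np.flatnonzero(self.retained)]
        )

    # -- interpretation -----------------------------------------------------
    def variable_loadings(self) -> pd.DataFrame:
        """Per active column: loading sqrt(lambda_j) * v_kj on each retained axis.

        For an all-quantitative fit these are the correlations between the
        columns and the synthetic variables; summing squared loadings over all
        components recovers each column's inertia.
        """
        idx = np.flatnonzero(self.retained)
        lam = np.sqrt(self.eigenvalues[idx])
        L = self.V[:, idx] * lam
        return pd.DataFrame(
            L, index=self.column_names, columns=[f"sv{i + 1}" for i in idx]
        )

    def qualitative_contributions(self) -> pd.DataFrame:
        """Correlation-ratio-style contribution of each qualitative variable.

        Summed squared loadings of the variable's indicators per retained axis.
        """
        load = self.variable_loadings()
        rows = {}
        for col, states in self.qual_states.items():
            ind_names = [_indicator_name(col, s) for s in states]
            rows[col] = (load.loc[ind_names] ** 2).sum(axis=0)
        return pd.DataFrame(rows).T

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "column_names": self.column_names,
            "kinds": self.kinds,
            "state_of": [list(s) if s else None for s in self.state_of],
            "qual_states": {k: list(v) for k, v in self.qual_states.items()},
            "n_rows": self.n_rows,
            "retained": self.retained.astype(int).tolist(),
        }
        (d / "meta.json").write_text(json.dumps(meta))
        pd.DataFrame({"center": self.centers, "weight": self.weights}).to_csv(
            d / "column_stats.csv", index=False
        )
        pd.DataFrame(self.V).to_csv(d / "V.csv", index=False)
        pd.DataFrame(
            {"singular_value": self.singular_values, "eigenvalue": self.eigenvalues}
        ).to_csv(d / "spectrum.csv", index=False)

    @classmethod
    def load(cls, directory) -> "FAMDResults":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        stats = pd.read_csv(d / "column_stats.csv")
        V = pd.read_csv(d / "V.csv").to_numpy()
        spec = pd.read_csv(d / "spectrum.csv")
        state_of = [tuple(s) if s else None for s in meta["state_of"]]
        res = cls(
            column_names=meta["column_names"],
            centers=stats["center"].to_numpy(),
            weights=stats["weight"].to_numpy(),
            kinds=meta["kinds"],
            state_of=state_of,
            qual_states=meta["qual_states"],
            V=V,
            singular_values=spec["singular_value"].to_numpy(),
            eigenvalues=spec["eigenvalue"].to_numpy(),
            n_rows=meta["n_rows"],
            retained=np.array(meta["retained"], dtype=bool),
            _M=np.empty((0, V.shape[0])),
            _scores=np.empty((0, V.shape[1])),
        )
        return res
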