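"""Per-chemical, per-index concentration models f(x | s, i).

For each standard chemical s and each characteristic-vector index i, the
index value is regressed on u = log10(x / 1 mM) by ordinary least squares
(linear or quadratic basis).  The residual scale sigma_{s,i} (with a floor
to prevent zero-variance collapse on small training sets) and the Gaussian
amplitude A(s,i) = 1 / (sqrt(2*pi) * sigma_{s,i}) make each index a proper
Gaussian likelihood factor for the Bayesian classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import BadConfigError, InvalidDataError
from .template import N_INDICES, UNKNOWN, CharacteristicVector

BASIS_DEGREE = {"linear": 1, "quadratic": 2}

FORMAT_VERSION = "1"


@dataclass
class TrainingSet:
    """Labelled characteristic vectors at known concentrations (mM)."""

    records: list
    chemicals: list

    def __post_init__(self):
        known = set(self.chemicals)
        for rec in self.records:
            if rec.label not in known:
                raise InvalidDataError(f"record label {rec.label!r} not in chemicals list")
            if not (np.isfinite(rec.concentration) and rec.concentration > 0):
                raise InvalidDataError(
                    f"record for {rec.label!r} has non-positive concentration "
                    f"{rec.concentration}"
                )

    @classmethod
    def from_records(cls, records: Iterable[CharacteristicVector]) -> "TrainingSet":
        records = list(records)
        chemicals = []
        for rec in records:
            if rec.label not in chemicals:
                chemicals.append(rec.label)
        return cls(records=records, chemicals=chemicals)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrainingSet":
        """Build from a frame with columns y1..y15, label, concentration_mM."""
        ycols = [f"y{i}" for i in range(1, N_INDICES + 1)]
        missing = [c for c in ycols + ["label", "concentration_mM"] if c not in df]
        if missing:
            raise InvalidDataError(f"training frame missing columns {missing}")
        records = [
            CharacteristicVector(
                y=row[ycols].to_numpy(dtype=float),
                label=str(row["label"]),
                concentration=float(row["concentration_mM"]),
                fit_rms=float(row[ycols[-1]]),
            )
            for _, row in df.iterrows()
        ]
        return cls.from_records(records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {f"y{i + 1}": rec.y[i] for i in range(N_INDICES)}
            row["label"] = rec.label
            row["concentration_mM"] = rec.concentration
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, chemicals: Sequence[str]) -> "TrainingSet":
        keep = [c for c in self.chemicals if c in set(chemicals)]
        missing = set(chemicals) - set(keep)
        if missing:
            raise BadConfigError(f"chemicals not in training set: {sorted(missing)}")
        return TrainingSet(
            records=[r for r in self.records if r.label in set(keep)],
            chemicals=keep,
        )

    def records_for(self, chemical: str) -> list:
        return [r for r in self.records if r.label == chemical]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ModelFunction:
    """OLS fit of one index against log10 concentration for one chemical.

    ``coef`` holds coefficients in increasing powers of u = log10(x/1 mM);
    ``sigma`` is the (floored) residual SD; ``x_lo``/``x_hi`` bound the
    training concentrations.
    """

    chemical: str
    index: int  # 1-based, matching y1..y15
    coef: np.ndarray
    sigma: float
    x_lo: float
    x_hi: float

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.sigma <= 0:
            raise InvalidDataError(f"sigma must be > 0, got {self.sigma}")
        if not (0 < self.x_lo < self.x_hi):
            raise InvalidDataError(f"bad concentration range [{self.x_lo}, {self.x_hi}]")

    @property
    def amplitude(self) -> float:
        """Gaussian normalisation A(s,i) = 1/(sqrt(2 pi) sigma)."""
        return 1.0 / (np.sqrt(2 * np.pi) * self.sigma)

    def predict(self, x) -> np.ndarray:
        """Evaluate at concentration x (mM); extrapolates outside the range."""
        u = np.log10(np.asarray(x, dtype=float))
        return np.polynomial.polynomial.polyval(u, self.coef)

    def predict_u(self, u) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(u, dtype=float), self.coef)

    def in_range(self, x) -> np.ndarray:
        return (np.asarray(x) >= self.x_lo) & (np.asarray(x) <= self.x_hi)


@dataclass
class ModelSet:
    """All N x 15 model functions plus the basis configuration."""

    chemicals: list
    functions: dict  # (chemical, index) -> ModelFunction
    basis: str = "linear"
    sigma_floor_frac: float = 0.05

    def __post_init__(self):
        expected = {(s, i) for s in self.chemicals for i in range(1, N_INDICES + 1)}
        if set(self.functions) != expected:
            raise InvalidDataError(
                f"model set must contain exactly {len(expected)} (chemical, index) "
                f"functions, got {len(self.functions)}"
            )

    def function(self, chemical: str, index: int) -> ModelFunction:
        try:
            return self.functions[(chemical, index)]
        except KeyError:
            raise BadConfigError(f"no model function for ({chemical!r}, {index})") from None

    def conc_range(self, chemical: str) -> tuple:
        f = self.function(chemical, 1)
        return (f.x_lo, f.x_hi)


def fit_model_functions(
    training: TrainingSet,
    basis: str = "linear",
    sigma_floor_frac: float = 0.05,
    sigma_eps: float = 1e-6,
) -> ModelSet:
    """OLS fit of every (chemical, index) dose-response model.

    Per index the sigma floor is ``max(sigma_floor_frac * SD(y_i over the
    whole training set), sigma_eps)``; the residual SD uses a degrees-of-
    freedom correction.  A chemical needs at least (basis parameters + 1)
    distinct concentrations.
    """
    if basis not in BASIS_DEGREE:
        raise BadConfigError(f"basis must be one of {sorted(BASIS_DEGREE)}, got {basis!r}")
    deg = BASIS_DEGREE[basis]
    n_par = deg + 1

    all_y = np.array([rec.y for rec in training.records])  # (n, 15)
    global_sd = all_y.std(axis=0, ddof=1) if len(training) > 1 else np.zeros(N_INDICES)
    floors = np.maximum(sigma_floor_frac * global_sd, sigma_eps)

    functions = {}
    for s in training.chemicals:
        recs = training.records_for(s)
        x = np.array([r.concentration for r in recs])
        if np.unique(x).size < n_par + 1:
            raise InvalidDataError(
                f"chemical {s!r} has {np.unique(x).size} distinct concentrations; "
                f"need >= {n_par + 1} for the {basis} basis"
            )
        u = np.log10(x)
        X = np.vander(u, n_par, increasing=True)
        Y = np.array([r.y for r in recs])  # (n_s, 15)
        coefs, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coefs
        dof = max(len(recs) - n_par, 1)
        resid_sd = np.sqrt((resid**2).sum(axis=0) / dof)
        if len(recs) <= n_par:
            resid_sd[:] = 0.0
        for i in range(1, N_INDICES + 1):
            functions[(s, i)] = ModelFunction(
                chemical=s,
                index=i,
                coef=coefs[:, i - 1],
                sigma=float(max(resid_sd[i - 1], floors[i - 1])),
                x_lo=float(x.min()),
                x_hi=float(x.max()),
            )
    return ModelSet(
        chemicals=list(training.chemicals),
        functions=functions,
        basis=basis,
        sigma_floor_frac=sigma_floor_frac,
    )


def predict_index(models: ModelSet, chemical: str, index: int, x: float) -> float:
    """Evaluate f(x | s, i); x outside the training range extrapolates."""
    if not (np.isfinite(x) and x > 0):
        raise BadConfigError(f"concentration must be > 0, got {x}")
    return float(models.function(chemical, index).predict(x))
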