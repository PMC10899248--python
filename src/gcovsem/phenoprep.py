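"""Phenotype preparation: covariate adjustment and Z-standardization.

Models downstream assume each trait is expressed as a deviation from its
mean with unit variance, so that mean structure can be omitted from the
likelihood.  Binary traits are adjusted with logistic regression and
carried forward as deviance residuals; continuous traits get a
fully-adjusted two-stage rank normalisation (covariate regression →
rank-based inverse-normal transform → re-regression on the same
covariates).  Standardization uses the population (1/n) variance; the
rank-to-normal offset is Blom's 3/8 with average ranks for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "CovariateTable",
    "adjust_categorical",
    "adjust_continuous",
    "standardize",
    "rank_inverse_normal",
    "prepare",
]

_BLOM = 3.0 / 8.0


@dataclass
class CovariateTable:
    """Numeric covariates (sex, age, age², ancestry PCs, ...) with IDs."""

    values: np.ndarray
    sample_ids: np.ndarray
    names: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if self.values.shape[0] != self.sample_ids.shape[0]:
            raise ValueError("covariate rows must match sample_ids")
        if self.names is None:
            self.names = [f"c{i}" for i in range(self.values.shape[1])]

    @classmethod
    def intercept_only(cls, sample_ids) -> "CovariateTable":
        """An empty covariate set: adjustment regresses on the mean only."""
        ids = np.asarray(sample_ids, dtype=str)
        return cls(values=np.empty((ids.size, 0)), sample_ids=ids, names=[])

    def design(self) -> np.ndarray:
        """Design matrix with a leading intercept column."""
        X = np.column_stack([np.ones(self.values.shape[0]), self.values])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate design is rank deficient with intercept")
        return X


@dataclass
class PhenotypeTable:
    """n × k trait matrix with missing mask and per-trait kind.

    ``trait_kinds`` entries are ``"continuous"`` or ``"categorical"``;
    NaN encodes missingness throughout.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    trait_names: list
    trait_kinds: list = field(default=None)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.sample_ids) != 1:
            self.values = self.values.T
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.trait_names = list(self.trait_names)
        if self.trait_kinds is None:
            self.trait_kinds = ["continuous"] * self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.trait_names
        )

    def reindex(self, ids) -> "PhenotypeTable":
        """Align rows to the given ID order (missing IDs become NaN rows)."""
        frame = self.to_frame().reindex(np.asarray(ids, dtype=str))
        return PhenotypeTable(
            values=frame.to_numpy(),
            sample_ids=frame.index.to_numpy(),
            trait_names=self.trait_names,
            trait_kinds=self.trait_kinds,
        )


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y on X over complete rows; NaN propagates."""
    out = np.full(y.shape, np.nan)
    rows = ~np.isnan(y)
    beta, *_ = np.linalg.lstsq(X[rows], y[rows], rcond=None)
    out[rows] = y[rows] - X[rows] @ beta
    return out


def adjust_categorical(y, covars: CovariateTable, name: str = "trait") -> np.ndarray:
    """Deviance residuals of a binary trait after logistic covariate adjustment.

    d_i = sign(y_i − p̂_i) · √(−2 [y_i ln p̂_i + (1 − y_i) ln(1 − p̂_i)]),
    the signed square root of observation i's contribution to the residual
    deviance of the logistic fit.  Missing y propagates as NaN.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    rows = ~np.isnan(y)
    yv = y[rows]
    classes = np.unique(yv)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size != 2:
        raise ValueError(f"trait {name!r} is not binary 0/1 with both classes")
    prev = min(yv.mean(), 1 - yv.mean())
    if prev < 0.05:
        warnings.warn(
            f"trait {name!r} within-sample prevalence {prev:.3f} is below 5%"
        )
    X = covars.design()[rows]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(f"logistic adjustment failed for trait {name!r}: {exc}")
    p = np.clip(fit.fittedvalues, 1e-12, 1 - 1e-12)
    dev = -2.0 * (yv * np.log(p) + (1 - yv) * np.log(1 - p))
    out = np.full(y.shape, np.nan)
    out[rows] = np.sign(yv - p) * np.sqrt(np.maximum(dev, 0.0))
    return out


def rank_inverse_normal(x: np.ndarray, offset: float = _BLOM) -> np.ndarray:
    """Rank-based inverse-normal transform, Φ⁻¹((r − c)/(n + 1 − 2c)).

    Blom's c = 3/8 by default; ties get average ranks; NaN propagates.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    rows = ~np.isnan(x)
    r = stats.rankdata(x[rows], method="average")
    n = rows.sum()
    out[rows] = stats.norm.ppf((r - offset) / (n + 1.0 - 2.0 * offset))
    return out


def adjust_continuous(y, covars: CovariateTable, name: str = "trait") -> np.ndarray:
    """Fully-adjusted two-stage rank normalisation of a continuous trait.

    Stage 1 regresses y on the covariates, stage 2 maps the residual ranks
    to normal quantiles, stage 3 re-regresses the transformed scores on the
    same covariates so covariate effects are not re-introduced by the rank
    map.  The result is standardized to mean 0, unit (population) variance.
    """
    y = np.asarray(y, dtype=float)
    rows = ~np.isnan(y)
    if rows.sum() < 10:
        raise ValueError(f"trait {name!r} has fewer than 10 non-missing values")
    if np.unique(y[rows]).size < 2:
        raise ValueError(f"trait {name!r} is constant")
    X = covars.design()
    stage1 = _ols_residuals(y, X)
    stage2 = rank_inverse_normal(stage1)
    stage3 = _ols_residuals(stage2, X)
    return _zscore(stage3)


def _zscore(x: np.ndarray) -> np.ndarray:
    rows = ~np.isnan(x)
    mu = x[rows].mean()
    sd = x[rows].std()  # population (1/n) convention
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    out = np.full(x.shape, np.nan)
    out[rows] = (x[rows] - mu) / sd
    return out


def standardize(table: PhenotypeTable) -> PhenotypeTable:
    """Z-standardize every column over its non-missing entries.

    Population-SD convention: after this step each column has mean 0 and
    1/n variance exactly 1, which is the contract the SEM likelihood relies
    on to omit mean estimation.
    """
    Z = np.column_stack([_zscore(table.values[:, j]) for j in range(table.k)])
    return PhenotypeTable(
        values=Z,
        sample_ids=table.sample_ids,
        trait_names=table.trait_names,
        trait_kinds=table.trait_kinds,
    )


def prepare(table: PhenotypeTable, covars: CovariateTable) -> PhenotypeTable:
    """Adjust every trait by kind, then Z-standardize the table."""
    if not np.array_equal(table.sample_ids, covars.sample_ids):
        raise ValueError("phenotype and covariate tables must share IDs/order")
    cols = []
    for j, (name, kind) in enumerate(zip(table.trait_names, table.trait_kinds)):
        y = table.values[:, j]
        if kind == "categorical":
            cols.append(adjust_categorical(y, covars, name=name))
        else:
            cols.append(adjust_continuous(y, covars, name=name))
    out = PhenotypeTable(
        values=np.column_stack(cols),
        sample_ids=table.sample_ids,
        trait_names=table.trait_names,
        trait_kinds=table.trait_kinds,
    )
    return standardize(out)
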