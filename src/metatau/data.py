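"""Study-level data containers for random-effects meta-regression.

The random-effects meta-regression model is

    y_i | x_i ~ Normal(x_i beta, sigma_i^2 + tau^2),   i = 1, ..., n,

where ``y_i`` is the estimated effect from study *i*, ``x_i`` a 1 x p row of
study-level covariates (first entry 1 unless an intercept-free regression is
requested), ``sigma_i^2`` the within-study variance (estimated in practice but
treated as fixed and known), and ``tau^2`` the residual between-study variance
— the parameter all interval methods in this package target.

This module holds the dataset container, delimited-text I/O, and log
relative-risk computation from 2x2 event tables with the usual 1/2 continuity
correction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetaRegressionDataset",
    "TwoByTwoTable",
    "RankError",
    "SmallSampleWarning",
    "log_rr",
    "read_dataset",
]


class RankError(ValueError):
    """Design matrix is rank deficient (collinear covariates)."""


class SmallSampleWarning(UserWarning):
    """Fewer studies than recommended for a meta-regression."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Event counts for one study comparing a treatment and a control arm."""

    events_trt: int
    n_trt: int
    events_ctl: int
    n_ctl: int

    def __post_init__(self) -> None:
        for name in ("events_trt", "n_trt", "events_ctl", "n_ctl"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_trt <= 0 or self.n_ctl <= 0:
            raise ValueError("group sizes must be positive")
        if self.events_trt > self.n_trt or self.events_ctl > self.n_ctl:
            raise ValueError("events cannot exceed the group size")


def log_rr(
    table: TwoByTwoTable,
    correction: float = 0.5,
    always_correct: bool = False,
) -> tuple[float, float]:
    """Log relative risk and its variance from a 2x2 table.

    The continuity correction is added to all four cells (events and
    non-events in both arms), and by default only when the table contains a
    zero cell; ``always_correct=True`` applies it unconditionally for
    comparability with software that corrects every table.

    The variance is the standard delta-method (normal-approximation) formula
    ``1/a - 1/(a+b) + 1/c - 1/(c+d)`` evaluated on the corrected cells.

    Returns
    -------
    (estimate, variance)
        Log relative risk (treatment vs control) and its variance.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    a = float(table.events_trt)
    b = float(table.n_trt - table.events_trt)
    c = float(table.events_ctl)
    d = float(table.n_ctl - table.events_ctl)
    cells = np.array([a, b, c, d])
    has_zero = bool((cells == 0.0).any())
    if has_zero and correction == 0.0:
        raise ValueError(
            "table contains a zero cell and correction=0: "
            "log relative risk or its variance would be non-finite"
        )
    if (has_zero or always_correct) and correction > 0.0:
        cells = cells + correction
    a, b, c, d = cells
    estimate = math.log((a / (a + b)) / (c / (c + d)))
    variance = 1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d)
    return estimate, variance


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise RankError naming the collinear columns if X is rank deficient."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) == p:
        return
    bad: list[str] = []
    rank_so_far = 0
    for j in range(p):
        rj = int(np.linalg.matrix_rank(X[:, : j + 1]))
        if rj == rank_so_far:
            bad.append(names[j])
        else:
            rank_so_far = rj
    raise RankError(
        f"design matrix is rank deficient; collinear column(s): {', '.join(bad)}"
    )


@dataclass
class MetaRegressionDataset:
    """The (y, X, sigma2) triple of a random-effects meta-regression.

    Parameters
    ----------
    y : array, shape (n,)
        Effect estimates, one per study.
    X : array, shape (n, p)
        Design matrix of full column rank. The first column is all ones
        unless ``intercept_free`` is set.
    sigma2 : array, shape (n,)
        Strictly positive within-study variances, treated as known.
    study_labels : list of str, optional
        Study identifiers; defaults to ``study_1 ... study_n``.
    covariate_names : list of str, optional
        Column names of X (including the intercept when present).
    intercept_free : bool
        If True, no ones column is required.
    """

    y: np.ndarray
    X: np.ndarray
    sigma2: np.ndarray
    study_labels: list[str] | None = None
    covariate_names: list[str] | None = None
    intercept_free: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        n, p = self.X.shape
        if self.y.shape[0] != n or self.sigma2.shape[0] != n:
            raise ValueError("y, X and sigma2 must agree on the number of studies")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("y and X must be finite")
        if not np.all(np.isfinite(self.sigma2)) or np.any(self.sigma2 <= 0.0):
            raise ValueError("all within-study variances must be strictly positive")
        if n < p + 1:
            raise ValueError(
                f"need at least p+1 = {p + 1} studies to identify tau^2, got n = {n}"
            )
        if not self.intercept_free and not np.allclose(self.X[:, 0], 1.0):
            raise ValueError(
                "first design column must be the intercept (all ones); "
                "pass intercept_free=True for an intercept-free regression"
            )
        if self.covariate_names is None:
            names = ["intercept"] if not self.intercept_free else []
            names += [f"x{j}" for j in range(1, p - len(names) + 1)]
            self.covariate_names = names[:p]
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names must have one entry per design column")
        _check_full_rank(self.X, self.covariate_names)
        if self.study_labels is None:
            self.study_labels = [f"study_{i + 1}" for i in range(n)]
        if len(self.study_labels) != n:
            raise ValueError("study_labels must have one entry per study")
        if n < 10 and p >= 2:
            warnings.warn(
                f"n = {n} studies is below the recommended minimum of 10 for a "
                "meta-regression with covariates",
                SmallSampleWarning,
                stacklevel=2,
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def Delta(self) -> np.ndarray:
        """diag(sigma_i^2), the within-study covariance matrix."""
        return np.diag(self.sigma2)

    @property
    def w(self) -> np.ndarray:
        """Conventional fixed-effect weights w_i = 1/sigma_i^2."""
        return 1.0 / self.sigma2

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        y,
        sigma2,
        covariates=None,
        intercept_free: bool = False,
        study_labels=None,
        covariate_names=None,
    ) -> "MetaRegressionDataset":
        """Build a dataset, prepending an intercept column by default.

        ``covariates`` is an (n, k) array of study-level covariates (or None
        for an intercept-only analysis, i.e. plain meta-analysis).
        """
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if covariates is None:
            C = np.empty((n, 0))
            cnames: list[str] = []
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n and C.shape[1] == n:
                C = C.T
            cnames = (
                list(covariate_names)
                if covariate_names is not None
                else [f"x{j + 1}" for j in range(C.shape[1])]
            )
        if intercept_free:
            X = C
            names = cnames
        else:
            X = np.column_stack([np.ones(n), C])
            names = ["intercept"] + cnames
        return cls(
            y=y,
            X=X,
            sigma2=sigma2,
            study_labels=study_labels,
            covariate_names=names,
            intercept_free=intercept_free,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        yi: str | None = None,
        vi: str | None = None,
        covariates: list[str] | None = None,
        events_trt: str | None = None,
        n_trt: str | None = None,
        events_ctl: str | None = None,
        n_ctl: str | None = None,
        label: str | None = None,
        intercept_free: bool = False,
        correction: float = 0.5,
        always_correct: bool = False,
    ) -> "MetaRegressionDataset":
        """Build a dataset from a data frame.

        Either ``yi``/``vi`` name columns of precomputed effect sizes and
        within-study variances, or the four count columns name a 2x2 table
        per study, in which case log relative risks are computed via
        :func:`log_rr`.
        """
        covariates = list(covariates) if covariates else []
        count_cols = [events_trt, n_trt, events_ctl, n_ctl]
        use_counts = all(c is not None for c in count_cols)
        if yi is not None and vi is not None:
            needed = [yi, vi] + covariates
        elif use_counts:
            needed = [c for c in count_cols if c is not None] + covariates
        else:
            raise ValueError(
                "provide either yi/vi columns or all four 2x2 count columns"
            )
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        for c in needed:
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().any():
                bad_rows = list(df.index[col.isna()])
                raise ValueError(f"non-numeric value(s) in column {c!r}, rows {bad_rows}")
        if yi is not None and vi is not None:
            y = df[yi].to_numpy(dtype=float)
            v = df[vi].to_numpy(dtype=float)
        else:
            pairs = [
                log_rr(
                    TwoByTwoTable(int(r[events_trt]), int(r[n_trt]),
                                  int(r[events_ctl]), int(r[n_ctl])),
                    correction=correction,
                    always_correct=always_correct,
                )
                for _, r in df.iterrows()
            ]
            y = np.array([p[0] for p in pairs])
            v = np.array([p[1] for p in pairs])
        C = df[covariates].to_numpy(dtype=float) if covariates else None
        labels = df[label].astype(str).tolist() if label is not None else None
        return cls.from_arrays(
            y,
            v,
            covariates=C,
            intercept_free=intercept_free,
            study_labels=labels,
            covariate_names=covariates if covariates else None,
        )

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tabular view: label, yi, vi, then the non-intercept covariates."""
        out = pd.DataFrame({"study": self.study_labels, "yi": self.y, "vi": self.sigma2})
        start = 0 if self.intercept_free else 1
        for j in range(start, self.p):
            out[self.covariate_names[j]] = self.X[:, j]
        return out

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_dataset(
    path,
    yi: str | None = None,
    vi: str | None = None,
    covariates: list[str] | None = None,
    events_trt: str | None = None,
    n_trt: str | None = None,
    events_ctl: str | None = None,
    n_ctl: str | None = None,
    label: str | None = None,
    sep: str | None = None,
    intercept_free: bool = False,
    correction: float = 0.5,
    always_correct: bool = False,
) -> MetaRegressionDataset:
    """Read a delimited text file into a validated dataset.

    The delimiter is sniffed when ``sep`` is None (CSV and TSV both work).
    Column roles are given by name; see :meth:`MetaRegressionDataset.from_dataframe`.
    Floats are parsed with the round-trip parser so that writing a dataset
    and re-reading it reproduces the values bit-for-bit.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return MetaRegressionDataset.from_dataframe(
        df,
        yi=yi,
        vi=vi,
        covariates=covariates,
        events_trt=events_trt,
        n_trt=n_trt,
        events_ctl=events_ctl,
        n_ctl=n_ctl,
        label=label,
        intercept_free=intercept_free,
        correction=correction,
        always_correct=always_correct,
    )
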