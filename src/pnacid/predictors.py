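"""Linear predictors for titratable acidity (TA) and pH of PN admixtures.

Both quantities are modelled as affine functions of eight final-admixture
covariates — glucose, lipid and amino acid in g/100 mL; calcium, phosphorus,
sodium, potassium and magnesium in mmol/L:

    TA (mmol/bag) = [b0 + sum_k b_k * c_k] * volume/1000
    pH            =  a0 + sum_k a_k * c_k

The bracket of the TA model is an acidity *concentration* (mmol per litre of
admixture); multiplying by the bag volume yields the per-bag (per-day)
titratable acidity.  pH, an intensive property, carries no volume term.

A shipped :class:`CoefficientSet` holds published coefficients for one
product line.  Because different manufacturers acidify their stock solutions
differently, the coefficients must be re-derived for any new product line
from a set of bench titrations; :class:`TitratableAcidityModel` and
:class:`MixturePHModel` are scikit-learn-style estimators that perform that
refit by ordinary least squares and interoperate with sklearn model
selection.  The organic anions (acetate, gluconate, chloride) and individual
amino-acid species are deliberately not covariates: under a single product
line they are collinear with amino acid, calcium, and sodium+potassium.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .composition import COVARIATE_FIELDS, MixtureComposition

__all__ = [
    "COVARIATES",
    "CoefficientSet",
    "TitrationRecord",
    "TitratableAcidityModel",
    "MixturePHModel",
    "default_coefficients",
    "predict_ta",
    "predict_ph",
    "fit_ta_coefficients",
    "fit_ph_coefficients",
    "fit_coefficients",
    "read_titrations",
    "write_titrations",
]

COVARIATES = COVARIATE_FIELDS


@dataclass(frozen=True)
class CoefficientSet:
    """Intercepts and per-covariate coefficients of the TA and pH predictors."""

    name: str
    ta_intercept: float
    ta_coeffs: Mapping[str, float]
    ph_intercept: float
    ph_coeffs: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for label, coeffs in (("ta", self.ta_coeffs), ("ph", self.ph_coeffs)):
            if set(coeffs) != set(COVARIATES):
                raise ValueError(
                    f"{label}_coeffs must contain exactly the covariates "
                    f"{sorted(COVARIATES)}, got {sorted(coeffs)}"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "CoefficientSet":
        ta = dict(data["ta"])
        ph = dict(data["ph"])
        return cls(
            name=data.get("name", ""),
            ta_intercept=float(ta.pop("intercept")),
            ta_coeffs={k: float(v) for k, v in ta.items()},
            ph_intercept=float(ph.pop("intercept")),
            ph_coeffs={k: float(v) for k, v in ph.items()},
            provenance=data.get("provenance", ""),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "ta": {"intercept": self.ta_intercept, **dict(self.ta_coeffs)},
            "ph": {"intercept": self.ph_intercept, **dict(self.ph_coeffs)},
            "provenance": self.provenance,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "CoefficientSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def default_coefficients() -> CoefficientSet:
    """The shipped published coefficient set (single-product-line fit)."""
    text = resources.files("pnacid").joinpath("coefficients/iacone2018.json").read_text()
    return CoefficientSet.from_dict(json.loads(text))


@dataclass(frozen=True)
class TitrationRecord:
    """One bench measurement: pH-metry and NaOH titration to pH 7.4."""

    mixture_id: str
    measured_ph: float
    measured_ta: float  # mmol 0.1 M NaOH to reach pH 7.4

    def __post_init__(self) -> None:
        if not (0.0 < self.measured_ph < 14.0):
            raise ValueError(f"measured_ph must be in (0, 14), got {self.measured_ph!r}")
        if not math.isfinite(self.measured_ta):
            raise ValueError("measured_ta must be finite")


# ---------------------------------------------------------------------------
# point predictions


def predict_ta(m: MixtureComposition, c: CoefficientSet | None = None) -> float:
    """Predicted titratable acidity of one bag, in mmol (full precision)."""
    c = c or default_coefficients()
    bracket = c.ta_intercept + sum(c.ta_coeffs[k] * getattr(m, k) for k in COVARIATES)
    return bracket * m.volume_ml / 1000.0


def predict_ph(m: MixtureComposition, c: CoefficientSet | None = None) -> float:
    """Predicted pH of the admixture (volume-independent)."""
    c = c or default_coefficients()
    ph = c.ph_intercept + sum(c.ph_coeffs[k] * getattr(m, k) for k in COVARIATES)
    if not (0.0 < ph < 14.0):
        warnings.warn(
            f"predicted pH {ph:.3f} lies outside (0, 14); the linear model is "
            "extrapolating far beyond its calibration range",
            stacklevel=2,
        )
    return ph


# ---------------------------------------------------------------------------
# estimators


def _design_frame(X) -> pd.DataFrame:
    """Coerce mixtures / DataFrame / array into a covariate+volume frame."""
    if isinstance(X, pd.DataFrame):
        df = X
    else:
        X = list(X)
        if X and isinstance(X[0], MixtureComposition):
            df = pd.DataFrame(
                [{**m.covariates(), "volume_ml": m.volume_ml} for m in X]
            )
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] not in (8, 9):
                raise ValueError(
                    "X must be a DataFrame, a sequence of MixtureComposition, or "
                    "an (n, 8|9) array of covariates [+ volume_ml]"
                )
            cols = list(COVARIATES) + (["volume_ml"] if arr.shape[1] == 9 else [])
            df = pd.DataFrame(arr, columns=cols)
    missing = [c for c in COVARIATES if c not in df.columns]
    if missing:
        raise ValueError(f"design is missing covariate columns {missing}")
    return df


def _check_design_rank(M: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the offending columns when the design is rank-deficient."""
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the dependent ones
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(M, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(M.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[j] for j in piv[diag <= tol]] if diag.size else list(names)
        if not bad:
            bad = [names[j] for j in piv[rank:]]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {M.shape[1]}); "
            f"collinear or constant columns: {bad}"
        )


class _LinearMixtureModel(RegressorMixin, BaseEstimator):
    """Shared OLS machinery for the TA and pH models.

    Subclasses define how the raw per-bag response maps to the regression
    response (TA is volume-normalised, pH is used as-is) and back.
    """

    _min_n = 10

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    # response transforms -------------------------------------------------
    def _to_regression_response(self, y: np.ndarray, volume_ml: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _from_linear(self, linear: np.ndarray, volume_ml: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _needs_volume(self) -> bool:
        raise NotImplementedError

    # sklearn API ----------------------------------------------------------
    def fit(self, X, y):
        df = _design_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(df) != len(y):
            raise ValueError("X and y have different lengths")
        if len(y) < self._min_n:
            raise ValueError(
                f"at least {self._min_n} paired observations are required, got {len(y)}"
            )
        if self._needs_volume():
            if "volume_ml" not in df.columns:
                raise ValueError("TA fitting requires a volume_ml column")
            volume = df["volume_ml"].to_numpy(dtype=float)
        else:
            volume = np.ones(len(y))
        C = df.loc[:, list(COVARIATES)].to_numpy(dtype=float)
        design = sm.add_constant(C, has_constant="add") if self.fit_intercept else C
        names = (["intercept"] if self.fit_intercept else []) + list(COVARIATES)
        _check_design_rank(design, names)
        resp = self._to_regression_response(y, volume)
        res = sm.OLS(resp, design).fit()
        params = np.asarray(res.params, dtype=float)
        if self.fit_intercept:
            self.intercept_ = float(params[0])
            self.coef_ = params[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = params.copy()
        self.bse_ = np.asarray(res.bse, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rsq = res.rsquared  # -inf/nan for a constant response
        self.rvalue_ = float(np.sqrt(rsq)) if np.isfinite(rsq) and rsq > 0 else 0.0
        self.n_obs_ = int(res.nobs)
        self.feature_names_in_ = np.asarray(list(COVARIATES), dtype=object)
        self._ols_result = res
        return self

    def _linear_part(self, df: pd.DataFrame) -> np.ndarray:
        C = df.loc[:, list(COVARIATES)].to_numpy(dtype=float)
        return self.intercept_ + C @ self.coef_

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        df = _design_frame(X)
        if self._needs_volume():
            if "volume_ml" not in df.columns:
                raise ValueError("TA prediction requires a volume_ml column")
            volume = df["volume_ml"].to_numpy(dtype=float)
        else:
            volume = np.ones(len(df))
        return self._from_linear(self._linear_part(df), volume)

    def coef_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(COVARIATES, self.coef_)}


class TitratableAcidityModel(_LinearMixtureModel):
    """OLS model of titratable acidity on mixture composition.

    The regression response is the volume-normalised acidity
    ``TA * 1000 / volume`` (mmol per litre of admixture), so the fitted model
    has the same [bracket] * volume/1000 structure as the shipped predictor
    and predictions scale exactly linearly with bag volume.

    Fitted attributes: ``intercept_``, ``coef_`` (aligned with
    :data:`COVARIATES`), ``bse_`` (standard errors, intercept first),
    ``rvalue_`` (multiple correlation), ``n_obs_``.
    """

    def _needs_volume(self) -> bool:
        return True

    def _to_regression_response(self, y, volume_ml):
        return y * 1000.0 / volume_ml

    def _from_linear(self, linear, volume_ml):
        return linear * volume_ml / 1000.0

    @classmethod
    def from_coefficients(cls, c: CoefficientSet) -> "TitratableAcidityModel":
        model = cls()
        model.intercept_ = float(c.ta_intercept)
        model.coef_ = np.array([c.ta_coeffs[k] for k in COVARIATES], dtype=float)
        model.rvalue_ = float("nan")
        return model


class MixturePHModel(_LinearMixtureModel):
    """OLS model of admixture pH on mixture composition (no volume term)."""

    def _needs_volume(self) -> bool:
        return False

    def _to_regression_response(self, y, volume_ml):
        return y

    def _from_linear(self, linear, volume_ml):
        return linear

    @classmethod
    def from_coefficients(cls, c: CoefficientSet) -> "MixturePHModel":
        model = cls()
        model.intercept_ = float(c.ph_intercept)
        model.coef_ = np.array([c.ph_coeffs[k] for k in COVARIATES], dtype=float)
        model.rvalue_ = float("nan")
        return model


# ---------------------------------------------------------------------------
# functional refit interface


def _pair(mixtures: Sequence[MixtureComposition], records: Sequence[TitrationRecord]):
    by_id = {r.mixture_id: r for r in records}
    pairs = [(m, by_id[m.mixture_id]) for m in mixtures if m.mixture_id in by_id]
    if len(pairs) < len(mixtures) or len(pairs) < len(records):
        matched = {m.mixture_id for m, _ in pairs}
        unmatched = sorted(
            ({m.mixture_id for m in mixtures} | set(by_id)) - matched
        )
        raise ValueError(f"mixtures and titration records do not pair up: {unmatched}")
    return pairs


def fit_ta_coefficients(
    mixtures: Sequence[MixtureComposition],
    records: Sequence[TitrationRecord],
    name: str = "refit-ta",
    base: CoefficientSet | None = None,
) -> CoefficientSet:
    """Re-derive the TA coefficients for a new product line by OLS.

    Pairs mixtures with titration records by ``mixture_id`` and regresses the
    volume-normalised measured acidity on the eight covariates.  The returned
    set keeps the pH half of ``base`` (default: the shipped set) untouched,
    recording in the provenance which half was fitted and the achieved
    multiple correlation.
    """
    base = base or default_coefficients()
    pairs = _pair(mixtures, records)
    X = pd.DataFrame([{**m.covariates(), "volume_ml": m.volume_ml} for m, _ in pairs])
    y = np.array([r.measured_ta for _, r in pairs])
    model = TitratableAcidityModel().fit(X, y)
    return replace(
        base,
        name=name,
        ta_intercept=model.intercept_,
        ta_coeffs=model.coef_dict(),
        provenance=(
            f"TA half fitted by OLS on {model.n_obs_} titrations (r = {model.rvalue_:.4f}); "
            f"pH half inherited from {base.name!r}"
        ),
    )


def fit_ph_coefficients(
    mixtures: Sequence[MixtureComposition],
    records: Sequence[TitrationRecord],
    name: str = "refit-ph",
    base: CoefficientSet | None = None,
) -> CoefficientSet:
    """Re-derive the pH coefficients by OLS; counterpart of
    :func:`fit_ta_coefficients` with the pH measurement as the response."""
    base = base or default_coefficients()
    pairs = _pair(mixtures, records)
    X = pd.DataFrame([m.covariates() for m, _ in pairs])
    y = np.array([r.measured_ph for _, r in pairs])
    model = MixturePHModel().fit(X, y)
    return replace(
        base,
        name=name,
        ph_intercept=model.intercept_,
        ph_coeffs=model.coef_dict(),
        provenance=(
            f"pH half fitted by OLS on {model.n_obs_} measurements (r = {model.rvalue_:.4f}); "
            f"TA half inherited from {base.name!r}"
        ),
    )


def fit_coefficients(
    mixtures: Sequence[MixtureComposition],
    records: Sequence[TitrationRecord],
    name: str = "refit",
) -> CoefficientSet:
    """Fit both halves from the same paired titration data."""
    with_ta = fit_ta_coefficients(mixtures, records, name=name)
    both = fit_ph_coefficients(mixtures, records, name=name, base=with_ta)
    return replace(
        both,
        provenance=f"TA and pH halves fitted by OLS on {len(records)} titrations",
    )


# ---------------------------------------------------------------------------
# titration CSV I/O

TITRATION_CSV_COLUMNS = ("mixture_id", "measured_ph", "measured_ta_mmol")


def read_titrations(path: str | Path) -> list[TitrationRecord]:
    df = pd.read_csv(path)
    missing = [c for c in TITRATION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"titration CSV is missing columns {missing}")
    return [
        TitrationRecord(
            mixture_id=str(row.mixture_id),
            measured_ph=float(row.measured_ph),
            measured_ta=float(row.measured_ta_mmol),
        )
        for row in df.itertuples(index=False)
    ]


def write_titrations(records: Iterable[TitrationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "mixture_id": r.mixture_id,
                "measured_ph": r.measured_ph,
                "measured_ta_mmol": r.measured_ta,
            }
            for r in records
        ],
        columns=list(TITRATION_CSV_COLUMNS),
    )
    df.to_csv(path, index=False)
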