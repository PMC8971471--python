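"""Vegetation indices from band reflectance and empirical LAI inversion models.

Six indices (EVI, EVI2, MSR, NDVI, OSAVI, RVI) are computed from blue /
green / red / near-infrared reflectance.  LAI inversion supports one
univariate model per index (linear, power or exponential form) and a
multi-index partial-least-squares regression, with a seeded split-sample
evaluation that fits on a modeling subset and scores on a held-out
validation subset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from safyassim import metrics

__all__ = [
    "BandReflectance",
    "VegIndexVector",
    "InversionModel",
    "PlsrModel",
    "INDEX_NAMES",
    "DEFAULT_FORMS",
    "compute_vegetation_indices",
    "indices_frame",
    "fit_univariate_inversion",
    "fit_plsr",
    "predict_lai",
    "split_and_evaluate",
]

INDEX_NAMES = ("evi", "evi2", "msr", "ndvi", "osavi", "rvi")

#: functional form used for each index's univariate inversion model
DEFAULT_FORMS = {
    "evi": "linear",
    "evi2": "power",
    "msr": "exponential",
    "ndvi": "linear",
    "osavi": "exponential",
    "rvi": "linear",
}


@dataclass(frozen=True)
class BandReflectance:
    """Canopy reflectance in the four bands, each in [0, 1]."""

    blue: float
    green: float
    red: float
    nir: float
    plot_id: str = ""
    date: int = 0

    def __post_init__(self) -> None:
        for name in ("blue", "green", "red", "nir"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} reflectance {v} outside [0, 1]")


@dataclass(frozen=True)
class VegIndexVector:
    evi: float
    evi2: float
    msr: float
    ndvi: float
    osavi: float
    rvi: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def compute_vegetation_indices(bands: BandReflectance) -> VegIndexVector:
    """Evaluate all six indices; any index with a zero or invalid denominator
    is returned as NaN while the others are still computed."""
    b, r, nir = bands.blue, bands.red, bands.nir

    def safe(num: float, den: float) -> float:
        return num / den if den != 0.0 else math.nan

    evi = safe(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0)
    evi2 = safe(2.5 * (nir - r), nir + 2.4 * r + 1.0)
    ndvi = safe(nir - r, nir + r)
    osavi = safe(nir - r, nir + r + 0.16)
    if r > 0.0:
        rvi = nir / r
        msr = (rvi - 1.0) / (math.sqrt(rvi) + 1.0)
    else:
        rvi = math.nan
        msr = math.nan
    return VegIndexVector(evi=evi, evi2=evi2, msr=msr, ndvi=ndvi, osavi=osavi, rvi=rvi)


def indices_frame(reflectances: pd.DataFrame) -> pd.DataFrame:
    """Vectorized index computation over a reflectance table.

    Expects columns ``b_blue, b_green, b_red, b_nir`` (plus any id columns,
    which are carried through); adds one column per index.
    """
    out = reflectances.copy()
    b = reflectances["b_blue"].to_numpy(float)
    r = reflectances["b_red"].to_numpy(float)
    nir = reflectances["b_nir"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(r > 0, nir / r, np.nan)
        out["evi"] = 2.5 * (nir - r) / (nir + 6.0 * r - 7.5 * b + 1.0)
        out["evi2"] = 2.5 * (nir - r) / (nir + 2.4 * r + 1.0)
        out["msr"] = (ratio - 1.0) / (np.sqrt(ratio) + 1.0)
        out["ndvi"] = (nir - r) / (nir + r)
        out["osavi"] = (nir - r) / (nir + r + 0.16)
        out["rvi"] = ratio
    return out


@dataclass
class InversionModel:
    """Fitted univariate LAI model: y = a*x + b, y = a*x^b or y = a*e^(b*x)."""

    index_name: str
    form: str
    a: float
    b: float
    diagnostics: dict = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            y = self.a * x + self.b
        elif self.form == "power":
            y = self.a * np.power(x, self.b)
        elif self.form == "exponential":
            y = self.a * np.exp(self.b * x)
        else:
            raise ValueError(f"unknown form {self.form!r}")
        return np.maximum(y, 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "index": self.index_name,
                "form": self.form,
                "a": self.a,
                "b": self.b,
                "diagnostics": self.diagnostics,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "InversionModel":
        d = json.loads(s)
        return cls(d["index"], d["form"], d["a"], d["b"], d.get("diagnostics", {}))


def _diagnostics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    try:
        r2 = metrics.r_squared((y_true, y_pred))
    except metrics.UndefinedStatisticError:
        r2 = math.nan
    e = metrics.rmse((y_true, y_pred))
    try:
        n = metrics.nrmse((y_true, y_pred))
    except metrics.UndefinedStatisticError:
        n = math.nan
    return {"r2": r2, "rmse": e, "nrmse_pct": n}


def fit_univariate_inversion(
    x, y, form: str, index_name: str = ""
) -> InversionModel:
    """Least-squares fit of one functional form.

    Nonlinear forms are initialized from the log-transformed closed-form
    solution and refined by direct nonlinear least squares on the original
    scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate predictor: x is constant")

    if form == "linear":
        a, b = np.polyfit(x, y, 1)
    elif form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential form requires y > 0")
        lb, la = np.polyfit(x, np.log(y), 1)
        (a, b), _ = curve_fit(
            lambda t, a_, b_: a_ * np.exp(b_ * t), x, y, p0=(math.exp(la), lb), maxfev=10000
        )
    elif form == "power":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power form requires x > 0 and y > 0")
        lb, la = np.polyfit(np.log(x), np.log(y), 1)
        (a, b), _ = curve_fit(
            lambda t, a_, b_: a_ * np.power(t, b_), x, y, p0=(math.exp(la), lb), maxfev=10000
        )
    else:
        raise ValueError(f"unknown form {form!r}")

    model = InversionModel(index_name=index_name, form=form, a=float(a), b=float(b))
    model.diagnostics = _diagnostics(y, model.predict(x))
    return model


@dataclass
class PlsrModel:
    """Partial least squares regression with a single response.

    Components are extracted iteratively (NIPALS-style deflation) from
    centered/scaled predictors; ``coef`` and ``intercept`` express the final
    linear predictor in original units.
    """

    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, m)
    loadings: np.ndarray  # (p, m)
    coef: np.ndarray  # (p,) original-unit regression coefficients
    intercept: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept


def fit_plsr(X, y, n_components: int) -> PlsrModel:
    """Fit PLSR by sequential component extraction and deflation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in [1, {p}]")
    if n <= n_components:
        raise ValueError("need more samples than components")

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    x_std[x_std == 0.0] = 1.0
    y_mean = float(y.mean())
    E = (X - x_mean) / x_std
    f = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for j in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # residual predictor information exhausted
            W, P, q = W[:, : j], P[:, : j], q[:j]
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        pj = E.T @ t / tt
        qj = float(f @ t) / tt
        E = E - np.outer(t, pj)
        f = f - qj * t
        W[:, j], P[:, j], q[j] = w, pj, qj

    # map latent-space regression back to (scaled) predictors, then to
    # original units
    B_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef = B_scaled / x_std
    intercept = y_mean - float(x_mean @ coef)
    return PlsrModel(
        n_components=W.shape[1],
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        coef=coef,
        intercept=intercept,
    )


def predict_lai(model, x) -> np.ndarray:
    """Evaluate a fitted inversion model; negative predictions floored at 0."""
    if isinstance(model, PlsrModel):
        return np.maximum(model.predict(x), 0.0)
    return model.predict(x)


def _stratified_split(dates: np.ndarray, frac: float, rng: np.random.Generator):
    """Seeded split stratified by acquisition date."""
    model_idx: list[int] = []
    valid_idx: list[int] = []
    for d in np.unique(dates):
        grp = np.flatnonzero(dates == d)
        grp = rng.permutation(grp)
        k = int(round(frac * grp.size))
        model_idx.extend(grp[:k])
        valid_idx.extend(grp[k:])
    return np.sort(model_idx), np.sort(valid_idx)


def split_and_evaluate(
    dataset: pd.DataFrame,
    split_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    forms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fit one model per index on a modeling subset and score both subsets.

    ``dataset`` needs the six index columns, a ``lai`` column and a ``date``
    column (used to stratify the split).  Returns one row per index with
    modeling/validation R^2, RMSE and nRMSE, ranked by validation R^2
    (ties broken by lower validation RMSE).
    """
    if len(dataset) < 6:
        raise ValueError("need at least 6 samples")
    forms = dict(DEFAULT_FORMS if forms is None else forms)
    rng = np.random.default_rng(seed)
    midx, vidx = _stratified_split(dataset["date"].to_numpy(), split_fraction, rng)
    mod = dataset.iloc[midx]
    val = dataset.iloc[vidx]
    if len(mod) < 3 or len(val) < 2:
        raise ValueError("split subsets too small to fit/evaluate")

    rows = []
    for name in INDEX_NAMES:
        try:
            model = fit_univariate_inversion(
                mod[name].to_numpy(), mod["lai"].to_numpy(), forms[name], index_name=name
            )
        except ValueError:
            # data outside the form's domain (e.g. non-positive values for a
            # power/exponential fit): report the index as unfit
            rows.append(
                {
                    "index": name,
                    "form": forms[name],
                    "a": math.nan,
                    "b": math.nan,
                    "n_model": len(mod),
                    "n_valid": len(val),
                    "model_r2": math.nan,
                    "model_rmse": math.nan,
                    "model_nrmse_pct": math.nan,
                    "valid_r2": math.nan,
                    "valid_rmse": math.nan,
                    "valid_nrmse_pct": math.nan,
                }
            )
            continue
        dm = _diagnostics(mod["lai"].to_numpy(), model.predict(mod[name].to_numpy()))
        dv = _diagnostics(val["lai"].to_numpy(), model.predict(val[name].to_numpy()))
        rows.append(
            {
                "index": name,
                "form": model.form,
                "a": model.a,
                "b": model.b,
                "n_model": len(mod),
                "n_valid": len(val),
                "model_r2": dm["r2"],
                "model_rmse": dm["rmse"],
                "model_nrmse_pct": dm["nrmse_pct"],
                "valid_r2": dv["r2"],
                "valid_rmse": dv["rmse"],
                "valid_nrmse_pct": dv["nrmse_pct"],
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["valid_r2", "valid_rmse"], ascending=[False, True], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
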