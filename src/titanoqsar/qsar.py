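"""Monolinear QSAR machinery.

Implements the statistics behind the titanocene structure-activity study:
the pIC50 transform, ordinary-least-squares monolinear fits reported with
the signed Pearson correlation and the one-predictor F statistic
F = r^2 (n-2) / (1 - r^2), descriptor intercorrelation screening,
leave-half-out cross-validation (q^2 = 1 - PRESS/TSS over pooled held-out
predictions), and experimental-vs-predicted activity tables.

Activity is expressed as pA = pIC50 = -log10(IC50 in mol/L); with IC50 in
micromolar this is 6 - log10(IC50_uM). All fits use pairwise-complete
cases and pA recomputed from IC50 at full precision (the printed 2-dp pA
values lose the digits needed to recover the published slopes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets_io import (CELL_LINES, CompoundTable, DescriptorRecord,
                          load_fixture, round_half_up)

__all__ = [
    "LinearModel",
    "PredictionTable",
    "pic50_from_uM",
    "fit_monolinear",
    "predict",
    "prediction_table",
    "intercorrelation_matrix",
    "cross_validate_lho",
    "refit_paper_equations",
]


@dataclass(frozen=True)
class LinearModel:
    """A fitted monolinear model y = a0 + b*x with the reporting
    conventions of the study (signed r; F = r^2 (n-2)/(1-r^2))."""

    a0: float
    b: float
    se_a0: float
    se_b: float
    r: float
    F: float
    n: int
    q2cv: Optional[float] = None
    predictor: str = "x"
    response: str = "y"

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("monolinear fit needs n >= 3")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| > 1")
        if abs(self.r) < 1:
            f_expected = self.r ** 2 * (self.n - 2) / (1 - self.r ** 2)
            if abs(self.F - f_expected) > 1e-6 * max(1.0, f_expected):
                raise ValueError("F inconsistent with r and n")


@dataclass
class PredictionTable:
    """Experimental vs predicted activities per compound; ``delta`` is
    experimental minus predicted. Missing activities propagate as NaN."""

    df: pd.DataFrame  # columns: code, experimental, predicted, delta

    def __post_init__(self):
        both = self.df["experimental"].notna() & self.df["predicted"].notna()
        resid = (self.df.loc[both, "experimental"]
                 - self.df.loc[both, "predicted"]
                 - self.df.loc[both, "delta"])
        if len(resid) and np.abs(resid).max() > 1e-6:
            raise ValueError("delta != experimental - predicted")

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        out = self.df.copy()
        for col in ("experimental", "predicted", "delta"):
            out[col] = [np.nan if pd.isna(v) else round_half_up(v, decimals)
                        for v in out[col]]
        return out


def pic50_from_uM(ic50) -> float:
    """pA = pIC50 = -log10(IC50 in mol/L) = 6 - log10(IC50 in uM)."""
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("IC50 must be positive")
    out = 6.0 - np.log10(ic50)
    return float(out) if out.ndim == 0 else out


def _complete_cases(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def fit_monolinear(x, y, predictor: str = "x",
                   response: str = "y") -> LinearModel:
    """Ordinary least squares y = a0 + b*x on pairwise-complete cases.

    Returns coefficient standard errors from the OLS fit, the signed
    Pearson correlation, and F computed as r^2 (n-2)/(1-r^2).
    """
    x, y = _complete_cases(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    a0, b = res.params
    se_a0, se_b = res.bse
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
        F = math.inf
    else:
        F = r ** 2 * (n - 2) / (1 - r ** 2)
    return LinearModel(a0=float(a0), b=float(b), se_a0=float(se_a0),
                       se_b=float(se_b), r=r, F=float(F), n=n,
                       predictor=predictor, response=response)


def predict(model: LinearModel, x):
    """a0 + b*x at full precision (display rounding is the report's job)."""
    x = np.asarray(x, dtype=float)
    out = model.a0 + model.b * x
    return float(out) if out.ndim == 0 else out


def prediction_table(model: LinearModel, table: CompoundTable,
                     predictor_values: pd.Series,
                     line: str) -> PredictionTable:
    """Experimental/predicted/delta activities for one cell line.

    ``predictor_values`` is a code-indexed series (e.g. logP from the
    descriptor table). Compounds without a measured activity keep NaN in
    every derived column.
    """
    if line not in CELL_LINES:
        raise ValueError(f"unknown cell line {line!r}")
    codes = table.codes
    missing = [c for c in codes if c not in predictor_values.index]
    if missing:
        raise ValueError(f"predictor values missing for {missing}")
    exp = table.pa(line, recompute=True)
    rows = []
    for code in codes:
        e = exp.loc[code]
        p = predict(model, predictor_values.loc[code])
        if pd.isna(e):
            rows.append((code, np.nan, np.nan, np.nan))
        else:
            rows.append((code, float(e), float(p), float(e) - float(p)))
    return PredictionTable(pd.DataFrame(
        rows, columns=["code", "experimental", "predicted", "delta"]))


def intercorrelation_matrix(descriptors: Sequence[DescriptorRecord]
                            ) -> pd.DataFrame:
    """Pairwise Pearson correlations over the six structural descriptors."""
    cols = ["s_vdw", "v_vdw", "e_hydr", "logp", "rf", "pol"]
    df = pd.DataFrame([{c: getattr(d, c) for c in cols}
                       for d in descriptors])
    if len(df) < 3:
        raise ValueError("need at least 3 complete descriptor rows")
    for c in cols:
        if df[c].nunique() == 1:
            raise ValueError(f"descriptor {c} is constant")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cross_validate_lho(x, y, n_splits: int = 200,
                       seed: Optional[int] = None) -> float:
    """Leave-half-out cross-validated q^2.

    Splits the n complete pairs into a held-out half of size floor(n/2)
    and a training half; fits on the training half and predicts the
    held-out half. All C(n, floor(n/2)) balanced splits are enumerated
    when there are at most 1000, otherwise ``n_splits`` seeded random
    splits are drawn. Held-out predictions are pooled across splits and
    q^2 = 1 - PRESS/TSS with TSS about the full-sample mean. Training
    halves with zero predictor variance are skipped (and counted).
    """
    x, y = _complete_cases(x, y)
    n = len(x)
    if n < 4:
        raise ValueError("leave-half-out needs n >= 4")
    k = n // 2
    total = math.comb(n, k)
    idx = np.arange(n)
    if total <= 1000:
        splits = [np.array(c) for c in combinations(idx, k)]
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.choice(idx, size=k, replace=False)
                  for _ in range(n_splits)]
    ybar = y.mean()
    press = tss = 0.0
    used = skipped = 0
    for held in splits:
        train = np.setdiff1d(idx, held)
        xt, yt = x[train], y[train]
        if np.ptp(xt) == 0:
            skipped += 1
            continue
        b, a0 = np.polyfit(xt, yt, 1)
        pred = a0 + b * x[held]
        press += float(np.sum((y[held] - pred) ** 2))
        tss += float(np.sum((y[held] - ybar) ** 2))
        used += 1
    if used == 0:
        raise ValueError("all splits degenerate (zero x variance)")
    return 1.0 - press / tss


#: The seven published pairings: (name, response table/column, predictor).
_PAPER_FITS = (
    ("eq1", "pa_hela", "logp"),
    ("eq2", "pa_k562", "logp"),
    ("eq3", "pa_femx", "logp"),
    ("eq4", "pa_k562", "rf"),
    ("eq5", "e_int_aCD", "e_hydr"),
    ("eq6", "e_int_bCD", "logp"),
    ("eq7", "e_int_gCD", "logp"),
)


def refit_paper_equations(activities: Optional[CompoundTable] = None,
                          descriptors=None, energies=None,
                          with_cv: bool = True) -> list:
    """Refit the seven published monolinear models from the fixtures.

    Activity responses use pA recomputed from IC50 at full precision;
    interaction-energy responses come straight from the energy table.
    With 7-11 compounds all balanced half-splits are enumerable, so the
    attached q2cv values are deterministic.
    """
    if activities is None:
        activities = load_fixture("activities")
    if descriptors is None:
        descriptors = load_fixture("descriptors")
    if energies is None:
        energies = load_fixture("energies")

    desc = pd.DataFrame([{ "code": d.code, "logp": d.logp, "rf": d.rf,
                           "e_hydr": d.e_hydr} for d in descriptors]
                        ).set_index("code")
    eint = {}
    for cd in ("aCD", "bCD", "gCD"):
        eint[f"e_int_{cd}"] = pd.Series(
            {r.complex_code.split("_")[0]: r.e_int
             for r in energies if r.cd == cd})

    models = []
    for name, response, predictor in _PAPER_FITS:
        if response.startswith("pa_"):
            line = response[3:]
            yser = activities.pa(line, recompute=True)
        else:
            yser = eint[response]
        codes = [c for c in activities.codes if c in yser.index]
        y = yser.loc[codes].to_numpy(dtype=float)
        x = desc.loc[codes, predictor].to_numpy(dtype=float)
        m = fit_monolinear(x, y, predictor=predictor, response=response)
        if with_cv:
            q2 = cross_validate_lho(x, y)
            m = replace(m, q2cv=q2)
        models.append(m)
    return models
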