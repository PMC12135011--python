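"""Developmental-rate trade-off analysis.

Resistance to ivermectin carries a developmental cost: without drug,
resistant (GluCl triple mutant) animals reach adulthood more slowly than
wild type, while under drug the wild type is the one delayed.  The assay
scores drops of synchronized liquid cultures at fixed times
post-synchronization (72 and 96 h) for total animals and adults.

This module computes pooled adult fractions with Wilson score intervals,
fits a binomial logistic dose-response logit p(c) = beta0 + beta1 * c per
genotype x timepoint (maximum likelihood via iteratively reweighted least
squares, with drops as the sampling units), and locates the developmental
crossover: the drug concentration where the two genotypes' fitted
adult-fraction curves intersect, i.e. where the developmental advantage
switches sides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .patterns import GenotypeClass
from .simulate import DevAssayRecord

__all__ = [
    "LogisticDoseFit",
    "adult_fraction",
    "fit_logistic_dose",
    "development_crossover",
    "records_to_frame",
    "read_dev_records",
    "write_dev_records",
]

DEV_COLUMNS = ["genotype", "concentration", "hours", "drop_id", "n_total", "n_adult"]


def records_to_frame(records: Iterable[DevAssayRecord]) -> pd.DataFrame:
    rows = [
        {
            "genotype": r.genotype.value,
            "concentration": r.concentration,
            "hours": r.hours,
            "drop_id": r.drop_id,
            "n_total": r.n_total,
            "n_adult": r.n_adult,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=DEV_COLUMNS)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(DEV_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"records frame missing columns {sorted(missing)}")
        return records
    return records_to_frame(records)


def write_dev_records(records, path: str | Path) -> None:
    _as_frame(records).to_csv(path, sep="\t", index=False)


def read_dev_records(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    return _as_frame(df)


def adult_fraction(
    records,
    by: Sequence[str] = ("genotype", "concentration", "hours"),
) -> pd.DataFrame:
    """Pooled adult fraction per group with a 95% Wilson score interval.

    Drops partitioning the same pooled counts give identical results: the
    fraction is sum(n_adult) / sum(n_total) over the group.  A group with
    zero animals is an error naming the group.
    """
    df = _as_frame(records)
    rows = []
    for key, grp in df.groupby(list(by), sort=True):
        tot = int(grp["n_total"].sum())
        if tot == 0:
            raise ValueError(f"group {key!r} has no animals")
        adults = int(grp["n_adult"].sum())
        lo, hi = proportion_confint(adults, tot, alpha=0.05, method="wilson")
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n_total=tot,
            n_adult=adults,
            fraction=adults / tot,
            ci_low=float(lo),
            ci_high=float(hi),
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LogisticDoseFit:
    """Binomial logistic fit logit p(c) = beta0 + beta1 * c for one
    genotype x timepoint."""

    genotype: str
    hours: int
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    deviance: float
    converged: bool
    separated: bool = False

    def predict(self, c) -> np.ndarray:
        z = self.beta0 + self.beta1 * np.asarray(c, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "hours": self.hours,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se_beta0": self.se_beta0,
            "se_beta1": self.se_beta1,
            "deviance": self.deviance,
            "converged": self.converged,
            "separated": self.separated,
        }


_BETA_BOUND = 50.0  # coefficient clamp reported under complete separation


def fit_logistic_dose(records, *, genotype=None, hours: int | None = None
                      ) -> LogisticDoseFit:
    """Fit the logistic dose-response for one genotype x timepoint.

    ``records`` may be pre-filtered, or ``genotype``/``hours`` select the
    subset.  Requires >= 2 distinct concentrations with both outcomes
    observed overall.  Complete separation is flagged and the coefficients
    reported clamped at +/-50 rather than diverging.
    """
    df = _as_frame(records)
    if genotype is not None:
        gval = genotype.value if isinstance(genotype, GenotypeClass) else genotype
        df = df[df["genotype"] == gval]
    if hours is not None:
        df = df[df["hours"] == hours]
    if df.empty:
        raise ValueError("no records for requested genotype/hours")
    gval = df["genotype"].iloc[0]
    hval = int(df["hours"].iloc[0])
    if df["concentration"].nunique() < 2:
        raise ValueError("need >= 2 distinct concentrations")
    adults = df["n_adult"].sum()
    if adults == 0 or adults == df["n_total"].sum():
        raise ValueError("need both outcomes observed")

    endog = df[["n_adult"]].copy()
    endog["n_nonadult"] = df["n_total"] - df["n_adult"]
    X = sm.add_constant(df["concentration"].to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            res = sm.GLM(
                endog.to_numpy(dtype=float), X, family=sm.families.Binomial()
            ).fit(tol=1e-10)
        beta0, beta1 = res.params
        se0, se1 = res.bse
        return LogisticDoseFit(
            genotype=gval,
            hours=hval,
            beta0=float(beta0),
            beta1=float(beta1),
            se_beta0=float(se0),
            se_beta1=float(se1),
            deviance=float(res.deviance),
            converged=bool(res.converged),
        )
    except (PerfectSeparationError, UserWarning, np.linalg.LinAlgError):
        # complete separation: report clamped coefficients, flagged
        frac = df.groupby("concentration").apply(
            lambda g: g["n_adult"].sum() / g["n_total"].sum(),
            include_groups=False,
        )
        slope_sign = 1.0 if frac.iloc[-1] >= frac.iloc[0] else -1.0
        return LogisticDoseFit(
            genotype=gval,
            hours=hval,
            beta0=-slope_sign * _BETA_BOUND,
            beta1=slope_sign * _BETA_BOUND,
            se_beta0=math.nan,
            se_beta1=math.nan,
            deviance=math.nan,
            converged=False,
            separated=True,
        )


def development_crossover(
    fit_wt: LogisticDoseFit,
    fit_mut: LogisticDoseFit,
    c_range: tuple[float, float] = (0.0, 5.0),
    tol: float = 1e-6,
) -> float | None:
    """Concentration where the fitted adult-fraction curves intersect.

    Root of p_wt(c) - p_mut(c) on ``c_range`` by bisection (Brent), None
    when there is no sign change on the interval.  For two logistics this
    equals (beta0_wt - beta0_mut) / (beta1_mut - beta1_wt) when that lies
    in range.  Identical fits have no unique crossover (warned, None).
    """
    if (fit_wt.beta0, fit_wt.beta1) == (fit_mut.beta0, fit_mut.beta1):
        warnings.warn("identical fits: no unique crossover", RuntimeWarning,
                      stacklevel=2)
        return None

    def diff(c: float) -> float:
        return float(fit_wt.predict(c) - fit_mut.predict(c))

    lo, hi = c_range
    flo, fhi = diff(lo), diff(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if flo * fhi > 0:
        return None
    return float(brentq(diff, lo, hi, xtol=tol))
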