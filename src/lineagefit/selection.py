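"""Dose-response analysis of normalized selection coefficients.

Lineage-level normalized selection coefficients S (mutant relative to the
wild-type mean, see :mod:`lineagefit.fitness`) collected across replicate
populations and drug concentrations c are summarised three ways:

* a quadratic ordinary-least-squares fit S = a c^2 + b c + c0 on the
  lineage-level points (each retained mutant lineage is one observation),
* per-concentration LS-mean-style summaries that respect the nesting of
  lineages within replicates: a replicate's mean is the mean of its lineage
  values, the concentration LS-mean is the unweighted mean of replicate
  means, and the 95% CI uses the t distribution on the between-replicate
  standard error (an explicit two-stage stand-in for a mixed-model
  emmeans analysis; equivalent for balanced designs),
* advisory outlier-replicate flags by a robust rule: a replicate whose mean
  is more than k MAD-based robust SDs from the median of the other
  replicates at the same concentration is flagged (the default k = 3).
  Downstream fits accept an explicit include/exclude list, so expert
  judgment can override the rule.

The neutrality crossover — the concentration where the fitted S crosses
zero and the advantage switches between genotypes — comes from the
closed-form roots of the quadratic, with a linear LS-mean interpolation
offered as an alternative reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .fitness import FitnessEstimateSet
from .patterns import GenotypeClass

__all__ = [
    "LineagePoint",
    "DoseResponseFit",
    "ConcentrationSummary",
    "points_from_estimates",
    "fit_quadratic",
    "concentration_summaries",
    "flag_outlier_replicates",
    "neutrality_crossover",
    "interpolate_neutrality",
]

POINT_COLUMNS = ["concentration", "s_norm", "replicate_id", "lineage"]


@dataclass(frozen=True)
class LineagePoint:
    """One lineage's normalized selection coefficient at one concentration."""

    concentration: float
    s_norm: float
    replicate_id: str
    lineage: str

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not np.isfinite(self.s_norm):
            raise ValueError("s_norm must be finite")


def _as_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        missing = set(POINT_COLUMNS) - set(points.columns)
        if missing:
            raise ValueError(f"points frame missing columns {sorted(missing)}")
        return points
    return pd.DataFrame([vars(p) for p in points], columns=POINT_COLUMNS)


def points_from_estimates(
    estimates: Iterable[FitnessEstimateSet],
    cls: GenotypeClass = GenotypeClass.MUTANT,
) -> pd.DataFrame:
    """Collect included lineages of one class into a lineage-point frame."""
    rows = []
    for est in estimates:
        sub = est.included_class(cls)
        for bc, r in sub.iterrows():
            rows.append(
                {
                    "concentration": est.concentration,
                    "s_norm": float(r["s_norm"]),
                    "replicate_id": est.replicate_id,
                    "lineage": bc,
                }
            )
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


@dataclass(frozen=True)
class DoseResponseFit:
    """Quadratic S = a c^2 + b c + c0 fitted by OLS on lineage points."""

    a: float
    b: float
    c0: float
    r2: float
    adj_r2: float
    f_stat: float
    df1: int
    df2: int
    n: int
    excluded_replicates: tuple[tuple[float, str], ...] = ()

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.a * c**2 + self.b * c + self.c0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("a", "b", "c0", "r2", "adj_r2", "f_stat", "df1", "df2", "n")}
        d["excluded_replicates"] = [list(t) for t in self.excluded_replicates]
        return d


def _apply_exclusions(
    df: pd.DataFrame,
    exclude: Iterable[tuple[float, str]] | None,
) -> tuple[pd.DataFrame, tuple[tuple[float, str], ...]]:
    if not exclude:
        return df, ()
    excl = {(float(c), str(r)) for c, r in exclude}
    mask = [
        (float(c), str(r)) not in excl
        for c, r in zip(df["concentration"], df["replicate_id"])
    ]
    return df[mask], tuple(sorted(excl))


def fit_quadratic(
    points,
    exclude_replicates: Iterable[tuple[float, str]] | None = None,
) -> DoseResponseFit:
    """OLS fit of the quadratic dose-response on lineage-level points.

    ``points`` is a frame with columns concentration, s_norm, replicate_id,
    lineage, or a sequence of :class:`LineagePoint`.  ``exclude_replicates``
    lists (concentration, replicate_id) pairs — typically flagged outliers —
    to drop before fitting.  Requires >= 4 points at >= 3 distinct
    concentrations (the design matrix is rank-deficient otherwise).
    """
    df = _as_frame(points)
    df, excl = _apply_exclusions(df, exclude_replicates)
    n = len(df)
    c = df["concentration"].to_numpy(dtype=float)
    y = df["s_norm"].to_numpy(dtype=float)
    if n < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations (design rank-deficient)")
    X = np.column_stack([np.ones_like(c), c, c**2])
    res = sm.OLS(y, X).fit()
    c0, b, a = res.params
    return DoseResponseFit(
        a=float(a),
        b=float(b),
        c0=float(c0),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df1=int(res.df_model),
        df2=int(res.df_resid),
        n=n,
        excluded_replicates=excl,
    )


@dataclass(frozen=True)
class ConcentrationSummary:
    """LS-mean-style summary of one concentration (outliers excluded), with
    the outlier-included variant alongside (mirroring black vs gray CI bars)."""

    concentration: float
    ls_mean: float
    ci_low: float
    ci_high: float
    replicate_means: tuple[float, ...]
    n_replicates: int
    ls_mean_all: float = np.nan
    ci_low_all: float = np.nan
    ci_high_all: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low):
            assert self.ci_low <= self.ls_mean <= self.ci_high


def _two_stage(df: pd.DataFrame) -> tuple[float, float, float, tuple[float, ...]]:
    rep_means = df.groupby("replicate_id")["s_norm"].mean()
    m = float(rep_means.mean())
    k = len(rep_means)
    if k < 2:
        return m, np.nan, np.nan, tuple(rep_means)
    se = float(rep_means.std(ddof=1)) / np.sqrt(k)
    tcrit = stats.t.ppf(0.975, df=k - 1)
    return m, m - tcrit * se, m + tcrit * se, tuple(rep_means)


def concentration_summaries(
    points,
    outlier_flags: Iterable[tuple[float, str]] | None = None,
) -> list[ConcentrationSummary]:
    """Two-stage LS-means with 95% t CIs per concentration.

    Computed twice: excluding the flagged (concentration, replicate) pairs
    and including everything; both variants are carried on each summary.
    With a single replicate the mean is reported and the CI is NaN.
    """
    df = _as_frame(points)
    flagged = {(float(c), str(r)) for c, r in (outlier_flags or [])}
    out: list[ConcentrationSummary] = []
    for c, grp in df.groupby("concentration", sort=True):
        keep = grp[
            [(float(c), str(r)) not in flagged for r in grp["replicate_id"]]
        ]
        if keep.empty:  # every replicate flagged: fall back to all
            keep = grp
        m, lo, hi, rmeans = _two_stage(keep)
        m_all, lo_all, hi_all, _ = _two_stage(grp)
        out.append(
            ConcentrationSummary(
                concentration=float(c),
                ls_mean=m,
                ci_low=lo,
                ci_high=hi,
                replicate_means=rmeans,
                n_replicates=len(rmeans),
                ls_mean_all=m_all,
                ci_low_all=lo_all,
                ci_high_all=hi_all,
            )
        )
    return out


def flag_outlier_replicates(points, k: float = 3.0) -> list[tuple[float, str]]:
    """Advisory outlier flags per (concentration, replicate).

    A replicate is flagged when its mean lies more than ``k`` robust SDs
    (1.4826 x median absolute deviation of the *other* replicates' means)
    from the median of the others.  Requires >= 3 replicates at the
    concentration; with fewer, no flags are possible.  When the other
    replicates are exactly equal (zero MAD) any discernible deviation flags.
    """
    df = _as_frame(points)
    flags: list[tuple[float, str]] = []
    for c, grp in df.groupby("concentration", sort=True):
        rep_means = grp.groupby("replicate_id")["s_norm"].mean()
        if len(rep_means) < 3:
            continue
        for rid, m in rep_means.items():
            others = rep_means.drop(rid).to_numpy()
            med = float(np.median(others))
            mad = float(np.median(np.abs(others - med))) * 1.4826
            dev = abs(m - med)
            if mad > 0:
                if dev > k * mad:
                    flags.append((float(c), str(rid)))
            elif dev > 1e-9:
                flags.append((float(c), str(rid)))
    return flags


def neutrality_crossover(
    fit: DoseResponseFit, c_range: tuple[float, float] = (0.0, 5.0)
) -> list[float]:
    """Concentrations in ``c_range`` where the fitted S crosses zero.

    Closed-form roots of a c^2 + b c + c0; the linear case (a = 0) is
    handled directly; a = b = 0 admits no crossover and is an error.
    """
    lo, hi = c_range
    a, b, c0 = fit.a, fit.b, fit.c0
    if a == 0 and b == 0:
        raise ValueError("degenerate fit (a = b = 0): no crossover definable")
    if a == 0:
        roots = [-c0 / b]
    else:
        disc = b * b - 4 * a * c0
        if disc < 0:
            return []
        sq = np.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    return sorted(r for r in roots if lo <= r <= hi)


def interpolate_neutrality(
    summaries: Sequence[ConcentrationSummary],
) -> float | None:
    """Linear interpolation of LS-means to the first sign change; None if
    the LS-means never cross zero."""
    ss = sorted(summaries, key=lambda s: s.concentration)
    for s0, s1 in zip(ss, ss[1:]):
        if s0.ls_mean == 0:
            return s0.concentration
        if s0.ls_mean * s1.ls_mean < 0:
            f = -s0.ls_mean / (s1.ls_mean - s0.ls_mean)
            return s0.concentration + f * (s1.concentration - s0.concentration)
    return None


def write_fit_report(
    path: str | Path,
    fit: DoseResponseFit,
    summaries: Sequence[ConcentrationSummary],
    flags: Sequence[tuple[float, str]],
    crossovers: Sequence[float],
) -> None:
    payload = {
        "fit": fit.to_dict(),
        "neutrality_crossovers_nM": list(crossovers),
        "outlier_flags": [list(t) for t in flags],
        "summaries": [
            {
                "concentration": s.concentration,
                "ls_mean": s.ls_mean,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_replicates": s.n_replicates,
                "ls_mean_all": s.ls_mean_all,
                "ci_low_all": s.ci_low_all,
                "ci_high_all": s.ci_high_all,
            }
            for s in summaries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))
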