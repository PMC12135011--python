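"""Per-lineage selection-coefficient inference from count trajectories.

Given read counts r_i(k) for lineages i at timepoints k (parental P0 and
transfers T1..TK) this module estimates each lineage's Malthusian
per-generation selection coefficient s_i by maximising a Poisson read-count
likelihood under the serial-transfer propagation model

    xhat_i(k) = x_i(k-1) * exp(g * s_i) / sum_j x_j(k-1) * exp(g * shat_j)

anchored on the previous *observed* frequency vector x(k-1) (one-step
conditional propagation).  The per-transfer expected read count is
R(k) * xhat_i(k) and the log-likelihood for lineage i is

    L_i(s_i) = sum_k  r_i(k) * ln(R(k) * xhat_i(k)) - R(k) * xhat_i(k)

maximised over a bounded interval by 1-D optimisation with all other
lineages' estimates held fixed, sweeping lineages until the largest update
falls below tolerance.  Only differences of selection coefficients are
identified by frequency data (the likelihood is invariant to a common
shift), which is why estimates are reported relative to the wild-type class
mean: :func:`normalize_to_wildtype` subtracts the mean estimate over
included wild-type lineages, making wild type the zero reference.

Quality control mirrors standard practice for pooled barcode assays:
lineages whose parental count is at or below a floor (default 10 reads) are
too noisy to regress, and lineages with zero reads at the final transfer
did not survive the experiment (the Wrightian fitness w = e^s - 1 = -1
extinction case); both are excluded with logged reasons before estimation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .countio import LineageCountTable
from .patterns import GenotypeClass

__all__ = [
    "InferenceOptions",
    "FitnessEstimateSet",
    "apply_qc_filters",
    "estimate_fitness",
    "normalize_to_wildtype",
    "fit_replicate",
    "QCError",
]

EXCLUSION_REASONS = (
    "low_parental_count",
    "not_surviving",
    "pattern_nonconforming",
    "none",
)


class QCError(ValueError):
    """Raised when quality filtering leaves a replicate unusable."""


@dataclass(frozen=True)
class InferenceOptions:
    """Tunable knobs of the likelihood optimisation.

    ``g`` is generations per transfer (one 5-day transfer is about one
    generation in this design).  ``s_bounds`` constrain the per-generation
    Malthusian coefficient; estimates pinned at a bound are flagged.
    ``epsilon_scale`` sets the pseudo-frequency eps = epsilon_scale / R(k)
    used only when initialising from log-frequency slopes.
    """

    g: float = 1.0
    s_bounds: tuple[float, float] = (-5.0, 5.0)
    tol: float = 1e-6
    max_iter: int = 100
    epsilon_scale: float = 0.5
    min_parental_count: int = 10
    low_count_scope: str = "parental"  # parental | any | total

    def __post_init__(self) -> None:
        lo, hi = self.s_bounds
        if not lo < 0 < hi:
            raise ValueError("s_bounds must straddle 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.low_count_scope not in ("parental", "any", "total"):
            raise ValueError("low_count_scope must be parental, any or total")


@dataclass
class FitnessEstimateSet:
    """Estimates and diagnostics for one replicate population.

    ``frame`` has one row per lineage of the input table with columns
    ``class``, ``s`` (per-generation Malthusian estimate), ``s_norm``
    (relative to the wild-type class mean; NaN until normalised), ``logL``,
    ``included``, ``exclusion_reason`` and ``at_bound``.  ``mean_fitness``
    is the read-frequency-weighted population mean sbar(k) under the final
    estimates.
    """

    frame: pd.DataFrame
    mean_fitness: pd.Series
    replicate_id: str
    concentration: float
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        wt = self.included_class(GenotypeClass.WILD_TYPE)
        if len(wt) and self.frame["s_norm"].notna().any():
            assert abs(float(wt["s_norm"].mean())) < 1e-9

    def included_class(self, cls: GenotypeClass) -> pd.DataFrame:
        f = self.frame
        return f[(f["class"] == cls.value) & f["included"]]

    def wrightian(self) -> pd.Series:
        """Wrightian fitness w = e^s - 1 per lineage (reporting option)."""
        return np.expm1(self.frame["s"])

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "lineage", out.index)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# replicate_id={self.replicate_id}\t"
                f"concentration_nM={self.concentration}\n"
            )
            out.to_csv(fh, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "replicate_id": self.replicate_id,
            "concentration_nM": self.concentration,
            "mean_fitness": {k: float(v) for k, v in self.mean_fitness.items()},
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_included": int(self.frame["included"].sum()),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_estimates_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-lineage estimates TSV written by :meth:`FitnessEstimateSet.write_tsv`,
    returning the frame with replicate metadata attached as columns."""
    path = Path(path)
    replicate_id, concentration = "rep1", 0.0
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first[1:].strip().split("\t"):
            if tok.startswith("replicate_id="):
                replicate_id = tok.split("=", 1)[1]
            elif tok.startswith("concentration_nM="):
                concentration = float(tok.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    df["replicate_id"] = replicate_id
    df["concentration"] = concentration
    return df


def apply_qc_filters(
    table: LineageCountTable, opts: InferenceOptions | None = None
) -> tuple[LineageCountTable, dict[str, str]]:
    """Drop low-information lineages; both genotype classes filtered alike.

    Excludes lineages whose parental (P0) count is <= ``min_parental_count``
    (reason ``low_parental_count``; scope configurable to any/total counts)
    and lineages with zero reads at the final timepoint (reason
    ``not_surviving``).  Raises :class:`QCError` if either genotype class
    present in the input loses all its lineages.
    """
    if opts is None:
        opts = InferenceOptions()
    counts = table.counts
    excluded: dict[str, str] = {}
    floor = opts.min_parental_count
    for bc in counts.index:
        row = counts.loc[bc]
        if opts.low_count_scope == "parental":
            low = row.iloc[0] <= floor
        elif opts.low_count_scope == "any":
            low = bool((row <= floor).any())
        else:
            low = row.sum() <= floor
        if low:
            excluded[bc] = "low_parental_count"
        elif row.iloc[-1] == 0:
            excluded[bc] = "not_surviving"
    keep = [bc for bc in counts.index if bc not in excluded]
    for cls in (GenotypeClass.WILD_TYPE, GenotypeClass.MUTANT):
        had = [bc for bc in counts.index if table.classes[bc] == cls]
        left = [bc for bc in keep if table.classes[bc] == cls]
        if had and not left:
            raise QCError(
                f"replicate {table.replicate_id!r}: all {cls.value} lineages "
                "removed by quality filters; replicate unusable"
            )
    return table.subset(keep), excluded


def _init_slopes(
    freq: np.ndarray, totals: np.ndarray, counts: np.ndarray, g: float,
    eps_scale: float,
) -> np.ndarray:
    """Least-squares slope of ln(x + eps) over generations, centred so the
    read-weighted mean is zero."""
    eps = eps_scale / totals
    logx = np.log(freq + eps[None, :])
    t = g * np.arange(freq.shape[1], dtype=float)
    tc = t - t.mean()
    slopes = (logx * tc[None, :]).sum(axis=1) / (tc**2).sum()
    w = counts.sum(axis=1).astype(float)
    w = w / w.sum()
    return slopes - float(np.dot(w, slopes))


def _lineage_negloglik(
    s: float,
    i: int,
    freq: np.ndarray,
    counts: np.ndarray,
    totals: np.ndarray,
    denom: np.ndarray,
    g: float,
) -> float:
    """-L_i(s) over transfers.

    The normalising denominator (the population mean-fitness term) is held
    fixed at the current estimates, the lineage's own contribution included:
    this makes the sweep's fixed point a coordinate-wise stationary point of
    the joint likelihood, whereas letting the own term track s would weight
    transfers by (1 - xhat_i) and bias large-frequency lineages.
    """
    x_prev = freq[i, :-1]
    r = counts[i, 1:]
    mu = totals[1:] * x_prev * np.exp(g * s) / denom
    mask = x_prev > 0
    mu = mu[mask]
    r = r[mask]
    if mu.size == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        ll = np.where(r > 0, r * np.log(mu), 0.0) - mu
    return -float(ll.sum())


def estimate_fitness(
    table: LineageCountTable, opts: InferenceOptions | None = None
) -> FitnessEstimateSet:
    """Maximum-likelihood per-lineage selection coefficients.

    Implements the iterative scheme described in the module docstring:
    log-slope initialisation, then coordinate sweeps of bounded 1-D Poisson
    likelihood maximisation until max |delta s| < ``opts.tol`` or
    ``opts.max_iter`` sweeps.  Non-convergence and bound-pinned estimates
    are flagged, not fatal.
    """
    if opts is None:
        opts = InferenceOptions()
    if table.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if len(table.lineages) < 2:
        raise ValueError("need at least 2 lineages")

    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("timepoint with zero total reads")
    freq = counts / totals[None, :]
    n = counts.shape[0]
    g = opts.g
    lo, hi = opts.s_bounds
    xatol = min(1e-8, opts.tol / 10)

    s = np.clip(
        _init_slopes(freq, totals, counts, g, opts.epsilon_scale), lo, hi
    )
    # The likelihood depends on s only through differences (a common shift
    # cancels in xhat), so the gauge is fixed by re-centring the
    # read-weighted mean to zero after every sweep, matching initialisation.
    weights = counts.sum(axis=1) / counts.sum()
    converged = False
    it = 0
    ew = np.exp(g * s)
    denom_full = freq[:, :-1].T @ ew  # shape (K,)
    for it in range(1, opts.max_iter + 1):
        # Gauss-Seidel sweep: each lineage sees the others' newest estimates
        s_prev = s.copy()
        for i in range(n):
            res = minimize_scalar(
                _lineage_negloglik,
                bounds=(lo, hi),
                method="bounded",
                args=(i, freq, counts, totals, denom_full, g),
                options={"xatol": xatol},
            )
            denom_full = denom_full - freq[i, :-1] * ew[i]
            s[i] = res.x
            ew[i] = np.exp(g * s[i])
            denom_full = denom_full + freq[i, :-1] * ew[i]
        if not ((s <= lo + 10 * xatol).any() or (s >= hi - 10 * xatol).any()):
            shift = float(np.dot(weights, s))
            s -= shift
            ew = np.exp(g * s)
            denom_full = freq[:, :-1].T @ ew
        delta = float(np.max(np.abs(s - s_prev)))
        if delta < opts.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fitness estimation did not converge in {opts.max_iter} sweeps "
            f"for replicate {table.replicate_id!r}",
            RuntimeWarning,
            stacklevel=2,
        )

    # final per-lineage log-likelihoods under the converged estimates
    ew = np.exp(g * s)
    denom_full = freq[:, :-1].T @ ew
    logL = np.array(
        [
            -_lineage_negloglik(s[i], i, freq, counts, totals, denom_full, g)
            for i in range(n)
        ]
    )
    at_bound = (np.abs(s - lo) < 10 * xatol) | (np.abs(s - hi) < 10 * xatol)
    if at_bound.any():
        warnings.warn(
            f"{int(at_bound.sum())} estimate(s) pinned at an s bound",
            RuntimeWarning,
            stacklevel=2,
        )

    mean_fitness = pd.Series(freq.T @ s, index=table.timepoints, name="mean_fitness")
    frame = pd.DataFrame(
        {
            "class": [table.classes[bc].value for bc in table.lineages],
            "s": s,
            "s_norm": np.nan,
            "logL": logL,
            "included": True,
            "exclusion_reason": "none",
            "at_bound": at_bound,
        },
        index=pd.Index(table.lineages, name="barcode"),
    )
    return FitnessEstimateSet(
        frame=frame,
        mean_fitness=mean_fitness,
        replicate_id=table.replicate_id,
        concentration=table.concentration,
        converged=converged,
        n_iter=it,
    )


def normalize_to_wildtype(est: FitnessEstimateSet) -> FitnessEstimateSet:
    """Express every estimate relative to the wild-type class mean.

    Sets ``s_norm = s - mean(s over included wild-type lineages)`` for all
    lineages; the wild-type normalised mean is exactly zero by construction.
    Raises :class:`QCError` when no included wild-type lineage exists.
    """
    wt = est.included_class(GenotypeClass.WILD_TYPE)
    if wt.empty:
        raise QCError("no included wild-type lineage to normalise against")
    shift = float(wt["s"].mean())
    frame = est.frame.copy()
    frame["s_norm"] = np.where(frame["included"], frame["s"] - shift, np.nan)
    return FitnessEstimateSet(
        frame=frame,
        mean_fitness=est.mean_fitness,
        replicate_id=est.replicate_id,
        concentration=est.concentration,
        converged=est.converged,
        n_iter=est.n_iter,
    )


def fit_replicate(
    table: LineageCountTable, opts: InferenceOptions | None = None
) -> FitnessEstimateSet:
    """QC-filter, estimate and wild-type-normalise one replicate.

    The returned frame covers every lineage of the input table exactly once;
    excluded lineages carry ``included=False`` with their exclusion reason
    and NaN estimates.
    """
    filtered, excluded = apply_qc_filters(table, opts)
    est = normalize_to_wildtype(estimate_fitness(filtered, opts))
    if excluded:
        extra = pd.DataFrame(
            {
                "class": [table.classes[bc].value for bc in excluded],
                "s": np.nan,
                "s_norm": np.nan,
                "logL": np.nan,
                "included": False,
                "exclusion_reason": list(excluded.values()),
                "at_bound": False,
            },
            index=pd.Index(list(excluded), name="barcode"),
        )
        frame = pd.concat([est.frame, extra]).loc[table.lineages]
        est = FitnessEstimateSet(
            frame=frame,
            mean_fitness=est.mean_fitness,
            replicate_id=est.replicate_id,
            concentration=est.concentration,
            converged=est.converged,
            n_iter=est.n_iter,
        )
    return est
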