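"""Synthetic barcoded serial-transfer experiments with known ground truth.

The generator emulates a pooled fitness-competition design in *C. elegans*:
barcoded wild-type and GluCl triple-mutant lineages are mixed at a parental
generation (P0), then serially transferred five times (T1..T5), each 5-day
transfer corresponding to roughly one generation and passing ~10% of the
census through a bottleneck.  Barcode read counts are observed at every
timepoint at a configurable sequencing depth.

Model per transfer, on the frequency vector x over lineages with Malthusian
per-generation selection coefficients s and g generations per transfer:

1. selection:   x_i <- x_i * exp(g * s_i) / sum_j x_j * exp(g * s_j)
2. drift (stochastic mode): a single multinomial founder draw of
   floor(bottleneck_fraction * census_N) individuals, then renormalise
3. observation: read counts by multinomial draw of ``read_depth`` reads on x
   (stochastic) or deterministic rounding (deterministic mode)

Growth back to census between transfers is not modelled: only frequencies
enter the observation model, and within-transfer growth is collapsed into
the exponential selection update — exactly the propagation assumed by the
fitness-inference model, which makes the generator a self-consistent oracle.

Default experiment-level parameters mirror the study design: ivermectin
0-5 nM in 1 nM steps, three replicate populations per concentration plus two
extra at 3 nM, starting mixes of ~10% wild type at 0 nM, 30% at 1 nM and
~50% at 2-5 nM, census 10^6, 10% bottleneck, and a quadratic mutant
dose-response S(c) = 0.053 c^2 + 0.18 c - 0.5 with the wild type pinned at
s = 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .countio import LineageCountTable
from .patterns import (
    DegeneratePattern,
    GenotypeClass,
    MUTANT_PATTERN,
    WILDTYPE_PATTERN,
)

__all__ = [
    "SimDesign",
    "SimResult",
    "DevAssayRecord",
    "simulate_replicate",
    "simulate_experiment",
    "simulate_dev_assay",
    "quadratic_dose_response",
    "wildtype_adult_response",
    "mutant_adult_response",
    "default_start_freq_wt",
    "make_fastq_records",
    "DEFAULT_DOSE_RESPONSE_COEF",
    "DEFAULT_LINEAGE_SD",
    "DEFAULT_REPLICATE_SD",
]

#: (a, b, c0) of the mutant dose-response S = a c^2 + b c + c0 used as the
#: generator's default truth.
DEFAULT_DOSE_RESPONSE_COEF = (0.053, 0.18, -0.5)

#: Default sd of per-lineage deviations of true s around the class mean.
DEFAULT_LINEAGE_SD = 0.15

#: Default sd of whole-replicate shifts of the mutant class mean.
DEFAULT_REPLICATE_SD = 0.01


def quadratic_dose_response(c: float, coef=DEFAULT_DOSE_RESPONSE_COEF) -> float:
    """Mutant selection coefficient at ivermectin concentration ``c`` (nM)."""
    a, b, c0 = coef
    return a * c * c + b * c + c0


def default_start_freq_wt(concentration: float) -> float:
    """Parental wild-type fraction by concentration: 10% at 0 nM, 30% at
    1 nM, 50% at 2 nM and above (the unequal mixes give more room for the
    class expected to win at low drug)."""
    if concentration < 0.5:
        return 0.10
    if concentration < 1.5:
        return 0.30
    return 0.50


class PopulationExtinctError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimDesign:
    """Design of one simulated replicate population."""

    n_wt: int = 48
    n_mut: int = 48
    start_freq_wt: float = 0.5
    s_wt: float | Sequence[float] = 0.0
    s_mut: float | Sequence[float] = 0.0
    g: float = 1.0
    n_transfers: int = 5
    census_N: int = 1_000_000
    bottleneck_fraction: float = 0.10
    read_depth: int = 1_000_000
    seed: int | None = 0
    mode: str = "stochastic"

    def __post_init__(self) -> None:
        if not 0 < self.bottleneck_fraction <= 1:
            raise ValueError("bottleneck_fraction must be in (0, 1]")
        if not 0 <= self.start_freq_wt <= 1:
            raise ValueError("start_freq_wt must be in [0, 1]")
        if self.census_N < 1 or self.read_depth < 1:
            raise ValueError("census_N and read_depth must be >= 1")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")
        if min(self.n_wt, self.n_mut) < 0 or self.n_wt + self.n_mut < 1:
            raise ValueError("need at least one lineage")

    def s_vector(self) -> np.ndarray:
        """Per-lineage s, wild-type lineages first."""
        s_wt = np.broadcast_to(np.asarray(self.s_wt, float), (self.n_wt,))
        s_mut = np.broadcast_to(np.asarray(self.s_mut, float), (self.n_mut,))
        return np.concatenate([s_wt, s_mut])


@dataclass
class SimResult:
    """A simulated replicate: count table, truth manifest, realized censuses."""

    table: LineageCountTable
    truth: dict[str, float]
    founders_per_transfer: list[int]
    design: SimDesign

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"barcode": bc, "class": self.table.classes[bc].value, "s_true": s}
            for bc, s in self.truth.items()
        ]
        return pd.DataFrame(rows).set_index("barcode")


def _random_barcode(pattern: DegeneratePattern, rng: np.random.Generator) -> str:
    bases = "ACGT"
    return "".join(
        sym if sym != "N" else bases[rng.integers(4)] for sym in pattern.slots
    )


def _unique_barcodes(
    pattern: DegeneratePattern, n: int, rng: np.random.Generator
) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = _random_barcode(pattern, rng)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _observe(
    x: np.ndarray, depth: int, rng: np.random.Generator, stochastic: bool
) -> np.ndarray:
    if stochastic:
        return rng.multinomial(depth, x)
    return np.round(depth * x).astype(np.int64)


def simulate_replicate(
    design: SimDesign,
    *,
    wt_pattern: DegeneratePattern = WILDTYPE_PATTERN,
    mut_pattern: DegeneratePattern = MUTANT_PATTERN,
    replicate_id: str = "rep1",
    concentration: float = 0.0,
) -> SimResult:
    """Simulate one replicate population for ``design.n_transfers`` transfers.

    Identical seeds give identical output; deterministic mode ignores the
    seed entirely for the dynamics (it is still used to draw barcode
    sequences so tables are reproducible).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_wt + design.n_mut
    barcodes = _unique_barcodes(wt_pattern, design.n_wt, rng) + _unique_barcodes(
        mut_pattern, design.n_mut, rng
    )
    classes = dict(
        zip(
            barcodes,
            [GenotypeClass.WILD_TYPE] * design.n_wt
            + [GenotypeClass.MUTANT] * design.n_mut,
        )
    )
    s = design.s_vector()
    stoch = design.mode == "stochastic"

    x = np.empty(n)
    if design.n_wt:
        x[: design.n_wt] = design.start_freq_wt / design.n_wt
    if design.n_mut:
        x[design.n_wt :] = (1.0 - design.start_freq_wt) / design.n_mut
    x /= x.sum()

    growth = np.exp(design.g * s)
    n_founders = int(math.floor(design.bottleneck_fraction * design.census_N))
    columns = ["P0"] + [f"T{k}" for k in range(1, design.n_transfers + 1)]
    counts = np.empty((n, design.n_transfers + 1), dtype=np.int64)
    counts[:, 0] = _observe(x, design.read_depth, rng, stoch)
    founders_per_transfer: list[int] = []
    for k in range(1, design.n_transfers + 1):
        w = x * growth
        tot = w.sum()
        if tot <= 0 or not np.isfinite(tot):
            raise PopulationExtinctError(f"population extinct at transfer {k}")
        x = w / tot
        if stoch:
            draw = rng.multinomial(n_founders, x)
            if draw.sum() == 0:
                raise PopulationExtinctError(f"population extinct at transfer {k}")
            x = draw / draw.sum()
            founders_per_transfer.append(n_founders)
        else:
            founders_per_transfer.append(design.census_N)
        counts[:, k] = _observe(x, design.read_depth, rng, stoch)

    table = LineageCountTable(
        counts=pd.DataFrame(
            counts, index=pd.Index(barcodes, name="barcode"), columns=columns
        ),
        classes=classes,
        replicate_id=replicate_id,
        concentration=concentration,
    )
    truth = dict(zip(barcodes, s.tolist()))
    return SimResult(
        table=table, truth=truth, founders_per_transfer=founders_per_transfer,
        design=design,
    )


def simulate_experiment(
    concentrations: Sequence[float] = (0, 1, 2, 3, 4, 5),
    dose_response: Callable[[float], float] = quadratic_dose_response,
    replicates: int | Mapping[float, int] | None = None,
    design: SimDesign | None = None,
    *,
    lineage_sd: float = DEFAULT_LINEAGE_SD,
    replicate_sd: float = DEFAULT_REPLICATE_SD,
    outlier_shifts: Mapping[tuple[float, int], float] | None = None,
    start_freq_wt: Callable[[float], float] = default_start_freq_wt,
    seed: int | None = 0,
) -> list[SimResult]:
    """Simulate a full concentration-gradient competition experiment.

    One :class:`SimResult` per (concentration, replicate).  Wild-type
    lineages have s = 0 exactly; each mutant lineage draws
    ``s = dose_response(c) + replicate_shift + lineage_deviation`` with the
    two noise scales given by ``replicate_sd`` and ``lineage_sd``.

    ``replicates`` defaults to the study layout: 3 per concentration with 2
    extra at 3 nM.  ``outlier_shifts`` maps ``(concentration, replicate
    index)`` to an additive shift applied to every mutant lineage of that
    replicate, emulating a whole-replicate protocol failure (for example an
    accidental misapplication of the drug).
    """
    if design is None:
        design = SimDesign()
    if replicates is None:
        replicates = {c: (5 if c == 3 else 3) for c in concentrations}
    if isinstance(replicates, int):
        replicates = {c: replicates for c in concentrations}
    outlier_shifts = dict(outlier_shifts or {})

    ss = np.random.SeedSequence(seed)
    results: list[SimResult] = []
    for c in concentrations:
        s_class = dose_response(c)
        for r in range(replicates[c]):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            s_mut = (
                s_class
                + rng.normal(0.0, replicate_sd)
                + rng.normal(0.0, lineage_sd, size=design.n_mut)
                + outlier_shifts.get((c, r), 0.0)
            )
            d = replace(
                design,
                s_wt=0.0,
                s_mut=tuple(s_mut.tolist()),
                start_freq_wt=start_freq_wt(c),
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            results.append(
                simulate_replicate(
                    d, replicate_id=f"c{c}_r{r}", concentration=float(c)
                )
            )
    return results


# --- developmental assay -------------------------------------------------

@dataclass(frozen=True)
class DevAssayRecord:
    """One scored drop of a developmental assay: adults / total animals."""

    genotype: GenotypeClass
    concentration: float
    hours: int
    drop_id: int
    n_total: int
    n_adult: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or not 0 <= self.n_adult <= self.n_total:
            raise ValueError("need 0 <= n_adult <= n_total")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


# Wild-type adult-fraction response at 72 h: logistic through the observed
# endpoint fractions 63.1% at 0 nM and 3.4% at 5 nM.
_WT_B0 = math.log(0.631 / 0.369)
_WT_B1 = (math.log(0.034 / 0.966) - _WT_B0) / 5.0


def wildtype_adult_response(concentration: float, hours: int = 72) -> float:
    """Probability a synchronized wild-type animal is adult at 72/96 h."""
    if hours >= 96:
        # near-complete development by 96 h irrespective of drug for survivors
        return _logistic(2.5 + 0.6 * _WT_B1 * concentration)
    return _logistic(_WT_B0 + _WT_B1 * concentration)


#: Mutant 72 h adult fraction: flat in concentration (resistant animals
#: develop at the same, slightly delayed, rate at every dose).  The flat
#: level equals the wild-type curve at 2.5 nM, the developmental crossover.
_MUT_P72 = _logistic(_WT_B0 + 2.5 * _WT_B1)


def mutant_adult_response(concentration: float, hours: int = 72) -> float:
    if hours >= 96:
        return _logistic(2.5)
    return _MUT_P72


def simulate_dev_assay(
    p_adult: Callable[[GenotypeClass, float], float],
    *,
    concentrations: Sequence[float] = (0, 1, 2, 3, 4, 5),
    genotypes: Sequence[GenotypeClass] = (
        GenotypeClass.WILD_TYPE,
        GenotypeClass.MUTANT,
    ),
    hours: int = 72,
    n_per_drop: int = 100,
    n_drops: int = 100,
    seed: int | None = 0,
) -> list[DevAssayRecord]:
    """Simulate drop counts of a developmental assay.

    Each drop's total is Poisson around ``n_per_drop`` (at least 1) and its
    adult count binomial with probability ``p_adult(genotype, c)``.
    """
    rng = np.random.default_rng(seed)
    records: list[DevAssayRecord] = []
    for gt in genotypes:
        for c in concentrations:
            p = float(p_adult(gt, c))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_adult({gt}, {c}) = {p} outside [0, 1]")
            for d in range(n_drops):
                n_total = max(1, int(rng.poisson(n_per_drop)))
                n_adult = int(rng.binomial(n_total, p))
                records.append(
                    DevAssayRecord(
                        genotype=gt,
                        concentration=float(c),
                        hours=hours,
                        drop_id=d,
                        n_total=n_total,
                        n_adult=n_adult,
                    )
                )
    return records


def default_dev_response(genotype: GenotypeClass, concentration: float,
                         hours: int = 72) -> float:
    """Adult-fraction truth used by the default developmental simulation."""
    if genotype == GenotypeClass.WILD_TYPE:
        return wildtype_adult_response(concentration, hours)
    return mutant_adult_response(concentration, hours)


# --- synthetic reads ------------------------------------------------------

def make_fastq_records(
    barcode_counts: Mapping[str, int],
    flank5: str,
    flank3: str,
    *,
    pad5: str = "ACGT",
    pad3: str = "TGCA",
    shuffle_seed: int | None = None,
) -> list[str]:
    """Render barcode counts as FASTQ text records (flank5+barcode+flank3).

    A small deterministic fixture generator for demultiplexing tests and
    examples; returns a list of 4-line FASTQ record strings.
    """
    seqs = []
    for bc, n in barcode_counts.items():
        seqs.extend([pad5 + flank5 + bc + flank3 + pad3] * n)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(seqs)
    return [
        f"@read{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs)
    ]
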