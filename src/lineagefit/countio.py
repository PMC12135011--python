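"""Reading reads and count tables; the lineage x timepoint count matrix.

The unit of analysis is a :class:`LineageCountTable`: read counts r_i(k) for
every barcoded lineage i at every serial-transfer timepoint k (parental P0,
then T1..TK) for one replicate population at one drug concentration.  Column
totals R(k) give observed frequencies x_i(k) = r_i(k) / R(k).

Barcodes are extracted from amplicon reads by locating fixed flanking
sequences (the priming regions either side of the barcode in the construct)
and taking the intervening subsequence; the flank sequences are experiment
configuration, never hard-coded.  Extracted barcodes that do not conform to
a class template are excluded from the table and tallied in a rejection log
so that total input counts are conserved.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .patterns import DegeneratePattern, GenotypeClass, classify_barcode

__all__ = [
    "BarcodeReadLayout",
    "LineageCountTable",
    "extract_barcodes",
    "build_count_table",
    "read_count_table",
    "write_count_table",
]


@dataclass(frozen=True)
class BarcodeReadLayout:
    """Where the barcode sits in a read: fixed 5' and 3' flanking sequences."""

    flank5: str
    flank3: str
    max_mismatches_flank: int = 0
    barcode_lengths: tuple[int, ...] = (15,)

    def __post_init__(self) -> None:
        for name, fl in (("flank5", self.flank5), ("flank3", self.flank3)):
            if not fl or not set(fl.upper()) <= set("ACGT"):
                raise ValueError(f"{name} must be non-empty over A/C/G/T")
        if self.max_mismatches_flank < 0:
            raise ValueError("max_mismatches_flank must be >= 0")


class MalformedFastqError(ValueError):
    pass


def _find_approx(haystack: str, needle: str, max_mm: int, start: int = 0) -> int:
    """Index of first occurrence of needle allowing <= max_mm mismatches; -1 if none."""
    if max_mm == 0:
        return haystack.find(needle, start)
    n = len(needle)
    for i in range(start, len(haystack) - n + 1):
        mm = 0
        for a, b in zip(haystack[i : i + n], needle):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(source) -> Iterator[str]:
    """Yield uppercase read sequences; wrap parse errors with the record index."""
    if isinstance(source, (str, Path)):
        handle = _open_maybe_gzip(source)
        close = True
    else:
        handle = source
        close = False
    try:
        it = SeqIO.parse(handle, "fastq")
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise MalformedFastqError(
                    f"malformed FASTQ record at index {idx}: {exc}"
                ) from exc
            yield str(rec.seq).upper()
            idx += 1
    finally:
        if close:
            handle.close()


def extract_barcodes(
    reads, layout: BarcodeReadLayout
) -> tuple[Counter, Counter]:
    """Extract barcode sequences from reads.

    Parameters
    ----------
    reads
        FASTQ path (plain or .gz), open text handle, or an iterable of
        sequence strings.
    layout
        Flank definition.  Flanks are located by exact substring match, or
        with up to ``max_mismatches_flank`` mismatches each when configured.

    Returns
    -------
    (barcodes, rejections)
        ``barcodes`` counts each extracted barcode string; ``rejections``
        counts reads discarded by cause (``flank5_not_found``,
        ``flank3_not_found``, ``bad_barcode_length``).
    """
    if isinstance(reads, (str, Path)) or hasattr(reads, "read"):
        seqs: Iterable[str] = _iter_fastq(reads)
    else:
        seqs = (s.upper() for s in reads)

    f5 = layout.flank5.upper()
    f3 = layout.flank3.upper()
    mm = layout.max_mismatches_flank
    lengths = set(layout.barcode_lengths)
    barcodes: Counter = Counter()
    rejections: Counter = Counter()
    for seq in seqs:
        i5 = _find_approx(seq, f5, mm)
        if i5 < 0:
            rejections["flank5_not_found"] += 1
            continue
        bc_start = i5 + len(f5)
        i3 = _find_approx(seq, f3, mm, start=bc_start)
        if i3 < 0:
            rejections["flank3_not_found"] += 1
            continue
        bc = seq[bc_start:i3]
        if len(bc) not in lengths:
            rejections["bad_barcode_length"] += 1
            continue
        barcodes[bc] += 1
    return barcodes, rejections


class EmptyTimepointError(ValueError):
    pass


@dataclass
class LineageCountTable:
    """Lineage x timepoint read counts for one replicate population.

    ``counts`` is a DataFrame indexed by barcode with one integer column per
    timepoint label (P0, T1, ... in temporal order); ``classes`` maps each
    barcode to its genotype class.
    """

    counts: pd.DataFrame
    classes: dict[str, GenotypeClass]
    replicate_id: str = "rep1"
    concentration: float = 0.0
    rejected: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 nM")
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.classes)
        if missing:
            raise ValueError(f"lineages without a class: {sorted(missing)[:5]}")

    @property
    def timepoints(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lineages(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Column totals R(k)."""
        return self.counts.to_numpy().sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        """Observed frequencies x_i(k) = r_i(k)/R(k); columns with R(k)=0 are NaN."""
        totals = self.totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts.to_numpy(dtype=float) / totals
        return pd.DataFrame(freq, index=self.counts.index, columns=self.counts.columns)

    def class_mask(self, cls: GenotypeClass) -> np.ndarray:
        return np.array([self.classes[b] == cls for b in self.counts.index])

    def subset(self, lineages: Sequence[str]) -> "LineageCountTable":
        return LineageCountTable(
            counts=self.counts.loc[list(lineages)].copy(),
            classes={b: self.classes[b] for b in lineages},
            replicate_id=self.replicate_id,
            concentration=self.concentration,
            rejected=Counter(self.rejected),
        )


def build_count_table(
    counts_per_timepoint: Mapping[str, Mapping[str, int]],
    patterns: list[DegeneratePattern] | None = None,
    *,
    replicate_id: str = "rep1",
    concentration: float = 0.0,
) -> LineageCountTable:
    """Assemble a count table from per-timepoint barcode multisets.

    Rows are the union of classifiable barcodes seen at any timepoint
    (missing cells zero-filled); unclassifiable barcodes are excluded and
    their counts accumulated in the rejection log, so that classified plus
    rejected counts equal the input counts at every timepoint.

    Raises :class:`EmptyTimepointError` for a timepoint with no reads at all.
    """
    tps = list(counts_per_timepoint)
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    classes: dict[str, GenotypeClass] = {}
    rejected: Counter = Counter()
    kept: dict[str, dict[str, int]] = {tp: {} for tp in tps}
    cache: dict[str, GenotypeClass] = {}
    for tp in tps:
        bag = counts_per_timepoint[tp]
        if sum(bag.values()) == 0:
            raise EmptyTimepointError(f"timepoint {tp!r} has no reads")
        for bc, n in bag.items():
            cls = cache.get(bc)
            if cls is None:
                cls = cache[bc] = classify_barcode(bc, patterns)
            if cls is GenotypeClass.UNCLASSIFIED:
                rejected[f"unclassified:{tp}"] += n
            else:
                kept[tp][bc] = kept[tp].get(bc, 0) + n
                classes[bc] = cls
    all_bcs = sorted(classes)
    if not all_bcs:
        raise ValueError("no classifiable barcodes in input")
    mat = pd.DataFrame(
        {tp: [kept[tp].get(bc, 0) for bc in all_bcs] for tp in tps},
        index=pd.Index(all_bcs, name="barcode"),
        dtype=np.int64,
    )
    return LineageCountTable(
        counts=mat,
        classes=classes,
        replicate_id=replicate_id,
        concentration=concentration,
        rejected=rejected,
    )


# TSV dialect: tab-separated, UTF-8, header "barcode  class  P0  T1 ... TK".
# Leading lines starting with '#' carry provenance and are ignored on read.

def write_count_table(
    table: LineageCountTable, path: str | Path, *, header_comment: str | None = None
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            f"# replicate_id={table.replicate_id}\t"
            f"concentration_nM={table.concentration}\n"
        )
        cols = "\t".join(table.timepoints)
        fh.write(f"barcode\tclass\t{cols}\n")
        for bc in table.lineages:
            row = "\t".join(str(int(v)) for v in table.counts.loc[bc])
            fh.write(f"{bc}\t{table.classes[bc].value}\t{row}\n")


def read_count_table(path: str | Path) -> LineageCountTable:
    path = Path(path)
    replicate_id, concentration = "rep1", 0.0
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for tok in line[1:].strip().split("\t"):
                if tok.startswith("replicate_id="):
                    replicate_id = tok.split("=", 1)[1]
                elif tok.startswith("concentration_nM="):
                    concentration = float(tok.split("=", 1)[1])
            body_start = i + 1
        else:
            break
    import io as _io

    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    if list(df.columns[:2]) != ["barcode", "class"]:
        raise ValueError(f"unexpected count-table header in {path}")
    classes = {
        bc: GenotypeClass(c) for bc, c in zip(df["barcode"], df["class"])
    }
    counts = df.drop(columns=["class"]).set_index("barcode").astype(np.int64)
    return LineageCountTable(
        counts=counts,
        classes=classes,
        replicate_id=replicate_id,
        concentration=concentration,
    )


def write_rejection_log(rejections: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(rejections), indent=2, sort_keys=True))
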