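"""Muller-style stacked lineage-frequency export.

Turns a lineage x timepoint count table into a plot-ready long-format
table of cumulative frequency bands: at each timepoint the wild-type
lineages form one contiguous block of bands followed by the mutant block,
each band's width equal to that lineage's frequency, bands summing to 1.
Band order is fixed across timepoints (same lineage, same band index), so
the table can be fed directly to a stacked-area or ribbon plot.
"""

from __future__ import annotations

import pandas as pd

from .countio import LineageCountTable
from .patterns import GenotypeClass

__all__ = ["export_frequency_stack"]

_CLASS_ORDER = {GenotypeClass.WILD_TYPE: 0, GenotypeClass.MUTANT: 1,
                GenotypeClass.UNCLASSIFIED: 2}


def export_frequency_stack(table: LineageCountTable) -> pd.DataFrame:
    """Long-format cumulative bands per (timepoint, lineage).

    Columns: timepoint, timepoint_index, lineage, class, frequency,
    band_index, band_lo, band_hi.  Within a timepoint, band_lo/band_hi give
    the cumulative interval of the lineage's band; bands are ordered
    wild-type block first, then mutant, stable in table row order.
    """
    freq = table.frequencies()
    order = sorted(
        table.lineages,
        key=lambda bc: (_CLASS_ORDER[table.classes[bc]],
                        table.lineages.index(bc)),
    )
    rows = []
    for t_idx, tp in enumerate(table.timepoints):
        lo = 0.0
        for band_idx, bc in enumerate(order):
            f = float(freq.loc[bc, tp])
            rows.append(
                {
                    "timepoint": tp,
                    "timepoint_index": t_idx,
                    "lineage": bc,
                    "class": table.classes[bc].value,
                    "frequency": f,
                    "band_index": band_idx,
                    "band_lo": lo,
                    "band_hi": lo + f,
                }
            )
            lo += f
    return pd.DataFrame(rows)
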