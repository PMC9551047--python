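"""Zonal aggregation of extensive gridded fields to regions.

The input must be tagged ``kg_per_cell`` (explicit conversion first); region
totals are plain sums over member cells, so the sum over all regions equals
the domain total exactly.  Passing a normalizer (an area field, ha) turns
totals into kg per hectare of that area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fields import AnnualField
from .grid import GridSpec, RegionMask


def aggregate_to_regions(
    field: AnnualField,
    mask: RegionMask,
    grid: GridSpec,
    normalizer: AnnualField | None = None,
) -> pd.DataFrame:
    """Region x year table of sums (kg) or, with a normalizer, kg per ha.

    Returns a frame indexed by year with one column per region id.
    """
    if field.units != "kg_per_cell":
        raise ValueError(f"aggregate requires kg_per_cell input, got {field.units!r}")
    if field.values.shape[1] != grid.n_cells or mask.region_id.shape[0] != grid.n_cells:
        raise ValueError("field and mask must share the GridSpec")
    regions = mask.regions
    n_regions = int(mask.region_id.max()) + 1
    totals = np.empty((field.n_years, len(regions)))
    for t in range(field.n_years):
        acc = np.bincount(mask.region_id, weights=field.values[t], minlength=n_regions)
        totals[t] = acc[regions]
    if normalizer is not None:
        if normalizer.units != "ha":
            raise ValueError("normalizer must be an area field (ha)")
        for t in range(field.n_years):
            # normalizer may be static (1 year) or annual
            row = normalizer.values[min(t, normalizer.n_years - 1)]
            acc = np.bincount(mask.region_id, weights=row, minlength=n_regions)
            with np.errstate(invalid="ignore", divide="ignore"):
                totals[t] = np.where(acc[regions] > 0, totals[t] / acc[regions], np.nan)
    return pd.DataFrame(totals, index=pd.Index(field.years, name="year"),
                        columns=pd.Index(regions, name="region_id"))
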