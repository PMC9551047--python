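"""N outputs: removal by harvested crops, grazed/cut pasture, and forest.

Crop removal multiplies production by crop-specific N contents.  Pasture
removal follows a nitrogen-use-efficiency rule, Rem = C x (Inp - losses x
Man), with scenario-dependent coefficients (a single NUE of 0.6 with 20%
manure losses, or 0.4/0.5 for eastern/western countries with no loss
term); results are floored at zero since removal is physically
non-negative.  Forest removal is a fixed fraction (0.02) of forest
deposition, representing the fertilization effect of deposited N on woody
biomass.
"""

from __future__ import annotations

import numpy as np

from .coefficients import CoefficientSet, PastureScenario
from .fields import AnnualField
from .grid import GridSpec
from .registry import CountryRegistry

KG_PER_TONNE = 1000.0


def crop_removal(
    production: dict[str, AnnualField],
    coefficients: CoefficientSet,
) -> AnnualField:
    """Rem_cr = sum over crops of production (t) x N content (kg/t).

    Gridded production is carried in kg per cell, hence the tonne
    conversion here.  Crops without an N content (fodder categories, whose
    N leaves via the grazing/cutting budget) contribute nothing.
    """
    first = next(iter(production.values()))
    out = np.zeros_like(first.values)
    for crop, field in production.items():
        content = coefficients.n_content.get(crop)
        if content is None:
            continue
        out += field.values / KG_PER_TONNE * content
    return AnnualField("Rem_cr", "kg_per_cell", first.year0, out)


def pasture_removal(
    inp_past: AnnualField,
    man_past: AnnualField,
    scenario: PastureScenario,
    registry: CountryRegistry,
    grid: GridSpec,
) -> AnnualField:
    """NUE-based grass removal, per scenario, floored at zero.

    The removal coefficient may differ between eastern and western
    countries; the loss fraction discounts the manure share of the input
    before the efficiency is applied.  The rule is linear, so it holds
    identically in extensive (kg per cell) units.
    """
    c = np.empty(grid.n_cells)
    for u in grid.countries:
        c[grid.country_id == u] = scenario.coefficient(int(u) in registry.eastern)
    c[grid.country_id == 0] = 0.0
    rem = c[None, :] * (inp_past.values - scenario.n_losses * man_past.values)
    return AnnualField("Rem_past", "kg_per_cell", inp_past.year0, np.maximum(rem, 0.0))


def forest_removal(dep_for: AnnualField, coefficients: CoefficientSet) -> AnnualField:
    """Rem_For = removal rate x forest deposition, cellwise."""
    return AnnualField("Rem_For", "kg_per_cell", dep_for.year0,
                       coefficients.forest_removal_rate * dep_for.values)
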