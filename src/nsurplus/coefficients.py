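"""Nitrogen coefficients: crop N contents, fixation rates, removal parameters.

Defaults reproduce the study's coefficient table: N content in kg N per
tonne of product, biological fixation (BNF) in kg N per hectare per year
for area-based fixers, the pasture nitrogen-use-efficiency scenarios, the
forest removal rate, and the manure application cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: kg N per tonne of harvested product
N_CONTENT: dict[str, float] = {
    "wheat": 20.0,
    "maize": 13.0,
    "rice": 12.0,
    "soybean": 45.0,
    "sunflower": 23.0,
    "millet": 24.0,
    "sorghum": 14.0,
    "rye": 22.0,
    "barley": 18.0,
    "oats": 20.0,
    "triticale": 16.0,
    "buckwheat": 16.0,
    "rapeseed": 35.0,
    "sesame": 35.0,
    "pulses": 40.0,
    "sugar_beet": 1.5,
    "potato": 3.0,
}

#: kg N per ha per year, N-fixing crops only
BNF_CROP_RATE: dict[str, float] = {
    "soybean": 80.0,
    "pulses": 50.0,
}

BNF_PASTURE_RATE = 5.0       # kg N ha-1 yr-1
BNF_FOREST_TEMPERATE = 16.0  # kg N ha-1 yr-1
BNF_FOREST_BOREAL = 1.77     # kg N ha-1 yr-1
BNF_NATVEG_RATE = 2.7        # kg N ha-1 yr-1


@dataclass(frozen=True)
class PastureScenario:
    """NUE-based pasture removal: Rem = C * (Inp - losses * Man)."""

    name: str
    c_east: float
    c_west: float
    n_losses: float

    def coefficient(self, is_eastern: bool) -> float:
        return self.c_east if is_eastern else self.c_west


#: Scenario 1: single NUE 0.6 everywhere, 20% manure losses.
SCENARIO_1 = PastureScenario("S1", c_east=0.6, c_west=0.6, n_losses=0.2)
#: Scenario 2: NUE 0.4 (eastern) / 0.5 (western), no loss adjustment.
SCENARIO_2 = PastureScenario("S2", c_east=0.4, c_west=0.5, n_losses=0.0)

PASTURE_SCENARIOS = {"S1": SCENARIO_1, "S2": SCENARIO_2}


@dataclass(frozen=True)
class CoefficientSet:
    n_content: dict[str, float] = field(default_factory=lambda: dict(N_CONTENT))
    bnf_crop_rate: dict[str, float] = field(default_factory=lambda: dict(BNF_CROP_RATE))
    bnf_pasture: float = BNF_PASTURE_RATE
    bnf_forest_temperate: float = BNF_FOREST_TEMPERATE
    bnf_forest_boreal: float = BNF_FOREST_BOREAL
    bnf_natveg: float = BNF_NATVEG_RATE
    forest_removal_rate: float = 0.02
    #: kg N per ha of agricultural area per year; permissible range 170-250.
    manure_cap: float = 250.0

    def __post_init__(self) -> None:
        if not 170.0 <= self.manure_cap <= 250.0:
            raise ValueError("manure cap must lie within [170, 250] kg ha-1")
        for name, v in list(self.n_content.items()) + list(self.bnf_crop_rate.items()):
            if v < 0:
                raise ValueError(f"negative coefficient for {name}")
        if not 0.0 <= self.forest_removal_rate <= 1.0:
            raise ValueError("forest removal rate must be a fraction")


DEFAULT_COEFFICIENTS = CoefficientSet()
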