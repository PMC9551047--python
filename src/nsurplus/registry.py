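"""Country and crop registries.

The country registry records the statistical-reporting quirks the pipeline
has to handle: countries whose series only start in 1992, pairs reported as
a single merged entity until a split year, the Eastern-European donor pool
used to back-fill missing fertilizer series, boreal countries (low forest
N-fixation), the east/west split used by the second pasture-removal
scenario, and the neighbour-proxy map used to borrow fodder ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MergeGroup:
    """Countries reported as one combined series before ``split_year``."""

    members: tuple[int, ...]
    split_year: int


@dataclass(frozen=True)
class CountryRegistry:
    names: dict[int, str]
    merge_groups: tuple[MergeGroup, ...] = ()
    missing_before_1992: frozenset[int] = frozenset()
    east_eu_donors: frozenset[int] = frozenset()
    boreal: frozenset[int] = frozenset()
    eastern: frozenset[int] = frozenset()
    proxy_map: dict[int, int] = field(default_factory=dict)
    ifa_members: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.merge_groups:
            if seen & set(g.members):
                raise ValueError("merge groups must be disjoint")
            seen |= set(g.members)
        for k, v in self.proxy_map.items():
            if k == v:
                raise ValueError("proxy map must not map a country to itself")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.names))

    def merge_group_of(self, country: int) -> MergeGroup | None:
        for g in self.merge_groups:
            if country in g.members:
                return g
        return None

    @classmethod
    def synthetic(cls, n_countries: int) -> "CountryRegistry":
        """Deterministic role assignment for a toy world of ``n_countries``.

        Needs at least 8 countries so every gap-handling rule downstream is
        exercisable: one merge pair, one missing-before-1992 country with a
        neighbour proxy, one missing country relying on the Eastern-European
        aggregate, a three-country donor pool and one boreal country.
        """
        if n_countries < 3:
            raise ValueError("need at least 3 countries")
        names = {i: f"C{i:02d}" for i in range(1, n_countries + 1)}
        merge_groups: tuple[MergeGroup, ...] = ()
        missing: frozenset[int] = frozenset()
        donors: frozenset[int] = frozenset()
        boreal: frozenset[int] = frozenset()
        proxy: dict[int, int] = {}
        if n_countries >= 8:
            merge_groups = (MergeGroup((1, 2), split_year=2000),)
            missing = frozenset({5, 6})
            proxy = {5: 4}  # country 5 borrows country 4's fodder ratio
            donors = frozenset({3, 7, 8})
            boreal = frozenset({8})
        eastern = frozenset(i for i in names if i % 2 == 1)
        ifa = frozenset(i for i in names if i <= max(2, n_countries - 2))
        return cls(
            names=names,
            merge_groups=merge_groups,
            missing_before_1992=missing,
            east_eu_donors=donors,
            boreal=boreal,
            eastern=eastern,
            proxy_map=proxy,
            ifa_members=ifa,
        )


# --- crop registry -----------------------------------------------------------

#: The 17 non-fodder crops carried through the whole pipeline.
NON_FODDER_CROPS: tuple[str, ...] = (
    "wheat",
    "maize",
    "rice",
    "soybean",
    "sunflower",
    "millet",
    "sorghum",
    "rye",
    "barley",
    "oats",
    "triticale",
    "buckwheat",
    "rapeseed",
    "sesame",
    "pulses",
    "sugar_beet",
    "potato",
)

#: The 6 fodder-crop categories (cropland feed) handled separately.
FODDER_CROPS: tuple[str, ...] = (
    "temporary_grassland",
    "lucerne",
    "other_legumes",
    "green_maize",
    "other_arable_feed",
    "root_feed",
)

ALL_CROPS: tuple[str, ...] = NON_FODDER_CROPS + FODDER_CROPS

#: Mapping from the 13 fertilizer-industry crop groups to the crop registry.
#: The grassland group covers pasture and all fodder categories and is
#: handled separately via the grassland application rate.
IFA_GROUP_TO_CROPS: dict[str, tuple[str, ...]] = {
    "wheat": ("wheat",),
    "rice": ("rice",),
    "maize": ("maize",),
    "other_cereals": ("barley", "sorghum", "oats", "rye", "triticale", "millet", "buckwheat"),
    "soybean": ("soybean",),
    "oil_palm": (),
    "other_oilseeds": ("rapeseed", "sunflower", "sesame"),
    "fiber_crops": (),
    "sugar_crops": ("sugar_beet",),
    "roots_tubers": ("potato",),
    "fruits": (),
    "vegetables": (),
    "residual": ("pulses",),
}

IFA_GROUPS: tuple[str, ...] = tuple(IFA_GROUP_TO_CROPS) + ("grassland",)


def ifa_group_of(crop: str) -> str:
    for group, crops in IFA_GROUP_TO_CROPS.items():
        if crop in crops:
            return group
    raise KeyError(f"no fertilizer crop group covers {crop!r}")
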