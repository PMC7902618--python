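"""Registry of environmental predictors.

Every predictor used anywhere in the pipeline is declared here with its
category (forest / climate / landscape), whether it is static or annually
resolved, and the location/scale used by the synthetic generator. The
categories drive the category-level interaction averages and the marginal
sensitivity shares; static vs dynamic drives which predictors are held at
their current (2009-2018 mean) value during backward predictive runs.
"""

from __future__ import annotations

from dataclasses import dataclass

FOREST = "forest"
CLIMATE = "climate"
LANDSCAPE = "landscape"

CATEGORIES = (FOREST, CLIMATE, LANDSCAPE)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str
    dynamic: bool
    mu: float  # generator location
    sd: float  # generator scale
    lower: float | None = None  # physical lower bound, clip in the generator
    upper: float | None = None


#: All model predictors known to the pipeline. Anomaly variables (``a_*``)
#: are derived from the corresponding dynamic series against the early-period
#: baseline climatology; their mu is 0 by construction.
FEATURES: dict[str, FeatureDef] = {
    f.name: f
    for f in [
        # forest structure (static stand properties)
        FeatureDef("tree_age", FOREST, False, 80.0, 30.0, lower=1.0),
        FeatureDef("tree_height", FOREST, False, 20.0, 6.0, lower=1.0),
        FeatureDef("tree_density", FOREST, False, 400.0, 150.0, lower=10.0),
        # climate
        FeatureDef("tavg_longterm", CLIMATE, False, 8.0, 4.0),
        FeatureDef("tmax", CLIMATE, True, 28.0, 4.0),
        FeatureDef("pcum", CLIMATE, True, 800.0, 250.0, lower=0.0),
        FeatureDef("wind_speed", CLIMATE, True, 12.0, 4.0, lower=0.0),
        FeatureDef("a_tavg", CLIMATE, True, 0.0, 0.5),
        FeatureDef("a_pcum", CLIMATE, True, 0.0, 100.0),
        # landscape
        FeatureDef("elevation", LANDSCAPE, False, 500.0, 300.0, lower=0.0),
        FeatureDef("slope", LANDSCAPE, False, 10.0, 6.0, lower=0.0),
        FeatureDef("homogeneity", LANDSCAPE, False, 0.5, 0.15, lower=0.0, upper=1.0),
        FeatureDef("cv", LANDSCAPE, False, 0.3, 0.1, lower=0.01),
    ]
}

STATIC_FEATURES = tuple(n for n, f in FEATURES.items() if not f.dynamic)
DYNAMIC_FEATURES = tuple(n for n, f in FEATURES.items() if f.dynamic)

#: Plant functional types used to stratify models.
PFTS = ("BrDe", "BrEv", "NeDe", "NeEv")


def category_of(name: str) -> str:
    """Category of a predictor (raises ``KeyError`` for unknown names)."""
    return FEATURES[name].category


def categories_map(names) -> dict[str, str]:
    return {n: category_of(n) for n in names}
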