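"""Predictor schema: the ordered set of model inputs and their valid ranges.

The default schema carries 13 predictors: field/satellite leaf area index
(LAI) plus 12 daily-mean climate variables (shortwave radiation, soil
temperature and soil water content at three depths, sensible and latent heat
flux, precipitation, air temperature, wind speed).  Each predictor has the
units, valid range, and marginal distribution family observed across the
eddy-covariance tower network used to train the flux models; the ranges
double as the training-domain bounds used for out-of-range screening during
upscaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PredictorDescriptor",
    "PredictorSchema",
    "default_schema",
    "VEGETATION_CLASSES",
    "FLUX_VARIABLES",
]

#: IGBP-style vegetation classes used for stratification and per-class metrics.
VEGETATION_CLASSES = (
    "CRO", "ENF", "DBF", "EBF", "DNF", "GRA", "WET", "CSH", "OSH", "MF", "MSF",
)

#: Target flux variables, all in micromol CO2 m-2 s-1 at daily resolution.
FLUX_VARIABLES = ("GPP", "RECO", "NEE")

_FAMILIES = ("exponential", "uniform", "chi-square", "gamma")


@dataclass(frozen=True)
class PredictorDescriptor:
    """One predictor: name, physical units, valid range, distribution family."""

    name: str
    units: str
    valid_min: float
    valid_max: float
    family: str

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not self.valid_min < self.valid_max:
            raise ValueError(
                f"{self.name}: valid_min {self.valid_min} must be < valid_max "
                f"{self.valid_max}"
            )

    def in_range(self, value: float) -> bool:
        return self.valid_min <= value <= self.valid_max


@dataclass(frozen=True)
class PredictorSchema:
    """Ordered predictor descriptors; the model dimension D is ``len(schema)``."""

    predictors: tuple[PredictorDescriptor, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.predictors]

    @property
    def D(self) -> int:
        return len(self.predictors)

    def __len__(self) -> int:
        return len(self.predictors)

    def __iter__(self):
        return iter(self.predictors)

    def __getitem__(self, name: str) -> PredictorDescriptor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def index(self, name: str) -> int:
        for i, p in enumerate(self.predictors):
            if p.name == name:
                return i
        raise KeyError(name)

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": p.name,
                "units": p.units,
                "valid_min": p.valid_min,
                "valid_max": p.valid_max,
                "family": p.family,
            }
            for p in self.predictors
        ]

    @classmethod
    def from_dict(cls, entries: list[dict]) -> "PredictorSchema":
        return cls(
            tuple(
                PredictorDescriptor(
                    e["name"], e["units"], e["valid_min"], e["valid_max"], e["family"]
                )
                for e in entries
            )
        )


def default_schema() -> PredictorSchema:
    """Default 13-predictor schema: LAI plus 12 climate variables.

    Ranges are the daily-mean training ranges observed at the flux towers;
    distribution families describe the marginal shape of each variable across
    the network (right-skewed LAI/precipitation, near-uniform daily shortwave
    radiation, chi-square-like temperatures, gamma-like moisture and latent
    heat).
    """
    return PredictorSchema(
        (
            PredictorDescriptor("LAI", "m2 m-2", 0.0, 9.38, "exponential"),
            PredictorDescriptor("SW", "W m-2", 2.94, 357.39, "uniform"),
            PredictorDescriptor("TS_1", "degC", -0.79, 28.02, "chi-square"),
            PredictorDescriptor("TS_2", "degC", -0.79, 28.02, "chi-square"),
            PredictorDescriptor("TS_3", "degC", -0.79, 28.02, "chi-square"),
            PredictorDescriptor("SWC_1", "%", 0.0, 94.54, "gamma"),
            PredictorDescriptor("SWC_2", "%", 0.0, 94.54, "gamma"),
            PredictorDescriptor("SWC_3", "%", 0.0, 94.54, "gamma"),
            PredictorDescriptor("H", "W m-2", -80.42, 163.58, "chi-square"),
            PredictorDescriptor("LE", "W m-2", -15.60, 238.44, "gamma"),
            PredictorDescriptor("P", "mm", 0.0, 36.46, "exponential"),
            PredictorDescriptor("TA", "degC", -4.92, 26.71, "chi-square"),
            PredictorDescriptor("WS", "m s-1", 0.64, 8.41, "gamma"),
        )
    )
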