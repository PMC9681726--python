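"""Wing morphometrics: wing area, wing loading, aspect ratio and covariates.

Raw inputs per species are the hand length H (the standard "wing length"
measurement, carpal joint to tip), the first secondary feather length S, a
published wingspan range, body mass, and the centroid latitude of the
breeding/resident range.  Wing area is approximated as a central rectangle
plus two triangular hand sections:

    area = (wingspan - 2 H) * S + 2 * (H * S / 2)  =  S * (wingspan - H)

Wing loading is body mass per unit wing area (g per mm^2); aspect ratio is
wingspan squared over area.  Both are standard flight-performance indices:
high wing loading lowers lift per unit mass, high aspect ratio marks long
narrow wings efficient for gliding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidMeasurementError

__all__ = [
    "SpeciesRecord",
    "DerivedMorphology",
    "wing_area",
    "wing_loading",
    "aspect_ratio",
    "z_standardize",
    "absolute_latitude",
    "wingspan_midpoint",
    "aggregate_subspecies",
    "derive_morphology",
    "read_species_csv",
    "write_species_csv",
]

#: columns of the species CSV, one row per species or subspecies.  Subspecies
#: rows carry their parent's name in ``parent_species`` and are averaged.
CSV_COLUMNS = [
    "species",
    "parent_species",
    "hand_length_mm",
    "secondary_length_mm",
    "wingspan_min_mm",
    "wingspan_max_mm",
    "body_mass_g",
    "centroid_latitude_deg",
    "mantle_kgs",
    "wingtip_black",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """Raw measurements for one species (or subspecies row).

    ``mantle_kgs`` is mantle darkness on the Kodak grey scale (0 white to
    19 black); ``wingtip_black`` is the proportion of black on the hand
    region of the upperwing.  Either may be ``None`` when unmeasured, as may
    the wingspan range.
    """

    name: str
    hand_length_H: float
    secondary_length_S: float
    wingspan_min: float | None
    wingspan_max: float | None
    body_mass: float
    centroid_latitude: float
    mantle_kgs: float | None = None
    wingtip_black: float | None = None

    def __post_init__(self):
        for fld in ("hand_length_H", "secondary_length_S", "body_mass"):
            v = getattr(self, fld)
            if v is not None and not v > 0:
                raise InvalidMeasurementError(f"{self.name}: {fld} must be > 0, got {v}")
        if self.wingspan_min is not None and self.wingspan_max is not None:
            if self.wingspan_min > self.wingspan_max:
                raise InvalidMeasurementError(
                    f"{self.name}: wingspan_min {self.wingspan_min} > wingspan_max {self.wingspan_max}"
                )
            if not self.wingspan_min > 0:
                raise InvalidMeasurementError(f"{self.name}: wingspan must be > 0")
        if not -90.0 <= self.centroid_latitude <= 90.0:
            raise InvalidMeasurementError(
                f"{self.name}: centroid latitude {self.centroid_latitude} outside [-90, 90]"
            )
        if self.mantle_kgs is not None and not 0.0 <= self.mantle_kgs <= 19.0:
            raise InvalidMeasurementError(
                f"{self.name}: mantle KGS {self.mantle_kgs} outside [0, 19]"
            )
        if self.wingtip_black is not None and not 0.0 <= self.wingtip_black <= 1.0:
            raise InvalidMeasurementError(
                f"{self.name}: wingtip proportion {self.wingtip_black} outside [0, 1]"
            )


@dataclass(frozen=True)
class DerivedMorphology:
    """Derived flight-morphology quantities for one species."""

    name: str
    wing_area: float            # mm^2
    wing_loading: float         # g / mm^2
    wing_loading_std: float     # z-score over the analysis set
    aspect_ratio: float         # unitless
    abs_latitude: float         # degrees >= 0


def wing_area(wingspan: float, H: float, S: float) -> float:
    """Wing area (mm^2) from wingspan, hand length H and secondary length S.

    Central rectangle ``(wingspan - 2H) * S`` plus two triangular hand panels
    ``H * S / 2`` each; algebraically ``S * (wingspan - H)``.  If the span is
    not wider than twice the hand the rectangle term is non-positive: the
    formula value is still returned (with a warning) when positive overall,
    otherwise the measurements are rejected.
    """
    if H <= 0 or S <= 0 or wingspan <= 0:
        raise InvalidMeasurementError("wingspan, H and S must all be > 0")
    area = (wingspan - 2.0 * H) * S + 2.0 * (H * S * 0.5)
    if wingspan <= 2.0 * H:
        if area > 0:
            warnings.warn(
                f"wingspan {wingspan} <= 2*H ({2 * H}): central rectangle is "
                "non-positive; returning the formula value",
                stacklevel=2,
            )
        else:
            raise InvalidMeasurementError(
                f"non-positive wing area from wingspan={wingspan}, H={H}, S={S}"
            )
    return area


def wing_loading(mass: float, area: float) -> float:
    """Body mass per unit wing area, g / mm^2."""
    if mass <= 0 or area <= 0:
        raise InvalidMeasurementError("mass and area must be > 0")
    return mass / area


def aspect_ratio(wingspan: float, area: float) -> float:
    """Wingspan squared over wing area (unitless)."""
    if wingspan <= 0 or area <= 0:
        raise InvalidMeasurementError("wingspan and area must be > 0")
    return wingspan * wingspan / area


def z_standardize(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to unit SD (population convention, divisor n).

    Effects of a standardized predictor then read "per SD increase".  With
    the sample-SD convention (divisor n-1) coefficients would differ by
    sqrt(n/(n-1)), about 1% at n=50.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DegenerateInputError("need a 1-d vector of length >= 2")
    sd = arr.std()  # population SD
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


def absolute_latitude(lat: float) -> float:
    """Unsigned distance from the equator in degrees (insolation proxy)."""
    if not -90.0 <= lat <= 90.0:
        raise InvalidMeasurementError(f"latitude {lat} outside [-90, 90]")
    return abs(lat)


def wingspan_midpoint(lo: float, hi: float) -> float:
    """Central value of a published wingspan range."""
    if lo > hi:
        raise InvalidMeasurementError(f"wingspan range lo {lo} > hi {hi}")
    return 0.5 * (lo + hi)


_NUMERIC_FIELDS = [
    "hand_length_H",
    "secondary_length_S",
    "wingspan_min",
    "wingspan_max",
    "body_mass",
    "centroid_latitude",
    "mantle_kgs",
    "wingtip_black",
]


def aggregate_subspecies(records: Iterable[SpeciesRecord], name: str | None = None) -> SpeciesRecord:
    """Collapse subspecies rows into one species record by field-wise means.

    Missing values are excluded pairwise; a field missing in every record
    stays missing.
    """
    recs = list(records)
    if not recs:
        raise DegenerateInputError("no records to aggregate")
    if name is None:
        name = recs[0].name
    out = {"name": name}
    for fld in _NUMERIC_FIELDS:
        vals = [getattr(r, fld) for r in recs if getattr(r, fld) is not None]
        out[fld] = float(np.mean(vals)) if vals else None
    return SpeciesRecord(**out)


def derive_morphology(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Compute wing area, loading, aspect ratio and covariates for an analysis set.

    Species lacking a wingspan range are dropped (complete-case policy); the
    wing-loading z-score is computed over the retained set, so its mean is 0
    on exactly the species analysed.
    """
    rows = []
    for r in records:
        if r.wingspan_min is None or r.wingspan_max is None:
            continue
        span = wingspan_midpoint(r.wingspan_min, r.wingspan_max)
        area = wing_area(span, r.hand_length_H, r.secondary_length_S)
        rows.append(
            {
                "species": r.name,
                "wingspan": span,
                "wing_area": area,
                "wing_loading": wing_loading(r.body_mass, area),
                "aspect_ratio": aspect_ratio(span, area),
                "abs_latitude": absolute_latitude(r.centroid_latitude),
                "mantle_kgs": r.mantle_kgs,
                "wingtip_black": r.wingtip_black,
            }
        )
    if len(rows) < 2:
        raise DegenerateInputError("need at least 2 species with complete wingspans")
    df = pd.DataFrame(rows)
    df["wing_loading_std"] = z_standardize(df["wing_loading"].to_numpy())
    return df


def _records_from_frame(df: pd.DataFrame) -> list[SpeciesRecord]:
    def _get(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    groups: dict[str, list[SpeciesRecord]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        parent = row.get("parent_species")
        if parent is None or (isinstance(parent, float) and np.isnan(parent)) or parent == "":
            parent = row["species"]
        rec = SpeciesRecord(
            name=str(row["species"]),
            hand_length_H=_get(row, "hand_length_mm"),
            secondary_length_S=_get(row, "secondary_length_mm"),
            wingspan_min=_get(row, "wingspan_min_mm"),
            wingspan_max=_get(row, "wingspan_max_mm"),
            body_mass=_get(row, "body_mass_g"),
            centroid_latitude=_get(row, "centroid_latitude_deg"),
            mantle_kgs=_get(row, "mantle_kgs"),
            wingtip_black=_get(row, "wingtip_black"),
        )
        parent = str(parent)
        if parent not in groups:
            groups[parent] = []
            order.append(parent)
        groups[parent].append(rec)
    return [aggregate_subspecies(groups[p], name=p) for p in order]


def read_species_csv(path) -> list[SpeciesRecord]:
    """Read a species table CSV, averaging subspecies rows into species."""
    df = pd.read_csv(path)
    missing = {"species"} - set(df.columns)
    if missing:
        raise InvalidMeasurementError(f"species CSV lacks required columns: {missing}")
    return _records_from_frame(df)


def write_species_csv(records: Sequence[SpeciesRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.name,
                "parent_species": "",
                "hand_length_mm": r.hand_length_H,
                "secondary_length_mm": r.secondary_length_S,
                "wingspan_min_mm": r.wingspan_min,
                "wingspan_max_mm": r.wingspan_max,
                "body_mass_g": r.body_mass,
                "centroid_latitude_deg": r.centroid_latitude,
                "mantle_kgs": r.mantle_kgs,
                "wingtip_black": r.wingtip_black,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
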