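"""Ocular biometry and histological-shrinkage calibration.

Standard histology (fixation, dehydration, paraffin embedding) shrinks
ocular tissue, so dimensions measured on sections underestimate the
living eye.  The shrinkage factor of a parameter is the ratio of its
post-processing mean to its in-vivo mean; dividing a model's physical
scale by that factor restores in-vivo dimensions.  A packaged reference
table ships in-vivo and post-processing means (± SD) for corneal
diameter, ocular axial length and central retinal thickness in mouse,
rat and rabbit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Maximum distance (mm) from the optic nerve head at which retinal
#: thickness is sampled, per species.
RETINA_DISTANCE_LIMIT_MM = {"mouse": 0.6, "rat": 0.6, "rabbit": 3.0}

#: Number of retinal-thickness sampling positions entering the average.
RETINA_SAMPLE_COUNT = 6


@dataclass(frozen=True)
class BiometryRecord:
    """In-vivo vs. post-histology means of one ocular parameter.

    Units of the two means must agree (mm for diameters and lengths,
    micrometers for retinal thickness).
    """

    species: str
    parameter: str
    in_vivo_mean: float
    measured_mean: float
    in_vivo_sd: float = 0.0
    measured_sd: float = 0.0
    unit: str = "mm"
    n: int | None = None
    source: str = "own measurement"

    def __post_init__(self) -> None:
        if self.in_vivo_mean <= 0 or self.measured_mean <= 0:
            raise ValidationError("means must be strictly positive")
        if self.in_vivo_sd < 0 or self.measured_sd < 0:
            raise ValidationError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ShrinkageFactor:
    """Dimensionless post-processing / in-vivo ratio, rounded to 3 decimals."""

    value: float
    species: str = "other"
    parameter: str = "other"

    def __post_init__(self) -> None:
        if not (0 < self.value <= 1.5):
            raise ValidationError(f"shrinkage factor {self.value} outside (0, 1.5]")


def _round3(x: float) -> float:
    """Round half away from zero to 3 decimals (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def shrinkage_factor(record: BiometryRecord) -> ShrinkageFactor:
    """Shrinkage factor of a record: measured mean over in-vivo mean."""
    return ShrinkageFactor(
        value=_round3(record.measured_mean / record.in_vivo_mean),
        species=record.species,
        parameter=record.parameter,
    )


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 2:
        raise ValidationError(f"need at least 2 values, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1))


def retinal_thickness_average(measurements, species: str) -> tuple[float, float]:
    """Mean ± SD of retinal thickness sampled around the optic nerve head.

    ``measurements`` is a sequence of ``(thickness, distance_from_onh_mm)``
    pairs; exactly six positions are required and every position must lie
    within the species' distance limit (0.6 mm for mouse and rat, 3.0 mm
    for rabbit).
    """
    if species not in RETINA_DISTANCE_LIMIT_MM:
        raise ValidationError(f"unknown species {species!r}")
    measurements = list(measurements)
    if len(measurements) != RETINA_SAMPLE_COUNT:
        raise ValidationError(
            f"expected {RETINA_SAMPLE_COUNT} measurements, got {len(measurements)}"
        )
    limit = RETINA_DISTANCE_LIMIT_MM[species]
    for pos, (_, dist) in enumerate(measurements):
        if dist > limit:
            raise ValidationError(
                f"position {pos}: distance {dist} mm exceeds the "
                f"{limit} mm limit for {species}"
            )
    return mean_sd([t for t, _ in measurements])


def scale_to_invivo(scale: float, factor: ShrinkageFactor | float) -> float:
    """Correct a physical scale (size per unit) for histological shrinkage.

    Dividing by the shrinkage factor enlarges the model so dimensions
    measured on the corrected model reproduce the in-vivo values.  The
    correction is isotropic; anisotropic shrinkage is not modeled.
    """
    value = factor.value if isinstance(factor, ShrinkageFactor) else float(factor)
    if value <= 0:
        raise ValidationError(f"shrinkage factor must be positive, got {value}")
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    return scale / value


def load_reference_table(path=None) -> pd.DataFrame:
    """Species biometry table (packaged default, or a user CSV of the same layout)."""
    if path is None:
        src = resources.files("eye3d.data") / "biometry_reference.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {
        "species", "parameter", "in_vivo_mean", "in_vivo_sd",
        "measured_mean", "measured_sd", "unit",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"biometry table missing columns: {sorted(missing)}")
    return df


def reference_record(
    species: str, parameter: str, table: pd.DataFrame | None = None
) -> BiometryRecord:
    """Look one record up in the reference table."""
    df = load_reference_table() if table is None else table
    row = df[(df.species == species) & (df.parameter == parameter)]
    if row.empty:
        raise ValidationError(f"no reference entry for {species}/{parameter}")
    r = row.iloc[0]
    return BiometryRecord(
        species=species,
        parameter=parameter,
        in_vivo_mean=float(r.in_vivo_mean),
        in_vivo_sd=float(r.in_vivo_sd),
        measured_mean=float(r.measured_mean),
        measured_sd=float(r.measured_sd),
        unit=str(r.unit),
        n=int(r.n) if "n" in df.columns else None,
        source=str(r.source) if "source" in df.columns else "",
    )


def shrinkage_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """All shrinkage factors recomputed from the reference means."""
    df = load_reference_table() if table is None else table
    out = df.copy()
    out["shrinkage_factor"] = [
        _round3(m / v) for m, v in zip(df.measured_mean, df.in_vivo_mean)
    ]
    return out
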