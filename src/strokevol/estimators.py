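"""The od-value and ABC/2 lesion-volume estimators and cutoff classifiers.

Both estimators reduce a 3D DWI lesion to one or two numbers measured on
a single slice:

* od-value: the product a x b of the maximum in-slice diameter *a* (cm)
  and the maximal orthogonal diameter *b* (cm).  Cutoffs of 32 and 42
  classify lesions as larger than 70 ml and 100 ml respectively, and a
  calibrated polynomial ``1.1*od + 0.03*od**2`` converts the od-value to
  a volume in ml.
* ABC/2: the classic ellipsoid approximation A*B*C/2, with A = a, B = b,
  and C = (number of lesion-bearing slices) x slice thickness, in cm;
  the result is directly in ml.

Computations are carried in full precision; values are rounded to one
decimal only at presentation (see :func:`reported`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs, volume thresholds and the od-to-ml polynomial.

    Defaults are the published operating points: od-value cutoffs 32 and
    42 for the >70 ml and >100 ml questions, and polynomial coefficients
    1.1 (linear) and 0.03 (quadratic).  The od cutoff comparison is
    inclusive (>=) by default; set ``od_cutoff_inclusive=False`` for a
    strict comparison.
    """

    od_cutoff_70: float = 32.0
    od_cutoff_100: float = 42.0
    volume_threshold_small: float = 70.0
    volume_threshold_large: float = 100.0
    od_poly_lin: float = 1.1
    od_poly_quad: float = 0.03
    od_cutoff_inclusive: bool = True

    def __post_init__(self) -> None:
        for name in ("od_cutoff_70", "od_cutoff_100", "volume_threshold_small",
                     "volume_threshold_large", "od_poly_lin", "od_poly_quad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.od_cutoff_70 >= self.od_cutoff_100:
            raise ValueError("od_cutoff_70 must be below od_cutoff_100")

    def od_cutoff(self, threshold_label: str) -> float:
        return {"70ml": self.od_cutoff_70, "100ml": self.od_cutoff_100}[
            _check_label(threshold_label)
        ]

    def volume_threshold(self, threshold_label: str) -> float:
        return {
            "70ml": self.volume_threshold_small,
            "100ml": self.volume_threshold_large,
        }[_check_label(threshold_label)]


DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass(frozen=True)
class VolumeEstimates:
    """All volume readouts for one lesion."""

    od_value: float
    od_volume_ml: float
    abc2_volume_ml: float
    manual_volume_ml: float
    n_slices: int
    slice_thickness_cm: float


def _check_label(threshold_label: str) -> str:
    if threshold_label not in ("70ml", "100ml"):
        raise ValueError(
            f"unknown threshold label {threshold_label!r}; expected '70ml' or '100ml'"
        )
    return threshold_label


def od_value(a_cm: float, b_cm: float) -> float:
    """The orthogonal-diameter product a x b (cm^2, used as dimensionless)."""
    if a_cm < 0 or b_cm < 0:
        raise ValueError("diameters must be non-negative")
    return a_cm * b_cm


def od_to_volume(od: float, config: ThresholdConfig = DEFAULT_THRESHOLDS) -> float:
    """Convert an od-value to ml via the calibrated polynomial.

    ``volume = 1.1*od + 0.03*od**2`` with the default coefficients; the
    curve maps the cutoffs 32 and 42 to 65.92 ml and 99.12 ml, close to
    the 70/100 ml thresholds they stand in for.
    """
    if od < 0:
        raise ValueError("od-value must be non-negative")
    return config.od_poly_lin * od + config.od_poly_quad * od**2


def abc2_volume(a_cm: float, b_cm: float, n_slices: int, thickness_cm: float) -> float:
    """ABC/2 ellipsoid-approximation volume in ml.

    ``a*b*(n_slices*thickness)/2`` with a, b and thickness in cm.  The
    division by two is the ellipsoid halving of the A*B*C product.
    """
    if a_cm < 0 or b_cm < 0:
        raise ValueError("diameters must be non-negative")
    if n_slices < 0:
        raise ValueError("slice count must be non-negative")
    if thickness_cm <= 0:
        raise ValueError("slice thickness must be positive")
    return a_cm * b_cm * (n_slices * thickness_cm) / 2.0


def classify_large_lesion(
    estimates: VolumeEstimates,
    config: ThresholdConfig = DEFAULT_THRESHOLDS,
    method: str = "od_cutoff",
    threshold_label: str = "70ml",
) -> bool:
    """Binary large-lesion call for one method at one volume threshold.

    ``od_cutoff``: positive iff the od-value reaches the cutoff for the
    label (inclusive by default).  ``abc2``: positive iff the ABC/2
    volume exceeds the threshold in ml (strict, matching the '>70 ml'
    phrasing of the question being asked).
    """
    label = _check_label(threshold_label)
    if method == "od_cutoff":
        cutoff = config.od_cutoff(label)
        if config.od_cutoff_inclusive:
            return estimates.od_value >= cutoff
        return estimates.od_value > cutoff
    if method == "abc2":
        return estimates.abc2_volume_ml > config.volume_threshold(label)
    raise ValueError(f"unknown method {method!r}; expected 'od_cutoff' or 'abc2'")


def true_large_lesion(
    estimates: VolumeEstimates,
    config: ThresholdConfig = DEFAULT_THRESHOLDS,
    threshold_label: str = "70ml",
) -> bool:
    """Ground-truth label: manual (volumetric) volume strictly above threshold."""
    return estimates.manual_volume_ml > config.volume_threshold(_check_label(threshold_label))


def reported(value: float, decimals: int = 1) -> float:
    """Presentation rounding: one decimal, half away from zero.

    Clinical tables round half up (81.25% prints as 81.3), unlike
    Python's built-in banker's rounding.
    """
    scale = 10**decimals
    return math.copysign(math.floor(abs(float(value)) * scale + 0.5) / scale, value)
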