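"""Relative transcript quantification from qPCR Ct values.

Quantities are computed by the 2^ΔCt method against the geometric mean of a
panel of reference (housekeeping) genes.  Normalizing on the Ct scale with
the arithmetic mean of reference Cts is mathematically identical to taking
the geometric mean of the per-reference 2^ΔCt quantities (2^x is monotone
and turns means of exponents into geometric means); the Ct-scale form is
used for numerical robustness.  Amplification efficiency per assay comes
from a dilution standard curve: Ct regressed on log10 input quantity,
efficiency = 10^(-1/slope) - 1 (a perfect doubling chemistry has slope
-1/log10(2) ≈ -3.3219 and efficiency 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class CtRecord:
    """Replicate Ct measurements of one assay in one sample."""

    sample: str
    assay: str
    replicates: Tuple[float, ...]

    def __post_init__(self) -> None:
        if any(ct <= 0 for ct in self.replicates):
            raise ValueError("Ct values must be positive cycle numbers")

    @property
    def mean_ct(self) -> Optional[float]:
        """Arithmetic mean of replicate cycles; None when no replicate."""
        return fmean(self.replicates) if self.replicates else None


def relative_quantity(
    target_ct: Optional[float], reference_cts: Sequence[float]
) -> Optional[float]:
    """Relative quantity of a target: 2^(mean reference Ct − target Ct).

    A missing (undetermined) target Ct yields None — absent, never zero.
    """
    if not reference_cts:
        raise ValueError("at least one reference Ct is required")
    if target_ct is None:
        return None
    return 2.0 ** (fmean(reference_cts) - target_ct)


@dataclass
class StandardCurve:
    """Dilution-series fit: Ct against log10 input quantity."""

    slope: float                       # cycles per log10 quantity
    intercept: float
    efficiency: float                  # 10^(-1/slope) - 1; 1.0 = perfect doubling
    r_squared: float
    quantities: Tuple[float, ...] = ()
    cts: Tuple[float, ...] = ()


def fit_standard_curve(
    points: Sequence[Tuple[float, float]]
) -> StandardCurve:
    """Least-squares fit of a dilution series of (quantity, Ct) points.

    Requires at least 3 points with non-degenerate quantities.
    """
    if len(points) < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    quantities = np.asarray([q for q, _ in points], dtype=float)
    cts = np.asarray([ct for _, ct in points], dtype=float)
    if np.any(quantities <= 0):
        raise ValueError("input quantities must be positive")
    log_q = np.log10(quantities)
    if np.ptp(log_q) == 0:
        raise ValueError("degenerate dilution series: all quantities equal")
    fit = stats.linregress(log_q, cts)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue ** 2),
        quantities=tuple(quantities),
        cts=tuple(cts),
    )


#: Slope of an ideal doubling-per-cycle chemistry.
PERFECT_SLOPE = -1.0 / math.log10(2.0)
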