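"""Gray relational analysis (GRA) between bioactivity and peak areas.

GRA scores the shape similarity between a reference series x0 (one
bioactivity indicator over batches) and each comparison series xi (one
common peak's areas over batches).  With pointwise deviations
Delta_i(k) = |x0(k) - xi(k)| and global extrema Dmin/Dmax over all series,
the relational coefficient is

    xi_i(k) = (Dmin + rho * Dmax) / (Delta_i(k) + rho * Dmax)

and the relational grade r_i is the mean of xi_i(k) over batches.  rho in
(0, 1) is the distinguishing coefficient, conventionally 0.5.  Grades lie in
(0, 1]; peaks whose grade exceeds a threshold (0.9 by convention in
spectrum-effect work) are flagged as contributors to the effect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .fingerprint import CommonPeakMatrix
from .panel import INDICATORS, ORIENTATION, BioactivityPanel

logger = logging.getLogger(__name__)

Normalization = Literal["mean", "minmax", "none"]


@dataclass(frozen=True)
class GraConfig:
    """GRA parameters.

    rho
        Distinguishing coefficient in (0, 1); 0.5 is the near-universal
        default and mostly rescales contrast between coefficients.
    normalization
        Per-series preprocessing: "mean" divides by the series mean (the
        common choice in spectrum-effect GRA, makes series dimensionless with
        mean 1), "minmax" maps to [0, 1], "none" uses raw values.
    orientation_handling
        "protection_score" flips lower-is-better indicators (LDH, ROS) about
        the model-group reference before analysis, so a high grade always
        reads "contributes to protection"; "raw" uses series as measured.
    """

    rho: float = 0.5
    normalization: Normalization = "mean"
    orientation_handling: Literal["protection_score", "raw"] = "protection_score"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ConfigError("rho must lie strictly between 0 and 1")
        if self.normalization not in ("mean", "minmax", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.orientation_handling not in ("protection_score", "raw"):
            raise ConfigError(f"unknown orientation_handling {self.orientation_handling!r}")


@dataclass
class GraResult:
    """Relational grades plus per-element diagnostics.

    grades: DataFrame [indicators x peaks].  coefficients: per indicator the
    peaks x batches xi matrix.  delta_min/delta_max: the global extrema used
    in the coefficient formula, per indicator.
    """

    grades: pd.DataFrame
    coefficients: dict[str, np.ndarray]
    delta_min: dict[str, float]
    delta_max: dict[str, float]
    config: GraConfig = field(default_factory=GraConfig)

    def __post_init__(self) -> None:
        g = self.grades.to_numpy(dtype=float)
        if g.size and (np.any(g <= 0) or np.any(g > 1 + 1e-12)):
            raise ValidationError("relational grades must lie in (0, 1]")


def normalize_series(series: np.ndarray, method: Normalization) -> np.ndarray:
    """Normalize one series for GRA comparison.

    mean: divide by the mean (requires nonzero mean); minmax: map onto
    [0, 1] (requires max > min); none: identity.
    """
    x = np.asarray(series, dtype=float)
    if method == "none":
        return x.copy()
    if method == "mean":
        mu = x.mean()
        if mu == 0:
            raise ValidationError("mean normalization undefined for zero-mean series")
        return x / mu
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise ValidationError("minmax normalization undefined for constant series")
        return (x - lo) / (hi - lo)
    raise ConfigError(f"unknown normalization {method!r}")


def relational_grade(
    ref: np.ndarray, comps: np.ndarray, config: GraConfig = GraConfig()
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Gray relational grades of comparison series against one reference.

    Parameters
    ----------
    ref
        Reference series, shape (batches,).
    comps
        Comparison series, shape (peaks, batches).  Normalization is applied
        to the reference and to each comparison independently.

    Returns
    -------
    (grades [peaks], xi coefficients [peaks x batches], delta_min, delta_max)
    """
    ref = np.asarray(ref, dtype=float)
    comps = np.atleast_2d(np.asarray(comps, dtype=float))
    if ref.ndim != 1 or comps.shape[1] != ref.size:
        raise ValidationError("ref and comparison series must share batch length")
    if ref.size < 2:
        raise ValidationError("GRA needs at least 2 batches")
    x0 = normalize_series(ref, config.normalization)
    xi_mat = np.vstack([normalize_series(c, config.normalization) for c in comps])
    delta = np.abs(xi_mat - x0[None, :])
    dmin = float(delta.min())
    dmax = float(delta.max())
    if dmax == 0.0:
        logger.warning("all comparison series identical to reference; grades set to 1.0")
        coeffs = np.ones_like(delta)
        return np.ones(comps.shape[0]), coeffs, dmin, dmax
    coeffs = (dmin + config.rho * dmax) / (delta + config.rho * dmax)
    return coeffs.mean(axis=1), coeffs, dmin, dmax


def gra_analysis(
    matrix: CommonPeakMatrix,
    panel: BioactivityPanel,
    config: GraConfig = GraConfig(),
) -> GraResult:
    """Run GRA of every indicator against every common peak.

    Each indicator is a reference series; each peak's area series is a
    comparison.  With ``protection_score`` handling, LDH and ROS are flipped
    about the model-group reference first (see
    :meth:`BioactivityPanel.protection_series`).
    """
    if not matrix.is_complete:
        raise ValidationError("GRA requires a complete common-peak matrix")
    if list(matrix.batch_ids) != panel.batch_ids:
        raise ValidationError("matrix and panel batch ids differ (order matters)")
    comps = matrix.areas.T  # peaks x batches
    grades_rows = {}
    coefficients = {}
    delta_min = {}
    delta_max = {}
    for ind in INDICATORS:
        if config.orientation_handling == "protection_score" and ORIENTATION[ind] < 0:
            ref = panel.protection_series(ind)
        else:
            ref = panel.series(ind)
        g, coeffs, dmin, dmax = relational_grade(ref, comps, config)
        grades_rows[ind] = g
        coefficients[ind] = coeffs
        delta_min[ind] = dmin
        delta_max[ind] = dmax
    grades = pd.DataFrame(grades_rows, index=matrix.peak_ids).T
    grades.index.name = "indicator"
    grades.columns.name = "peak_id"
    return GraResult(
        grades=grades,
        coefficients=coefficients,
        delta_min=delta_min,
        delta_max=delta_max,
        config=config,
    )


def gra_screen(result: GraResult, threshold: float = 0.9) -> set[tuple[str, int]]:
    """(indicator, peak) pairs whose grade strictly exceeds the threshold."""
    hits = set()
    for ind in result.grades.index:
        row = result.grades.loc[ind]
        for peak_id, grade in row.items():
            if grade > threshold:
                hits.add((str(ind), int(peak_id)))
    return hits
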