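"""Batch x indicator bioactivity panel.

Four indicators measured per extract batch on an oxygen-glucose-deprivation
(OGD) cardiomyocyte injury model: cell viability (MTT), LDH release, ATP
content and ROS level.  Viability and ATP point "up" (higher readout = more
protection); LDH and ROS point "down".  Orientation is carried as metadata so
raw assay values stay interpretable and every consumer must handle direction
explicitly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Canonical indicator order used throughout the package.
INDICATORS: tuple[str, ...] = ("viability", "ldh", "atp", "ros")

#: +1 = higher readout means more protection, -1 = less.
ORIENTATION: dict[str, int] = {"viability": 1, "ldh": -1, "atp": 1, "ros": -1}


@dataclass
class BioactivityPanel:
    """Per-batch bioactivity readouts.

    Parameters
    ----------
    values
        DataFrame indexed by batch id with exactly the columns
        ``("viability", "ldh", "atp", "ros")``, finite values.
    model_values
        Optional per-indicator readout of the injured model group (no
        extract).  Used as the reference level when converting
        lower-is-better indicators to protection scores; when absent the
        per-indicator series maximum is used instead.
    """

    values: pd.DataFrame
    model_values: Mapping[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != INDICATORS:
            raise ValidationError(
                f"panel columns must be {INDICATORS}, got {tuple(self.values.columns)}"
            )
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("panel contains non-finite indicator values")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate batch ids in panel")
        if self.model_values is not None:
            missing = [m for m in INDICATORS if m not in self.model_values]
            if missing:
                raise ValidationError(f"model_values missing indicators: {missing}")

    @property
    def batch_ids(self) -> list[str]:
        return [str(b) for b in self.values.index]

    @property
    def n_batches(self) -> int:
        return len(self.values)

    def series(self, indicator: str) -> np.ndarray:
        """Raw readout of one indicator across batches (panel order)."""
        return self.values[indicator].to_numpy(dtype=float)

    def protection_series(self, indicator: str) -> np.ndarray:
        """Series oriented so that larger = more protective.

        Higher-is-better indicators are returned as measured.  For
        lower-is-better indicators the series is flipped about the model-group
        reference: protection = reference - readout.
        """
        x = self.series(indicator)
        if ORIENTATION[indicator] > 0:
            return x
        ref = (
            float(self.model_values[indicator])
            if self.model_values is not None
            else float(x.max())
        )
        return ref - x

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.values.copy()
        df.insert(0, "batch_id", self.values.index)
        df.to_csv(path, index=False)
        if self.model_values is not None:
            sidecar = path.with_suffix(".model.json")
            sidecar.write_text(
                json.dumps({m: float(self.model_values[m]) for m in INDICATORS},
                           indent=2, sort_keys=True)
            )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "BioactivityPanel":
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - wrap any parser failure
            raise ParseError(f"cannot parse bioactivity panel {path}: {exc}") from exc
        required = ("batch_id",) + INDICATORS
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"panel {path} missing columns: {missing}")
        values = df.set_index("batch_id")[list(INDICATORS)].astype(float)
        model_values = None
        sidecar = path.with_suffix(".model.json")
        if sidecar.exists():
            model_values = {
                k: float(v) for k, v in json.loads(sidecar.read_text()).items()
            }
        return cls(values=values, model_values=model_values)
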