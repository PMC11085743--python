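"""Synthetic multi-batch fingerprint / bioactivity / binding generator.

Emulates the data regime of a spectrum-effect study on a steamed ginseng
extract: ~12 production batches profiled by HPLC (~36 common peaks), four
cell-injury indicators measured per batch (viability, LDH, ATP, ROS on an
OGD cardiomyocyte model), and a target-cell-extraction binding list that
contains the truly active constituents plus binding-only false positives
(17 bound, 7 active by default).

The planted truth is fully known, so every downstream stage of the screen
can be benchmarked for recovery.  Generation model:

* peak areas: lognormal per (batch, peak) - positive and right-skewed, the
  chromatographic convention - composed of a shared per-batch log-strength
  effect (batches differ in overall potency), a per-batch *active-family*
  effect shared by the planted actives (co-regulated constituents of one
  compound family rise and fall together across batches, which is exactly
  what makes their peaks track the bioactivity), and idiosyncratic per-peak
  variation.  Peak sizes are heterogeneous: per-peak log-mean offsets span
  about e^3 in content (fingerprints mix major constituents with trace
  peaks), the planted actives sit among the larger peaks (the nominated
  compounds of such screens are major constituents), and below-average-size
  peaks carry inflated relative variation (small-peak integration is
  noisier), which is what drives the global Delta_max in gray relational
  analysis;
* retention times: fixed peak positions plus per-batch Gaussian jitter;
* indicators: linear in the areas of the planted active peaks (positive
  coefficients for viability/ATP, negative for LDH/ROS) plus Gaussian assay
  noise; each active has one *primary* indicator it drives strongly and
  small secondary effects elsewhere (different constituents act through
  different mechanisms); intercepts are the injured-baseline readouts and
  are chosen large enough that every simulated readout is positive.

All randomness flows from ``SimConfig.seed`` through ``numpy``'s PCG64
``default_rng``; fixed seed means bit-identical output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingSet
from .errors import ConfigError, ValidationError
from .fingerprint import CommonPeakMatrix, PeakTable, write_peak_table
from .panel import INDICATORS, ORIENTATION, BioactivityPanel

#: Default planted actives (7 of 36), spread across the chromatogram.
DEFAULT_ACTIVE_PEAKS = frozenset({3, 8, 12, 17, 22, 28, 33})
#: Default binding-only false positives; with the actives: 17 bound peaks.
DEFAULT_BINDING_EXTRA = frozenset({2, 5, 10, 15, 19, 24, 27, 30, 34, 36})


def default_rt_base(n_peaks: int) -> np.ndarray:
    """Evenly spaced peak positions, 3 min apart from 8 min (145-min run)."""
    return 8.0 + 3.0 * np.arange(n_peaks, dtype=float)


def default_beta(
    n_peaks: int,
    active_peaks: frozenset[int],
    mean_areas: np.ndarray | None = None,
    base_area: float | None = None,
) -> np.ndarray:
    """Deterministic 4 x n_peaks effect matrix.

    Each active peak is assigned one primary indicator (round-robin over the
    sorted actives) on which it acts strongly and weak secondary effects on
    the other three - different constituents protect through different
    mechanisms, so each assay is dominated by a couple of compounds.
    Coefficients are scaled inversely to each peak's expected area (potency
    per unit area differs between compounds), so every active contributes a
    comparable signal to its primary indicator regardless of its content.
    Signs follow indicator orientation; zero on non-actives.
    """
    if mean_areas is None:
        mean_areas = np.ones(n_peaks)
    if base_area is None:
        base_area = float(np.exp(np.mean(np.log(mean_areas))))
    beta = np.zeros((len(INDICATORS), n_peaks))
    for k, j in enumerate(sorted(active_peaks)):
        primary = k % len(INDICATORS)
        scale = base_area / float(mean_areas[j - 1])
        for m, ind in enumerate(INDICATORS):
            beta[m, j - 1] = ORIENTATION[ind] * (2.0 if m == primary else 0.3) * scale
    return beta


def default_size_offsets(n_peaks: int, active_peaks: frozenset[int], spread: float) -> np.ndarray:
    """Per-peak log-mean size offsets, evenly spaced over [-spread, +spread].

    The planted actives take alternating slots among the largest size ranks
    (screens of this kind nominate major constituents); the remaining ranks
    go to the other peaks in id order, so trace-level peaks are all
    non-active.
    """
    if n_peaks == 1:
        return np.zeros(1)
    ranks = np.empty(n_peaks, dtype=int)
    actives = sorted(active_peaks)
    top = [n_peaks - 1 - 2 * k for k in range(len(actives))]
    if top and top[-1] < 0:
        raise ConfigError("too many active peaks for the default size layout")
    used = set(top)
    rest = [r for r in range(n_peaks) if r not in used]
    for j, r in zip(actives, top):
        ranks[j - 1] = r
    others = [j for j in range(1, n_peaks + 1) if j not in active_peaks]
    for j, r in zip(others, rest):
        ranks[j - 1] = r
    return -spread + 2.0 * spread * ranks / (n_peaks - 1)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the regime of the emulated study: 12 batches x 36 common
    peaks, 7 planted actives inside a 17-peak binding set.  ``area_log_mean``
    and ``area_log_sd`` may be scalars (expanded with the default size-offset
    and trace-inflation layout) or per-peak vectors.  ``noise_sd`` is the
    assay noise on the indicator readout scale.
    """

    n_batches: int = 12
    n_peaks: int = 36
    active_peaks: frozenset[int] = DEFAULT_ACTIVE_PEAKS
    binding_peaks: frozenset[int] = frozenset(DEFAULT_ACTIVE_PEAKS | DEFAULT_BINDING_EXTRA)
    beta: np.ndarray | None = None
    area_log_mean: float | np.ndarray = 6.0
    area_log_sd: float | np.ndarray = 0.12
    batch_log_sd: float = 0.1
    active_log_sd: float = 0.3
    size_spread: float = 1.5
    trace_sd_factor: float = 6.0
    noise_sd: float = 120.0
    rt_base: np.ndarray | None = None
    rt_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 3:
            raise ConfigError("n_batches must be >= 3")
        if self.n_peaks < 1:
            raise ConfigError("n_peaks must be >= 1")
        peaks = set(range(1, self.n_peaks + 1))
        object.__setattr__(self, "active_peaks", frozenset(int(j) for j in self.active_peaks))
        object.__setattr__(self, "binding_peaks", frozenset(int(j) for j in self.binding_peaks))
        if not self.active_peaks <= self.binding_peaks:
            raise ConfigError("active_peaks must be a subset of binding_peaks")
        if not self.binding_peaks <= peaks:
            raise ConfigError(f"binding_peaks must lie in 1..{self.n_peaks}")
        for name in ("batch_log_sd", "active_log_sd", "rt_jitter_sd", "noise_sd", "size_spread"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.trace_sd_factor < 1:
            raise ConfigError("trace_sd_factor must be >= 1")
        # Expand scalar lognormal parameters into per-peak vectors.
        if np.ndim(self.area_log_mean) == 0:
            offsets = default_size_offsets(self.n_peaks, self.active_peaks, self.size_spread)
            log_means = float(self.area_log_mean) + offsets
        else:
            log_means = np.asarray(self.area_log_mean, dtype=float)
            offsets = log_means - log_means.mean()
        if log_means.shape != (self.n_peaks,):
            raise ConfigError(f"area_log_mean vector must have length {self.n_peaks}")
        if np.ndim(self.area_log_sd) == 0:
            if self.area_log_sd < 0:
                raise ConfigError("area_log_sd must be >= 0")
            # below-average-size peaks get inflated relative noise, scaling up
            # to trace_sd_factor x for the smallest (integration noise)
            span = max(float(-offsets.min()), 1e-12)
            infl = 1.0 + (self.trace_sd_factor - 1.0) * np.maximum(0.0, -offsets) / span
            log_sds = float(self.area_log_sd) * infl
        else:
            log_sds = np.asarray(self.area_log_sd, dtype=float)
        if log_sds.shape != (self.n_peaks,):
            raise ConfigError(f"area_log_sd vector must have length {self.n_peaks}")
        if np.any(log_sds < 0):
            raise ConfigError("area_log_sd must be >= 0")
        object.__setattr__(self, "peak_log_means", log_means)
        object.__setattr__(self, "peak_log_sds", log_sds)
        if self.beta is not None:
            beta = self.beta
        else:
            total_var = log_sds**2 + self.batch_log_sd**2
            for j in self.active_peaks:
                total_var[j - 1] += self.active_log_sd**2
            mean_areas = np.exp(log_means + 0.5 * total_var)
            base = float(np.exp(np.mean(log_means)))
            beta = default_beta(self.n_peaks, self.active_peaks, mean_areas, base)
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (len(INDICATORS), self.n_peaks):
            raise ConfigError(
                f"beta must have shape {(len(INDICATORS), self.n_peaks)}, got {beta.shape}"
            )
        inactive = np.array([j - 1 for j in sorted(peaks - self.active_peaks)], dtype=int)
        if inactive.size and np.any(beta[:, inactive] != 0):
            raise ConfigError("beta must be exactly 0 on non-active peaks")
        for m, ind in enumerate(INDICATORS):
            sign = ORIENTATION[ind]
            active = [j - 1 for j in sorted(self.active_peaks)]
            if np.any(sign * beta[m, active] < 0):
                raise ConfigError(f"beta row for {ind} must have sign {sign:+d} on active peaks")
        object.__setattr__(self, "beta", beta)
        rt = self.rt_base if self.rt_base is not None else default_rt_base(self.n_peaks)
        rt = np.asarray(rt, dtype=float)
        if rt.shape != (self.n_peaks,):
            raise ConfigError(f"rt_base must have length {self.n_peaks}")
        if np.any(np.diff(rt) <= 0):
            raise ConfigError("rt_base must be strictly increasing")
        object.__setattr__(self, "rt_base", rt)

    @property
    def intercepts(self) -> np.ndarray:
        """Injured-baseline readout per indicator; keeps all readouts positive.

        For lower-is-better indicators the linear peak term is subtractive, so
        the baseline is set at three times the expected magnitude of that
        term; for higher-is-better indicators a modest positive floor is used.
        """
        total_var = self.peak_log_sds**2 + self.batch_log_sd**2
        total_var = total_var.copy()
        for j in self.active_peaks:
            total_var[j - 1] += self.active_log_sd**2
        mean_areas = np.exp(self.peak_log_means + 0.5 * total_var)
        out = np.empty(len(INDICATORS))
        for m, ind in enumerate(INDICATORS):
            if ORIENTATION[ind] > 0:
                out[m] = 50.0
            else:
                out[m] = 3.0 * float(np.abs(self.beta[m]) @ mean_areas)
        return out


@dataclass
class GroundTruth:
    """Planted truth of one simulated dataset."""

    active_peaks: frozenset[int]
    binding_peaks: frozenset[int]
    beta: np.ndarray
    intercepts: np.ndarray
    rt_base: np.ndarray
    areas: np.ndarray  # batches x peaks, the realized (noise-free) areas
    expected_indicators: pd.DataFrame  # batches x 4, before assay noise
    batch_ids: list[str] = field(default_factory=list)

    @property
    def model_values(self) -> dict[str, float]:
        """Zero-extract (model group) readout per indicator = intercept."""
        return {ind: float(self.intercepts[m]) for m, ind in enumerate(INDICATORS)}

    def labels(self) -> dict[int, int]:
        """Per-peak binary activity label (1 = active) keyed by peak id."""
        n = self.beta.shape[1]
        return {j: int(j in self.active_peaks) for j in range(1, n + 1)}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "active_peaks": sorted(self.active_peaks),
            "binding_peaks": sorted(self.binding_peaks),
            "beta": self.beta.tolist(),
            "intercepts": self.intercepts.tolist(),
            "rt_base": self.rt_base.tolist(),
            "areas": self.areas.tolist(),
            "expected_indicators": self.expected_indicators.to_dict(orient="list"),
            "batch_ids": self.batch_ids,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            active_peaks=frozenset(d["active_peaks"]),
            binding_peaks=frozenset(d["binding_peaks"]),
            beta=np.asarray(d["beta"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            rt_base=np.asarray(d["rt_base"], dtype=float),
            areas=np.asarray(d["areas"], dtype=float),
            expected_indicators=pd.DataFrame(
                d["expected_indicators"], index=d["batch_ids"]
            )[list(INDICATORS)],
            batch_ids=list(d["batch_ids"]),
        )


def _batch_ids(n: int) -> list[str]:
    return [f"B{i + 1:02d}" for i in range(n)]


def simulate_fingerprints(config: SimConfig) -> tuple[list[PeakTable], GroundTruth]:
    """Draw per-batch peak tables and the associated ground truth.

    Log-areas are mu_j + b_i + a_i*1[j active] + eps_ij with a shared
    per-batch strength effect b_i ~ N(0, batch_log_sd), an active-family
    effect a_i ~ N(0, active_log_sd) common to the planted actives, and
    idiosyncratic eps_ij ~ N(0, sd_j); RTs are ``rt_base`` plus
    N(0, rt_jitter_sd) jitter per (batch, peak).  The noise-free expected
    indicator values are computed here so the truth is self-contained.
    """
    rng = np.random.default_rng(config.seed)
    B, P = config.n_batches, config.n_peaks
    batch_effect = (
        rng.normal(0.0, config.batch_log_sd, size=B)
        if config.batch_log_sd > 0
        else np.zeros(B)
    )
    family_effect = (
        rng.normal(0.0, config.active_log_sd, size=B)
        if config.active_log_sd > 0
        else np.zeros(B)
    )
    eps = rng.normal(0.0, 1.0, size=(B, P)) * config.peak_log_sds[None, :]
    log_areas = config.peak_log_means[None, :] + batch_effect[:, None] + eps
    for j in config.active_peaks:
        log_areas[:, j - 1] += family_effect
    areas = np.exp(log_areas)
    jitter = rng.normal(0.0, config.rt_jitter_sd, size=(B, P)) if config.rt_jitter_sd > 0 else np.zeros((B, P))
    batch_ids = _batch_ids(B)
    tables = [
        PeakTable(batch_id=b, rt=config.rt_base + jitter[i], area=areas[i])
        for i, b in enumerate(batch_ids)
    ]
    expected = pd.DataFrame(
        config.intercepts[None, :] + areas @ config.beta.T,
        index=batch_ids,
        columns=list(INDICATORS),
    )
    truth = GroundTruth(
        active_peaks=config.active_peaks,
        binding_peaks=config.binding_peaks,
        beta=config.beta.copy(),
        intercepts=config.intercepts,
        rt_base=config.rt_base.copy(),
        areas=areas,
        expected_indicators=expected,
        batch_ids=batch_ids,
    )
    return tables, truth


def simulate_bioactivity(
    areas: CommonPeakMatrix | np.ndarray, config: SimConfig
) -> BioactivityPanel:
    """Indicator panel = intercept + areas @ beta' + N(0, noise_sd).

    Accepts the generated area matrix (or a recovered CommonPeakMatrix); the
    noise stream is seeded independently of the fingerprint stream so the
    same config always yields the same panel.
    """
    if isinstance(areas, CommonPeakMatrix):
        if not areas.is_complete:
            raise ValidationError("bioactivity simulation requires a complete area matrix")
        batch_ids = list(areas.batch_ids)
        A = areas.areas
    else:
        A = np.asarray(areas, dtype=float)
        batch_ids = _batch_ids(A.shape[0])
    if A.ndim != 2 or A.shape[1] != config.beta.shape[1]:
        raise ValidationError(
            f"area matrix has {A.shape[1] if A.ndim == 2 else '?'} peaks, "
            f"beta expects {config.beta.shape[1]}"
        )
    rng = np.random.default_rng([config.seed, 1])
    values = config.intercepts[None, :] + A @ config.beta.T
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    df = pd.DataFrame(values, index=batch_ids, columns=list(INDICATORS))
    truth_models = {ind: float(config.intercepts[m]) for m, ind in enumerate(INDICATORS)}
    return BioactivityPanel(values=df, model_values=truth_models)


def simulate_binding(truth: GroundTruth, config: SimConfig) -> BindingSet:
    """The target-cell-extraction result: the configured binding peaks."""
    return BindingSet(peak_ids=frozenset(truth.binding_peaks))


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[PeakTable], BioactivityPanel, BindingSet, GroundTruth]:
    """Convenience wrapper: fingerprints + panel + binding list + truth."""
    tables, truth = simulate_fingerprints(config)
    panel = simulate_bioactivity(truth.areas, config)
    binding = simulate_binding(truth, config)
    return tables, panel, binding, truth


def write_dataset(
    config: SimConfig, out_dir: str | Path
) -> dict[str, Path | list[Path]]:
    """Write a full synthetic dataset as plain-text files.

    Layout: ``peaks/<batch>.csv`` peak tables, ``bioactivity.csv`` (+ model
    sidecar), ``binding.csv``, ``ground_truth.json``.
    """
    out = Path(out_dir)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    tables, panel, binding, truth = simulate_dataset(config)
    peak_paths = [write_peak_table(t, peaks_dir / f"{t.batch_id}.csv") for t in tables]
    panel_path = panel.to_csv(out / "bioactivity.csv")
    binding_path = binding.to_csv(out / "binding.csv")
    truth_path = truth.to_json(out / "ground_truth.json")
    return {
        "peaks": peak_paths,
        "bioactivity": panel_path,
        "binding": binding_path,
        "ground_truth": truth_path,
    }
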