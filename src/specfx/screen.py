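"""Full screening decision: spectrum-effect hits -> binding -> content -> BPNN.

The screen nominates candidate bioactive peaks by combining four evidence
streams in a fixed order:

1. spectrum-effect hits: a peak passes if its GRA grade exceeds the GRA
   threshold for at least ``min_indicator_hits`` indicators, or its VIP does
   likewise (union of methods by default - each method alone is known to
   miss true actives);
2. binding intersection: candidates must appear in the target-cell binding
   set (binding shows interaction, the spectrum link shows effect);
3. low-content exclusion: peaks below a minimum mean relative area are
   dropped (trace constituents are impractical leads);
4. BP neural-network classification over the assembled per-peak features,
   keeping only peaks classified as active.

Every peak receives a decision trace naming the rules that fired, so the
final candidate list is fully auditable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bpnn as bpnn_mod
from .binding import BindingSet, intersect_hits
from .bpnn import BpnnConfig
from .errors import ConfigError, PipelineError, ValidationError
from .fingerprint import (
    CommonPeakMatrix,
    MatchConfig,
    PeakTable,
    match_common_peaks,
    relative_content,
)
from .gra import GraConfig, gra_analysis, gra_screen
from .panel import INDICATORS, BioactivityPanel
from .pls import PlsConfig, pls_analysis, vip_screen

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Decision thresholds and switches of the screening cascade."""

    gra_threshold: float = 0.9
    vip_threshold: float = 1.0
    min_indicator_hits: int = 1
    combine_methods: Literal["union", "intersection"] = "union"
    content_min: float = 0.005
    require_binding: bool = True
    use_bpnn: bool = True

    def __post_init__(self) -> None:
        if self.gra_threshold < 0 or self.vip_threshold < 0:
            raise ConfigError("thresholds must be >= 0")
        if not 0.0 <= self.content_min < 1.0:
            raise ConfigError("content_min must lie in [0, 1)")
        if self.min_indicator_hits < 1:
            raise ConfigError("min_indicator_hits must be >= 1")
        if self.combine_methods not in ("union", "intersection"):
            raise ConfigError(f"unknown combine_methods {self.combine_methods!r}")


def spectrum_effect_hits(
    gra_hits: Iterable[tuple[str, int]],
    vip_hits: Iterable[tuple[str, int]],
    config: ScreenConfig = ScreenConfig(),
) -> frozenset[int]:
    """Combine per-indicator GRA and VIP hits into a peak-level hit set.

    Under "union" a peak passes if either method supports it on at least
    ``min_indicator_hits`` indicators; under "intersection" both methods
    must.
    """
    def counts(hits: Iterable[tuple[str, int]]) -> dict[int, int]:
        c: dict[int, int] = {}
        for _ind, j in hits:
            c[int(j)] = c.get(int(j), 0) + 1
        return c

    k = config.min_indicator_hits
    g = {j for j, c in counts(gra_hits).items() if c >= k}
    v = {j for j, c in counts(vip_hits).items() if c >= k}
    return frozenset(g | v if config.combine_methods == "union" else g & v)


def _jsonable(obj):
    """Recursively strip numpy scalar types (and NaN) for JSON round trips."""
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class CandidateReport:
    """Per-peak decision trace plus the final nominated candidate set."""

    peaks: pd.DataFrame
    candidates: list[int]
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "candidates": [int(j) for j in self.candidates],
            "peaks": _jsonable(self.peaks.to_dict(orient="records")),
            "metadata": _jsonable(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CandidateReport":
        peaks = pd.DataFrame(d["peaks"])
        return cls(peaks=peaks, candidates=[int(j) for j in d["candidates"]],
                   metadata=dict(d["metadata"]))


def _config_hash(meta: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    tables: Sequence[PeakTable],
    panel: BioactivityPanel,
    binding: BindingSet | None = None,
    labels: Mapping[int, int] | None = None,
    *,
    screen_config: ScreenConfig = ScreenConfig(),
    match_config: MatchConfig = MatchConfig(),
    gra_config: GraConfig = GraConfig(),
    pls_config: PlsConfig = PlsConfig(),
    bpnn_config: BpnnConfig = BpnnConfig(),
) -> CandidateReport:
    """Execute the whole screen and return the per-peak decision trace.

    ``labels`` (peak id -> 1 active / 0 inactive) are the classifier's
    training labels: planted truth in a synthetic run, literature-verified
    assignments in a real one.  Required when ``use_bpnn`` is on.
    """
    cfg = screen_config

    def stage(name: str, fn):
        try:
            out = fn()
            logger.info("stage %s done", name)
            return out
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(name, exc) from exc

    matrix: CommonPeakMatrix = stage(
        "fingerprint", lambda: match_common_peaks(tables, match_config)
    )
    if matrix.n_peaks == 0:
        raise PipelineError("fingerprint", ValidationError("no common peaks found"))
    content = stage("content", lambda: relative_content(matrix))
    gra_res = stage("gra", lambda: gra_analysis(matrix, panel, gra_config))
    _models, vips = stage("pls", lambda: pls_analysis(matrix, panel, pls_config))

    gra_hits = gra_screen(gra_res, cfg.gra_threshold)
    vip_hits = vip_screen(vips, cfg.vip_threshold)
    spectrum = spectrum_effect_hits(gra_hits, vip_hits, cfg)

    if cfg.require_binding:
        if binding is None:
            raise PipelineError(
                "binding", ValidationError("require_binding=True but no binding set given")
            )
        unknown = sorted(binding.peak_ids - set(matrix.peak_ids))
        if unknown:
            raise PipelineError(
                "binding", ValidationError(f"binding set names unknown peaks: {unknown}")
            )
        after_binding = intersect_hits(spectrum, binding)
    else:
        after_binding = frozenset(spectrum)

    content_by_peak = {j: float(c) for j, c in zip(matrix.peak_ids, content)}
    after_content = frozenset(
        j for j in after_binding if content_by_peak[j] >= cfg.content_min
    )

    bpnn_class: dict[int, str] = {}
    bpnn_score: dict[int, float] = {}
    bpnn_eval = None
    if cfg.use_bpnn:
        if labels is None:
            raise PipelineError(
                "bpnn", ValidationError("use_bpnn=True requires per-peak training labels")
            )
        missing = [j for j in matrix.peak_ids if j not in labels]
        if missing:
            raise PipelineError(
                "bpnn", ValidationError(f"labels missing for peaks {missing}")
            )
        feats = stage(
            "bpnn",
            lambda: bpnn_mod.assemble_features(
                gra_res, vips, binding or BindingSet(frozenset()), content,
                peak_ids=matrix.peak_ids,
            ),
        )
        y = [labels[j] for j in matrix.peak_ids]
        model = stage("bpnn", lambda: bpnn_mod.train(feats, y, bpnn_config))
        proba = bpnn_mod.predict_proba(model, feats)
        classes = bpnn_mod.predict_class(model, feats)
        bpnn_score = {j: float(p) for j, p in zip(matrix.peak_ids, proba)}
        bpnn_class = {j: str(c) for j, c in zip(matrix.peak_ids, classes)}
        bpnn_eval = bpnn_mod.evaluate(model, feats, y)
        final = frozenset(j for j in after_content if bpnn_class[j] == bpnn_mod.CLASS_A)
    else:
        final = after_content

    # ------------------------------------------------------------- trace
    rows = []
    gra_by_peak: dict[int, list[str]] = {}
    for ind, j in sorted(gra_hits):
        gra_by_peak.setdefault(j, []).append(ind)
    vip_by_peak: dict[int, list[str]] = {}
    for ind, j in sorted(vip_hits):
        vip_by_peak.setdefault(j, []).append(ind)
    for i, j in enumerate(matrix.peak_ids):
        rules: list[str] = []
        rules += [f"gra_hit:{m}" for m in gra_by_peak.get(j, [])]
        rules += [f"vip_hit:{m}" for m in vip_by_peak.get(j, [])]
        if j in spectrum:
            rules.append("spectrum_hit")
        if cfg.require_binding:
            rules.append("binding" if j in (binding or BindingSet(frozenset())) else "not_bound")
        if j in after_binding:
            if content_by_peak[j] >= cfg.content_min:
                rules.append("content_pass")
            else:
                rules.append("content_filtered")
        if cfg.use_bpnn:
            rules.append(f"bpnn:{bpnn_class[j]}")
        if j in final:
            rules.append("selected")
        row = {
            "peak_id": int(j),
            "consensus_rt": float(matrix.consensus_rt[i]),
            **{f"gra_{m}": float(gra_res.grades.loc[m, j]) for m in INDICATORS},
            **{
                f"vip_{m}": float(vips[m].vip[list(matrix.peak_ids).index(j)])
                for m in INDICATORS
            },
            "n_gra_hits": len(gra_by_peak.get(j, [])),
            "n_vip_hits": len(vip_by_peak.get(j, [])),
            "spectrum_hit": j in spectrum,
            "binding": (j in binding) if binding is not None else None,
            "relative_content": content_by_peak[j],
            "bpnn_score": bpnn_score.get(j),
            "bpnn_class": bpnn_class.get(j),
            "selected": j in final,
            "rules": rules,
        }
        rows.append(row)

    meta_cfg = {
        "screen": asdict(cfg),
        "match": asdict(match_config),
        "gra": asdict(gra_config),
        "pls": asdict(pls_config),
        "bpnn": asdict(bpnn_config) if cfg.use_bpnn else None,
    }
    metadata = {
        "config": meta_cfg,
        "config_hash": _config_hash(meta_cfg),
        "seed": bpnn_config.seed if cfg.use_bpnn else None,
        "n_batches": matrix.n_batches,
        "n_common_peaks": matrix.n_peaks,
        "n_spectrum_hits": len(spectrum),
        "n_after_binding": len(after_binding),
        "n_after_content": len(after_content),
        "bpnn_training_accuracy": bpnn_eval.accuracy if bpnn_eval else None,
    }
    return CandidateReport(
        peaks=pd.DataFrame(rows), candidates=sorted(final), metadata=metadata
    )


# ------------------------------------------------------------------ report IO
def write_report(report: CandidateReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as JSON (machine), CSV (table) and markdown (summary)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    csv_path = out / "report.csv"
    flat = report.peaks.copy()
    flat["rules"] = flat["rules"].map(";".join)
    flat.to_csv(csv_path, index=False)
    md_path = out / "report.md"
    md = [
        "# Screening report",
        "",
        f"- common peaks: {report.metadata['n_common_peaks']}"
        f" across {report.metadata['n_batches']} batches",
        f"- spectrum-effect hits: {report.metadata['n_spectrum_hits']}",
        f"- after binding intersection: {report.metadata['n_after_binding']}",
        f"- after content filter: {report.metadata['n_after_content']}",
        f"- final candidates: {len(report.candidates)} -> {report.candidates}",
        f"- config hash: {report.metadata['config_hash']}",
        "",
    ]
    md_path.write_text("\n".join(md))
    return {"json": json_path, "csv": csv_path, "md": md_path}


def read_report(json_path: str | Path) -> CandidateReport:
    return CandidateReport.from_dict(json.loads(Path(json_path).read_text()))
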