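"""Chromatographic fingerprints: peak tables, common-peak matching, content.

A per-batch HPLC peak table lists (retention time, area) pairs.  Peaks that
occur in every batch within a retention-time (RT) tolerance are "common
peaks"; stacking their areas over batches gives the common-peak matrix that
all spectrum-effect modelling downstream consumes.  Matching here is RT-only
(real studies corroborate with UV spectra; that is a documented limitation).
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError

PEAK_TABLE_COLUMNS = ("batch_id", "rt_min", "area")


@dataclass
class PeakTable:
    """Peaks of one batch, sorted by retention time.

    ``rt`` in minutes, ``area`` in arbitrary detector units (> 0).
    """

    batch_id: str
    rt: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.rt.shape != self.area.shape or self.rt.ndim != 1:
            raise ValidationError("rt and area must be 1-D arrays of equal length")
        order = np.argsort(self.rt, kind="stable")
        self.rt = self.rt[order]
        self.area = self.area[order]
        if self.n_peaks and not np.all(self.area > 0):
            raise ValidationError(f"batch {self.batch_id!r}: non-positive peak area")
        if self.n_peaks and not np.all(np.isfinite(self.rt)):
            raise ValidationError(f"batch {self.batch_id!r}: non-finite retention time")

    @property
    def n_peaks(self) -> int:
        return int(self.rt.size)


@dataclass(frozen=True)
class MatchConfig:
    """Common-peak matching parameters.

    rt_tolerance
        Maximum |RT - cluster consensus RT| (minutes) for a peak to join a
        cluster.  The matching tolerance of published fingerprint studies is
        rarely reported, so it is an explicit parameter here.
    require_all_batches
        If True (the definition of a *common* peak) a cluster must have a
        member in every batch.
    """

    rt_tolerance: float = 0.5
    require_all_batches: bool = True

    def __post_init__(self) -> None:
        if self.rt_tolerance < 0:
            raise ConfigError("rt_tolerance must be >= 0")


@dataclass
class CommonPeakMatrix:
    """Batches x common peaks area matrix.

    Peaks are numbered 1..P in order of consensus retention time (the field
    convention for fingerprint peak numbering).  When built with
    ``require_all_batches=True`` (the definition of a common peak) the matrix
    is complete; with the relaxed setting, absent peaks are NaN and
    downstream modelling refuses the matrix until it is filtered.
    """

    batch_ids: list[str]
    peak_ids: list[int]
    consensus_rt: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.consensus_rt = np.asarray(self.consensus_rt, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        B, P = len(self.batch_ids), len(self.peak_ids)
        if self.areas.shape != (B, P):
            raise ValidationError(
                f"areas shape {self.areas.shape} does not match {B} batches x {P} peaks"
            )
        if self.consensus_rt.shape != (P,):
            raise ValidationError("consensus_rt length must equal number of peaks")
        if P and not np.all(np.diff(self.consensus_rt) > 0):
            raise ValidationError("consensus retention times must be strictly increasing")
        present = ~np.isnan(self.areas)
        if P and not np.all(self.areas[present] > 0):
            raise ValidationError("common-peak areas must be strictly positive")

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.areas))

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.areas,
            index=pd.Index(self.batch_ids, name="batch_id"),
            columns=[f"peak_{j}" for j in self.peak_ids],
        )

    def to_csv(self, path: str | Path) -> Path:
        """Wide CSV (batch rows x peak columns) + JSON sidecar of consensus RTs."""
        path = Path(path)
        self.to_frame().to_csv(path)
        sidecar = path.with_suffix(".rt.json")
        sidecar.write_text(
            json.dumps(
                {str(j): float(rt) for j, rt in zip(self.peak_ids, self.consensus_rt)},
                indent=2,
            )
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommonPeakMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="batch_id")
        peak_ids = [int(c.removeprefix("peak_")) for c in df.columns]
        sidecar = path.with_suffix(".rt.json")
        if sidecar.exists():
            rt_map = {int(k): float(v) for k, v in json.loads(sidecar.read_text()).items()}
            consensus = np.array([rt_map[j] for j in peak_ids])
        else:
            consensus = np.arange(1, len(peak_ids) + 1, dtype=float)
        return cls(
            batch_ids=[str(b) for b in df.index],
            peak_ids=peak_ids,
            consensus_rt=consensus,
            areas=df.to_numpy(dtype=float),
        )


# --------------------------------------------------------------------- IO
def read_peak_table(path: str | Path) -> PeakTable:
    """Read one batch's peak table from CSV (batch_id, rt_min, area).

    An empty file yields an empty table whose batch id is the file stem.
    Malformed rows raise :class:`ParseError` naming the line; non-positive
    areas raise :class:`ValidationError`.
    """
    path = Path(path)
    rows: list[tuple[str, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:3]] == list(PEAK_TABLE_COLUMNS):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                rows.append((row[0].strip(), float(row[1]), float(row[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return PeakTable(batch_id=path.stem, rt=np.empty(0), area=np.empty(0))
    batch_ids = {r[0] for r in rows}
    if len(batch_ids) != 1:
        raise ParseError(f"{path}: more than one batch id in file: {sorted(batch_ids)}")
    rt = np.array([r[1] for r in rows])
    area = np.array([r[2] for r in rows])
    if np.any(area <= 0):
        bad = int(np.flatnonzero(area <= 0)[0])
        raise ValidationError(f"{path}: non-positive area {area[bad]} at rt {rt[bad]}")
    return PeakTable(batch_id=batch_ids.pop(), rt=rt, area=area)


def write_peak_table(table: PeakTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAK_TABLE_COLUMNS)
        for rt, area in zip(table.rt, table.area):
            writer.writerow([table.batch_id, repr(float(rt)), repr(float(area))])
    return path


def read_peak_tables(directory: str | Path, pattern: str = "*.csv") -> list[PeakTable]:
    """Read every peak-table CSV in a directory (sorted by file name)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise ParseError(f"no peak tables matching {pattern!r} in {directory}")
    return [read_peak_table(p) for p in paths]


# --------------------------------------------------------------- matching
def _assign_batch(
    table: PeakTable, consensus: np.ndarray, tol: float
) -> dict[int, int]:
    """Greedy nearest-RT assignment of one batch's peaks to clusters.

    Candidate (cluster, peak) pairs within tolerance are accepted in order of
    increasing |dRT|, ties broken toward the earlier-eluting peak then the
    earlier cluster; each cluster takes at most one peak and each peak joins
    at most one cluster.  Returns {cluster index: peak index}.
    """
    cands: list[tuple[float, float, int, int]] = []
    for c, crt in enumerate(consensus):
        d = np.abs(table.rt - crt)
        for p in np.flatnonzero(d <= tol):
            cands.append((float(d[p]), float(table.rt[p]), c, int(p)))
    cands.sort()
    taken_c: set[int] = set()
    taken_p: set[int] = set()
    out: dict[int, int] = {}
    for _, _, c, p in cands:
        if c in taken_c or p in taken_p:
            continue
        out[c] = p
        taken_c.add(c)
        taken_p.add(p)
    return out


def match_common_peaks(
    tables: Sequence[PeakTable], config: MatchConfig = MatchConfig()
) -> CommonPeakMatrix:
    """Cluster peaks across batches by RT and build the common-peak matrix.

    Clusters are seeded at the peak RTs of the reference batch (the one with
    the most peaks; ties -> lexicographically first batch id).  Two
    assignment passes are made: first against the seed RTs, then against the
    consensus means of the first pass.  Clusters represented in every batch
    (when ``require_all_batches``) become common peaks, numbered by consensus
    RT.
    """
    if not tables:
        raise ValidationError("match_common_peaks requires at least one peak table")
    ids = [t.batch_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate batch ids among peak tables")
    tol = config.rt_tolerance
    reference = min(tables, key=lambda t: (-t.n_peaks, t.batch_id))
    consensus = reference.rt.copy()
    ordered = sorted(tables, key=lambda t: t.batch_id)

    members: dict[int, dict[str, int]] = {}
    for _pass in range(2):
        members = {c: {} for c in range(consensus.size)}
        for t in ordered:
            for c, p in _assign_batch(t, consensus, tol).items():
                members[c][t.batch_id] = p
        by_batch = {t.batch_id: t for t in tables}
        consensus = np.array(
            [
                np.mean([by_batch[b].rt[p] for b, p in mem.items()])
                if mem
                else consensus[c]
                for c, mem in members.items()
            ]
        )

    # Final consistency: drop members that drifted beyond tolerance of the
    # final consensus mean (possible only with overlapping clusters).
    by_batch = {t.batch_id: t for t in tables}
    for c, mem in members.items():
        for b in [b for b, p in mem.items() if abs(by_batch[b].rt[p] - consensus[c]) > tol]:
            del mem[b]

    need = len(tables) if config.require_all_batches else 1
    kept = [c for c, mem in members.items() if len(mem) >= need]
    kept.sort(key=lambda c: consensus[c])

    batch_order = [t.batch_id for t in ordered]
    if not kept:
        return CommonPeakMatrix(
            batch_ids=batch_order, peak_ids=[], consensus_rt=np.empty(0),
            areas=np.empty((len(batch_order), 0)),
        )
    areas = np.array(
        [
            [
                by_batch[b].area[members[c][b]] if b in members[c] else np.nan
                for c in kept
            ]
            for b in batch_order
        ]
    )
    return CommonPeakMatrix(
        batch_ids=batch_order,
        peak_ids=list(range(1, len(kept) + 1)),
        consensus_rt=consensus[kept],
        areas=areas,
    )


def relative_content(matrix: CommonPeakMatrix) -> np.ndarray:
    """Mean (over batches) share of each peak in its batch's total area.

    Entries sum to 1 up to floating tolerance; this is the "relative content"
    used by the low-content exclusion in the screening stage.
    """
    if not matrix.is_complete:
        raise ValidationError("relative_content requires a complete common-peak matrix")
    row_tot = matrix.areas.sum(axis=1, keepdims=True)
    return (matrix.areas / row_tot).mean(axis=0)
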