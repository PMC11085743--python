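"""Target-cell-extraction binding set and its intersection with hits.

Incubating an extract with living cells, washing away unbound material and
identifying the cell-associated compounds yields a *binding set*: peaks whose
compounds physically associate with the target cells.  Binding indicates
interaction, not activity, so the screen intersects it with the
spectrum-effect hits.  The wet-lab extraction itself is outside this
package; the set is consumed as a given list.
"""
from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .fingerprint import CommonPeakMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSet:
    """Common-peak ids detected as cell-bound, with optional compound names."""

    peak_ids: frozenset[int]
    names: Mapping[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_ids", frozenset(int(j) for j in self.peak_ids))
        if self.names is not None:
            unknown = set(self.names) - set(self.peak_ids)
            if unknown:
                raise ValidationError(f"names given for peaks not in the set: {sorted(unknown)}")

    def __contains__(self, peak_id: int) -> bool:
        return int(peak_id) in self.peak_ids

    def __len__(self) -> int:
        return len(self.peak_ids)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["peak_id", "name"])
            for j in sorted(self.peak_ids):
                writer.writerow([j, (self.names or {}).get(j, "")])
        return path


def load_binding_set(path: str | Path, matrix: "CommonPeakMatrix") -> BindingSet:
    """Read a binding list (one peak id per row, optional name column).

    Ids are validated against the common-peak matrix; unknown ids raise a
    :class:`ValidationError` listing them.  An empty file yields an empty set
    with a warning.
    """
    path = Path(path)
    ids: list[int] = []
    names: dict[int, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and row[0].strip().lower() == "peak_id":
                continue
            try:
                j = int(row[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: invalid peak id {row[0]!r}") from exc
            ids.append(j)
            if len(row) > 1 and row[1].strip():
                names[j] = row[1].strip()
    if not ids:
        warnings.warn(f"binding list {path} is empty", stacklevel=2)
        return BindingSet(peak_ids=frozenset())
    unknown = sorted(set(ids) - set(matrix.peak_ids))
    if unknown:
        raise ValidationError(f"binding list {path} names unknown peaks: {unknown}")
    return BindingSet(peak_ids=frozenset(ids), names=names or None)


def intersect_hits(spectrum_hits: Iterable[int], binding: BindingSet) -> frozenset[int]:
    """Peaks that both bind the target cells and are spectrum-effect hits."""
    return frozenset(int(j) for j in spectrum_hits) & binding.peak_ids
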