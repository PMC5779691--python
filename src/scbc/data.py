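"""Data model for single-cell barcode chip (SCBC) experiments.

An SCBC run produces one *merged chamber table*: one row per ~1 nl
microchamber, holding the bright-field cell count and the background-
uncorrected fluorescence intensity of each barcode stripe (one stripe per
analyte of the multiplexed antibody panel). This module defines the in-memory
containers for that table — :class:`AnalytePanel`, :class:`CohortCondition`,
:class:`ChamberRecord`, :class:`ChipDataset` — together with readers/writers
for a self-describing delimited-text format and the count/intensity merge.

File format
-----------
Comma-separated, ``#``-prefixed ``key = value`` metadata header, then a
header row ``chamber_id,row,col,cell_count,<analyte1>,...,<analyteN>`` and
one data row per chamber. Floats are written with ``repr`` so a
read -> write -> read cycle is bitwise exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("scbc")

__all__ = [
    "AnalytePanel",
    "ChamberRecord",
    "ChipDataset",
    "CohortCondition",
    "FormatError",
    "IntegrityError",
    "DEFAULT_PANEL_NAMES",
    "DEFAULT_SATURATION_CEILING",
    "merge_counts_and_intensities",
    "partition_by_occupancy",
    "read_chamber_table",
    "write_chamber_table",
]

#: Default 11-plex T-cell effector panel. The assay is panel-agnostic and the
#: panel is configuration-driven; these defaults cover the analytes discussed
#: in the accompanying analyses (IL2, CCL3, CCL4, IFNg, TNFa) plus common
#: T-cell effector proteins as placeholders for the remaining stripes.
DEFAULT_PANEL_NAMES: tuple[str, ...] = (
    "IL2",
    "CCL3",
    "CCL4",
    "IFNg",
    "TNFa",
    "GMCSF",
    "IL6",
    "IL10",
    "IL17A",
    "GzmB",
    "Perforin",
)

#: 16-bit scanner full scale; intensities at or above it are flagged saturated.
DEFAULT_SATURATION_CEILING: float = 65535.0


class FormatError(ValueError):
    """A chamber table (or config) does not conform to the expected format."""


class IntegrityError(ValueError):
    """Structurally valid input that violates a dataset invariant."""


@dataclass(frozen=True)
class AnalytePanel:
    """Ordered multiplexed antibody panel.

    Parameters
    ----------
    names
        Unique analyte identifiers, in barcode-stripe order.
    stripe_index
        Map analyte -> stripe position on the barcode. Defaults to the
        position of the analyte in ``names``.
    """

    names: tuple[str, ...]
    stripe_index: Mapping[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise IntegrityError("panel analyte names must be unique")
        if not names:
            raise IntegrityError("panel must contain at least one analyte")
        stripes = self.stripe_index
        if stripes is None:
            stripes = {name: i for i, name in enumerate(names)}
        stripes = dict(stripes)
        if set(stripes) != set(names):
            raise IntegrityError("every analyte needs exactly one stripe index")
        for name, idx in stripes.items():
            if not isinstance(idx, (int, np.integer)) or idx < 0:
                raise IntegrityError(f"stripe index for {name!r} must be a non-negative integer")
        object.__setattr__(self, "stripe_index", stripes)

    @property
    def size(self) -> int:
        return len(self.names)

    def index_of(self, analyte: str) -> int:
        """Column index of ``analyte`` in intensity vectors."""
        try:
            return self.names.index(analyte)
        except ValueError:
            raise KeyError(f"analyte {analyte!r} not in panel") from None

    @classmethod
    def default(cls) -> "AnalytePanel":
        return cls(DEFAULT_PANEL_NAMES)


@dataclass(frozen=True)
class CohortCondition:
    """One experimental condition of a priming-sweep cohort.

    ``T1_hours`` is the bulk-culture priming window (cells interact under
    molecular stimulation); ``T2_hours`` is the on-chip secretion window over
    which single cells accumulate signal. When the protocol holds the total
    molecular-stimulation time T = T1 + T2 constant, conditions are most
    conveniently built with :meth:`from_total`.
    """

    label: str
    T1_hours: float
    T2_hours: float
    stimulation: str = ""
    cell_density: float | None = None

    def __post_init__(self) -> None:
        if self.T1_hours < 0:
            raise IntegrityError("T1_hours must be non-negative")
        if not self.T2_hours > 0:
            raise IntegrityError("T2_hours must be positive")
        if self.cell_density is not None and not self.cell_density > 0:
            raise IntegrityError("cell_density must be positive when given")

    @classmethod
    def from_total(
        cls,
        label: str,
        T1_hours: float,
        total_hours: float,
        stimulation: str = "",
        cell_density: float | None = None,
    ) -> "CohortCondition":
        """Build a condition with T2 = total - T1 (constant-T protocol)."""
        T2 = total_hours - T1_hours
        cond = cls(label, T1_hours, T2, stimulation, cell_density)
        if abs(cond.T1_hours + cond.T2_hours - total_hours) > 1e-9:
            raise IntegrityError("T1 + T2 must equal the declared total time")
        return cond


@dataclass
class ChamberRecord:
    """One microchamber: occupancy, grid position, per-analyte raw intensity."""

    chamber_id: int
    row: int
    col: int
    cell_count: int
    raw_intensity: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        self.raw_intensity = np.asarray(self.raw_intensity, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if self.chamber_id < 0 or self.row < 0 or self.col < 0:
            raise IntegrityError("chamber_id, row and col must be non-negative")
        if self.cell_count < 0 or int(self.cell_count) != self.cell_count:
            raise IntegrityError("cell_count must be a non-negative integer")
        if self.raw_intensity.shape != self.saturated.shape:
            raise IntegrityError("raw_intensity and saturated must have equal length")
        if not np.all(np.isfinite(self.raw_intensity)) or np.any(self.raw_intensity < 0):
            raise IntegrityError("raw intensities must be finite and non-negative")


@dataclass
class ChipDataset:
    """All chambers of one chip plus its cohort condition and analyte panel."""

    chip_id: str
    panel: AnalytePanel
    condition: CohortCondition
    chambers: list[ChamberRecord]

    def __post_init__(self) -> None:
        ids = [c.chamber_id for c in self.chambers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate chamber_id(s): {dupes}")
        for c in self.chambers:
            if c.raw_intensity.shape[0] != self.panel.size:
                raise IntegrityError(
                    f"chamber {c.chamber_id}: {c.raw_intensity.shape[0]} intensities "
                    f"for a {self.panel.size}-analyte panel"
                )
        if not any(c.cell_count == 0 for c in self.chambers):
            raise IntegrityError(
                "dataset contains no 0-cell chamber; background fitting is impossible"
            )

    @property
    def n_chambers(self) -> int:
        return len(self.chambers)

    def intensity_matrix(self) -> np.ndarray:
        """(n_chambers, panel.size) raw intensity matrix in chamber order."""
        return np.vstack([c.raw_intensity for c in self.chambers])

    def cell_counts(self) -> np.ndarray:
        return np.array([c.cell_count for c in self.chambers], dtype=int)

    def rows(self) -> np.ndarray:
        return np.array([c.row for c in self.chambers], dtype=int)

    def zero_cell(self) -> list[ChamberRecord]:
        return [c for c in self.chambers if c.cell_count == 0]

    def single_cell(self) -> list[ChamberRecord]:
        return [c for c in self.chambers if c.cell_count == 1]

    def copy(self) -> "ChipDataset":
        chambers = [
            replace(c, raw_intensity=c.raw_intensity.copy(), saturated=c.saturated.copy())
            for c in self.chambers
        ]
        return ChipDataset(self.chip_id, self.panel, self.condition, chambers)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("chamber_id", "row", "col", "cell_count")


def _format_float(x: float) -> str:
    # repr round-trips float64 exactly; integers stay compact
    return repr(float(x))


def write_chamber_table(dataset: ChipDataset, path: str | Path) -> None:
    """Write ``dataset`` to the self-describing delimited chamber-table format."""
    path = Path(path)
    cond = dataset.condition
    lines = [
        f"# chip_id = {dataset.chip_id}",
        f"# T1_hours = {_format_float(cond.T1_hours)}",
        f"# T2_hours = {_format_float(cond.T2_hours)}",
        f"# stimulation = {cond.stimulation}",
        f"# label = {cond.label}",
    ]
    if cond.cell_density is not None:
        lines.append(f"# cell_density = {_format_float(cond.cell_density)}")
    lines.append(",".join(_FIXED_COLUMNS + dataset.panel.names))
    for c in dataset.chambers:
        vals = [str(c.chamber_id), str(c.row), str(c.col), str(c.cell_count)]
        vals += [_format_float(v) for v in c.raw_intensity]
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n")


def read_chamber_table(
    path: str | Path,
    panel: AnalytePanel | None = None,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
) -> ChipDataset:
    """Read a merged chamber table.

    Parameters
    ----------
    path
        Chamber-table file (see module docstring for the format).
    panel
        Expected panel. When given, every panel analyte must appear as a
        column (a missing one raises :class:`FormatError` naming it). When
        ``None``, the panel is inferred from the intensity columns.
    saturation_ceiling
        Intensities at or above this value get their ``saturated`` flag set.

    Raises
    ------
    FormatError
        Malformed header/rows, missing analyte column, bad cell counts.
    IntegrityError
        Duplicate chamber ids or no 0-cell chamber.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    records: list[ChamberRecord] = []

    with path.open() as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [h.strip() for h in line.split(",")]
                for col in _FIXED_COLUMNS:
                    if col not in header:
                        raise FormatError(f"missing required column {col!r}")
                analyte_cols = [h for h in header if h not in _FIXED_COLUMNS]
                if panel is None:
                    panel = AnalytePanel(tuple(analyte_cols))
                else:
                    for name in panel.names:
                        if name not in analyte_cols:
                            raise FormatError(f"missing analyte column {name!r}")
                col_pos = {h: i for i, h in enumerate(header)}
                continue
            fields = line.split(",")
            if len(fields) != len(header):
                raise FormatError(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
            try:
                cid = int(fields[col_pos["chamber_id"]])
                row = int(fields[col_pos["row"]])
                col = int(fields[col_pos["col"]])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer id/coordinate") from exc
            count_raw = fields[col_pos["cell_count"]]
            try:
                count_f = float(count_raw)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unreadable cell_count {count_raw!r}") from exc
            if count_f < 0 or count_f != int(count_f):
                raise FormatError(
                    f"line {lineno}: cell_count must be a non-negative integer, got {count_raw!r}"
                )
            try:
                intens = np.array(
                    [float(fields[col_pos[name]]) for name in panel.names], dtype=float
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unreadable intensity value") from exc
            sat = intens >= saturation_ceiling
            records.append(ChamberRecord(cid, row, col, int(count_f), intens, sat))

    if header is None:
        raise FormatError(f"{path}: no header row found")
    if "chip_id" not in meta:
        raise FormatError(f"{path}: metadata header must declare chip_id")
    for key in ("T1_hours", "T2_hours"):
        if key not in meta:
            raise FormatError(f"{path}: metadata header must declare {key}")
    condition = CohortCondition(
        label=meta.get("label", meta["chip_id"]),
        T1_hours=float(meta["T1_hours"]),
        T2_hours=float(meta["T2_hours"]),
        stimulation=meta.get("stimulation", ""),
        cell_density=float(meta["cell_density"]) if "cell_density" in meta else None,
    )
    return ChipDataset(meta["chip_id"], panel, condition, records)


# ---------------------------------------------------------------------------
# Merge and partition
# ---------------------------------------------------------------------------

def merge_counts_and_intensities(
    counts: Mapping[int, int],
    intensities: Mapping[int, Sequence[float]],
    positions: Mapping[int, tuple[int, int]] | None = None,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
) -> list[ChamberRecord]:
    """Inner-join bright-field cell counts with barcode intensities.

    The two acquisition channels (video cell counting; fluorescence scan) are
    keyed by chamber id. Chambers present in only one table are logged and
    dropped; an empty intersection raises :class:`IntegrityError`.

    ``positions`` optionally supplies (row, col) grid coordinates per chamber
    id; chambers without one get (0, 0).
    """
    shared = sorted(set(counts) & set(intensities))
    dropped = (set(counts) | set(intensities)) - set(shared)
    if not shared:
        raise IntegrityError("count and intensity tables share no chamber ids")
    if dropped:
        logger.info(
            "merge_counts_and_intensities: dropped %d chamber id(s) present in "
            "only one table: %s",
            len(dropped),
            sorted(dropped),
        )
    records = []
    for cid in shared:
        row, col = (positions or {}).get(cid, (0, 0))
        intens = np.asarray(intensities[cid], dtype=float)
        records.append(
            ChamberRecord(
                chamber_id=cid,
                row=row,
                col=col,
                cell_count=int(counts[cid]),
                raw_intensity=intens,
                saturated=intens >= saturation_ceiling,
            )
        )
    return records


def partition_by_occupancy(dataset: ChipDataset) -> dict[int, list[ChamberRecord]]:
    """Partition chambers by cell count.

    The 0-cell class feeds background fitting, the 1-cell class feeds all
    single-cell statistics; classes with >= 2 cells are kept for QC only and
    are never mixed into single-cell statistics downstream.
    """
    out: dict[int, list[ChamberRecord]] = {}
    for c in dataset.chambers:
        out.setdefault(c.cell_count, []).append(c)
    return out
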