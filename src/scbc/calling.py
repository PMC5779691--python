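"""Secretion calling for 1-cell microchambers.

Only chambers holding exactly one cell enter single-cell statistics. For
each such chamber and each panel analyte:

* ``call``  — raw intensity strictly above the analyte's cutoff
  (background mean + 2 sd). Saturated stripes are called positive and
  flagged: a railed detector is unambiguous evidence of secretion even
  though the level is censored.
* ``net``   — ``max(raw - background mean, 0)`` (zero-clamped background
  subtraction, applied after any gradient correction).
* ``rate``  — ``net / T2_hours``: secreted signal per hour of the on-chip
  secretion window, the unit in which conditions with different T2 are
  comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .background import BackgroundModel
from .data import AnalytePanel, ChipDataset, CohortCondition, IntegrityError

__all__ = [
    "EmptyTableError",
    "SecretionCallTable",
    "call_secretion",
    "fraction_secreting",
]


class EmptyTableError(ValueError):
    """An operation that needs at least one cell received none."""


@dataclass
class SecretionCallTable:
    """Single cells x analytes: boolean calls, net intensities, rates.

    All arrays have shape ``(n_cells, panel.size)`` and share row order with
    ``chamber_ids``. Rates are T2-normalized (AU/hour).
    """

    condition: CohortCondition
    panel: AnalytePanel
    chamber_ids: np.ndarray
    calls: np.ndarray
    net: np.ndarray
    rates: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        self.chamber_ids = np.asarray(self.chamber_ids, dtype=int)
        self.calls = np.asarray(self.calls, dtype=bool)
        self.net = np.asarray(self.net, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        n, p = self.calls.shape
        if p != self.panel.size:
            raise IntegrityError("call table width must equal the panel size")
        for name, arr in (("net", self.net), ("rates", self.rates), ("saturated", self.saturated)):
            if arr.shape != (n, p):
                raise IntegrityError(f"{name} must have shape (n_cells, panel.size)")
        if self.chamber_ids.shape != (n,):
            raise IntegrityError("one chamber id per cell is required")
        if np.any(self.net < 0) or np.any(self.rates < 0):
            raise IntegrityError("net intensities and rates must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.calls.shape[0])

    def calls_per_cell(self) -> np.ndarray:
        """Number of positive calls (polyfunctionality k) per cell."""
        return self.calls.sum(axis=1)

    def called_rate_per_cell(self) -> np.ndarray:
        """Per-cell total secretion rate, summed over *called* analytes only."""
        return (self.rates * self.calls).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per cell, (call, net, rate) triplets per analyte."""
        data: dict[str, np.ndarray] = {"chamber_id": self.chamber_ids}
        for j, name in enumerate(self.panel.names):
            data[f"{name}_call"] = self.calls[:, j].astype(int)
            data[f"{name}_net"] = self.net[:, j]
            data[f"{name}_rate"] = self.rates[:, j]
            data[f"{name}_saturated"] = self.saturated[:, j].astype(int)
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# label = {self.condition.label}\n")
            fh.write(f"# T1_hours = {self.condition.T1_hours!r}\n")
            fh.write(f"# T2_hours = {self.condition.T2_hours!r}\n")
            fh.write(f"# stimulation = {self.condition.stimulation}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SecretionCallTable":
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open() as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            df = pd.read_csv(fh)
        names = tuple(c[: -len("_call")] for c in df.columns if c.endswith("_call"))
        panel = AnalytePanel(names)
        condition = CohortCondition(
            label=meta.get("label", path.stem),
            T1_hours=float(meta.get("T1_hours", 0.0)),
            T2_hours=float(meta["T2_hours"]),
            stimulation=meta.get("stimulation", ""),
        )
        return cls(
            condition=condition,
            panel=panel,
            chamber_ids=df["chamber_id"].to_numpy(),
            calls=df[[f"{n}_call" for n in names]].to_numpy(dtype=bool),
            net=df[[f"{n}_net" for n in names]].to_numpy(dtype=float),
            rates=df[[f"{n}_rate" for n in names]].to_numpy(dtype=float),
            saturated=df[[f"{n}_saturated" for n in names]].to_numpy(dtype=bool),
        )


def call_secretion(
    dataset: ChipDataset, models: dict[str, BackgroundModel]
) -> SecretionCallTable:
    """Score every 1-cell chamber of a chip against its background models.

    ``models`` must contain exactly one fitted :class:`BackgroundModel` per
    panel analyte, fitted on this same (gradient-consistent) dataset.
    """
    panel = dataset.panel
    if set(models) != set(panel.names):
        missing = set(panel.names) - set(models)
        extra = set(models) - set(panel.names)
        raise IntegrityError(
            f"background models do not match the panel (missing: {sorted(missing)}, "
            f"unexpected: {sorted(extra)})"
        )
    T2 = dataset.condition.T2_hours
    if not T2 > 0:
        raise ValueError("T2_hours must be positive")

    singles = dataset.single_cell()
    mu = np.array([models[name].mu for name in panel.names])
    cutoff = np.array([models[name].cutoff for name in panel.names])

    ids = np.array([c.chamber_id for c in singles], dtype=int)
    raw = (
        np.vstack([c.raw_intensity for c in singles])
        if singles
        else np.empty((0, panel.size))
    )
    sat = (
        np.vstack([c.saturated for c in singles])
        if singles
        else np.empty((0, panel.size), dtype=bool)
    )
    calls = (raw > cutoff[None, :]) | sat  # strict inequality; saturation => positive
    net = np.maximum(raw - mu[None, :], 0.0)
    rates = net / T2
    return SecretionCallTable(
        condition=dataset.condition,
        panel=panel,
        chamber_ids=ids,
        calls=calls,
        net=net,
        rates=rates,
        saturated=sat,
    )


def fraction_secreting(table: SecretionCallTable, min_k: int = 1) -> float:
    """Fraction of cells with at least ``min_k`` positive calls."""
    if min_k < 1:
        raise ValueError("min_k must be a positive integer")
    if table.n_cells == 0:
        raise EmptyTableError("call table holds no cells")
    return float(np.mean(table.calls_per_cell() >= min_k))
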