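"""Polyfunctionality histograms and the polyfunctional strength index (pSI).

A single cell's polyfunctionality k is the number of distinct panel proteins
it secretes above cutoff. Stratifying cells by exact k, the pSI of stratum k
is

    psi_k = (n_k / n_cells) * mean over cells with exactly k calls of
            (sum over called analytes of the T2-normalized net rate)

i.e. the fraction of cells secreting k proteins multiplied by their mean
measured (per-hour) intensity, and the total index is psi_total =
sum_{k>=1} psi_k. Cells with k = 0 contribute psi_0 = 0 by definition.
Display conventions that pool "3 or more" are a reporting view; internal
computation always keeps exact k.

A per-analyte decomposition (:func:`psi_by_analyte`) attributes psi_total to
analytes; it sums to psi_total exactly because each called analyte's rate
appears in exactly one stratum mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import EmptyTableError, SecretionCallTable
from .data import AnalytePanel, CohortCondition

__all__ = [
    "PolyfunctionalProfile",
    "compute_psi",
    "polyfunction_histogram",
    "psi_by_analyte",
]


def polyfunction_histogram(
    table: SecretionCallTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts and fractions of cells by exact polyfunctionality k = 0..panel.size."""
    if table.n_cells == 0:
        raise EmptyTableError("call table holds no cells")
    k = table.calls_per_cell()
    counts = np.bincount(k, minlength=table.panel.size + 1)
    return counts, counts / table.n_cells


@dataclass(frozen=True)
class PolyfunctionalProfile:
    """Per-k cell fractions, pSI values and per-analyte rates for one condition."""

    condition: CohortCondition
    panel: AnalytePanel
    n_cells: int
    n_k: np.ndarray            # cells with exactly k calls, k = 0..panel.size
    fraction_k: np.ndarray
    mean_total_rate_k: np.ndarray  # mean called-rate sum within stratum k (0 where empty)
    psi_k: np.ndarray
    #: mean net rate per analyte over *all* cells (ensemble mean, AU/h)
    per_analyte_mean_rate: np.ndarray
    #: per-analyte decomposition of psi_total (sums to psi_total)
    per_analyte_psi: np.ndarray

    @property
    def psi_total(self) -> float:
        return float(self.psi_k[1:].sum())

    def fraction_secreting(self, min_k: int = 1) -> float:
        """Fraction of cells with polyfunctionality >= min_k."""
        return float(self.fraction_k[min_k:].sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-k rows of the profile (long-form, for reports)."""
        return pd.DataFrame(
            {
                "k": np.arange(self.panel.size + 1),
                "n_cells": self.n_k,
                "fraction": self.fraction_k,
                "mean_total_rate": self.mean_total_rate_k,
                "psi": self.psi_k,
            }
        )


def compute_psi(
    table: SecretionCallTable, use_rates: bool = True
) -> PolyfunctionalProfile:
    """Compute the full polyfunctional profile of one condition.

    ``use_rates=False`` switches the intensity inside the index from
    T2-normalized rates to raw net AU (a sensitivity view; cross-condition
    comparisons should keep the default).
    """
    if table.n_cells == 0:
        raise EmptyTableError("call table holds no cells")
    size = table.panel.size
    k = table.calls_per_cell()
    counts = np.bincount(k, minlength=size + 1)
    fractions = counts / table.n_cells

    values = table.rates if use_rates else table.net
    called_values = values * table.calls
    per_cell_total = called_values.sum(axis=1)

    mean_total = np.zeros(size + 1)
    for kk in range(1, size + 1):
        members = k == kk
        if members.any():
            mean_total[kk] = per_cell_total[members].mean()
    psi_k = fractions * mean_total
    psi_k[0] = 0.0

    per_analyte_psi = called_values.sum(axis=0) / table.n_cells
    per_analyte_mean_rate = values.mean(axis=0)
    return PolyfunctionalProfile(
        condition=table.condition,
        panel=table.panel,
        n_cells=table.n_cells,
        n_k=counts,
        fraction_k=fractions,
        mean_total_rate_k=mean_total,
        psi_k=psi_k,
        per_analyte_mean_rate=per_analyte_mean_rate,
        per_analyte_psi=per_analyte_psi,
    )


def psi_by_analyte(table: SecretionCallTable, use_rates: bool = True) -> dict[str, float]:
    """Per-analyte contribution to psi_total (sums to psi_total exactly)."""
    profile = compute_psi(table, use_rates=use_rates)
    return {
        name: float(profile.per_analyte_psi[j])
        for j, name in enumerate(table.panel.names)
    }
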