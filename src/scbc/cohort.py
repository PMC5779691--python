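"""Cross-condition cohort comparison, composition, embedding and clustering.

Summarizes :class:`~scbc.polyfunctionality.PolyfunctionalProfile` objects
across the conditions of a priming sweep (T1 sweep, stimulation strength,
cell density): secreting fractions, pSI totals, per-analyte mean rates and
their fold changes between conditions, plus a PCA embedding with k-means
labels of the single-cell rate matrix. A full-pipeline convenience,
:func:`analyze_chip` / :func:`analyze_cohort`, chains background fitting,
gradient correction, calling and pSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .background import fit_background_all
from .calling import SecretionCallTable, call_secretion
from .data import ChipDataset, IntegrityError
from .polyfunctionality import PolyfunctionalProfile, compute_psi

logger = logging.getLogger("scbc")

__all__ = [
    "CohortSummary",
    "EmptySignalError",
    "analyze_chip",
    "analyze_cohort",
    "compare_conditions",
    "embed_and_cluster",
    "secretion_composition",
]


class EmptySignalError(ValueError):
    """A composition was requested for a profile with no signal at all."""


@dataclass
class CohortSummary:
    """Per-condition summary rows plus pairwise per-analyte fold changes.

    ``fold_changes`` maps ``(analyte, label_from, label_to)`` to the ratio of
    mean net rates (to / from); the pseudo-analyte ``"total"`` uses summed
    mean rates. Pairs whose denominator is zero are stored as ``None``
    (undefined, never infinite) and listed in ``undefined_pairs``.
    """

    table: pd.DataFrame
    fold_changes: dict[tuple[str, str, str], float | None]
    undefined_pairs: list[tuple[str, str, str]]

    def fold(self, analyte: str, label_from: str, label_to: str) -> float | None:
        return self.fold_changes[(analyte, label_from, label_to)]


def compare_conditions(profiles: list[PolyfunctionalProfile]) -> CohortSummary:
    """Summarize >= 2 profiles sharing one panel and compute fold changes."""
    if len(profiles) < 2:
        raise IntegrityError("need at least two profiles to compare")
    panel = profiles[0].panel
    for p in profiles[1:]:
        if p.panel.names != panel.names:
            raise IntegrityError("profiles do not share a panel")
    labels = [p.condition.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise IntegrityError("condition labels must be unique")

    rows = []
    for p in profiles:
        row = {
            "label": p.condition.label,
            "T1_hours": p.condition.T1_hours,
            "T2_hours": p.condition.T2_hours,
            "n_cells": p.n_cells,
            "fraction_secreting_k1": p.fraction_secreting(1),
            "fraction_secreting_k2": p.fraction_secreting(2),
            "psi_total": p.psi_total,
        }
        for j, name in enumerate(panel.names):
            row[f"rate_{name}"] = float(p.per_analyte_mean_rate[j])
        row["rate_total"] = float(p.per_analyte_mean_rate.sum())
        rows.append(row)
    table = pd.DataFrame(rows)

    fold_changes: dict[tuple[str, str, str], float | None] = {}
    undefined: list[tuple[str, str, str]] = []
    analytes = list(panel.names) + ["total"]
    rates = {
        p.condition.label: np.append(
            p.per_analyte_mean_rate, p.per_analyte_mean_rate.sum()
        )
        for p in profiles
    }
    for la in labels:
        for lb in labels:
            for j, name in enumerate(analytes):
                denom = rates[la][j]
                num = rates[lb][j]
                key = (name, la, lb)
                if denom == 0.0:
                    fold_changes[key] = None
                    undefined.append(key)
                else:
                    fold_changes[key] = float(num / denom)
    if undefined:
        logger.info("compare_conditions: %d fold change(s) undefined (zero denominator)", len(undefined))
    return CohortSummary(table, fold_changes, undefined)


def secretion_composition(profile: PolyfunctionalProfile) -> dict[str, float]:
    """Per-analyte share of the summed mean net rates (sums to 1)."""
    total = float(profile.per_analyte_mean_rate.sum())
    if total <= 0.0:
        raise EmptySignalError("profile carries no secretion signal")
    return {
        name: float(profile.per_analyte_mean_rate[j] / total)
        for j, name in enumerate(profile.panel.names)
    }


def embed_and_cluster(
    table: SecretionCallTable,
    n_components: int = 2,
    n_clusters: int = 2,
    seed: int = 0,
    log_transform: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA embedding + k-means labels of the cells x analyte-rate matrix.

    Rates are log1p-transformed by default (secretion rates are heavy-
    tailed) and centered by PCA. Zero-variance input (all cells identical)
    returns an all-zero embedding and a single cluster. Deterministic for a
    fixed ``seed``.
    """
    if n_components > table.panel.size:
        raise ValueError("n_components cannot exceed the panel size")
    if table.n_cells < n_clusters:
        raise ValueError("need at least n_clusters cells")
    X = table.rates.copy()
    if log_transform:
        X = np.log1p(X)
    if np.allclose(X, X[0], atol=1e-12):
        return (
            np.zeros((table.n_cells, n_components)),
            np.zeros(table.n_cells, dtype=int),
        )
    n_comp = min(n_components, min(X.shape) - 1) or 1
    coords = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if coords.shape[1] < n_components:
        coords = np.pad(coords, ((0, 0), (0, n_components - coords.shape[1])))
    labels = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(X)
    return coords, labels


# ---------------------------------------------------------------------------
# Full pipeline conveniences
# ---------------------------------------------------------------------------

def analyze_chip(
    dataset: ChipDataset,
    correct_gradient: bool = True,
) -> tuple[SecretionCallTable, PolyfunctionalProfile]:
    """Background fit (+ gradient correction) -> calls -> pSI for one chip."""
    corrected, models = fit_background_all(dataset, correct_gradient=correct_gradient)
    calls = call_secretion(corrected, models)
    return calls, compute_psi(calls)


def analyze_cohort(
    datasets: list[ChipDataset],
    correct_gradient: bool = True,
) -> tuple[list[SecretionCallTable], list[PolyfunctionalProfile], CohortSummary]:
    """Run the full per-chip pipeline over a cohort and compare conditions."""
    calls, profiles = [], []
    for ds in datasets:
        c, p = analyze_chip(ds, correct_gradient=correct_gradient)
        calls.append(c)
        profiles.append(p)
    return calls, profiles, compare_conditions(profiles)
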