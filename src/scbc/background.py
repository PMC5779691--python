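"""Per-analyte background estimation from 0-cell microchambers.

Chambers that trapped no cell measure pure assay background for every
barcode stripe. Per analyte (stripe) and per chip, this module fits a
Gaussian to those 0-cell intensities, checks Gaussianity with a one-sample
Kolmogorov-Smirnov test (reported alongside a 20-bin histogram, matching how
the background is usually inspected), optionally detects and removes a
linear spatial gradient along the device, and derives the secretion cutoff

    cutoff = mu + 2 sigma.

Notes on the diagnostics: because mu and sigma are estimated from the same
values the KS test is run on, the test is anti-conservative (the Lilliefors
effect); ``ks_p`` is therefore advisory — the pipeline warns below 0.05 but
never gates on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data import ChipDataset

logger = logging.getLogger("scbc")

__all__ = [
    "BackgroundModel",
    "DegenerateBackgroundError",
    "InsufficientSpanError",
    "SampleSizeError",
    "compute_cutoff",
    "detect_and_correct_gradient",
    "fit_background",
    "fit_background_all",
    "histogram_gaussian_fit",
    "test_normality",
]

#: Minimum number of 0-cell chambers for a trustworthy background fit.
DEFAULT_MIN_BACKGROUND = 30

#: Significance level of the slope test that triggers gradient correction.
DEFAULT_GRADIENT_ALPHA = 0.01


class SampleSizeError(ValueError):
    """Too few 0-cell chambers to fit a background."""


class DegenerateBackgroundError(ValueError):
    """Zero-variance background — no meaningful Gaussian fit or cutoff."""


class InsufficientSpanError(ValueError):
    """0-cell chambers do not span enough device rows to estimate a gradient."""


def compute_cutoff(mu: float, sigma: float) -> float:
    """Secretion cutoff: background mean plus twice the background sd."""
    if not sigma > 0:
        raise DegenerateBackgroundError("sigma must be positive")
    return mu + 2.0 * sigma


@dataclass(frozen=True)
class BackgroundModel:
    """Fitted per-analyte Gaussian background and its secretion cutoff."""

    analyte: str
    mu: float
    sigma: float
    ks_stat: float
    ks_p: float
    n_background: int
    gradient_slope: float = 0.0
    gradient_applied: bool = False
    #: 20-bin histogram least-squares estimates, for cross-checking the
    #: moment fit (they agree closely on Gaussian data).
    hist_mu: float | None = None
    hist_sigma: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DegenerateBackgroundError("sigma must be positive")

    @property
    def cutoff(self) -> float:
        return compute_cutoff(self.mu, self.sigma)


def test_normality(
    values: np.ndarray,
    mu: float,
    sigma: float,
    n_bins: int = 20,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """One-sample KS test of ``values`` against Normal(mu, sigma).

    Returns ``(ks_stat, ks_p, (bin_counts, bin_edges))`` where the histogram
    uses ``n_bins`` evenly spaced bins over the value range, for reporting.
    The p-value is advisory: with mu/sigma estimated from the same sample it
    is anti-conservative and should never silently gate an analysis.
    """
    values = np.asarray(values, dtype=float)
    if values.size < DEFAULT_MIN_BACKGROUND:
        raise SampleSizeError(
            f"need >= {DEFAULT_MIN_BACKGROUND} values for the KS diagnostic, got {values.size}"
        )
    if not sigma > 0:
        raise DegenerateBackgroundError("sigma must be positive")
    ks = stats.kstest(values, "norm", args=(mu, sigma))
    counts, edges = np.histogram(values, bins=n_bins)
    return float(ks.statistic), float(ks.pvalue), (counts, edges)


def histogram_gaussian_fit(
    values: np.ndarray, n_bins: int = 20
) -> tuple[float, float]:
    """Least-squares Gaussian fit to the ``n_bins``-bin histogram of ``values``.

    Mirrors the visual binned-Gaussian check; provided alongside the moment
    estimates, which are the defaults for all downstream computation.
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sigma):
        return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))

    p0 = (float(values.mean()), float(values.std(ddof=1)))
    popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0)
    return float(popt[0]), abs(float(popt[1]))


def _background_values(
    dataset: ChipDataset, analyte_idx: int
) -> tuple[np.ndarray, np.ndarray]:
    """(values, rows) of unsaturated 0-cell intensities for one analyte."""
    vals, rows = [], []
    for c in dataset.zero_cell():
        if not c.saturated[analyte_idx]:
            vals.append(c.raw_intensity[analyte_idx])
            rows.append(c.row)
    return np.asarray(vals, dtype=float), np.asarray(rows, dtype=int)


def fit_background(
    dataset: ChipDataset,
    analyte: str,
    min_background: int = DEFAULT_MIN_BACKGROUND,
    n_bins: int = 20,
    gradient_slope: float = 0.0,
    gradient_applied: bool = False,
) -> BackgroundModel:
    """Fit the per-analyte Gaussian background of one chip.

    Saturated 0-cell values are excluded (they are censored, not Gaussian).
    Raises :class:`SampleSizeError` below ``min_background`` usable chambers
    and :class:`DegenerateBackgroundError` for zero-variance backgrounds.
    """
    idx = dataset.panel.index_of(analyte)
    values, _ = _background_values(dataset, idx)
    if values.size < min_background:
        raise SampleSizeError(
            f"{analyte}: {values.size} usable 0-cell chambers < minimum {min_background}"
        )
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if not sigma > 0:
        raise DegenerateBackgroundError(f"{analyte}: zero-variance background")
    ks_stat, ks_p, _hist = test_normality(values, mu, sigma, n_bins=n_bins)
    if ks_p < 0.05:
        logger.warning(
            "background of %s deviates from a single Gaussian (KS p=%.3g); "
            "proceeding — the KS diagnostic is advisory",
            analyte,
            ks_p,
        )
    try:
        hist_mu, hist_sigma = histogram_gaussian_fit(values, n_bins=n_bins)
    except RuntimeError:  # curve_fit non-convergence on pathological data
        hist_mu = hist_sigma = None
    return BackgroundModel(
        analyte=analyte,
        mu=mu,
        sigma=sigma,
        ks_stat=ks_stat,
        ks_p=ks_p,
        n_background=int(values.size),
        gradient_slope=gradient_slope,
        gradient_applied=gradient_applied,
        hist_mu=hist_mu,
        hist_sigma=hist_sigma,
    )


def detect_and_correct_gradient(
    dataset: ChipDataset,
    analyte: str,
    alpha: float = DEFAULT_GRADIENT_ALPHA,
    axis: str = "row",
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> tuple[ChipDataset, float, bool]:
    """Detect (and, if significant, remove) a linear spatial background trend.

    The trend of 0-cell intensity on the grid coordinate (``axis`` one of
    ``"row"``/``"col"``) is estimated by least squares. If the slope's
    p-value is below ``alpha`` the centered trend ``slope * (coord - mean
    coord)`` is subtracted from **all** chambers (the gradient is a device
    property, not a 0-cell property) and ``corrected=True`` is returned with
    a new dataset; otherwise the original dataset is returned unchanged.

    Returns ``(dataset, slope, corrected)``.
    """
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    idx = dataset.panel.index_of(analyte)
    vals, rows = [], []
    for c in dataset.zero_cell():
        if not c.saturated[idx]:
            vals.append(c.raw_intensity[idx])
            rows.append(c.row if axis == "row" else c.col)
    values = np.asarray(vals, dtype=float)
    coords = np.asarray(rows, dtype=float)
    if values.size < min_background:
        raise SampleSizeError(
            f"{analyte}: {values.size} usable 0-cell chambers < minimum {min_background}"
        )
    if np.unique(coords).size < 5:
        raise InsufficientSpanError(
            f"{analyte}: 0-cell chambers span {np.unique(coords).size} distinct "
            f"{axis}s; >= 5 required for gradient estimation"
        )
    fit = stats.linregress(coords, values)
    slope = float(fit.slope)
    if fit.pvalue >= alpha:
        return dataset, slope, False
    center = float(coords.mean())
    logger.info(
        "correcting %s background gradient: slope %.4g AU/%s (p=%.3g), centered at %s=%.2f",
        analyte,
        slope,
        axis,
        fit.pvalue,
        axis,
        center,
    )
    out = dataset.copy()
    for c in out.chambers:
        coord = c.row if axis == "row" else c.col
        c.raw_intensity[idx] -= slope * (coord - center)
        if c.raw_intensity[idx] < 0:
            c.raw_intensity[idx] = 0.0
    return out, slope, True


def fit_background_all(
    dataset: ChipDataset,
    correct_gradient: bool = True,
    alpha: float = DEFAULT_GRADIENT_ALPHA,
    axis: str = "row",
    min_background: int = DEFAULT_MIN_BACKGROUND,
) -> tuple[ChipDataset, dict[str, BackgroundModel]]:
    """Gradient-correct (optionally) and fit the background of every analyte.

    Returns the (possibly corrected) dataset and one :class:`BackgroundModel`
    per panel analyte, fitted on that dataset — the form
    :func:`scbc.calling.call_secretion` expects.
    """
    models: dict[str, BackgroundModel] = {}
    current = dataset
    for analyte in dataset.panel.names:
        slope, corrected = 0.0, False
        if correct_gradient:
            current, slope, corrected = detect_and_correct_gradient(
                current, analyte, alpha=alpha, axis=axis, min_background=min_background
            )
        models[analyte] = fit_background(
            current,
            analyte,
            min_background=min_background,
            gradient_slope=slope if corrected else 0.0,
            gradient_applied=corrected,
        )
    return current, models
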