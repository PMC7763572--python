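"""Spectral preprocessing: reference calibration, fixed-width ppm bucketing
with water-region exclusion, total-area normalization, and metabolite
signal-area integration.

The bucket table is the feature matrix consumed by the latent-variable models;
the metabolite integrals feed the univariate statistics. Buckets are half-open
intervals ``[low, low + bin_width)`` tiling the configured ppm range from its
low end; any bucket whose interval overlaps an exclusion region (by default the
residual-water region 4.3-6.5 ppm) is dropped entirely rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureMatrix
from .spectra import Spectrum, calibrate_reference, correct_baseline


@dataclass
class PreprocessConfig:
    """Parameters of the spectrum-to-feature-matrix reduction.

    All positions are chemical shifts in ppm. ``bin_width`` 0.02 ppm and the
    4.3-6.5 ppm water exclusion follow standard 1H saliva bucketing practice;
    ``ppm_range`` [0.0, 10.0] covers the usual 1H metabolite window (the
    reference peak at 0.00 ppm sits on its low edge).
    """

    reference_ppm: float = 0.0
    reference_search_window: tuple[float, float] = (-0.2, 0.2)
    bin_width: float = 0.02
    ppm_range: tuple[float, float] = (0.0, 10.0)
    exclusion_regions: list[tuple[float, float]] = field(
        default_factory=lambda: [(4.3, 6.5)]
    )
    normalization_total: float = 1.0
    baseline_method: str = "none"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not self.ppm_range[0] < self.ppm_range[1]:
            raise ValueError("ppm_range low must be < high")
        for lo, hi in self.exclusion_regions:
            if not lo < hi:
                raise ValueError(f"exclusion region ({lo}, {hi}) has low >= high")
        if self.normalization_total <= 0:
            raise ValueError("normalization_total must be > 0")


def candidate_bins(cfg: PreprocessConfig) -> np.ndarray:
    """All half-open bin intervals [low, low+width) tiling ppm_range.

    Returns an array of shape (n_bins, 2) of (low, high) edges.
    """
    lo, hi = cfg.ppm_range
    w = cfg.bin_width
    n = int(np.floor((hi - lo) / w + 1e-9))
    lows = lo + w * np.arange(n)
    return np.column_stack([lows, lows + w])


def retained_bins(cfg: PreprocessConfig) -> np.ndarray:
    """Candidate bins minus those intersecting any exclusion region."""
    bins = candidate_bins(cfg)
    keep = np.ones(len(bins), dtype=bool)
    for ex_lo, ex_hi in cfg.exclusion_regions:
        keep &= ~((bins[:, 0] < ex_hi) & (bins[:, 1] > ex_lo))
    return bins[keep]


def _trapz_interval(ppm: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of the piecewise-linear spectrum over [a, b],
    with linear interpolation at the interval endpoints."""
    i0 = np.searchsorted(ppm, a, side="right")
    i1 = np.searchsorted(ppm, b, side="left")
    xs = np.concatenate([[a], ppm[i0:i1], [b]])
    ys = np.concatenate([[np.interp(a, ppm, y)], y[i0:i1], [np.interp(b, ppm, y)]])
    return float(np.trapezoid(ys, xs))


def bin_spectrum(
    spec: Spectrum, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Integrate a calibrated spectrum into fixed-width buckets.

    Each retained bucket's value is the trapezoidal integral of intensity over
    the bucket interval; bucket ids name the bucket centre to 3 decimals.
    Raises if the spectrum does not cover the binned span.
    """
    cfg = cfg or PreprocessConfig()
    bins = retained_bins(cfg)
    span_lo = cfg.ppm_range[0]
    span_hi = candidate_bins(cfg)[-1, 1]
    if spec.ppm[0] > span_lo or spec.ppm[-1] < span_hi:
        raise ValueError(
            f"spectrum {spec.sample_id!r} covers [{spec.ppm[0]:.3f}, "
            f"{spec.ppm[-1]:.3f}] but binning needs [{span_lo:.3f}, {span_hi:.3f}]"
        )
    values = np.array(
        [_trapz_interval(spec.ppm, spec.intensity, lo, hi) for lo, hi in bins]
    )
    ids = [f"{0.5 * (lo + hi):.3f}" for lo, hi in bins]
    return values, ids


def normalize_total_area(
    fm: FeatureMatrix, total: float = 1.0
) -> FeatureMatrix:
    """Scale each sample row so its sum equals ``total`` (dilution removal).

    Idempotent; raises for any sample whose total area is not strictly
    positive.
    """
    sums = fm.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [fm.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive total area for sample(s): {names}")
    return FeatureMatrix(
        fm.values * (total / sums)[:, None],
        list(fm.sample_ids),
        list(fm.feature_ids),
        normalized=True,
    )


class TotalAreaNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for row-sum (total-area) normalization.

    Stateless: ``fit`` only validates; ``transform`` rescales each row to sum
    to ``total``.
    """

    def __init__(self, total: float = 1.0):
        self.total = total

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        sums = X.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("non-positive row total(s)")
        return X * (self.total / sums)[:, None]


def assemble_feature_matrix(
    specs: Sequence[Spectrum],
    cfg: PreprocessConfig | None = None,
    normalize: bool = True,
) -> FeatureMatrix:
    """Calibrate, (optionally) baseline-correct, bin and stack spectra.

    Rows follow input order; all samples share one bucket id list. By default
    the stacked matrix is total-area normalized, the last preprocessing step
    before pattern recognition.
    """
    cfg = cfg or PreprocessConfig()
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids among input spectra")
    rows, bin_ids = [], None
    for spec in specs:
        cal = calibrate_reference(
            spec, cfg.reference_ppm, cfg.reference_search_window
        )
        cal = correct_baseline(cal, cfg.baseline_method)
        vals, bids = bin_spectrum(cal, cfg)
        rows.append(vals)
        bin_ids = bids
    fm = FeatureMatrix(np.vstack(rows), ids, bin_ids)
    if normalize:
        fm = normalize_total_area(fm, cfg.normalization_total)
    return fm


@dataclass
class AssignmentTable:
    """Metabolite -> ppm integration windows (assignments are an input,
    taken from literature/reference databases, not derived here)."""

    windows: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for met, wins in self.windows.items():
            if not wins:
                raise ValueError(f"metabolite {met!r} has no windows")
            for lo, hi in wins:
                if not lo < hi:
                    raise ValueError(f"{met}: window ({lo}, {hi}) has low >= high")

    def warn_exclusion_overlaps(self, cfg: PreprocessConfig) -> list[str]:
        """Warn for windows overlapping an exclusion region; returns offenders."""
        offenders = []
        for met, wins in self.windows.items():
            for lo, hi in wins:
                for ex_lo, ex_hi in cfg.exclusion_regions:
                    if lo < ex_hi and hi > ex_lo:
                        offenders.append(met)
                        warnings.warn(
                            f"{met}: window ({lo}, {hi}) overlaps exclusion "
                            f"region ({ex_lo}, {ex_hi})",
                            stacklevel=2,
                        )
        return offenders

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssignmentTable":
        """Columns: metabolite, window_low_ppm, window_high_ppm (repeated
        rows per metabolite)."""
        df = pd.read_csv(path)
        wins: dict[str, list[tuple[float, float]]] = {}
        for _, row in df.iterrows():
            wins.setdefault(str(row["metabolite"]), []).append(
                (float(row["window_low_ppm"]), float(row["window_high_ppm"]))
            )
        return cls(wins)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"metabolite": m, "window_low_ppm": lo, "window_high_ppm": hi}
            for m, wins in self.windows.items()
            for lo, hi in wins
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def integrate_metabolite_regions(
    spec: Spectrum, assignments: AssignmentTable
) -> dict[str, float]:
    """Relative metabolite concentrations by signal-area integration.

    For each metabolite, the value is the sum of trapezoidal integrals of the
    (calibrated) spectrum over its assigned windows.
    """
    out: dict[str, float] = {}
    for met, wins in assignments.windows.items():
        total = 0.0
        for lo, hi in wins:
            if lo < spec.ppm[0] or hi > spec.ppm[-1]:
                raise ValueError(
                    f"{met}: window ({lo}, {hi}) outside spectrum range "
                    f"[{spec.ppm[0]:.3f}, {spec.ppm[-1]:.3f}]"
                )
            total += _trapz_interval(spec.ppm, spec.intensity, lo, hi)
        out[met] = total
    return out


def integrate_metabolite_matrix(
    specs: Iterable[Spectrum], assignments: AssignmentTable
) -> FeatureMatrix:
    """Stack per-spectrum metabolite integrals into a samples x metabolites
    table (column order = assignment-table order)."""
    mets = list(assignments.windows)
    rows, ids = [], []
    for spec in specs:
        vals = integrate_metabolite_regions(spec, assignments)
        rows.append([vals[m] for m in mets])
        ids.append(spec.sample_id)
    return FeatureMatrix(np.asarray(rows, dtype=float), ids, mets)
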