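"""1D 1H-NMR spectra: the data object, file ingestion, chemical-shift
calibration against the TMSP reference, and a simple baseline correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Spectrum:
    """One sample's 1D spectrum: intensity versus chemical shift (ppm).

    The ppm axis is stored strictly ascending regardless of file order
    (NMR spectra are conventionally plotted with ppm decreasing).
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity length mismatch")
        if self.ppm.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.ppm)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending file order: flip
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")

    def copy(self) -> "Spectrum":
        return Spectrum(self.sample_id, self.ppm.copy(), self.intensity.copy())


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) ASCII file.

    Whitespace- or comma-delimited; lines starting with '#' are ignored.
    The filename stem is used as sample_id unless given.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if ("," in text.splitlines()[0] if text.strip() else False) else None
    data = np.loadtxt(path, delimiter=delimiter, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(sample_id or path.stem, data[:, 0], data[:, 1])


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([spec.ppm, spec.intensity]), fmt="%.6f %.8e")


def calibrate_reference(
    spec: Spectrum,
    reference_ppm: float = 0.0,
    search_window: tuple[float, float] = (-0.2, 0.2),
) -> Spectrum:
    """Rigidly shift the ppm axis so the reference peak sits at reference_ppm.

    The reference (TMSP) apex is located as the intensity argmax inside
    ``search_window``; ties on intensity are broken toward the axis point
    closest to ``reference_ppm``. Intensities are unchanged.
    """
    lo, hi = search_window
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not np.any(mask):
        raise ValueError(
            f"no spectral points inside reference search window [{lo}, {hi}]"
        )
    ppm_w = spec.ppm[mask]
    int_w = spec.intensity[mask]
    peak = int_w.max()
    candidates = np.flatnonzero(int_w == peak)
    # tie-break: the candidate apex closest to the reference position
    apex = ppm_w[candidates[np.argmin(np.abs(ppm_w[candidates] - reference_ppm))]]
    shift = reference_ppm - apex
    return Spectrum(spec.sample_id, spec.ppm + shift, spec.intensity.copy())


def correct_baseline(
    spec: Spectrum, method: str = "none", window_ppm: float = 0.5
) -> Spectrum:
    """Optional baseline correction.

    ``none`` returns the input unchanged. ``rolling_min_subtract`` subtracts a
    windowed running-minimum envelope (window ``window_ppm`` wide), a crude but
    deterministic stand-in for instrument-side baseline correction; the output
    never exceeds the input pointwise.
    """
    if method == "none":
        return spec
    if method != "rolling_min_subtract":
        raise ValueError(f"unknown baseline method {method!r}")
    n = spec.ppm.size
    step = np.median(np.diff(spec.ppm))
    half = max(1, int(round(window_ppm / (2 * step))))
    env = np.empty(n)
    for i in range(n):
        j0, j1 = max(0, i - half), min(n, i + half + 1)
        env[i] = spec.intensity[j0:j1].min()
    # only subtract non-negative envelope, so output <= input pointwise
    env = np.maximum(env, 0.0)
    return Spectrum(spec.sample_id, spec.ppm.copy(), spec.intensity - env)
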