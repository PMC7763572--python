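"""Synthetic saliva-metabolome generator.

No raw spectra were deposited by the study this pipeline targets, so this
module generates datasets with the study's statistical structure: ``n_pairs``
subjects sampled at baseline (B) and after therapy (AT) — the pair sharing a
latent subject effect that induces a within-subject correlation ``rho`` — plus
``n_healthy`` independent healthy (HI) samples, over 31 metabolites whose
group means and SDs come from the printed study table packaged in
``data/metabolite_reference.csv``.

The per-group mean used for generation is
``grand_mean + kappa * (mu_g - grand_mean)`` where ``grand_mean`` averages the
three group means; ``kappa=1`` reproduces the printed moments and larger
``kappa`` gives a strong-signal regime for validating the discrimination
machinery. Values are kept non-negative by censoring at zero
(``truncated_normal``) or by a moment-matched lognormal.

A Lorentzian peak library (illustrative singlet positions, not a claim about
true multiplet structure) lets a generated metabolite table be rendered into
full spectra so the preprocessing stage can be exercised end to end.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, SampleMetadata
from .preprocessing import AssignmentTable
from .spectra import Spectrum


def _data_path(name: str):
    return importlib.resources.files("salimet.data").joinpath(name)


def reference_table() -> pd.DataFrame:
    """The packaged 31-metabolite study table: per-group means/SDs and the
    three printed raw p-value columns (Kruskal-Wallis across B/AT/HI, paired
    Wilcoxon B vs AT, Mann-Whitney HI vs AT)."""
    with importlib.resources.as_file(_data_path("metabolite_reference.csv")) as p:
        return pd.read_csv(p)


def peak_library() -> pd.DataFrame:
    """Illustrative 1H singlet positions per metabolite (synthetic rendering
    aid; one Lorentzian per metabolite, all outside the 4.3-6.5 water region)."""
    with importlib.resources.as_file(_data_path("peak_library.csv")) as p:
        return pd.read_csv(p)


@dataclass
class MetaboliteSpec:
    """Generative parameters for one metabolite: group means/SDs in relative
    concentration units, plus optional Lorentzian peaks (center ppm,
    relative height, FWHM ppm) for spectrum rendering."""

    name: str
    mean_B: float
    sd_B: float
    mean_AT: float
    sd_AT: float
    mean_HI: float
    sd_HI: float
    peaks: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        for g in ("B", "AT", "HI"):
            if self.sd(g) < 0:
                raise ValueError(f"{self.name}: negative SD for group {g}")

    def mean(self, group: str) -> float:
        return float(getattr(self, f"mean_{group}"))

    def sd(self, group: str) -> float:
        return float(getattr(self, f"sd_{group}"))

    @property
    def grand_mean(self) -> float:
        return (self.mean_B + self.mean_AT + self.mean_HI) / 3.0

    def effective_mean(self, group: str, kappa: float) -> float:
        """Group mean with its deviation from the grand mean scaled by kappa."""
        return self.grand_mean + kappa * (self.mean(group) - self.grand_mean)


def default_metabolite_specs(with_peaks: bool = True) -> list[MetaboliteSpec]:
    """The 31 packaged metabolites with study-table moments (and peaks)."""
    ref = reference_table()
    peaks = peak_library().set_index("metabolite") if with_peaks else None
    specs = []
    for _, r in ref.iterrows():
        pk = None
        if peaks is not None and r["metabolite"] in peaks.index:
            rows = peaks.loc[[r["metabolite"]]]
            pk = [
                (float(p.center_ppm), float(p.rel_height), float(p.width_ppm))
                for p in rows.itertuples()
            ]
        specs.append(
            MetaboliteSpec(
                name=str(r["metabolite"]),
                mean_B=float(r["mean_B"]), sd_B=float(r["sd_B"]),
                mean_AT=float(r["mean_AT"]), sd_AT=float(r["sd_AT"]),
                mean_HI=float(r["mean_HI"]), sd_HI=float(r["sd_HI"]),
                peaks=pk,
            )
        )
    return specs


def default_assignment_table(half_width: float = 0.02) -> AssignmentTable:
    """Integration windows of +-half_width ppm around each library peak."""
    lib = peak_library()
    wins: dict[str, list[tuple[float, float]]] = {}
    for r in lib.itertuples():
        wins.setdefault(str(r.metabolite), []).append(
            (float(r.center_ppm) - half_width, float(r.center_ppm) + half_width)
        )
    return AssignmentTable(wins)


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults are the study's conditions: 12 paired subjects, 11 healthy
    individuals, within-subject correlation 0.8, effect multiplier 1 (printed
    moments reproduced as-is).
    """

    n_pairs: int = 12
    n_healthy: int = 11
    within_subject_corr: float = 0.8
    effect_multiplier: float = 1.0
    noise_floor: float = 0.0
    seed: int = 0
    distribution: str = "truncated_normal"

    def __post_init__(self) -> None:
        if self.n_pairs < 2 or self.n_healthy < 2:
            raise ValueError("n_pairs and n_healthy must be >= 2")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ValueError("within_subject_corr must be in [0, 1)")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be > 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if self.distribution not in ("truncated_normal", "lognormal_matched"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class SyntheticDataset:
    """Generated metabolite table + metadata + the generating truth."""

    features: FeatureMatrix
    metadata: SampleMetadata
    truth_specs: list[MetaboliteSpec] = field(repr=False)
    config: SimulationConfig = field(repr=False)

    def truth_json(self) -> str:
        specs = [
            {k: v for k, v in asdict(s).items() if k != "peaks"}
            for s in self.truth_specs
        ]
        return json.dumps(
            {"config": asdict(self.config), "metabolites": specs}, indent=1
        )


def _draw_group(
    rng: np.random.Generator,
    z: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    distribution: str,
) -> np.ndarray:
    """Map standard-normal draws z (n x m) to the target marginal moments."""
    if distribution == "truncated_normal":
        return np.maximum(mean + sd * z, 0.0)
    # lognormal matched by mean/SD; degenerate (mean<=0 or sd==0) falls back
    # to the censored normal for that metabolite
    out = np.empty_like(z)
    ok = (mean > 0) & (sd > 0)
    cv2 = np.zeros_like(mean)
    cv2[ok] = (sd[ok] / mean[ok]) ** 2
    s2 = np.log1p(cv2)
    mu = np.where(ok, np.log(np.where(ok, mean, 1.0)) - s2 / 2.0, 0.0)
    out = np.exp(mu + np.sqrt(s2) * z)
    out[:, ~ok] = np.maximum(mean + sd * z, 0.0)[:, ~ok]
    return out


def _generate(
    specs: list[MetaboliteSpec], cfg: SimulationConfig, null: bool
) -> SyntheticDataset:
    if not specs:
        raise ValueError("no metabolite specs given")
    rng = np.random.default_rng(cfg.seed)
    m = len(specs)
    rho = cfg.within_subject_corr
    kappa = cfg.effect_multiplier

    if null:
        grand = np.array([s.grand_mean for s in specs])
        pooled_sd = np.array([(s.sd_B + s.sd_AT + s.sd_HI) / 3.0 for s in specs])
        means = {g: grand for g in ("B", "AT", "HI")}
        sds = {g: pooled_sd for g in ("B", "AT", "HI")}
    else:
        means = {
            g: np.array([s.effective_mean(g, kappa) for s in specs])
            for g in ("B", "AT", "HI")
        }
        sds = {g: np.array([s.sd(g) for s in specs]) for g in ("B", "AT", "HI")}

    # paired draws: shared latent subject effect + independent residuals
    z_subj = rng.standard_normal((cfg.n_pairs, m))
    e_b = rng.standard_normal((cfg.n_pairs, m))
    e_at = rng.standard_normal((cfg.n_pairs, m))
    z_b = np.sqrt(rho) * z_subj + np.sqrt(1 - rho) * e_b
    z_at = np.sqrt(rho) * z_subj + np.sqrt(1 - rho) * e_at
    z_hi = rng.standard_normal((cfg.n_healthy, m))

    x_b = _draw_group(rng, z_b, means["B"], sds["B"], cfg.distribution)
    x_at = _draw_group(rng, z_at, means["AT"], sds["AT"], cfg.distribution)
    x_hi = _draw_group(rng, z_hi, means["HI"], sds["HI"], cfg.distribution)

    if cfg.noise_floor > 0:
        for x in (x_b, x_at, x_hi):
            x += cfg.noise_floor * rng.standard_normal(x.shape)
            np.maximum(x, 0.0, out=x)

    subj = [f"GP{i + 1:02d}" for i in range(cfg.n_pairs)]
    healthy = [f"HI{i + 1:02d}" for i in range(cfg.n_healthy)]
    sample_ids = (
        [f"{s}_B" for s in subj] + [f"{s}_AT" for s in subj] + healthy
    )
    records = (
        [{"sample_id": f"{s}_B", "subject_id": s, "group": "B"} for s in subj]
        + [{"sample_id": f"{s}_AT", "subject_id": s, "group": "AT"} for s in subj]
        + [{"sample_id": h, "subject_id": h, "group": "HI"} for h in healthy]
    )
    fm = FeatureMatrix(
        np.vstack([x_b, x_at, x_hi]), sample_ids, [s.name for s in specs]
    )
    md = SampleMetadata.from_records(records)
    return SyntheticDataset(fm, md, list(specs), cfg)


def generate_feature_table(
    specs: list[MetaboliteSpec] | None = None,
    cfg: SimulationConfig | None = None,
) -> SyntheticDataset:
    """Generate the paired B/AT + independent HI metabolite table.

    Deterministic under ``cfg.seed``; marginal per-group moments match the
    kappa-scaled target values up to the (small, documented) censoring bias.
    """
    return _generate(
        specs if specs is not None else default_metabolite_specs(),
        cfg or SimulationConfig(),
        null=False,
    )


def generate_null_dataset(
    specs: list[MetaboliteSpec] | None = None,
    cfg: SimulationConfig | None = None,
) -> SyntheticDataset:
    """Same pairing structure but no group effect: every group generated from
    the metabolite grand mean and pooled SD (exchangeable null, suitable for
    type-I-error harnesses)."""
    return _generate(
        specs if specs is not None else default_metabolite_specs(),
        cfg or SimulationConfig(),
        null=True,
    )


def render_spectrum(
    concentrations: dict[str, float],
    specs: list[MetaboliteSpec],
    noise_sd: float = 0.0,
    shift_jitter_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "synthetic",
    ppm_range: tuple[float, float] = (-0.7, 10.2),
    n_points: int = 16384,
) -> Spectrum:
    """Render a metabolite concentration map into a full 1D spectrum.

    Intensity is a sum of concentration-scaled Lorentzians from each
    metabolite's peak list, all peak centres shifted by one per-sample global
    offset ~ N(0, shift_jitter_sd), plus white noise. A TMSP reference peak is
    always added at 0.00 ppm (plus the same offset) so the calibration step has
    its anchor. A Lorentzian with FWHM w and amplitude h has analytic area
    h * pi * w / 2.
    """
    by_name = {s.name: s for s in specs}
    rng = np.random.default_rng(seed)
    delta = float(rng.normal(0.0, shift_jitter_sd)) if shift_jitter_sd > 0 else 0.0
    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    intensity = np.zeros_like(ppm)

    def add_lorentzian(center: float, amplitude: float, fwhm: float) -> None:
        hw = fwhm / 2.0
        intensity[:] += amplitude * hw**2 / ((ppm - center) ** 2 + hw**2)

    max_amp = 0.0
    for name, conc in concentrations.items():
        spec = by_name.get(name)
        if spec is None or not spec.peaks:
            raise ValueError(f"no peak list for metabolite {name!r}")
        for center, rel_height, width in spec.peaks:
            amp = conc * rel_height
            add_lorentzian(center + delta, amp, width)
            max_amp = max(max_amp, abs(amp))

    tmsp_amp = max_amp if max_amp > 0 else 1.0
    add_lorentzian(0.0 + delta, tmsp_amp, 0.01)

    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum(sample_id, ppm, intensity)


def render_dataset_spectra(
    ds: SyntheticDataset,
    noise_sd: float = 0.0,
    shift_jitter_sd: float = 0.0,
    **kwargs,
) -> list[Spectrum]:
    """Render every sample of a generated dataset (per-sample jitter/noise
    seeds derived deterministically from the dataset seed)."""
    fm = ds.features
    out = []
    for i, sid in enumerate(fm.sample_ids):
        conc = dict(zip(fm.feature_ids, fm.values[i]))
        out.append(
            render_spectrum(
                conc,
                ds.truth_specs,
                noise_sd=noise_sd,
                shift_jitter_sd=shift_jitter_sd,
                seed=int(
                    np.random.SeedSequence([ds.config.seed, i]).generate_state(1)[0]
                    % (2**31)
                ),
                sample_id=sid,
                **kwargs,
            )
        )
    return out


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.features.to_csv(outdir / "features.csv")
    ds.metadata.to_csv(outdir / "metadata.csv")
    (outdir / "truth.json").write_text(ds.truth_json())
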