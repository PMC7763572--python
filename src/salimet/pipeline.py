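"""End-to-end orchestration: (simulate | ingest) -> preprocess -> paired
multilevel PLS with permutation inference -> three-group OPLS-DA with Monte
Carlo CV and permutation inference -> univariate metabolite table.

Every intermediate (feature matrix, model JSON, score coordinates, validation
JSON, stats TSV) is persisted as diffable text; one master seed determines
simulation, CV splits and permutations, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemometrics import (
    MultilevelPLSDA,
    OPLSDAClassifier,
    fit_mpls_paired,
    model_to_dict,
)
from .containers import FeatureMatrix, SampleMetadata
from .preprocessing import PreprocessConfig, assemble_feature_matrix
from .simulate import (
    SimulationConfig,
    default_metabolite_specs,
    generate_feature_table,
    write_dataset,
)
from .spectra import read_spectrum
from .univariate import build_metabolite_stats_table
from .validation import CVConfig, monte_carlo_cv, permutation_test

log = logging.getLogger("salimet")


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """One of three input modes (simulate, features_csv, spectra_dir) plus
    nested stage configurations."""

    mode: str = "simulate"
    features_csv: str | None = None
    metadata_csv: str | None = None
    spectra_dir: str | None = None
    assignments_csv: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mpls_components: int = 2
    oplsda_components: int = 2
    oplsda_orthogonal: int = 1
    cv: CVConfig = field(default_factory=CVConfig)
    n_permutations: int = 100
    output_dir: str = "salimet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "features_csv", "spectra_dir"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "features_csv" and not (self.features_csv and self.metadata_csv):
            raise ValueError("features_csv mode needs features_csv and metadata_csv")
        if self.mode == "spectra_dir" and not (self.spectra_dir and self.metadata_csv):
            raise ValueError("spectra_dir mode needs spectra_dir and metadata_csv")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("simulation", SimulationConfig),
            ("cv", CVConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


def load_inputs(cfg: PipelineConfig) -> tuple[FeatureMatrix, SampleMetadata]:
    """Resolve the configured input mode into (features, metadata)."""
    if cfg.mode == "simulate":
        sim = SimulationConfig(**{
            **asdict(cfg.simulation), "seed": _subseed(cfg.seed, 0)
        })
        ds = generate_feature_table(default_metabolite_specs(), sim)
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(ds, outdir)
        return ds.features, ds.metadata
    md = SampleMetadata.from_csv(cfg.metadata_csv)
    if cfg.mode == "features_csv":
        return FeatureMatrix.from_csv(cfg.features_csv), md
    specs = sorted(Path(cfg.spectra_dir).glob("*.txt"))
    if not specs:
        raise ValueError(f"no *.txt spectra in {cfg.spectra_dir}")
    spectra = [read_spectrum(p) for p in specs]
    return assemble_feature_matrix(spectra, cfg.preprocess), md


def _scores_frame(model, fm: FeatureMatrix, md: SampleMetadata,
                  subjects=None) -> pd.DataFrame:
    if subjects is not None:
        T = model.transform(fm.values, subjects=subjects)
    else:
        T = model.transform(fm.values)
    df = pd.DataFrame(
        T, index=fm.sample_ids,
        columns=[f"t{a + 1}" for a in range(T.shape[1])],
    )
    if isinstance(model, OPLSDAClassifier) and model.n_orthogonal:
        To = model.orthogonal_scores(fm.values)
        for a in range(To.shape[1]):
            df[f"t_orth{a + 1}"] = To[:, a]
    df["group"] = md.group_of(fm.sample_ids)
    return df


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to
    report.json in the output directory)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_echo(cfg), "stages": {}}

    t0 = time.perf_counter()
    fm, md = load_inputs(cfg)
    fm.to_csv(outdir / "feature_matrix.csv")
    md.to_csv(outdir / "metadata.csv")
    log.info("inputs: %d samples x %d features (%.2fs)",
             fm.n_samples, fm.n_features, time.perf_counter() - t0)

    # --- paired multilevel PLS: B vs AT, permutation inference -------------
    t0 = time.perf_counter()
    groups = md.group_of(fm.sample_ids)
    paired_ids = [s for s, g in zip(fm.sample_ids, groups) if g in ("B", "AT")]
    fm_paired = fm.subset(paired_ids)
    mpls = fit_mpls_paired(fm, md, cfg.mpls_components)
    subj_map = md.subjects
    subjects = np.asarray([subj_map[s] for s in paired_ids], dtype=object)
    _scores_frame(mpls, fm_paired, md, subjects=subjects).to_csv(
        outdir / "mpls_scores.tsv", sep="\t"
    )
    (outdir / "mpls_model.json").write_text(json.dumps(model_to_dict(mpls)))
    cv_seeded = CVConfig(**{**asdict(cfg.cv), "seed": _subseed(cfg.seed, 1)})
    mpls_cv = monte_carlo_cv(fm_paired, md, MultilevelPLSDA(cfg.mpls_components), cv_seeded)
    mpls_perm = permutation_test(
        fm_paired, md, MultilevelPLSDA(cfg.mpls_components), cv_seeded,
        n_permutations=cfg.n_permutations, seed=_subseed(cfg.seed, 2),
    )
    report["stages"]["mpls"] = {
        "accuracy": mpls_cv.mean_accuracy,
        "permutation_p": mpls_perm.p_value,
        "confusion": mpls_cv.pooled_confusion.to_dict(),
        "scores": "mpls_scores.tsv",
        "model": "mpls_model.json",
    }
    log.info("MPLS: accuracy %.3f, permutation p %.4f (%.2fs)",
             mpls_cv.mean_accuracy, mpls_perm.p_value, time.perf_counter() - t0)

    # --- three-group OPLS-DA with Monte Carlo CV ---------------------------
    t0 = time.perf_counter()
    oplsda = OPLSDAClassifier(
        n_components=cfg.oplsda_components, n_orthogonal=cfg.oplsda_orthogonal,
        class_order=["B", "AT", "HI"],
    ).fit(fm.values, groups)
    _scores_frame(oplsda, fm, md).to_csv(outdir / "oplsda_scores.tsv", sep="\t")
    (outdir / "oplsda_model.json").write_text(json.dumps(model_to_dict(oplsda)))
    o_cv = monte_carlo_cv(
        fm, md,
        OPLSDAClassifier(cfg.oplsda_components, cfg.oplsda_orthogonal,
                         class_order=["B", "AT", "HI"]),
        CVConfig(**{**asdict(cfg.cv), "seed": _subseed(cfg.seed, 3)}),
    )
    o_perm = permutation_test(
        fm, md,
        OPLSDAClassifier(cfg.oplsda_components, cfg.oplsda_orthogonal,
                         class_order=["B", "AT", "HI"]),
        CVConfig(**{**asdict(cfg.cv), "seed": _subseed(cfg.seed, 3)}),
        n_permutations=cfg.n_permutations, seed=_subseed(cfg.seed, 4),
    )
    o_cv.pooled_confusion.to_csv(outdir / "oplsda_confusion.tsv", sep="\t")
    report["stages"]["oplsda"] = {
        "accuracy": o_cv.mean_accuracy,
        "permutation_p": o_perm.p_value,
        "confusion": o_cv.pooled_confusion.to_dict(),
        "scores": "oplsda_scores.tsv",
        "model": "oplsda_model.json",
    }
    validation = {
        "mpls": {
            "per_run_accuracy": mpls_cv.per_run_accuracy.tolist(),
            "permutation_p": mpls_perm.p_value,
        },
        "oplsda": {
            "per_run_accuracy": o_cv.per_run_accuracy.tolist(),
            "confusion": o_cv.pooled_confusion.to_dict(),
            "permutation_p": o_perm.p_value,
        },
    }
    (outdir / "validation.json").write_text(json.dumps(validation, indent=1))
    log.info("OPLS-DA: accuracy %.3f, permutation p %.4f (%.2fs)",
             o_cv.mean_accuracy, o_perm.p_value, time.perf_counter() - t0)

    # --- univariate metabolite table ---------------------------------------
    t0 = time.perf_counter()
    stats_table = build_metabolite_stats_table(fm, md)
    stats_table.to_tsv(outdir / "metabolite_stats.tsv")
    long = fm.to_frame().reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="feature", value_name="value"
    )
    long["group"] = long["sample_id"].map(md.groups)
    long.to_csv(outdir / "boxplot_long.tsv", sep="\t", index=False)
    report["stages"]["univariate"] = {
        "table": "metabolite_stats.tsv",
        "boxplot_data": "boxplot_long.tsv",
        "fdr_significant_kruskal_wallis":
            stats_table.significant("fdr_kruskal_wallis"),
        "fdr_significant_wilcoxon_paired":
            stats_table.significant("fdr_wilcoxon_paired"),
    }
    log.info("univariate table done (%.2fs)", time.perf_counter() - t0)

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _config_echo(cfg: PipelineConfig) -> dict:
    import salimet

    echo = asdict(cfg)
    echo["salimet_version"] = salimet.__version__
    return echo
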