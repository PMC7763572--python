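"""Model validation: Monte Carlo cross-validation with pooled confusion
matrix, and permutation tests on the cross-validated accuracy.

Splits are drawn at the *subject* level by default so a paired subject's B and
AT samples never straddle the train/test boundary (no pairing leakage), and
stratified by class composition so every draw keeps all classes represented.
The permutation null preserves the design: for paired two-group models the
B/AT labels are independently swapped (or not) within each subject; otherwise
group labels are shuffled across samples. The permutation p-value uses the
add-one estimator p = (b + 1) / (N + 1) with ties counted in b, so the
smallest attainable p with N = 100 permutations is 1/101 = 0.0099.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .containers import GROUPS, FeatureMatrix, SampleMetadata


@dataclass
class CVConfig:
    n_runs: int = 100
    test_fraction: float = 1 / 3
    unit: str = "subject"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.unit not in ("sample", "subject"):
            raise ValueError("unit must be 'sample' or 'subject'")


@dataclass
class ValidationResult:
    per_run_accuracy: np.ndarray
    pooled_confusion: pd.DataFrame  # rows true class, columns predicted
    n_runs: int

    @property
    def mean_accuracy(self) -> float:
        """Pooled accuracy: correct / total over all held-out predictions."""
        m = self.pooled_confusion.to_numpy()
        return float(np.trace(m) / m.sum())


@dataclass
class PermutationResult:
    observed_stat: float
    permuted_stats: np.ndarray
    n_permutations: int

    @property
    def p_value(self) -> float:
        b = int(np.sum(self.permuted_stats >= self.observed_stat - 1e-12))
        return (b + 1) / (self.n_permutations + 1)


def confusion_and_accuracy(
    true_labels, predicted_labels, class_levels
) -> tuple[np.ndarray, float]:
    """Count matrix (rows = true, columns = predicted) and trace accuracy."""
    true_labels = [str(v) for v in true_labels]
    predicted_labels = [str(v) for v in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    levels = [str(c) for c in class_levels]
    index = {c: i for i, c in enumerate(levels)}
    unknown = sorted((set(true_labels) | set(predicted_labels)) - set(levels))
    if unknown:
        raise ValueError(f"labels outside class_levels: {unknown}")
    mat = np.zeros((len(levels), len(levels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        mat[index[t], index[p]] += 1
    acc = float(np.trace(mat) / mat.sum()) if mat.sum() else 0.0
    return mat, acc


def _class_levels(groups: np.ndarray) -> list[str]:
    present = set(map(str, groups))
    ordered = [g for g in GROUPS if g in present]
    return ordered + sorted(present - set(GROUPS))


def _units_and_strata(
    fm: FeatureMatrix, md: SampleMetadata, unit: str
) -> tuple[list[str], dict[str, list[int]], dict[str, str]]:
    """Unit ids, unit -> sample row indices, unit -> stratum key."""
    groups = md.group_of(fm.sample_ids)
    if unit == "sample":
        ids = list(fm.sample_ids)
        rows = {s: [i] for i, s in enumerate(ids)}
        strata = {s: str(groups[i]) for i, s in enumerate(ids)}
    else:
        subj = md.subjects
        ids = list(dict.fromkeys(subj[s] for s in fm.sample_ids))
        rows = {u: [] for u in ids}
        for i, s in enumerate(fm.sample_ids):
            rows[subj[s]].append(i)
        strata = {
            u: "+".join(sorted({str(groups[i]) for i in rows[u]})) for u in ids
        }
    return ids, rows, strata


def _fit_predict(model, fm, groups, subjects, train_rows, test_rows):
    model = clone(model)
    needs_subj = getattr(model, "requires_subjects", False)
    Xtr, Xte = fm.values[train_rows], fm.values[test_rows]
    ytr = groups[train_rows]
    if needs_subj:
        model.fit(Xtr, ytr, subjects=subjects[train_rows])
        pred = model.predict(Xte, subjects=subjects[test_rows])
    else:
        model.fit(Xtr, ytr)
        pred = model.predict(Xte)
    return pred


def monte_carlo_cv(
    fm: FeatureMatrix,
    md: SampleMetadata,
    model,
    cv: CVConfig | None = None,
) -> ValidationResult:
    """Repeated random stratified train/test splitting.

    Each run holds out ceil(test_fraction x n_units) units per stratum, fits a
    clone of ``model`` on the remaining samples and predicts the held-out
    samples; per-run accuracies and one pooled confusion matrix are
    accumulated. Deterministic given ``cv.seed`` (per-run substreams derived
    by counter, independent of execution order).
    """
    cv = cv or CVConfig()
    groups = md.group_of(fm.sample_ids)
    subj_map = md.subjects
    subjects = np.asarray([subj_map[s] for s in fm.sample_ids], dtype=object)
    if getattr(model, "requires_subjects", False) and cv.unit != "subject":
        raise ValueError("paired multilevel models require unit='subject'")
    levels = _class_levels(groups)
    for c in levels:
        n_units = len({
            subjects[i] if cv.unit == "subject" else fm.sample_ids[i]
            for i in np.flatnonzero(groups == c)
        })
        if n_units < 2:
            raise ValueError(f"class {c!r} has fewer than 2 {cv.unit} units")
    unit_ids, rows, strata = _units_and_strata(fm, md, cv.unit)
    by_stratum: dict[str, list[str]] = {}
    for u in unit_ids:
        by_stratum.setdefault(strata[u], []).append(u)

    accs = np.empty(cv.n_runs)
    pooled = np.zeros((len(levels), len(levels)), dtype=int)
    for run in range(cv.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([cv.seed, run]))
        for attempt in range(10):
            test_units: list[str] = []
            for key in sorted(by_stratum):
                members = by_stratum[key]
                n_test = math.ceil(cv.test_fraction * len(members))
                if not cv.stratified:
                    continue
                pick = rng.choice(len(members), size=n_test, replace=False)
                test_units += [members[i] for i in pick]
            if not cv.stratified:
                n_test = math.ceil(cv.test_fraction * len(unit_ids))
                pick = rng.choice(len(unit_ids), size=n_test, replace=False)
                test_units = [unit_ids[i] for i in pick]
            test_set = set(test_units)
            train_rows = np.asarray(
                [i for u in unit_ids if u not in test_set for i in rows[u]]
            )
            test_rows = np.asarray(
                [i for u in unit_ids if u in test_set for i in rows[u]]
            )
            if set(map(str, groups[train_rows])) == set(levels) and len(test_rows):
                break
        else:
            raise RuntimeError(
                f"run {run}: a class was absent from the training split in "
                f"10 consecutive draws"
            )
        pred = _fit_predict(model, fm, groups, subjects, train_rows, test_rows)
        mat, acc = confusion_and_accuracy(groups[test_rows], pred, levels)
        pooled += mat
        accs[run] = acc
    conf = pd.DataFrame(pooled, index=levels, columns=levels)
    return ValidationResult(accs, conf, cv.n_runs)


def swap_paired_labels(
    md: SampleMetadata, pattern: dict[str, bool]
) -> SampleMetadata:
    """Return metadata with B/AT labels swapped for the flagged subjects
    (pairing preserved; HI rows untouched)."""
    df = md.table.copy()
    flip = {"B": "AT", "AT": "B"}
    for subj, do_swap in pattern.items():
        if do_swap:
            sel = (df["subject_id"] == subj) & df["group"].isin(["B", "AT"])
            df.loc[sel, "group"] = df.loc[sel, "group"].map(flip)
    return SampleMetadata(df)


def shuffle_labels(
    md: SampleMetadata, sample_ids, rng: np.random.Generator
) -> SampleMetadata:
    """Return metadata with the group labels of ``sample_ids`` permuted."""
    df = md.table.copy().set_index("sample_id")
    labels = df.loc[list(sample_ids), "group"].to_numpy()
    df.loc[list(sample_ids), "group"] = rng.permutation(labels)
    return SampleMetadata(df.reset_index())


def permutation_test(
    fm: FeatureMatrix,
    md: SampleMetadata,
    model,
    cv: CVConfig | None = None,
    n_permutations: int = 100,
    seed: int = 0,
    scheme: str = "auto",
    statistic=None,
) -> PermutationResult:
    """Permutation test of a model's cross-validated accuracy.

    ``statistic(fm, md)`` defaults to the pooled Monte Carlo CV accuracy of
    ``model``; the null distribution is built by relabelling: independent
    within-subject B/AT swaps for paired multilevel models
    (``scheme='within_pair_swap'``), a full label shuffle otherwise.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cv = cv or CVConfig()
    if scheme == "auto":
        scheme = (
            "within_pair_swap"
            if getattr(model, "requires_subjects", False)
            else "shuffle"
        )
    if scheme not in ("within_pair_swap", "shuffle"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if statistic is None:
        def statistic(fm_, md_):
            return monte_carlo_cv(fm_, md_, model, cv).mean_accuracy

    observed = float(statistic(fm, md))
    pairs = list(md.pairing_map())
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1 + b]))
        if scheme == "within_pair_swap":
            pattern = {s: bool(rng.integers(2)) for s in pairs}
            md_perm = swap_paired_labels(md, pattern)
        else:
            md_perm = shuffle_labels(md, fm.sample_ids, rng)
        permuted[b] = float(statistic(fm, md_perm))
    return PermutationResult(observed, permuted, n_permutations)
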