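"""Study protocol stages.

- GOSE-stratified 80/20-style split with deterministic per-class rounding
  (floor of fraction x class size to the test set).
- GOSE-stratified k-fold cross-validation with per-fold metric reports.
- Sample-size/accuracy curves: models fitted on increasingly large fresh
  synthetic training cohorts and scored on one fixed large test cohort,
  isolating training-size variance from evaluation noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gosepred._rng import substream
from gosepred.cohort import Cohort, EncodingSpec, encode_design
from gosepred.metrics import MetricReport, full_report
from gosepred.polr import PolrError, polr_fit_reduced, polr_predict
from gosepred.predictors import PredictorSpec, argmax_labels, fit_predictor, predict_set
from gosepred.synthetic import GeneratorConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "SampleSizeCurve",
    "stratified_split",
    "cross_validate",
    "sample_size_curve",
]


@dataclass
class SplitPlan:
    """Disjoint train/test patient-id sets covering the cohort."""

    train_ids: list[str]
    test_ids: list[str]
    test_fraction: float
    seed: int


@dataclass
class SampleSizeCurve:
    """Accuracy as a function of training-set size."""

    points: list[tuple[int, float, float, int]] = field(default_factory=list)
    # (n_train, mean accuracy, sd accuracy, completed replicates)

    @property
    def sizes(self) -> list[int]:
        return [p[0] for p in self.points]

    @property
    def means(self) -> list[float]:
        return [p[1] for p in self.points]


def stratified_split(cohort: Cohort, test_fraction: float, seed: int = 0) -> SplitPlan:
    """Randomized GOSE-stratified split.

    Per observed GOSE level, floor(test_fraction x class size) patients go
    to the test set (so a singleton class lands in training); assignment
    within a level is randomized, deterministic per seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    gose = cohort.data["gose"]
    if gose.isna().any():
        raise ValueError("cohort must be complete-case for a stratified split")
    y = gose.to_numpy(dtype=int)
    ids = cohort.data["patient_id"].astype(str).to_numpy()
    rng = substream(seed, "stratified_split")
    train: list[str] = []
    test: list[str] = []
    for lvl in np.unique(y):
        idx = np.flatnonzero(y == lvl)
        n_test = int(np.floor(test_fraction * idx.size))
        perm = rng.permutation(idx)
        test.extend(ids[perm[:n_test]].tolist())
        train.extend(ids[perm[n_test:]].tolist())
    order = {pid: i for i, pid in enumerate(ids)}
    train.sort(key=order.__getitem__)
    test.sort(key=order.__getitem__)
    return SplitPlan(train_ids=train, test_ids=test, test_fraction=test_fraction, seed=seed)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per record, balanced within each GOSE level."""
    assignment = np.empty(y.size, dtype=int)
    offset = 0
    for lvl in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == lvl))
        folds = (np.arange(idx.size) + offset) % k
        assignment[idx] = folds
        offset += idx.size  # rotate so small classes spread across folds
    return assignment


def cross_validate(
    cohort: Cohort,
    spec: PredictorSpec,
    k: int = 10,
    seed: int = 0,
    encoding_spec: EncodingSpec | None = None,
) -> list[MetricReport]:
    """GOSE-stratified k-fold cross-validation.

    Fits the predictor on k-1 folds and evaluates the held-out fold with
    the full metric report. Every record is held out exactly once. Folds
    that cannot be fitted or evaluated are flagged by a log warning and
    skipped in the returned list.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    gose = cohort.data["gose"]
    if gose.isna().any():
        raise ValueError("cohort must be complete-case for cross-validation")
    y = gose.to_numpy(dtype=int)
    rng = substream(seed, "cross_validate")
    assignment = _stratified_folds(y, k, rng)
    encoding_spec = encoding_spec or EncodingSpec()
    reports: list[MetricReport] = []
    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if test_idx.size == 0:
            logger.warning("cross_validate: fold %d empty, skipped", fold)
            continue
        train = cohort.subset(train_idx)
        test = cohort.subset(test_idx)
        design_train = encode_design(train, encoding_spec)
        design_test = encode_design(test, design_train.spec)
        try:
            model = fit_predictor(spec, design_train, train.data["gose"].to_numpy(dtype=int))
        except PolrError as exc:
            logger.warning("cross_validate: fold %d fit failed (%s), skipped", fold, exc)
            continue
        pset = predict_set(model, design_test, test.data["gose"].to_numpy(dtype=int))
        reports.append(full_report(pset))
    return reports


def sample_size_curve(
    config: GeneratorConfig,
    sizes: list[int],
    replicates: int = 10,
    test_n: int = 10_000,
    seed: int = 0,
    encoding_spec: EncodingSpec | None = None,
) -> SampleSizeCurve:
    """Accuracy of freshly fitted proportional-odds models vs training size.

    For each size n, ``replicates`` independent training cohorts of n
    patients are simulated and fitted; each fit is scored (argmax accuracy)
    on one fixed simulated test cohort of ``test_n`` patients. Fit failures
    at tiny n are skipped and reflected in the recorded replicate count.
    """
    if not sizes:
        raise ValueError("sizes must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sizes = sorted(int(s) for s in sizes)
    encoding_spec = encoding_spec or config.encoding
    from dataclasses import replace as _replace

    test_seed = int(substream(seed, "samplesize_test").integers(2**31))
    test_cohort = simulate_cohort(_replace(config, seed=test_seed, n=int(test_n)))
    design_test = encode_design(test_cohort, encoding_spec)
    y_test = test_cohort.data["gose"].to_numpy(dtype=int)

    curve = SampleSizeCurve()
    for n in sizes:
        accs = []
        for r in range(replicates):
            rep_seed = int(
                substream(seed, "samplesize_train", f"{n}:{r}").integers(2**31)
            )
            train = simulate_cohort(_replace(config, seed=rep_seed, n=n))
            design_train = encode_design(train, encoding_spec)
            labels = train.data["gose"].to_numpy(dtype=int)
            try:
                fit = polr_fit_reduced(design_train, labels)
            except PolrError as exc:
                logger.warning("sample_size_curve: n=%d rep=%d failed (%s)", n, r, exc)
                continue
            probs = polr_predict(fit, design_test)
            pred = argmax_labels(probs)
            accs.append(float(np.mean(pred == y_test)))
        mean = float(np.mean(accs)) if accs else float("nan")
        sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else float("nan")
        curve.points.append((n, mean, sd, len(accs)))
    return curve
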