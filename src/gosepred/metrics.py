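"""Multi-category evaluation suite for 8-level GOSE predictions.

Implements every summary statistic of the study's results table plus the
numbers behind its graphical summaries:

- accuracy and accuracy within one/two categories (AW1, AW2)
- average balanced accuracy (ABA) and macro precision/recall/specificity
  from one-vs-rest confusion counts
- mean discrepancy (MD) and standard-deviation discrepancy (SDD) between
  predicted and observed labels (sample sd, n-1); positive MD = optimistic
- predicted/observed category proportions (PCP/OCP) and their total and
  maximum absolute discrepancies (TCPD in [0, 2], MCPD in [0, 1])
- AUROC for the classic dichotomies: mortality (GOSE 1 vs 2-8, scored by
  p1) and unfavorable outcome (GOSE 1-4 vs 5-8, scored by p1+p2+p3+p4),
  via the Mann-Whitney rank formulation with ties credited 0.5
- 8x8 confusion matrix (rows observed, columns predicted), the error
  distribution (observed - predicted over -7..+7), and per-category
  quantile-binned calibration curves

Per-category terms that are undefined (a category absent from both
predictions and the relevant denominator) are excluded from macro
averages, with the number of exclusions recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from gosepred.cohort import GOSE_LEVELS

__all__ = [
    "MetricReport",
    "CalibrationCurve",
    "accuracy_within",
    "discrepancy_stats",
    "category_proportion_discrepancy",
    "one_vs_rest_stats",
    "dichotomized_auroc",
    "confusion_matrix",
    "error_distribution",
    "calibration_curve",
    "full_report",
]

N_CATEGORIES = len(GOSE_LEVELS)


def _check_pair(pred: Sequence[int], obs: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=int)
    o = np.asarray(obs, dtype=int)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {o.size} observations")
    if p.size == 0:
        raise ValueError("empty input")
    for name, arr in (("pred", p), ("obs", o)):
        if arr.min() < 1 or arr.max() > N_CATEGORIES:
            raise ValueError(f"{name} labels must lie in 1..{N_CATEGORIES}")
    return p, o


def accuracy_within(pred: Sequence[int], obs: Sequence[int], k: int = 0) -> float:
    """Fraction of predictions within ``k`` categories of the observation.

    ``k=0`` is plain accuracy; ``k=7`` is always 1 on the 8-level scale.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    p, o = _check_pair(pred, obs)
    return float(np.mean(np.abs(p - o) <= k))


def discrepancy_stats(pred: Sequence[int], obs: Sequence[int]) -> tuple[float, float]:
    """Mean discrepancy and standard-deviation discrepancy (pred - obs).

    MD > 0 means the model is optimistic (overestimates outcome), MD < 0
    pessimistic. SDD uses the sample standard deviation (n-1) and is NaN
    for n < 2.
    """
    p, o = _check_pair(pred, obs)
    md = float(np.mean(p) - np.mean(o))
    if p.size < 2:
        return md, float("nan")
    sdd = float(np.std(p, ddof=1) - np.std(o, ddof=1))
    return md, sdd


def category_proportion_discrepancy(
    pred: Sequence[int], obs: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """PCP, OCP over all 8 levels, and their total/maximum discrepancies.

    TCPD = sum_j |PCP_j - OCP_j| in [0, 2]; MCPD = max_j |...| in [0, 1].
    Levels absent from both vectors contribute zeros.
    """
    p, o = _check_pair(pred, obs)
    pcp = np.bincount(p, minlength=N_CATEGORIES + 1)[1:] / p.size
    ocp = np.bincount(o, minlength=N_CATEGORIES + 1)[1:] / o.size
    diff = np.abs(pcp - ocp)
    return pcp, ocp, float(diff.sum()), float(diff.max())


def one_vs_rest_stats(
    pred: Sequence[int], obs: Sequence[int]
) -> tuple[float, float, float, float]:
    """ABA and macro precision/recall/specificity from one-vs-rest counts.

    Categories are those present in obs or pred. Per-category terms with a
    zero denominator (e.g. precision when the category is never predicted)
    are excluded from their macro average; ABA averages (sensitivity +
    specificity)/2 over categories with both terms defined.
    """
    p, o = _check_pair(pred, obs)
    categories = sorted(set(p.tolist()) | set(o.tolist()))
    sens_list, spec_list, prec_list, aba_list = [], [], [], []
    for c in categories:
        tp = int(np.sum((p == c) & (o == c)))
        fp = int(np.sum((p == c) & (o != c)))
        fn = int(np.sum((p != c) & (o == c)))
        tn = int(np.sum((p != c) & (o != c)))
        sens = tp / (tp + fn) if (tp + fn) else None
        spec = tn / (tn + fp) if (tn + fp) else None
        prec = tp / (tp + fp) if (tp + fp) else None
        if sens is not None:
            sens_list.append(sens)
        if spec is not None:
            spec_list.append(spec)
        if prec is not None:
            prec_list.append(prec)
        if sens is not None and spec is not None:
            aba_list.append(0.5 * (sens + spec))

    def _macro(values: list[float]) -> float:
        return float(np.mean(values)) if values else float("nan")

    return _macro(aba_list), _macro(prec_list), _macro(sens_list), _macro(spec_list)


def _rank_auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUROC with ties counted 0.5, via midranks."""
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size, dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # midrank (1-based)
        i = j + 1
    rank_sum = float(ranks[positives].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def dichotomized_auroc(
    probabilities: np.ndarray,
    obs: Sequence[int],
    split: str,
) -> float:
    """AUROC for the classic dichotomies of the 8-level outcome.

    ``split="mortality"`` scores GOSE 1 (positive) vs 2-8 by p1;
    ``split="unfavorable"`` scores GOSE 1-4 (positive) vs 5-8 by
    p1+p2+p3+p4. Returns NaN with a warning if only one class is present.
    """
    probs = np.asarray(probabilities, dtype=float)
    o = np.asarray(obs, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != N_CATEGORIES:
        raise ValueError("probabilities must be an (n, 8) matrix")
    if probs.shape[0] != o.size:
        raise ValueError("length mismatch between probabilities and observations")
    if split == "mortality":
        scores = probs[:, 0]
        positives = o == 1
    elif split == "unfavorable":
        scores = probs[:, :4].sum(axis=1)
        positives = o <= 4
    else:
        raise ValueError(f"unknown split {split!r}")
    if positives.all() or not positives.any():
        warnings.warn(
            f"AUROC ({split}) undefined: one class after dichotomization",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return _rank_auroc(scores, positives)


def confusion_matrix(pred: Sequence[int], obs: Sequence[int]) -> np.ndarray:
    """8x8 count matrix with rows = observed GOSE, columns = predicted."""
    p = np.asarray(pred, dtype=int)
    o = np.asarray(obs, dtype=int)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    mat = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(mat, (o - 1, p - 1), 1)
    return mat


def error_distribution(pred: Sequence[int], obs: Sequence[int]) -> dict[int, int]:
    """Histogram of observed - predicted over -7..+7.

    Negative values mean prognosis was overestimated (prediction above the
    observed outcome).
    """
    p = np.asarray(pred, dtype=int)
    o = np.asarray(obs, dtype=int)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    hist = {d: 0 for d in range(-(N_CATEGORIES - 1), N_CATEGORIES)}
    for d in (o - p).tolist():
        hist[int(d)] += 1
    return hist


@dataclass
class CalibrationCurve:
    """Quantile-binned reliability summary for one GOSE category."""

    category: int
    bins: list[tuple[float, float, float, int]]  # (mean pred, obs freq, SE, count)

    @property
    def total(self) -> int:
        return sum(b[3] for b in self.bins)


def calibration_curve(
    probabilities: np.ndarray,
    obs: Sequence[int],
    category: int,
    n_bins: int = 10,
) -> CalibrationCurve:
    """Bin patients by predicted probability of one category.

    Quantile bins; per bin the mean predicted probability, the observed
    fraction with that category, the binomial standard error, and the
    count. Duplicate quantile edges (many identical probabilities) merge
    bins with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if category not in GOSE_LEVELS:
        raise ValueError(f"category must lie in 1..{N_CATEGORIES}")
    probs = np.asarray(probabilities, dtype=float)
    o = np.asarray(obs, dtype=int)
    scores = probs[:, category - 1]
    hits = (o == category).astype(float)
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    if edges.size - 1 < n_bins:
        warnings.warn(
            f"calibration: merged to {max(edges.size - 1, 1)} bins "
            f"(too few distinct probabilities for {n_bins})",
            RuntimeWarning,
            stacklevel=2,
        )
    if edges.size < 2:
        bin_index = np.zeros(scores.size, dtype=int)
        n_eff = 1
    else:
        bin_index = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, edges.size - 2)
        n_eff = edges.size - 1
    bins = []
    for b in range(n_eff):
        mask = bin_index == b
        count = int(mask.sum())
        if count == 0:
            continue
        freq = float(hits[mask].mean())
        se = math.sqrt(freq * (1.0 - freq) / count)
        bins.append((float(scores[mask].mean()), freq, se, count))
    return CalibrationCurve(category=category, bins=bins)


@dataclass
class MetricReport:
    """One row of the results table plus the confusion matrix."""

    accuracy: float
    aw1: float
    aw2: float
    aba: float
    precision_macro: float
    recall_macro: float
    specificity_macro: float
    md: float
    sdd: float
    pcp: np.ndarray
    ocp: np.ndarray
    tcpd: float
    mcpd: float
    auroc_mortality: float
    auroc_unfavorable: float
    confusion: np.ndarray
    n: int
    model_tag: str = ""
    error_hist: dict[int, int] = field(default_factory=dict)

    _TABLE_FIELDS = (
        "accuracy",
        "aw1",
        "aw2",
        "aba",
        "precision_macro",
        "recall_macro",
        "specificity_macro",
        "md",
        "sdd",
        "tcpd",
        "mcpd",
        "auroc_unfavorable",
        "auroc_mortality",
    )

    def to_dict(self) -> dict:
        out = {name: getattr(self, name) for name in self._TABLE_FIELDS}
        out.update(
            {
                "n": self.n,
                "model_tag": self.model_tag,
                "pcp": self.pcp.tolist(),
                "ocp": self.ocp.tolist(),
                "confusion": self.confusion.tolist(),
                "error_hist": {str(k): v for k, v in sorted(self.error_hist.items())},
            }
        )
        return out

    def table_row(self, sep: str = "\t") -> str:
        """Flat TSV row in results-table column order."""
        return sep.join(
            f"{getattr(self, name):.4f}" for name in self._TABLE_FIELDS
        )

    @classmethod
    def table_header(cls, sep: str = "\t") -> str:
        return sep.join(cls._TABLE_FIELDS)


def full_report(prediction_set) -> MetricReport:
    """Compute every report field from a :class:`PredictionSet`."""
    pred = np.asarray(prediction_set.predicted, dtype=int)
    obs = np.asarray(prediction_set.observed, dtype=int)
    probs = np.asarray(prediction_set.probabilities, dtype=float)
    if pred.size == 0:
        raise ValueError("empty prediction set")
    md, sdd = discrepancy_stats(pred, obs)
    pcp, ocp, tcpd, mcpd = category_proportion_discrepancy(pred, obs)
    aba, prec, rec, spec = one_vs_rest_stats(pred, obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        auroc_m = dichotomized_auroc(probs, obs, "mortality")
        auroc_u = dichotomized_auroc(probs, obs, "unfavorable")
    return MetricReport(
        accuracy=accuracy_within(pred, obs, 0),
        aw1=accuracy_within(pred, obs, 1),
        aw2=accuracy_within(pred, obs, 2),
        aba=aba,
        precision_macro=prec,
        recall_macro=rec,
        specificity_macro=spec,
        md=md,
        sdd=sdd,
        pcp=pcp,
        ocp=ocp,
        tcpd=tcpd,
        mcpd=mcpd,
        auroc_mortality=auroc_m,
        auroc_unfavorable=auroc_u,
        confusion=confusion_matrix(pred, obs),
        n=int(pred.size),
        model_tag=getattr(prediction_set, "model_tag", ""),
        error_hist=error_distribution(pred, obs),
    )
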