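"""Balanced-undersampling ensemble of proportional-odds models.

Class imbalance in the 8-level outcome is mitigated by drawing, for each
ensemble member, a balanced subsample (per observed GOSE level, up to a
target count sampled without replacement), fitting an unpenalized
proportional-odds model on it, and aggregating the members' predicted
probability vectors by the per-category median. The 8 medians do not sum
to 1, so the aggregated vector is renormalized by its sum.

Members whose subsample never contains a GOSE level contribute zero
probability for it, so rare levels can keep a zero median — the mechanism
behind the persistent failure to predict near-empty categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gosepred._rng import substream
from gosepred.cohort import Cohort, DesignMatrix, EncodingSpec, encode_design
from gosepred.polr import PolrError, PolrFit, polr_fit_reduced, polr_predict

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleModel",
    "balanced_undersample",
    "fit_ensemble",
    "ensemble_predict",
]


@dataclass
class EnsembleModel:
    """Collection of member fits plus the audit trail of their subsamples."""

    members: list[PolrFit]
    subsample_plan: list[list[str]]
    seed: int
    aggregation: str = "median"
    encoding_spec: EncodingSpec = field(default_factory=EncodingSpec)
    retries: int = 0

    @property
    def m(self) -> int:
        return len(self.members)

    def coverage(self, patient_ids: list[str]) -> float:
        """Fraction of the given patients drawn into at least one member."""
        seen: set[str] = set()
        for plan in self.subsample_plan:
            seen.update(plan)
        return sum(pid in seen for pid in patient_ids) / max(len(patient_ids), 1)

    def predict_proba(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        return ensemble_predict(self, design)


def balanced_undersample(
    cohort: Cohort,
    target_per_class: int | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Per-GOSE-level random subsample without replacement.

    Each observed level contributes min(target, level size) patients; the
    automatic target (``target_per_class=None``) is the smallest observed
    level size. Reproducible from ``seed``.
    """
    if len(cohort) == 0:
        raise ValueError("cannot undersample an empty cohort")
    gose = cohort.data["gose"]
    if gose.isna().any():
        raise ValueError("cohort must be complete-case (missing gose present)")
    y = gose.to_numpy(dtype=int)
    rng = rng if rng is not None else substream(seed, "balanced_undersample")
    levels, counts = np.unique(y, return_counts=True)
    target = int(counts.min()) if target_per_class is None else int(target_per_class)
    keep: list[int] = []
    for lvl in levels:
        idx = np.flatnonzero(y == lvl)
        take = min(target, idx.size)
        keep.extend(rng.choice(idx, size=take, replace=False).tolist())
    keep.sort()  # preserve original record order
    return cohort.subset(keep, name=f"{cohort.name}-balanced")


def fit_ensemble(
    cohort: Cohort,
    m: int = 200,
    target_per_class: int | None = None,
    seed: int = 0,
    encoding_spec: EncodingSpec | None = None,
    max_retries: int = 3,
) -> EnsembleModel:
    """Fit ``m`` proportional-odds members on independent balanced subsamples.

    Each member has its own seeded substream. Design columns that are
    constant within a member's subsample (a dummy level absent from the
    draw) are dropped for that fit and re-enter the full coefficient
    vector as zeros. Members that fail to fit are retried on a fresh
    subsample up to ``max_retries`` times; exhausting the cap raises.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    encoding_spec = encoding_spec or EncodingSpec()
    members: list[PolrFit] = []
    plan: list[list[str]] = []
    total_retries = 0
    for i in range(m):
        rng = substream(seed, "ensemble_member", str(i))
        last_error: Exception | None = None
        for attempt in range(max_retries + 1):
            sub = balanced_undersample(cohort, target_per_class, rng=rng)
            try:
                fit = _fit_member(sub, encoding_spec)
            except PolrError as exc:
                last_error = exc
                total_retries += 1
                continue
            if not fit.converged:
                last_error = PolrError("member did not converge")
                total_retries += 1
                continue
            members.append(fit)
            plan.append(sub.data["patient_id"].astype(str).tolist())
            break
        else:
            raise PolrError(
                f"ensemble member {i}: retry cap ({max_retries}) exhausted; "
                f"last error: {last_error}"
            )
    if total_retries:
        logger.info("fit_ensemble: %d member refits after failures", total_retries)
    model = EnsembleModel(
        members=members,
        subsample_plan=plan,
        seed=seed,
        encoding_spec=encoding_spec,
        retries=total_retries,
    )
    cov = model.coverage(cohort.data["patient_id"].astype(str).tolist())
    logger.info("fit_ensemble: %d members, training coverage %.3f", m, cov)
    return model


def _fit_member(sub: Cohort, encoding_spec: EncodingSpec) -> PolrFit:
    """Fit one member, dropping in-subsample-degenerate design columns."""
    design = encode_design(sub, encoding_spec)
    labels = sub.data["gose"].to_numpy(dtype=int)
    return polr_fit_reduced(design, labels, encoding_spec=encoding_spec)


def ensemble_predict(model: EnsembleModel, design: DesignMatrix | np.ndarray) -> np.ndarray:
    """Median-aggregated probability vectors, renormalized to sum to 1."""
    if model.m == 0:
        raise ValueError("empty ensemble")
    stack = np.stack([polr_predict(fit, design) for fit in model.members])  # (m, n, 8)
    med = np.median(stack, axis=0)
    sums = med.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):  # pragma: no cover - all-zero medians cannot normalize
        raise ValueError("degenerate median vector with zero total mass")
    return med / sums
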