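"""Scoring against truth, chart-review sampling, approach comparison.

Two truth modes mirror how rule-based phenotyping is validated in practice:

* ``review`` — truth labels exist only for predicted-positive encounters
  (manual chart review of flagged cases). Precision is computable; recall is
  undefined and reported as ``None``.
* ``full`` — truth covers the whole corpus (possible with synthetic data);
  precision and recall are both computed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "EvalReport",
    "OverlapSummary",
    "confusion",
    "sample_for_review",
    "compare_approaches",
]


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and precision/recall; ``None`` marks undefined."""

    n_reviewed: int
    true_positive: int
    false_positive: int
    false_negative: int | None = None
    precision: float | None = None
    recall: float | None = None
    mode: str = "full"


@dataclass(frozen=True)
class OverlapSummary:
    """Positive-set overlap between two approaches (Venn counts)."""

    a_only: int
    b_only: int
    both: int
    a_only_patients: int | None = None
    b_only_patients: int | None = None
    both_patients: int | None = None


def _truth_mapping(truth) -> dict:
    if isinstance(truth, Mapping):
        return dict(truth)
    out = {}
    for t in truth:
        out[t.encounter_id] = bool(t.is_ipv)
    return out


def confusion(pred: Sequence, truth, mode: str = "full") -> EvalReport:
    """Score predictions against truth records.

    ``pred`` is a sequence of per-encounter results (``encounter_id`` +
    boolean ``label``); ``truth`` is a mapping ``encounter_id -> bool`` or a
    sequence of truth records. In review mode only predicted positives with
    a truth label are scored (n_reviewed counts them); in full mode every
    prediction must have a truth label, and missing ids are a hard error.
    """
    if mode not in ("review", "full"):
        raise ValueError(f"unknown mode {mode!r}; expected 'review' or 'full'")
    tmap = _truth_mapping(truth)
    if mode == "review":
        reviewed = [r for r in pred if r.label and r.encounter_id in tmap]
        tp = sum(1 for r in reviewed if tmap[r.encounter_id])
        fp = len(reviewed) - tp
        precision = tp / (tp + fp) if (tp + fp) > 0 else None
        return EvalReport(
            n_reviewed=len(reviewed),
            true_positive=tp,
            false_positive=fp,
            false_negative=None,
            precision=precision,
            recall=None,
            mode="review",
        )
    tp = fp = fn = 0
    for r in pred:
        if r.encounter_id not in tmap:
            raise KeyError(
                f"prediction for {r.encounter_id!r} has no truth record in full mode"
            )
        actual = tmap[r.encounter_id]
        if r.label and actual:
            tp += 1
        elif r.label and not actual:
            fp += 1
        elif not r.label and actual:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return EvalReport(
        n_reviewed=len(pred),
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        precision=precision,
        recall=recall,
        mode="full",
    )


def _allocate(sizes: dict, total: int) -> dict:
    """Largest-remainder allocation of ``total`` across strata (±1 fair)."""
    grand = sum(sizes.values())
    raw = {k: total * v / grand for k, v in sizes.items()}
    alloc = {k: math.floor(x) for k, x in raw.items()}
    short = total - sum(alloc.values())
    for k in sorted(raw, key=lambda k: (raw[k] - alloc[k], k), reverse=True)[:short]:
        alloc[k] += 1
    return {k: min(v, sizes[k]) for k, v in alloc.items()}


def sample_for_review(
    results: Sequence,
    fraction: float,
    seed: int,
    stratify_by_year: bool = False,
    visit_dates: Mapping | None = None,
):
    """Uniform random subset of positive results for manual chart review.

    Sample size is ``round(fraction * n_positive)``; with
    ``stratify_by_year`` the sample preserves each calendar year's share
    (within ±1, largest-remainder allocation) using ``visit_dates``
    (encounter_id -> date). Deterministic given the seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    positives = [r for r in results if r.label]
    if not positives:
        return []
    rng = random.Random(seed)
    total = round(fraction * len(positives))
    if not stratify_by_year:
        return rng.sample(positives, total)
    if visit_dates is None:
        raise ValueError("stratify_by_year requires visit_dates")
    by_year: dict[int, list] = {}
    for r in positives:
        by_year.setdefault(visit_dates[r.encounter_id].year, []).append(r)
    alloc = _allocate({y: len(v) for y, v in by_year.items()}, total)
    sample = []
    for year in sorted(by_year):
        sample.extend(rng.sample(by_year[year], alloc[year]))
    return sample


def compare_approaches(
    a: Sequence, b: Sequence, patient_ids: Mapping | None = None
) -> OverlapSummary:
    """Venn counts of the positive sets of two approaches on one corpus.

    Both result lists must cover the same encounter ids (hard error
    otherwise). Distinct-patient counts are included when a
    ``encounter_id -> patient_id`` mapping is supplied.
    """
    ids_a = {r.encounter_id for r in a}
    ids_b = {r.encounter_id for r in b}
    if ids_a != ids_b:
        raise ValueError("approach results cover different encounter id sets")
    pos_a = {r.encounter_id for r in a if r.label}
    pos_b = {r.encounter_id for r in b if r.label}
    a_only, b_only, both = pos_a - pos_b, pos_b - pos_a, pos_a & pos_b
    if patient_ids is None:
        return OverlapSummary(len(a_only), len(b_only), len(both))
    return OverlapSummary(
        len(a_only),
        len(b_only),
        len(both),
        a_only_patients=len({patient_ids[e] for e in a_only}),
        b_only_patients=len({patient_ids[e] for e in b_only}),
        both_patients=len({patient_ids[e] for e in both}),
    )
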