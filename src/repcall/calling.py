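"""Per-well positivity calling and k-of-n replicate combination.

A well is *positive* when its methylation-target Ct is detected at or below
the assay cutoff, *negative* otherwise, and *invalid* when its ACTB
internal control failed (undetected or beyond the cycle ceiling), since a
failed control means the well carried no assayable DNA. A subject is
positive under the k-of-n rule when at least k of the n wells are positive;
any invalid well invalidates the whole subject, which downstream statistics
exclude from denominators (with a logged warning) rather than guess at.

The ``1/1`` rule is not a per-subject vote: it is the mean of the
single-well sensitivities and specificities across replicate positions and
lives in :mod:`repcall.performance`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .cohort_io import (AssayConfig, Cohort, ReplicateMeasurement,
                        SubjectRecord, is_detected)
from .errors import ValidationError

logger = logging.getLogger(__name__)


class BinaryCall(Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    INVALID = "INVALID"


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named replicate-combination rule.

    ``1/3``, ``2/3`` and ``3/3`` require at least k positive wells of
    three; ``1/1`` denotes the averaged single-well summary and cannot be
    applied per subject.
    """

    name: str
    k_required: int

    _BY_NAME = {"1/3": 1, "2/3": 2, "3/3": 3, "1/1": 1}

    @classmethod
    def from_name(cls, name: str) -> "AlgorithmSpec":
        if name not in cls._BY_NAME:
            raise ValidationError(
                f"unknown algorithm {name!r}; allowed: "
                f"{sorted(cls._BY_NAME)}")
        return cls(name=name, k_required=cls._BY_NAME[name])

    @property
    def is_averaged(self) -> bool:
        return self.name == "1/1"


def call_replicate(m: ReplicateMeasurement, assay: AssayConfig) -> BinaryCall:
    """Call one well: INVALID on control failure, else positive iff the
    target Ct is detected and <= the cutoff (ties at the cutoff positive)."""
    if (not is_detected(m.control_ct)
            or float(m.control_ct) > assay.max_cycles):
        return BinaryCall.INVALID
    if is_detected(m.target_ct) and float(m.target_ct) <= assay.ct_cutoff:
        return BinaryCall.POSITIVE
    return BinaryCall.NEGATIVE


def combine_k_of_n(calls: Sequence[BinaryCall], k: int) -> BinaryCall:
    """Positive iff at least ``k`` of the calls are positive.

    ``k=1`` is logical OR, ``k=len(calls)`` logical AND. Calls must already
    be resolved (no INVALID entries; see :func:`call_subject`).
    """
    if not 1 <= k <= len(calls):
        raise ValidationError(
            f"k={k} out of range [1, {len(calls)}]")
    if any(c is BinaryCall.INVALID for c in calls):
        raise ValidationError("combine_k_of_n received an INVALID call; "
                              "resolve validity first (see call_subject)")
    n_pos = sum(c is BinaryCall.POSITIVE for c in calls)
    return BinaryCall.POSITIVE if n_pos >= k else BinaryCall.NEGATIVE


def call_subject(s: SubjectRecord, assay: AssayConfig,
                 alg: AlgorithmSpec) -> BinaryCall:
    """Combined subject call under a k-of-n rule.

    Any invalid well (failed ACTB control) makes the subject INVALID.
    """
    if alg.is_averaged:
        raise ValidationError(
            "the 1/1 algorithm is an averaged performance summary, not a "
            "per-subject call; use "
            "performance.averaged_single_replicate_performance")
    calls = [call_replicate(m, assay) for m in s.replicates]
    if any(c is BinaryCall.INVALID for c in calls):
        return BinaryCall.INVALID
    return combine_k_of_n(calls, alg.k_required)


def per_replicate_calls(cohort: Cohort,
                        assay: AssayConfig | None = None) -> pd.DataFrame:
    """Complete (subject x replicate) matrix of single-well calls.

    Returns a DataFrame indexed by subject_id with one column per replicate
    position, cells holding :class:`BinaryCall`.
    """
    assay = assay or cohort.assay
    index, rows = [], []
    for s in cohort.subjects:
        index.append(s.subject_id)
        rows.append([call_replicate(m, assay) for m in s.replicates])
    cols = [f"replicate_{i}" for i in range(1, assay.n_replicates + 1)]
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"),
                        columns=cols)
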