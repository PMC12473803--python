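"""Bilateral aggregation: 72 per-foot features -> 144 per scenario.

Each registered feature yields two scenario-level columns: the
arithmetic mean of the left and right foot values, and a normalized
asymmetry index |L - R| / (|L| + |R|) in [0, 1] quantifying lateralized
imbalance.  Column names follow the ``<feature>—Average`` /
``<feature>—Asymmetry`` convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector
from .registry import ASYMMETRY_SUFFIX, AVERAGE_SUFFIX, FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FootFeaturePair",
    "average_feature",
    "asymmetry_feature",
    "aggregate_pair",
    "build_scenario_table",
    "scenario_feature_columns",
]

_DENOM_EPS = 1e-12


@dataclass
class FootFeaturePair:
    """Left- and right-foot feature vectors sharing the registry order."""

    left: FeatureVector
    right: FeatureVector


def average_feature(left_value: float, right_value: float) -> float:
    """Arithmetic mean of the two sides; NaN propagates from either side."""
    return (left_value + right_value) / 2.0


def asymmetry_feature(left_value: float, right_value: float, signed: bool = False) -> float:
    """Normalized left-right difference.

    Default (absolute) form is |L - R| / (|L| + |R|), bounded in [0, 1].
    Both sides exactly zero is perfect symmetry at null magnitude and
    returns 0; a denominator at floating-noise level with unequal sides
    is undefined (NaN).  ``signed=True`` gives the raw (L - R)/(L + R)
    variant for sensitivity analyses.
    """
    if math.isnan(left_value) or math.isnan(right_value):
        return float("nan")
    if left_value == 0.0 and right_value == 0.0:
        logger.debug("asymmetry of a zero-magnitude pair defined as 0")
        return 0.0
    if signed:
        denom = left_value + right_value
        return (left_value - right_value) / denom if abs(denom) > _DENOM_EPS else float("nan")
    denom = abs(left_value) + abs(right_value)
    if denom < _DENOM_EPS:
        return float("nan")
    return abs(left_value - right_value) / denom


def scenario_feature_columns() -> list[str]:
    """The 144 scenario column names in fixed order: all averages, then
    all asymmetries, each in registry order."""
    return [f"{n}{AVERAGE_SUFFIX}" for n in FEATURE_NAMES] + [
        f"{n}{ASYMMETRY_SUFFIX}" for n in FEATURE_NAMES
    ]


def aggregate_pair(pair: FootFeaturePair, signed_asymmetry: bool = False) -> pd.Series:
    """One participant's 144-value scenario row from a foot pair."""
    left, right = pair.left.values, pair.right.values
    averages = [average_feature(left[n], right[n]) for n in FEATURE_NAMES]
    asymmetries = [
        asymmetry_feature(left[n], right[n], signed=signed_asymmetry)
        for n in FEATURE_NAMES
    ]
    return pd.Series(averages + asymmetries, index=scenario_feature_columns(), dtype=float)


def build_scenario_table(
    pairs: Mapping[str, Sequence[FootFeaturePair] | FootFeaturePair],
    labels: Mapping[str, str],
    scenario: str,
    signed_asymmetry: bool = False,
) -> pd.DataFrame:
    """Assemble the participants x 144 scenario feature table.

    ``pairs`` maps participant id to one foot pair or to a sequence of
    pairs (repeated trials); per-feature values are averaged across a
    participant's trials.  Participants missing from ``labels`` or with
    no usable pair are excluded with a logged reason.  The result
    carries the 144 feature columns in fixed order plus ``group`` and
    ``scenario`` columns, indexed by participant id.
    """
    rows: dict[str, pd.Series] = {}
    for pid, entry in pairs.items():
        if pid not in labels:
            logger.warning("participant %s excluded: no group label", pid)
            continue
        trial_pairs = [entry] if isinstance(entry, FootFeaturePair) else list(entry)
        if not trial_pairs:
            logger.warning("participant %s excluded: no foot pairs", pid)
            continue
        per_trial = [aggregate_pair(p, signed_asymmetry) for p in trial_pairs]
        rows[pid] = pd.concat(per_trial, axis=1).mean(axis=1)

    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=scenario_feature_columns())
    table.index.name = "participant_id"
    table["group"] = [labels[pid] for pid in table.index]
    table["scenario"] = scenario
    return table
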