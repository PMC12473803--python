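"""End-to-end convenience: cohort of trials -> scenario feature table."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .aggregate import FootFeaturePair, build_scenario_table
from .features import extract_all
from .sensor_io import SimulatedTrial, extract_scenario

__all__ = ["trial_feature_pair", "cohort_feature_table"]


def trial_feature_pair(trial: SimulatedTrial, scenario: str = "full_tug") -> FootFeaturePair:
    """Per-foot 72-feature vectors for one trial under a scenario cut."""
    left, right = extract_scenario(trial, scenario)
    return FootFeaturePair(left=extract_all(left), right=extract_all(right))


def cohort_feature_table(
    trials: Iterable[SimulatedTrial],
    scenario: str = "full_tug",
    signed_asymmetry: bool = False,
) -> pd.DataFrame:
    """The participants x 144 scenario table for a cohort.

    Multiple trials sharing a participant id are feature-averaged.
    """
    pairs: dict[str, list[FootFeaturePair]] = {}
    labels: dict[str, str] = {}
    for trial in trials:
        pairs.setdefault(trial.participant_id, []).append(
            trial_feature_pair(trial, scenario)
        )
        labels[trial.participant_id] = trial.group_label
    return build_scenario_table(pairs, labels, scenario, signed_asymmetry)
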