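"""Frozen registry of the 72 per-foot CoP features.

The feature set spans four domains of postural-sway description --
positional (geometry of the CoP cloud), dynamic (velocity-based),
frequency (Welch power-spectrum descriptors per axis) and stochastic
(stabilogram-diffusion quantities) -- and is frozen in a versioned
manifest shipped with the package.  The count of exactly 72 entries is
a structural contract of the pipeline (bilateral aggregation doubles it
to 144 per scenario) and is enforced at import time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "FeatureSpec",
    "FEATURES",
    "FEATURE_NAMES",
    "DOMAINS",
    "AXES",
    "N_FEATURES",
    "resolve",
    "features_in_domain",
]

DOMAINS = ("positional", "dynamic", "frequency", "stochastic")
AXES = ("ML", "AP", "ML-AP", "planar")
N_FEATURES = 72

#: suffixes appended by bilateral aggregation (em dash, Table-style naming)
AVERAGE_SUFFIX = "—Average"
ASYMMETRY_SUFFIX = "—Asymmetry"


@dataclass(frozen=True)
class FeatureSpec:
    """One registered feature: its canonical name, domain and axis tag."""

    name: str
    domain: str
    axis: str
    description: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.name!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r} for {self.name!r}")


def _load_manifest() -> tuple[FeatureSpec, ...]:
    path = resources.files("copbench.data").joinpath("feature_manifest.csv")
    with path.open("r", encoding="utf-8") as handle:
        rows = list(csv.DictReader(handle))
    specs = tuple(
        FeatureSpec(r["name"], r["domain"], r["axis"], r["description"]) for r in rows
    )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise RuntimeError("feature manifest contains duplicate names")
    if len(specs) != N_FEATURES:
        raise RuntimeError(
            f"feature manifest must define exactly {N_FEATURES} features, "
            f"found {len(specs)}"
        )
    return specs


FEATURES: tuple[FeatureSpec, ...] = _load_manifest()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in FEATURES)
_BY_NAME = {s.name: s for s in FEATURES}


def resolve(name: str) -> FeatureSpec:
    """Look up a feature by canonical name.

    Aggregated names carrying an em-dash ``—Average`` / ``—Asymmetry``
    suffix (the scenario-table column style) resolve to their base
    feature.  Raises ``KeyError`` for unknown names.
    """
    base = name
    for suffix in (AVERAGE_SUFFIX, ASYMMETRY_SUFFIX):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    try:
        return _BY_NAME[base]
    except KeyError:
        raise KeyError(f"{name!r} is not a registered CoP feature") from None


def features_in_domain(domain: str) -> tuple[FeatureSpec, ...]:
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    return tuple(s for s in FEATURES if s.domain == domain)
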