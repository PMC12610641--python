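"""Relative Odor Activity Value (ROAV) computation and classification.

The odor activity value of a compound is its concentration divided by its
odor detection threshold; the *relative* OAV rescales within each sample so
that the most odor-potent compound scores 100:

    ROAV_i = (C_i / T_i) / (C_ref / T_ref) * 100

where C_i is the relative abundance (percent of total peak area), T_i the
resolved odor threshold, and the reference the compound maximizing C/T among
detected, thresholded compounds.  ROAV >= 1.0 marks a key aroma compound
(decisive impact on the overall flavor); 0.1 <= ROAV < 1.0 a modifier
(nuance-enhancing); smaller values are negligible; 0 means absent.

Threshold resolution: air-medium thresholds take priority; water-medium
values are the fallback; when the selected medium has several reports, their
arithmetic mean is the representative threshold.  Threshold magnitudes are
used in their source units (mg/m3 in air, mg/kg in water) without
conversion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Medium, ThresholdDB, ThresholdEntry, VOCTable, canonical_name

__all__ = [
    "Tier",
    "ResolutionRule",
    "ResolvedThreshold",
    "ROAVProfile",
    "resolve_threshold",
    "resolve_all",
    "find_reference",
    "compute_roav_profile",
    "compute_all_profiles",
    "classify_roav",
    "compare_cultivars",
]


class Tier(str, enum.Enum):
    KEY = "key"
    MODIFIER = "modifier"
    NEGLIGIBLE = "negligible"
    ABSENT = "absent"


class ResolutionRule(str, enum.Enum):
    SINGLE = "single"
    AIR_PRIORITY = "air_priority"
    WATER_FALLBACK = "water_fallback"
    MEAN = "mean"


@dataclass(frozen=True)
class ResolvedThreshold:
    compound_id: str
    value: float
    medium: Medium
    n_sources: int
    rule_applied: ResolutionRule


def resolve_threshold(entries: Sequence[ThresholdEntry]) -> ResolvedThreshold:
    """Collapse a compound's threshold reports to one representative value.

    Air entries are preferred; water entries are used only when no air value
    exists.  Within the selected medium the arithmetic mean of all reports is
    taken.  The medium filter is applied *before* averaging.
    """
    if not entries:
        raise ValueError("cannot resolve an empty threshold entry list")
    cid = entries[0].compound_id
    if any(e.compound_id != cid for e in entries):
        raise ValueError("threshold entries span multiple compounds")
    air = [e for e in entries if e.medium is Medium.AIR]
    water = [e for e in entries if e.medium is Medium.WATER]
    if air:
        chosen, medium = air, Medium.AIR
        rule = (
            ResolutionRule.SINGLE
            if len(entries) == 1
            else (ResolutionRule.AIR_PRIORITY if water else ResolutionRule.MEAN)
        )
        if len(entries) > 1 and not water and len(air) > 1:
            rule = ResolutionRule.MEAN
    else:
        chosen, medium = water, Medium.WATER
        rule = ResolutionRule.SINGLE if len(entries) == 1 else ResolutionRule.MEAN
        if len(entries) == len(water) and len(water) == 1:
            rule = ResolutionRule.WATER_FALLBACK if entries[0].medium is Medium.WATER else rule
    # a single water entry is simultaneously "single" and a water fallback;
    # report the more informative label
    if medium is Medium.WATER and len(chosen) == 1:
        rule = ResolutionRule.WATER_FALLBACK
    value = float(np.mean([e.value for e in chosen]))
    return ResolvedThreshold(cid, value, medium, n_sources=len(entries), rule_applied=rule)


def resolve_all(db: ThresholdDB) -> dict[str, ResolvedThreshold]:
    """Resolve every compound in a threshold multimap."""
    return {cid: resolve_threshold(db.entries(cid)) for cid in db.compound_ids}


def _threshold_value(t) -> float:
    return t.value if isinstance(t, ResolvedThreshold) else float(t)


def find_reference(
    abundances: Mapping[str, float] | pd.Series,
    thresholds: Mapping[str, "ResolvedThreshold | float"],
    *,
    rule: str = "ct-max",
) -> str:
    """Select the sample's reference (ROAV = 100) compound.

    ``"ct-max"`` (default) picks the compound maximizing C/T among detected,
    thresholded compounds — the rule that reproduces published ROAV tables.
    ``"conc-max"`` picks the highest-concentration thresholded compound
    instead.  Ties break lexicographically on compound id.
    """
    if rule not in ("ct-max", "conc-max"):
        raise ValueError(f"unknown reference rule {rule!r}")
    norm = {canonical_name(k): _threshold_value(v) for k, v in thresholds.items()}
    best: tuple[float, str] | None = None
    for cid, c in dict(abundances).items():
        cid = canonical_name(cid)
        if c <= 0 or cid not in norm:
            continue
        score = c / norm[cid] if rule == "ct-max" else c
        if best is None or score > best[0] or (score == best[0] and cid < best[1]):
            best = (score, cid)
    if best is None:
        raise ValueError("no detected compound with a resolved threshold")
    return best[1]


def classify_roav(value: float) -> Tier:
    """Tier a ROAV: key (>=1), modifier ([0.1, 1)), negligible ((0, 0.1)), absent (0)."""
    if not (0 <= value <= 100):
        raise ValueError(f"ROAV {value} outside [0, 100]")
    return _tier(value)


def _tier(value: float) -> Tier:
    if value == 0:
        return Tier.ABSENT
    if value >= 1.0:
        return Tier.KEY
    if value >= 0.1:
        return Tier.MODIFIER
    return Tier.NEGLIGIBLE


@dataclass
class ROAVProfile:
    """Per-sample ROAV values, reference compound, and classification tiers."""

    sample_id: str
    reference_compound: str
    roav: dict[str, float]
    tier: dict[str, Tier]
    excluded: list[str] = field(default_factory=list)  # detected but no threshold

    def key_compounds(self) -> list[str]:
        return [c for c, t in self.tier.items() if t is Tier.KEY]

    def as_series(self) -> pd.Series:
        return pd.Series(self.roav, name=self.sample_id)


def compute_roav_profile(
    table: VOCTable,
    thresholds: ThresholdDB | Mapping[str, ResolvedThreshold],
    sample: str,
    *,
    reference_rule: str = "ct-max",
) -> ROAVProfile:
    """ROAV profile of one sample column, computed on replicate means.

    Compounds without any threshold report are excluded from the ROAV map and
    listed in ``excluded`` (when detected); undetected compounds get ROAV 0
    and tier ``absent``.
    """
    resolved = resolve_all(thresholds) if isinstance(thresholds, ThresholdDB) else dict(thresholds)
    profile = table.sample_profile(sample)
    detected = table.detected[sample]
    abund = {cid: (float(profile[cid]) if detected[cid] else 0.0) for cid in table.compound_ids}
    ref = find_reference(abund, resolved, rule=reference_rule)
    ref_ratio = abund[ref] / resolved[ref].value

    roav: dict[str, float] = {}
    tier: dict[str, Tier] = {}
    excluded: list[str] = []
    for cid in table.compound_ids:
        if cid not in resolved:
            if abund[cid] > 0:
                excluded.append(cid)
            continue
        value = (abund[cid] / resolved[cid].value) / ref_ratio * 100.0
        roav[cid] = value
        tier[cid] = _tier(value)
    return ROAVProfile(sample, ref, roav, tier, excluded)


def compute_all_profiles(
    table: VOCTable,
    thresholds: ThresholdDB | Mapping[str, ResolvedThreshold],
    *,
    reference_rule: str = "ct-max",
) -> dict[str, ROAVProfile]:
    return {
        s: compute_roav_profile(table, thresholds, s, reference_rule=reference_rule)
        for s in table.samples
    }


def compare_cultivars(profiles: Sequence[ROAVProfile]) -> pd.DataFrame:
    """Cross-sample ROAV table with odor-impact flags.

    Returns a DataFrame indexed by compound with one ROAV column per sample
    plus boolean flags: ``universal_key`` (key tier in every sample),
    ``sample_specific_key`` (key in exactly one), and
    ``chemotaxonomic_marker`` (detected in exactly one sample *and* key
    there).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    samples = [p.sample_id for p in profiles]
    compounds = sorted({c for p in profiles for c in p.roav})
    roav = pd.DataFrame(
        {p.sample_id: [p.roav.get(c, np.nan) for c in compounds] for p in profiles},
        index=compounds,
    )
    key = pd.DataFrame(
        {p.sample_id: [p.tier.get(c) is Tier.KEY for c in compounds] for p in profiles},
        index=compounds,
    )
    present = pd.DataFrame(
        {p.sample_id: [p.tier.get(c) not in (None, Tier.ABSENT) for c in compounds] for p in profiles},
        index=compounds,
    )
    n_key = key.sum(axis=1)
    n_present = present.sum(axis=1)
    out = roav.copy()
    out["universal_key"] = n_key == len(samples)
    out["sample_specific_key"] = n_key == 1
    out["chemotaxonomic_marker"] = (n_present == 1) & (n_key == 1)
    return out
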