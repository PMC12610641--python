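"""Seeded generator of cultivar-structured aroma datasets with ground truth.

Emulates the statistical shape of a small GC-MS cultivar study: a few dozen
volatiles with log-normally spread relative abundances (roughly 0.04-34% of
total peak area), a shared/unique detection structure across three
cultivars, an odor-threshold table that covers only about half the
compounds (mixing air and water media, occasionally with multiple reports
per compound), and a trained 12-assessor x 3-session x 7-attribute panel.

Every draw comes from one :class:`numpy.random.Generator` stream seeded from
a single integer, so outputs are byte-identical across runs and platforms.

What it deliberately does not emulate: chromatographic peak shapes,
retention-time drift, co-elution, mass-spectral identity errors, or
assessor drift across sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ChemicalClass,
    CompoundRecord,
    Medium,
    SensoryPanel,
    ThresholdDB,
    ThresholdEntry,
    VOCTable,
)
from .roav import ROAVProfile, Tier
from .multivariate import ColocalizationResult
from .sensory import compact_letter_display

__all__ = [
    "PlantedMarker",
    "LinkedPair",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "recovery_report",
    "DEFAULT_ATTRIBUTE_MEANS",
]

#: Default 0-10 panel intensity means, one chemotype per cultivar:
#: CV1 woody-pungent, CV2 sweet-aromatic, CV3 fresh-herbaceous.
DEFAULT_ATTRIBUTE_MEANS = pd.DataFrame(
    {
        "citrus": [3.0, 4.5, 7.3],
        "minty": [2.5, 3.0, 6.8],
        "woody": [8.5, 3.2, 5.5],
        "floral": [2.0, 7.9, 4.0],
        "coconut-milk": [2.9, 8.2, 3.0],
        "herbal": [3.5, 3.0, 6.5],
        "spicy": [7.6, 2.5, 4.0],
    },
    index=["CV1", "CV2", "CV3"],
)

#: Class mixture mirroring a terpene-dominated fruit volatilome
#: (counts out of 49: 12/20/4/7 terpenoids + 6 aliphatics + 1 lactone).
DEFAULT_CLASS_MIXTURE = {
    ChemicalClass.MONOTERPENE_HYDROCARBON: 12 / 49,
    ChemicalClass.SESQUITERPENE_HYDROCARBON: 20 / 49,
    ChemicalClass.OXYGENATED_MONOTERPENE: 4 / 49,
    ChemicalClass.OXYGENATED_SESQUITERPENE: 7 / 49,
    ChemicalClass.ALIPHATIC_ESTER: 2 / 49,
    ChemicalClass.ALIPHATIC_ALKENE: 1 / 49,
    ChemicalClass.ALIPHATIC_ALCOHOL: 1 / 49,
    ChemicalClass.ALIPHATIC_ALDEHYDE: 1 / 49,
    ChemicalClass.LACTONE: 1 / 49,
}


@dataclass(frozen=True)
class PlantedMarker:
    """A compound planted in one cultivar's unique set with a target ROAV tier."""

    cultivar: str
    tier: Tier
    compound: str | None = None  # auto-assigned from the cultivar's unique block


@dataclass(frozen=True)
class LinkedPair:
    """A compound whose abundance tracks a sensory attribute across cultivars."""

    attribute: str
    slope: float = 0.4  # percent abundance per intensity unit
    compound: str | None = None  # auto-assigned from the shared block


@dataclass
class SimulationConfig:
    n_cultivars: int = 3
    cultivar_names: tuple[str, ...] | None = None
    n_compounds: int = 49
    n_shared: int = 19
    n_unique_per_cultivar: tuple[int, ...] = (1, 7, 4)
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    # log-normal relative-abundance model (before per-sample normalization)
    abundance_log_mu: float = math.log(0.6)
    abundance_log_sigma: float = 1.3
    cultivar_sigma: float = 0.4  # log-scale cultivar-to-cultivar jitter
    replicate_cv: float = 0.10  # fractional SD across triplicates
    n_replicates: int = 3
    # threshold model
    threshold_range: tuple[float, float] = (0.005, 40.0)
    threshold_coverage: float = 0.5  # fraction of compounds with any entry
    multi_entry_prob: float = 0.15
    water_prob: float = 0.2
    # planted ground truth
    planted_markers: tuple[PlantedMarker, ...] = (PlantedMarker("CV2", Tier.KEY),)
    marker_margin: float = 2.0  # min multiplicative distance to tier boundaries
    linked_pairs: tuple[LinkedPair, ...] = (
        LinkedPair("coconut-milk", 0.4),
        LinkedPair("woody", 0.4),
    )
    link_jitter_sd: float = 0.05  # log-scale noise around the linear link
    # sensory panel
    n_assessors: int = 12
    n_sessions: int = 3
    attribute_means: pd.DataFrame | None = None  # cultivar x attribute
    assessor_bias_sd: float = 0.5
    residual_sd: float = 0.8
    letter_gap: float = 0.75  # min mean separation counted as a true difference
    # detection-limit censoring (None = structural absence only)
    censor_limit: float | None = None
    seed: int = 0

    def cultivars(self) -> list[str]:
        if self.cultivar_names is not None:
            return list(self.cultivar_names)
        return [f"CV{i + 1}" for i in range(self.n_cultivars)]

    def attr_means(self) -> pd.DataFrame:
        if self.attribute_means is not None:
            return self.attribute_means
        if self.n_cultivars != 3:
            raise ValueError("default attribute means are defined for 3 cultivars")
        return DEFAULT_ATTRIBUTE_MEANS.set_axis(self.cultivars(), axis=0)

    def validate(self) -> None:
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture proportions must sum to 1")
        if len(self.n_unique_per_cultivar) != self.n_cultivars:
            raise ValueError("one unique-count per cultivar required")
        if self.n_shared + sum(self.n_unique_per_cultivar) > self.n_compounds:
            raise ValueError("shared + unique blocks exceed n_compounds")
        for sd in (self.cultivar_sigma, self.replicate_cv, self.assessor_bias_sd,
                   self.residual_sd, self.link_jitter_sd):
            if sd < 0:
                raise ValueError("all noise SDs must be >= 0")
        cultivars = set(self.cultivars())
        for m in self.planted_markers:
            if m.cultivar not in cultivars:
                raise ValueError(f"marker cultivar {m.cultivar!r} not in design")
            if m.tier is Tier.ABSENT:
                raise ValueError("cannot plant an 'absent' tier marker")
        attrs = set(self.attr_means().columns)
        for lp in self.linked_pairs:
            if lp.attribute not in attrs:
                raise ValueError(f"linked attribute {lp.attribute!r} not in lexicon")


@dataclass
class GroundTruth:
    true_reference: dict[str, str]  # cultivar -> compound id
    true_tier: dict[tuple[str, str], Tier]  # (cultivar, compound) -> tier
    true_letters: dict[str, dict[str, str]]  # attribute -> {cultivar: letters}
    true_coloc: list[tuple[str, str]]  # (compound, attribute)
    marker_compounds: dict[str, str] = field(default_factory=dict)  # cultivar -> compound
    expected_abundance: pd.DataFrame | None = None  # compound x cultivar, pre-noise


@dataclass
class SimulatedDataset:
    voc: VOCTable
    thresholds: ThresholdDB
    panel: SensoryPanel
    truth: GroundTruth
    config: SimulationConfig


def _class_counts(mixture: dict, n: int) -> list[ChemicalClass]:
    """Deterministic largest-remainder apportionment of classes to compounds."""
    items = sorted(mixture.items(), key=lambda kv: kv[0].value)
    exact = [(cls, p * n) for cls, p in items]
    counts = {cls: int(math.floor(x)) for cls, x in exact}
    short = n - sum(counts.values())
    for cls, x in sorted(exact, key=lambda kv: -(kv[1] - math.floor(kv[1])))[:short]:
        counts[cls] += 1
    out: list[ChemicalClass] = []
    for cls, _ in items:
        out.extend([cls] * counts[cls])
    return out


_TIER_TARGETS = {Tier.KEY: 4.0, Tier.MODIFIER: math.sqrt(0.1), Tier.NEGLIGIBLE: math.sqrt(0.001)}


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate (VOCTable, ThresholdDB, SensoryPanel, GroundTruth) from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cultivars = config.cultivars()
    k = len(cultivars)
    n = config.n_compounds

    classes = _class_counts(config.class_mixture, n)
    ids = [f"{classes[i].value.split('_')[0][:4]}-{i + 1:03d}" for i in range(n)]
    compounds = [CompoundRecord(ids[i], chemical_class=classes[i]) for i in range(n)]

    # --- detection design: shared block, unique blocks, remainder in 2-of-k
    detected = pd.DataFrame(False, index=ids, columns=cultivars)
    pos = 0
    shared_ids = ids[pos : pos + config.n_shared]
    detected.loc[shared_ids, :] = True
    pos += config.n_shared
    unique_blocks: dict[str, list[str]] = {}
    for c, n_u in zip(cultivars, config.n_unique_per_cultivar):
        block = ids[pos : pos + n_u]
        unique_blocks[c] = block
        detected.loc[block, c] = True
        pos += n_u
    for cid in ids[pos:]:
        if k >= 3:
            subset = rng.choice(k, size=int(rng.integers(2, k)), replace=False)
        else:
            subset = np.arange(k)
        detected.loc[cid, [cultivars[j] for j in subset]] = True

    # --- expected (pre-noise) raw abundances
    base = rng.lognormal(config.abundance_log_mu, config.abundance_log_sigma, size=n)
    jitter = rng.lognormal(0.0, config.cultivar_sigma, size=(n, k))
    expected = pd.DataFrame(base[:, None] * jitter, index=ids, columns=cultivars)
    expected = expected.where(detected, 0.0)

    # --- linked compound-attribute pairs (compound tracks the attribute mean)
    attr_means = config.attr_means()
    linked: list[tuple[str, str]] = []
    used: set[str] = set()
    shared_pool = iter(shared_ids)
    for lp in config.linked_pairs:
        cid = lp.compound
        if cid is None:
            cid = next(c for c in shared_pool if c not in used)
        used.add(cid)
        noise = rng.lognormal(0.0, config.link_jitter_sd, size=k) if config.link_jitter_sd > 0 else np.ones(k)
        expected.loc[cid] = lp.slope * attr_means[lp.attribute].to_numpy() * noise
        linked.append((cid, lp.attribute))

    # Equalize expected totals across cultivars (linked compounds untouched):
    # closure to percent would otherwise distort the planted proportional
    # links, since dividing by a cultivar-dependent total breaks linearity.
    target_total = 100.0
    linked_ids = [c for c, _ in linked]
    linked_sum = expected.loc[linked_ids].sum(axis=0) if linked_ids else pd.Series(0.0, index=cultivars)
    if (linked_sum >= target_total).any():
        raise ValueError("linked-pair abundances exceed the total pool")
    nonlinked = [c for c in ids if c not in linked_ids]
    factor = (target_total - linked_sum) / expected.loc[nonlinked].sum(axis=0)
    expected.loc[nonlinked] = expected.loc[nonlinked].mul(factor, axis=1)

    # --- thresholds: partial coverage, air/water mix, occasional multi-entry
    must_cover = set(c for c, _ in linked)
    covered = set(
        cid for cid in ids if cid in must_cover or rng.random() < config.threshold_coverage
    )
    lo, hi = config.threshold_range
    db = ThresholdDB()
    thresholds: dict[str, float] = {}
    for cid in ids:
        in_cov = cid in covered
        t = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        medium = Medium.WATER if rng.random() < config.water_prob else Medium.AIR
        extra = rng.random() < config.multi_entry_prob
        t2 = t * float(rng.lognormal(0.0, 0.3))
        if not in_cov:
            continue  # rng draws above keep the stream aligned regardless
        db.add(ThresholdEntry(cid, t, medium, source="simulated"))
        if extra:
            db.add(ThresholdEntry(cid, t2, medium, source="simulated"))
            thresholds[cid] = (t + t2) / 2  # same medium, so the mean rule applies
        else:
            thresholds[cid] = t

    # --- planted tier markers inside unique blocks
    marker_compounds: dict[str, str] = {}
    for m in config.planted_markers:
        cid = m.compound
        if cid is None:
            pool = [c for c in unique_blocks[m.cultivar] if c not in used]
            if not pool:
                raise ValueError(f"no free unique compound in {m.cultivar!r} for marker")
            cid = pool[0]
        elif cid not in unique_blocks[m.cultivar]:
            raise ValueError(f"marker compound {cid!r} not unique to {m.cultivar!r}")
        used.add(cid)
        target = _TIER_TARGETS[m.tier]
        others = [
            c for c in ids if c != cid and c in thresholds and detected.loc[c, m.cultivar]
        ]
        if not others:
            raise ValueError("no reference-eligible compound; marker tier unreachable")
        ref_ratio = max(expected.loc[c, m.cultivar] / thresholds[c] for c in others)
        if not (target * config.marker_margin < 100):
            raise ValueError("marker target too close to the reference ceiling")
        t_marker = float(expected.loc[cid, m.cultivar] / (ref_ratio * target / 100.0))
        # replace any sampled entries with the planted single air entry
        db.remove(cid)
        db.add(ThresholdEntry(cid, t_marker, Medium.AIR, source="planted"))
        thresholds[cid] = t_marker
        marker_compounds[m.cultivar] = cid

    # --- replicate measurements, normalized to percent within each replicate
    sigma_rep = math.sqrt(math.log(1.0 + config.replicate_cv**2))
    reps = np.zeros((n, k, config.n_replicates))
    for r in range(config.n_replicates):
        noise = rng.lognormal(0.0, sigma_rep, size=(n, k)) if sigma_rep > 0 else np.ones((n, k))
        raw = expected.to_numpy() * noise
        reps[:, :, r] = raw / raw.sum(axis=0, keepdims=True) * 100.0
    means = reps.mean(axis=2)
    sds = reps.std(axis=2, ddof=1)
    det_mask = detected.to_numpy().copy()
    if config.censor_limit is not None:
        det_mask &= means >= config.censor_limit
    means = np.where(det_mask, means, 0.0)
    sds = np.where(det_mask, sds, 0.0)
    voc = VOCTable(compounds, cultivars, means, sds, config.n_replicates, det_mask)

    # --- sensory panel
    records = []
    for a in range(config.n_assessors):
        bias = rng.normal(0.0, config.assessor_bias_sd)
        for session in range(1, config.n_sessions + 1):
            for c in cultivars:
                for att in attr_means.columns:
                    score = attr_means.loc[c, att] + bias + rng.normal(0.0, config.residual_sd)
                    records.append(
                        {
                            "assessor": f"A{a + 1:02d}",
                            "session": session,
                            "sample": c,
                            "attribute": att,
                            "score": float(np.clip(score, 0.0, 10.0)),
                        }
                    )
    panel = SensoryPanel(pd.DataFrame(records), lexicon=list(attr_means.columns))

    truth = _ground_truth(config, cultivars, ids, detected, expected, thresholds,
                          attr_means, linked, marker_compounds)
    return SimulatedDataset(voc, db, panel, truth, config)


def _analytic_tier(value: float) -> Tier:
    if value == 0:
        return Tier.ABSENT
    if value >= 1.0:
        return Tier.KEY
    if value >= 0.1:
        return Tier.MODIFIER
    return Tier.NEGLIGIBLE


def _ground_truth(config, cultivars, ids, detected, expected, thresholds,
                  attr_means, linked, marker_compounds) -> GroundTruth:
    true_reference: dict[str, str] = {}
    true_tier: dict[tuple[str, str], Tier] = {}
    for c in cultivars:
        ratios = {
            cid: expected.loc[cid, c] / thresholds[cid]
            for cid in ids
            if cid in thresholds and detected.loc[cid, c]
        }
        ref = max(sorted(ratios), key=lambda cid: ratios[cid])
        true_reference[c] = ref
        for cid in ids:
            if cid not in thresholds:
                continue
            if not detected.loc[cid, c]:
                true_tier[(c, cid)] = Tier.ABSENT
            else:
                true_tier[(c, cid)] = _analytic_tier(ratios[cid] / ratios[ref] * 100.0)

    true_letters: dict[str, dict[str, str]] = {}
    for att in attr_means.columns:
        means = {c: float(attr_means.loc[c, att]) for c in cultivars}
        sig = pd.DataFrame(
            [
                [abs(means[a] - means[b]) >= config.letter_gap for b in cultivars]
                for a in cultivars
            ],
            index=cultivars,
            columns=cultivars,
        )
        true_letters[att] = compact_letter_display(means, sig)

    return GroundTruth(
        true_reference=true_reference,
        true_tier=true_tier,
        true_letters=true_letters,
        true_coloc=list(linked),
        marker_compounds=marker_compounds,
        expected_abundance=expected,
    )


def recovery_report(
    truth: GroundTruth,
    profiles: dict[str, ROAVProfile] | None = None,
    letters: dict[str, dict[str, str]] | None = None,
    coloc: ColocalizationResult | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against the generator's planted ground truth.

    Any subset of outputs may be supplied; only the corresponding metrics are
    reported.  Co-localization precision/recall is computed over the pairs
    that were actually evaluated (flagged vs planted), so the evaluated set
    should include null control pairs for precision to be informative.
    """
    metrics: dict[str, float] = {}
    if profiles is not None:
        if set(profiles) != set(truth.true_reference):
            raise ValueError("profile sample set does not match ground truth")
        hits = sum(
            profiles[c].reference_compound == truth.true_reference[c] for c in profiles
        )
        metrics["reference_match_rate"] = hits / len(profiles)
        total = correct = key_total = key_correct = 0
        for (c, cid), t in truth.true_tier.items():
            got = profiles[c].tier.get(cid)
            if got is None:
                continue
            total += 1
            correct += got is t
            if t is Tier.KEY:
                key_total += 1
                key_correct += got is t
        metrics["tier_accuracy"] = correct / total if total else float("nan")
        metrics["key_tier_recovery"] = key_correct / key_total if key_total else float("nan")
    if letters is not None:
        atts = list(truth.true_letters)
        match = sum(letters.get(a) == truth.true_letters[a] for a in atts)
        metrics["letter_pattern_match"] = match / len(atts)
    if coloc is not None:
        flagged = set(coloc.co_localized_pairs())
        evaluated = set(zip(coloc.pairs["variable_a"], coloc.pairs["variable_b"]))
        true_pairs = {(c, a) for c, a in truth.true_coloc} & evaluated
        tp = len(flagged & true_pairs)
        metrics["coloc_precision"] = tp / len(flagged) if flagged else 1.0
        metrics["coloc_recall"] = tp / len(true_pairs) if true_pairs else 1.0
    return metrics
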