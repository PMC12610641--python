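"""Peak-area normalization and compositional accounting across cultivars.

Covers three bookkeeping steps that precede odor-activity ranking:
normalizing raw integrated peak areas to percent of total, splitting the
detected compound sets into shared/unique partitions (with a terpenoid
filter), and summing relative abundances by chemical class or by an explicit
compound list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    TERPENOID_CLASSES,
    ChemicalClass,
    CompoundRecord,
    VOCTable,
    canonical_name,
)

__all__ = [
    "DetectionReport",
    "CompositionReport",
    "normalize_peak_areas",
    "detection_sets",
    "class_composition",
    "named_sum",
]


def normalize_peak_areas(
    raw_areas: pd.DataFrame,
    compounds: list[CompoundRecord] | None = None,
    *,
    n_replicates: int = 3,
) -> VOCTable:
    """Express each compound's peak area as percent of its sample's total.

    ``raw_areas`` is a compound x sample frame of non-negative integrated
    areas.  Each column is divided by its total and scaled to 100, so
    per-sample sums are exactly 100 (up to floating error).
    """
    areas = raw_areas.astype(float)
    if (areas.to_numpy() < 0).any():
        raise ValueError("peak areas must be non-negative")
    totals = areas.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total peak area")
    percent = areas.div(totals, axis=1) * 100.0
    if compounds is None:
        compounds = [CompoundRecord(canonical_name(c)) for c in areas.index]
    return VOCTable(
        compounds,
        list(areas.columns),
        percent.to_numpy(),
        n_replicates=n_replicates,
        detected=percent.to_numpy() > 0,
    )


@dataclass
class DetectionReport:
    """Shared/unique accounting of the detected compound sets."""

    per_sample_counts: dict[str, int]
    shared_all: set[str]
    unique_per_sample: dict[str, set[str]]
    unique_terpenoids_per_sample: dict[str, set[str]]
    diagnostics: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, n in self.per_sample_counts.items():
            rows.append(
                {
                    "sample": s,
                    "n_detected": n,
                    "n_unique": len(self.unique_per_sample[s]),
                    "n_unique_terpenoids": len(self.unique_terpenoids_per_sample[s]),
                    "unique_compounds": ";".join(sorted(self.unique_per_sample[s])),
                }
            )
        return pd.DataFrame(rows)


def detection_sets(table: VOCTable) -> DetectionReport:
    """Partition detected compounds into universally shared and sample-unique sets.

    "Unique" means detected in exactly one sample of the table.  The terpenoid
    filter keeps mono-/sesquiterpene hydrocarbons and their oxygenated forms.
    """
    detected = {s: table.detected_set(s) for s in table.samples}
    shared = set.intersection(*detected.values()) if detected else set()
    classes = {c.compound_id: c.chemical_class for c in table.compounds}
    unique: dict[str, set[str]] = {}
    unique_terp: dict[str, set[str]] = {}
    for s in table.samples:
        others = set().union(*(detected[o] for o in table.samples if o != s)) if len(table.samples) > 1 else set()
        u = detected[s] - others if len(table.samples) > 1 else set(detected[s])
        unique[s] = u
        unique_terp[s] = {c for c in u if classes[c] in TERPENOID_CLASSES}
    report = DetectionReport(
        per_sample_counts={s: len(detected[s]) for s in table.samples},
        shared_all=shared,
        unique_per_sample=unique,
        unique_terpenoids_per_sample=unique_terp,
    )
    for s in table.samples:
        n_nonterp = len(unique[s] - unique_terp[s])
        if unique[s]:
            report.diagnostics.append(
                f"{s}: {len(unique[s])} unique compounds "
                f"({len(unique_terp[s])} terpenoid, {n_nonterp} non-terpenoid)"
            )
    return report


@dataclass
class CompositionReport:
    """Per-sample abundance sums by chemical class, plus identified totals."""

    class_sums: pd.DataFrame  # chemical class x sample, percent
    identified_total: pd.Series  # per-sample sum over detected compounds

    def to_frame(self) -> pd.DataFrame:
        out = self.class_sums.copy()
        out.loc["identified_total"] = self.identified_total
        return out


def class_composition(table: VOCTable) -> CompositionReport:
    """Sum mean relative abundances within each chemical class, per sample."""
    classes = pd.Series(
        {c.compound_id: c.chemical_class.value for c in table.compounds}, name="class"
    )
    masked = table.means.where(table.detected, 0.0)
    sums = masked.groupby(classes).sum()
    sums = sums.reindex([c.value for c in ChemicalClass], fill_value=0.0)
    totals = masked.sum(axis=0)
    totals.name = "identified_total"
    return CompositionReport(class_sums=sums, identified_total=totals)


def named_sum(table: VOCTable, sample: str, compound_ids: list[str], label: str = "") -> float:
    """Sum of mean abundances of the named compounds in one sample.

    Used for statements like "the six dominant volatiles collectively
    constitute X% of the total".  Unknown compound names raise.
    """
    known = set(table.compound_ids)
    total = 0.0
    for cid in compound_ids:
        cid = canonical_name(cid)
        if cid not in known:
            raise KeyError(f"compound {cid!r} not in table" + (f" (sum {label!r})" if label else ""))
        if table.detected.loc[cid, sample]:
            total += float(table.means.loc[cid, sample])
    return total
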