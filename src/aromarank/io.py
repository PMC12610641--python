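"""Tabular data model and readers/writers for the aroma pipeline.

Three kinds of input drive the analysis:

* a volatile-compound (VOC) composition table: compound x sample matrix of
  relative abundances (percent of total GC-MS peak area), cells holding either
  a replicate summary ``"mean ± sd"``, a bare number, or a not-detected token;
* an odor-threshold table: one or more threshold records per compound, each
  tagged with the medium the threshold was determined in (air or water);
* a long-format sensory panel table: one score per
  (assessor, session, sample, attribute) on a 0-10 intensity scale.

All readers validate on construction and never silently drop rows; all writers
emit fixed column order with 6-significant-digit floats so that write-then-read
is the identity.
"""

from __future__ import annotations

import csv
import enum
import math
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChemicalClass",
    "CompoundRecord",
    "VOCTable",
    "ThresholdEntry",
    "ThresholdDB",
    "SensoryPanel",
    "read_voc_table",
    "write_voc_table",
    "read_threshold_table",
    "write_threshold_table",
    "read_sensory_scores",
    "write_sensory_scores",
]

#: Tolerance allowed above 100 for a per-sample sum of relative percentages
#: (the identified fraction of a normalized chromatogram).
SUM_TOLERANCE = 1e-6


class ChemicalClass(str, enum.Enum):
    """Structural class of a volatile compound."""

    MONOTERPENE_HYDROCARBON = "monoterpene_hydrocarbon"
    SESQUITERPENE_HYDROCARBON = "sesquiterpene_hydrocarbon"
    OXYGENATED_MONOTERPENE = "oxygenated_monoterpene"
    OXYGENATED_SESQUITERPENE = "oxygenated_sesquiterpene"
    ALIPHATIC_ESTER = "aliphatic_ester"
    ALIPHATIC_ALKENE = "aliphatic_alkene"
    ALIPHATIC_ALCOHOL = "aliphatic_alcohol"
    ALIPHATIC_ALDEHYDE = "aliphatic_aldehyde"
    LACTONE = "lactone"
    OTHER = "other"


#: Classes counted as terpenoids (oxygenated forms included).
TERPENOID_CLASSES = frozenset(
    {
        ChemicalClass.MONOTERPENE_HYDROCARBON,
        ChemicalClass.SESQUITERPENE_HYDROCARBON,
        ChemicalClass.OXYGENATED_MONOTERPENE,
        ChemicalClass.OXYGENATED_SESQUITERPENE,
    }
)


class Medium(str, enum.Enum):
    """Medium in which an odor threshold was determined."""

    AIR = "air"
    WATER = "water"


def canonical_name(name: str) -> str:
    """Unicode-NFC-normalized, whitespace-stripped compound name.

    Matching between composition and threshold tables is exact (case
    sensitive) after this normalization; fuzzy matching is deliberately not
    offered because a silent mismatch corrupts every downstream odor-activity
    value.
    """
    return unicodedata.normalize("NFC", str(name)).strip()


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    molecular_formula: str = ""
    chemical_class: ChemicalClass = ChemicalClass.OTHER
    retention_time: float | None = None  # minutes

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


class VOCTable:
    """Compound x sample matrix of relative abundances with replicate summary.

    Parameters
    ----------
    compounds
        Metadata records, one per row; ``compound_id`` values must be unique.
    samples
        Ordered sample identifiers (table columns).
    means, sds
        Per-cell replicate mean and standard deviation of the relative
        abundance in percent of total peak area.  Not-detected cells hold
        exactly 0.
    n_replicates
        Number of replicate measurements summarized per cell.
    detected
        Boolean detection mask; defaults to ``means > 0``.
    """

    def __init__(
        self,
        compounds: Sequence[CompoundRecord],
        samples: Sequence[str],
        means: np.ndarray | pd.DataFrame,
        sds: np.ndarray | pd.DataFrame | None = None,
        n_replicates: int = 3,
        detected: np.ndarray | pd.DataFrame | None = None,
    ) -> None:
        ids = [c.compound_id for c in compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound rows: {', '.join(dupes)}")
        self.compounds = list(compounds)
        self.samples = [str(s) for s in samples]
        self.means = pd.DataFrame(np.asarray(means, dtype=float), index=ids, columns=self.samples)
        if sds is None:
            sds = np.zeros_like(self.means.to_numpy())
        self.sds = pd.DataFrame(np.asarray(sds, dtype=float), index=ids, columns=self.samples)
        self.n_replicates = int(n_replicates)
        if detected is None:
            detected = self.means.to_numpy() > 0
        self.detected = pd.DataFrame(
            np.asarray(detected, dtype=bool), index=ids, columns=self.samples
        )
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        m = self.means.to_numpy()
        if (m < 0).any():
            bad = self.means.index[(m < 0).any(axis=1)][0]
            raise ValueError(f"negative abundance for compound {bad!r}")
        det = self.detected.to_numpy()
        if not np.isfinite(m[det]).all() or not np.isfinite(self.sds.to_numpy()[det]).all():
            raise ValueError("non-finite mean/sd in a detected cell")
        if (m[~det] != 0).any():
            raise ValueError("not-detected cells must carry abundance exactly 0")
        sums = np.where(det, m, 0.0).sum(axis=0)
        if (sums > 100 + 100 * SUM_TOLERANCE + 1e-9).any():
            s = self.samples[int(np.argmax(sums))]
            raise ValueError(f"sample {s!r}: detected abundances sum above 100%")

    # -- conveniences ----------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return list(self.means.index)

    def record(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    def sample_profile(self, sample: str) -> pd.Series:
        """Mean abundances of one sample column (0 where not detected)."""
        return self.means[sample]

    def detected_set(self, sample: str) -> set[str]:
        return set(self.detected.index[self.detected[sample]])

    def equals(self, other: "VOCTable") -> bool:
        return (
            self.compounds == other.compounds
            and self.samples == other.samples
            and self.n_replicates == other.n_replicates
            and np.array_equal(self.means.to_numpy(), other.means.to_numpy())
            and np.array_equal(self.sds.to_numpy(), other.sds.to_numpy())
            and np.array_equal(self.detected.to_numpy(), other.detected.to_numpy())
        )


@dataclass(frozen=True)
class ThresholdEntry:
    """One reported odor threshold: magnitude in the source's units
    (mg/m3 for air, mg/kg for water), kept as-is and never converted."""

    compound_id: str
    value: float
    medium: Medium = Medium.AIR
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(
                f"non-positive threshold {self.value!r} for {self.compound_id!r}"
            )


class ThresholdDB:
    """Multimap compound_id -> list of threshold entries. Lookup never mutates."""

    def __init__(self, entries: Iterable[ThresholdEntry] = ()) -> None:
        self._entries: dict[str, list[ThresholdEntry]] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ThresholdEntry) -> None:
        self._entries.setdefault(canonical_name(entry.compound_id), []).append(entry)

    def entries(self, compound_id: str) -> list[ThresholdEntry]:
        return list(self._entries.get(canonical_name(compound_id), []))

    def remove(self, compound_id: str) -> None:
        self._entries.pop(canonical_name(compound_id), None)

    def __contains__(self, compound_id: str) -> bool:
        return canonical_name(compound_id) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def compound_ids(self) -> list[str]:
        return list(self._entries)

    def all_entries(self) -> list[ThresholdEntry]:
        return [e for lst in self._entries.values() for e in lst]


class SensoryPanel:
    """Long-format quantitative-descriptive-analysis scores.

    One record per (assessor, session, sample, attribute); scores live on a
    0-10 intensity scale. The attribute set must equal the lexicon.
    """

    def __init__(self, records: pd.DataFrame, lexicon: Sequence[str] | None = None) -> None:
        required = ["assessor", "session", "sample", "attribute", "score"]
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise ValueError(f"sensory records missing columns: {missing}")
        rec = records.loc[:, required].copy()
        rec["assessor"] = rec["assessor"].astype(str)
        rec["session"] = rec["session"].astype(int)
        rec["sample"] = rec["sample"].astype(str)
        rec["attribute"] = rec["attribute"].astype(str)
        rec["score"] = rec["score"].astype(float)
        bad = rec[(rec["score"] < 0) | (rec["score"] > 10) | ~np.isfinite(rec["score"])]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"score {r['score']} outside [0, 10] "
                f"(assessor {r['assessor']}, sample {r['sample']}, attribute {r['attribute']})"
            )
        keys = rec[["assessor", "session", "sample", "attribute"]]
        if keys.duplicated().any():
            r = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate record: {tuple(r)}")
        observed = sorted(rec["attribute"].unique())
        if lexicon is None:
            lexicon = observed
        else:
            unknown = set(observed) - set(lexicon)
            if unknown:
                raise ValueError(f"attributes outside lexicon: {sorted(unknown)}")
        self.records = rec.reset_index(drop=True)
        self.lexicon = list(lexicon)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    @property
    def attributes(self) -> list[str]:
        return list(self.lexicon)

    def scores(self, sample: str, attribute: str) -> np.ndarray:
        r = self.records
        return r.loc[(r["sample"] == sample) & (r["attribute"] == attribute), "score"].to_numpy()

    def equals(self, other: "SensoryPanel") -> bool:
        a = self.records.sort_values(["assessor", "session", "sample", "attribute"]).reset_index(drop=True)
        b = other.records.sort_values(["assessor", "session", "sample", "attribute"]).reset_index(drop=True)
        return self.lexicon == other.lexicon and a.equals(b)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_PM_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(?:±|\+/-)\s*([0-9.eE+-]+)\s*$")
_MEDIUM_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(?:\(\s*(OA|OW)\s*\))?\s*$", re.IGNORECASE)


def _sniff_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if ("\t" in header and "," not in header) else ","


def _parse_abundance_cell(cell: str, nd_token: str) -> tuple[float, float, bool]:
    """Return (mean, sd, detected) for one composition cell."""
    text = str(cell).strip()
    if text == "" or text.lower() == nd_token.lower() or text.lower() == "nan":
        return 0.0, 0.0, False
    m = _PM_RE.match(text)
    if m:
        return float(m.group(1)), float(m.group(2)), True
    return float(text), 0.0, True


_FORMULA_SUBSCRIPTS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def read_voc_table(
    path: str | Path,
    *,
    nd_token: str = "ND",
    zero_is_nd: bool = True,
    default_n: int = 3,
    sep: str | None = None,
) -> VOCTable:
    """Read a compound x sample composition table.

    Expected columns: ``compound,formula,class,rt`` then one column per sample;
    cells are ``"m ± s"``, a bare number, or the not-detected token.  With
    ``zero_is_nd`` (default), a parsed 0 is treated as not detected — an
    undetected compound must carry odor activity exactly 0 downstream.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    df.columns = [str(c).strip() for c in df.columns]
    meta_cols = [c for c in ("compound", "formula", "class", "rt") if c in df.columns]
    if "compound" not in meta_cols:
        raise ValueError(f"{path}: missing 'compound' column")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")

    compounds: list[CompoundRecord] = []
    means = np.zeros((len(df), len(sample_cols)))
    sds = np.zeros_like(means)
    det = np.zeros(means.shape, dtype=bool)
    for i, row in df.iterrows():
        name = canonical_name(row["compound"])
        formula_raw = row.get("formula") if "formula" in meta_cols else None
        formula = (
            ""
            if formula_raw is None or pd.isna(formula_raw)
            else canonical_name(formula_raw).translate(_FORMULA_SUBSCRIPTS)
        )
        cls_raw = row.get("class") if "class" in meta_cols else None
        cls_label = "" if cls_raw is None or pd.isna(cls_raw) else str(cls_raw).strip()
        if cls_label:
            try:
                cls = ChemicalClass(cls_label)
            except ValueError:
                warnings.warn(
                    f"{path}: unknown chemical class {cls_label!r} for {name!r}; using 'other'",
                    stacklevel=2,
                )
                cls = ChemicalClass.OTHER
        else:
            cls = ChemicalClass.OTHER
        rt_raw = row.get("rt") if "rt" in meta_cols else None
        rt = float(rt_raw) if rt_raw not in (None, "", "nan") and not pd.isna(rt_raw) else None
        compounds.append(CompoundRecord(name, formula, cls, rt))
        for j, s in enumerate(sample_cols):
            try:
                mean, sd, d = _parse_abundance_cell(row[s], nd_token)
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable cell {row[s]!r} for {name!r}") from exc
            if mean < 0:
                raise ValueError(f"{path}: negative abundance {mean} for {name!r}")
            if zero_is_nd and mean == 0:
                d = False
                sd = 0.0
            means[i, j], sds[i, j], det[i, j] = mean, sd, d
    return VOCTable(compounds, sample_cols, means, sds, n_replicates=default_n, detected=det)


def _fmt(x: float) -> str:
    # shortest decimal string that parses back to the identical float, so
    # write-then-read is the exact identity
    return repr(float(x))


def write_voc_table(table: VOCTable, path: str | Path, *, nd_token: str = "ND") -> None:
    """Write a composition table in the same dialect ``read_voc_table`` accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound", "formula", "class", "rt", *table.samples])
        for c in table.compounds:
            cells = []
            for s in table.samples:
                if not table.detected.loc[c.compound_id, s]:
                    cells.append(nd_token)
                else:
                    m = table.means.loc[c.compound_id, s]
                    sd = table.sds.loc[c.compound_id, s]
                    cells.append(f"{_fmt(m)} ± {_fmt(sd)}" if sd > 0 else _fmt(m))
            rt = "" if c.retention_time is None else _fmt(c.retention_time)
            w.writerow([c.compound_id, c.molecular_formula, c.chemical_class.value, rt, *cells])


def read_threshold_table(path: str | Path, *, sep: str | None = None) -> ThresholdDB:
    """Read an odor-threshold table into a multimap.

    Columns: ``compound,threshold`` and optionally ``medium,source``.  A
    threshold cell may carry an inline medium annotation, e.g. ``"0.14 (OW)"``;
    entries default to air when unannotated. Multiple rows per compound are
    retained (resolution happens downstream).
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    df.columns = [str(c).strip() for c in df.columns]
    if "compound" not in df.columns or "threshold" not in df.columns:
        raise ValueError(f"{path}: need 'compound' and 'threshold' columns")
    db = ThresholdDB()
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        name = canonical_name(row["compound"])
        cell = str(row["threshold"]).strip()
        m = _MEDIUM_RE.match(cell)
        if not m:
            raise ValueError(f"{path}:{lineno}: unparseable threshold cell {cell!r}")
        value = float(m.group(1))
        if m.group(2):
            medium = Medium.WATER if m.group(2).upper() == "OW" else Medium.AIR
        elif "medium" in df.columns and not pd.isna(row["medium"]):
            medium = Medium(str(row["medium"]).strip().lower())
        else:
            medium = Medium.AIR
        source = "" if "source" not in df.columns or pd.isna(row.get("source")) else str(row["source"])
        if value <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive threshold for {name!r}")
        db.add(ThresholdEntry(name, value, medium, source))
    return db


def write_threshold_table(db: ThresholdDB, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound", "threshold", "medium", "source"])
        for cid in db.compound_ids:
            for e in db.entries(cid):
                w.writerow([e.compound_id, _fmt(e.value), e.medium.value, e.source])


def read_sensory_scores(
    path: str | Path, *, lexicon: Sequence[str] | None = None, sep: str | None = None
) -> SensoryPanel:
    """Read long-format panel scores (columns assessor,session,sample,attribute,score)."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, encoding="utf-8", float_precision="round_trip")
    return SensoryPanel(df, lexicon=lexicon)


def write_sensory_scores(panel: SensoryPanel, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["assessor", "session", "sample", "attribute", "score"])
        for r in panel.records.itertuples(index=False):
            w.writerow([r.assessor, r.session, r.sample, r.attribute, _fmt(r.score)])
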