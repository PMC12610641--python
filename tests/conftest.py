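"""Shared fixtures: the bundled cultivar dataset and small table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aromarank.io import CompoundRecord, ThresholdDB, ThresholdEntry, VOCTable
from aromarank.datasets import load_kadsura_thresholds, load_kadsura_voc


@pytest.fixture(scope="session")
def kadsura_voc() -> VOCTable:
    return load_kadsura_voc()


@pytest.fixture(scope="session")
def kadsura_thresholds() -> ThresholdDB:
    return load_kadsura_thresholds()


def make_voc_table(abundances: dict[str, dict[str, float]], **kwargs) -> VOCTable:
    """Build a VOCTable from {sample: {compound: mean percent}} (0 = not detected)."""
    samples = list(abundances)
    compounds = sorted({c for col in abundances.values() for c in col})
    means = np.array([[abundances[s].get(c, 0.0) for s in samples] for c in compounds])
    return VOCTable(
        [CompoundRecord(c) for c in compounds], samples, means,
        detected=means > 0, **kwargs,
    )


def make_threshold_db(values: dict[str, float]) -> ThresholdDB:
    return ThresholdDB(ThresholdEntry(c, v) for c, v in values.items())


def oracle_roav(abundances: dict[str, float], thresholds: dict[str, float]) -> dict[str, float]:
    """Independent brute-force ROAV: all C/T ratios divided by their max."""
    ratios = {
        c: abundances[c] / thresholds[c]
        for c in abundances
        if c in thresholds and abundances[c] > 0
    }
    top = max(ratios.values())
    return {
        c: (ratios.get(c, 0.0) / top) * 100.0 for c in abundances if c in thresholds
    }


def as_percent(abundances: dict[str, float], total: float = 90.0) -> dict[str, float]:
    """Rescale abundances so they sum to `total` (an identified fraction of a
    normalized chromatogram); ROAV is invariant to this scaling."""
    s = sum(abundances.values())
    return {c: v * total / s for c, v in abundances.items()}


def random_profile(rng: np.random.Generator, n: int) -> tuple[dict, dict]:
    """A random relative-percentage/threshold pair with occasional non-detects."""
    names = [f"c{i}" for i in range(n)]
    abund = {c: float(rng.uniform(0.01, 30)) for c in names}
    for c in names:
        if rng.random() < 0.2:
            abund[c] = 0.0
    if all(v == 0 for v in abund.values()):
        abund[names[0]] = 1.0
    abund = as_percent(abund)
    thr = {c: float(10 ** rng.uniform(-3, 1.5)) for c in names}
    return abund, thr
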