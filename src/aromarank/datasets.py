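"""Bundled reference dataset: aroma profiles of three Kadsura coccinea cultivars.

Ships the identified-volatile composition table (49 compounds x 3 fruit
accessions F023/F054/F055, replicate means ± SD in percent of total GC-MS
peak area), the matching odor-threshold table (24 compounds, air thresholds
in mg/m3 with water-medium fallbacks in mg/kg), and the 7-attribute sensory
lexicon used for descriptive panel work on the same fruit.

Replicate-level panel scores are not part of the bundle; use
:func:`example_sensory_panel` for a seeded synthetic panel whose per-cultivar
attribute means follow the published intensity pattern of these cultivars.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import SensoryPanel, ThresholdDB, VOCTable, read_threshold_table, read_voc_table
from .roav import Tier
from .simulate import (
    DEFAULT_ATTRIBUTE_MEANS,
    PlantedMarker,
    SimulationConfig,
    simulate_dataset,
)

__all__ = [
    "load_kadsura_voc",
    "load_kadsura_thresholds",
    "load_kadsura_lexicon",
    "example_sensory_panel",
    "KADSURA_SAMPLES",
]

KADSURA_SAMPLES = ("F023", "F054", "F055")


def _data_path(name: str):
    return resources.files("aromarank.data") / name


def load_kadsura_voc() -> VOCTable:
    """The 49-compound x 3-cultivar relative-abundance table."""
    with resources.as_file(_data_path("kadsura_voc.csv")) as p:
        return read_voc_table(p)


def load_kadsura_thresholds() -> ThresholdDB:
    """Odor thresholds for the 24 compounds with literature values."""
    with resources.as_file(_data_path("kadsura_thresholds.csv")) as p:
        return read_threshold_table(p)


def load_kadsura_lexicon() -> pd.DataFrame:
    """Sensory attribute lexicon (attribute, reference standard, definition)."""
    with resources.as_file(_data_path("kadsura_lexicon.csv")) as p:
        return pd.read_csv(p, encoding="utf-8")


def example_sensory_panel(seed: int = 0) -> SensoryPanel:
    """Synthetic 12-assessor x 3-session panel for the three cultivars.

    Cultivar-attribute intensity means follow the published pattern (F054
    dominant in coconut-milk/floral, F023 in woody/spicy, F055 in
    citrus/minty/herbal); assessor bias and residual noise are simulated.
    """
    means = DEFAULT_ATTRIBUTE_MEANS.set_axis(list(KADSURA_SAMPLES), axis=0)
    config = SimulationConfig(
        cultivar_names=KADSURA_SAMPLES,
        attribute_means=means,
        planted_markers=(PlantedMarker("F054", Tier.KEY),),
        seed=seed,
    )
    return simulate_dataset(config).panel
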