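"""aromarank: prioritize aroma-active volatiles and tie them to sensory data.

From a GC-MS relative-abundance table and an odor-threshold table the package
computes Relative Odor Activity Values (ROAV), classifies key and modifier
odorants per sample, accounts for shared/unique compound sets and chemical
class composition, aggregates descriptive sensory-panel scores with ANOVA and
compact-letter post hoc grouping, and co-localizes compounds with sensory
attributes in a joint PCA loading space.
"""

__version__ = "0.1.0"

from .io import (  # noqa: F401
    ChemicalClass,
    CompoundRecord,
    Medium,
    SensoryPanel,
    ThresholdDB,
    ThresholdEntry,
    VOCTable,
    read_sensory_scores,
    read_threshold_table,
    read_voc_table,
    write_sensory_scores,
    write_threshold_table,
    write_voc_table,
)
from .roav import (  # noqa: F401
    ROAVProfile,
    ResolvedThreshold,
    Tier,
    classify_roav,
    compare_cultivars,
    compute_all_profiles,
    compute_roav_profile,
    find_reference,
    resolve_all,
    resolve_threshold,
)
from .profiles import (  # noqa: F401
    class_composition,
    detection_sets,
    named_sum,
    normalize_peak_areas,
)
from .sensory import (  # noqa: F401
    aggregate_scores,
    anova_attribute,
    compact_letter_display,
    posthoc_letters,
    summarize_panel,
)
from .multivariate import (  # noqa: F401
    cluster_heatmap,
    colocalize,
    hcluster,
    joint_pca,
    run_pca,
    zscore_rows,
)
from .simulate import (  # noqa: F401
    GroundTruth,
    LinkedPair,
    PlantedMarker,
    SimulationConfig,
    recovery_report,
    simulate_dataset,
)
from .datasets import (  # noqa: F401
    example_sensory_panel,
    load_kadsura_lexicon,
    load_kadsura_thresholds,
    load_kadsura_voc,
)
from .pipeline import RunConfig, run_all  # noqa: F401
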