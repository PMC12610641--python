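"""End-to-end orchestration: ROAV -> profile stats -> sensory -> multivariate.

``run_all`` wires the stages together from a single configuration, writes
every result table to an output directory, and records a manifest with the
echoed configuration and SHA-256 content hashes of each artifact so repeated
runs are auditable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import multivariate, profiles, roav, sensory
from .io import read_sensory_scores, read_threshold_table, read_voc_table

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("aromarank")


@dataclass
class RunConfig:
    voc_path: str
    thresholds_path: str
    sensory_path: str
    out_dir: str = "aromarank_out"
    reference_rule: str = "ct-max"
    alpha: float = 0.05
    posthoc: str = "tukey"
    theta_max: float = 10.0
    r_min: float = 0.9
    heatmap_linkage: str = "average"
    heatmap_metric: str = "euclidean"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.theta_max <= 0 or not (-1 <= self.r_min <= 1):
            raise ValueError("invalid co-localization thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format="%.6g", encoding="utf-8", **kwargs)


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage failure raises after a partial manifest (with the failure
    record) is written to the output directory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": [], "artifacts": {}}

    def checkpoint(stage: str) -> None:
        manifest["stages"].append(stage)
        log.info("stage complete: %s", stage)

    try:
        # ---- inputs
        voc = read_voc_table(config.voc_path)
        thresholds = read_threshold_table(config.thresholds_path)
        panel = read_sensory_scores(config.sensory_path)
        log.info(
            "inputs: %d compounds x %d samples; %d thresholded compounds; %d panel records",
            len(voc.compound_ids), len(voc.samples), len(thresholds), len(panel.records),
        )
        checkpoint("io")

        # ---- ROAV
        profs = roav.compute_all_profiles(voc, thresholds, reference_rule=config.reference_rule)
        for p in profs.values():
            if p.excluded:
                log.warning(
                    "%s: %d detected compounds excluded (no odor threshold): %s",
                    p.sample_id, len(p.excluded), ", ".join(sorted(p.excluded)),
                )
        report = roav.compare_cultivars(list(profs.values()))
        _write(report, out / "roav.csv", index_label="compound")
        tiers = pd.DataFrame(
            {s: {c: profs[s].tier[c].value for c in profs[s].tier} for s in voc.samples}
        )
        tiers.loc["__reference__"] = [profs[s].reference_compound for s in voc.samples]
        _write(tiers, out / "tiers.csv", index_label="compound")
        checkpoint("roav")

        # ---- profile statistics
        det = profiles.detection_sets(voc)
        for d in det.diagnostics:
            log.warning("detection diagnostic: %s", d)
        _write(det.to_frame(), out / "detection_report.csv", index=False)
        comp = profiles.class_composition(voc)
        _write(comp.to_frame(), out / "composition_report.csv", index_label="class")
        checkpoint("profile")

        # ---- sensory
        summaries = sensory.summarize_panel(panel, method=config.posthoc, alpha=config.alpha)
        _write(sensory.summary_frame(summaries), out / "sensory_summary.csv", index=False)
        checkpoint("sensory")

        # ---- multivariate
        agg = sensory.aggregate_scores(panel)
        sens_means = agg["mean"].unstack("attribute")[panel.attributes]
        pca = multivariate.run_pca(sens_means, preprocessing="zscore")
        pca_rows = [
            pd.DataFrame(
                [["variance_ratio", ""] + list(pca.explained_variance_ratio)],
                columns=["kind", "name", *pca.scores.columns],
            ),
            pca.scores.reset_index(names="name").assign(kind="score"),
            pca.loadings.reset_index(names="name").assign(kind="loading"),
        ]
        _write(pd.concat(pca_rows)[["kind", "name", *pca.scores.columns]],
               out / "pca.csv", index=False)
        checkpoint("pca")

        # key odorants (key tier in >=1 sample) drive the heatmap and joint PCA
        key_compounds = sorted({c for p in profs.values() for c in p.key_compounds()})
        key_means = voc.means.loc[key_compounds]
        if len(key_compounds) >= 2:
            hm = multivariate.cluster_heatmap(
                key_means, linkage=config.heatmap_linkage, metric=config.heatmap_metric
            )
            hm_out = hm.zmatrix.copy()
            hm_out["row_rank"] = pd.Series(
                {hm.zmatrix.index[i]: r for r, i in enumerate(hm.row_order)}
            )
            _write(hm_out, out / "heatmap.csv", index_label="compound")
        joint = multivariate.joint_pca(sens_means, key_means.T)
        pairs = [(c, a) for c in key_compounds for a in panel.attributes]
        coloc = multivariate.colocalize(
            joint, pairs, theta_max=config.theta_max, r_min=config.r_min
        )
        _write(coloc.pairs, out / "coloc.csv", index=False)
        checkpoint("joint")

    except Exception as exc:
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        raise

    for f in sorted(out.glob("*.csv")):
        manifest["artifacts"][f.name] = _sha256(f)
    checkpoint("manifest")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
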