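"""Quantitative descriptive analysis (QDA) statistics for trained-panel scores.

Aggregates 0-10 intensity scores over assessors and sessions, tests
per-attribute sample differences with one-way fixed-effects ANOVA, and
summarizes all pairwise post hoc comparisons as a compact letter display
(CLD): samples sharing a letter do not differ significantly, and the letter
"a" always attaches to the highest mean.

Sessions are treated as independent replicate observations (pooled), i.e. no
assessor random effect — the design intended here is the plain one-way
layout.  Two post hoc procedures are offered: Tukey's HSD (default) and
Duncan's multiple-range test (a stepwise studentized-range procedure with
span-dependent protection levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SensoryPanel

__all__ = [
    "AttributeSummary",
    "aggregate_scores",
    "anova_attribute",
    "pairwise_significance",
    "compact_letter_display",
    "posthoc_letters",
    "summarize_panel",
]


def aggregate_scores(panel: SensoryPanel) -> pd.DataFrame:
    """Mean, sd (n-1 denominator) and n per (sample, attribute) cell.

    Every sample x attribute combination must carry at least two
    observations; an empty cell is an error naming the cell.
    """
    out = []
    for sample in panel.samples:
        for attribute in panel.attributes:
            x = panel.scores(sample, attribute)
            if len(x) == 0:
                raise ValueError(f"no scores for sample {sample!r}, attribute {attribute!r}")
            if len(x) < 2:
                raise ValueError(
                    f"need >=2 observations for sample {sample!r}, attribute {attribute!r}"
                )
            out.append(
                {
                    "sample": sample,
                    "attribute": attribute,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "n": len(x),
                }
            )
    return pd.DataFrame(out).set_index(["sample", "attribute"])


def _groups(panel: SensoryPanel, attribute: str) -> tuple[list[str], list[np.ndarray]]:
    samples = panel.samples
    groups = [panel.scores(s, attribute) for s in samples]
    for s, g in zip(samples, groups):
        if len(g) < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 observations for {attribute!r}")
    return samples, groups


def anova_attribute(panel: SensoryPanel, attribute: str) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of one attribute's scores grouped by sample.

    Returns (F, p).  When every group has zero within-group variance but the
    means differ, F is infinite and p is reported as the 0 limit.
    """
    _, groups = _groups(panel, attribute)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    grand = np.mean(np.concatenate(groups))
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def _pooled_mse(groups: list[np.ndarray]) -> tuple[float, int]:
    df = sum(len(g) - 1 for g in groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    return float(mse), int(df)


def _tukey_significant(groups: list[np.ndarray], alpha: float) -> np.ndarray:
    res = stats.tukey_hsd(*groups)
    return np.asarray(res.pvalue) < alpha


def _duncan_significant(groups: list[np.ndarray], alpha: float) -> np.ndarray:
    """Duncan's multiple-range test as a boolean significance matrix.

    Means are ordered; a pair spanning p ordered means is compared against
    q(1-(1-alpha)^(p-1); p, df) * sqrt(MSE/n_h), with n_h the harmonic mean
    of the two group sizes.  Stepwise protection applies: a range nested in a
    non-significant range is itself declared non-significant.
    """
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    mse, df = _pooled_mse(groups)
    order = np.argsort(means)  # ascending
    sig = np.zeros((k, k), dtype=bool)
    if mse == 0:
        for i in range(k):
            for j in range(k):
                sig[i, j] = means[i] != means[j]
        return sig
    nonsig_windows: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            if any(w_lo <= lo and hi <= w_hi for w_lo, w_hi in nonsig_windows):
                continue
            gi, gj = order[lo], order[hi]
            n_h = 2.0 / (1.0 / ns[gi] + 1.0 / ns[gj])
            q_crit = stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, df)
            diff = means[gj] - means[gi]
            if diff > q_crit * np.sqrt(mse / n_h):
                sig[gi, gj] = sig[gj, gi] = True
            else:
                nonsig_windows.append((lo, hi))
    return sig


def pairwise_significance(
    panel: SensoryPanel, attribute: str, method: str = "tukey", alpha: float = 0.05
) -> pd.DataFrame:
    """Boolean matrix (sample x sample) of significant post hoc differences."""
    samples, groups = _groups(panel, attribute)
    if method == "tukey":
        sig = _tukey_significant(groups, alpha)
    elif method == "duncan":
        sig = _duncan_significant(groups, alpha)
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return pd.DataFrame(sig, index=samples, columns=samples)


def compact_letter_display(
    means: dict[str, float], significant: pd.DataFrame
) -> dict[str, str]:
    """Assemble a CLD from pairwise significance by insert-and-absorb.

    Starts with one letter column holding every group; each significant pair
    splits every column containing both members into two (one without each
    member); columns that become subsets of another are absorbed.  Letters
    are then ordered so "a" goes to the column whose best member has the
    highest mean; two groups share a letter iff their comparison is
    non-significant.
    """
    names = list(significant.index)
    columns: list[set[str]] = [set(names)]
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            a, b = names[ai], names[bi]
            if not significant.loc[a, b]:
                continue
            new_cols: list[set[str]] = []
            for col in columns:
                if a in col and b in col:
                    new_cols.extend([col - {a}, col - {b}])
                else:
                    new_cols.append(col)
            # absorb: drop any column contained in another
            columns = [
                c
                for idx, c in enumerate(new_cols)
                if c
                and not any(
                    (c < other) or (c == other and idx > jdx)
                    for jdx, other in enumerate(new_cols)
                    if jdx != idx
                )
            ]
    columns.sort(key=lambda col: (-max(means[g] for g in col), sorted(col)))
    letters = {g: "" for g in names}
    for idx, col in enumerate(columns):
        ch = chr(ord("a") + idx)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in names}


def posthoc_letters(
    panel: SensoryPanel, attribute: str, method: str = "tukey", alpha: float = 0.05
) -> dict[str, str]:
    """Post hoc letter grouping of the samples for one attribute."""
    sig = pairwise_significance(panel, attribute, method=method, alpha=alpha)
    agg = aggregate_scores(panel)
    means = {s: float(agg.loc[(s, attribute), "mean"]) for s in panel.samples}
    return compact_letter_display(means, sig)


@dataclass
class AttributeSummary:
    attribute: str
    per_sample: pd.DataFrame  # index sample, columns mean/sd/n
    anova_F: float
    anova_p: float
    letters: dict[str, str]


def summarize_panel(
    panel: SensoryPanel, method: str = "tukey", alpha: float = 0.05
) -> list[AttributeSummary]:
    """Full per-attribute summary: aggregation, ANOVA, and letter display."""
    agg = aggregate_scores(panel)
    out = []
    for attribute in panel.attributes:
        per_sample = agg.xs(attribute, level="attribute")
        F, p = anova_attribute(panel, attribute)
        letters = posthoc_letters(panel, attribute, method=method, alpha=alpha)
        out.append(AttributeSummary(attribute, per_sample, F, p, letters))
    return out


def summary_frame(summaries: list[AttributeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for sample, r in s.per_sample.iterrows():
            rows.append(
                {
                    "attribute": s.attribute,
                    "sample": sample,
                    "mean": r["mean"],
                    "sd": r["sd"],
                    "n": int(r["n"]),
                    "anova_F": s.anova_F,
                    "anova_p": s.anova_p,
                    "letters": s.letters[sample],
                }
            )
    return pd.DataFrame(rows)
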