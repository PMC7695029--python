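"""Descriptive composition statistics: group mean +/- SD, fatty-acid class
sums, the omega-3/omega-6 ratio, and one-way ANOVA with Tukey HSD compact
letters.

The unit of analysis is the fish: replicate chromatograms are averaged per
sample before any statistic is computed, so n per group is the number of
specimens, not the number of injections (analyzing injections directly
would pseudo-replicate).  Derived quantities (SFA/MUFA/PUFA sums, n3/n6)
are computed per sample and then summarized — for the ratio this gives the
mean of per-fish ratios, which is what a reported SD of the ratio implies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LabeledDataset

SFA = ("14:0", "16:0", "18:0")
MUFA = ("16:1", "18:1n9c", "18:1n7", "20:1n9", "22:1n11+22:1n9", "24:1n9")
PUFA = ("18:2n6c", "18:3n3", "18:4n3", "20:2n6", "20:3n3+20:4n6",
        "20:5n3", "22:5n3", "22:6n3")

# The co-eluting peak 20:3n3+20:4n6 mixes an n3 and an n6 acid.  Default
# convention: exclude it from both sums; "half" apportions it 50/50.
N3 = ("18:3n3", "18:4n3", "20:5n3", "22:5n3", "22:6n3")
N6 = ("18:2n6c", "20:2n6")
COELUTED_N3N6 = "20:3n3+20:4n6"

ALPHA = 0.05


def derived_quantities(sample_features: pd.DataFrame,
                       n3n6_coelution: str = "exclude") -> pd.DataFrame:
    """Per-sample SFA/MUFA/PUFA sums and the n3/n6 ratio.

    ``sample_features``: one row per sample, canonical feature columns.
    ``n3n6_coelution``: "exclude" (default) or "half" — how the co-eluting
    n3+n6 peak enters the omega sums.
    """
    if n3n6_coelution not in ("exclude", "half"):
        raise ValueError("n3n6_coelution must be 'exclude' or 'half'")
    out = pd.DataFrame(index=sample_features.index)
    out["SFA"] = sample_features[list(SFA)].sum(axis=1)
    out["MUFA"] = sample_features[list(MUFA)].sum(axis=1)
    out["PUFA"] = sample_features[list(PUFA)].sum(axis=1)
    n3 = sample_features[list(N3)].sum(axis=1)
    n6 = sample_features[list(N6)].sum(axis=1)
    if n3n6_coelution == "half":
        n3 = n3 + 0.5 * sample_features[COELUTED_N3N6]
        n6 = n6 + 0.5 * sample_features[COELUTED_N3N6]
    out["n3/n6"] = n3 / n6
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD per group for every feature and derived quantity, plus Tukey
    compact letters (features only have letters when ANOVA input is valid)."""

    table: pd.DataFrame  # index: quantity; columns: MultiIndex (group, stat)
    letters: dict[str, dict[int, str]]  # quantity -> {group code -> letters}

    def formatted(self) -> pd.DataFrame:
        """'mean +/- sd^letters' strings in a publication-style layout."""
        groups = sorted({g for g, _ in self.table.columns})
        out = {}
        for g in groups:
            col = []
            for q in self.table.index:
                m = self.table.loc[q, (g, "mean")]
                s = self.table.loc[q, (g, "sd")]
                let = self.letters.get(q, {}).get(g, "")
                col.append(f"{m:.2f} +/- {s:.2f}" + (f" {let}" if let else ""))
            out[g] = col
        return pd.DataFrame(out, index=self.table.index)


def summarize_groups(dataset: LabeledDataset,
                     n3n6_coelution: str = "exclude",
                     with_letters: bool = True) -> GroupSummary:
    """Per-group mean +/- SD over samples for the 17 features and the four
    derived quantities, with Tukey compact letters at alpha = 0.05."""
    tab = dataset.sample_table()
    feats = list(dataset.feature_names)
    derived = derived_quantities(tab[feats], n3n6_coelution) \
        if set(feats) >= set(SFA + MUFA + PUFA) else pd.DataFrame(index=tab.index)
    full = pd.concat([tab[["class_code"]], tab[feats], derived], axis=1)

    quantities = feats + list(derived.columns)
    groups = sorted(full["class_code"].unique())
    cols = pd.MultiIndex.from_product([groups, ["mean", "sd", "n"]])
    table = pd.DataFrame(index=quantities, columns=cols, dtype=float)
    for g in groups:
        sub = full[full["class_code"] == g]
        if len(sub) == 1:
            warnings.warn(f"group {g} has a single sample; SD reported as 0")
        for q in quantities:
            table.loc[q, (g, "mean")] = sub[q].mean()
            table.loc[q, (g, "sd")] = sub[q].std(ddof=1) if len(sub) > 1 else 0.0
            table.loc[q, (g, "n")] = len(sub)

    letters: dict[str, dict[int, str]] = {}
    if with_letters and len(groups) >= 2:
        for q in quantities:
            per_group = [full.loc[full["class_code"] == g, q].to_numpy()
                         for g in groups]
            if min(len(v) for v in per_group) < 2:
                continue
            _, _, _, lets = anova_tukey_values(per_group)
            letters[q] = {g: lets[i] for i, g in enumerate(groups)}
    return GroupSummary(table, letters)


def anova_tukey(dataset: LabeledDataset, feature: str):
    """One-way ANOVA + Tukey HSD on sample-level values of one feature.

    Returns (F, p, pairwise p-value matrix as DataFrame, letters dict keyed
    by class code)."""
    tab = dataset.sample_table()
    groups = sorted(tab["class_code"].unique())
    values = [tab.loc[tab["class_code"] == g, feature].to_numpy()
              for g in groups]
    F, p, pw, lets = anova_tukey_values(values)
    pw_df = pd.DataFrame(pw, index=groups, columns=groups)
    return F, p, pw_df, {g: lets[i] for i, g in enumerate(groups)}


def anova_tukey_values(values: list[np.ndarray], alpha: float = ALPHA):
    """ANOVA + Tukey + compact letters on raw per-group value arrays."""
    k = len(values)
    if k < 2 or min(len(v) for v in values) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    within_var = sum(((v - v.mean()) ** 2).sum() for v in values)
    means = np.array([v.mean() for v in values])
    if within_var == 0.0:
        warnings.warn("zero within-group variance; exact ties treated as "
                      "fully significant between distinct means")
        pw = np.where(np.abs(means[:, None] - means[None, :]) > 0, 0.0, 1.0)
        F, p = np.inf, 0.0
    else:
        F, p = stats.f_oneway(*values)
        pw = stats.tukey_hsd(*values).pvalue
    letters = compact_letter_display(pw < alpha, means)
    return float(F), float(p), pw, letters


def compact_letter_display(significant: np.ndarray,
                           means: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` marks pairs that differ; two groups share a letter
    iff their comparison is non-significant.  Letters are assigned
    alphabetically starting from the group with the lowest mean.
    """
    k = len(means)
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not significant[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
            # absorb: drop columns contained in another
            columns = [c for c in columns
                       if not any(c < d for d in columns)]
            # dedupe
            seen, uniq = set(), []
            for c in columns:
                key = frozenset(c)
                if key not in seen:
                    seen.add(key)
                    uniq.append(c)
            columns = uniq
    # letter order: columns sorted by the smallest mean they contain
    columns.sort(key=lambda c: min(means[i] for i in c) if c else np.inf)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: list[list[str]] = [[] for _ in range(k)]
    for letter, col in zip(alphabet, columns):
        for i in col:
            assigned[i].append(letter)
    return ["".join(sorted(a)) for a in assigned]
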