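"""Group statistics: two-way mixed-design ANOVA with Bonferroni post hoc
contrasts and the Mann–Whitney U test.

The mixed (split-plot) ANOVA treats genotype as the between-subjects factor
and stimulus frequency as the within-subjects (repeated) factor, with
subject nested in genotype.  Per-frequency genotype contrasts are
Bonferroni-adjusted by the number of frequencies tested.  Unpaired metric
comparisons (firing rate, CV, CV2, percent learning) use the two-sided
Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .types import ValidationError


@dataclass(frozen=True)
class EffectResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-design decomposition plus per-level post hoc contrasts."""

    between: EffectResult
    within: EffectResult
    interaction: EffectResult
    posthoc: pd.DataFrame = field(repr=False)   # per within-level contrast


@dataclass(frozen=True)
class MannWhitneyResult:
    u_stat: float
    n1: int
    n2: int
    p_two_sided: float
    method: str     # "exact" | "normal_approx"


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p: ``min(1, p · m)``."""
    return min(1.0, float(p_raw) * int(n_comparisons))


def _check_balanced(table: pd.DataFrame, dv: str, within: str,
                    subject: str, between: str) -> None:
    counts = table.groupby([subject, within], observed=True)[dv].count()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValidationError(
            "unbalanced design: every subject must contribute exactly one "
            f"value per {within} level; offending cells: "
            f"{list(bad.index[:5])}")
    levels = table[within].nunique()
    per_subject = table.groupby(subject, observed=True)[within].nunique()
    if (per_subject != levels).any():
        missing = per_subject[per_subject != levels]
        raise ValidationError(
            f"unbalanced design: subjects missing {within} levels: "
            f"{list(missing.index[:5])}")
    geno_per_subject = table.groupby(subject, observed=True)[between].nunique()
    if (geno_per_subject != 1).any():
        raise ValidationError(f"subject assigned to multiple {between} groups")


def mixed_anova(table: pd.DataFrame, dv: str, between: str = "genotype",
                within: str = "frequency_hz", subject: str = "animal",
                sphericity_correction: bool = False) -> AnovaResult:
    """Two-way mixed-design (split-plot) ANOVA with Bonferroni post hoc.

    Requires a complete balanced layout (every subject at every within
    level); missing cells raise rather than being imputed.  Post hoc
    contrasts are independent two-sample t tests between the two
    ``between`` groups at each ``within`` level, Bonferroni-multiplied by
    the number of levels.  No sphericity correction is applied unless
    requested.
    """
    _check_balanced(table, dv, within, subject, between)
    if table[within].nunique() < 2:
        raise ValidationError(f"mixed ANOVA needs >= 2 {within} levels")
    if table[between].nunique() < 2:
        raise ValidationError(f"mixed ANOVA needs >= 2 {between} groups")
    aov = pg.mixed_anova(data=table, dv=dv, within=within, between=between,
                         subject=subject, correction=sphericity_correction)
    aov = aov.set_index("Source")
    p_unc = "p_unc" if "p_unc" in aov.columns else "p-unc"
    corr_cols = [c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns]
    p_col = corr_cols[0] if sphericity_correction and corr_cols else p_unc

    def effect(source: str) -> EffectResult:
        row = aov.loc[source]
        p = row[p_col] if not pd.isna(row.get(p_col, np.nan)) else row[p_unc]
        return EffectResult(f_stat=float(row["F"]), df_num=int(row["DF1"]),
                            df_den=int(row["DF2"]), p_value=float(p))

    levels = sorted(table[within].unique())
    groups = sorted(table[between].unique())
    if len(groups) != 2:
        raise ValidationError(
            f"post hoc contrasts need exactly 2 {between} groups, "
            f"got {groups}")
    rows = []
    m = len(levels)
    for lev in levels:
        sub = table[table[within] == lev]
        x = sub.loc[sub[between] == groups[0], dv].to_numpy(float)
        y = sub.loc[sub[between] == groups[1], dv].to_numpy(float)
        t_stat, p_raw = sps.ttest_ind(x, y)
        rows.append({within: lev, "mean_diff": float(x.mean() - y.mean()),
                     "t_stat": float(t_stat), "p_raw": float(p_raw),
                     "p_adj": bonferroni(p_raw, m)})
    posthoc = pd.DataFrame(rows)
    return AnovaResult(between=effect(between), within=effect(within),
                       interaction=effect("Interaction"), posthoc=posthoc)


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    ``U = Σ_{i,j} [x_i > y_j] + ½ [x_i = y_j]``.  The exact null
    distribution is enumerated when the data are tie-free and
    ``n1 + n2 <= 40``; otherwise the normal approximation with continuity
    and tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and (x.size + y.size) <= 40
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return MannWhitneyResult(u_stat=float(res.statistic), n1=int(x.size),
                             n2=int(y.size), p_two_sided=float(res.pvalue),
                             method="exact" if exact else "normal_approx")
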