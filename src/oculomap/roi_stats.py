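"""Observer-level ROI scores and mixed-design effect statistics.

Regions of interest are the significant clusters of a differential
Z-map.  Each observer contributes the mean of their own (pooled-
normalised) Z-map over every ROI; the resulting balanced table feeds a
two-way mixed ANOVA (face region within subjects, observer group
between subjects) with partial eta squared, plus per-region independent
t-tests and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fixmap import StatMap
from .pixel_test import ClusterSet

__all__ = [
    "EffectSizeResult",
    "observer_roi_scores",
    "mixed_anova",
    "cohens_d",
    "region_comparisons",
]


@dataclass
class EffectSizeResult:
    F: float
    df: Tuple[int, int]
    p: float
    partial_eta_sq: float


def observer_roi_scores(
    observer_z_maps: Mapping[str, StatMap | np.ndarray],
    groups: Mapping[str, str],
    clusters: ClusterSet,
    region_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean Z per observer within each significant cluster.

    ``observer_z_maps`` maps observer id -> Z-map (normalised with the
    pooled group moments so scores are comparable across observers);
    ``groups`` maps observer id -> group label.  Returns a long-format
    balanced table with columns observer, group, region, mean_z.
    """
    if len(clusters) == 0:
        raise ValueError("empty cluster set: no regions of interest")
    if region_names is None:
        region_names = [f"roi{i}{c.sign}" for i, c in enumerate(clusters)]
    if len(region_names) != len(clusters):
        raise ValueError("need one region name per cluster")
    rows = []
    for obs, m in observer_z_maps.items():
        grid = m.grid if isinstance(m, StatMap) else np.asarray(m, dtype=float)
        if grid.shape != clusters.shape:
            raise ValueError("observer map dimensions do not match clusters")
        for name, c in zip(region_names, clusters):
            if c.area_px == 0:
                raise ValueError("empty cluster")
            vals = grid[c.pixels[:, 0], c.pixels[:, 1]]
            rows.append((obs, groups[obs], name, float(vals.mean())))
    return pd.DataFrame(rows, columns=["observer", "group", "region", "mean_z"])


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "mean_z",
    within: str = "region",
    between: str = "group",
    subject: str = "observer",
) -> EffectSizeResult:
    """Two-way mixed ANOVA; returns the region-by-group interaction.

    Classical (balanced) sums-of-squares decomposition with one
    between-subject and one within-subject factor; partial eta squared
    is SS_interaction / (SS_interaction + SS_error).  With two within
    levels and N subjects the interaction df are (1, N - k) for k
    groups.  Requires a balanced table (every subject measured in every
    region).
    """
    counts = table.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise ValueError("unbalanced table: need exactly one score per subject and region")
    per_subj = table.groupby(subject, observed=True)[within].nunique()
    if per_subj.nunique() != 1:
        raise ValueError("unbalanced table: subjects measured in different region sets")

    import pingouin as pg

    aov = pg.mixed_anova(
        data=table, dv=dv, within=within, between=between, subject=subject
    )
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    df_ = (int(inter["DF1"]), int(inter["DF2"]))
    if "F" not in aov.columns or (np.isnan(float(inter.get("F", np.nan)))
                                  and abs(float(inter["SS"])) < 1e-12):
        # degenerate 0/0 case (e.g. all scores identical): no effect
        return EffectSizeResult(F=0.0, df=df_, p=1.0, partial_eta_sq=0.0)
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return EffectSizeResult(F=float(inter["F"]), df=df_, p=float(inter[p_col]),
                            partial_eta_sq=float(inter["np2"]))


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardised mean difference with the pooled-SD convention.

    d = (mean_a - mean_b) / s_p with the pooled variance using the
    (n_a + n_b - 2) denominator.  Antisymmetric under group swap.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("degenerate samples: zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def region_comparisons(
    table: pd.DataFrame,
    dv: str = "mean_z",
    within: str = "region",
    between: str = "group",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-region independent two-tailed t-tests with Cohen's d.

    The classical equal-variance test matches the balanced design;
    ``welch=True`` switches to the unequal-variance correction.
    """
    groups = sorted(table[between].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for region, sub in table.groupby(within, observed=True):
        a = sub.loc[sub[between] == groups[0], dv].to_numpy()
        b = sub.loc[sub[between] == groups[1], dv].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append((region, float(t), float(p), cohens_d(a, b)))
    return pd.DataFrame(rows, columns=["region", "t", "p", "cohens_d"])
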