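"""Cell-assembly mapping and the statistics layer.

A neuron belongs to a word's cell assembly (CA) when it is active -
fires at least once - in at least four of the word's six evaluation
trials (three auditory-port, three articulatory-port probes).  CA counts
per area feed a two-way repeated-measures ANOVA with the within-subject
factors WordType (action / object) and Area (12 levels), networks as
subjects, followed by Bonferroni-corrected per-area paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import AREAS, N_E

__all__ = [
    "ca_mask", "ca_membership", "ca_counts", "ca_table", "AnovaResult",
    "rm_anova", "bonferroni_critical", "posthoc_wordtype_by_area",
    "time_course",
]


def ca_mask(rasters, min_trials: int = 4, criterion: str = "trials",
            n_trials: int = 6) -> np.ndarray:
    """Boolean CA-membership mask over all excitatory neurons.

    ``criterion='trials'`` (default): member iff active (>= 1 spike) in at
    least ``min_trials`` of the ``n_trials`` rasters.  ``criterion='spikes'``
    applies the alternative reading - at least ``min_trials`` spikes in
    total across all trials.
    """
    if len(rasters) != n_trials:
        raise ValueError(f"expected {n_trials} evaluation rasters, got {len(rasters)}")
    stacked = np.stack([np.asarray(r) for r in rasters])  # (trials, steps, n_e)
    if criterion == "trials":
        active = stacked.any(axis=1)                      # (trials, n_e)
        return active.sum(axis=0) >= min_trials
    if criterion == "spikes":
        return stacked.sum(axis=(0, 1)) >= min_trials
    raise ValueError(f"unknown CA criterion {criterion!r}")


def ca_membership(rasters, areas=AREAS, cells_per_area: int = N_E,
                  min_trials: int = 4, criterion: str = "trials",
                  n_trials: int = 6) -> set:
    """CA membership as a set of ``(area_name, local_cell_index)`` pairs."""
    mask = ca_mask(rasters, min_trials=min_trials, criterion=criterion,
                   n_trials=n_trials)
    idx = np.flatnonzero(mask)
    return {(areas[i // cells_per_area], int(i % cells_per_area)) for i in idx}


def ca_counts(rasters, areas=AREAS, cells_per_area: int = N_E, **kw) -> np.ndarray:
    """Per-area CA-neuron counts for one word."""
    mask = ca_mask(rasters, **kw)
    return mask.reshape(len(areas), cells_per_area).sum(axis=1)


def ca_table(evaluations: dict, categories: dict, areas=AREAS,
             cells_per_area: int = N_E, **kw) -> pd.DataFrame:
    """Tidy CA-count table over networks, words and areas.

    ``evaluations`` maps ``network_id -> {word_id: [rasters]}``;
    ``categories`` maps ``word_id -> 'action' | 'object'``.  The result
    has one row per (network, word, area) with columns ``network_id,
    word_id, category, area, ca_count`` - the complete grid.
    """
    rows = []
    for net_id, words in evaluations.items():
        for word_id, rasters in words.items():
            counts = ca_counts(rasters, areas=areas,
                               cells_per_area=cells_per_area, **kw)
            for area, c in zip(areas, counts):
                rows.append((net_id, word_id, categories[word_id], area, int(c)))
    return pd.DataFrame(rows, columns=["network_id", "word_id", "category",
                                       "area", "ca_count"])


@dataclass
class AnovaResult:
    """Two-way repeated-measures ANOVA outcome (WordType x Area)."""

    F_area: float
    df_area: tuple[int, int]
    p_area: float
    F_wordtype: float
    df_wordtype: tuple[int, int]
    p_wordtype: float
    F_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("Area", self.F_area, *self.df_area, self.p_area),
                ("WordType", self.F_wordtype, *self.df_wordtype, self.p_wordtype),
                ("WordType x Area", self.F_interaction, *self.df_interaction,
                 self.p_interaction)]
        return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])


def _cell_means(table: pd.DataFrame) -> np.ndarray:
    """Balanced (subject, area, wordtype) cell means, words averaged within
    category."""
    piv = (table.groupby(["network_id", "area", "category"])["ca_count"]
           .mean().unstack(["area", "category"]))
    if piv.isna().any().any():
        raise ValueError("unbalanced design: every network needs every "
                         "area x wordtype cell")
    counts = table.groupby(["network_id", "area", "category"]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal words per category")
    n_sub = piv.shape[0]
    areas = piv.columns.get_level_values(0).unique()
    cats = piv.columns.get_level_values(1).unique()
    Y = np.empty((n_sub, len(areas), len(cats)))
    for i, a in enumerate(areas):
        for j, c in enumerate(cats):
            Y[:, i, j] = piv[(a, c)].to_numpy()
    return Y


def rm_anova(table: pd.DataFrame) -> AnovaResult:
    """Two-way within-subject ANOVA on CA counts.

    Factors: Area (a levels) and WordType (w levels), subjects = networks
    (n >= 2).  Uses the standard repeated-measures sums-of-squares
    decomposition; each effect is tested against its own effect-by-subject
    interaction.  No sphericity correction is applied (degrees of freedom
    are reported uncorrected).
    """
    Y = _cell_means(table)
    n, a, w = Y.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 networks")
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_w = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sw = Y.mean(axis=1)
    m_aw = Y.mean(axis=0)

    ss_a = n * w * np.sum((m_a - grand) ** 2)
    ss_w = n * a * np.sum((m_w - grand) ** 2)
    ss_aw = n * np.sum((m_aw - m_a[:, None] - m_w[None, :] + grand) ** 2)
    ss_sa = w * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sw = a * np.sum((m_sw - m_s[:, None] - m_w[None, :] + grand) ** 2)
    resid = (Y - m_sa[:, :, None] - m_sw[:, None, :] - m_aw[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_w[None, None, :]
             - grand)
    ss_saw = np.sum(resid ** 2)

    df_a, df_w = a - 1, w - 1
    df_sa, df_sw = (a - 1) * (n - 1), (w - 1) * (n - 1)
    df_aw, df_saw = (a - 1) * (w - 1), (a - 1) * (w - 1) * (n - 1)

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err
        if ms_err == 0.0:
            f = 0.0 if ss_eff == 0.0 else np.inf
        else:
            f = (ss_eff / df_eff) / ms_err
        return float(f), float(stats.f.sf(f, df_eff, df_err))

    F_a, p_a = f_and_p(ss_a, df_a, ss_sa, df_sa)
    F_w, p_w = f_and_p(ss_w, df_w, ss_sw, df_sw)
    F_aw, p_aw = f_and_p(ss_aw, df_aw, ss_saw, df_saw)
    return AnovaResult(F_a, (df_a, df_sa), p_a,
                       F_w, (df_w, df_sw), p_w,
                       F_aw, (df_aw, df_saw), p_aw)


def bonferroni_critical(alpha: float = 0.05, n_comparisons: int = 12) -> float:
    """Per-comparison critical p-value under Bonferroni correction."""
    return alpha / n_comparisons


def posthoc_wordtype_by_area(table: pd.DataFrame, alpha: float = 0.05,
                             n_comparisons: int = 12) -> pd.DataFrame:
    """Paired Action-vs-Object comparison per area, Bonferroni corrected.

    With only two WordType levels the post-hoc range test degenerates to
    a paired comparison, implemented as a paired t-test across networks
    on the per-network category means.  Significance is declared at
    ``p < alpha / n_comparisons``.
    """
    crit = bonferroni_critical(alpha, n_comparisons)
    piv = (table.groupby(["network_id", "area", "category"])["ca_count"]
           .mean().unstack("category"))
    rows = []
    for area, sub in piv.groupby(level="area", sort=False):
        x = sub["action"].to_numpy()
        y = sub["object"].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append((area, float(t), float(p), bool(p < crit)))
    out = pd.DataFrame(rows, columns=["area", "statistic", "p", "significant"])
    out.attrs["critical_p"] = crit
    return out


def time_course(raster: np.ndarray, areas=AREAS, cells_per_area: int = N_E,
                stim_window: tuple[int, int] | None = (5, 7)) -> pd.DataFrame:
    """Per-area spike counts per step for one evaluation raster.

    Rows are time steps, columns areas; the stimulation window (default
    steps 5-6, the two probe steps after the 5-step baseline) is attached
    as ``DataFrame.attrs['stim_window']``.
    """
    r = np.asarray(raster)
    counts = r.reshape(r.shape[0], len(areas), cells_per_area).sum(axis=2)
    df = pd.DataFrame(counts, columns=list(areas))
    df.index.name = "time_step"
    df.attrs["stim_window"] = stim_window
    return df
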