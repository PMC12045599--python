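"""Replicate-aware summaries ("superplots") and standard omnibus tests.

Per-cell measurements are first collapsed to per-replicate means; inference
(two-way ANOVA followed by Tukey's HSD) then runs on the replicate means, so
the sample size is the number of independent experiments, never the pooled
cell count.  This guards against pseudo-replication: cells within a replicate
are not independent observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from invkit.errors import ConfigurationError

__all__ = ["SuperplotData", "superplot_summary", "superplot_figure"]


@dataclass
class SuperplotData:
    """Replicate-aware summary of per-cell values.

    ``anova`` is a two-way ANOVA table on the replicate means (factors as
    configured); ``tukey`` the pairwise Tukey-HSD comparisons of factor-level
    combinations, also on replicate means.
    """

    cells: pd.DataFrame
    replicate_means: pd.DataFrame
    group_summary: pd.DataFrame       # per group: grand mean of replicate means, sem, n
    anova: pd.DataFrame | None
    tukey: pd.DataFrame | None
    factors: tuple[str, ...] = ()
    value: str = "value"


def superplot_summary(
    cells: pd.DataFrame,
    value: str = "value",
    factors: tuple[str, ...] = ("condition",),
    replicate: str = "replicate",
    run_tests: bool = True,
) -> SuperplotData:
    """Summarize per-cell values into replicate means and run omnibus tests.

    Parameters
    ----------
    cells : per-cell table; every row needs the value, the factor columns and
        a replicate label.  Replicates with zero cells are simply absent;
        empty groups are excluded with a warning.
    factors : one or two categorical factor columns (e.g. construct and
        treatment).  With two factors the ANOVA is two-way with interaction.

    Tests require >= 2 replicates per group; otherwise they are skipped with
    a warning and the summary alone is returned.
    """
    factors = tuple(factors)
    if not 1 <= len(factors) <= 2:
        raise ConfigurationError("need one or two factor columns")
    missing = [c for c in (value, replicate, *factors) if c not in cells.columns]
    if missing:
        raise ConfigurationError(f"missing columns: {missing}")
    cells = cells.dropna(subset=[value])
    if cells.empty:
        raise ConfigurationError("no cells to summarize")
    group_cols = [*factors, replicate]
    rep_means = (cells.groupby(group_cols, dropna=False)[value]
                 .agg(["mean", "size"]).reset_index()
                 .rename(columns={"mean": value, "size": "n_cells"}))
    empty = rep_means["n_cells"] == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} empty replicates")
        rep_means = rep_means[~empty]
    summary = (rep_means.groupby(list(factors))[value]
               .agg(grand_mean="mean",
                    sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1
                    else np.nan,
                    n_replicates="size")
               .reset_index())

    anova = tukey = None
    if run_tests:
        if (summary["n_replicates"] < 2).any():
            warnings.warn("fewer than 2 replicates in some group; tests skipped")
        else:
            df = rep_means.rename(columns={value: "_y"})
            terms = " * ".join(f"C({f})" for f in factors)
            model = ols(f"_y ~ {terms}", data=df).fit()
            typ = 2 if len(factors) > 1 else 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova = sm.stats.anova_lm(model, typ=typ)
            groups = df[list(factors)].astype(str).agg(":".join, axis=1)
            if groups.nunique() > 1:
                res = pairwise_tukeyhsd(df["_y"], groups)
                tukey = pd.DataFrame(res.summary().data[1:],
                                     columns=res.summary().data[0])
    return SuperplotData(cells=cells, replicate_means=rep_means,
                         group_summary=summary, anova=anova, tukey=tukey,
                         factors=factors, value=value)


def superplot_figure(data: SuperplotData, ax=None):
    """Draw a superplot: per-cell spots colored by replicate, replicate means
    as squares, group grand mean ± s.e.m. as a bar."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 1.1 * len(data.group_summary), 3.2))
    factors = list(data.factors)
    groups = data.group_summary[factors].astype(str).agg(":".join, axis=1)
    positions = {g: i for i, g in enumerate(groups)}
    reps = sorted(data.cells["replicate"].astype(str).unique())
    cmap = plt.get_cmap("tab10")
    rng = np.random.default_rng(0)
    for _, row in data.cells.iterrows():
        g = ":".join(str(row[f]) for f in factors)
        rep_i = reps.index(str(row["replicate"]))
        ax.plot(positions[g] + rng.uniform(-0.18, 0.18), row[data.value],
                "o", ms=3, alpha=0.5, color=cmap(rep_i % 10))
    for _, row in data.replicate_means.iterrows():
        g = ":".join(str(row[f]) for f in factors)
        rep_i = reps.index(str(row["replicate"]))
        ax.plot(positions[g], row[data.value], "s", ms=7, mec="k",
                color=cmap(rep_i % 10))
    for (_, row), g in zip(data.group_summary.iterrows(), groups):
        ax.errorbar(positions[g], row["grand_mean"], yerr=row["sem"],
                    fmt="_", color="k", capsize=4, ms=18)
    ax.set_xticks(list(positions.values()), list(positions.keys()),
                  rotation=30, ha="right")
    ax.set_ylabel(data.value)
    return ax
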