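"""Protein-group enrichment statistics for defining a vesicle proteome.

The workflow mirrors the standard label-free quantification (LFQ) analysis of
pulldown experiments: read a MaxQuant-style protein-group table, log2
transform, impute left-censored missing values from a downshifted normal
distribution, call enrichment per protein with a Welch two-sample test and a
fold-change cutoff, consolidate enriched sets across experiments, and test
annotation or reference-set enrichment with Pearson's chi-squared statistic.

Enrichment classes follow the four-color volcano-plot convention:

* ``pink`` — fold change > 2 and P < 0.05 (the enriched set),
* ``red``  — fold change > 2 and P > 0.05,
* ``blue`` — fold change < 2 and P < 0.05,
* ``gray`` — remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from invkit.errors import ConfigurationError

__all__ = [
    "QuantTable",
    "ContingencyResult",
    "read_quant_table",
    "write_quant_table",
    "log2_transform",
    "impute_missing",
    "differential_enrichment",
    "consolidate_proteomes",
    "contingency_enrichment",
    "tmd_count_enrichment",
    "overlap_enrichment",
    "rank_correlation",
]


# ---------------------------------------------------------------------------
# table container and IO
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Protein x sample intensity matrix with sample and row metadata.

    ``values`` is indexed by protein id with one column per sample; NaN marks
    missing values (zero intensities on disk).  ``samples`` maps each sample
    to its condition and replicate.  ``flags`` carries contaminant / reverse /
    site-only row flags.
    """

    values: pd.DataFrame
    samples: pd.DataFrame            # index sample, columns condition, replicate
    flags: pd.DataFrame              # index protein, bool columns
    is_log2: bool = False

    def filtered(self) -> "QuantTable":
        """Drop contaminant / reverse / site-only rows."""
        bad = self.flags.any(axis=1)
        return QuantTable(self.values.loc[~bad], self.samples,
                          self.flags.loc[~bad], self.is_log2)

    def condition_columns(self, condition: str) -> list[str]:
        cols = list(self.samples.index[self.samples["condition"] == condition])
        if not cols:
            raise ConfigurationError(f"no samples for condition {condition!r}")
        return cols


_FLAG_COLUMNS = {
    "Potential contaminant": "contaminant",
    "Reverse": "reverse",
    "Only identified by site": "site_only",
}


def read_quant_table(
    path_or_frame,
    intensity_prefix: str = "LFQ intensity ",
    id_column: str = "Protein IDs",
) -> QuantTable:
    """Read a tab-delimited protein-group table.

    Sample columns are identified by ``intensity_prefix``; the remainder of
    the column name is parsed as ``<condition>_R<replicate>`` (falling back to
    the whole name as the condition).  Zero intensities become missing values.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t")
    int_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not int_cols:
        raise ConfigurationError(
            f"no intensity columns with prefix {intensity_prefix!r}")
    if id_column not in df.columns:
        raise ConfigurationError(f"missing id column {id_column!r}")
    values = df.set_index(id_column)[int_cols].astype(float)
    values.columns = [c[len(intensity_prefix):] for c in int_cols]
    values = values.where(values > 0)    # 0 (and negatives) -> missing
    sample_rows = []
    for s in values.columns:
        cond, _, rep = s.rpartition("_R")
        if cond and rep.isdigit():
            sample_rows.append({"sample": s, "condition": cond,
                                "replicate": int(rep)})
        else:
            sample_rows.append({"sample": s, "condition": s, "replicate": 1})
    samples = pd.DataFrame(sample_rows).set_index("sample")
    flags = pd.DataFrame(index=values.index)
    for col, name in _FLAG_COLUMNS.items():
        flags[name] = (df.set_index(id_column)[col] == "+") if col in df.columns \
            else False
    return QuantTable(values, samples, flags)


def write_quant_table(table: QuantTable, path,
                      intensity_prefix: str = "LFQ intensity ",
                      id_column: str = "Protein IDs") -> None:
    """Write a :class:`QuantTable` back to the tab-delimited dialect."""
    out = table.values.copy()
    out.columns = [intensity_prefix + c for c in out.columns]
    out = out.fillna(0.0)
    out.insert(0, id_column, out.index)
    for col, name in _FLAG_COLUMNS.items():
        out[col] = np.where(table.flags[name], "+", "")
    out.to_csv(path, sep="\t", index=False)


def log2_transform(table: QuantTable) -> QuantTable:
    if table.is_log2:
        return table
    return replace(table, values=np.log2(table.values), is_log2=True)


# ---------------------------------------------------------------------------
# imputation and differential enrichment
# ---------------------------------------------------------------------------

def impute_missing(table: QuantTable, shift: float = 1.8, width: float = 0.3,
                   seed: int | None = 0) -> QuantTable:
    """Impute missing log2 intensities from a downshifted normal.

    Per sample, missing entries are drawn from
    ``Normal(mean - shift * sd, (width * sd)^2)`` of that sample's observed
    values — the standard model for left-censored LFQ missingness.  Observed
    values are unchanged; results are deterministic under ``seed``.
    """
    if not table.is_log2:
        raise ConfigurationError("impute_missing expects log2 intensities "
                                 "(call log2_transform first)")
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    for sample in values.columns:
        col = values[sample]
        observed = col.dropna()
        if len(observed) < 2:
            raise ConfigurationError(
                f"sample {sample!r} has fewer than 2 observed values")
        mu, sd = observed.mean(), observed.std(ddof=1)
        missing = col.isna()
        if missing.any():
            values.loc[missing, sample] = rng.normal(
                mu - shift * sd, width * sd, size=int(missing.sum()))
    return replace(table, values=values)


def differential_enrichment(
    table: QuantTable,
    condition_a: str,
    condition_b: str,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Per-protein log2 fold change, Welch-test p-value and volcano class.

    ``log2fc = mean(A) - mean(B)`` on the log2 scale; the p-value is a
    two-sided Welch (unequal-variance) two-sample t test.  Identical groups
    get ``p = 1`` and ``log2fc = 0`` by convention.  The fold-change cutoff is
    applied on the linear scale with strict inequality
    (``FC > 2  <=>  log2fc > 1``).  An optional Benjamini-Hochberg ``fdr``
    column is included for reference; the class calls use the raw p-value.
    """
    if not table.is_log2:
        table = log2_transform(table)
    if exclude_flagged:
        table = table.filtered()
    a = table.values[table.condition_columns(condition_a)]
    b = table.values[table.condition_columns(condition_b)]
    n_a, n_b = a.notna().sum(axis=1), b.notna().sum(axis=1)
    if (n_a.min() < 2) or (n_b.min() < 2):
        raise ConfigurationError(
            "need >= 2 replicates per condition for every protein "
            "(impute missing values first)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # zero-variance rows handled below
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False,
                                    nan_policy="omit")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    identical = np.isclose(a.var(axis=1, ddof=1), 0) & \
        np.isclose(b.var(axis=1, ddof=1), 0) & np.isclose(log2fc, 0)
    p = np.where(identical | ~np.isfinite(p), 1.0, p)
    log2fc = np.where(identical, 0.0, log2fc)
    lfc_cut = np.log2(fc_cut)
    high_fc = log2fc > lfc_cut
    sig = p < p_cut
    cls = np.select(
        [high_fc & sig, high_fc & ~sig, ~high_fc & sig],
        ["pink", "red", "blue"], default="gray")
    out = pd.DataFrame({"protein": a.index, "log2fc": log2fc, "p": p,
                        "class": cls}).set_index("protein")
    out["fdr"] = _benjamini_hochberg(out["p"].to_numpy())
    return out.reset_index()


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def consolidate_proteomes(runs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of enriched (pink) proteins across named enrichment runs.

    Each run contributes a boolean provenance column; proteins are ranked by
    their maximum fold enrichment across runs.  Duplicate ids within a run
    are merged (keeping the larger fold change) with a warning.  The
    operation is idempotent and order independent.
    """
    if not runs:
        raise ConfigurationError("need at least one enrichment run")
    pieces = []
    for name, df in runs.items():
        pink = df[df["class"] == "pink"][["protein", "log2fc"]].copy()
        if pink["protein"].duplicated().any():
            warnings.warn(f"run {name!r}: duplicate protein ids merged")
            pink = pink.sort_values("log2fc").drop_duplicates(
                "protein", keep="last")
        pink["run"] = name
        pieces.append(pink)
    tall = pd.concat(pieces, ignore_index=True)
    out = tall.pivot_table(index="protein", columns="run", values="log2fc",
                           aggfunc="max")
    flags = out.notna()
    flags.columns = [f"in_{c}" for c in flags.columns]
    consolidated = pd.DataFrame({"max_log2fc": out.max(axis=1)}).join(flags)
    consolidated = consolidated.sort_values("max_log2fc", ascending=False)
    return consolidated.reset_index().sort_values(
        ["max_log2fc", "protein"], ascending=[False, True],
        ignore_index=True)


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    """A 2x2 enrichment test (Pearson chi-squared, 1 df)."""

    table: np.ndarray                # [[a, b], [c, d]]: rows set/rest, cols flag yes/no
    chi2: float
    p: float
    proportion_set: float            # flagged fraction within the set
    proportion_rest: float
    direction: str                   # "enriched" | "depleted" | "none"

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return tuple(int(v) for v in self.table.ravel())


def _pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-squared for a 2x2 table (no continuity
    correction): n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ConfigurationError("chi-squared undefined: a margin is zero")
    return n * (a * d - b * c) ** 2 / denom


def contingency_enrichment(
    set_members,
    background,
    flag,
    correction: bool = False,
) -> ContingencyResult:
    """Test whether an annotation is enriched in a protein set vs the rest.

    Parameters
    ----------
    set_members, background : protein id iterables; the set must be a subset
        of the background.
    flag : mapping / Series protein -> bool, defined for every background
        protein.
    correction : apply the Yates continuity correction (off by default, as
        is conventional when reporting the Pearson statistic itself).

    Raises on zero expected cell counts.
    """
    set_members = set(set_members)
    background = list(dict.fromkeys(background))
    if not set_members <= set(background):
        raise ConfigurationError("set_members must be a subset of background")
    flag = pd.Series(flag)
    missing = [p for p in background if p not in flag.index]
    if missing:
        raise ConfigurationError(
            f"flag undefined for {len(missing)} background proteins")
    in_set = np.array([p in set_members for p in background])
    flagged = flag.loc[background].to_numpy().astype(bool)
    a = int((in_set & flagged).sum())
    b = int((in_set & ~flagged).sum())
    c = int((~in_set & flagged).sum())
    d = int((~in_set & ~flagged).sum())
    table = np.array([[a, b], [c, d]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected == 0).any():
        raise ConfigurationError("zero expected cell count in the 2x2 table")
    if correction:
        chi2 = float(stats.chi2_contingency(table, correction=True)[0])
    else:
        chi2 = _pearson_chi2_2x2(a, b, c, d)
    p = float(stats.chi2.sf(chi2, df=1))
    prop_set = a / (a + b) if (a + b) else float("nan")
    prop_rest = c / (c + d) if (c + d) else float("nan")
    if prop_set > prop_rest:
        direction = "enriched"
    elif prop_set < prop_rest:
        direction = "depleted"
    else:
        direction = "none"
    return ContingencyResult(table, chi2, p, prop_set, prop_rest, direction)


def tmd_count_enrichment(
    set_members, background, tmd_counts, counts=None,
) -> pd.DataFrame:
    """Per-TMD-count 2x2 enrichment tests (each count vs all other proteins)."""
    tmd_counts = pd.Series(tmd_counts)
    counts = sorted(set(int(c) for c in (
        counts if counts is not None else tmd_counts.loc[list(background)].unique())))
    rows = []
    for k in counts:
        flag = tmd_counts == k
        res = contingency_enrichment(set_members, background, flag)
        rows.append({"tmd_count": k, "chi2": res.chi2, "p": res.p,
                     "proportion_set": res.proportion_set,
                     "proportion_rest": res.proportion_rest,
                     "direction": res.direction})
    return pd.DataFrame(rows)


def overlap_enrichment(set_a, set_b, background) -> dict:
    """Enrichment of one reference set in another, with overlap fractions.

    Returns the 2x2 test of ``set_b`` membership inside ``set_a`` versus the
    rest of the background, plus the overlap fractions in both directions
    (|A∩B|/|A| and |A∩B|/|B|).
    """
    set_a, set_b = set(set_a), set(set_b)
    flag = pd.Series({p: p in set_b for p in background})
    res = contingency_enrichment(set_a, background, flag)
    inter = len(set_a & set_b)
    return {
        "result": res,
        "overlap": inter,
        "fraction_of_a": inter / len(set_a) if set_a else float("nan"),
        "fraction_of_b": inter / len(set_b) if set_b else float("nan"),
    }


def rank_correlation(values_a, values_b) -> tuple[float, float]:
    """Spearman rank correlation of matched per-protein quantities.

    Average ranks are used for ties; the p-value uses the standard
    large-sample t approximation.  Requires n >= 4.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("values must be matched 1D arrays")
    if len(a) < 4:
        raise ConfigurationError("need n >= 4 pairs")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
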