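"""Genetic-interaction calling from paired replicate screens.

Per array position across replicate sets this module computes:

* the **ratio** score, experimental / control normalized size — a
  position with no interaction scores ~1, an aggravating interaction
  (double mutant sicker than expected) scores below 1, an alleviating
  interaction above 1;
* the **diff** score, experimental - control, analogous to the
  multiplicative-model epsilon score used by large-scale interaction
  datasets;
* a paired two-tailed t-test across replicates.

The ratio is preferred because it is less sensitive to the growth rate
of the control: halving the growth of a slow strain (0.4 -> 0.2) and
shaving a fast one (1.0 -> 0.8) both give diff -0.2, but ratios 0.5
vs. 0.8 rank the slow-strain interaction as the stronger one.

Hit calling applies three criteria: the mean ratio falls outside the
[p, q] cut-off band, it does so in at least ``min_replicates``
individual replicates, and the paired t-test p-value is below
``max_p``.  Cut-offs can be estimated from the sorted-ratio curve by
extrapolating its linear central portion to both ends of the rank
axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutoffPair",
    "ratio_score",
    "diff_score",
    "paired_t_test",
    "build_replicate_table",
    "clamp_sizes",
    "slow_growth_filter",
    "linkage_exclude",
    "estimate_cutoffs",
    "call_hits",
    "attach_descriptions",
    "description_filter",
    "export_table",
    "read_exported",
    "analyze_screen",
]

EXPORT_COLUMNS = ["plate", "row", "col", "orf", "gene",
                  "ctrl_mean", "ctrl_sd", "exp_mean", "exp_sd",
                  "ratio", "diff", "n_below", "n_above", "p_value",
                  "hit", "excluded", "exclude_reason"]


@dataclass(frozen=True)
class CutoffPair:
    """Low (p) and high (q) ratio cut-offs bracketing non-interactions."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < 1 < self.high):
            raise ValueError(
                f"cut-offs must satisfy 0 < p < 1 < q, got "
                f"p={self.low}, q={self.high}")


def ratio_score(ctrl: float, exp: float) -> float:
    """Ratio of experimental to control normalized colony size."""
    if ctrl <= 0:
        raise ValueError("control size must be positive for a ratio score")
    return exp / ctrl


def diff_score(ctrl: float, exp: float) -> float:
    """Signed difference, experimental minus control normalized size."""
    return exp - ctrl


def paired_t_test(ctrl_sizes, exp_sizes) -> float:
    """Paired two-tailed t-test p-value across replicates.

    Degenerate inputs are resolved deterministically: identical paired
    values give p = 1 (no evidence of a difference); nonzero constant
    differences with zero spread give p = 0 (the t statistic diverges).
    Fewer than two replicates give NaN.
    """
    ctrl = np.asarray(ctrl_sizes, dtype=float)
    exp = np.asarray(exp_sizes, dtype=float)
    if ctrl.shape != exp.shape:
        raise ValueError("control and experiment must have equal lengths")
    if ctrl.size < 2:
        return float("nan")
    d = exp - ctrl
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d, 0.0) else 0.0
    return float(stats.ttest_rel(exp, ctrl).pvalue)


def build_replicate_table(scored_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Collate per-set scored tables into one replicate table.

    Each input table must have columns plate/row/col/orf/gene/ctrl/exp
    (one replicate per table, as written by per-set scoring).  The
    result has one row per array position with per-replicate size
    columns ``ctrl_1..n`` / ``exp_1..n``.
    """
    if not scored_tables:
        raise ValueError("no scored tables given")
    base = scored_tables[0][["plate", "row", "col", "orf", "gene"]].copy()
    key_cols = ["plate", "row", "col"]
    merged = base
    for i, tab in enumerate(scored_tables, 1):
        sub = tab[key_cols + ["ctrl", "exp"]].rename(
            columns={"ctrl": f"ctrl_{i}", "exp": f"exp_{i}"})
        merged = merged.merge(sub, on=key_cols, how="inner", validate="1:1")
    merged["excluded"] = False
    merged["exclude_reason"] = ""
    return merged


def _replicate_columns(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    ctrl_cols = sorted((c for c in table.columns if c.startswith("ctrl_")),
                       key=lambda s: int(s.split("_")[1]))
    exp_cols = sorted((c for c in table.columns if c.startswith("exp_")),
                      key=lambda s: int(s.split("_")[1]))
    if len(ctrl_cols) != len(exp_cols) or not ctrl_cols:
        raise ValueError("malformed replicate table")
    return ctrl_cols, exp_cols


def slow_growth_filter(table: pd.DataFrame, threshold: float,
                       apply_to: str = "control") -> pd.DataFrame:
    """Zero out replicate pairs where growth is too poor to score.

    For each replicate pair where the selected side(s) fall below
    ``threshold``, both sizes of that pair are set to 0, excluding the
    pair from downstream means and tests (a near-dead control cannot
    distinguish a synthetic-lethal interaction from noise).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if apply_to not in ("control", "experiment", "both"):
        raise ValueError(f"unknown apply_to {apply_to!r}")
    table = table.copy()
    ctrl_cols, exp_cols = _replicate_columns(table)
    for cc, ec in zip(ctrl_cols, exp_cols):
        if apply_to == "control":
            mask = table[cc] < threshold
        elif apply_to == "experiment":
            mask = table[ec] < threshold
        else:
            mask = (table[cc] < threshold) | (table[ec] < threshold)
        table.loc[mask, [cc, ec]] = 0.0
    return table


def clamp_sizes(table: pd.DataFrame, min_value: float = 0.0,
                max_value: float = float("inf")) -> pd.DataFrame:
    """Clamp every per-replicate size into [min_value, max_value].

    Assigning a floor makes all truly lethal interactions score alike:
    residual pixels from the original pinning otherwise make one dead
    colony look 'deader' than another.  Pairs zeroed by the slow-growth
    filter stay zero (they are exclusions, not measurements).
    """
    if not (0 <= min_value < max_value):
        raise ValueError("need 0 <= min_value < max_value")
    table = table.copy()
    ctrl_cols, exp_cols = _replicate_columns(table)
    for col in ctrl_cols + exp_cols:
        nonzero = table[col] > 0
        table.loc[nonzero, col] = table.loc[nonzero, col].clip(
            lower=min_value, upper=max_value)
    return table


def linkage_exclude(table: pd.DataFrame, excluded_orfs,
                    reason: str = "linkage") -> pd.DataFrame:
    """Mark records by ORF as excluded (linkage or manual).

    Genes physically near the query locus recombine with it rarely, so
    their double mutants are systematically small and would be called
    as false aggravating hits; they are flagged and kept out of hit
    lists and cut-off estimation.
    """
    table = table.copy()
    targets = set(excluded_orfs)
    mask = table["orf"].isin(targets)
    table.loc[mask, "excluded"] = True
    table.loc[mask & (table["exclude_reason"] == ""), "exclude_reason"] = reason
    return table


def compute_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-position means, SDs, ratio, diff, per-replicate ratio
    bookkeeping columns and the paired t-test p-value.

    Replicate pairs where both sizes are zero (slow-growth exclusions
    or empty positions) are omitted from the statistics.  Positions
    with zero control mean get an undefined-ratio flag and are marked
    excluded.
    """
    table = table.copy()
    ctrl_cols, exp_cols = _replicate_columns(table)
    ctrl = table[ctrl_cols].to_numpy(float)
    exp = table[exp_cols].to_numpy(float)
    valid = ~((ctrl == 0) & (exp == 0))
    n_valid = valid.sum(axis=1)

    def masked_stat(arr, fn, fill=np.nan):
        marr = np.where(valid, arr, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = fn(marr)
        return np.where(n_valid > 0, out, fill)

    table["n_replicates"] = n_valid
    table["ctrl_mean"] = masked_stat(ctrl, lambda a: np.nanmean(a, axis=1))
    table["exp_mean"] = masked_stat(exp, lambda a: np.nanmean(a, axis=1))
    table["ctrl_sd"] = masked_stat(ctrl, lambda a: np.nanstd(a, axis=1, ddof=1)
                                   if a.shape[1] > 1 else np.zeros(a.shape[0]))
    table["exp_sd"] = masked_stat(exp, lambda a: np.nanstd(a, axis=1, ddof=1)
                                  if a.shape[1] > 1 else np.zeros(a.shape[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ratio"] = np.where(table["ctrl_mean"] > 0,
                                  table["exp_mean"] / table["ctrl_mean"],
                                  np.nan)
        rep_ratio = np.where(valid & (ctrl > 0), exp / ctrl, np.nan)
    table["diff"] = table["exp_mean"] - table["ctrl_mean"]
    for j in range(rep_ratio.shape[1]):
        table[f"ratio_{j + 1}"] = rep_ratio[:, j]

    pvals = np.full(len(table), np.nan)
    for i in range(len(table)):
        m = valid[i]
        if m.sum() >= 2:
            pvals[i] = paired_t_test(ctrl[i, m], exp[i, m])
    table["p_value"] = pvals

    undefined = ~(table["ctrl_mean"] > 0)
    table.loc[undefined, "excluded"] = True
    table.loc[undefined & (table["exclude_reason"] == ""),
              "exclude_reason"] = "undefined_ratio"
    return table


def estimate_cutoffs(ratios, central: tuple[float, float] = (0.25, 0.75),
                     min_count: int = 100) -> CutoffPair:
    """Estimate hit cut-offs from the sorted-ratio curve.

    Ratios sorted ascending against their rank form a characteristic
    curve: steep tails (interactions) flanking a shallow linear middle
    (no interaction).  An ordinary least-squares line is fitted to the
    central portion (interquartile ranks by default) and evaluated at
    the first and last rank; those extrapolated intercepts are the low
    (p) and high (q) cut-offs.
    """
    arr = np.asarray([r for r in np.ravel(ratios) if np.isfinite(r)])
    if arr.size < min_count:
        raise ValueError(
            f"need at least {min_count} finite ratios, got {arr.size}")
    arr = np.sort(arr)
    n = arr.size
    lo_i, hi_i = int(np.floor(central[0] * n)), int(np.ceil(central[1] * n))
    x = np.arange(n, dtype=float)
    xc, yc = x[lo_i:hi_i], arr[lo_i:hi_i]
    if np.allclose(yc.std(), 0.0) and np.allclose(arr.std(), 0.0):
        raise ValueError("cutoffs not estimable: ratios are degenerate")
    fit = stats.linregress(xc, yc)
    p = float(fit.intercept)  # fitted line at rank 0
    q = float(fit.intercept + fit.slope * (n - 1))  # at the last rank
    if not (0 < p < 1 < q):
        raise ValueError(
            f"cutoffs not estimable: extrapolated p={p:.4g}, q={q:.4g} "
            "violate 0 < p < 1 < q; supply manual cut-offs")
    return CutoffPair(low=p, high=q)


def call_hits(table: pd.DataFrame, cutoffs: CutoffPair,
              min_replicates: int = 3, max_p: float = 0.05) -> pd.DataFrame:
    """Apply the three hit criteria and label each position.

    A position is an **aggravating** hit iff its mean ratio is below
    the low cut-off, the per-replicate ratio is below the cut-off in at
    least ``min_replicates`` replicates, and the paired-t p-value is
    below ``max_p``; **alleviating** symmetrically above the high
    cut-off.  Excluded records are never hits.  The result carries
    ``n_below``/``n_above`` replicate counts and is sorted hits first,
    strongest (most extreme ratio) first.
    """
    table = table.copy()
    ratio_cols = sorted((c for c in table.columns
                         if c.startswith("ratio_")),
                        key=lambda s: int(s.split("_")[1]))
    if not ratio_cols:
        raise ValueError("table lacks per-replicate ratios; "
                         "run compute_scores first")
    rep_ratio = table[ratio_cols].to_numpy(float)
    with np.errstate(invalid="ignore"):
        n_below = np.nansum(rep_ratio < cutoffs.low, axis=1).astype(int)
        n_above = np.nansum(rep_ratio > cutoffs.high, axis=1).astype(int)
    table["n_below"] = n_below
    table["n_above"] = n_above
    ratio = table["ratio"].to_numpy(float)
    pv = table["p_value"].to_numpy(float)
    p_ok = np.isfinite(pv) & (pv < max_p)
    usable = ~table["excluded"].to_numpy(bool) & np.isfinite(ratio)
    aggr = usable & (ratio < cutoffs.low) & (n_below >= min_replicates) & p_ok
    alle = usable & (ratio > cutoffs.high) & (n_above >= min_replicates) & p_ok
    hit = np.full(len(table), "none", dtype=object)
    hit[aggr] = "aggravating"
    hit[alle] = "alleviating"
    table["hit"] = hit
    # sort hits first, strongest (most extreme log-ratio) first
    with np.errstate(divide="ignore", invalid="ignore"):
        strength = np.abs(np.log(np.where(ratio > 0, ratio, np.nan)))
    strength = np.where(np.isfinite(strength), strength, -1.0)
    table["_sort"] = np.where(hit != "none", 1, 0)
    table["_strength"] = strength
    table = table.sort_values(["_sort", "_strength"],
                              ascending=[False, False], kind="stable")
    return table.drop(columns=["_sort", "_strength"]).reset_index(drop=True)


def attach_descriptions(table: pd.DataFrame,
                        descriptions: dict[str, str]) -> pd.DataFrame:
    """Attach gene description text (from a feature table) per ORF."""
    table = table.copy()
    table["description"] = table["orf"].map(descriptions).fillna("")
    return table


def description_filter(table: pd.DataFrame, query: str) -> pd.DataFrame:
    """Case-insensitive substring filter on gene descriptions."""
    if "description" not in table.columns:
        raise ValueError("no descriptions loaded; call attach_descriptions")
    if query == "":
        return table
    mask = table["description"].str.contains(query, case=False, regex=False)
    return table[mask]


def export_table(table: pd.DataFrame, path: str | Path,
                 fmt: str = "tsv") -> None:
    """Export the analysis table as delimited text (tsv or csv) with a
    deterministic column order."""
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    cols = [c for c in EXPORT_COLUMNS if c in table.columns]
    out = table[cols].copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(
                lambda v: "" if not np.isfinite(v) else f"{v:.6g}")
    out.to_csv(path, sep=sep, index=False)


def read_exported(path: str | Path) -> pd.DataFrame:
    """Re-import a table written by :func:`export_table`."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, keep_default_na=False,
                       na_values=[""])


def analyze_screen(
    scored_tables: list[pd.DataFrame],
    cutoffs: CutoffPair | None = None,
    min_replicates: int = 3,
    max_p: float = 0.05,
    clamp_min: float = 0.05,
    clamp_max: float = 4.0,
    slow_growth_threshold: float | None = None,
    slow_growth_apply_to: str = "control",
    excluded_orfs=(),
) -> tuple[pd.DataFrame, CutoffPair]:
    """Full analysis pipeline over per-set scored tables.

    Builds the replicate table, applies the slow-growth filter and
    clamping, computes scores and the paired t-test, excludes listed
    ORFs, estimates cut-offs from the non-excluded ratio distribution
    when none are given, and calls hits.
    """
    table = build_replicate_table(scored_tables)
    if slow_growth_threshold is not None:
        table = slow_growth_filter(table, slow_growth_threshold,
                                   slow_growth_apply_to)
    table = clamp_sizes(table, clamp_min, clamp_max)
    table = linkage_exclude(table, excluded_orfs)
    table = compute_scores(table)
    if cutoffs is None:
        # cut-offs are compared against per-replicate ratios (hit
        # criterion 2), so they are estimated on that scale: pool the
        # per-replicate ratios of all non-excluded positions
        ratio_cols = [c for c in table.columns if c.startswith("ratio_")]
        usable = table.loc[~table["excluded"], ratio_cols].to_numpy().ravel()
        cutoffs = estimate_cutoffs(usable)
    table = call_hits(table, cutoffs, min_replicates, max_p)
    return table, cutoffs
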