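"""Site-level aggregation and cohort statistics.

Spectral counts of cluster-assigned PSMs are aggregated into a
(protein, site, cluster) x sample table. On top of that table:

* paired tumor-vs-NAT differential modification levels (log2 fold change
  of pseudocounted normalized levels, two-sided Wilcoxon signed-rank,
  Benjamini-Hochberg adjustment);
* Spearman correlation between row profiles with midrank tie handling;
* optimal-cutpoint log-rank survival: scan the distinct marker values in
  a quantile interval, keep the cutpoint maximizing the standardized
  log-rank statistic, and report both the naive p at that cutpoint and a
  permutation-adjusted p that accounts for the selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_sites",
    "differential_modification",
    "correlation_matrix",
    "logrank_statistic",
    "optimal_cutpoint_survival",
    "CutpointResult",
]

PSEUDOCOUNT = 0.5


def aggregate_sites(psms: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Spectral-count table: rows (protein, site, cluster_center), columns
    samples. ``psms`` must carry cluster assignments (``cluster_center``
    from :func:`deltascan.discovery.assign_members`).

    The grand total of the table equals the number of assigned PSMs.
    """
    required = {"protein", "site", "cluster_center", "sample_id"}
    missing = required - set(psms.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if psms.empty:
        index = pd.MultiIndex.from_arrays(
            [[], [], []], names=["protein", "site", "cluster_center"])
        return pd.DataFrame(index=index,
                            columns=list(samples) if samples is not None else [])
    table = (psms.groupby(["protein", "site", "cluster_center", "sample_id"])
             .size().unstack("sample_id", fill_value=0))
    if samples is not None:
        table = table.reindex(columns=list(samples), fill_value=0)
    table.columns.name = None
    return table


def _normalized_levels(table: pd.DataFrame, normalization: str) -> pd.DataFrame:
    """Pseudocounted modification levels.

    'protein': modified count / total counts of the protein in the sample;
    'sample': modified count / total counts in the sample;
    'none': raw counts plus pseudocount.
    """
    counts = table.astype(float)
    if normalization == "protein":
        totals = counts.groupby(level="protein").transform("sum")
    elif normalization == "sample":
        totals = pd.DataFrame(
            np.tile(counts.sum(axis=0).to_numpy(), (len(counts), 1)),
            index=counts.index, columns=counts.columns)
    elif normalization == "none":
        return counts + PSEUDOCOUNT
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return (counts + PSEUDOCOUNT) / (totals + 2 * PSEUDOCOUNT)


def differential_modification(table: pd.DataFrame,
                              pairing: list[tuple[str, str]],
                              normalization: str = "protein",
                              method: str = "wilcoxon") -> pd.DataFrame:
    """Paired tumor-vs-NAT differential statistics per table row.

    ``pairing`` lists (tumor sample, NAT sample) column pairs; a sample
    named there but absent from the table raises an error naming it.
    Rows with all-zero counts are flagged ``tested = False`` and get no
    p-value, as do degenerate single-pair designs.
    """
    for tumor, nat in pairing:
        for sample in (tumor, nat):
            if sample not in table.columns:
                raise ValueError(f"unpaired or missing sample {sample!r}")
    levels = _normalized_levels(table, normalization)
    tumor_cols = [t for t, _ in pairing]
    nat_cols = [n for _, n in pairing]
    rows = []
    for key, row in levels.iterrows():
        counts = table.loc[key]
        tumor_levels = row[tumor_cols].to_numpy(dtype=float)
        nat_levels = row[nat_cols].to_numpy(dtype=float)
        all_zero = int(counts.sum()) == 0
        log2fc = float(np.log2(tumor_levels.mean() / nat_levels.mean()))
        tested = not all_zero and len(pairing) >= 2
        p_value = np.nan
        if tested:
            diff = tumor_levels - nat_levels
            if np.allclose(diff, 0.0):
                p_value = 1.0
            elif method == "wilcoxon":
                p_value = float(sps.wilcoxon(
                    tumor_levels, nat_levels, zero_method="wilcox",
                    alternative="two-sided").pvalue)
            elif method == "paired-t":
                p_value = float(sps.ttest_rel(
                    np.log2(tumor_levels), np.log2(nat_levels)).pvalue)
            else:
                raise ValueError(f"unknown method {method!r}")
        rows.append({
            "protein": key[0], "site": key[1], "cluster_center": key[2],
            "log2_fold_change": log2fc, "p_value": p_value,
            "tested": tested, "all_zero": all_zero,
        })
    result = pd.DataFrame(rows, columns=[
        "protein", "site", "cluster_center", "log2_fold_change",
        "p_value", "tested", "all_zero"])
    result["q_value"] = np.nan
    tested_mask = result["tested"].to_numpy()
    if tested_mask.any():
        result.loc[tested_mask, "q_value"] = multipletests(
            result.loc[tested_mask, "p_value"], method="fdr_bh")[1]
    return result


def correlation_matrix(table: pd.DataFrame, rows=None) -> tuple[pd.DataFrame,
                                                                pd.DataFrame]:
    """Spearman correlation (midrank ties) between row profiles.

    Returns (rho, p) frames. Requires >= 3 samples. Correlations
    involving a constant row are reported as missing (NaN), never 0.
    """
    if table.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {table.shape[1]}")
    sub = table if rows is None else table.loc[rows]
    n = len(sub)
    labels = list(sub.index)
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    values = sub.to_numpy(dtype=float)
    constant = np.array([np.all(v == v[0]) for v in values])
    for i in range(n):
        if not constant[i]:
            rho[i, i], pval[i, i] = 1.0, 0.0
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                continue
            r, p = sps.spearmanr(values[i], values[j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    index = pd.Index(labels)
    return (pd.DataFrame(rho, index=index, columns=index),
            pd.DataFrame(pval, index=index, columns=index))


# ---------------------------------------------------------------------------
# Optimal-cutpoint log-rank survival
# ---------------------------------------------------------------------------

def logrank_statistic(time, event, group) -> float:
    """Two-group log-rank chi-square statistic (no tie correction beyond
    the standard hypergeometric variance).

    ``group`` is a boolean array marking membership of group 1. Returns
    0.0 when either group is empty or there are no events.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    o_minus_e, variance = _logrank_terms(time, event,
                                         group.reshape(-1, 1))
    if variance[0] <= 0:
        return 0.0
    return float(o_minus_e[0] ** 2 / variance[0])


def _logrank_terms(time, event, groups):
    """Vectorized log-rank O-E and variance for many candidate groupings.

    ``groups`` is (n_subjects, n_cuts) boolean. Returns (o_minus_e, var)
    arrays of length n_cuts.
    """
    order = np.argsort(time, kind="stable")
    time = time[order]
    event = event[order]
    groups = groups[order]
    n = len(time)
    _, start_idx = np.unique(time, return_index=True)
    end_idx = np.append(start_idx[1:], n)
    # prefix sums; at-risk counts are suffix sums taken from them
    group_cum = np.vstack([np.zeros((1, groups.shape[1])),
                           np.cumsum(groups, axis=0)])
    event_cum = np.concatenate([[0], np.cumsum(event)])
    ge_cum = np.vstack([np.zeros((1, groups.shape[1])),
                        np.cumsum(groups * event.reshape(-1, 1), axis=0)])
    d = event_cum[end_idx] - event_cum[start_idx]          # deaths per time
    has_deaths = d > 0
    d = d[has_deaths]
    s_idx = start_idx[has_deaths]
    e_idx = end_idx[has_deaths]
    n_total = (n - s_idx).astype(float)                    # at risk
    n1 = group_cum[n] - group_cum[s_idx]                   # at risk, group 1
    d1 = ge_cum[e_idx] - ge_cum[s_idx]                     # deaths, group 1
    frac = n1 / n_total[:, None]
    o_minus_e = np.sum(d1 - d[:, None] * frac, axis=0)
    with np.errstate(invalid="ignore"):
        var_terms = (d * (n_total - d) / np.maximum(n_total - 1, 1.0)
                     )[:, None] * frac * (1 - frac)
    variance = np.sum(var_terms, axis=0)
    return o_minus_e, variance


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    statistic: float          # chi-square of the log-rank test at the cut
    p_value: float            # naive p at the selected cutpoint
    p_adjusted: float | None  # permutation-adjusted p (None if B = 0)
    n_low: int
    n_high: int
    scanned: int              # number of admissible cutpoints


def _scan(time, event, marker, candidates):
    groups = marker.reshape(-1, 1) > candidates.reshape(1, -1)
    o_minus_e, variance = _logrank_terms(time, event, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(variance > 0, o_minus_e ** 2 / variance, 0.0)
    return chi2


def optimal_cutpoint_survival(records: pd.DataFrame,
                              scan_range: tuple[float, float] = (0.10, 0.90),
                              n_permutations: int = 0,
                              seed: int = 0) -> CutpointResult:
    """Best marker cutpoint by maximal standardized log-rank statistic.

    Scans every distinct marker value whose quantile lies inside
    ``scan_range`` (subjects with marker strictly above the cut form the
    high group). The naive p is the chi-square(1) tail at the selected
    cut, as conventionally reported after cut-off optimisation; the
    permutation-adjusted p re-runs the full scan on ``n_permutations``
    marker relabelings and counts maxima at least as large.
    """
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=bool)
    marker = np.asarray(records["marker"], dtype=float)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.all(marker == marker[0]):
        raise ValueError("marker is constant")
    lo_q, hi_q = np.quantile(marker, scan_range)
    candidates = np.unique(marker)
    candidates = candidates[(candidates >= lo_q) & (candidates <= hi_q)]
    # a cut at the maximum would leave the high group empty
    candidates = candidates[candidates < marker.max()]
    if candidates.size == 0:
        raise ValueError("no admissible cutpoint in scan range")
    chi2 = _scan(time, event, marker, candidates)
    best = int(np.argmax(chi2))
    best_stat = float(chi2[best])
    cutpoint = float(candidates[best])
    p_naive = float(sps.chi2.sf(best_stat, df=1))
    p_adjusted = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            permuted = rng.permutation(marker)
            perm_candidates = np.unique(permuted)
            perm_candidates = perm_candidates[
                (perm_candidates >= lo_q) & (perm_candidates <= hi_q)]
            perm_candidates = perm_candidates[perm_candidates < permuted.max()]
            if perm_candidates.size == 0:
                continue
            perm_max = float(np.max(_scan(time, event, permuted,
                                          perm_candidates)))
            if perm_max >= best_stat:
                hits += 1
        p_adjusted = (hits + 1) / (n_permutations + 1)
    high = marker > cutpoint
    return CutpointResult(
        cutpoint=cutpoint,
        statistic=best_stat,
        p_value=p_naive,
        p_adjusted=p_adjusted,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        scanned=int(candidates.size),
    )
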