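"""Delta-mass variant discovery: confidence filtering and peak calling.

The delta masses of filtered PSMs are partitioned into half-open 1-Da
windows anchored at integer Da. Each window is fitted with Gaussian
mixtures of 1..k_max components by EM; the Bayesian Information Criterion
selects the component count (ties go to the smaller k). A window-level
goodness-of-fit R^2 compares the fitted mixture density against the
empirical histogram; clusters from poorly fitted windows, clusters with
too few hard-assigned members, and implausibly broad clusters are
discarded. Peaks split by a window boundary are re-unified by a final
merge pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "FilterCriteria",
    "ClusterConfig",
    "DeltaMassCluster",
    "filter_psms",
    "window_deltas",
    "fit_window",
    "call_variant_peaks",
    "assign_members",
    "clusters_frame",
]


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds applied to PSM confidence columns (all inclusive)."""

    min_score: float = 300.0
    min_delta_mod_score: float = 10.0
    max_fdr_2d: float = 0.01
    delta_range: tuple[float, float] = (-150.0, 500.0)
    target_residue: str = "W"
    exclude_zero: bool = True

    def __post_init__(self):
        if not self.delta_range[0] < self.delta_range[1]:
            raise ValueError(
                f"delta_range lower must be < upper, got {self.delta_range}")


@dataclass(frozen=True)
class ClusterConfig:
    """Knobs for per-window mixture fitting and cluster retention."""

    k_max: int = 4
    min_support: int = 10
    r2_threshold: float = 0.90
    max_sd: float = 0.05          # Da; broader components are background
    merge_tolerance: float = 0.01  # Da; cross-boundary re-unification
    histogram_bin: float = 0.002   # Da; R^2 evaluation grid
    n_init: int = 10
    seed: int = 0


@dataclass
class DeltaMassCluster:
    """One fitted Gaussian component surviving the retention filters."""

    center: float
    sd: float
    weight: float
    window: int
    n_psms: int
    r_squared: float
    member_ids: tuple[str, ...] = field(default_factory=tuple)


def filter_psms(psms: pd.DataFrame, criteria: FilterCriteria | None = None
                ) -> pd.DataFrame:
    """Apply confidence, residue and delta-range filters; order preserved."""
    criteria = criteria or FilterCriteria()
    lo, hi = criteria.delta_range
    mask = (
        (psms["score"] >= criteria.min_score)
        & (psms["delta_mod_score"] >= criteria.min_delta_mod_score)
        & (psms["fdr_2d"] <= criteria.max_fdr_2d)
        & (psms["residue"] == criteria.target_residue)
        & (psms["delta_mass"] >= lo)
        & (psms["delta_mass"] <= hi)
    )
    if criteria.exclude_zero:
        mask &= psms["delta_mass"] != 0.0
    return psms.loc[mask]


def window_deltas(psms: pd.DataFrame, width: float = 1.0) -> dict[int, np.ndarray]:
    """Partition delta masses into half-open windows [k*width, (k+1)*width).

    Returns a mapping from the integer window index k to the array of
    deltas that fall in it; every delta lands in exactly one window.
    """
    deltas = np.asarray(psms["delta_mass"], dtype=float)
    if deltas.size == 0:
        return {}
    keys = np.floor(deltas / width).astype(int)
    return {int(k): deltas[keys == k] for k in np.unique(keys)}


def _mixture_r_squared(deltas: np.ndarray, gm: GaussianMixture,
                       bin_width: float) -> float:
    """Coefficient of determination of the fitted density vs. the
    empirical histogram, evaluated on occupied bins only."""
    lo = math.floor(deltas.min() / bin_width) * bin_width
    hi = math.ceil(deltas.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(deltas, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    occupied = counts > 0
    if occupied.sum() < 2:
        return 1.0
    density = np.exp(gm.score_samples(centers[occupied].reshape(-1, 1)))
    expected = density * len(deltas) * bin_width
    observed = counts[occupied].astype(float)
    ss_res = float(np.sum((observed - expected) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0 if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def _fit_best_mixture(deltas: np.ndarray, k_max: int, n_init: int,
                      seed: int) -> GaussianMixture:
    """Fit k = 1..k_max and keep the BIC minimizer (ties: smaller k)."""
    x = deltas.reshape(-1, 1)
    best, best_bic = None, np.inf
    k_cap = min(k_max, len(np.unique(deltas)))
    for k in range(1, max(k_cap, 1) + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init,
            init_params="k-means++", random_state=seed, reg_covar=1e-10,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    return best


def fit_window(deltas, k_max: int = 4, min_support: int = 10, seed: int = 0,
               n_init: int = 10, histogram_bin: float = 0.002,
               member_ids=None, window: int | None = None,
               ) -> list[DeltaMassCluster]:
    """Fit one window's deltas with a BIC-selected Gaussian mixture.

    Members are hard-assigned to components by maximum posterior
    responsibility; components with fewer than ``min_support`` members are
    discarded. Returns an empty list when the window holds fewer deltas
    than ``min_support``.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0 or deltas.size < min_support:
        return []
    if member_ids is None:
        member_ids = np.array([""] * deltas.size, dtype=object)
    else:
        member_ids = np.asarray(member_ids, dtype=object)
    gm = _fit_best_mixture(deltas, k_max, n_init, seed)
    r2 = _mixture_r_squared(deltas, gm, histogram_bin)
    labels = gm.predict(deltas.reshape(-1, 1))
    clusters = []
    for comp in range(gm.n_components):
        members = labels == comp
        n = int(members.sum())
        if n < min_support:
            continue
        center = float(gm.means_[comp, 0])
        clusters.append(DeltaMassCluster(
            center=center,
            sd=float(np.sqrt(gm.covariances_[comp, 0, 0])),
            weight=float(gm.weights_[comp]),
            window=int(math.floor(center)) if window is None else window,
            n_psms=n,
            r_squared=r2,
            member_ids=tuple(member_ids[members]),
        ))
    clusters.sort(key=lambda c: c.center)
    return clusters


def _merge_pair(a: DeltaMassCluster, b: DeltaMassCluster) -> DeltaMassCluster:
    n = a.n_psms + b.n_psms
    center = (a.center * a.n_psms + b.center * b.n_psms) / n
    # pooled second moment about the merged center
    var = (a.n_psms * (a.sd ** 2 + (a.center - center) ** 2)
           + b.n_psms * (b.sd ** 2 + (b.center - center) ** 2)) / n
    return DeltaMassCluster(
        center=center,
        sd=math.sqrt(var),
        weight=a.weight + b.weight,
        window=int(math.floor(center)),
        n_psms=n,
        r_squared=(a.r_squared * a.n_psms + b.r_squared * b.n_psms) / n,
        member_ids=a.member_ids + b.member_ids,
    )


def call_variant_peaks(psms: pd.DataFrame, config: ClusterConfig | None = None,
                       log=None) -> list[DeltaMassCluster]:
    """Fit every 1-Da window independently and return retained peaks.

    ``psms`` must already be confidence-filtered. Retention requires
    window R^2 >= ``r2_threshold``, component support >= ``min_support``
    and component sd <= ``max_sd``; adjacent-window clusters closer than
    ``merge_tolerance`` are merged. Result is sorted by center.
    """
    config = config or ClusterConfig()
    notes = log if log is not None else []
    deltas = np.asarray(psms["delta_mass"], dtype=float)
    ids = np.asarray(psms["spectrum_id"], dtype=object)
    if deltas.size == 0:
        return []
    keys = np.floor(deltas).astype(int)
    clusters: list[DeltaMassCluster] = []
    for k in sorted(np.unique(keys)):
        in_window = keys == k
        fitted = fit_window(
            deltas[in_window], k_max=config.k_max,
            min_support=config.min_support,
            seed=config.seed, n_init=config.n_init,
            histogram_bin=config.histogram_bin,
            member_ids=ids[in_window], window=int(k))
        for cluster in fitted:
            if cluster.r_squared < config.r2_threshold:
                notes.append(
                    f"window {k}: dropped cluster at {cluster.center:.4f} "
                    f"(R^2 {cluster.r_squared:.3f} < {config.r2_threshold})")
                continue
            if cluster.sd > config.max_sd:
                notes.append(
                    f"window {k}: dropped cluster at {cluster.center:.4f} "
                    f"(sd {cluster.sd:.4f} > {config.max_sd}, background)")
                continue
            clusters.append(cluster)
    clusters.sort(key=lambda c: c.center)
    merged: list[DeltaMassCluster] = []
    for cluster in clusters:
        if (merged and abs(cluster.center - merged[-1].center)
                < config.merge_tolerance):
            notes.append(
                f"merged boundary clusters at {merged[-1].center:.4f} and "
                f"{cluster.center:.4f}")
            merged[-1] = _merge_pair(merged[-1], cluster)
        else:
            merged.append(cluster)
    return merged


def assign_members(psms: pd.DataFrame, clusters: list[DeltaMassCluster]
                   ) -> pd.DataFrame:
    """Tag PSMs with the id of the cluster they belong to.

    Returns a copy of ``psms`` restricted to member spectra, with
    ``cluster_id`` (index into ``clusters``) and ``cluster_center`` columns.
    """
    by_spectrum: dict[str, int] = {}
    for idx, cluster in enumerate(clusters):
        for spectrum_id in cluster.member_ids:
            by_spectrum[spectrum_id] = idx
    member = psms["spectrum_id"].map(by_spectrum)
    out = psms.loc[member.notna()].copy()
    out["cluster_id"] = member.dropna().astype(int)
    out["cluster_center"] = out["cluster_id"].map(
        {i: c.center for i, c in enumerate(clusters)})
    return out


def clusters_frame(clusters: list[DeltaMassCluster]) -> pd.DataFrame:
    """Cluster list as the TSV-facing table."""
    return pd.DataFrame([{
        "cluster_id": i,
        "center": c.center,
        "sd": c.sd,
        "weight": c.weight,
        "window": c.window,
        "n_psms": c.n_psms,
        "r_squared": c.r_squared,
    } for i, c in enumerate(clusters)], columns=[
        "cluster_id", "center", "sd", "weight", "window", "n_psms",
        "r_squared"])
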