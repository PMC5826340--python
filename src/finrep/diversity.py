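"""Repertoire-size estimation and shared/private cluster profiling.

The total number of CDR-H3 lineages (clusters) is estimated from observed
cluster abundances by the abundance-based coverage estimator (ACE) of Chao
and Lee. Clusters are split at an abundance cutoff (default 10) into rare
and abundant groups; with ``S_rare`` rare clusters holding ``N_rare`` reads,
``F_i`` rare clusters of abundance ``i`` and sample coverage
``C_ace = 1 - F_1/N_rare``, the estimate is

    S_ace = S_abund + S_rare / C_ace + (F_1 / C_ace) * gamma^2

where ``gamma^2`` (the squared coefficient of variation of rare-cluster
abundances, floored at zero) is

    gamma^2 = max( (S_rare / C_ace) * sum_i i(i-1) F_i
                   / (N_rare (N_rare - 1)) - 1, 0 ).

When every rare cluster is a singleton the coverage is zero and ACE is
undefined; the estimator then falls back to Chao1 and flags it. The module
also profiles clusters by sharing level (the number of individuals a
cluster appears in), comparing convergent-recombination degree, abundance,
length and mutation load between private and common clusters.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cluster import Cluster
from .stats import round_half_up

__all__ = [
    "DiversityEstimate",
    "ace_estimate",
    "capture_report",
    "SharingProfile",
    "sharing_profile",
]


@dataclass
class DiversityEstimate:
    """ACE components and the estimated total cluster (lineage) count."""

    s_obs: int
    rare_cutoff: int
    s_rare: int
    s_abund: int
    n_rare: int
    f1: int
    c_ace: float
    gamma_sq: float
    s_ace: float
    estimator: str = "ace"  # "chao1" when the ACE coverage is undefined
    singleton_heavy: bool = False  # F1/S_obs > 0.5: estimate may be inflated

    @property
    def capture_fraction(self) -> float:
        return self.s_obs / self.s_ace if self.s_ace else 1.0


def ace_estimate(
    abundances: Sequence[int], rare_cutoff: int = 10
) -> DiversityEstimate:
    """Abundance-based coverage estimate of total cluster richness.

    ``abundances`` holds one positive integer per observed cluster. With no
    rare clusters the estimate equals ``S_obs`` exactly. When the rare group
    is all singletons (``C_ace = 0``, including the single-rare-singleton
    case where the variance term is undefined), the bias-corrected Chao1
    estimator is substituted and flagged.
    """
    counts = np.asarray(list(abundances), dtype=int)
    if len(counts) == 0:
        return DiversityEstimate(0, rare_cutoff, 0, 0, 0, 0, 1.0, 0.0, 0.0)
    if (counts < 1).any():
        raise ValueError("abundances must all be >= 1")
    rare = counts[counts <= rare_cutoff]
    s_obs = len(counts)
    s_rare = len(rare)
    s_abund = s_obs - s_rare
    n_rare = int(rare.sum())
    freq = Counter(rare.tolist())
    f1 = freq.get(1, 0)
    if s_rare == 0:
        return DiversityEstimate(
            s_obs, rare_cutoff, 0, s_abund, 0, 0, 1.0, 0.0, float(s_obs)
        )
    singleton_heavy = f1 / s_obs > 0.5
    if f1 == n_rare or n_rare < 2:
        # all-singleton rare group: coverage 0 (or variance undefined)
        f2 = freq.get(2, 0)
        s_chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        est = DiversityEstimate(
            s_obs,
            rare_cutoff,
            s_rare,
            s_abund,
            n_rare,
            f1,
            0.0,
            0.0,
            float(s_chao1),
            estimator="chao1",
            singleton_heavy=singleton_heavy,
        )
        warnings.warn(
            "ACE coverage undefined (all rare clusters are singletons); "
            "falling back to Chao1",
            stacklevel=2,
        )
        return est
    c_ace = 1.0 - f1 / n_rare
    ss = sum(i * (i - 1) * f for i, f in freq.items())
    gamma_sq = max(
        (s_rare / c_ace) * ss / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
    )
    s_ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq
    if singleton_heavy:
        warnings.warn(
            "more than half of observed clusters are singletons; the ACE "
            "estimate may be inflated",
            stacklevel=2,
        )
    return DiversityEstimate(
        s_obs,
        rare_cutoff,
        s_rare,
        s_abund,
        n_rare,
        f1,
        c_ace,
        gamma_sq,
        float(s_ace),
        singleton_heavy=singleton_heavy,
    )


def capture_report(
    estimates: Mapping[str, DiversityEstimate],
    combination_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate observed vs estimated cluster counts per sample.

    Capture fraction is reported in percent rounded to the nearest integer;
    when ``combination_counts`` provides the observed VDJ combination count
    for a sample, the clusters-per-combination ratio (estimated clusters /
    observed combinations, rounded to the nearest integer) is included.
    """
    rows = []
    for label, est in estimates.items():
        row: dict = {
            "sample": label,
            "s_obs": est.s_obs,
            "s_ace": est.s_ace,
            "estimator": est.estimator,
            "capture_pct": round_half_up(100.0 * est.capture_fraction),
        }
        if combination_counts and label in combination_counts:
            n_comb = combination_counts[label]
            row["clusters_per_combination"] = round_half_up(
                est.s_ace / n_comb
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SharingProfile:
    """Cluster characteristics stratified by sharing level."""

    per_level: pd.DataFrame  # level, n_clusters, codings median/mean, ...
    venn: dict[frozenset[str], int]  # individual-set -> cluster count
    comparisons: pd.DataFrame  # private-vs-common rank-sum results

    @property
    def total_clusters(self) -> int:
        return int(self.per_level["n_clusters"].sum())


def sharing_profile(
    clusters: Sequence[Cluster], alpha: float = 0.05
) -> SharingProfile:
    """Profile clusters by how many individuals share them.

    Reports, per sharing level, the cluster count and the distribution
    (median and mean) of distinct nt codings, total abundance, mean aa
    length and mean V-mutation load. Private (level 1) and common (level
    >= 2) clusters are compared by two-sided Mann-Whitney rank-sum tests
    on abundance, length and mutation load — a descriptive comparison at
    significance ``alpha``.
    """
    if not clusters:
        return SharingProfile(
            per_level=pd.DataFrame(
                columns=["sharing_level", "n_clusters"]
            ),
            venn={},
            comparisons=pd.DataFrame(),
        )
    data = pd.DataFrame(
        {
            "sharing_level": [c.sharing_level for c in clusters],
            "nt_codings": [c.nt_codings for c in clusters],
            "abundance": [c.total_abundance for c in clusters],
            "mean_aa_length": [c.mean_aa_length for c in clusters],
            "mean_v_mutations": [c.mean_v_mutations for c in clusters],
        }
    )
    per_level = (
        data.groupby("sharing_level")
        .agg(
            n_clusters=("nt_codings", "size"),
            codings_median=("nt_codings", "median"),
            codings_mean=("nt_codings", "mean"),
            abundance_median=("abundance", "median"),
            abundance_mean=("abundance", "mean"),
            aa_length_mean=("mean_aa_length", "mean"),
            v_mutations_mean=("mean_v_mutations", "mean"),
        )
        .reset_index()
    )
    venn = dict(Counter(c.individuals for c in clusters))
    private = data[data["sharing_level"] == 1]
    common = data[data["sharing_level"] >= 2]
    rows = []
    for metric in ("abundance", "mean_aa_length", "mean_v_mutations"):
        a = private[metric].dropna()
        b = common[metric].dropna()
        if len(a) and len(b):
            stat, p = mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "metric": metric,
                    "u_statistic": float(stat),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return SharingProfile(
        per_level=per_level, venn=venn, comparisons=pd.DataFrame(rows)
    )


def pairwise_overlap_from_venn(
    venn: Mapping[frozenset[str], int], a: str, b: str
) -> int:
    """Clusters containing both individuals, from the Venn region counts."""
    return sum(n for inds, n in venn.items() if a in inds and b in inds)
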