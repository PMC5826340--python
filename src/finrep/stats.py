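"""Repertoire-level summary statistics.

Operates on the per-read annotation DataFrame produced by
:func:`finrep.assign.annotate_reads` (or any frame with the same columns):
segment usage frequencies, VDJ combination tables and coverage of the
theoretical combination space, rarefaction of combination diversity,
CDR-H3 length and junction indel histograms, convergent-recombination
summaries, assignment-rate bookkeeping and cross-individual averages.

Reported assignment rates and convergence ratios are truncated (floored) to
three decimals, and cross-individual count averages round half up — the
conventions the reference study tables use; raw float values are always
kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .germline import GermlineSet

__all__ = [
    "usage_frequencies",
    "vdj_combinations",
    "CombinationTable",
    "rarefaction",
    "junction_distributions",
    "convergence_counts",
    "ConvergenceSummary",
    "assignment_rates",
    "summarize_across_individuals",
    "truncate_rate",
    "round_half_up",
]

AMBIGUOUS = "AMBIGUOUS"


def truncate_rate(numerator: int, denominator: int, digits: int = 3) -> float:
    """Ratio floored (truncated) to ``digits`` decimals, via integer math."""
    if denominator == 0:
        raise ZeroDivisionError("rate denominator is zero")
    scale = 10**digits
    return (numerator * scale // denominator) / scale


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def usage_frequencies(
    assignments: pd.DataFrame,
    germline: GermlineSet,
    segment_class: str,
) -> pd.DataFrame:
    """Per-segment read counts and frequencies for one segment class.

    Segments appear in germline (genomic) order including zero-count ones.
    D frequencies are normalised over D-identified reads only; ambiguous-D
    reads do not contribute. An empty input yields zero counts and zero
    frequencies with ``empty_input=True`` in ``DataFrame.attrs``.
    """
    col = {"V": "v_id", "D": "d_id", "J": "j_id"}[segment_class]
    segs = [s.id for s in germline.segments(segment_class)]  # type: ignore[arg-type]
    values = assignments[col].dropna() if len(assignments) else pd.Series([], dtype=object)
    values = values[values != AMBIGUOUS]
    unknown = set(values) - set(segs)
    if unknown:
        raise ValueError(f"unknown {segment_class} segment ids: {sorted(unknown)}")
    counts = values.value_counts()
    table = pd.DataFrame(
        {
            "segment_id": segs,
            "count": [int(counts.get(s, 0)) for s in segs],
        }
    )
    total = table["count"].sum()
    table["frequency"] = table["count"] / total if total else 0.0
    table.attrs["empty_input"] = bool(total == 0)
    return table


@dataclass
class CombinationTable:
    """Observed VDJ combination counts against the theoretical space."""

    counts: pd.DataFrame  # columns v_id, d_id, j_id, count
    observed: int  # distinct combinations with D identified
    theoretical: int
    total_reads: int

    @property
    def coverage(self) -> float:
        return self.observed / self.theoretical if self.theoretical else 0.0


def vdj_combinations(
    assignments: pd.DataFrame, germline: GermlineSet
) -> CombinationTable:
    """Tabulate reads per (V, D, J) triple.

    Ambiguous-D reads form a separate ``AMBIGUOUS`` stratum that is excluded
    from both the coverage numerator and the theoretical denominator.
    """
    df = assignments.dropna(subset=["v_id", "j_id"])
    if len(df):
        d = df["d_id"].fillna(AMBIGUOUS)
        counts = (
            pd.DataFrame({"v_id": df["v_id"], "d_id": d, "j_id": df["j_id"]})
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["v_id", "d_id", "j_id"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        counts = pd.DataFrame(columns=["v_id", "d_id", "j_id", "count"])
    observed = int((counts["d_id"] != AMBIGUOUS).sum()) if len(counts) else 0
    return CombinationTable(
        counts=counts,
        observed=observed,
        theoretical=germline.theoretical_combinations,
        total_reads=int(len(df)),
    )


def rarefaction(
    assignments: pd.DataFrame,
    depths: Sequence[int],
    n_resamples: int = 1000,
    seed: int = 0,
    keys: Sequence[str] = ("v_id", "d_id", "j_id"),
) -> pd.DataFrame:
    """Rarefaction of distinct VDJ-combination counts.

    For each depth, subsample reads without replacement ``n_resamples``
    times and record the number of distinct combinations; classic
    rarefaction, deterministic under a fixed seed. Returns a frame with
    depth, mean, std and the observed full-depth value in ``attrs``.
    """
    df = assignments.dropna(subset=list(keys))
    df = df[(df[list(keys)] != AMBIGUOUS).all(axis=1)]
    labels = pd.MultiIndex.from_frame(df[list(keys)])
    codes = pd.factorize(labels)[0]
    n = len(codes)
    for depth in depths:
        if depth > n:
            raise ValueError(f"depth {depth} exceeds dataset size {n}")
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    n_distinct = int(codes.max()) + 1 if n else 0
    rows = []
    for depth in depths:
        if depth == n:
            values = np.full(n_resamples, n_distinct)
        else:
            values = np.empty(n_resamples, dtype=int)
            for r in range(n_resamples):
                take = rng.choice(codes, size=depth, replace=False)
                values[r] = len(np.unique(take))
        rows.append(
            {
                "depth": depth,
                "mean": float(values.mean()),
                "std": float(values.std(ddof=1)) if n_resamples > 1 else 0.0,
                "n_resamples": n_resamples,
            }
        )
    out = pd.DataFrame(rows)
    if not out["mean"].is_monotonic_increasing:  # guaranteed in expectation
        out.attrs["monotone"] = False
    out.attrs["observed_distinct"] = n_distinct
    return out


def expected_distinct(counts: Sequence[int], depth: int) -> float:
    """Closed-form expected distinct categories in a size-``depth`` subsample.

    Hypergeometric expectation: ``sum_i 1 - C(N - n_i, k)/C(N, k)``.
    Used as the analytic reference for :func:`rarefaction`.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts)
    N = counts.sum()

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    probs = np.where(
        N - counts >= depth,
        np.exp(log_comb(N - counts, depth) - log_comb(N, depth)),
        0.0,
    )
    return float(np.sum(1.0 - probs))


def junction_distributions(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Histograms of CDR-H3 length and junction indel metrics, per isotype.

    Metrics: amino-acid length, V-D deletions (v3+d5), D-J deletions
    (d3+j5), vd_ins, dj_ins for D-identified records, and vj_ins for the
    ambiguous-D stratum. Each histogram conserves its record count.
    """
    out: dict[str, pd.DataFrame] = {}
    for isotype, sub in records.groupby("isotype"):
        metrics = {}
        aa_len = sub["cdr3_aa_length"].dropna()
        metrics["aa_length"] = aa_len.astype(int)
        with_d = sub.dropna(subset=["d5_del"])
        metrics["vd_del"] = (with_d["v3_del"] + with_d["d5_del"]).astype(int)
        metrics["dj_del"] = (with_d["d3_del"] + with_d["j5_del"]).astype(int)
        metrics["vd_ins"] = with_d["vd_ins"].dropna().astype(int)
        metrics["dj_ins"] = with_d["dj_ins"].dropna().astype(int)
        metrics["vj_ins"] = sub["vj_ins"].dropna().astype(int)
        frames = []
        for name, values in metrics.items():
            hist = values.value_counts().sort_index()
            frames.append(
                pd.DataFrame(
                    {"metric": name, "value": hist.index, "count": hist.values}
                )
            )
        out[str(isotype)] = pd.concat(frames, ignore_index=True)
    return out


@dataclass
class ConvergenceSummary:
    """Convergent recombination: one aa sequence from many nt rearrangements."""

    unique_aa: int
    one_coding: int
    multi_coding: int
    nt_multi_vj: int  # nt sequences observed with >1 distinct (V, J) pairing

    @property
    def ratio(self) -> float:
        return self.multi_coding / self.unique_aa if self.unique_aa else 0.0

    @property
    def ratio_reported(self) -> float:
        """Ratio truncated to 3 decimals (table convention)."""
        if not self.unique_aa:
            return 0.0
        return truncate_rate(self.multi_coding, self.unique_aa)


def convergence_counts(records: pd.DataFrame) -> ConvergenceSummary:
    """Count aa sequences by their number of distinct nt codings.

    Expects productive records (aa defined). Also counts nt sequences
    associated with more than one distinct (V, J) pairing.
    """
    df = records.dropna(subset=["cdr3_aa"])
    df = df[df["cdr3_aa"] != ""]
    if not len(df):
        return ConvergenceSummary(0, 0, 0, 0)
    codings = df.groupby("cdr3_aa")["cdr3_nt"].nunique()
    unique_aa = int(len(codings))
    multi = int((codings > 1).sum())
    vj = df.groupby("cdr3_nt").apply(
        lambda g: g[["v_id", "j_id"]].drop_duplicates().shape[0],
        include_groups=False,
    )
    return ConvergenceSummary(
        unique_aa=unique_aa,
        one_coding=unique_aa - multi,
        multi_coding=multi,
        nt_multi_vj=int((vj > 1).sum()),
    )


def assignment_rates(
    stage_counts: Mapping[str, int], digits: int = 3
) -> dict[str, float]:
    """VJ and VDJ assignment rates, truncated to ``digits`` decimals.

    ``stage_counts`` carries ``total`` (reads of the isotype), ``vj``
    (identifiable V+J) and optionally ``vdj`` (identifiable V+D+J). The VJ
    rate is vj/total; the VDJ rate is vdj/vj (the D-identification rate
    among VJ-identifiable reads). Zero denominators yield NaN.
    """
    total = int(stage_counts["total"])
    vj = int(stage_counts["vj"])
    out: dict[str, float] = {}
    out["vj_rate"] = (
        truncate_rate(vj, total, digits) if total else float("nan")
    )
    if "vdj" in stage_counts:
        vdj = int(stage_counts["vdj"])
        out["vdj_rate"] = (
            truncate_rate(vdj, vj, digits) if vj else float("nan")
        )
    return out


def summarize_across_individuals(
    per_individual: Mapping[str, Sequence[float]],
    count_metrics: set[str] | None = None,
) -> dict[str, float | int]:
    """Arithmetic mean per metric across individuals.

    Metrics named in ``count_metrics`` (default: all metrics whose values
    are integral) are rounded half-up to the nearest integer, matching how
    count averages are tabulated.
    """
    out: dict[str, float | int] = {}
    for metric, values in per_individual.items():
        if not len(values):
            raise ValueError(f"{metric}: no values")
        mean = float(np.mean(values))
        is_count = (
            metric in count_metrics
            if count_metrics is not None
            else all(float(v).is_integer() for v in values)
        )
        out[metric] = round_half_up(mean) if is_count else mean
    return out
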