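"""Greedy identity clustering of CDR-H3 amino-acid sequences.

Groups CDR-H3 aa sequences into clusters at >=80% identity with >=80%
length coverage, following greedy incremental (CD-HIT style) semantics:
sequences are processed longest first and join the first existing cluster
whose representative satisfies both thresholds, else found a new cluster.

Identity is the maximal number of identical aligned residues between the
pair — the score of a global alignment with free gaps, which equals the
length of their longest common subsequence — divided by the length of the
shorter sequence (CD-HIT's denominator; an "alignment-columns" mode divides
by the minimal alignment length instead). Greedy order ties are broken by
abundance then lexicographically, so the clustering is a pure function of
the input multiset, independent of input order.

An optional residue-composition screen skips pairs whose per-letter
composition already bounds the match count below the threshold; the bound
is provably conservative, so the screen can never change the result
(asserted in the test suite).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "ClusterMember",
    "Cluster",
    "cluster_cdrh3",
    "merge_clusterings",
    "pair_identity",
    "write_clstr",
    "clusters_to_frames",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = re.compile(rf"^[{_AA}X]+$")
_ALPHABET = _AA + "Xx"

_lcs_aligner = Align.PairwiseAligner()
_lcs_aligner.mode = "global"
_lcs_aligner.match_score = 1
_lcs_aligner.mismatch_score = 0
_lcs_aligner.open_gap_score = 0
_lcs_aligner.extend_gap_score = 0


def _mask_x(seq: str) -> str:
    # X never matches, including X vs X: lowercase one side of the pair
    return seq.replace("X", "x")


def lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length = max identical aligned residues."""
    if not a or not b:
        return 0
    return int(_lcs_aligner.score(a, _mask_x(b)))


def pair_identity(a: str, b: str, mode: str = "shorter") -> float:
    """Pairwise identity between two aa sequences.

    ``mode="shorter"``: identical residues / length of the shorter sequence
    (CD-HIT convention). ``mode="columns"``: identical residues / minimal
    global-alignment length, counting gaps as mismatched columns.
    """
    matches = lcs_length(a, b)
    if mode == "shorter":
        denom = min(len(a), len(b))
    elif mode == "columns":
        denom = len(a) + len(b) - matches
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    return matches / denom if denom else 0.0


@dataclass
class ClusterMember:
    """One distinct aa sequence inside a cluster."""

    aa: str
    abundance_by_individual: dict[str, int]
    nt_codings: set[str] = field(default_factory=set)
    v_mutations: list[int] = field(default_factory=list)

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance_by_individual.values())


@dataclass
class Cluster:
    """A group of CDR-H3 aa sequences within the identity/coverage thresholds.

    The representative is the founding (longest; ties by abundance then
    lexicographic) member.
    """

    representative: str
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def total_abundance(self) -> int:
        return sum(m.total_abundance for m in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(
            ind
            for m in self.members
            for ind, n in m.abundance_by_individual.items()
            if n > 0
        )

    @property
    def sharing_level(self) -> int:
        return len(self.individuals)

    @property
    def nt_codings(self) -> int:
        return len(set().union(*(m.nt_codings for m in self.members)))

    @property
    def mean_aa_length(self) -> float:
        return float(np.mean([len(m.aa) for m in self.members]))

    @property
    def mean_v_mutations(self) -> float:
        muts = [v for m in self.members for v in m.v_mutations]
        return float(np.mean(muts)) if muts else float("nan")


def _aggregate(
    records: Iterable[tuple],
) -> dict[str, ClusterMember]:
    """Collapse input records to one :class:`ClusterMember` per aa sequence.

    Records are ``(aa, abundance, individual[, nt[, v_mutations]])``.
    """
    members: dict[str, ClusterMember] = {}
    for rec in records:
        aa, abundance, individual = rec[0], int(rec[1]), rec[2]
        nt = rec[3] if len(rec) > 3 and rec[3] else None
        vmut = rec[4] if len(rec) > 4 and rec[4] is not None else None
        if not aa or not _VALID_AA.match(aa):
            raise ValueError(f"invalid amino-acid sequence {aa!r}")
        m = members.setdefault(aa, ClusterMember(aa, {}))
        m.abundance_by_individual[individual] = (
            m.abundance_by_individual.get(individual, 0) + abundance
        )
        if nt:
            m.nt_codings.add(nt)
        if vmut is not None:
            m.v_mutations.append(int(vmut))
    return members


def _composition(seq: str) -> np.ndarray:
    comp = np.zeros(len(_AA), dtype=np.int32)
    for ch in seq:
        idx = _AA.find(ch)
        if idx >= 0:  # X contributes no possible match
            comp[idx] += 1
    return comp


def cluster_cdrh3(
    records: Iterable[tuple],
    identity: float = 0.8,
    length_cov: float = 0.8,
    mode: str = "shorter",
    screen: bool = True,
) -> list[Cluster]:
    """Greedy incremental clustering of aa sequences.

    ``records`` are ``(aa, abundance, individual[, nt[, v_mutations]])``
    tuples; identical aa sequences are pooled first. Distinct sequences are
    sorted by length descending (ties: total abundance descending, then
    lexicographic) and each joins the FIRST existing cluster whose
    representative passes both the identity and the length-coverage
    threshold (shorter/longer length ratio), else founds a new cluster.
    Output order is cluster-creation order; the result is independent of
    input order.
    """
    members = _aggregate(records)
    if not members:
        return []
    order = sorted(
        members.values(), key=lambda m: (-len(m.aa), -m.total_abundance, m.aa)
    )
    clusters: list[Cluster] = []
    reps: list[str] = []
    rep_lens = np.zeros(len(order), dtype=np.int32)
    rep_comps = np.zeros((len(order), len(_AA)), dtype=np.int32)
    n_reps = 0
    for member in order:
        seq = member.aa
        n = len(seq)
        placed = False
        if n_reps:
            lens = rep_lens[:n_reps]
            # reps were inserted longest-first: every rep is >= n long
            ok = lens * length_cov <= n
            if screen:
                bound = np.minimum(
                    rep_comps[:n_reps], _composition(seq)
                ).sum(axis=1)
                if mode == "shorter":
                    ok &= bound >= identity * n
                else:
                    # matches/(la+lb-matches) >= c => matches >= c(la+lb)/(1+c)
                    ok &= bound >= identity * (lens + n) / (1.0 + identity)
            for idx in np.nonzero(ok)[0]:
                if pair_identity(reps[idx], seq, mode) >= identity:
                    clusters[idx].members.append(member)
                    placed = True
                    break
        if not placed:
            clusters.append(Cluster(representative=seq, members=[member]))
            reps.append(seq)
            rep_lens[n_reps] = n
            rep_comps[n_reps] = _composition(seq)
            n_reps += 1
    return clusters


def merge_clusterings(
    per_individual: dict[str, Iterable[tuple]],
    identity: float = 0.8,
    length_cov: float = 0.8,
    mode: str = "shorter",
) -> list[Cluster]:
    """Pool per-individual record sets and cluster jointly.

    Each record is ``(aa, abundance[, nt[, v_mutations]])``; the individual
    label is taken from the dict key. Every cluster then reports its
    sharing level (the number of individuals contributing at least one
    member).
    """
    pooled = []
    for individual, records in per_individual.items():
        for rec in records:
            aa, abundance = rec[0], rec[1]
            rest = tuple(rec[2:])
            pooled.append((aa, abundance, individual) + rest)
    return cluster_cdrh3(pooled, identity, length_cov, mode)


def clusters_to_frames(
    clusters: Sequence[Cluster],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Membership and summary DataFrames for a clustering."""
    membership = pd.DataFrame(
        [
            {
                "cluster": ci,
                "aa": m.aa,
                "individual": ind,
                "abundance": n,
                "nt_codings": len(m.nt_codings),
            }
            for ci, cl in enumerate(clusters)
            for m in cl.members
            for ind, n in sorted(m.abundance_by_individual.items())
        ]
    )
    summary = pd.DataFrame(
        [
            {
                "cluster": ci,
                "representative": cl.representative,
                "n_members": cl.n_members,
                "total_abundance": cl.total_abundance,
                "sharing_level": cl.sharing_level,
                "nt_codings": cl.nt_codings,
                "mean_aa_length": cl.mean_aa_length,
                "mean_v_mutations": cl.mean_v_mutations,
            }
            for ci, cl in enumerate(clusters)
        ]
    )
    return membership, summary


def write_clstr(clusters: Sequence[Cluster], path: str | Path) -> None:
    """Write a CD-HIT ``.clstr``-style text file for interoperability."""
    with open(path, "w") as fh:
        for ci, cl in enumerate(clusters):
            fh.write(f">Cluster {ci}\n")
            for mi, m in enumerate(cl.members):
                star = "*" if m.aa == cl.representative else ""
                fh.write(f"{mi}\t{len(m.aa)}aa, >{m.aa}... {star}\n")
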