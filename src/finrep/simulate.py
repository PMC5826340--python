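"""Ground-truthed V(D)J rearrangement simulator.

Generates synthetic germline segment sets (with planted 2nd-CYS and WGxG
anchors) and repertoires of rearranged reads with known V/D/J identity,
exonuclease trimming, non-template junction insertions, substitution noise,
isotype primers and paired overlapping mates — everything the downstream
pipeline consumes, with a truth table for every read.

Junctional decompositions are not identifiable in general: an inserted
nucleotide that happens to equal the adjacent germline base cannot be told
apart from germline, and inserted bases can counterfeit a short D remnant.
With ``require_unambiguous_junctions`` (the default) the simulator therefore
rejects-and-resamples junctions whose canonical re-analysis disagrees with
the generative truth, so that truth labels are exactly recoverable on
noise-free data. This is a ground-truthing device, not a biological claim;
disable it to emulate the full ambiguity of real rearrangements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .germline import GermlineSet, GeneSegment
from .assign import ScoringScheme, align_segment, identify_d

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "make_germline",
    "simulate_repertoire",
    "reconstruct_core",
    "write_fastq_pair",
    "write_truth_table",
    "DEFAULT_PRIMERS",
]

_NT = np.array(list("ACGT"))
_GLY = ("GGT", "GGC", "GGA", "GGG")

# synthetic isotype-specific forward primers (V-side) and constant-region stubs
DEFAULT_PRIMERS = {
    "IgM": "ACGAGTCTGGACCTGAACCA",
    "IgT": "TGCATCGTTACAGGCTCAGT",
}
DEFAULT_C_STUBS = {
    "IgM": "CATCCGATACCAGTGGTTGCTCAACGTGAGCCTGAAGTCA",
    "IgT": "GTTGACGCTTCACTAAGGCAACTGGTCCTTTGACACAGTC",
}


class SimulationConfigError(ValueError):
    """Impossible or inconsistent simulator settings."""


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _identity(a: str, b: str) -> float:
    """Positional identity over the shorter sequence (dissimilarity screen)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / n


def make_germline(
    n_v: int = 32,
    n_d: int = 6,
    n_j: int = 5,
    seed: int = 0,
    isotype: str = "IgM",
    v_length: int = 291,
    d_length_range: tuple[int, int] = (12, 18),
    j_length: int = 48,
    v_tail: int = 6,
    j_head: int = 6,
    n_v_families: int = 3,
    max_pairwise_identity: float = 0.9,
) -> GermlineSet:
    """Generate a synthetic germline set with planted anchors.

    V segments carry their 2nd-CYS codon ``v_tail`` nt before the 3' end
    (and no in-frame cysteine after it, so the planted codon is the last);
    J segments carry a WGxG motif starting ``j_head`` nt from the 5' end
    (and none earlier). Segments more than ``max_pairwise_identity``
    identical to an existing segment of the same class are resampled, so
    self-alignment is unambiguous. Defaults mirror the torafugu IgM locus
    scale: 32 V x 6 D x 5 J = 960 combinations.
    """
    if min(n_v, n_d, n_j) < 1:
        raise SimulationConfigError("segment counts must be >= 1")
    if v_length % 3 or v_tail % 3 or j_head % 3 or j_length % 3:
        raise SimulationConfigError(
            "v_length, v_tail, j_head and j_length must be multiples of 3"
        )
    if v_length < v_tail + 6:
        raise SimulationConfigError("v_length too short for anchor + tail")
    if j_length < j_head + 12:
        raise SimulationConfigError("j_length too short for WGxG + head")
    rng = np.random.default_rng(seed)

    def sample_v() -> str:
        anchor = v_length - v_tail - 3
        seq = list(_rand_nt(rng, v_length))
        seq[anchor : anchor + 3] = rng.choice(["TGT", "TGC"])
        # no in-frame cysteine after the planted one: it must be the last
        for off in range(anchor + 3, v_length - 2, 3):
            while "".join(seq[off : off + 3]) in ("TGT", "TGC"):
                seq[off] = rng.choice(_NT)
        return "".join(seq)

    def sample_j() -> str:
        seq = list(_rand_nt(rng, j_length))
        motif = "TGG" + rng.choice(_GLY) + _rand_nt(rng, 3) + rng.choice(_GLY)
        seq[j_head : j_head + 12] = motif
        # no in-frame WGxG before the planted one
        for off in range(0, j_head, 3):
            while (
                "".join(seq[off : off + 3]) == "TGG"
                and "".join(seq[off + 3 : off + 6]) in _GLY
                and "".join(seq[off + 9 : off + 12]) in _GLY
            ):
                seq[off] = rng.choice(_NT)
        return "".join(seq)

    def sample_many(n, sampler):
        out: list[str] = []
        while len(out) < n:
            cand = sampler()
            if all(_identity(cand, s) < max_pairwise_identity for s in out):
                out.append(cand)
        return out

    lo, hi = d_length_range
    v_seqs = sample_many(n_v, sample_v)
    d_seqs = sample_many(
        n_d, lambda: _rand_nt(rng, int(rng.integers(lo, hi + 1)))
    )
    j_seqs = sample_many(n_j, sample_j)

    tag = {"IgM": "m", "IgT": "t"}.get(isotype, "")
    v_segments = [
        GeneSegment(
            id=f"V{(i % n_v_families) + 1}.{i // n_v_families + 1}",
            segment_class="V",
            sequence=s,
            family=f"IGHV{(i % n_v_families) + 1}",
            isotype_scope=isotype,  # type: ignore[arg-type]
            anchor_offset=v_length - v_tail - 3,
        )
        for i, s in enumerate(v_seqs)
    ]
    d_segments = [
        GeneSegment(
            id=f"D{tag}{i + 1}", segment_class="D", sequence=s,
            isotype_scope=isotype,  # type: ignore[arg-type]
        )
        for i, s in enumerate(d_seqs)
    ]
    j_segments = [
        GeneSegment(
            id=f"J{tag}{i + 1}", segment_class="J", sequence=s,
            isotype_scope=isotype,  # type: ignore[arg-type]
            anchor_offset=j_head,
        )
        for i, s in enumerate(j_seqs)
    ]
    return GermlineSet(
        isotype=isotype,
        v_segments=v_segments,
        d_segments=d_segments,
        j_segments=j_segments,
        name=f"synthetic-{isotype}-{n_v}x{n_d}x{n_j}-seed{seed}",
    )


@dataclass
class SimulationConfig:
    """Study conditions for one simulated repertoire.

    Deletion counts at each segment end default to geometric with mean 1
    (so >80% of junctions lose 0-2 nt per side); junction insertions default
    to Poisson with mean 6, making the repertoire insertion-dominated with
    bell-shaped CDR-H3 lengths around 8-16 aa under the default germline
    geometry. All distributions are parameters, not claims.
    """

    seed: int = 0
    n_reads: int = 1000
    isotype_mix: float = 1.0  # proportion of IgM reads
    segment_usage: dict[str, float] | None = None  # id -> weight override
    usage_decay: dict[str, float] = field(
        default_factory=lambda: {"V": 0.85, "D": 0.7, "J": 0.5}
    )
    del_dist: tuple[str, dict] = ("geometric", {"mean": 1.0})
    ins_dist: tuple[str, dict] = ("poisson", {"mean": 6.0})
    error_rate: float = 0.0
    read_length: int = 250
    mate_overlap: int = 30
    primer_sequences: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PRIMERS)
    )
    c_stubs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_C_STUBS)
    )
    quality_profile: str = "constant"  # or "decay"
    q_constant: int = 37
    require_unambiguous_junctions: bool = True
    max_junction_resamples: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.isotype_mix <= 1.0:
            raise SimulationConfigError("isotype_mix must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise SimulationConfigError("error_rate must be in [0, 1]")
        if self.n_reads < 0:
            raise SimulationConfigError("n_reads must be >= 0")
        if self.quality_profile not in ("constant", "decay"):
            raise SimulationConfigError(
                f"unknown quality_profile {self.quality_profile!r}"
            )


@dataclass
class TruthRecord:
    """Generative ground truth for one simulated read."""

    read_id: str
    isotype: str
    v_id: str
    d_id: str
    j_id: str
    v3_del: int
    d5_del: int
    d3_del: int
    j5_del: int
    vd_ins: int
    dj_ins: int
    vd_ins_seq: str
    dj_ins_seq: str
    cdr3_nt: str
    cdr3_aa: str
    d_remnant_len: int
    productive: bool


def _sample_count(rng: np.random.Generator, dist: tuple[str, dict]) -> int:
    name, params = dist
    if name == "constant":
        return int(params["value"])
    if name == "geometric":
        mean = float(params["mean"])
        if mean <= 0:
            return 0
        # geometric on {0, 1, 2, ...}: number of failures before success
        return int(rng.geometric(1.0 / (1.0 + mean)) - 1)
    if name == "poisson":
        return int(rng.poisson(float(params["mean"])))
    raise SimulationConfigError(f"unknown distribution {name!r}")


def _usage_weights(
    segments: Sequence[GeneSegment],
    decay: float,
    override: dict[str, float] | None,
) -> np.ndarray:
    if override:
        w = np.array([override.get(s.id, 0.0) for s in segments], float)
        if w.sum() <= 0:
            raise SimulationConfigError("segment_usage weights sum to 0")
    else:
        w = decay ** np.arange(len(segments), dtype=float)
    return w / w.sum()


def reconstruct_core(truth: TruthRecord, germline: GermlineSet) -> str:
    """Rebuild the pre-error rearrangement from germline + truth fields."""
    v = germline.get(truth.v_id).sequence
    d = germline.get(truth.d_id).sequence
    j = germline.get(truth.j_id).sequence
    return (
        v[: len(v) - truth.v3_del]
        + truth.vd_ins_seq
        + d[truth.d5_del : len(d) - truth.d3_del]
        + truth.dj_ins_seq
        + j[truth.j5_del :]
    )


def _translate_or_empty(nt: str) -> tuple[str, bool]:
    from Bio.Seq import Seq

    if len(nt) % 3 != 0:
        return "", False
    aa = str(Seq(nt).translate())
    return aa, ("*" not in aa and "X" not in aa)


def _junction_recoverable(
    core: str,
    truth: TruthRecord,
    germline: GermlineSet,
    scoring: ScoringScheme,
    min_d_match: int,
) -> bool:
    """Does canonical re-analysis of a noise-free read reproduce the truth?"""
    v_seg = germline.get(truth.v_id)
    j_seg = germline.get(truth.j_id)
    v_hit = align_segment(core, [v_seg], scoring)
    if (
        v_hit is None
        or v_hit.mismatches
        or v_hit.gaps
        or v_hit.germline_span != (0, len(v_seg.sequence) - truth.v3_del)
        or v_hit.read_span != (0, len(v_seg.sequence) - truth.v3_del)
    ):
        return False
    j_len = len(j_seg.sequence)
    j_hit = align_segment(core, [j_seg], scoring)
    if (
        j_hit is None
        or j_hit.mismatches
        or j_hit.gaps
        or j_hit.germline_span != (truth.j5_del, j_len)
        or j_hit.read_span != (len(core) - (j_len - truth.j5_del), len(core))
    ):
        return False
    d_match = identify_d(truth.cdr3_nt, germline.d_segments, min_d_match)
    if truth.d_remnant_len >= min_d_match:
        if d_match is None or d_match.segment_id != truth.d_id:
            return False
        v_tail = len(v_seg.sequence) - (v_seg.anchor_offset + 3)
        expect_start = (v_tail - truth.v3_del) + truth.vd_ins
        return (
            d_match.cdrh3_start == expect_start
            and d_match.length == truth.d_remnant_len
            and d_match.d5_del == truth.d5_del
            and d_match.d3_del == truth.d3_del
        )
    return d_match is None


def simulate_repertoire(
    germline_by_isotype: dict[str, GermlineSet],
    config: SimulationConfig,
    scoring: ScoringScheme = ScoringScheme(),
    min_d_match: int = 4,
) -> tuple[list[tuple[str, str, str, str, str]], list[TruthRecord]]:
    """Simulate a repertoire of paired reads with per-read ground truth.

    Returns ``(pairs, truth)`` where each pair is
    ``(read_id, mate1, qual1, mate2, qual2)``. Mate 2 is reverse-complemented,
    mates always overlap (by at least ``mate_overlap`` nt), and the primer /
    constant-region stub of the read's isotype flank the rearrangement.
    """
    for iso in set(
        k for k, p in (("IgM", config.isotype_mix), ("IgT", 1 - config.isotype_mix))
        if p > 0
    ):
        if iso not in germline_by_isotype:
            raise SimulationConfigError(f"no germline set for isotype {iso}")
    rng = np.random.default_rng(config.seed)
    pairs: list[tuple[str, str, str, str, str]] = []
    truths: list[TruthRecord] = []
    weights_cache: dict[tuple[str, str], np.ndarray] = {}

    def weights(iso: str, cls: str) -> np.ndarray:
        key = (iso, cls)
        if key not in weights_cache:
            weights_cache[key] = _usage_weights(
                germline_by_isotype[iso].segments(cls),  # type: ignore[arg-type]
                config.usage_decay[cls],
                config.segment_usage,
            )
        return weights_cache[key]

    for i in range(config.n_reads):
        iso = "IgM" if rng.random() < config.isotype_mix else "IgT"
        gs = germline_by_isotype[iso]
        read_id = f"sim{i:07d}"
        v = gs.v_segments[rng.choice(len(gs.v_segments), p=weights(iso, "V"))]
        d = gs.d_segments[rng.choice(len(gs.d_segments), p=weights(iso, "D"))]
        j = gs.j_segments[rng.choice(len(gs.j_segments), p=weights(iso, "J"))]
        assert v.anchor_offset is not None and j.anchor_offset is not None
        v_tail = len(v.sequence) - (v.anchor_offset + 3)
        truth = None
        for _ in range(config.max_junction_resamples):
            while True:  # deletions exceeding the available bases: resample
                v3 = _sample_count(rng, config.del_dist)
                if v3 <= v_tail:
                    break
            while True:
                j5 = _sample_count(rng, config.del_dist)
                if j5 <= j.anchor_offset:
                    break
            while True:
                d5 = _sample_count(rng, config.del_dist)
                d3 = _sample_count(rng, config.del_dist)
                if d5 + d3 <= len(d.sequence):
                    break
            vd_seq = _rand_nt(rng, _sample_count(rng, config.ins_dist))
            dj_seq = _rand_nt(rng, _sample_count(rng, config.ins_dist))
            remnant = len(d.sequence) - d5 - d3
            cdr3_nt = (
                v.sequence[v.anchor_offset + 3 : len(v.sequence) - v3]
                + vd_seq
                + d.sequence[d5 : len(d.sequence) - d3]
                + dj_seq
                + j.sequence[j5 : j.anchor_offset]
            )
            aa, productive = _translate_or_empty(cdr3_nt)
            cand = TruthRecord(
                read_id=read_id,
                isotype=iso,
                v_id=v.id,
                d_id=d.id,
                j_id=j.id,
                v3_del=v3,
                d5_del=d5,
                d3_del=d3,
                j5_del=j5,
                vd_ins=len(vd_seq),
                dj_ins=len(dj_seq),
                vd_ins_seq=vd_seq,
                dj_ins_seq=dj_seq,
                cdr3_nt=cdr3_nt,
                cdr3_aa=aa,
                d_remnant_len=remnant,
                productive=productive,
            )
            core = reconstruct_core(cand, gs)
            if not config.require_unambiguous_junctions or _junction_recoverable(
                core, cand, gs, scoring, min_d_match
            ):
                truth = cand
                break
        if truth is None:
            raise SimulationConfigError(
                f"{read_id}: no unambiguous junction found in "
                f"{config.max_junction_resamples} resamples"
            )
        truths.append(truth)
        amplicon = (
            config.primer_sequences[iso]
            + reconstruct_core(truth, gs)
            + config.c_stubs.get(iso, "")
        )
        if config.error_rate > 0:
            arr = np.array(list(amplicon))
            hit = rng.random(len(arr)) < config.error_rate
            for pos in np.nonzero(hit)[0]:
                choices = [c for c in "ACGT" if c != arr[pos]]
                arr[pos] = choices[rng.integers(0, 3)]
            amplicon = "".join(arr)
        pairs.append(_split_mates(read_id, amplicon, config))
    return pairs, truths


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _qualities(length: int, config: SimulationConfig) -> str:
    if config.quality_profile == "constant":
        return chr(config.q_constant + 33) * length
    # linear decay from q_constant down to 2 over the mate length
    qs = np.maximum(
        2, config.q_constant - (np.arange(length) * 35) // max(length, 1)
    )
    return "".join(chr(int(q) + 33) for q in qs)


def _split_mates(
    read_id: str, amplicon: str, config: SimulationConfig
) -> tuple[str, str, str, str, str]:
    L = len(amplicon)
    len1 = len2 = min(config.read_length, L)
    if len1 + len2 - L < config.mate_overlap:
        len1 = (L + config.mate_overlap + 1) // 2
        len2 = L + config.mate_overlap - len1
    mate1 = amplicon[:len1]
    mate2 = revcomp(amplicon[L - len2 :])
    return (
        read_id,
        mate1,
        _qualities(len1, config),
        mate2,
        _qualities(len2, config),
    )


def write_fastq_pair(
    pairs: Sequence[tuple[str, str, str, str, str]],
    path1: str | Path,
    path2: str | Path,
) -> None:
    """Write mates as a Phred+33 FASTQ pair."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for read_id, m1, q1, m2, q2 in pairs:
            f1.write(f"@{read_id}/1\n{m1}\n+\n{q1}\n")
            f2.write(f"@{read_id}/2\n{m2}\n+\n{q2}\n")


def write_truth_table(truths: Sequence[TruthRecord], path: str | Path) -> None:
    """Write the truth table as TSV (one documented column per field)."""
    df = pd.DataFrame([dataclasses.asdict(t) for t in truths])
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
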