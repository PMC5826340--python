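"""Read pre-processing: isotype demultiplexing, quality trimming, pair merging.

Re-implements the semantics of the standard amplicon pre-processing chain —
primer-based isotype sorting (cutadapt-style, overlap >= 10 and error rate
<= 0.2 by default), Phred-threshold end trimming (LEADING:20 / TRAILING:20 /
MINLEN:30 semantics) and overlap merging of mate pairs (minimum overlap 10,
significance 0.05, minimum assembled length 300) — as audited, dependency-free
functions over in-memory reads.

The overlap-merge acceptance statistic is a binomial tail test of the number
of matching bases in the best ungapped overlap against a null of 50%
per-base identity: an overlap is accepted only when its identity is
significantly above one half. This is deliberately more stringent than the
uniform-random null (p = 1/4), under which even a half-mismatched overlap
would count as significant; requiring identity clearly above 50% keeps the
user-facing parameters of the assembler it replaces while rejecting
half-corrupted overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import binom

from .simulate import revcomp

__all__ = [
    "ReadPair",
    "ConsensusRead",
    "PrimerMatch",
    "demultiplex",
    "quality_trim",
    "merge_pairs",
    "preprocess_pairs",
    "read_fastq_pair",
    "StageCounts",
]

UNASSIGNED = "unassigned"


@dataclass
class ReadPair:
    id: str
    mate1: str
    qual1: list[int]
    mate2: str
    qual2: list[int]

    def __post_init__(self) -> None:
        if len(self.mate1) != len(self.qual1) or len(self.mate2) != len(
            self.qual2
        ):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class ConsensusRead:
    """A merged (consensus) read with provenance flags."""

    id: str
    sequence: str
    quals: list[int]
    isotype: str = UNASSIGNED
    overlap: int = 0
    trimmed1: int = 0  # bases quality-trimmed from mate 1
    trimmed2: int = 0


@dataclass(frozen=True)
class PrimerMatch:
    isotype: str
    start: int  # read position where the matched primer bases begin
    end: int  # read position just past the primer (cut point)
    matched_length: int
    errors: int

    @property
    def error_rate(self) -> float:
        return self.errors / self.matched_length


def _best_primer_placement(
    read: str, primer: str, min_overlap: int, max_error_rate: float
) -> tuple[int, int, int, int] | None:
    """Best qualifying placement of a 5'-end primer in ``read``.

    Considers the primer starting at any read position (fully contained) and
    partial placements where the read begins mid-primer (primer suffix of
    length >= ``min_overlap`` aligned to the read start). Returns
    ``(start, end, matched_length, errors)`` minimising errors, ties to the
    leftmost placement, or None if no placement passes the error threshold.
    """
    n, m = len(read), len(primer)
    if m >= min_overlap and read.startswith(primer):
        return (0, m, m, 0)  # exact full match at the start is unbeatable
    best: tuple[int, int, int, int] | None = None

    def consider(start: int, end: int, matched: int, errors: int) -> None:
        nonlocal best
        if matched < min_overlap or errors > int(max_error_rate * matched):
            return
        if best is None or (errors, start) < (best[3], best[0]):
            best = (start, end, matched, errors)

    # read begins inside the primer: align a primer suffix to the read start
    for k in range(min(m - 1, n), min_overlap - 1, -1):
        suffix = primer[m - k :]
        errors = sum(a != b for a, b in zip(suffix, read))
        consider(0, m - len(suffix), len(suffix), errors)
    # primer fully contained at offset s
    for s in range(0, n - m + 1):
        errors = sum(a != b for a, b in zip(primer, read[s : s + m]))
        consider(s, s + m, m, errors)
    return best


def demultiplex(
    read: str,
    primers: dict[str, str],
    min_overlap: int = 10,
    max_error_rate: float = 0.2,
) -> tuple[str, int]:
    """Assign an isotype by primer match and return ``(isotype, cut)``.

    ``cut`` is the read position just past the primer; the caller strips
    ``read[:cut]``. An unassigned read (no primer, or an exact tie between
    isotypes) returns ``(UNASSIGNED, 0)``.
    """
    if not primers or any(not p for p in primers.values()):
        raise ValueError("primers must be nonempty")
    matches: list[PrimerMatch] = []
    for isotype, primer in primers.items():
        placement = _best_primer_placement(
            read, primer, min_overlap, max_error_rate
        )
        if placement is not None:
            s, e, matched, errors = placement
            matches.append(PrimerMatch(isotype, s, e, matched, errors))
    if not matches:
        return UNASSIGNED, 0
    matches.sort(key=lambda pm: (pm.error_rate, -pm.matched_length, pm.start))
    if len(matches) > 1 and (
        matches[0].error_rate == matches[1].error_rate
        and matches[0].matched_length == matches[1].matched_length
    ):
        return UNASSIGNED, 0  # ambiguous between isotypes
    return matches[0].isotype, matches[0].end


def quality_trim(
    sequence: str,
    quals: Sequence[int],
    q_threshold: int = 20,
    min_len: int = 30,
) -> tuple[str, list[int]] | None:
    """Trim low-quality bases from both ends; None when the rest is too short.

    Bases with quality below ``q_threshold`` are removed from each end
    inward until a base at or above the threshold is met; a result shorter
    than ``min_len`` is discarded (a counted, valid outcome).
    """
    if len(sequence) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    lo, hi = 0, len(sequence)
    while lo < hi and quals[lo] < q_threshold:
        lo += 1
    while hi > lo and quals[hi - 1] < q_threshold:
        hi -= 1
    if hi - lo < min_len:
        return None
    return sequence[lo:hi], list(quals[lo:hi])


def _overlap_pvalue(matches: int, overlap: int, p_null: float = 0.5) -> float:
    """P(X >= matches) for X ~ Binomial(overlap, ``p_null``)."""
    return float(binom.sf(matches - 1, overlap, p_null))


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = 10,
    p_value: float = 0.05,
    min_assembled_len: int = 300,
) -> ConsensusRead | None:
    """Merge a mate pair over its best ungapped overlap, or None.

    Mate 2 is reverse-complemented, then every overlap length from
    ``min_overlap`` up is scored by match count minus mismatch count. The
    best overlap is accepted when its match count is significant at
    ``p_value`` under a binomial null of random matching and the assembled
    length reaches ``min_assembled_len``. Disagreeing overlap bases resolve
    to the higher-quality base (ties to mate 1).
    """
    m1, q1 = pair.mate1, pair.qual1
    m2 = revcomp(pair.mate2)
    q2 = pair.qual2[::-1]
    l1, l2 = len(m1), len(m2)
    best: tuple[int, int, int] | None = None  # (score, overlap, matches)
    for o in range(min_overlap, min(l1, l2) + 1):
        a = m1[l1 - o :]
        b = m2[:o]
        matches = sum(x == y for x, y in zip(a, b))
        score = 2 * matches - o
        if best is None or (score, o) > (best[0], best[1]):
            best = (score, o, matches)
    if best is None:
        return None
    _, overlap, matches = best
    if _overlap_pvalue(matches, overlap) > p_value:
        return None
    merged_len = l1 + l2 - overlap
    if merged_len < min_assembled_len:
        return None
    seq = list(m1[: l1 - overlap])
    quals = list(q1[: l1 - overlap])
    for k in range(overlap):
        b1, b2 = m1[l1 - overlap + k], m2[k]
        s1, s2 = q1[l1 - overlap + k], q2[k]
        if b1 == b2:
            seq.append(b1)
            quals.append(max(s1, s2))
        elif s2 > s1:
            seq.append(b2)
            quals.append(s2)
        else:
            seq.append(b1)  # ties resolve to mate 1
            quals.append(s1)
    seq.extend(m2[overlap:])
    quals.extend(q2[overlap:])
    return ConsensusRead(
        id=pair.id, sequence="".join(seq), quals=quals, overlap=overlap
    )


@dataclass
class StageCounts:
    """Per-stage read bookkeeping; categories partition the input exactly."""

    total: int = 0
    discarded_quality: int = 0
    unmerged: int = 0
    merged_unassigned: int = 0
    merged_by_isotype: dict[str, int] = field(default_factory=dict)

    @property
    def accounted(self) -> int:
        return (
            self.discarded_quality
            + self.unmerged
            + self.merged_unassigned
            + sum(self.merged_by_isotype.values())
        )


def preprocess_pairs(
    pairs: Iterable[ReadPair],
    primers: dict[str, str],
    q_threshold: int = 20,
    min_len: int = 30,
    min_overlap_merge: int = 10,
    p_value: float = 0.05,
    min_assembled_len: int = 300,
    min_overlap_primer: int = 10,
    max_error_rate: float = 0.2,
) -> tuple[list[ConsensusRead], StageCounts]:
    """Quality-trim, merge and demultiplex read pairs.

    Every input pair ends in exactly one of: discarded (quality), unmerged,
    merged-but-unassigned, or merged and isotyped; the counts report mirrors
    that partition. Unassigned merged reads are returned too (flagged) but
    are meant to be excluded downstream.
    """
    out: list[ConsensusRead] = []
    counts = StageCounts(merged_by_isotype={iso: 0 for iso in primers})
    for pair in pairs:
        counts.total += 1
        t1 = quality_trim(pair.mate1, pair.qual1, q_threshold, min_len)
        t2 = quality_trim(pair.mate2, pair.qual2, q_threshold, min_len)
        if t1 is None or t2 is None:
            counts.discarded_quality += 1
            continue
        trimmed = ReadPair(pair.id, t1[0], t1[1], t2[0], t2[1])
        merged = merge_pairs(
            trimmed, min_overlap_merge, p_value, min_assembled_len
        )
        if merged is None:
            counts.unmerged += 1
            continue
        merged.trimmed1 = len(pair.mate1) - len(t1[0])
        merged.trimmed2 = len(pair.mate2) - len(t2[0])
        isotype, cut = demultiplex(
            merged.sequence, primers, min_overlap_primer, max_error_rate
        )
        merged.isotype = isotype
        if isotype == UNASSIGNED:
            counts.merged_unassigned += 1
        else:
            merged.sequence = merged.sequence[cut:]
            merged.quals = merged.quals[cut:]
            counts.merged_by_isotype[isotype] += 1
        out.append(merged)
    assert counts.accounted == counts.total
    return out, counts


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load a Phred+33 FASTQ mate pair into :class:`ReadPair` objects."""
    from Bio import SeqIO

    def load(path):
        return [
            (r.id.rsplit("/", 1)[0], str(r.seq),
             list(r.letter_annotations["phred_quality"]))
            for r in SeqIO.parse(str(path), "fastq")
        ]

    mates1, mates2 = load(path1), load(path2)
    if len(mates1) != len(mates2):
        raise ValueError("FASTQ mate files differ in read count")
    out = []
    for (id1, s1, q1), (id2, s2, q2) in zip(mates1, mates2):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        out.append(ReadPair(id1, s1, q1, s2, q2))
    return out
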