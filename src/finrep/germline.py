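"""Germline V/D/J segment references and CDR-H3 anchor annotation.

An immunoglobulin heavy-chain variable exon is assembled from one V
(variable), one D (diversity) and one J (joining) germline segment. The
CDR-H3 loop is delimited by two conserved framework residues: the second
conserved cysteine near the 3' end of the V segment and the tryptophan of
the WGxG motif at the 5' end of the J segment. This module models segment
references, locates those anchors from sequence alone (so the toolkit works
for organisms without a curated database), and reads/writes them as FASTA.

Coordinates are 0-based, half-open throughout; reports that need 1-based
positions convert at the formatting layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSegment",
    "GermlineSet",
    "AnchorNotFoundError",
    "GermlineValidationError",
    "load_germline_set",
    "write_fasta",
    "locate_v_anchor",
    "locate_j_anchor",
]

SegmentClass = Literal["V", "D", "J"]
Isotype = Literal["IgM", "IgT", "both"]

_VALID_NT = re.compile(r"^[ACGTN]+$")

# codons read through a 3-letter window; N never matches any codon test
_CYS_CODONS = frozenset({"TGT", "TGC"})
_TRP_CODON = "TGG"
_GLY_CODONS = frozenset({"GGT", "GGC", "GGA", "GGG"})


class GermlineValidationError(ValueError):
    """A germline record or set violates a structural invariant."""


class AnchorNotFoundError(ValueError):
    """The expected conserved anchor motif is absent from a segment."""


@dataclass
class GeneSegment:
    """One germline gene segment.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"V1.13"``, ``"Dm1"``, ``"Jm2"``.
    segment_class : {"V", "D", "J"}
    sequence : str
        Nucleotides over ``ACGTN``, uppercase.
    family : str, optional
        Family label for V segments, e.g. ``"IGHV1"``.
    isotype_scope : {"IgM", "IgT", "both"}
    anchor_offset : int, optional
        0-based offset of the first base of the anchor codon: the 2nd-CYS
        codon for V segments, the W of WGxG for J segments.
    """

    id: str
    segment_class: SegmentClass
    sequence: str
    family: str | None = None
    isotype_scope: Isotype = "both"
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise GermlineValidationError("segment id must be nonempty")
        if self.segment_class not in ("V", "D", "J"):
            raise GermlineValidationError(
                f"{self.id}: segment_class must be V, D or J, got "
                f"{self.segment_class!r}"
            )
        self.sequence = self.sequence.upper()
        if not self.sequence or not _VALID_NT.match(self.sequence):
            raise GermlineValidationError(
                f"{self.id}: sequence must be nonempty over ACGTN"
            )
        if self.anchor_offset is not None:
            self._check_anchor()

    def _check_anchor(self) -> None:
        off = self.anchor_offset
        assert off is not None
        if off < 0 or off + 3 > len(self.sequence):
            raise GermlineValidationError(
                f"{self.id}: anchor_offset {off} out of bounds"
            )
        if self.segment_class == "V":
            codon = self.sequence[off : off + 3]
            if codon not in _CYS_CODONS:
                raise GermlineValidationError(
                    f"{self.id}: codon at V anchor ({codon}) is not cysteine"
                )
        elif self.segment_class == "J":
            if not _is_wgxg(self.sequence, off):
                raise GermlineValidationError(
                    f"{self.id}: no WGxG motif at J anchor offset {off}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _is_wgxg(seq: str, off: int) -> bool:
    """True when the four codons starting at ``off`` translate W, G, x, G."""
    if off < 0 or off + 12 > len(seq):
        return False
    c = [seq[off + 3 * k : off + 3 * k + 3] for k in range(4)]
    return (
        c[0] == _TRP_CODON
        and c[1] in _GLY_CODONS
        and "N" not in c[2]
        and c[3] in _GLY_CODONS
    )


def locate_v_anchor(segment: GeneSegment, reading_frame: int = 0) -> int:
    """Locate the 2nd-CYS anchor: the last in-frame TGT/TGC codon.

    The conserved cysteine closest to the segment 3' end delimits the start
    of CDR-H3. The offset is stored on the segment and returned.

    Raises
    ------
    AnchorNotFoundError
        If no in-frame cysteine codon exists.
    """
    if segment.segment_class != "V":
        raise GermlineValidationError(f"{segment.id}: not a V segment")
    if reading_frame not in (0, 1, 2):
        raise GermlineValidationError("reading_frame must be 0, 1 or 2")
    seq = segment.sequence
    found = -1
    for off in range(reading_frame, len(seq) - 2, 3):
        if seq[off : off + 3] in _CYS_CODONS:
            found = off
    if found < 0:
        raise AnchorNotFoundError(
            f"{segment.id}: no in-frame cysteine codon (frame {reading_frame})"
        )
    segment.anchor_offset = found
    return found


def locate_j_anchor(segment: GeneSegment, reading_frame: int = 0) -> int:
    """Locate the J anchor: the first in-frame TGG starting a WGxG motif."""
    if segment.segment_class != "J":
        raise GermlineValidationError(f"{segment.id}: not a J segment")
    if reading_frame not in (0, 1, 2):
        raise GermlineValidationError("reading_frame must be 0, 1 or 2")
    seq = segment.sequence
    for off in range(reading_frame, len(seq) - 11, 3):
        if _is_wgxg(seq, off):
            segment.anchor_offset = off
            return off
    raise AnchorNotFoundError(
        f"{segment.id}: no in-frame WGxG motif (frame {reading_frame})"
    )


@dataclass
class GermlineSet:
    """An ordered collection of V, D and J segments for one isotype locus."""

    isotype: str
    v_segments: list[GeneSegment] = field(default_factory=list)
    d_segments: list[GeneSegment] = field(default_factory=list)
    j_segments: list[GeneSegment] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.all_segments()]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise GermlineValidationError(
                f"duplicate segment ids: {sorted(dupes)}"
            )

    def all_segments(self) -> list[GeneSegment]:
        return [*self.v_segments, *self.d_segments, *self.j_segments]

    def segments(self, segment_class: SegmentClass) -> list[GeneSegment]:
        return {
            "V": self.v_segments,
            "D": self.d_segments,
            "J": self.j_segments,
        }[segment_class]

    def get(self, segment_id: str) -> GeneSegment:
        for s in self.all_segments():
            if s.id == segment_id:
                return s
        raise KeyError(segment_id)

    @property
    def theoretical_combinations(self) -> int:
        """|V| x |D| x |J|, the size of the combinatorial VDJ space."""
        return (
            len(self.v_segments) * len(self.d_segments) * len(self.j_segments)
        )

    def annotate_anchors(self, reading_frame: int = 0) -> None:
        """Compute anchors for every V and J segment lacking one."""
        for v in self.v_segments:
            if v.anchor_offset is None:
                locate_v_anchor(v, reading_frame)
        for j in self.j_segments:
            if j.anchor_offset is None:
                locate_j_anchor(j, reading_frame)


def prefix_class_map(
    v_prefix: str = "V", d_prefix: str = "D", j_prefix: str = "J"
) -> Callable[[str], SegmentClass]:
    """Build a record-id → segment-class rule matching on id prefixes."""

    def classify(record_id: str) -> SegmentClass:
        if record_id.startswith(v_prefix):
            return "V"
        if record_id.startswith(d_prefix):
            return "D"
        if record_id.startswith(j_prefix):
            return "J"
        raise GermlineValidationError(
            f"record id {record_id!r} matches no segment-class prefix"
        )

    return classify


def load_germline_set(
    fasta_path: str | Path,
    segment_class_map: Callable[[str], SegmentClass] | None = None,
    isotype: str = "IgM",
    name: str = "",
) -> GermlineSet:
    """Read a germline FASTA into a :class:`GermlineSet`.

    ``segment_class_map`` maps each record id to ``"V"``, ``"D"`` or ``"J"``
    (default: match on V/D/J id prefixes). Anchors are left unset; call
    :meth:`GermlineSet.annotate_anchors` afterwards.
    """
    path = Path(fasta_path)
    if segment_class_map is None:
        segment_class_map = prefix_class_map()
    segments: dict[SegmentClass, list[GeneSegment]] = {"V": [], "D": [], "J": []}
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise GermlineValidationError(
                f"{path}: duplicate record id {record.id!r}"
            )
        seen.add(record.id)
        cls = segment_class_map(record.id)
        seq = str(record.seq).upper()
        if not seq or not _VALID_NT.match(seq):
            raise GermlineValidationError(
                f"{path}: record {record.id!r} is empty or not over ACGTN"
            )
        segments[cls].append(
            GeneSegment(id=record.id, segment_class=cls, sequence=seq,
                        isotype_scope=isotype)  # type: ignore[arg-type]
        )
    if not seen:
        raise GermlineValidationError(f"{path}: no FASTA records")
    return GermlineSet(
        isotype=isotype,
        v_segments=segments["V"],
        d_segments=segments["D"],
        j_segments=segments["J"],
        name=name or path.stem,
    )


def write_fasta(
    segments: GermlineSet | Iterable[GeneSegment], fasta_path: str | Path
) -> None:
    """Write segments as FASTA, wrapped at 70 columns."""
    if isinstance(segments, GermlineSet):
        segments = segments.all_segments()
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in segments
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def translate(nt: str) -> str:
    """Translate a nucleotide string (length divisible by 3) to amino acids."""
    if len(nt) % 3 != 0:
        raise ValueError("length not divisible by 3")
    return str(Seq(nt).translate())
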