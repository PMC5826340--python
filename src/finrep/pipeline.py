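"""End-to-end pipeline orchestration: simulate → preprocess → assign → report.

A :class:`PipelineConfig` (readable from a flat ``key = value`` file)
drives the whole chain and writes every stage's TSV report into an output
directory, together with the fully-resolved configuration, so a run is
reproducible from its own outputs. Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assign as assign_mod
from . import cluster as cluster_mod
from . import diversity as diversity_mod
from . import stats as stats_mod
from .germline import GermlineSet, write_fasta, load_germline_set
from .preprocess import ReadPair, preprocess_pairs
from .simulate import (
    SimulationConfig,
    make_germline,
    simulate_repertoire,
    write_fastq_pair,
    write_truth_table,
    DEFAULT_PRIMERS,
)

logger = logging.getLogger("finrep")

__all__ = ["PipelineConfig", "PipelineConfigError", "run_pipeline"]


class PipelineConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


_BOOL = {"true": True, "false": False, "1": True, "0": False}


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str = "finrep-out"
    seed: int = 0
    log_level: str = "INFO"
    # simulator-backed input (used when no FASTQ paths are given)
    n_reads: int = 1000
    error_rate: float = 0.0
    isotype_mix: float = 0.5
    igm_segments: tuple[int, int, int] = (32, 6, 5)
    igt_segments: tuple[int, int, int] = (32, 3, 2)
    # external input (optional)
    fastq1: str = ""
    fastq2: str = ""
    germline_igm: str = ""
    germline_igt: str = ""
    # preprocess
    q_threshold: int = 20
    min_len: int = 30
    merge_min_overlap: int = 10
    merge_p_value: float = 0.05
    min_assembled_len: int = 300
    primer_min_overlap: int = 10
    primer_max_error_rate: float = 0.2
    # assignment
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 50
    min_d_match: int = 4
    # clustering / diversity
    cluster_identity: float = 0.8
    cluster_length_cov: float = 0.8
    rare_cutoff: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineConfigError(
                    f"{path}:{lineno}: expected 'key = value'"
                )
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise PipelineConfigError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _coerce(raw, known[key].type)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(raw: str, annotation) -> object:
    ann = str(annotation)
    if "tuple" in ann:
        return tuple(int(x) for x in raw.split(","))
    if ann in ("int", "<class 'int'>"):
        return int(raw)
    if ann in ("float", "<class 'float'>"):
        return float(raw)
    if ann in ("bool", "<class 'bool'>"):
        if raw.lower() not in _BOOL:
            raise PipelineConfigError(f"not a boolean: {raw!r}")
        return _BOOL[raw.lower()]
    return raw


def _build_germlines(config: PipelineConfig) -> dict[str, GermlineSet]:
    germlines: dict[str, GermlineSet] = {}
    if config.germline_igm or config.germline_igt:
        for iso, path in (
            ("IgM", config.germline_igm),
            ("IgT", config.germline_igt),
        ):
            if not path:
                continue
            if not Path(path).exists():
                raise PipelineConfigError(f"germline path not found: {path}")
            gs = load_germline_set(path, isotype=iso)
            gs.annotate_anchors()
            germlines[iso] = gs
    else:
        nv, nd, nj = config.igm_segments
        germlines["IgM"] = make_germline(
            nv, nd, nj, seed=config.seed, isotype="IgM"
        )
        nv, nd, nj = config.igt_segments
        germlines["IgT"] = make_germline(
            nv, nd, nj, seed=config.seed + 1, isotype="IgT"
        )
    return germlines


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a summary dict (stage counts, rates, diversity estimates).
    Conservation is asserted: every input read ends in exactly one
    disposition category.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_file(out / "config.resolved.txt")

    germlines = _build_germlines(config)
    for iso, gs in germlines.items():
        write_fasta(gs, out / f"germline_{iso}.fasta")
        logger.info(
            "%s germline: %d V x %d D x %d J (%d combinations)",
            iso,
            len(gs.v_segments),
            len(gs.d_segments),
            len(gs.j_segments),
            gs.theoretical_combinations,
        )

    scoring = assign_mod.ScoringScheme(
        match=config.match,
        mismatch=config.mismatch,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        min_score=config.min_score,
    )

    if config.fastq1:
        from .preprocess import read_fastq_pair

        if not Path(config.fastq1).exists() or not Path(config.fastq2).exists():
            raise PipelineConfigError("FASTQ input path not found")
        pairs = read_fastq_pair(config.fastq1, config.fastq2)
    else:
        sim = SimulationConfig(
            seed=config.seed,
            n_reads=config.n_reads,
            isotype_mix=config.isotype_mix,
            error_rate=config.error_rate,
        )
        raw_pairs, truths = simulate_repertoire(germlines, sim, scoring,
                                                config.min_d_match)
        write_fastq_pair(raw_pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
        write_truth_table(truths, out / "truth.tsv")
        pairs = [
            ReadPair(rid, m1, [ord(c) - 33 for c in q1], m2,
                     [ord(c) - 33 for c in q2])
            for rid, m1, q1, m2, q2 in raw_pairs
        ]

    consensus, counts = preprocess_pairs(
        pairs,
        DEFAULT_PRIMERS,
        q_threshold=config.q_threshold,
        min_len=config.min_len,
        min_overlap_merge=config.merge_min_overlap,
        p_value=config.merge_p_value,
        min_assembled_len=config.min_assembled_len,
        min_overlap_primer=config.primer_min_overlap,
        max_error_rate=config.primer_max_error_rate,
    )
    pd.DataFrame(
        [
            {"category": "total", "count": counts.total},
            {"category": "discarded_quality", "count": counts.discarded_quality},
            {"category": "unmerged", "count": counts.unmerged},
            {"category": "merged_unassigned", "count": counts.merged_unassigned},
            *(
                {"category": f"merged_{iso}", "count": n}
                for iso, n in sorted(counts.merged_by_isotype.items())
            ),
        ]
    ).to_csv(out / "preprocess_counts.tsv", sep="\t", index=False)
    assert counts.accounted == counts.total

    assigned_input = [
        (c.id, c.sequence, c.isotype)
        for c in consensus
        if c.isotype in germlines
    ]
    annotations = assign_mod.annotate_reads(
        assigned_input, germlines, scoring, config.min_d_match
    )
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)

    summary: dict = {"preprocess": dataclasses.asdict(counts)}
    rate_rows = []
    for iso, gs in germlines.items():
        sub = annotations[annotations["isotype"] == iso]
        if not len(sub):
            continue
        vj = sub.dropna(subset=["v_id", "j_id"])
        vdj = vj[vj["d_id"].notna() & (vj["d_id"] != assign_mod.AMBIGUOUS)]
        rates = stats_mod.assignment_rates(
            {"total": len(sub), "vj": len(vj), "vdj": len(vdj)}
        )
        rate_rows.append({"isotype": iso, "total": len(sub), "vj": len(vj),
                          "vdj": len(vdj), **rates})
        for cls in "VDJ":
            stats_mod.usage_frequencies(vj, gs, cls).to_csv(
                out / f"usage_{iso}_{cls}.tsv", sep="\t", index=False
            )
        combos = stats_mod.vdj_combinations(vj, gs)
        combos.counts.to_csv(out / f"combinations_{iso}.tsv", sep="\t",
                             index=False)
        summary[f"combinations_{iso}"] = {
            "observed": combos.observed,
            "theoretical": combos.theoretical,
            "coverage": combos.coverage,
        }
        productive = sub[sub["productive"] == True]  # noqa: E712
        conv = stats_mod.convergence_counts(productive)
        summary[f"convergence_{iso}"] = dataclasses.asdict(conv)
        records = [
            (row.cdr3_aa, 1, "sample", row.cdr3_nt, row.v_mismatches)
            for row in productive.itertuples()
            if row.cdr3_aa
        ]
        clusters = cluster_mod.cluster_cdrh3(
            records,
            identity=config.cluster_identity,
            length_cov=config.cluster_length_cov,
        )
        membership, csummary = cluster_mod.clusters_to_frames(clusters)
        membership.to_csv(out / f"clusters_{iso}_members.tsv", sep="\t",
                          index=False)
        csummary.to_csv(out / f"clusters_{iso}_summary.tsv", sep="\t",
                        index=False)
        if clusters:
            est = diversity_mod.ace_estimate(
                [c.total_abundance for c in clusters],
                rare_cutoff=config.rare_cutoff,
            )
            summary[f"diversity_{iso}"] = dataclasses.asdict(est)
            diversity_mod.capture_report(
                {iso: est}, {iso: combos.observed or 1}
            ).to_csv(out / f"diversity_{iso}.tsv", sep="\t", index=False)
    rates_df = pd.DataFrame(rate_rows)
    rates_df.to_csv(out / "assignment_rates.tsv", sep="\t",
                    float_format="%.3f", index=False)
    summary["assignment_rates"] = rate_rows
    for iso, hists in stats_mod.junction_distributions(
        annotations.dropna(subset=["v_id"])
    ).items():
        hists.to_csv(out / f"junctions_{iso}.tsv", sep="\t", index=False)
    return summary
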