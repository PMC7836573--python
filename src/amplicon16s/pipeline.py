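"""End-to-end workflows: community profiling and mock-community evaluation.

``run_profile`` executes the full chain on a FASTQ file --

    mean-Q pass filter > primer trimming > size selection > seeded
    subsampling > low-complexity masking > (optional) host screening >
    best-hit + LCA classification > rank profiles with the <0.01%
    low-abundance filter

-- and writes per-read classifications, profile tables, stage statistics
and a reproducibility manifest (parameter values, seeds, config hash,
per-stage read counts). Read counts are conserved at every stage:
input = retained + removed, exactly.

``run_mock_eval`` wraps the same chain with the mock-community defaults
(3000-read subsample) and scores the outcome at genus and species level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .classify import (
    ReadClassification,
    ReferenceDB,
    Scoring,
    build_reference_db,
    classify_batch,
    write_classifications,
)
from .preprocess import (
    PRIMERS_V1V9,
    PRIMERS_V3V4,
    PreprocessStats,
    PrimerSet,
    length_filter,
    mask_low_complexity,
    pass_filter,
    screen_host,
    subsample,
    trim_to_amplicon,
)
from .profile_eval import (
    AbundanceProfile,
    EvalReport,
    build_profile,
    filter_low_abundance,
    score_mock,
)
from .seqio import SequenceRecord, read_fasta, read_fastq
from .simulate import SimTruth
from .taxonomy import Taxonomy, load_taxonomy

__all__ = ["RunConfig", "PipelineResult", "process_reads", "run_profile", "run_mock_eval"]

_REGIONS = {"V1V9": PRIMERS_V1V9, "V3V4": PRIMERS_V3V4}


@dataclass
class RunConfig:
    """All pipeline parameters plus input/output paths.

    Defaults mirror the standard full-length workflow: V1-V9 window
    1300-1950 bp (V3-V4: 350-600 bp), mean-Q pass threshold >7, 0.01%
    abundance filter; subsampling (3000 reads for mock runs, 20,000 for
    community runs) is opt-in via ``subsample_n``.
    """

    region: str = "V1V9"
    min_mean_q: float = 7.0
    max_primer_mismatches: int = 3
    length_window: Optional[tuple[int, int]] = None  # default from region
    subsample_n: Optional[int] = None
    seed: int = 0
    abundance_threshold_pct: float = 0.01
    ranks: tuple[str, ...] = ("phylum", "family", "genus", "species")
    k: int = 13
    scoring: Scoring = field(default_factory=Scoring)
    # paths (only needed by the file-based entry points)
    input_fastq: Optional[str] = None
    reference_fasta: Optional[str] = None
    mapping_tsv: Optional[str] = None
    taxonomy_tsv: Optional[str] = None
    taxonomy_nodes: Optional[str] = None
    taxonomy_names: Optional[str] = None
    host_fasta: Optional[str] = None
    outdir: Optional[str] = None

    def primers(self) -> PrimerSet:
        if self.region not in _REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        base = _REGIONS[self.region]
        if self.length_window is not None:
            return PrimerSet(base.name, base.fwd, base.rev, tuple(self.length_window))
        return base

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    classifications: list[ReadClassification]
    summary: dict[str, int]
    profiles: dict[str, AbundanceProfile]           # filtered, per rank
    raw_profiles: dict[str, AbundanceProfile]       # unfiltered, per rank
    stats: PreprocessStats
    stage_counts: dict[str, int]
    manifest: dict


def process_reads(
    records: Sequence[SequenceRecord],
    db: ReferenceDB,
    taxonomy: Taxonomy,
    config: RunConfig,
    host_records: Optional[Sequence[SequenceRecord]] = None,
) -> PipelineResult:
    """Run the processing + classification chain on in-memory reads."""
    primers = config.primers()
    records = list(records)
    stage_counts: dict[str, int] = {"input": len(records)}

    have_quals = all(r.qual is not None for r in records)
    passed = pass_filter(records, config.min_mean_q) if have_quals else list(records)
    stage_counts["pass_q"] = len(passed)
    stage_counts["removed_low_q"] = len(records) - len(passed)

    trimmed: list[SequenceRecord] = []
    for rec in passed:
        t = trim_to_amplicon(rec, primers, config.max_primer_mismatches)
        if t is not None:
            trimmed.append(t)
    stage_counts["trimmed"] = len(trimmed)
    stage_counts["untrimmable"] = len(passed) - len(trimmed)

    sized, stats = length_filter(trimmed, primers.length_window)
    stats.n_input = len(records)
    stats.retained_fraction = (
        100.0 * len(sized) / len(records) if records else 0.0
    )
    stage_counts["size_selected"] = len(sized)
    stage_counts["removed_by_size"] = len(trimmed) - len(sized)

    if config.subsample_n is not None and config.subsample_n < len(sized):
        sized = subsample(sized, config.subsample_n, config.seed)
    stage_counts["subsampled"] = len(sized)

    masked = [mask_low_complexity(r) for r in sized]

    if host_records:
        host, non_host = screen_host(masked, host_records, k=config.k)
    else:
        host, non_host = [], masked
    stage_counts["host"] = len(host)
    stage_counts["non_host"] = len(non_host)

    classifications, summary = classify_batch(
        non_host, db, taxonomy, config.scoring
    )
    stage_counts["classified"] = sum(
        v for k, v in summary.items() if k != "unclassified"
    )
    stage_counts["unclassified"] = summary.get("unclassified", 0)

    raw_profiles = {
        rank: build_profile(classifications, taxonomy, rank)
        for rank in config.ranks
    }
    profiles = {
        rank: filter_low_abundance(p, config.abundance_threshold_pct)
        for rank, p in raw_profiles.items()
    }
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_counts": stage_counts,
        "status_counts": summary,
    }
    return PipelineResult(
        classifications, summary, profiles, raw_profiles, stats, stage_counts, manifest
    )


def _load_inputs(config: RunConfig):
    if config.input_fastq is None:
        raise ValueError("config.input_fastq is required")
    records = list(read_fastq(config.input_fastq))
    if config.taxonomy_tsv:
        taxonomy = load_taxonomy(tsv=config.taxonomy_tsv)
    elif config.taxonomy_nodes and config.taxonomy_names:
        taxonomy = load_taxonomy(
            nodes=config.taxonomy_nodes, names=config.taxonomy_names
        )
    else:
        raise ValueError("config needs taxonomy_tsv or taxonomy_nodes+names")
    db = build_reference_db(
        config.reference_fasta, config.mapping_tsv, taxonomy, k=config.k
    )
    host = list(read_fasta(config.host_fasta)) if config.host_fasta else None
    return records, db, taxonomy, host


def _write_outputs(result: PipelineResult, config: RunConfig, taxonomy: Taxonomy):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.manifest["config_hash"]
    write_classifications(
        result.classifications,
        outdir / "classifications.tsv",
        header_comment=f"config_hash={h}",
    )
    for rank, prof in result.profiles.items():
        frame = prof.to_frame(taxonomy)
        with open(outdir / f"profile_{rank}.tsv", "w") as fh:
            fh.write(f"# config_hash={h}\n")
            frame.to_csv(fh, sep="\t", index=False)
    with open(outdir / "stats.tsv", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        fh.write("\t".join(dataclasses.asdict(result.stats)) + "\n")
        fh.write(
            "\t".join(str(v) for v in dataclasses.asdict(result.stats).values())
            + "\n"
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_profile(config: RunConfig) -> PipelineResult:
    """File-based community profiling run; writes outputs when outdir is set."""
    records, db, taxonomy, host = _load_inputs(config)
    result = process_reads(records, db, taxonomy, config, host_records=host)
    if config.outdir:
        _write_outputs(result, config, taxonomy)
    return result


def run_mock_eval(
    config: RunConfig, truth: SimTruth
) -> tuple[dict[str, EvalReport], PipelineResult]:
    """Mock-community evaluation: profile run + scoring at genus and species.

    Applies the mock default of subsampling 3000 reads unless the config
    sets its own depth.
    """
    if config.subsample_n is None:
        config = dataclasses.replace(config, subsample_n=3000)
    records, db, taxonomy, host = _load_inputs(config)
    result = process_reads(records, db, taxonomy, config, host_records=host)
    reports = {
        rank: score_mock(result.classifications, truth, taxonomy, rank)
        for rank in ("genus", "species")
    }
    if config.outdir:
        _write_outputs(result, config, taxonomy)
        outdir = Path(config.outdir)
        payload = {
            rank: dataclasses.asdict(rep) for rank, rep in reports.items()
        }
        with open(outdir / "mock_eval.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return reports, result
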