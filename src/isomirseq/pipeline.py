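"""End-to-end orchestration: ingest -> classify -> quantify -> enrich.

Outputs are plain TSVs plus a JSON manifest echoing every parameter and
the package version, so a run can be reproduced exactly from the
manifest alone.  Every stage logs one structured line with input/output
record counts; outputs are byte-deterministic for identical inputs,
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ingest import ingest_fastq, write_collapsed_tsv
from .isomir import ClassifierLimits, classify_library, write_calls_tsv
from .quantify import (
    CountTable,
    arm_usage,
    build_count_table,
    isoform_diversity,
    isomir_composition,
    normalize_cpm,
    rank_cumulative,
)
from .reference import ReferenceSet, load_reference
from .rip import SelectionFilter, compute_enrichment, select_candidates
from .simulate import RIP_LIBRARIES

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ["sample_id", "fastq", "condition", "fraction"]


class SampleSheetError(ValueError):
    """Sample sheet does not match the expected schema."""


@dataclass
class PipelineConfig:
    """All thresholds and paths for a pipeline run."""

    hairpin_fasta: str = ""
    mature_fasta: str = ""
    coords_gff3: str | None = None
    sample_sheet: str = ""
    adapter: str | None = None
    min_len: int = 16
    max_len: int = 36
    min_mean_q: float = 20.0
    limits: ClassifierLimits = field(default_factory=ClassifierLimits)
    arm_min_cpm: float = 1.0
    diversity_min_reads: float = 100.0
    rip_filter: SelectionFilter = field(default_factory=SelectionFilter)
    rip_contrast: str = "RIP:IL1B-vs-control"  # or "IL1B:RIP-vs-input", ...
    rng_seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        limits = ClassifierLimits(**raw.pop("limits", {}))
        filt = SelectionFilter(**raw.pop("rip_filter", {}))
        return cls(limits=limits, rip_filter=filt, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"sample sheet missing column(s): {missing}")
    bad_cond = set(df["condition"]) - {"control", "IL1B"}
    if bad_cond:
        raise SampleSheetError(f"unknown condition value(s): {sorted(bad_cond)}")
    bad_frac = set(df["fraction"]) - {"input", "RIP"}
    if bad_frac:
        raise SampleSheetError(f"unknown fraction value(s): {sorted(bad_frac)}")
    if df["sample_id"].duplicated().any():
        raise SampleSheetError("duplicate sample_id in sample sheet")
    return df


def _write_manifest(out_dir: Path, config: PipelineConfig, stages: dict) -> None:
    manifest = {
        "package": "isomirseq",
        "version": __version__,
        "config": config.to_dict(),
        "stages": stages,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_and_classify(
    config: PipelineConfig, out_dir: Path, stages: dict
) -> tuple[ReferenceSet, CountTable]:
    ref = load_reference(config.hairpin_fasta, config.mature_fasta, config.coords_gff3)
    stages["reference"] = {
        "hairpins": len(ref.hairpins),
        "matures": len(ref.matures),
    }
    sheet = read_sample_sheet(config.sample_sheet)
    all_collapsed = []
    all_calls = []
    unassigned_total = 0
    for row in sheet.itertuples():
        fastq = Path(row.fastq)
        if not fastq.exists():
            raise FileNotFoundError(fastq)
        collapsed, report = ingest_fastq(
            fastq,
            row.sample_id,
            adapter=config.adapter,
            min_len=config.min_len,
            max_len=config.max_len,
            min_mean_q=config.min_mean_q,
        )
        calls, unassigned = classify_library(collapsed, ref, config.limits)
        unassigned_total += sum(u.count for u in unassigned)
        logger.info(
            "sample %s: reads_kept=%d distinct=%d calls=%d unassigned_reads=%d",
            row.sample_id,
            report.kept,
            len(collapsed),
            len(calls),
            sum(u.count for u in unassigned),
        )
        all_collapsed.extend(collapsed)
        all_calls.extend(calls)
    write_collapsed_tsv(all_collapsed, out_dir / "collapsed.tsv")
    write_calls_tsv(all_calls, out_dir / "calls.tsv")
    table = normalize_cpm(build_count_table(all_calls))
    stages["classify"] = {
        "collapsed_records": len(all_collapsed),
        "calls": len(all_calls),
        "unassigned_reads": unassigned_total,
        "variants": int(table.counts.shape[0]),
        "samples": table.samples,
    }
    return ref, table


def run_profile(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Expression/isomiR profiling run; returns the output directory.

    Writes collapsed reads, per-read calls, the count table (raw + CPM),
    ranked abundance with cumulative contribution, arm usage, isomiR
    composition, isoform diversity, and a manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    ref, table = _load_and_classify(config, out_dir, stages)
    table.to_tsv(out_dir / "counts.tsv", "counts")
    table.to_tsv(out_dir / "cpm.tsv", "cpm")
    rank_cumulative(table, "mature").to_csv(
        out_dir / "ranked_abundance.tsv", sep="\t", index=False, float_format="%.6g"
    )
    arm_usage(table, ref, config.arm_min_cpm).to_csv(
        out_dir / "arm_usage.tsv", sep="\t", index=False, float_format="%.6g"
    )
    per_mature, global_frac, summary = isomir_composition(table)
    per_mature.to_csv(out_dir / "composition_per_mature.tsv", sep="\t", float_format="%.6g")
    global_frac.to_frame("fraction").to_csv(
        out_dir / "composition_global.tsv", sep="\t", float_format="%.6g"
    )
    with open(out_dir / "composition_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    isoform_diversity(table, config.diversity_min_reads).to_frame().to_csv(
        out_dir / "isoform_diversity.tsv", sep="\t"
    )
    stages["quantify"] = {"summary": summary}
    _write_manifest(out_dir, config, stages)
    return out_dir


def _contrast_groups(sheet: pd.DataFrame, contrast: str) -> tuple[list[str], list[str]]:
    """Resolve a contrast spec into (samples_a, samples_b).

    ``"RIP:IL1B-vs-control"`` fixes fraction=RIP and contrasts
    conditions; ``"IL1B:RIP-vs-input"`` fixes condition=IL1B and
    contrasts fractions.  Group *a* is the reference (second) level.
    """
    fixed, _, rest = contrast.partition(":")
    level_b, _, level_a = rest.partition("-vs-")
    if not (fixed and level_a and level_b):
        raise ValueError(f"malformed contrast: {contrast!r}")
    if fixed in {"input", "RIP"}:
        sub = sheet[sheet["fraction"] == fixed]
        col = "condition"
    elif fixed in {"control", "IL1B"}:
        sub = sheet[sheet["condition"] == fixed]
        col = "fraction"
    else:
        raise ValueError(f"unknown fixed level in contrast: {fixed!r}")
    samples_a = sub.loc[sub[col] == level_a, "sample_id"].tolist()
    samples_b = sub.loc[sub[col] == level_b, "sample_id"].tolist()
    if not samples_a or not samples_b:
        raise ValueError(
            f"contrast {contrast!r} resolves to an empty group "
            f"(a={samples_a}, b={samples_b})"
        )
    return samples_a, samples_b


def run_rip(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Differential-association run; returns the output directory.

    Writes the enrichment table (M, A, p, q per variant), M-A and
    volcano plot coordinates, the selected-candidate list, and a
    manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    _, table = _load_and_classify(config, out_dir, stages)
    sheet = read_sample_sheet(config.sample_sheet)
    samples_a, samples_b = _contrast_groups(sheet, config.rip_contrast)
    records = compute_enrichment(table, samples_a, samples_b)
    records.to_csv(out_dir / "enrichment.tsv", sep="\t", float_format="%.6g")
    records[["A", "M"]].to_csv(out_dir / "ma_coordinates.tsv", sep="\t", float_format="%.6g")
    volcano = records[["M", "q"]].copy()
    volcano.to_csv(out_dir / "volcano_coordinates.tsv", sep="\t", float_format="%.6g")
    selected = select_candidates(records, config.rip_filter)
    selected.to_csv(out_dir / "selected_candidates.tsv", sep="\t", float_format="%.6g")
    stages["rip"] = {
        "contrast": config.rip_contrast,
        "samples_a": samples_a,
        "samples_b": samples_b,
        "tested_variants": int(records.shape[0]),
        "selected": int(selected.shape[0]),
    }
    logger.info(
        "rip: tested=%d selected=%d contrast=%s",
        records.shape[0],
        selected.shape[0],
        config.rip_contrast,
    )
    _write_manifest(out_dir, config, stages)
    return out_dir
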