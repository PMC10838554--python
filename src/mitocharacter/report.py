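"""Report rendering and pipeline orchestration.

Reports are TSV with a ``# key: value`` metadata header block recording the
configuration flags in force (so a reader can always tell, e.g., which
synonymous-family map produced an RSCU table). Outputs contain no
timestamps: identical configuration + inputs give byte-identical reports.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import pandas as pd

from . import __version__
from .annotation import (
    GenomeAnnotation,
    feature_length,
    parse_genbank,
    read_fasta,
    read_feature_table,
)
from .architecture import (
    architecture_summary,
    gene_order_string,
    junction_table,
    reconcile_with_reported,
    trna_table,
    validate_spacers,
)
from .codons import codon_label, compute_rscu, count_codons, incomplete_stop_genes
from .composition import region_composition_table


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration for the characterize pipeline."""

    genbank: str | None = None
    table: str | None = None
    fasta: str | None = None
    out_prefix: str = "mitocharacter"
    codon_mode: str = "pcg_concat"
    code: str = "standard"
    remnant_threshold: float = 0.5
    orient_by_strand: bool = False
    decimals: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.codon_mode not in ("pcg_concat", "whole_genome_frame1"):
            raise ConfigError(f"invalid codon_mode {self.codon_mode!r}")
        if self.code not in ("standard", "vertebrate_mitochondrial"):
            raise ConfigError(f"invalid code {self.code!r}")
        if not (0.0 < self.remnant_threshold < 1.0):
            raise ConfigError("remnant_threshold must be in (0, 1)")
        if self.decimals < 0:
            raise ConfigError("decimals must be >= 0")
        if self.genbank is None and self.table is None:
            raise ConfigError("provide a GenBank file or a feature table")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def _meta_block(config: RunConfig, extra: dict | None = None) -> str:
    flags = {k: v for k, v in asdict(config).items()
             if k not in ("out_prefix", "log_level")}  # not part of the result
    pairs = {"mitocharacter_version": __version__, **flags, **(extra or {})}
    return "".join(f"# {k}: {v}\n" for k, v in pairs.items())


def write_tsv(df: pd.DataFrame, path: str, config: RunConfig, extra: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_block(config, extra))
        df.to_csv(fh, sep="\t", index=False)


def load_inputs(config: RunConfig) -> tuple[GenomeAnnotation, str | None]:
    """Resolve annotation + optional sequence from the configured inputs."""
    if config.genbank:
        ann, seq = parse_genbank(open(config.genbank, encoding="utf-8").read())
        return ann, seq
    ann = read_feature_table(config.table)
    seq = read_fasta(config.fasta) if config.fasta else None
    return ann, seq


def annotation_echo(ann: GenomeAnnotation) -> pd.DataFrame:
    """Annotation table with recomputed length and intergenic columns."""
    gaps = {j.prev.name: j.gap for j in junction_table(ann)}
    rows = []
    for f in ann:
        rows.append({
            "gene": f.name, "ftype": f.ftype, "strand": f.strand,
            "start": f.start, "stop": f.stop,
            "length": feature_length(f, ann.length, ann.circular),
            "intergenic": gaps.get(f.name, ""),
            "anticodon": f.anticodon or "",
            "start_codon": f.start_codon or "",
            "stop_codon": f.stop_codon or "",
        })
    return pd.DataFrame(rows)


def run_characterize(config: RunConfig) -> dict[str, str]:
    """Run all stages and write the report bundle.

    Returns ``{stage: path}`` for the outputs written. Stages that need the
    nucleotide sequence (composition, codon usage) are skipped with a notice
    when only a coordinate table is available. On any stage failure, files
    already written for this run are removed and the error re-raised.
    """
    prefix = config.out_prefix
    written: dict[str, str] = {}
    notices: list[str] = []
    try:
        ann, seq = load_inputs(config)

        path = f"{prefix}.annotation.tsv"
        write_tsv(annotation_echo(ann), path, config,
                  {"genome_id": ann.genome_id, "genome_length": ann.length,
                   "circular": ann.circular})
        written["annotation"] = path

        junctions = junction_table(ann)
        summary = architecture_summary(junctions, ann, config.remnant_threshold)
        arch = summary.to_dict()
        arch["incomplete_stop_genes"] = incomplete_stop_genes(ann)
        arch["spacer_validation"] = validate_spacers(ann)
        if ann.of_type("tRNA"):
            _, arch["trna_summary"] = trna_table(ann)
        path = f"{prefix}.architecture.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(arch, fh, indent=1, sort_keys=True, default=str)
        written["architecture"] = path

        if seq is not None:
            comp = region_composition_table(seq, ann, config.orient_by_strand,
                                            config.decimals)
            path = f"{prefix}.composition.tsv"
            write_tsv(comp, path, config)
            written["composition"] = path

            counts = count_codons(ann, seq, config.codon_mode, config.code)
            rscu = compute_rscu(counts, decimals=config.decimals)
            rscu = rscu.assign(codon=[codon_label(c, f) for c, f in
                                      zip(rscu["codon"], rscu["family"])])
            path = f"{prefix}.codon_usage.tsv"
            write_tsv(rscu[["codon", "count", "rscu"]], path, config,
                      {"total_codons": counts.total})
            written["codon_usage"] = path
        else:
            notices.append("no nucleotide sequence supplied: composition and "
                           "codon-usage stages skipped")

        path = f"{prefix}.summary.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_summary(ann, summary, arch, notices))
        written["summary"] = path
        return written
    except Exception:
        for p in written.values():
            if os.path.exists(p):
                os.remove(p)
        raise


def render_summary(ann: GenomeAnnotation, summary, arch: dict, notices: list[str]) -> str:
    """One-page text summary in the conventional narrative order:
    organization, architecture, then per-class notes."""
    lines = [
        f"Genome {ann.genome_id}: {'circular' if ann.circular else 'linear'}, "
        f"{ann.length} bp, {len(ann)} annotated features "
        f"({len(ann.pcgs)} PCGs, {len(ann.of_type('tRNA'))} tRNAs, "
        f"{len(ann.of_type('rRNA'))} rRNAs, {len(ann.of_type('CR'))} control regions).",
    ]
    if summary.gene_order:
        lines.append(f"Gene order ({gene_order_string(summary.gene_order)}): "
                     f"classified as {summary.gene_order_class}.")
    lines.append(
        f"Overlaps: {summary.overlap_total} nt in {summary.overlap_pairs} pairs"
        + (f"; longest {summary.longest_overlap[1]} nt between "
           f"{summary.longest_overlap[0][0]} and {summary.longest_overlap[0][1]}."
           if summary.longest_overlap else ".")
    )
    lines.append(
        f"Intergenic spacers: {summary.spacer_total} nt in {summary.spacer_count} locations"
        + (f"; longest {summary.longest_spacer[1]} nt between "
           f"{summary.longest_spacer[0][0]} and {summary.longest_spacer[0][1]}."
           if summary.longest_spacer else ".")
    )
    if arch.get("incomplete_stop_genes"):
        genes = ", ".join(sorted(arch["incomplete_stop_genes"]))
        lines.append(f"Incomplete stop codons (completed by polyadenylation): {genes}.")
    if arch.get("trna_summary"):
        t = arch["trna_summary"]
        lines.append(
            f"tRNAs: {t['count']} totalling {t['total_length']} bp "
            f"({100 * t['fraction_of_genome']:.2f}% of the genome); "
            f"longest {'/'.join(t['longest'])} ({t['longest_length']} bp), "
            f"shortest {'/'.join(t['shortest'])} ({t['shortest_length']} bp)."
        )
    for n in notices:
        lines.append(f"NOTE: {n}")
    return "\n".join(lines) + "\n"


def reconciliation_report(ann: GenomeAnnotation, reported: pd.DataFrame) -> pd.DataFrame:
    """Convenience re-export: recomputed-vs-printed reconciliation."""
    return reconcile_with_reported(ann, reported)
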