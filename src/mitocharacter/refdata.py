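"""Bundled reference data.

The package ships the published annotation, composition and codon-usage
tables of the *Pterorhinus chinensis* (Black-throated Laughingthrush)
complete mitogenome, GenBank accession MT457820 — a 17,827 bp circular
genome with a duplicated control region. These tables serve as fixtures for
replication tests and as worked-example input; the raw sequence itself is
not bundled and is never required.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .annotation import GenomeAnnotation, read_feature_table

_DATA = "mitocharacter.data"


def _path(name: str):
    return resources.files(_DATA).joinpath(name)


def reference_annotation() -> GenomeAnnotation:
    """The published MT457820 feature table (39 features, 17,827 bp, circular)."""
    with resources.as_file(_path("mt457820_annotation.tsv")) as p:
        return read_feature_table(p)


def reference_annotation_table() -> pd.DataFrame:
    """The published annotation table verbatim, including the printed
    (advisory) length and intergenic columns."""
    text = _path("mt457820_annotation.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    for col in ("start", "stop", "length", "intergenic"):
        df[col] = df[col].astype(int)
    return df


def reference_composition() -> pd.DataFrame:
    """The published per-region composition/skew table, cells as printed."""
    text = _path("mt457820_composition.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def reference_codon_usage() -> pd.DataFrame:
    """The published 64-row codon count / RSCU table, cells as printed."""
    text = _path("mt457820_codon_usage.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def canonical_anticodons() -> dict[str, str]:
    """Canonical vertebrate-mitochondrial tRNA anticodons (DNA alphabet)."""
    text = _path("vertmito_anticodons.tsv").read_text()
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("trna\t"):
            continue
        trna, anticodon = line.split("\t")
        out[trna] = anticodon
    return out
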