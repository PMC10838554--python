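"""Supermatrix preparation from multiple annotated mitogenomes, plus a light
p-distance / neighbor-joining preview tree.

The 13 protein-coding genes are concatenated in a fixed order with each gene
block padded at its 3' end to the longest copy; no alignment is performed
(alignment, model selection and Bayesian/ML inference are deliberately left
to external tools — this module only prepares their input and offers a
quick-look NJ tree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .annotation import GenomeAnnotation, extract_feature_sequence

#: fixed concatenation order of the 13 PCGs
PCG_ORDER = (
    "nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
    "nad3", "nad4l", "nad4", "nad5", "cob", "nad6",
)

GAP = "-"


@dataclass
class Supermatrix:
    """Concatenated, gap-padded 13-PCG matrix with a partition table."""

    taxa: list[str]
    sequences: list[str]
    partitions: list[tuple[str, int, int]]  # (gene, 1-based start, 1-based end)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("supermatrix rows differ in length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for taxon, seq in zip(self.taxa, self.sequences):
                fh.write(f">{taxon}\n{seq}\n")

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP (full names, space-separated)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.taxa)} {self.length}\n")
            for taxon, seq in zip(self.taxa, self.sequences):
                fh.write(f"{taxon.replace(' ', '_')}  {seq}\n")

    def partition_text(self) -> str:
        """RAxML-style partition block, e.g. ``DNA, nad1 = 1-978``."""
        return "\n".join(f"DNA, {g} = {a}-{b}" for g, a, b in self.partitions) + "\n"


def concatenate_pcgs(
    genomes: list[tuple[GenomeAnnotation, str]],
    gene_order: tuple[str, ...] = PCG_ORDER,
) -> Supermatrix:
    """Build a 13-PCG supermatrix from ``(annotation, sequence)`` pairs.

    Every genome must annotate all genes in ``gene_order``; per-gene
    sequences are strand-oriented (L-strand genes reverse-complemented) and
    padded with gaps at the 3' end to the longest copy of that gene.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    per_gene: dict[str, list[str]] = {g: [] for g in gene_order}
    taxa = []
    for ann, seq in genomes:
        taxa.append(ann.genome_id)
        by_name = {f.name: f for f in ann}
        for gene in gene_order:
            if gene not in by_name:
                raise ValueError(f"taxon {ann.genome_id!r} is missing PCG {gene!r}")
            per_gene[gene].append(extract_feature_sequence(seq, by_name[gene], ann.circular))

    partitions: list[tuple[str, int, int]] = []
    blocks: list[list[str]] = []
    offset = 0
    for gene in gene_order:
        width = max(len(s) for s in per_gene[gene])
        blocks.append([s.ljust(width, GAP) for s in per_gene[gene]])
        partitions.append((gene, offset + 1, offset + width))
        offset += width
    sequences = ["".join(parts) for parts in zip(*blocks)]
    return Supermatrix(taxa, sequences, partitions)


def p_distance_matrix(sm: Supermatrix) -> pd.DataFrame:
    """Pairwise p-distances (proportion of differing sites among sites where
    both rows are ungapped). Pairs with zero comparable sites get NaN."""
    if len(sm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in sm.sequences]
    gap = GAP.encode()
    n = len(arrs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrs[i] != gap) & (arrs[j] != gap)
            total = int(ok.sum())
            d = float((arrs[i][ok] != arrs[j][ok]).sum()) / total if total else np.nan
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=sm.taxa, columns=sm.taxa)


def neighbor_joining(dm: pd.DataFrame | np.ndarray, taxa: list[str] | None = None) -> str:
    """Neighbor-joining preview tree; returns newick text.

    The input must be a symmetric, hollow distance matrix (a labelled
    DataFrame from :func:`p_distance_matrix`, or an array plus ``taxa``).
    Negative branch lengths are clamped to zero with a warning. Taxa are
    processed in label order, making ties deterministic.
    """
    if isinstance(dm, pd.DataFrame):
        taxa = list(dm.index)
        data = dm.to_numpy(dtype=float)
    else:
        data = np.asarray(dm, dtype=float)
        if taxa is None:
            raise ValueError("taxa labels required with a bare array")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    if np.isnan(data).any():
        raise ValueError("distance matrix contains missing values")
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")
    order = np.argsort(np.asarray(taxa, dtype=object))
    data = data[np.ix_(order, order)]
    labels = [taxa[i] for i in order]
    tree = _skbio_nj(DistanceMatrix(data, labels), neg_as_zero=False)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", UserWarning, stacklevel=2)
    return str(tree).strip()
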