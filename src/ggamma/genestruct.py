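"""Projection of CDS exon boundaries onto protein coordinates.

Gγ genes of structural types A and B carry four exons (three introns) in
the coding region; type C genes carry a fifth exon encoding most of the
cysteine-rich tail.  Projecting each intron position onto the encoded
protein lets gene structures be compared across genes and species: a
boundary is reported as the 1-based residue index of the codon containing
the split together with the codon phase (0, 1 or 2 nucleotides of that
codon completed 5' of the boundary).  The (residue, phase) pair makes the
projection exactly invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .seq_io import GAP, AlignedBlock, GeneModel


@dataclass(frozen=True)
class BoundaryProjection:
    """Exon boundaries of one gene in protein coordinates."""

    gene_id: str
    n_exons: int
    n_introns: int
    boundaries: tuple[tuple[int, int], ...]   # (residue_index, phase)
    protein_length: int
    includes_stop: bool


def project_boundaries(model: GeneModel) -> BoundaryProjection:
    """Project each internal exon boundary onto the protein.

    For cumulative CDS length ``c`` after an exon: residue = ceil(c/3),
    phase = c mod 3.  Phase 0 means the boundary falls between codons.
    """
    boundaries = []
    c = 0
    lengths = model.exon_lengths
    for length in lengths[:-1]:
        c += length
        boundaries.append((math.ceil(c / 3), c % 3))
    protein_length = model.cds_length // 3 - (1 if model.includes_stop else 0)
    return BoundaryProjection(
        gene_id=model.gene_id,
        n_exons=len(lengths),
        n_introns=len(lengths) - 1,
        boundaries=tuple(boundaries),
        protein_length=protein_length,
        includes_stop=model.includes_stop,
    )


def exon_lengths_from_projection(proj: BoundaryProjection) -> list[int]:
    """Invert a projection back to exon nucleotide lengths."""
    total = 3 * (proj.protein_length + (1 if proj.includes_stop else 0))
    cuts = []
    for residue, phase in proj.boundaries:
        c = 3 * residue if phase == 0 else 3 * (residue - 1) + phase
        cuts.append(c)
    edges = [0] + cuts + [total]
    return [b - a for a, b in zip(edges, edges[1:])]


def _residue_to_column(row: str, residue_index: int) -> int:
    """1-based alignment column of the residue_index-th non-gap character."""
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == residue_index:
                return col
    raise ValueError(
        f"residue index {residue_index} beyond row length ({count} residues)"
    )


def compare_boundaries(
    projections: Sequence[BoundaryProjection], alignment: AlignedBlock,
) -> pd.DataFrame:
    """Map every projected boundary to an alignment column.

    Each projection's gene_id must name a row of the alignment (the encoded
    protein).  Boundaries landing in the same column across genes mark a
    shared (homologous) intron position.  Returns a table with columns
    gene_id, boundary_ordinal, residue_index, phase, alignment_column.
    """
    rows = []
    for proj in projections:
        aligned = alignment.row(proj.gene_id)
        for ordinal, (residue, phase) in enumerate(proj.boundaries, start=1):
            col = _residue_to_column(aligned, residue)
            rows.append({
                "gene_id": proj.gene_id,
                "boundary_ordinal": ordinal,
                "residue_index": residue,
                "phase": phase,
                "alignment_column": col,
            })
    return pd.DataFrame(
        rows,
        columns=["gene_id", "boundary_ordinal", "residue_index", "phase",
                 "alignment_column"],
    )


def shared_boundary_columns(table: pd.DataFrame) -> list[int]:
    """Alignment columns hit by a boundary in every gene of the table."""
    if table.empty:
        return []
    per_gene = table.groupby("gene_id")["alignment_column"].apply(set)
    shared = set.intersection(*per_gene.tolist())
    return sorted(shared)
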