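"""Readers and writers for the text formats the pipeline touches.

Protein FASTA (optionally aligned), exon coordinate tables (TSV or a GFF3
subset), Newick trees and TSV reports.  This module carries no science: it
parses, validates and round-trips.  Conventions: gene-model coordinates are
1-based inclusive on the coding strand (GFF style); protein positions are
1-based; positions counted from the C-terminus are negative (-1 = last
residue).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in a ProteinRecord ('X' = unknown, never matches anything)
VALID_RESIDUES = AA20 | {"X"}
GAP = "-"

_ATTR_RE = re.compile(r"\[(\w+)=([^\]]*)\]")


@dataclass(frozen=True)
class ProteinRecord:
    """One Gγ candidate protein.

    ``species`` is a binomial ("Arabidopsis thaliana") and ``group`` a
    free-text taxon label ("eudicot", "monocot", ...); both may be empty.
    """

    id: str
    seq: str
    species: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if GAP in self.seq:
            raise ValueError(f"{self.id}: sequence contains gap characters")
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"{self.id}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass(frozen=True)
class AlignedBlock:
    """A gapped alignment: rows of equal length over residues plus '-'."""

    records: tuple[tuple[str, str], ...]
    ncols: int

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "AlignedBlock":
        rows = tuple((rid, s.upper()) for rid, s in rows)
        if not rows:
            raise ValueError("alignment has no rows")
        ncols = len(rows[0][1])
        for rid, s in rows:
            if len(s) != ncols:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has {len(s)} columns, "
                    f"expected {ncols}"
                )
        seen: set[str] = set()
        for rid, _ in rows:
            if rid in seen:
                raise ValueError(f"duplicate id in alignment: {rid!r}")
            seen.add(rid)
        return cls(records=rows, ncols=ncols)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")


@dataclass(frozen=True)
class GeneModel:
    """Ordered CDS exon spans of one gene, 1-based inclusive, coding strand.

    ``includes_stop`` states whether the final codon of the CDS is the stop
    codon (the default for annotated CDS features).
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    includes_stop: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(
                    f"{self.gene_id}: invalid exon span ({start}, {end})"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons overlap or are unordered at "
                    f"({start}, {end})"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: total CDS length {self.cds_length} nt is not "
                "divisible by 3"
            )

    @property
    def exon_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.exons]

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


def _parse_header(description: str) -> tuple[str, str, str]:
    rid = description.split()[0]
    attrs = dict(_ATTR_RE.findall(description))
    return rid, attrs.get("species", ""), attrs.get("group", "")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    Headers are parsed as ``id [species=...] [group=...]`` with the bracketed
    attributes optional.  Sequences are uppercased and a single terminal '*'
    (stop) is stripped.  Raises on an empty file, duplicate ids, or residues
    outside the 20 amino acids plus 'X'.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"{path}: no FASTA entries found")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in entries:
        rid, species, group = _parse_header(entry.description)
        if rid in seen:
            raise ValueError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinRecord(id=rid, seq=seq, species=species, group=group))
    return records


def read_alignment(path: str | Path) -> AlignedBlock:
    """Read an aligned protein FASTA; all rows must have equal length."""
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"{path}: no FASTA entries found")
    rows = []
    for entry in entries:
        rid, _, _ = _parse_header(entry.description)
        rows.append((rid, str(entry.seq).upper()))
    block = AlignedBlock.from_rows(rows)
    for rid, s in block.records:
        for pos, ch in enumerate(s, start=1):
            if ch != GAP and ch not in VALID_RESIDUES:
                raise ValueError(f"{rid}: invalid character {ch!r} at column {pos}")
    return block


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" [species={rec.species}]"
            if rec.group:
                header += f" [group={rec.group}]"
            fh.write(f">{header}\n{rec.seq}\n")


def write_alignment(block: AlignedBlock, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, s in block.records:
            fh.write(f">{rid}\n{s}\n")


def _gene_models_from_frame(frame: pd.DataFrame) -> list[GeneModel]:
    required = {"gene_id", "exon_start", "exon_end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"exon table missing columns: {sorted(missing)}")
    models = []
    for gene_id, sub in frame.groupby("gene_id", sort=False):
        exons = sorted(
            (int(s), int(e))
            for s, e in zip(sub["exon_start"], sub["exon_end"])
        )
        if "includes_stop" in sub.columns:
            includes_stop = bool(sub["includes_stop"].iloc[0])
        else:
            includes_stop = True
        models.append(
            GeneModel(gene_id=str(gene_id), exons=tuple(exons),
                      includes_stop=includes_stop)
        )
    return models


def _gff_attr(attributes: str, key: str) -> str | None:
    for part in attributes.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read CDS exon tables from TSV (gene_id/exon_start/exon_end columns)
    or a GFF3 subset (CDS features; gene id from Parent= or ID=)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty exon table")
    body = [ln for ln in lines if not ln.startswith("#")]
    if body and len(body[0].split("\t")) == 9:
        rows = []
        for ln in body:
            fields = ln.split("\t")
            if fields[2] != "CDS":
                continue
            gid = _gff_attr(fields[8], "Parent") or _gff_attr(fields[8], "ID")
            if gid is None:
                raise ValueError(f"{path}: CDS feature without Parent=/ID=: {ln!r}")
            rows.append({"gene_id": gid, "exon_start": int(fields[3]),
                         "exon_end": int(fields[4])})
        if not rows:
            raise ValueError(f"{path}: no CDS features found")
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    return _gene_models_from_frame(frame)


def write_gene_models_gff(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (CDS features on a synthetic contig)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            for start, end in model.exons:
                fh.write(
                    f"{model.gene_id}_locus\tggamma\tCDS\t{start}\t{end}\t.\t+\t.\t"
                    f"Parent={model.gene_id}\n"
                )


def write_newick(tree: dendropy.Tree, path: str | Path,
                 comment: str | None = None) -> None:
    """Write a tree as Newick with branch lengths and any internal-node labels.

    ``comment`` (provenance) is emitted as a leading bracketed Newick comment.
    """
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"[{comment}]\n")
        fh.write(text + "\n")


def read_newick(path: str | Path,
                taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick",
        taxon_namespace=taxon_namespace,
        suppress_internal_node_taxa=True,
    )


def write_tsv(table: pd.DataFrame, path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write a TSV report (UTF-8, '.' decimal separator) with optional '#'
    provenance header lines; an empty table yields a header-only file."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)
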