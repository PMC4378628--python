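"""Readers, writers and the internal gene model.

Internal coordinates are 0-based, half-open; GFF3 input/output converts at the
boundary (GFF3 is 1-based, end-inclusive), so for every exon the internal
length equals ``gff_end - gff_start + 1``.

The representative isoform of a gene is the one with the longest protein,
with ties broken lexicographically by mRNA id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

Interval = tuple[int, int]


class FormatError(ValueError):
    """Structurally invalid input (bad GFF3 hierarchy, bad coordinates...)."""


@dataclass
class GeneModel:
    """A protein-coding gene with its isoforms and representative sequences.

    ``isoforms`` maps mRNA id to a sorted list of exon intervals (0-based,
    half-open).  ``protein``/``cds`` belong to the representative isoform;
    the CDS has had any trailing stop codon trimmed so that
    ``3 * len(protein) == len(cds)``.  ``rank`` is the 0-based position of the
    gene among all genes on its chromosome ordered by start coordinate.
    """

    gene_id: str
    chromosome: str
    strand: str
    span: Interval
    isoforms: dict[str, list[Interval]]
    representative_mrna: str
    protein: str
    cds: str
    rank: int = -1

    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.isoforms:
            raise FormatError(f"{self.gene_id}: gene has no isoforms")
        if self.representative_mrna not in self.isoforms:
            raise FormatError(f"{self.gene_id}: representative mRNA unknown")
        for mrna_id, exons in self.isoforms.items():
            if not exons:
                raise FormatError(f"{mrna_id}: isoform has no exons")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise FormatError(f"{mrna_id}: exons overlap or are unsorted")
            lo, hi = exons[0][0], exons[-1][1]
            if lo < self.span[0] or hi > self.span[1]:
                raise FormatError(f"{mrna_id}: exon outside gene span")
        if 3 * len(self.protein) != len(self.cds):
            raise FormatError(
                f"{self.gene_id}: protein length x3 ({3 * len(self.protein)}) "
                f"!= CDS length ({len(self.cds)})"
            )

    @property
    def exons(self) -> list[Interval]:
        """Exons of the representative isoform."""
        return self.isoforms[self.representative_mrna]


def select_longest_isoform(isoforms: Sequence[tuple[str, str]]) -> str:
    """Return the mRNA id of the longest-protein isoform.

    Ties are broken lexicographically by mRNA id (smallest wins).
    """
    if not isoforms:
        raise ValueError("select_longest_isoform: empty isoform list")
    return min(isoforms, key=lambda it: (-len(it[1]), it[0]))[0]


def trim_terminal_stop(cds: str) -> str:
    """Trim one trailing stop codon when present on a frame-complete CDS."""
    cds = cds.upper()
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    return cds


def parse_genome_annotation(
    gff3: str | Path,
    protein_fasta: str | Path,
    cds_fasta: str | Path,
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per gene from GFF3 + protein/CDS FASTA.

    FASTA records are keyed by mRNA id.  Ranks are assigned per chromosome
    by start coordinate (ties by gene id); strand does not affect ordering.
    """
    with open(protein_fasta) as fh:
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}
    with open(cds_fasta) as fh:
        cds_seqs = {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}
    db = gffutils.create_db(
        str(gff3), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            raise FormatError(f"mRNA {mrna.id} has no parent gene")

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        isoforms: dict[str, list[Interval]] = {}
        for m in db.children(g, featuretype="mRNA"):
            exons = sorted((e.start - 1, e.end) for e in db.children(m, featuretype="exon"))
            if not exons:
                raise FormatError(f"mRNA {m.id} has no exons")
            isoforms[m.id] = exons
        if not isoforms:
            raise FormatError(f"gene {g.id} has no mRNA children")
        try:
            candidates = [(mid, proteins[mid]) for mid in isoforms]
        except KeyError as exc:
            raise KeyError(f"protein FASTA is missing mRNA id {exc.args[0]!r}") from exc
        rep = select_longest_isoform(candidates)
        if rep not in cds_seqs:
            raise KeyError(f"CDS FASTA is missing mRNA id {rep!r}")
        gene = GeneModel(
            gene_id=g.id,
            chromosome=g.seqid,
            strand=g.strand,
            span=(g.start - 1, g.end),
            isoforms={mid: isoforms[mid] for mid in sorted(isoforms)},
            representative_mrna=rep,
            protein=proteins[rep],
            cds=trim_terminal_stop(cds_seqs[rep]),
        )
        gene.validate()
        genes.append(gene)

    assign_ranks(genes)
    genes.sort(key=lambda g: (g.chromosome, g.rank))
    return genes


def assign_ranks(genes: Iterable[GeneModel]) -> None:
    """Assign per-chromosome ranks (0..n-1) ordered by start coordinate."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.span[0], g.gene_id))
        for rank, g in enumerate(members):
            g.rank = rank


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features, converting back to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chromosome, g.span[0], g.gene_id)):
        lines.append(
            f"{g.chromosome}\tkinomescan\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}"
        )
        for mrna_id in sorted(g.isoforms):
            exons = g.isoforms[mrna_id]
            lines.append(
                f"{g.chromosome}\tkinomescan\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}"
            )
            for i, (s, e) in enumerate(exons, 1):
                lines.append(
                    f"{g.chromosome}\tkinomescan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(records[name]), id=name, description="")
        for name in sorted(records)
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        return {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}


@dataclass
class ExpressionTable:
    """Normalized, non-negative expression intensities (genes x conditions).

    ``condition_labels`` maps each condition column to a tissue/treatment
    label (replicate columns may share a label and are mean-collapsed before
    relative transforms).  ``control_map`` (stress mode) maps each treatment
    condition to its control condition in the same table.
    """

    values: pd.DataFrame
    condition_labels: dict[str, str] = field(default_factory=dict)
    control_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.condition_labels:
            self.condition_labels = {c: c for c in self.values.columns}
        self.validate()

    def validate(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dupes}")
        if df.columns.has_duplicates:
            raise FormatError("duplicate condition ids")
        if (df.to_numpy() < 0).any():
            raise FormatError("expression table contains negative values")
        missing = [c for c in df.columns if c not in self.condition_labels]
        if missing:
            raise FormatError(f"conditions without labels: {missing}")
        if self.control_map is not None:
            cols = set(df.columns)
            for treat, ctrl in self.control_map.items():
                if treat not in cols:
                    raise FormatError(f"treatment condition {treat!r} not in table")
                if ctrl not in cols:
                    raise FormatError(f"control condition {ctrl!r} not in table")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def read_expression_table(
    tsv: str | Path,
    labels: str | Path | None = None,
    control_map: str | Path | None = None,
) -> ExpressionTable:
    """Read an expression TSV (header = condition ids, first column = genes)."""
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    label_map: dict[str, str] = {}
    if labels is not None:
        lab = pd.read_csv(labels, sep="\t", header=None, names=["condition", "label"])
        label_map = dict(zip(lab["condition"].astype(str), lab["label"].astype(str)))
    controls = None
    if control_map is not None:
        ctl = pd.read_csv(control_map, sep="\t", header=None, names=["treatment", "control"])
        controls = dict(zip(ctl["treatment"].astype(str), ctl["control"].astype(str)))
    return ExpressionTable(values=df, condition_labels=label_map, control_map=controls)


def write_expression_table(
    table: ExpressionTable,
    tsv: str | Path,
    labels: str | Path | None = None,
    control_map: str | Path | None = None,
) -> None:
    table.values.to_csv(tsv, sep="\t")
    if labels is not None:
        with open(labels, "w") as fh:
            for cond in table.values.columns:
                fh.write(f"{cond}\t{table.condition_labels[cond]}\n")
    if control_map is not None and table.control_map is not None:
        with open(control_map, "w") as fh:
            for treat in sorted(table.control_map):
                fh.write(f"{treat}\t{table.control_map[treat]}\n")
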