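"""Duplicate-pair evolution and genomic context.

Implements Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction, anchor
detection by global-alignment identity, collinear-block chaining by dynamic
programming, whole-genome-duplication era binning of Ks values, and tandem
cluster detection over per-chromosome gene ranks.

NG86 conventions used here: synonymous/nonsynonymous site fractions are
counted per codon position over the three possible point mutations, with
mutations creating stop codons counted as nonsynonymous (so S + N always
equals 3 x the number of aligned codons); multi-difference codons average
difference counts over all orderings of single-step paths, excluding paths
that pass through a stop codon (falling back to all paths when every
ordering is blocked).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io import GeneModel, trim_terminal_stop

NUCLEOTIDES = "ACGT"

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


def translate_codon(codon: str) -> str:
    return CODON_TABLE[codon]


# ---------------------------------------------------------------------------
# NG86 sites and differences
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3), stops-as-nonsynonymous."""
    aa = CODON_TABLE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site count")
    syn = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the single-step mutational paths; paths
    through intermediate stop codons are excluded when possible.
    """
    diff_positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            if CODON_TABLE[nxt] == "*" and nxt != codon_b:
                valid = False
            current = nxt
        paths.append((valid, sd, nd))
    usable = [p for p in paths if p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC-corrected substitutions per site; NaN when saturated (p >= 3/4)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan")
    return (-0.75 * math.log(arg)) + 0.0


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    aligned_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    omega: float

    @property
    def saturated(self) -> bool:
        return math.isnan(self.Ks) or math.isnan(self.Ka)


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _validate_cds(cds: str, name: str) -> str:
    cds = trim_terminal_stop(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length not divisible by 3")
    for i in range(0, len(cds), 3):
        if CODON_TABLE.get(cds[i:i + 3]) == "*":
            raise ValueError(f"{name}: internal stop codon at {i}")
    return cds


def codon_alignment(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Gap-free codon column pairs from a protein-level global alignment."""
    cds_a = _validate_cds(cds_a, "cds_a")
    cds_b = _validate_cds(cds_b, "cds_b")
    prot_a = "".join(CODON_TABLE[cds_a[i:i + 3]] for i in range(0, len(cds_a), 3))
    prot_b = "".join(CODON_TABLE[cds_b[i:i + 3]] for i in range(0, len(cds_b), 3))
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    pairs = []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            pairs.append((cds_a[3 * ia:3 * ia + 3], cds_b[3 * ib:3 * ib + 3]))
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return pairs


def compute_kaks(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> KaKsResult:
    """NG86 Ka/Ks for a CDS pair (gap codon columns excluded).

    Ks = -(3/4) ln(1 - (4/3) pS), likewise Ka; saturation (argument <= 0)
    gives NaN rather than raising.  omega is NaN when Ks is 0 or NaN.
    """
    pairs = codon_alignment(cds_a, cds_b)
    if not pairs:
        raise ValueError("zero aligned codons")
    S = sum((synonymous_sites(ca) + synonymous_sites(cb)) / 2 for ca, cb in pairs)
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sd, nd = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    if math.isnan(Ks) or math.isnan(Ka) or Ks == 0.0:
        omega = float("nan")
    else:
        omega = Ka / Ks
    return KaKsResult(
        gene_a=gene_a, gene_b=gene_b, aligned_codons=len(pairs),
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, omega=omega,
    )


# ---------------------------------------------------------------------------
# anchors and collinear blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorPair:
    """A putatively homologous gene pair, stored in sorted gene-id order."""

    gene_a: str
    gene_b: str
    similarity: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("anchor cannot pair a gene with itself")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


def make_anchor(gene_a: str, gene_b: str, similarity: float) -> AnchorPair:
    a, b = sorted((gene_a, gene_b))
    return AnchorPair(gene_a=a, gene_b=b, similarity=similarity)


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity (matches / alignment columns x100)."""
    aln = _protein_aligner().align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return 100.0 * matches / len(row_a)


def detect_anchor_pairs(
    genes: Sequence[GeneModel],
    min_identity: float = 40.0,
) -> list[AnchorPair]:
    """All-vs-all protein identity >= ``min_identity`` (inclusive)."""
    ordered = sorted(genes, key=lambda g: g.gene_id)
    anchors = []
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1:]:
            ident = percent_identity(ga.protein, gb.protein)
            if ident >= min_identity:
                anchors.append(make_anchor(ga.gene_id, gb.gene_id, ident))
    return anchors


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "plus" | "minus"
    anchors: list[AnchorPair]

    @property
    def size(self) -> int:
        return len(self.anchors)


def _chain_dp(points: list[tuple[int, int, AnchorPair]], max_gap: int,
              descending_b: bool) -> tuple[int, tuple]:
    """Longest monotone chain with rank gaps <= max_gap on both axes.

    Returns (length, chain) where ``chain`` is the lexicographically smallest
    tuple of (rank_a, rank_b) pairs among maximum-length chains.  ``points``
    must be sorted by (rank_a, rank_b).
    """
    n = len(points)
    best_len = [1] * n
    best_chain: list[tuple] = [((points[i][0], points[i][1]),) for i in range(n)]
    for i in range(n):
        ra, rb, _ = points[i]
        for j in range(i):
            qa, qb, _ = points[j]
            da = ra - qa
            db = (qb - rb) if descending_b else (rb - qb)
            if 1 <= da <= max_gap and 1 <= db <= max_gap:
                cand_len = best_len[j] + 1
                cand_chain = best_chain[j] + (((ra, rb)),)
                if cand_len > best_len[i] or (
                    cand_len == best_len[i] and cand_chain < best_chain[i]
                ):
                    best_len[i] = cand_len
                    best_chain[i] = cand_chain
    # maximal length, then lexicographically smallest chain
    max_len = max(best_len)
    candidates = [best_chain[i] for i in range(n) if best_len[i] == max_len]
    return max_len, min(candidates)


def chain_collinear_blocks(
    anchors: Iterable[AnchorPair],
    positions: Mapping[str, tuple[str, int]],
    min_block: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    A block is a chain of anchors strictly monotone in rank on both
    chromosomes (increasing on the first; increasing = plus or decreasing =
    minus on the second) with successive rank differences <= ``max_gap``.
    Blocks are extracted greedily best-first (longest chain, deterministic
    tie-break) and anchors are consumed, so each anchor joins at most one
    block; chains shorter than ``min_block`` are discarded.
    """
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for anchor in anchors:
        for gene in (anchor.gene_a, anchor.gene_b):
            if gene not in positions:
                raise KeyError(f"anchor gene {gene!r} has no known position")
        ca, _ = positions[anchor.gene_a]
        cb, _ = positions[anchor.gene_b]
        key = (ca, cb) if ca <= cb else (cb, ca)
        by_pair.setdefault(key, []).append(anchor)

    blocks: list[CollinearBlock] = []
    for (ca, cb), pair_anchors in sorted(by_pair.items()):
        remaining = set(pair_anchors)
        while True:
            points = []
            for anchor in remaining:
                chrom_1, rank_1 = positions[anchor.gene_a]
                chrom_2, rank_2 = positions[anchor.gene_b]
                if chrom_1 == ca and chrom_2 == cb:
                    pt = (rank_1, rank_2, anchor)
                else:
                    pt = (rank_2, rank_1, anchor)
                if ca == cb:
                    pt = (min(pt[0], pt[1]), max(pt[0], pt[1]), anchor)
                points.append(pt)
            points.sort(key=lambda p: (p[0], p[1], p[2].gene_a, p[2].gene_b))
            if not points:
                break
            candidates = []
            for orientation, descending in (("plus", False), ("minus", True)):
                length, chain = _chain_dp(points, max_gap, descending)
                candidates.append((-length, orientation, chain))
            candidates.sort()
            neg_len, orientation, chain = candidates[0]
            if -neg_len < min_block:
                break
            chain_set = set(chain)
            descending = orientation == "minus"
            chosen = [p for p in points if (p[0], p[1]) in chain_set]
            chosen.sort(key=lambda p: p[0])
            block_anchors = [p[2] for p in chosen]
            blocks.append(CollinearBlock(
                chrom_a=ca, chrom_b=cb, orientation=orientation,
                anchors=block_anchors,
            ))
            remaining -= set(block_anchors)
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b,
                               b.anchors[0].gene_a, b.anchors[0].gene_b))
    return blocks


# ---------------------------------------------------------------------------
# WGD eras
# ---------------------------------------------------------------------------

class WGDEra(str, enum.Enum):
    """Whole-genome-duplication era of a duplicate pair, from its Ks.

    The recent (13 Mya) event corresponds to Ks in [0.06, 0.39], the older
    (59 Mya) event to Ks in [0.40, 0.80]; everything else (including
    saturated/NA estimates) is "other".
    """

    ERA_13MYA = "13Mya"
    ERA_59MYA = "59Mya"
    OTHER = "other"


def assign_wgd_era(ks: float) -> WGDEra:
    if math.isnan(ks):
        return WGDEra.OTHER
    if ks < 0:
        raise ValueError("Ks cannot be negative")
    if 0.06 <= ks <= 0.39:
        return WGDEra.ERA_13MYA
    if 0.40 <= ks <= 0.80:
        return WGDEra.ERA_59MYA
    return WGDEra.OTHER


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

@dataclass
class TandemCluster:
    chromosome: str
    subfamily: str
    members: list[str]  # ordered by rank
    rank_span: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


def detect_tandem_clusters(
    genes: Sequence[GeneModel],
    assignments: Mapping[str, str],
    max_intervening: int = 5,
) -> list[TandemCluster]:
    """Same-subfamily genes at adjacent chromosomal positions.

    Per chromosome and subfamily, genes sorted by rank are clustered
    transitively when successive rank differences are at most
    ``max_intervening + 1``; singletons are not clusters.  Genes without a
    subfamily (absent from ``assignments`` or Unclassified) are skipped with
    a warning.
    """
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    skipped = []
    for gene in genes:
        subfamily = assignments.get(gene.gene_id)
        if subfamily is None or subfamily == "Unclassified":
            skipped.append(gene.gene_id)
            continue
        groups.setdefault((gene.chromosome, subfamily), []).append(gene)
    if skipped:
        warnings.warn(
            f"tandem clustering skipped {len(skipped)} gene(s) without a subfamily",
            stacklevel=2,
        )
    clusters = []
    for (chrom, subfamily), members in sorted(groups.items()):
        members.sort(key=lambda g: g.rank)
        run = [members[0]]
        for gene in members[1:]:
            if gene.rank - run[-1].rank <= max_intervening + 1:
                run.append(gene)
            else:
                if len(run) > 1:
                    clusters.append(_make_cluster(chrom, subfamily, run))
                run = [gene]
        if len(run) > 1:
            clusters.append(_make_cluster(chrom, subfamily, run))
    clusters.sort(key=lambda c: (c.chromosome, c.rank_span, c.subfamily))
    return clusters


def _make_cluster(chrom: str, subfamily: str, run: list[GeneModel]) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        subfamily=subfamily,
        members=[g.gene_id for g in run],
        rank_span=(run[0].rank, run[-1].rank),
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.4f}"


def write_collinearity_tsv(
    blocks: Sequence[CollinearBlock],
    kaks: Mapping[tuple[str, str], KaKsResult],
    path: str | Path,
) -> None:
    lines = ["block_id\tchrA\tchrB\torientation\tgene_a\tgene_b\tidentity\tKa\tKs\tomega\tera"]
    for bid, block in enumerate(blocks, 1):
        for anchor in block.anchors:
            res = kaks[(anchor.gene_a, anchor.gene_b)]
            era = assign_wgd_era(res.Ks).value
            lines.append(
                f"{bid}\t{block.chrom_a}\t{block.chrom_b}\t{block.orientation}\t"
                f"{anchor.gene_a}\t{anchor.gene_b}\t{anchor.similarity:.2f}\t"
                f"{_fmt(res.Ka)}\t{_fmt(res.Ks)}\t{_fmt(res.omega)}\t{era}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_tandem_tsv(clusters: Sequence[TandemCluster], path: str | Path) -> None:
    lines = ["cluster_id\tchromosome\tsubfamily\tmembers"]
    for cid, cluster in enumerate(clusters, 1):
        lines.append(
            f"{cid}\t{cluster.chromosome}\t{cluster.subfamily}\t"
            + ",".join(cluster.members)
        )
    Path(path).write_text("\n".join(lines) + "\n")
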