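"""Synthetic kinome genomes and expression tables with truth records.

Everything here is a pure function of (config, seed): the same inputs give
byte-identical outputs.  The generators plant exactly the structures the
pipeline's detectors look for — domain instances sampled from named
subfamily profile HMMs, tandem arrays at adjacent ranks, collinear
duplicated blocks with CDS pairs evolved to target Ks/Ka, multi-domain and
multi-isoform genes, and subfamily-level expression correlation — and
record every planted structure so recovery can be scored without consulting
generator internals.

Default genome layout (three chromosomes): the first two chromosomes carry
dispersed singletons cycling through seven subfamilies (cycle length 7, so
dispersed same-subfamily genes are never within the tandem window) plus one
tandem array each; the third chromosome carries the duplicated copies of
two collinear blocks, one in plus and one in minus orientation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .duplication import (CODON_TABLE, NUCLEOTIDES, synonymous_sites,
                          translate_codon)
from .hmm import AMINO_ACIDS, ProfileHMM
from .hmm import viterbi_best_score as _best_score
from .hmm import viterbi_domain_search as _hmm_search
from .io import ExpressionTable, GeneModel, assign_ranks, write_fasta, write_gff3

# codons per amino acid (sorted for determinism)
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)

DISPERSED_SUBFAMILIES = (
    "AGC_RSK-2", "CAMK_CDPK", "CK1_CK1-Pl", "CMGC_CDK",
    "CMGC_GSK", "STE_STE11", "TKL_Pl-4",
)
TANDEM_SUBFAMILIES = ("RLK-Pelle_DLSV", "RLK-Pelle_LRR-XI-1")
CLAN_MODEL_ID = "Pkinase"


# ---------------------------------------------------------------------------
# profile HMM library generation
# ---------------------------------------------------------------------------

def build_profile_hmm(
    model_id: str,
    consensus: str,
    match_p: float = 0.9,
    t_loop: float = 0.94,
) -> ProfileHMM:
    """A profile HMM peaked on ``consensus`` with simple indel transitions."""
    M = len(consensus)
    background = np.full(20, 1.0 / 20.0)
    match = np.full((M, 20), (1.0 - match_p) / 19.0)
    for k, aa in enumerate(consensus):
        match[k, AMINO_ACIDS.index(aa)] = match_p
    insert = np.tile(background, (M + 1, 1))
    branch = (1.0 - t_loop) / 2.0
    trans = {
        "mm": np.full(M + 1, t_loop),
        "mi": np.full(M + 1, branch),
        "md": np.full(M + 1, branch),
        "im": np.full(M + 1, 0.6),
        "ii": np.full(M + 1, 0.4),
        "dm": np.full(M + 1, 0.6),
        "dd": np.full(M + 1, 0.4),
    }
    # last node: no insert/delete continuation
    trans["mm"][M] = 1.0
    trans["mi"][M] = trans["md"][M] = 0.0
    trans["dm"][M] = 1.0
    trans["dd"][M] = 0.0
    trans["dm"][0] = 1.0
    trans["dd"][0] = 0.0
    model = ProfileHMM(
        model_id=model_id,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=background,
    )
    model.validate()
    return model


def make_hmm_library(
    seed: int,
    M: int = 40,
    divergence: float = 0.25,
    subfamilies: Sequence[str] = DISPERSED_SUBFAMILIES + TANDEM_SUBFAMILIES,
) -> tuple[ProfileHMM, dict[str, ProfileHMM]]:
    """A clan-level model plus per-subfamily models derived from it.

    Mimicking real kinase domains, conserved "motif" blocks at the start,
    middle and end of the domain (think glycine loop / HRD / DFG) are shared
    by every subfamily; each subfamily redraws ``divergence`` of the
    variable positions.  Members therefore score well against the clan model
    over the full domain span (the clan scan finds them at high coverage)
    while scoring best against their own subfamily model.
    """
    rng = np.random.default_rng(seed)
    clan_consensus = "".join(rng.choice(list(AMINO_ACIDS), size=M))
    clan = build_profile_hmm(CLAN_MODEL_ID, clan_consensus)
    block = max(2, M // 8)
    mid = M // 2
    conserved = set(range(block)) | set(range(M - block, M))
    conserved |= set(range(mid - block // 2, mid - block // 2 + block))
    variable = sorted(set(range(M)) - conserved)
    library = {}
    n_mut = min(int(round(divergence * M)), len(variable))
    for name in sorted(subfamilies):
        positions = rng.choice(variable, size=n_mut, replace=False)
        consensus = list(clan_consensus)
        for pos in positions:
            alternatives = [a for a in AMINO_ACIDS if a != consensus[pos]]
            consensus[pos] = str(rng.choice(alternatives))
        library[name] = build_profile_hmm(name, "".join(consensus))
    return clan, library


def sample_domain(model: ProfileHMM, rng: np.random.Generator,
                  n_states: int | None = None) -> str:
    """Sample a domain instance along the all-match (consensus) path."""
    n = model.M if n_states is None else n_states
    letters = list(AMINO_ACIDS)
    return "".join(
        str(rng.choice(letters, p=model.match_emissions[k]))
        for k in range(n)
    )


def sample_background(rng: np.random.Generator, n: int,
                      background: np.ndarray | None = None) -> str:
    p = background if background is not None else np.full(20, 1.0 / 20.0)
    return "".join(rng.choice(list(AMINO_ACIDS), size=n, p=p))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous-codon back-translation."""
    return "".join(str(rng.choice(_CODONS_FOR[aa])) for aa in protein)


# ---------------------------------------------------------------------------
# codon divergence to target Ks/Ka
# ---------------------------------------------------------------------------

def _invert_jc(k: float) -> float:
    """Proportion of differing sites that yields JC distance ``k``."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


def _single_step_variants(codon: str) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous non-stop) single-nucleotide variants."""
    aa = CODON_TABLE[codon]
    syn, nonsyn = [], []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            mut_aa = CODON_TABLE[mutant]
            if mut_aa == "*":
                continue
            (syn if mut_aa == aa else nonsyn).append(mutant)
    return syn, nonsyn


def simulate_codon_divergence(
    cds: str,
    target_ks: float,
    target_ka: float,
    seed: int | np.random.Generator,
) -> str:
    """Evolve a CDS so NG86 recovers approximately the target Ks and Ka.

    Substitutions are planted one per codon (synonymous or nonsynonymous
    single-nucleotide changes, never creating stops), with counts set to the
    NG86-expected synonymous/nonsynonymous differences implied by the
    targets — direct ground truth for the estimator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target_ks < 0 or target_ka < 0:
        raise ValueError("divergence targets must be non-negative")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for c in codons:
        if CODON_TABLE[c] == "*":
            raise ValueError("CDS contains an internal stop codon")
    pS = _invert_jc(target_ks)
    pN = _invert_jc(target_ka)
    if pS >= 0.75 or pN >= 0.75:
        raise ValueError(
            f"target beyond the Jukes-Cantor saturation bound pS/pN < 0.75 "
            f"(requested pS={pS:.3f}, pN={pN:.3f})"
        )
    S = sum(synonymous_sites(c) for c in codons)
    N = 3 * len(codons) - S
    if target_ks > 0 and S == 0:
        raise ValueError("target Ks > 0 but the CDS has no synonymous sites")
    sd_needed = int(round(pS * S))
    nd_needed = int(round(pN * N))
    variants = [_single_step_variants(c) for c in codons]
    syn_ok = [i for i, (s, _) in enumerate(variants) if s]
    nonsyn_ok = [i for i, (_, ns) in enumerate(variants) if ns]
    if sd_needed > len(syn_ok):
        raise ValueError(
            f"target Ks {target_ks} needs {sd_needed} synonymous changes but "
            f"only {len(syn_ok)} codons admit one (one change per codon)"
        )
    order = rng.permutation(len(codons))
    chosen_syn = [i for i in order if i in set(syn_ok)][:sd_needed]
    remaining = [i for i in order if i not in set(chosen_syn)]
    chosen_nonsyn = [i for i in remaining if i in set(nonsyn_ok)][:nd_needed]
    if len(chosen_nonsyn) < nd_needed:
        raise ValueError(
            f"target Ka {target_ka} needs {nd_needed} nonsynonymous changes "
            f"but only {len(chosen_nonsyn)} codons remain available"
        )
    out = list(codons)
    for i in chosen_syn:
        out[i] = str(rng.choice(variants[i][0]))
    for i in chosen_nonsyn:
        out[i] = str(rng.choice(variants[i][1]))
    return "".join(out)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """A collinear block: genes from ``source_chrom`` ranks
    [source_start, source_start + size) duplicated onto the target
    chromosome with the given orientation and divergence targets."""

    source_chrom: str
    source_start: int
    size: int
    target_chrom: str
    orientation: str  # "plus" | "minus"
    target_ks: float
    target_ka: float


@dataclass
class GenomeSimConfig:
    chromosomes: tuple[str, ...] = ("Chr01", "Chr02", "Chr03")
    dispersed_per_chromosome: int = 14
    tandem_arrays: tuple[tuple[str, str, int], ...] = (
        ("Chr01", TANDEM_SUBFAMILIES[0], 3),
        ("Chr02", TANDEM_SUBFAMILIES[1], 3),
    )
    blocks: tuple[BlockSpec, ...] = (
        BlockSpec("Chr01", 2, 6, "Chr03", "plus", 0.20, 0.05),
        BlockSpec("Chr02", 4, 6, "Chr03", "minus", 0.60, 0.10),
    )
    multi_domain_count: int = 4
    multi_isoform_count: int = 4
    intronless_fraction: float = 0.12
    atypical_count: int = 3
    nonkinase_count: int = 2
    flank_range: tuple[int, int] = (30, 45)
    domain_spacer: int = 25
    intron_length: int = 120
    min_block_size: int = 5
    # planted-structure verification: a gene only counts as carrying a
    # domain if the emitted sequence really contains a detectable instance;
    # degenerate draws are resampled.  Margins sit clear of the pipeline's
    # decision boundaries (coverage 0.5, tau 10) so verification does not
    # trace the detector.
    scan_tau: float = 12.0
    typical_min_coverage: float = 0.6
    atypical_max_coverage: float = 0.45
    atypical_domain_fraction: float = 0.3
    nonkinase_max_score: float = 8.0
    max_resample: int = 30

    def validate(self) -> None:
        if len(self.chromosomes) < 3:
            raise ValueError("need at least 3 chromosomes (two source + one target)")
        if self.dispersed_per_chromosome < len(DISPERSED_SUBFAMILIES) + 1:
            raise ValueError(
                "dispersed_per_chromosome must exceed the subfamily cycle length"
            )
        for spec in self.blocks:
            if spec.size < self.min_block_size:
                raise ValueError(
                    f"block on {spec.source_chrom} has size {spec.size} < "
                    f"min_block_size {self.min_block_size}"
                )
            if spec.source_start + spec.size > self.dispersed_per_chromosome:
                raise ValueError("block source range exceeds dispersed genes")
            if spec.orientation not in {"plus", "minus"}:
                raise ValueError("block orientation must be plus or minus")
        for _, _, size in self.tandem_arrays:
            if size < 2:
                raise ValueError("tandem arrays need at least 2 members")
        for frac in (self.intronless_fraction,):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class TruthRecord:
    """Every planted structure, keyed by id; see the per-field TSVs."""

    seed: int
    subfamily: dict[str, str] = field(default_factory=dict)
    domain_count: dict[str, int] = field(default_factory=dict)
    atypical: list[str] = field(default_factory=list)
    nonkinase: list[str] = field(default_factory=list)
    multi_isoform: list[str] = field(default_factory=list)
    intronless: list[str] = field(default_factory=list)
    tandem_clusters: list[dict] = field(default_factory=list)
    blocks: list[dict] = field(default_factory=list)
    expression: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": 1,
            "seed": self.seed,
            "counts": {
                "genes": len(self.subfamily) + len(self.nonkinase),
                "kinase_genes": len(self.subfamily),
                "atypical": len(self.atypical),
                "tandem_clusters": len(self.tandem_clusters),
                "blocks": len(self.blocks),
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        lines = ["gene\tsubfamily\tdomain_count\tatypical\tmulti_isoform\tintronless"]
        for gene in sorted(set(self.subfamily) | set(self.nonkinase)):
            lines.append("\t".join([
                gene,
                self.subfamily.get(gene, "none"),
                str(self.domain_count.get(gene, 0)),
                str(int(gene in self.atypical)),
                str(int(gene in self.multi_isoform)),
                str(int(gene in self.intronless)),
            ]))
        (outdir / "genes.tsv").write_text("\n".join(lines) + "\n")
        lines = ["cluster_id\tchromosome\tsubfamily\tmembers"]
        for cid, cluster in enumerate(self.tandem_clusters, 1):
            lines.append(f"{cid}\t{cluster['chromosome']}\t{cluster['subfamily']}\t"
                         + ",".join(cluster["members"]))
        (outdir / "tandem.tsv").write_text("\n".join(lines) + "\n")
        lines = ["block_id\tchrom_a\tchrom_b\torientation\ttarget_ks\ttarget_ka\tgene_a\tgene_b"]
        for bid, block in enumerate(self.blocks, 1):
            for ga, gb in block["pairs"]:
                lines.append(
                    f"{bid}\t{block['chrom_a']}\t{block['chrom_b']}\t"
                    f"{block['orientation']}\t{block['target_ks']}\t"
                    f"{block['target_ka']}\t{ga}\t{gb}"
                )
        (outdir / "blocks.tsv").write_text("\n".join(lines) + "\n")
        (outdir / "expression.json").write_text(
            json.dumps(self.expression, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, outdir: str | Path) -> "TruthRecord":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        truth = cls(seed=manifest["seed"])
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
        for _, row in genes.iterrows():
            gene = row["gene"]
            if row["subfamily"] == "none":
                truth.nonkinase.append(gene)
            else:
                truth.subfamily[gene] = row["subfamily"]
                truth.domain_count[gene] = int(row["domain_count"])
            if row["atypical"]:
                truth.atypical.append(gene)
            if row["multi_isoform"]:
                truth.multi_isoform.append(gene)
            if row["intronless"]:
                truth.intronless.append(gene)
        tandem = pd.read_csv(outdir / "tandem.tsv", sep="\t")
        for _, row in tandem.iterrows():
            truth.tandem_clusters.append({
                "chromosome": row["chromosome"],
                "subfamily": row["subfamily"],
                "members": row["members"].split(","),
            })
        blocks = pd.read_csv(outdir / "blocks.tsv", sep="\t")
        for bid, group in blocks.groupby("block_id"):
            first = group.iloc[0]
            truth.blocks.append({
                "chrom_a": first["chrom_a"],
                "chrom_b": first["chrom_b"],
                "orientation": first["orientation"],
                "target_ks": float(first["target_ks"]),
                "target_ka": float(first["target_ka"]),
                "pairs": [tuple(p) for p in group[["gene_a", "gene_b"]].to_numpy()],
            })
        expr_path = outdir / "expression.json"
        if expr_path.exists():
            truth.expression = json.loads(expr_path.read_text())
        return truth


@dataclass
class SimulatedKinome:
    genes: list[GeneModel]
    proteins: dict[str, str]  # mRNA id -> protein
    cds: dict[str, str]       # mRNA id -> CDS (with stop codon)
    truth: TruthRecord

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.faa")
        write_fasta(self.cds, outdir / "cds.fna")
        write_gff3(self.genes, outdir / "genes.gff3")
        self.truth.save(outdir / "truth")


def _gene_id(chrom: str, index: int) -> str:
    return f"{chrom}_g{index + 1:03d}"


def _layout_labels(config: GenomeSimConfig) -> dict[str, list[tuple[str, str]]]:
    """Per-chromosome ordered (slot_kind, subfamily) lists.

    slot_kind is "dispersed", "tandem", "copy:<block>:<source_index>",
    "atypical" or "nonkinase".
    """
    D = list(DISPERSED_SUBFAMILIES)
    nC = len(D)
    chrom_a, chrom_b, chrom_c = config.chromosomes[:3]
    layout: dict[str, list[tuple[str, str]]] = {c: [] for c in config.chromosomes}
    for i in range(config.dispersed_per_chromosome):
        layout[chrom_a].append(("dispersed", D[i % nC]))
        layout[chrom_b].append(("dispersed", D[(3 - i) % nC]))
    for chrom, subfamily, size in config.tandem_arrays:
        for _ in range(size):
            layout[chrom].append(("tandem", subfamily))
    for b, spec in enumerate(config.blocks):
        indices = range(spec.size)
        if spec.orientation == "minus":
            indices = reversed(indices)
        for i in indices:
            source = layout[spec.source_chrom][spec.source_start + i]
            layout[spec.target_chrom].append((f"copy:{b}:{i}", source[1]))
    return layout


def _check_layout(layout: Mapping[str, list[tuple[str, str]]],
                  max_intervening: int = 5) -> None:
    """Reject layouts whose dispersed/copy genes would form spurious tandem
    runs (the planted tandem truth must be exactly recoverable)."""
    for chrom, slots in layout.items():
        last_seen: dict[str, tuple[int, str]] = {}
        for rank, (kind, subfamily) in enumerate(slots):
            if subfamily in last_seen:
                prev_rank, prev_kind = last_seen[subfamily]
                gap = rank - prev_rank
                adjacent = gap <= max_intervening + 1
                both_tandem = kind == "tandem" and prev_kind == "tandem"
                if adjacent and not both_tandem:
                    raise ValueError(
                        f"layout places two {subfamily} genes {gap} ranks apart "
                        f"on {chrom}; would create an unplanted tandem cluster"
                    )
            last_seen[subfamily] = (rank, kind)


def simulate_kinome_genome(
    config: GenomeSimConfig,
    library: Mapping[str, ProfileHMM],
    seed: int,
    clan: ProfileHMM | None = None,
) -> SimulatedKinome:
    """Generate proteome + CDS + GFF3 + truth for a synthetic kinome.

    When ``clan`` is given, every planted gene is verified against it —
    kinase genes must carry their stated number of high-coverage domain
    instances, atypical genes a partial-coverage one, non-kinase genes no
    hit — and the rare degenerate random draw is resampled, so the truth
    record always describes what the sequences really contain.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    layout = _layout_labels(config)
    _check_layout(layout)
    for slots in layout.values():
        for kind, subfamily in slots:
            if subfamily not in library:
                raise ValueError(f"subfamily {subfamily!r} missing from HMM library")

    truth = TruthRecord(seed=seed)
    chrom_a, chrom_b, chrom_c = config.chromosomes[:3]

    # pick multi-domain / multi-isoform / atypical genes among dispersed
    # slots that are NOT block sources (copies must stay simple duplicates)
    source_slots = set()
    for spec in config.blocks:
        for i in range(spec.size):
            source_slots.add((spec.source_chrom, spec.source_start + i))
    eligible = []
    for chrom in (chrom_a, chrom_b):
        for rank, (kind, _) in enumerate(layout[chrom]):
            if kind == "dispersed" and (chrom, rank) not in source_slots:
                eligible.append((chrom, rank))
    eligible.sort()
    picks = rng.permutation(len(eligible))
    multi_domain_slots = {eligible[i] for i in picks[:config.multi_domain_count]}
    iso_picks = picks[config.multi_domain_count:
                      config.multi_domain_count + config.multi_isoform_count]
    multi_isoform_slots = {eligible[i] for i in iso_picks}

    # per-gene construction -------------------------------------------------
    flank_lo, flank_hi = config.flank_range
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    gene_records: list[dict] = []  # chrom, index, protein, cds, n_isoforms

    def _verified_hits(protein: str, n_domains: int, truncated: bool) -> bool:
        if clan is None:
            return True
        hits = _hmm_search(protein, clan, tau=config.scan_tau)
        if truncated:
            return (bool(hits)
                    and max(h.coverage for h in hits) <= config.atypical_max_coverage)
        full = sum(1 for h in hits if h.coverage >= config.typical_min_coverage)
        half = sum(1 for h in hits if h.coverage >= 0.5)
        return full == n_domains and half == n_domains

    def build_kinase_protein(subfamily: str, n_domains: int,
                             truncated: bool) -> str:
        model = library[subfamily]
        n_states = (max(2, int(config.atypical_domain_fraction * model.M))
                    if truncated else None)
        for _ in range(config.max_resample):
            parts = [sample_background(rng, int(rng.integers(flank_lo, flank_hi + 1)))]
            for d in range(n_domains):
                if d > 0:
                    parts.append(sample_background(rng, config.domain_spacer))
                parts.append(sample_domain(model, rng, n_states))
            parts.append(sample_background(rng, int(rng.integers(flank_lo, flank_hi + 1))))
            protein = "".join(parts)
            if _verified_hits(protein, n_domains, truncated):
                return protein
        raise RuntimeError(
            f"could not sample a verifiable {subfamily} gene in "
            f"{config.max_resample} attempts")

    copy_sources: dict[tuple[int, int], str] = {}  # (block, source_index) -> gene_id

    for chrom in config.chromosomes:
        for rank, (kind, subfamily) in enumerate(layout[chrom]):
            gene_id = _gene_id(chrom, rank)
            if kind.startswith("copy:"):
                continue  # built after sources exist
            n_domains = 2 if (chrom, rank) in multi_domain_slots else 1
            protein = build_kinase_protein(subfamily, n_domains, truncated=False)
            cds = back_translate(protein, rng)
            gene_records.append(dict(chrom=chrom, rank=rank, gene_id=gene_id,
                                     protein=protein, cds=cds,
                                     subfamily=subfamily, kind=kind))
            truth.subfamily[gene_id] = subfamily
            truth.domain_count[gene_id] = n_domains
            if (chrom, rank) in multi_isoform_slots:
                truth.multi_isoform.append(gene_id)
        # record which gene fills each block-source slot
    for spec_index, spec in enumerate(config.blocks):
        for i in range(spec.size):
            copy_sources[(spec_index, i)] = _gene_id(
                spec.source_chrom, spec.source_start + i)

    # now the block copies
    record_by_id = {r["gene_id"]: r for r in gene_records}
    for chrom in config.chromosomes:
        for rank, (kind, subfamily) in enumerate(layout[chrom]):
            if not kind.startswith("copy:"):
                continue
            _, block_s, idx_s = kind.split(":")
            source_id = copy_sources[(int(block_s), int(idx_s))]
            source = record_by_id[source_id]
            spec = config.blocks[int(block_s)]
            for _ in range(config.max_resample):
                diverged = simulate_codon_divergence(
                    source["cds"], spec.target_ks, spec.target_ka, rng)
                protein = "".join(translate_codon(diverged[i:i + 3])
                                  for i in range(0, len(diverged), 3))
                if _verified_hits(protein, truth.domain_count[source_id], False):
                    break
            else:
                raise RuntimeError(
                    f"could not diverge {source_id} into a verifiable copy")
            gene_id = _gene_id(chrom, rank)
            gene_records.append(dict(chrom=chrom, rank=rank, gene_id=gene_id,
                                     protein=protein, cds=diverged,
                                     subfamily=subfamily, kind=kind))
            truth.subfamily[gene_id] = subfamily
            truth.domain_count[gene_id] = truth.domain_count[source_id]

    # atypical (truncated-domain) and non-kinase genes, appended at the ends
    extra_slots = []
    for i in range(config.atypical_count):
        chrom = config.chromosomes[i % len(config.chromosomes)]
        subfamily = DISPERSED_SUBFAMILIES[i % len(DISPERSED_SUBFAMILIES)]
        extra_slots.append((chrom, "atypical", subfamily))
    for i in range(config.nonkinase_count):
        chrom = config.chromosomes[(i + 1) % len(config.chromosomes)]
        extra_slots.append((chrom, "nonkinase", None))
    next_rank = {c: len(layout[c]) for c in config.chromosomes}
    for chrom, kind, subfamily in extra_slots:
        rank = next_rank[chrom]
        next_rank[chrom] += 1
        gene_id = _gene_id(chrom, rank)
        if kind == "atypical":
            protein = build_kinase_protein(subfamily, 1, truncated=True)
            truth.subfamily[gene_id] = subfamily
            truth.domain_count[gene_id] = 0  # no full-coverage domain
            truth.atypical.append(gene_id)
        else:
            for _ in range(config.max_resample):
                protein = sample_background(rng, int(rng.integers(90, 130)))
                if clan is None or _best_score(protein, clan) < config.nonkinase_max_score:
                    break
            else:
                raise RuntimeError("could not sample a clean non-kinase gene")
            truth.nonkinase.append(gene_id)
        cds = back_translate(protein, rng)
        gene_records.append(dict(chrom=chrom, rank=rank, gene_id=gene_id,
                                 protein=protein, cds=cds,
                                 subfamily=subfamily, kind=kind))

    # tandem cluster truth
    for chrom, subfamily, size in config.tandem_arrays:
        start = config.dispersed_per_chromosome
        members = [_gene_id(chrom, start + i) for i in range(size)]
        truth.tandem_clusters.append({
            "chromosome": chrom, "subfamily": subfamily, "members": members})
    # block truth
    for spec_index, spec in enumerate(config.blocks):
        target_offset = sum(s.size for s in config.blocks[:spec_index])
        pairs = []
        for i in range(spec.size):
            source_id = copy_sources[(spec_index, i)]
            if spec.orientation == "plus":
                target_rank = target_offset + i
            else:
                target_rank = target_offset + (spec.size - 1 - i)
            pairs.append(tuple(sorted(
                (source_id, _gene_id(spec.target_chrom, target_rank)))))
        truth.blocks.append({
            "chrom_a": spec.source_chrom, "chrom_b": spec.target_chrom,
            "orientation": spec.orientation,
            "target_ks": spec.target_ks, "target_ka": spec.target_ka,
            "pairs": sorted(pairs),
        })

    # intronless picks over all genes
    gene_records.sort(key=lambda r: (r["chrom"], r["rank"]))
    n_intronless = int(round(config.intronless_fraction * len(gene_records)))
    intronless_idx = set(rng.permutation(len(gene_records))[:n_intronless])
    for i in sorted(intronless_idx):
        truth.intronless.append(gene_records[i]["gene_id"])

    # genomic coordinates + GeneModel construction
    genes: list[GeneModel] = []
    cursor: dict[str, int] = {c: 1000 for c in config.chromosomes}
    for i, rec in enumerate(gene_records):
        chrom = rec["chrom"]
        start = cursor[chrom]
        full_cds = rec["cds"] + "TAA"
        n_exons = 1 if i in intronless_idx else int(rng.integers(2, 7))
        exon_lengths = _split_lengths(len(full_cds), n_exons)
        exons = []
        pos = start
        for L in exon_lengths:
            exons.append((pos, pos + L))
            pos += L + config.intron_length
        span = (start, exons[-1][1])
        mrna_1 = rec["gene_id"] + ".1"
        isoforms = {mrna_1: exons}
        proteins[mrna_1] = rec["protein"]
        cds_map[mrna_1] = full_cds
        if rec["gene_id"] in truth.multi_isoform:
            n_codons = max(3, int(0.6 * len(rec["protein"])))
            short_cds = rec["cds"][:3 * n_codons]
            short_protein = "".join(translate_codon(short_cds[j:j + 3])
                                    for j in range(0, len(short_cds), 3))
            mrna_2 = rec["gene_id"] + ".2"
            isoforms[mrna_2] = [(start, start + len(short_cds) + 3)]
            proteins[mrna_2] = short_protein
            cds_map[mrna_2] = short_cds + "TAA"
        strand = "+" if rec["rank"] % 2 == 0 else "-"
        gene = GeneModel(
            gene_id=rec["gene_id"], chromosome=chrom, strand=strand,
            span=span, isoforms=isoforms, representative_mrna=mrna_1,
            protein=rec["protein"], cds=rec["cds"],
        )
        cursor[chrom] = span[1] + 500
        genes.append(gene)
    assign_ranks(genes)
    for gene in genes:
        gene.validate()
    genes.sort(key=lambda g: (g.chromosome, g.rank))
    return SimulatedKinome(genes=genes, proteins=proteins, cds=cds_map, truth=truth)


def _split_lengths(total: int, n: int) -> list[int]:
    if n > total:
        n = total
    q, r = divmod(total, n)
    return [q + (1 if i < r else 0) for i in range(n)]


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

TISSUE_LABELS = (
    "roots", "root_tips", "root_apex", "root_hairs", "nodules", "cotyledons",
    "leaves", "shoots", "pollen", "axillary_meristem", "embryos", "seeds",
    "seed_coats", "pods",
)

STRESS_TREATMENTS = tuple(
    f"{s}_{phase}" for s in (
        "drought", "salt", "heat", "cold", "submergence", "iron_deficiency",
        "aluminium", "LCO", "phytophthora", "rust", "SCN", "wounding",
    ) for phase in ("early", "late")
)


@dataclass
class ExpressionDesign:
    mode: str                       # "tissue" | "stress"
    conditions: list[str]           # table columns
    condition_labels: dict[str, str]
    control_map: dict[str, str] | None = None


def default_tissue_design(replicates: int = 1) -> ExpressionDesign:
    conditions = []
    labels = {}
    for t in TISSUE_LABELS:
        for r in range(replicates):
            cond = t if replicates == 1 else f"{t}_rep{r + 1}"
            conditions.append(cond)
            labels[cond] = t
    return ExpressionDesign("tissue", conditions, labels)


def default_stress_design(n_controls: int = 6) -> ExpressionDesign:
    controls = [f"control_{i + 1}" for i in range(n_controls)]
    conditions = list(STRESS_TREATMENTS) + controls
    labels = {c: c for c in conditions}
    control_map = {
        t: controls[i % n_controls] for i, t in enumerate(STRESS_TREATMENTS)
    }
    return ExpressionDesign("stress", conditions, labels, control_map)


def simulate_expression_table(
    members: Mapping[str, Sequence[str]],
    design: ExpressionDesign,
    planted_correlations: Sequence[tuple[Sequence[str], float]] = (),
    noise_sd: float = 0.3,
    amplitude: float = 2.0,
    masked_genes: Sequence[str] = (),
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionTable, dict]:
    """Expression intensities with planted subfamily-level correlation.

    Each subfamily receives a latent log2 profile over the design's
    effective axis (tissue labels, or stress treatments relative to their
    controls); subfamilies in a planted clique share a scaled common factor
    achieving the target pairwise population correlation; member genes are
    subfamily latent + gene noise, exponentiated so intensities are
    positive.  ``masked_genes`` are withheld from the table (unmeasured).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if design.mode == "tissue":
        axis = list(dict.fromkeys(design.condition_labels[c] for c in design.conditions))
    elif design.mode == "stress":
        if design.control_map is None:
            raise ValueError("stress design requires a control map")
        axis = sorted(design.control_map)
    else:
        raise ValueError(f"unknown design mode {design.mode!r}")
    n_axis = len(axis)

    clique_of: dict[str, tuple[int, float]] = {}
    for ci, (names, r) in enumerate(planted_correlations):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation {r} outside [-1, 1]")
        if r < 0:
            raise ValueError(
                "negative clique correlations are not positive semi-definite "
                "under the shared-factor construction")
        for name in names:
            if name in clique_of:
                raise ValueError(f"subfamily {name} in two cliques")
            if name not in members:
                raise ValueError(f"planted subfamily {name} has no members")
            clique_of[name] = (ci, r)

    factors = {ci: rng.standard_normal(n_axis)
               for ci in range(len(planted_correlations))}
    latent: dict[str, np.ndarray] = {}
    for subfamily in sorted(members):
        own = rng.standard_normal(n_axis)
        if subfamily in clique_of:
            ci, r = clique_of[subfamily]
            latent[subfamily] = math.sqrt(r) * factors[ci] + math.sqrt(1 - r) * own
        else:
            latent[subfamily] = own

    masked = set(masked_genes)
    rows = {}
    for subfamily in sorted(members):
        z = latent[subfamily]
        axis_index = {a: i for i, a in enumerate(axis)}
        for gene in sorted(members[subfamily]):
            base = rng.normal(6.0, 1.0)
            values = np.empty(len(design.conditions))
            for j, cond in enumerate(design.conditions):
                noise = rng.normal(0.0, noise_sd)
                if design.mode == "tissue":
                    signal = amplitude * z[axis_index[design.condition_labels[cond]]]
                else:
                    signal = amplitude * z[axis_index[cond]] if cond in axis_index else 0.0
                values[j] = 2.0 ** (base + signal + noise)
            if gene not in masked:
                rows[gene] = values
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(design.conditions))
    df.index.name = "gene"
    table = ExpressionTable(values=df, condition_labels=dict(design.condition_labels),
                            control_map=(dict(design.control_map)
                                         if design.control_map else None))
    truth = {
        "mode": design.mode,
        "planted": [
            {"members": sorted(names), "r": r}
            for names, r in planted_correlations
        ],
        "masked_genes": sorted(masked),
    }
    return table, truth


def default_masking(members: Mapping[str, Sequence[str]],
                    excluded_subfamily: str | None,
                    measured_fraction: float = 0.7,
                    seed: int | np.random.Generator = 0) -> list[str]:
    """Mask genes so one chosen subfamily falls below the one-third rule
    while every other subfamily stays at or above it."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masked = []
    for subfamily in sorted(members):
        genes = sorted(members[subfamily])
        total = len(genes)
        if subfamily == excluded_subfamily:
            keep = max(0, math.ceil(total / 3) - 1)
        else:
            keep = max(math.ceil(total / 3), int(round(measured_fraction * total)))
        order = rng.permutation(total)
        masked.extend(genes[i] for i in order[keep:])
    return sorted(masked)
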