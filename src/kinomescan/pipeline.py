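"""End-to-end orchestration: identification -> classification -> structure ->
duplication -> expression -> networks -> summary.

A run is a pure function of (config, seed): identical inputs produce a
byte-identical output tree (file writes are canonically ordered and the run
log carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import classify as _classify
from . import duplication as _dup
from . import expression as _expr
from . import hmm as _hmm
from . import network as _net
from . import simulate as _sim
from . import structure as _struct
from .groups import UNCLASSIFIED
from .io import GeneModel, parse_genome_annotation

logger = logging.getLogger("kinomescan")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    seed: int = 1
    # identification / classification thresholds
    tau: float = 10.0
    min_coverage: float = 0.5
    tau_classify: float = 10.0
    epsilon: float = 0.5
    # duplication
    min_identity: float = 40.0
    min_block: int = 5
    max_gap: int = 25
    max_intervening: int = 5
    # expression / network
    r_min: float = 0.7
    p_max: float = 0.01
    hub_degree_tissue: int = 10
    hub_degree_stress: int = 15
    use_abs_correlation: bool = False
    planted_r: float = 0.9
    noise_sd: float = 0.3
    amplitude: float = 2.0
    measured_fraction: float = 0.7
    # masked below the one-third rule; deliberately outside the planted
    # correlation cliques so the planted network stays recoverable
    excluded_subfamily: str = "TKL_Pl-4"
    # inputs: either paths to real data, or synthetic generation (default)
    gff3: str | None = None
    protein_fasta: str | None = None
    cds_fasta: str | None = None
    clan_hmm: str | None = None
    subfamily_hmms: list[str] | None = None
    genome: _sim.GenomeSimConfig = field(default_factory=_sim.GenomeSimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        genome_raw = raw.pop("genome", None)
        config = cls(**raw)
        if genome_raw:
            blocks = genome_raw.pop("blocks", None)
            genome = _sim.GenomeSimConfig(**genome_raw)
            if blocks is not None:
                genome = dataclasses.replace(
                    genome,
                    blocks=tuple(_sim.BlockSpec(**b) for b in blocks),
                )
            config.genome = genome
        return config

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# summary arithmetic
# ---------------------------------------------------------------------------

def percentage(numerator: int, denominator: int) -> float:
    """Percent of ``numerator/denominator`` rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def survey_count_arithmetic(
    group_sizes: Mapping[str, int],
    kinome_total: int,
    tandem_genes: int,
    segmental_genes: int,
    wgd_genes: int,
    intron_containing: int,
    n_largest: int = 7,
) -> dict[str, float]:
    """Derived sums and percentages from printed integer counts.

    Given per-group sizes and genome-wide totals, recomputes the share of
    the largest groups, the tandem/segmental/WGD-associated gene fractions
    and the intronless complement — the count arithmetic a kinome survey
    reports alongside its tables.
    """
    largest = sorted(group_sizes.values(), reverse=True)[:n_largest]
    total_largest = sum(largest)
    intronless = kinome_total - intron_containing
    return {
        "largest_groups_total": float(total_largest),
        "largest_groups_pct": percentage(total_largest, kinome_total),
        "tandem_pct": percentage(tandem_genes, kinome_total),
        "segmental_pct": percentage(segmental_genes, kinome_total),
        "wgd_genes_pct": percentage(wgd_genes, kinome_total),
        "intronless_count": float(intronless),
        "intronless_pct": percentage(intronless, kinome_total),
    }


@dataclass
class KinomeSummary:
    genes_scanned: int
    kinase_candidates: int
    typical: int
    atypical: int
    unclassified: int
    group_sizes: dict[str, int]
    subfamily_sizes: dict[str, int]
    multi_domain: int
    intronless: int
    intron_min: int
    intron_max: int
    tandem_genes: int
    tandem_clusters: int
    segmental_genes: int
    collinearity_events: int
    era_events: dict[str, int]
    percentages: dict[str, float]

    def validate(self) -> None:
        if self.typical + self.atypical != self.kinase_candidates:
            raise ValueError("typical + atypical != genes passing the scan")
        classified = sum(self.group_sizes.values())
        if classified + self.unclassified != self.typical:
            raise ValueError("group totals + unclassified != typical")
        if sum(self.subfamily_sizes.values()) != classified:
            raise ValueError("subfamily totals != classified total")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def summarize_kinome(
    genes_scanned: int,
    best_hits: Mapping[str, _hmm.DomainHit],
    typical: Sequence[str],
    atypical: Sequence[str],
    assignments: Sequence[_classify.SubfamilyAssignment],
    domain_counts: Mapping[str, int],
    structure_records: Sequence[_struct.StructureRecord],
    tandem: Sequence[_dup.TandemCluster],
    blocks: Sequence[_dup.CollinearBlock],
    kaks: Mapping[tuple[str, str], _dup.KaKsResult],
) -> KinomeSummary:
    group_sizes: dict[str, int] = {}
    subfamily_sizes: dict[str, int] = {}
    unclassified = 0
    for a in assignments:
        if a.subfamily == UNCLASSIFIED:
            unclassified += 1
            continue
        group_sizes[a.group] = group_sizes.get(a.group, 0) + 1
        subfamily_sizes[a.subfamily] = subfamily_sizes.get(a.subfamily, 0) + 1
    intron_counts = [r.intron_count for r in structure_records]
    tandem_gene_ids = {g for c in tandem for g in c.members}
    segmental_ids = {g for b in blocks for a in b.anchors
                     for g in (a.gene_a, a.gene_b)}
    era_events: dict[str, int] = {e.value: 0 for e in _dup.WGDEra}
    events = 0
    for block in blocks:
        for anchor in block.anchors:
            events += 1
            res = kaks[(anchor.gene_a, anchor.gene_b)]
            era_events[_dup.assign_wgd_era(res.Ks).value] += 1
    n_typical = len(typical)
    percentages = {}
    if n_typical:
        percentages = {
            "typical_of_candidates": percentage(n_typical, len(best_hits)),
            "multi_domain": percentage(
                sum(1 for g in typical if domain_counts.get(g, 0) >= 2), n_typical),
            "intronless": percentage(
                sum(1 for r in structure_records if r.is_intronless), n_typical),
            "tandem_genes": percentage(len(tandem_gene_ids), n_typical),
            "segmental_genes": percentage(len(segmental_ids), n_typical),
        }
    summary = KinomeSummary(
        genes_scanned=genes_scanned,
        kinase_candidates=len(best_hits),
        typical=n_typical,
        atypical=len(atypical),
        unclassified=unclassified,
        group_sizes=dict(sorted(group_sizes.items())),
        subfamily_sizes=dict(sorted(subfamily_sizes.items())),
        multi_domain=sum(1 for g in typical if domain_counts.get(g, 0) >= 2),
        intronless=sum(1 for r in structure_records if r.is_intronless),
        intron_min=min(intron_counts) if intron_counts else 0,
        intron_max=max(intron_counts) if intron_counts else 0,
        tandem_genes=len(tandem_gene_ids),
        tandem_clusters=len(tandem),
        segmental_genes=len(segmental_ids),
        collinearity_events=events,
        era_events=era_events,
        percentages=percentages,
    )
    summary.validate()
    return summary


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: PipelineConfig
    genes: list[GeneModel]
    truth: _sim.TruthRecord | None
    best_hits: dict[str, _hmm.DomainHit]
    all_hits: dict[str, list[_hmm.DomainHit]]
    typical: list[str]
    atypical: list[str]
    domain_counts: dict[str, int]
    assignments: list[_classify.SubfamilyAssignment]
    tree: _classify.UnrootedTree
    concordance: float
    discordant: list[str]
    structure_records: list[_struct.StructureRecord]
    anchors: list[_dup.AnchorPair]
    blocks: list[_dup.CollinearBlock]
    kaks: dict[tuple[str, str], _dup.KaKsResult]
    tandem: list[_dup.TandemCluster]
    profiles_tissue: list[_expr.SubfamilyProfile]
    profiles_stress: list[_expr.SubfamilyProfile]
    net_tissue: _net.Network
    net_stress: _net.Network
    shared_edges: list[tuple[str, str]]
    summary: KinomeSummary


def _load_or_simulate(config: PipelineConfig):
    if config.gff3:
        if not (config.protein_fasta and config.cds_fasta):
            raise ValueError("real-input mode needs gff3, protein_fasta and cds_fasta")
        genes = parse_genome_annotation(config.gff3, config.protein_fasta,
                                        config.cds_fasta)
        if config.clan_hmm and config.subfamily_hmms:
            clan = _hmm.read_profile_hmm(config.clan_hmm)
            models = [_hmm.read_profile_hmm(p) for p in config.subfamily_hmms]
            library = {m.model_id: m for m in models}
        else:
            # no model files supplied: fall back to the packaged synthetic
            # library so the pipeline stays runnable on bare annotations
            clan, library = _sim.make_hmm_library(seed=config.seed)
        return genes, clan, library, None, None
    clan, library = _sim.make_hmm_library(seed=config.seed)
    sim = _sim.simulate_kinome_genome(config.genome, library,
                                      seed=config.seed + 1, clan=clan)
    return sim.genes, clan, library, sim.truth, sim


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute all stages in dependency order; optionally write the output
    tree (TSVs, newick, JSON summary, log) under ``outdir``."""
    genes, clan, library, truth, sim = _load_or_simulate(config)
    gene_by_id = {g.gene_id: g for g in genes}
    logger.info("pipeline: %d genes, clan model M=%d, %d subfamily models",
                len(genes), clan.M, len(library))

    # --- identification ---------------------------------------------------
    all_hits: dict[str, list[_hmm.DomainHit]] = {}
    best_hits: dict[str, _hmm.DomainHit] = {}
    for gene in genes:
        hits = _hmm.viterbi_domain_search(gene.protein, clan, tau=config.tau,
                                          seq_id=gene.gene_id)
        if hits:
            all_hits[gene.gene_id] = hits
            best_hits[gene.gene_id] = max(hits, key=lambda h: h.bit_score)
    typical, atypical = _hmm.filter_typical_kinases(best_hits, config.min_coverage)
    domain_counts = {
        g: _hmm.count_kinase_domains(all_hits[g], config.min_coverage)
        for g in typical
    }
    logger.info("identify: %d candidates, %d typical, %d atypical",
                len(best_hits), len(typical), len(atypical))

    # --- classification ----------------------------------------------------
    model_list = [library[name] for name in sorted(library)]
    assignments = [
        _classify.assign_subfamily(gene_by_id[g].protein, model_list,
                                   config.tau_classify, config.epsilon, gene_id=g)
        for g in typical
    ]
    subfamily_of = {a.gene_id: a.subfamily for a in assignments}
    # kinase-domain sequences (best clan hit region) for the phylogeny
    domain_seqs = {
        g: gene_by_id[g].protein[best_hits[g].seq_range[0]:best_hits[g].seq_range[1]]
        for g in typical
    }
    dm = _classify.distance_matrix(domain_seqs)
    tree = _classify.nj_tree(dm)
    concordance, discordant = _classify.classification_concordance(tree, assignments)
    logger.info("classify: %d subfamilies, NJ concordance %.3f",
                len({a.subfamily for a in assignments}), concordance)

    # --- gene structure ----------------------------------------------------
    structure_records = [_struct.count_introns(gene_by_id[g]) for g in sorted(typical)]

    # --- duplication -------------------------------------------------------
    typical_genes = [gene_by_id[g] for g in typical]
    anchors = _dup.detect_anchor_pairs(typical_genes, config.min_identity)
    positions = {g.gene_id: (g.chromosome, g.rank) for g in genes}
    blocks = _dup.chain_collinear_blocks(anchors, positions,
                                         config.min_block, config.max_gap)
    kaks = {}
    for block in blocks:
        for anchor in block.anchors:
            kaks[(anchor.gene_a, anchor.gene_b)] = _dup.compute_kaks(
                gene_by_id[anchor.gene_a].cds, gene_by_id[anchor.gene_b].cds,
                anchor.gene_a, anchor.gene_b)
    tandem = _dup.detect_tandem_clusters(typical_genes, subfamily_of,
                                         config.max_intervening)
    logger.info("duplication: %d anchors, %d blocks, %d tandem clusters",
                len(anchors), len(blocks), len(tandem))

    # --- expression --------------------------------------------------------
    members: dict[str, list[str]] = {}
    for a in assignments:
        if a.subfamily != UNCLASSIFIED:
            members.setdefault(a.subfamily, []).append(a.gene_id)
    masked = _sim.default_masking(members, config.excluded_subfamily,
                                  config.measured_fraction, seed=config.seed + 2)
    dispersed_present = [s for s in _sim.DISPERSED_SUBFAMILIES if s in members]
    cliques = []
    if len(dispersed_present) >= 6:
        cliques = [
            (tuple(dispersed_present[0:3]), config.planted_r),
            (tuple(dispersed_present[3:6]), config.planted_r),
        ]
    tissue_design = _sim.default_tissue_design()
    stress_design = _sim.default_stress_design()
    table_tissue, expr_truth_t = _sim.simulate_expression_table(
        members, tissue_design, cliques, config.noise_sd, config.amplitude,
        masked, seed=config.seed + 3)
    table_stress, expr_truth_s = _sim.simulate_expression_table(
        members, stress_design, cliques, config.noise_sd, config.amplitude,
        masked, seed=config.seed + 4)
    if truth is not None:
        truth.expression = {"tissue": expr_truth_t, "stress": expr_truth_s}
    profiles_tissue = _expr.aggregate_subfamily(table_tissue, members, "tissue")
    profiles_stress = _expr.aggregate_subfamily(table_stress, members, "stress")

    # --- networks ----------------------------------------------------------
    net_tissue = _net.build_network(profiles_tissue, config.r_min, config.p_max,
                                    config.use_abs_correlation)
    net_stress = _net.build_network(profiles_stress, config.r_min, config.p_max,
                                    config.use_abs_correlation)
    shared = _net.network_intersection(net_tissue, net_stress)
    logger.info("network: tissue %d nodes / %d edges; stress %d nodes / %d edges; "
                "%d shared edges", len(net_tissue.nodes), len(net_tissue.edges),
                len(net_stress.nodes), len(net_stress.edges), len(shared))

    # --- summary -----------------------------------------------------------
    summary = summarize_kinome(
        genes_scanned=len(genes), best_hits=best_hits, typical=typical,
        atypical=atypical, assignments=assignments, domain_counts=domain_counts,
        structure_records=structure_records, tandem=tandem, blocks=blocks,
        kaks=kaks,
    )

    result = RunResult(
        config=config, genes=genes, truth=truth, best_hits=best_hits,
        all_hits=all_hits, typical=list(typical), atypical=list(atypical),
        domain_counts=domain_counts, assignments=assignments, tree=tree,
        concordance=concordance, discordant=discordant,
        structure_records=structure_records, anchors=anchors, blocks=blocks,
        kaks=kaks, tandem=tandem, profiles_tissue=profiles_tissue,
        profiles_stress=profiles_stress, net_tissue=net_tissue,
        net_stress=net_stress, shared_edges=shared, summary=summary,
    )
    if outdir is not None:
        _write_outputs(result, sim, table_tissue, table_stress, Path(outdir))
    return result


def _write_outputs(result: RunResult, sim, table_tissue, table_stress,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    try:
        config_dict = result.config.to_dict()
        (outdir / "run_manifest.json").write_text(
            json.dumps({"config": config_dict, "seed": result.config.seed},
                       indent=2, sort_keys=True, default=str) + "\n")
        if sim is not None:
            sim.write(outdir / "inputs")
        flat_hits = [h for g in sorted(result.all_hits)
                     for h in result.all_hits[g]]
        _hmm.write_hits_tsv(flat_hits, outdir / "hits.tsv")
        (outdir / "typical.txt").write_text("\n".join(result.typical) + "\n")
        (outdir / "atypical.txt").write_text(
            ("\n".join(result.atypical) + "\n") if result.atypical else "")
        _classify.write_assignments_tsv(result.assignments,
                                        outdir / "assignments.tsv")
        result.tree.write_newick(outdir / "kinase_tree.nwk")
        (outdir / "concordance.json").write_text(json.dumps({
            "concordance": result.concordance,
            "discordant": result.discordant,
        }, indent=2, sort_keys=True) + "\n")
        subfam = {a.gene_id: a.subfamily for a in result.assignments}
        _struct.write_structure_tsv(result.structure_records, subfam,
                                    outdir / "introns.tsv")
        _dup.write_collinearity_tsv(result.blocks, result.kaks,
                                    outdir / "collinearity.tsv")
        _dup.write_tandem_tsv(result.tandem, outdir / "tandem.tsv")
        _expr.write_profiles_tsv(result.profiles_tissue,
                                 outdir / "subfamily_tissue.tsv")
        _expr.write_profiles_tsv(result.profiles_stress,
                                 outdir / "subfamily_stress.tsv")
        _expr.write_inclusion_tsv(result.profiles_tissue,
                                  outdir / "inclusion.tsv")
        _net.write_edges_tsv(result.net_tissue, outdir / "tissue_edges.tsv")
        _net.write_edges_tsv(result.net_stress, outdir / "stress_edges.tsv")
        _net.write_components_tsv(result.net_tissue,
                                  outdir / "tissue_components.tsv")
        _net.write_components_tsv(result.net_stress,
                                  outdir / "stress_components.tsv")
        _net.write_hubs_tsv(result.net_tissue, result.config.hub_degree_tissue,
                            outdir / "tissue_hubs.tsv")
        _net.write_hubs_tsv(result.net_stress, result.config.hub_degree_stress,
                            outdir / "stress_hubs.tsv")
        shared_lines = ["source\ttarget"] + [f"{a}\t{b}" for a, b in result.shared_edges]
        (outdir / "shared_edges.tsv").write_text("\n".join(shared_lines) + "\n")
        (outdir / "summary.json").write_text(
            json.dumps(result.summary.to_dict(), indent=2, sort_keys=True) + "\n")
    finally:
        logger.removeHandler(handler)
        handler.close()
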