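"""Ka/Ks (NG86), anchors, collinear chaining, WGD eras and tandem clusters.

The per-codon difference counting is validated against an independent
recursive enumeration of single-step mutational pathways over every pair of
sense codons; the chaining DP against brute-force enumeration of monotone
chains.
"""

import itertools
import math
import warnings

import numpy as np
import pytest

from conftest import make_gene
from kinomescan.duplication import (CODON_TABLE, AnchorPair, WGDEra,
                                    assign_wgd_era, chain_collinear_blocks,
                                    codon_differences, compute_kaks,
                                    detect_anchor_pairs,
                                    detect_tandem_clusters, jukes_cantor,
                                    make_anchor, percent_identity,
                                    synonymous_sites)

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


# --- NG86 oracle -----------------------------------------------------------

def oracle_codon_differences(a, b):
    """Recursive pathway enumeration, independent of the implementation."""
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return 0.0, 0.0
    results = []

    def step(current, remaining, sd, nd, blocked):
        if not remaining:
            results.append((blocked, sd, nd))
            return
        for pos in remaining:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            syn = CODON_TABLE[current] == CODON_TABLE[nxt]
            hit_stop = CODON_TABLE[nxt] == "*" and nxt != b
            step(nxt, [p for p in remaining if p != pos],
                 sd + (1 if syn else 0), nd + (0 if syn else 1),
                 blocked or hit_stop)

    step(a, diffs, 0, 0, False)
    usable = [r for r in results if not r[0]] or results
    return (sum(r[1] for r in usable) / len(usable),
            sum(r[2] for r in usable) / len(usable))


class TestNG86:
    def test_pathway_counts_match_oracle_on_all_codon_pairs(self):
        for a, b in itertools.product(SENSE_CODONS, SENSE_CODONS):
            assert codon_differences(a, b) == pytest.approx(
                oracle_codon_differences(a, b)), (a, b)

    def test_identical_cds(self):
        res = compute_kaks("ATGGCC", "ATGGCC")
        assert res.Sd == res.Nd == 0
        assert res.Ks == 0.0 and res.Ka == 0.0
        assert math.isnan(res.omega)

    def test_glycine_third_position_example(self):
        # 4 Gly codons, one synonymous third-position change: each Gly codon
        # contributes exactly one synonymous site (4-fold third position)
        res = compute_kaks("GGGGGGGGGGGG", "GGGGGGGGGGGA")
        assert res.S == pytest.approx(4.0)
        assert res.Sd == pytest.approx(1.0)
        assert res.pS == pytest.approx(0.25)
        assert res.Ks == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-4)
        assert res.Nd == 0

    def test_site_counts_conserve_total(self):
        rng = np.random.default_rng(8)
        from kinomescan.simulate import back_translate, sample_background
        for _ in range(5):
            a = back_translate(sample_background(rng, 40), rng)
            b = back_translate(sample_background(rng, 40), rng)
            res = compute_kaks(a, b)
            assert res.S + res.N == pytest.approx(res.aligned_codons * 3)

    def test_saturation_gives_nan_not_exception(self):
        # Leu TTA vs CTG: 2 synonymous differences over an average of 1.0
        # synonymous sites -> pS = 2 is beyond the Jukes-Cantor domain
        res = compute_kaks("TTA", "CTG")
        assert math.isnan(res.Ks)
        assert res.saturated
        assert math.isnan(jukes_cantor(0.75))
        assert math.isnan(jukes_cantor(0.9))

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            compute_kaks("ATGTAAGCC", "ATGGCCGCC")

    def test_gly_has_one_synonymous_site(self):
        assert synonymous_sites("GGG") == pytest.approx(1.0)
        assert synonymous_sites("TGG") == pytest.approx(0.0)  # Trp: none

    def test_matches_biopython_ng86(self):
        # independent implementation cross-check on gapless CDS pairs
        analysis = pytest.importorskip("Bio.Align.analysis")
        from Bio.Align import Alignment

        from kinomescan.simulate import (back_translate, sample_background,
                                         simulate_codon_divergence)
        rng = np.random.default_rng(6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for target_ks, target_ka in [(0.1, 0.0), (0.3, 0.1), (0.6, 0.2)]:
                a = back_translate(sample_background(rng, 120), rng)
                b = simulate_codon_divergence(a, target_ks, target_ka, rng)
                res = compute_kaks(a, b)
                dn, ds = analysis.calculate_dn_ds(Alignment([a, b]), method="NG86")
                assert res.Ka == pytest.approx(dn, abs=1e-9)
                assert res.Ks == pytest.approx(ds, abs=1e-9)


class TestKsRecovery:
    def test_simulated_pairs_recover_target_ks(self):
        # targets 0.1/0.3/0.6 at 300 codons, 50 seeded replicates each:
        # mean estimate within +-0.05 of target; Ka stays 0
        from kinomescan.simulate import (back_translate, sample_background,
                                         simulate_codon_divergence)
        rng = np.random.default_rng(5)
        for target in (0.1, 0.3, 0.6):
            estimates = []
            for _ in range(50):
                cds = back_translate(sample_background(rng, 300), rng)
                res = compute_kaks(cds, simulate_codon_divergence(cds, target, 0.0, rng))
                estimates.append(res.Ks)
                assert res.Ka == 0.0
            assert abs(np.mean(estimates) - target) <= 0.05

    def test_purifying_regime_gives_omega_below_one(self):
        # nonsynonymous acceptance below synonymous -> Ka/Ks < 1 in >= 95%
        from kinomescan.simulate import (back_translate, sample_background,
                                         simulate_codon_divergence)
        rng = np.random.default_rng(17)
        below = 0
        n = 50
        for _ in range(n):
            cds = back_translate(sample_background(rng, 200), rng)
            div = simulate_codon_divergence(cds, 0.4, 0.1, rng)
            below += compute_kaks(cds, div).omega < 1.0
        assert below >= 0.95 * n


# --- anchors ---------------------------------------------------------------

class TestAnchors:
    def test_identical_proteins_are_anchors(self):
        genes = [make_gene("a", protein="MKLVNPQRST" * 3),
                 make_gene("b", protein="MKLVNPQRST" * 3, rank=1)]
        anchors = detect_anchor_pairs(genes)
        assert len(anchors) == 1
        assert anchors[0].similarity == pytest.approx(100.0)

    def test_unrelated_proteins_are_not_anchors(self):
        from kinomescan.simulate import sample_background
        rng = np.random.default_rng(23)
        genes = [make_gene(f"g{i}", protein=sample_background(rng, 80), rank=i)
                 for i in range(4)]
        assert detect_anchor_pairs(genes, min_identity=40.0) == []

    def test_boundary_identity_is_inclusive(self):
        a = "WWWWCCCCCC"
        b = "WWWWDEFGHI"  # 4 of 10 columns identical, gapless optimum
        assert percent_identity(a, b) == pytest.approx(40.0)
        genes = [make_gene("a", protein=a), make_gene("b", protein=b, rank=1)]
        assert len(detect_anchor_pairs(genes, min_identity=40.0)) == 1

    def test_canonical_ordering_and_self_pair_rejection(self):
        anchor = make_anchor("z", "a", 50.0)
        assert (anchor.gene_a, anchor.gene_b) == ("a", "z")
        with pytest.raises(ValueError):
            make_anchor("a", "a", 50.0)


# --- chaining --------------------------------------------------------------

def brute_force_blocks(anchors, positions, min_block, max_gap):
    """Greedy best-first chains by exhaustive enumeration (oracle)."""
    def chains(points, descending):
        out = []

        def extend(chain, rest):
            out.append(chain)
            for idx, p in enumerate(rest):
                last = chain[-1]
                da = p[0] - last[0]
                db = (last[1] - p[1]) if descending else (p[1] - last[1])
                if 1 <= da <= max_gap and 1 <= db <= max_gap:
                    extend(chain + (p,), rest[idx + 1:])

        pts = sorted(points, key=lambda p: (p[0], p[1], p[2].gene_a, p[2].gene_b))
        for i, p in enumerate(pts):
            extend((p,), pts[i + 1:])
        return out

    by_pair = {}
    for anchor in anchors:
        ca, ra = positions[anchor.gene_a]
        cb, rb = positions[anchor.gene_b]
        key = tuple(sorted((ca, cb)))
        if ca <= cb:
            pt = (ra, rb, anchor) if ca != cb else (min(ra, rb), max(ra, rb), anchor)
        else:
            pt = (rb, ra, anchor)
        by_pair.setdefault(key, []).append(pt)
    blocks = []
    for key in sorted(by_pair):
        remaining = list(by_pair[key])
        while True:
            best = None
            for orientation, descending in (("plus", False), ("minus", True)):
                for chain in chains(remaining, descending):
                    cand = (-len(chain), orientation,
                            tuple((p[0], p[1]) for p in chain))
                    if best is None or cand < best:
                        best = cand
            if best is None or -best[0] < min_block:
                break
            chosen = {rc for rc in best[2]}
            picked = [p for p in remaining if (p[0], p[1]) in chosen]
            blocks.append((key, best[1], tuple(sorted(
                (p[2].gene_a, p[2].gene_b) for p in picked))))
            remaining = [p for p in remaining if (p[0], p[1]) not in chosen]
    return blocks


def _blocks_as_tuples(blocks):
    return [((b.chrom_a, b.chrom_b), b.orientation,
             tuple(sorted((a.gene_a, a.gene_b) for a in b.anchors)))
            for b in blocks]


class TestChaining:
    def _mk(self, coords, chrom_a="A", chrom_b="B"):
        positions = {}
        anchors = []
        for i, (ra, rb) in enumerate(coords):
            ga, gb = f"a{i:02d}", f"b{i:02d}"
            positions[ga] = (chrom_a, ra)
            positions[gb] = (chrom_b, rb)
            anchors.append(make_anchor(ga, gb, 80.0))
        return anchors, positions

    def test_six_increasing_anchors_form_one_plus_block(self):
        anchors, pos = self._mk([(i, i + 2) for i in range(6)])
        blocks = chain_collinear_blocks(anchors, pos)
        assert len(blocks) == 1
        assert blocks[0].orientation == "plus"
        assert blocks[0].size == 6

    def test_four_anchors_below_min_block(self):
        anchors, pos = self._mk([(i, i) for i in range(4)])
        assert chain_collinear_blocks(anchors, pos) == []

    def test_seven_reversed_anchors_form_minus_block(self):
        anchors, pos = self._mk([(i, 10 - i) for i in range(7)])
        blocks = chain_collinear_blocks(anchors, pos)
        assert len(blocks) == 1
        assert blocks[0].orientation == "minus"
        assert blocks[0].size == 7

    def test_gap_bound_is_enforced(self):
        # a jump of 30 ranks on chromosome B splits the chain
        coords = [(i, i) for i in range(5)] + [(5 + i, 40 + i) for i in range(5)]
        anchors, pos = self._mk(coords)
        blocks = chain_collinear_blocks(anchors, pos, min_block=5, max_gap=25)
        assert [b.size for b in blocks] == [5, 5]

    @pytest.mark.parametrize("case", range(20))
    def test_matches_brute_force_enumeration(self, case):
        rng = np.random.default_rng(900 + case)
        n = int(rng.integers(2, 13))
        coords = set()
        while len(coords) < n:
            coords.add((int(rng.integers(0, 15)), int(rng.integers(0, 15))))
        anchors, pos = self._mk(sorted(coords))
        min_block = int(rng.integers(2, 5))
        max_gap = int(rng.integers(2, 8))
        ours = _blocks_as_tuples(
            chain_collinear_blocks(anchors, pos, min_block, max_gap))
        oracle = brute_force_blocks(anchors, pos, min_block, max_gap)
        # ordering of the final report is canonical, not extraction order
        assert sorted(ours) == sorted(oracle)

    def test_unknown_gene_raises(self):
        anchors = [make_anchor("x", "y", 80.0)]
        with pytest.raises(KeyError):
            chain_collinear_blocks(anchors, {"x": ("A", 0)})


# --- WGD eras --------------------------------------------------------------

class TestWGDEra:
    @pytest.mark.parametrize("ks, era", [
        (0.20, WGDEra.ERA_13MYA),
        (0.60, WGDEra.ERA_59MYA),
        (1.20, WGDEra.OTHER),
        (0.06, WGDEra.ERA_13MYA),
        (0.39, WGDEra.ERA_13MYA),
        (0.40, WGDEra.ERA_59MYA),
        (0.80, WGDEra.ERA_59MYA),
        (0.05, WGDEra.OTHER),
        (0.395, WGDEra.OTHER),
        (float("nan"), WGDEra.OTHER),
    ])
    def test_binning(self, ks, era):
        assert assign_wgd_era(ks) is era

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_wgd_era(-0.1)

    def test_every_ks_maps_to_exactly_one_era(self):
        for ks in np.linspace(0.0, 2.0, 401):
            assert isinstance(assign_wgd_era(float(ks)), WGDEra)


# --- tandem clusters -------------------------------------------------------

class TestTandem:
    def _genes(self, spec):
        return [make_gene(g, chromosome=c, rank=r) for g, c, r in spec]

    def test_adjacent_same_subfamily_genes_cluster(self):
        genes = self._genes([("g1", "Chr01", 10), ("g2", "Chr01", 11),
                             ("g3", "Chr01", 13)])
        clusters = detect_tandem_clusters(genes, {g.gene_id: "F" for g in genes})
        assert len(clusters) == 1
        assert clusters[0].members == ["g1", "g2", "g3"]

    def test_different_chromosomes_never_cluster(self):
        genes = self._genes([("g1", "Chr01", 10), ("g2", "Chr02", 10)])
        assert detect_tandem_clusters(genes, {"g1": "F", "g2": "F"}) == []

    def test_window_sensitivity(self):
        genes = self._genes([("g1", "Chr01", 10), ("g2", "Chr01", 30)])
        labels = {"g1": "F", "g2": "F"}
        assert detect_tandem_clusters(genes, labels, max_intervening=5) == []
        clusters = detect_tandem_clusters(genes, labels, max_intervening=25)
        assert len(clusters) == 1

    def test_unassigned_genes_skipped_with_warning(self):
        genes = self._genes([("g1", "Chr01", 1), ("g2", "Chr01", 2),
                             ("g3", "Chr01", 3)])
        with pytest.warns(UserWarning):
            clusters = detect_tandem_clusters(genes, {"g1": "F", "g2": "F"})
        assert len(clusters) == 1
        assert clusters[0].members == ["g1", "g2"]
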