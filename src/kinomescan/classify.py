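"""Subfamily assignment by best-scoring profile HMM, and its phylogenetic
cross-check: pairwise kinase-domain distances, neighbour-joining trees, and
nearest-labelled-leaf concordance between the HMM labels and the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Phylo
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Phylo.BaseTree import Clade, Tree

from .groups import UNCLASSIFIED, group_for_subfamily
from .hmm import ProfileHMM, viterbi_best_score


@dataclass
class SubfamilyAssignment:
    gene_id: str
    subfamily: str
    group: str
    best_score: float
    margin: float
    ambiguous: bool


def assign_subfamily(
    seq: str,
    library: Sequence[ProfileHMM],
    tau_classify: float = 10.0,
    epsilon: float = 0.5,
    gene_id: str = "",
) -> SubfamilyAssignment:
    """Assign a sequence to the best-scoring subfamily model.

    Ties within ``epsilon`` bits are flagged ambiguous and broken by higher
    score, then lexicographic model id.  If every score is below
    ``tau_classify`` the gene is Unclassified.
    """
    if not library:
        raise ValueError("assign_subfamily: empty model library")
    scored = sorted(
        ((viterbi_best_score(seq, m), m.model_id) for m in library),
        key=lambda it: (-it[0], it[1]),
    )
    best_score, best_id = scored[0]
    margin = best_score - scored[1][0] if len(scored) > 1 else math.inf
    if best_score < tau_classify:
        subfamily = UNCLASSIFIED
    else:
        subfamily = best_id
    return SubfamilyAssignment(
        gene_id=gene_id,
        subfamily=subfamily,
        group=group_for_subfamily(subfamily),
        best_score=best_score,
        margin=margin,
        ambiguous=margin < epsilon,
    )


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _aligned_rows(a: str, b: str) -> tuple[str, str]:
    aln = _global_aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_kinase_distance(a: str, b: str) -> float:
    """p-distance over the non-gap columns of a global BLOSUM62 alignment
    (affine gaps: open 10, extend 1)."""
    if not a or not b:
        raise ValueError("pairwise_kinase_distance: empty sequence")
    row_a, row_b = _aligned_rows(a, b)
    columns = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not columns:
        raise ValueError("no aligned non-gap columns; distance undefined")
    mismatches = sum(1 for x, y in columns if x != y)
    return mismatches / len(columns)


def poisson_corrected(p: float) -> float:
    """Poisson-corrected distance, -ln(1 - p); an alternative metric."""
    if p >= 1.0:
        raise ValueError("p-distance of 1 cannot be Poisson corrected")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def write_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.d):
            lines.append(label + "  " + "  ".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """All-vs-all p-distance matrix over the given (gene id -> domain) map."""
    labels = sorted(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_kinase_distance(
                sequences[labels[i]], sequences[labels[j]]
            )
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class UnrootedTree:
    """An unrooted tree stored with a root trifurcation, newick-exportable.

    Negative neighbour-joining branch lengths are clamped to zero and the
    affected child clades recorded in ``clamped``.
    """

    tree: Tree
    clamped: list[str] = field(default_factory=list)

    @property
    def leaf_names(self) -> list[str]:
        return sorted(t.name for t in self.tree.get_terminals())

    def to_newick(self) -> str:
        buf = StringIO()
        Phylo.write(self.tree, buf, "newick")
        return buf.getvalue().strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise path lengths between all leaves."""
        leaves = sorted(self.tree.get_terminals(), key=lambda t: t.name)
        names = [t.name for t in leaves]
        # accumulate depths from the root, then use LCA depths
        depths = self.tree.depths(unit_branch_lengths=False)
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                lca = self.tree.common_ancestor([leaves[i], leaves[j]])
                d[i, j] = d[j, i] = (
                    depths[leaves[i]] + depths[leaves[j]] - 2 * depths[lca]
                )
        return names, d


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaks.

    At each step the pair minimizing ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``
    is joined (ties broken by the lexicographically smallest label pair);
    branch lengths use the standard NJ formulas, clamped at zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    d = dm.d.astype(float).copy()
    clades = [Clade(name=label) for label in dm.labels]
    # sort key for each active node: its smallest leaf label
    keys = list(dm.labels)
    clamped: list[str] = []

    while len(clades) > 3:
        m = len(clades)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        vi = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        ci, cj = clades[i], clades[j]
        if vi < 0:
            clamped.append(ci.name or keys[i])
            vi = 0.0
        if vj < 0:
            clamped.append(cj.name or keys[j])
            vj = 0.0
        ci.branch_length = vi
        cj.branch_length = vj
        new = Clade(clades=[ci, cj])
        new_key = min(keys[i], keys[j])
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dn[keep]
        d = d_new
        clades = [clades[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # terminal trifurcation: branch lengths from the three pairwise distances
    a, b, c = 0, 1, 2
    va = (d[a, b] + d[a, c] - d[b, c]) / 2
    vb = (d[a, b] + d[b, c] - d[a, c]) / 2
    vc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for clade, v, key in zip(clades, (va, vb, vc), keys):
        if v < 0:
            clamped.append(clade.name or key)
            v = 0.0
        clade.branch_length = v
    root = Clade(clades=list(clades))
    return UnrootedTree(tree=Tree(root=root, rooted=False), clamped=sorted(set(clamped)))


def classification_concordance(
    tree: UnrootedTree,
    assignments: Sequence[SubfamilyAssignment],
) -> tuple[float, list[str]]:
    """HMM-vs-tree concordance by the nearest-labelled-leaf rule.

    A leaf is concordant when its nearest other leaf by path length (ties
    broken lexicographically) carries the same HMM subfamily label.
    """
    label_of = {a.gene_id: a.subfamily for a in assignments}
    names, d = tree.leaf_distances()
    for name in names:
        if name not in label_of:
            raise KeyError(f"tree leaf {name!r} has no subfamily assignment")
    discordant = []
    n = len(names)
    for i in range(n):
        neighbours = sorted(
            ((d[i, j], names[j]) for j in range(n) if j != i),
            key=lambda it: (it[0], it[1]),
        )
        nearest = neighbours[0][1]
        if label_of[nearest] != label_of[names[i]]:
            discordant.append(names[i])
    return (n - len(discordant)) / n, sorted(discordant)


def write_assignments_tsv(
    assignments: Sequence[SubfamilyAssignment], path: str | Path
) -> None:
    lines = ["gene\tgroup\tsubfamily\tscore\tmargin\tambiguous"]
    for a in sorted(assignments, key=lambda a: a.gene_id):
        margin = "inf" if math.isinf(a.margin) else f"{a.margin:.4f}"
        lines.append(
            f"{a.gene_id}\t{a.group}\t{a.subfamily}\t{a.best_score:.4f}\t"
            f"{margin}\t{int(a.ambiguous)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
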