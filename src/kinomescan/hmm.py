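"""Profile hidden Markov models: text I/O, local Viterbi search, coverage.

The model is a standard match/insert/delete profile.  Scoring is fully local
on both the sequence and the model: a hit may begin at any match state
(uniform entry mass ``1/M``) and end at any match state (free exit), and
residues outside the hit are scored at the background, so partial-coverage
hits exist and the coverage statistic ``(last - first + 1) / M`` over match
states is meaningful.  Scores are log-odds against the background, in bits.

The text format is a minimal HMMER3-style dialect: ``NAME``/``LENG``/``ALPH``
headers, an ``HMM`` block with per-node match-emission, insert-emission and
transition lines holding negative natural logs (``*`` = impossible), and the
background distribution on the ``COMPO`` line.  Values are printed with 10
decimals so a write/read round trip reproduces probabilities to 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_TRANS_KEYS = ("mm", "mi", "md", "im", "ii", "dm", "dd")

Interval = tuple[int, int]


class HMMFormatError(ValueError):
    """Malformed or unsupported profile HMM text."""


@dataclass
class ProfileHMM:
    """A match/insert/delete profile over the 20-letter amino alphabet.

    ``match_emissions`` has shape (M, 20) (row k-1 = match state k);
    ``insert_emissions`` has shape (M+1, 20) (row k = insert state k, k=0..M);
    ``transitions[key]`` has length M+1 indexed by source node 0..M with keys
    mm, mi, md, im, ii, dm, dd.  Node 0 holds the begin transitions; node M's
    ``mm`` is the exit; structurally impossible entries are probability 0.
    """

    model_id: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict[str, np.ndarray]
    background: np.ndarray

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-6) -> None:
        M = self.M
        if M < 1:
            raise HMMFormatError("model must have at least one match state")
        if self.match_emissions.shape != (M, 20):
            raise HMMFormatError("match emission shape mismatch")
        if self.insert_emissions.shape != (M + 1, 20):
            raise HMMFormatError("insert emission shape mismatch")
        for name, rows in (("match", self.match_emissions),
                           ("insert", self.insert_emissions),
                           ("background", self.background.reshape(1, -1))):
            sums = rows.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > tol):
                raise HMMFormatError(f"{name} emission rows must sum to 1")
        t = self.transitions
        for k in range(M + 1):
            m_out = t["mm"][k] + t["mi"][k] + t["md"][k]
            if abs(m_out - 1.0) > tol:
                raise HMMFormatError(f"node {k}: match transitions sum {m_out}")
            i_out = t["im"][k] + t["ii"][k]
            if abs(i_out - 1.0) > tol:
                raise HMMFormatError(f"node {k}: insert transitions sum {i_out}")
            if 1 <= k:
                d_out = t["dm"][k] + t["dd"][k]
                if abs(d_out - 1.0) > tol:
                    raise HMMFormatError(f"node {k}: delete transitions sum {d_out}")


@dataclass
class DomainHit:
    """A scored local alignment of a sequence region to a profile model.

    ``seq_range`` is 0-based half-open on the sequence; ``model_range`` is
    1-based inclusive over match states; ``coverage`` is the matched fraction
    of the model, ``(last - first + 1) / M``.
    """

    model_id: str
    seq_id: str
    bit_score: float
    seq_range: Interval
    model_range: Interval
    coverage: float


def _prob(token: str) -> float:
    return 0.0 if token == "*" else math.exp(-float(token))


def _token(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.10f}"


def read_profile_hmm(path: str | Path) -> ProfileHMM:
    """Read a profile HMM from the minimal HMMER3-style text dialect."""
    lines = Path(path).read_text().splitlines()
    name = None
    leng = None
    alph = None
    i = 0
    while i < len(lines):
        tokens = lines[i].split()
        if not tokens:
            i += 1
            continue
        key = tokens[0]
        if key == "NAME":
            name = tokens[1]
        elif key == "LENG":
            leng = int(tokens[1])
        elif key == "ALPH":
            alph = tokens[1].lower()
        elif key == "HMM":
            break
        i += 1
    else:
        raise HMMFormatError("no HMM block found")
    if alph != "amino":
        raise HMMFormatError(f"unsupported alphabet {alph!r} (only 'amino')")
    if name is None or leng is None:
        raise HMMFormatError("missing NAME or LENG header")

    i += 2  # skip the HMM alphabet line and the transition header line
    background = np.full(20, 1.0 / 20.0)
    tokens = lines[i].split()
    if tokens and tokens[0] == "COMPO":
        background = np.array([_prob(t) for t in tokens[1:21]])
        i += 1
    insert_rows = [np.array([_prob(t) for t in lines[i].split()[:20]])]
    i += 1
    trans_rows = [np.array([_prob(t) for t in lines[i].split()[:7]])]
    i += 1
    match_rows = []
    node = 0
    while i < len(lines) and lines[i].split() and lines[i].split()[0] != "//":
        mt = lines[i].split()
        node += 1
        if int(mt[0]) != node:
            raise HMMFormatError(f"expected node {node}, found {mt[0]}")
        match_rows.append(np.array([_prob(t) for t in mt[1:21]]))
        insert_rows.append(np.array([_prob(t) for t in lines[i + 1].split()[:20]]))
        trans_rows.append(np.array([_prob(t) for t in lines[i + 2].split()[:7]]))
        i += 3
    if node != leng:
        raise HMMFormatError(f"LENG {leng} but {node} nodes present")
    trans_mat = np.array(trans_rows)
    transitions = {key: trans_mat[:, j].copy() for j, key in enumerate(_TRANS_KEYS)}
    model = ProfileHMM(
        model_id=name,
        match_emissions=np.array(match_rows),
        insert_emissions=np.array(insert_rows),
        transitions=transitions,
        background=background,
    )
    model.validate()
    return model


def write_profile_hmm(model: ProfileHMM, path: str | Path) -> None:
    out = [
        "HMMER3/f [kinomescan profile dialect]",
        f"NAME  {model.model_id}",
        f"LENG  {model.M}",
        "ALPH  amino",
        "HMM          " + "        ".join(AMINO_ACIDS),
        "            " + "     ".join(f"{a}->{b}" for a, b in
                                      (("m", "m"), ("m", "i"), ("m", "d"),
                                       ("i", "m"), ("i", "i"),
                                       ("d", "m"), ("d", "d"))),
    ]

    def emission_line(prefix: str, row: np.ndarray) -> str:
        return prefix + "  ".join(_token(p) for p in row)

    def trans_line(k: int) -> str:
        return "          " + "  ".join(_token(model.transitions[key][k])
                                        for key in _TRANS_KEYS)

    out.append(emission_line("  COMPO   ", model.background))
    out.append(emission_line("          ", model.insert_emissions[0]))
    out.append(trans_line(0))
    for k in range(1, model.M + 1):
        out.append(emission_line(f"{k:7d}   ", model.match_emissions[k - 1]))
        out.append(emission_line("          ", model.insert_emissions[k]))
        out.append(trans_line(k))
    out.append("//")
    Path(path).write_text("\n".join(out) + "\n")


def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


class _Scorer:
    """Precomputed log-odds tables for one model."""

    def __init__(self, model: ProfileHMM):
        self.M = model.M
        bg = model.background
        # log-odds emission scores; ambiguous residues score 0 (background)
        self.msc = _log2(model.match_emissions / bg)   # (M, 20)
        self.isc = _log2(model.insert_emissions / bg)  # (M+1, 20)
        self.t = {key: _log2(model.transitions[key]) for key in _TRANS_KEYS}
        self.entry = -math.log2(self.M)


def _viterbi_best(seq: str, sc: _Scorer, mask: np.ndarray | None):
    """Best local hit by Viterbi; returns (score, seq_range, model_range) or None.

    State values: VM[i][k] = best log-odds for a path ending in match state k
    having just emitted residue i; VI analogous for insert k; VD[i][k] for
    delete k after i residues have been consumed.  Entry B->Mk costs
    ``-log2(M)``; exit from any match state is free; flanking residues score 0.
    """
    L, M = len(seq), sc.M
    NEG = float("-inf")
    VM = np.full((L + 1, M + 1), NEG)
    VI = np.full((L + 1, M + 1), NEG)
    VD = np.full((L + 1, M + 1), NEG)
    # back pointers: 0 entry, 1 from M, 2 from I, 3 from D
    PM = np.zeros((L + 1, M + 1), dtype=np.int8)
    PI = np.zeros((L + 1, M + 1), dtype=np.int8)
    PD = np.zeros((L + 1, M + 1), dtype=np.int8)
    t = sc.t
    best = (NEG, -1, -1)
    zero_m = np.zeros(M)
    zero_i = np.zeros(M + 1)
    with np.errstate(invalid="ignore"):
        for i in range(1, L + 1):
            if mask is not None and mask[i - 1]:
                continue
            a = AA_INDEX.get(seq[i - 1], -1)
            mrow = sc.msc[:, a] if a >= 0 else zero_m
            irow = sc.isc[:, a] if a >= 0 else zero_i
            # match states, vectorized over k = 1..M
            cands = np.vstack((
                np.full(M, sc.entry),
                VM[i - 1, :M] + t["mm"][:M],
                VI[i - 1, :M] + t["im"][:M],
                VD[i - 1, :M] + t["dm"][:M],
            ))
            np.nan_to_num(cands, copy=False, nan=NEG)
            arg = cands.argmax(axis=0)
            VM[i, 1:] = mrow + cands[arg, np.arange(M)]
            PM[i, 1:] = arg
            # insert states
            ci0 = VM[i - 1, 1:] + t["mi"][1:]
            ci1 = VI[i - 1, 1:] + t["ii"][1:]
            np.nan_to_num(ci0, copy=False, nan=NEG)
            np.nan_to_num(ci1, copy=False, nan=NEG)
            from_m = ci0 >= ci1
            VI[i, 1:] = irow[1:] + np.where(from_m, ci0, ci1)
            PI[i, 1:] = np.where(from_m, 1, 2)
            # delete states: left-to-right scan (D_k depends on D_{k-1})
            vm_row = VM[i]
            vd_row = VD[i]
            tmd, tdd = t["md"], t["dd"]
            for k in range(2, M + 1):
                c0 = vm_row[k - 1] + tmd[k - 1]
                c1 = vd_row[k - 1] + tdd[k - 1]
                if c0 != c0:
                    c0 = NEG
                if c1 != c1:
                    c1 = NEG
                if c0 >= c1:
                    vd_row[k] = c0
                    PD[i][k] = 1
                else:
                    vd_row[k] = c1
                    PD[i][k] = 3
            row_best = int(VM[i, 1:].argmax()) + 1
            if VM[i][row_best] > best[0]:
                best = (VM[i][row_best], i, row_best)
    if not math.isfinite(best[0]):
        return None
    # traceback to find the entry cell
    score, i, k = best
    end_i, end_k = i, k
    state = "M"
    while True:
        if state == "M":
            ptr = PM[i][k]
            if ptr == 0:
                start_i, start_k = i, k
                break
            i, k = i - 1, k - 1
            state = "MID"[ptr - 1]
        elif state == "I":
            ptr = PI[i][k]
            i = i - 1
            state = "M" if ptr == 1 else "I"
        else:  # D
            ptr = PD[i][k]
            k = k - 1
            state = "M" if ptr == 1 else "D"
    return score, (start_i - 1, end_i), (start_k, end_k)


def viterbi_best_score(seq: str, model: ProfileHMM) -> float:
    """Best local Viterbi bit score of ``seq`` against ``model``."""
    if not seq:
        raise ValueError("empty sequence")
    res = _viterbi_best(seq, _Scorer(model), None)
    return res[0] if res is not None else float("-inf")


def viterbi_domain_search(
    seq: str,
    model: ProfileHMM,
    tau: float = 10.0,
    seq_id: str = "",
) -> list[DomainHit]:
    """All non-overlapping hits with bit score >= ``tau``.

    Found by iterated best-hit-then-mask: the best local alignment is
    reported, its sequence region is masked, and the search repeats until no
    remaining alignment reaches ``tau``.  Hits are returned sorted by
    sequence position; successive hit scores are non-increasing in discovery
    order by construction.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not math.isfinite(tau):
        raise ValueError("tau must be finite")
    sc = _Scorer(model)
    mask = np.zeros(len(seq), dtype=bool)
    hits: list[DomainHit] = []
    while True:
        res = _viterbi_best(seq, sc, mask)
        if res is None or res[0] < tau:
            break
        score, seq_range, model_range = res
        first, last = model_range
        hits.append(DomainHit(
            model_id=model.model_id,
            seq_id=seq_id,
            bit_score=score,
            seq_range=seq_range,
            model_range=model_range,
            coverage=(last - first + 1) / model.M,
        ))
        mask[seq_range[0]:seq_range[1]] = True
        if mask.all():
            break
    hits.sort(key=lambda h: h.seq_range)
    return hits


def filter_typical_kinases(
    best_hits: dict[str, DomainHit],
    min_coverage: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split genes into (typical, atypical) by model coverage of the best hit.

    A gene is typical when its best kinase-domain alignment covers at least
    ``min_coverage`` of the model (boundary inclusive); both lists are
    returned sorted, the atypical list being retained for reporting.
    """
    typical, atypical = [], []
    for gene_id in sorted(best_hits):
        (typical if best_hits[gene_id].coverage >= min_coverage else atypical).append(gene_id)
    return typical, atypical


def count_kinase_domains(hits: list[DomainHit], min_coverage: float = 0.5) -> int:
    """Number of (non-overlapping) hits meeting the coverage threshold."""
    return sum(1 for h in hits if h.coverage >= min_coverage)


def write_hits_tsv(hits: list[DomainHit], path: str | Path) -> None:
    """Tab-delimited hit table with fixed column order."""
    lines = ["gene\tmodel\tbit_score\tseq_start\tseq_end\tmodel_start\tmodel_end\tcoverage"]
    for h in hits:
        lines.append(
            f"{h.seq_id}\t{h.model_id}\t{h.bit_score:.4f}\t{h.seq_range[0]}\t"
            f"{h.seq_range[1]}\t{h.model_range[0]}\t{h.model_range[1]}\t{h.coverage:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
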