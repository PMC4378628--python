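"""Shared fixtures: a toy HMM library, a simulated kinome and one full
pipeline run (session-scoped — several suites score recovery against it)."""

from __future__ import annotations

import numpy as np
import pytest

from kinomescan.hmm import ProfileHMM
from kinomescan.io import GeneModel
from kinomescan.pipeline import PipelineConfig, run_pipeline
from kinomescan.simulate import (GenomeSimConfig, make_hmm_library,
                                 simulate_kinome_genome)


@pytest.fixture(scope="session")
def hmm_library():
    clan, library = make_hmm_library(seed=3)
    return clan, library


@pytest.fixture(scope="session")
def simulated_kinome(hmm_library):
    clan, library = hmm_library
    return simulate_kinome_genome(GenomeSimConfig(), library, seed=11, clan=clan)


@pytest.fixture(scope="session")
def pipeline_run():
    return run_pipeline(PipelineConfig(seed=1))


def random_profile_hmm(rng: np.random.Generator, M: int,
                       model_id: str = "rand") -> ProfileHMM:
    """A fully random (but valid) profile HMM, for oracle comparisons."""
    match = rng.dirichlet(np.ones(20), size=M)
    insert = rng.dirichlet(np.ones(20), size=M + 1)
    background = rng.dirichlet(np.ones(20))
    m_out = rng.dirichlet(np.ones(3), size=M + 1)
    i_out = rng.dirichlet(np.ones(2), size=M + 1)
    d_out = rng.dirichlet(np.ones(2), size=M + 1)
    trans = {
        "mm": m_out[:, 0].copy(), "mi": m_out[:, 1].copy(), "md": m_out[:, 2].copy(),
        "im": i_out[:, 0].copy(), "ii": i_out[:, 1].copy(),
        "dm": d_out[:, 0].copy(), "dd": d_out[:, 1].copy(),
    }
    # structural impossibilities at the boundary nodes
    trans["mm"][M] += trans["md"][M]
    trans["md"][M] = 0.0
    trans["dm"][M] = 1.0
    trans["dd"][M] = 0.0
    trans["dm"][0] = 1.0
    trans["dd"][0] = 0.0
    model = ProfileHMM(
        model_id=model_id, match_emissions=match, insert_emissions=insert,
        transitions=trans, background=background,
    )
    model.validate()
    return model


def make_gene(gene_id: str, chromosome: str = "Chr01", rank: int = 0,
              protein: str = "MKKA", cds: str | None = None,
              n_exons: int = 1) -> GeneModel:
    """A minimal consistent GeneModel for positional/structural tests."""
    if cds is None:
        cds = "ATGAAAAAAGCA"[: 3 * len(protein)]
    start = 1000 * (rank + 1)
    total = len(cds) + 3
    per = max(1, total // n_exons)
    exons = []
    pos = start
    remaining = total
    for i in range(n_exons):
        size = remaining if i == n_exons - 1 else per
        exons.append((pos, pos + size))
        pos += size + 50
        remaining -= size
    mrna = gene_id + ".1"
    return GeneModel(
        gene_id=gene_id, chromosome=chromosome, strand="+",
        span=(start, exons[-1][1]), isoforms={mrna: exons},
        representative_mrna=mrna, protein=protein, cds=cds, rank=rank,
    )
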