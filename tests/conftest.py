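"""Shared fixtures: hand-built chains and occupancy-simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ejcsplice.gene_model import ExonChain, GenomicInterval
from ejcsplice.occupancy import EJCOccupancyTest, occupancy_from_frame
from ejcsplice.simulate import (
    SimulationConfig,
    designate_events,
    simulate_gene_models,
    simulate_occupancy,
)


def make_chain(
    gene_id: str = "G1",
    chrom: str = "chr1",
    strand: str = "+",
    exon_coords=((100, 200), (300, 400), (500, 600), (700, 800), (900, 1000), (1100, 1200)),
    cds=None,
) -> ExonChain:
    """Chain from genomic exon coordinates (ascending); transcript orientation applied."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    if strand == "-":
        exons = list(reversed(exons))
    cds_start, cds_end = cds if cds else (None, None)
    return ExonChain(
        gene_id=gene_id,
        transcript_id=f"T_{gene_id}",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


@pytest.fixture
def six_exon_chain() -> ExonChain:
    return make_chain()


@pytest.fixture
def six_exon_chain_minus() -> ExonChain:
    return make_chain(gene_id="G2", strand="-")


def occupancy_replicate(seed: int, gamma: float, B: int = 2000, n_genes: int = 250):
    """One occupancy simulation + bootstrap test under the calibration design:
    exactly 200 affected genes, one 2-exon skip event each, no silent genes.

    Returns (p offset 1, p offset 2, m offset 1).
    """
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        enrichment_gamma=gamma,
        fraction_affected_genes=0.8,
        silent_gene_fraction=0.0,
        skip_classes=(2,),
    )
    rng = np.random.default_rng(cfg.seed)
    chains = simulate_gene_models(cfg, rng)
    truth = designate_events(chains, cfg, rng)
    occ = occupancy_from_frame(simulate_occupancy(chains, truth, cfg, rng), chains)
    res = EJCOccupancyTest(truth.skip_events(), occ).fit(B=B, seed=seed + 10_000)
    return (
        res.by_offset(1).p_two_tailed,
        res.by_offset(2).p_two_tailed,
        res.by_offset(1).m_events,
    )
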