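"""Shared fixtures: hand-built toy genes and session-scoped synthetic
datasets with planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import fragile_exon as fx
from fragile_exon.models import _build_model, revcomp


def build_gene(
    exon_seqs: list[str],
    intron_seqs: list[str],
    gene_id: str = "toy",
    strand: str = "+",
    flank: int = 20,
) -> tuple[fx.GeneModel, dict[str, str]]:
    """Construct a gene (and its one-chromosome genome) from transcript-
    oriented exon/intron sequences, through the same construction path
    as annotation parsing."""
    assert len(intron_seqs) == len(exon_seqs) - 1
    pieces = []
    for i, e in enumerate(exon_seqs):
        pieces.append(e)
        if i < len(intron_seqs):
            pieces.append(intron_seqs[i])
    unspliced = "".join(pieces).upper()
    chrom = f"chr_{gene_id}"
    left = "A" * flank
    right = "C" * flank
    tx_coords = []
    off = 0
    for i, e in enumerate(exon_seqs):
        tx_coords.append((off, off + len(e)))
        off += len(e)
        if i < len(intron_seqs):
            off += len(intron_seqs[i])
    if strand == "+":
        genome = {chrom: left + unspliced + right}
        coords = [(flank + s, flank + e) for s, e in tx_coords]
    else:
        genome = {chrom: revcomp(left + unspliced + right)}
        total = flank * 2 + len(unspliced)
        coords = sorted((total - flank - e, total - flank - s) for s, e in tx_coords)
    return _build_model(gene_id, chrom, strand, coords, genome), genome


def variants_to_records(models, variants, include_nonsense=True, spec=None):
    raws = fx.raw_variants_from_frame(variants)
    return fx.annotate_all(
        raws, models, spec or fx.DomainSpec(), include_nonsense=include_nonsense
    )


@dataclass
class SimBundle:
    config: fx.SimulationConfig
    models: list
    genome: dict
    variants: object
    truth: fx.SyntheticTruth
    records: list


def _make_bundle(n_genes, truth, n_snps, seed, **cfg_kwargs) -> SimBundle:
    cfg = fx.SimulationConfig(n_genes=n_genes, **cfg_kwargs)
    models, genome = fx.simulate_genes(cfg, rng=seed)
    variants, realized = fx.plant_pathogenic_snps(
        models, truth, n_snps, rng=seed + 1, hexamers=cfg.hexamers
    )
    records = variants_to_records(models, variants)
    return SimBundle(cfg, models, genome, variants, realized, records)


@pytest.fixture(scope="session")
def biased_bundle() -> SimBundle:
    """End-enriched, 3'-half-biased SNP placement (known truth)."""
    truth = fx.SyntheticTruth(domain_multipliers=(8.0, 4.0, 1.0), gene_half_bias=1.5)
    return _make_bundle(60, truth, 2500, seed=101)


@pytest.fixture(scope="session")
def uniform_bundle() -> SimBundle:
    """Uniform SNP placement: the null every test should not reject."""
    return _make_bundle(60, fx.SyntheticTruth(), 2500, seed=201)


@pytest.fixture(scope="session")
def dense_uniform_bundle() -> SimBundle:
    """Uniform placement dense enough that essentially every internal
    exon carries a SNP.  The length-based expected distribution is
    computed over SNP-bearing exons, so sparse uniform data show a mild
    apparent end enrichment (short exons only enter the expected set
    when hit); near-complete coverage removes that conditioning bias
    and makes the null exact."""
    return _make_bundle(25, fx.SyntheticTruth(), 2500, seed=201)
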