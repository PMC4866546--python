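"""Synthetic genomes, gene models and planted pathogenic SNPs.

The generator emulates the exon/intron architecture features the
pipeline measures on real annotations: heavy-tailed intron lengths
(log-normal), shifted negative-binomial exon lengths, a target
distribution of junction phases, configurable AGgt/agGT splice-site
tetranucleotide rates (optionally phase-0 biased), and ESE-like
hexamers implanted preferentially at exon ends.  Every generated gene
passes the validity filters by construction (ATG start, single terminal
stop, no internal stop, no ambiguous base, introns present).

Pathogenic SNPs are planted with per-position probabilities
proportional to the product of ground-truth effect multipliers
(exon domain, gene half, flanking intron size, exon class, ESE
density), so parameter-recovery tests know the planted truth,
including the implied splice-affecting fraction (the probability mass
attributable to the exon-end mechanism).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .density import HexamerSet, ese_end_density
from .models import (
    DomainSpec,
    GeneModel,
    STOP_CODONS,
    _build_model,
    classify_domain,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "default_hexamer_set",
    "simulate_genes",
    "plant_pathogenic_snps",
    "end_multiplier_for_fraction",
    "write_fixture_bundle",
]

_STOPS = tuple(STOP_CODONS)
_BASES = np.array(list("ACGT"))


def _codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    return {
        a + b + c: str(Seq(a + b + c).translate())
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
    }


_AA = _codon_table()


def default_hexamer_set() -> HexamerSet:
    """A synthetic stand-in ESE set: purine-rich hexamers built from
    pairs of non-stop codons (GAR-like), so codon-aligned implantation
    can never introduce a stop codon."""
    codons = ["GAA", "GAG", "AAG", "AGA", "GGA"]
    motifs = frozenset(a + b for a in codons for b in codons)
    return HexamerSet(motifs, name="synthetic_ese")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters (defaults emulate a human-like architecture).

    Exon counts and lengths are shifted negative binomials; intron
    lengths are log-normal (median ~1.3 kb, heavy tail).  Junction
    phases follow ``phase_distribution`` exactly up to multinomial
    sampling.  ``donor_AG_rate``/``acceptor_GT_rate`` set how often
    exon-terminal dinucleotides are forced to AG / GT, producing AGgt
    donors and agGT acceptors against the invariant gt..ag introns;
    ``donor_AG_phase0_boost`` multiplies the donor rate at phase-0
    junctions.  ESE hexamers are implanted codon-aligned at rate
    ``ese_base_rate`` per two-codon slot, times ``ese_end_enrichment``
    within ``ese_end_len`` bp of an exon end.
    """

    n_genes: int = 100
    exon_count_min: int = 3
    exon_count_extra_mean: float = 6.0
    exon_count_dispersion: float = 2.0
    exon_length_min: int = 50
    exon_length_extra_mean: float = 120.0
    exon_length_dispersion: float = 0.5
    intron_log_mean: float = 7.2
    intron_log_sd: float = 1.0
    intron_min: int = 50
    gc: float = 0.45
    phase_distribution: tuple[float, float, float] = (0.47, 0.30, 0.23)
    donor_AG_rate: float = 0.35
    acceptor_GT_rate: float = 0.20
    donor_AG_phase0_boost: float = 1.0
    ese_hexamers: Optional[HexamerSet] = None
    ese_base_rate: float = 0.02
    ese_end_enrichment: float = 3.0
    ese_end_len: int = 69
    flank_len: int = 60

    def __post_init__(self) -> None:
        if self.exon_length_min < 12:
            raise ValueError("exon_length_min must be >= 12")
        if self.exon_count_min < 2:
            raise ValueError("genes need at least 2 exons (introns required)")
        if abs(sum(self.phase_distribution) - 1.0) > 1e-9:
            raise ValueError("phase_distribution must sum to 1")
        for rate in (self.donor_AG_rate, self.acceptor_GT_rate, self.gc):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def hexamers(self) -> HexamerSet:
        return self.ese_hexamers or default_hexamer_set()


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted SNP-placement effects; all multipliers are relative
    per-position rate factors (1 = no effect).

    ``intron_size_effect`` scales internal-exon positions by
    (1 kb / nearest flanking intron bp) ** effect, so a positive effect
    favors short introns.  ``ese_coupling`` scales positions by
    1 / (1 + coupling * exon ESE end density).  ``implied_splice_fraction``
    and ``seed`` are filled in by :func:`plant_pathogenic_snps`.
    """

    domain_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)  # splice, end, core
    gene_half_bias: float = 1.0  # multiplier on 3'-gene-half positions
    intron_size_effect: float = 0.0
    phase00_effect: float = 1.0
    donor_AGgt_effect: float = 1.0
    ese_coupling: float = 0.0
    region: str = "all_exonic"
    implied_splice_fraction: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.domain_multipliers) <= 0 or self.gene_half_bias <= 0:
            raise ValueError("multipliers must be positive")
        if self.region not in ("all_exonic", "internal_exonic"):
            raise ValueError(f"unknown region {self.region!r}")


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _shifted_nbinom(gen, minimum: int, extra_mean: float, dispersion: float, size: int):
    p = dispersion / (dispersion + extra_mean)
    return minimum + gen.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------

def _random_codons(gen, n: int, gc: float) -> list[str]:
    """n random codons avoiding stop codons, GC-biased base draws."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = _BASES[gen.choice(4, size=(n, 3), p=probs)]
    codons = ["".join(row) for row in draws]
    for i, c in enumerate(codons):
        while c in STOP_CODONS:
            c = "".join(_BASES[gen.choice(4, size=3, p=probs)])
        codons[i] = c
    return codons


def _fix_stop(cds: list[str], codon_idx: int, locked: set[int], gen) -> None:
    """If the codon at codon_idx became a stop, mutate one unlocked base."""
    codon = "".join(cds[3 * codon_idx : 3 * codon_idx + 3])
    if codon not in STOP_CODONS:
        return
    for offset in gen.permutation(3):
        pos = 3 * codon_idx + int(offset)
        if pos in locked:
            continue
        for base in "CAGT":
            trial = list(codon)
            trial[offset] = base
            if "".join(trial) not in STOP_CODONS:
                cds[pos] = base
                return
    raise RuntimeError("could not resolve stop codon around forced junction bases")


def _gene_cds(gen, config: SimulationConfig, exon_lengths: list[int]) -> list[str]:
    """CDS as a list of single bases: ATG + random non-stop codons +
    one terminal stop, with junction dinucleotides forced per config."""
    total = sum(exon_lengths)
    n_codons = total // 3
    codons = _random_codons(gen, n_codons - 2, config.gc)
    stop = _STOPS[gen.integers(len(_STOPS))]
    cds = list("ATG" + "".join(codons) + stop)
    locked: set[int] = set(range(3)) | set(range(total - 3, total))
    boundaries = np.cumsum(exon_lengths)[:-1]  # CDS offset of each junction
    for b in boundaries:
        phase = b % 3
        donor_rate = config.donor_AG_rate * (
            config.donor_AG_phase0_boost if phase == 0 else 1.0
        )
        if gen.random() < min(donor_rate, 0.95):
            cds[b - 2], cds[b - 1] = "A", "G"
            locked.update((b - 2, b - 1))
            for ci in {(b - 2) // 3, (b - 1) // 3}:
                _fix_stop(cds, ci, locked, gen)
        if gen.random() < config.acceptor_GT_rate:
            cds[b], cds[b + 1] = "G", "T"
            locked.update((b, b + 1))
            for ci in {b // 3, (b + 1) // 3}:
                _fix_stop(cds, ci, locked, gen)
    _implant_hexamers(cds, exon_lengths, config, gen)
    return cds


def _implant_hexamers(
    cds: list[str], exon_lengths: list[int], config: SimulationConfig, gen
) -> None:
    """Codon-aligned two-codon ESE implants, end-enriched per exon."""
    motifs = sorted(config.hexamers.motifs)
    total = len(cds)
    start = 0
    for length in exon_lengths:
        end = start + length
        first_slot = 3 * math.ceil((start + 2) / 3)
        for p in range(first_slot, end - 7, 3):
            if p < 3 or p + 6 > total - 3:
                continue
            in_end = (p - start) < config.ese_end_len or (end - (p + 6)) < config.ese_end_len
            rate = config.ese_base_rate * (config.ese_end_enrichment if in_end else 1.0)
            if gen.random() < rate:
                motif = motifs[gen.integers(len(motifs))]
                cds[p : p + 6] = list(motif)
        start = end


def _random_intron(gen, config: SimulationConfig) -> str:
    length = max(config.intron_min, int(gen.lognormal(config.intron_log_mean, config.intron_log_sd)))
    probs = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    interior = "".join(_BASES[gen.choice(4, size=length - 4, p=probs)])
    return "GT" + interior + "AG"


def simulate_genes(
    config: SimulationConfig = SimulationConfig(), rng=None
) -> tuple[list[GeneModel], dict[str, str]]:
    """Generate gene models and their genome (one chromosome per gene).

    Returns ``(models, genome)`` with models built through the same
    construction path as FASTA/annotation parsing, strand-normalized;
    roughly half the genes are placed on the minus strand.
    """
    gen = _rng(rng)
    models: list[GeneModel] = []
    genome: dict[str, str] = {}
    phase_p = np.asarray(config.phase_distribution)
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:04d}"
        k = int(_shifted_nbinom(gen, config.exon_count_min,
                                config.exon_count_extra_mean,
                                config.exon_count_dispersion, 1)[0])
        lengths = list(
            _shifted_nbinom(gen, config.exon_length_min,
                            config.exon_length_extra_mean,
                            config.exon_length_dispersion, k)
        )
        # nudge lengths (0..2 bp) so each junction hits its target phase
        # and the total CDS is a codon multiple
        cum = 0
        for i in range(k - 1):
            target = int(gen.choice(3, p=phase_p))
            lengths[i] += (target - (cum + lengths[i])) % 3
            cum += lengths[i]
        lengths[-1] += (-(cum + lengths[-1])) % 3
        lengths = [int(x) for x in lengths]
        cds = _gene_cds(gen, config, lengths)
        introns = [_random_intron(gen, config) for _ in range(k - 1)]
        # unspliced transcript-oriented sequence
        pieces = []
        start = 0
        for i, length in enumerate(lengths):
            pieces.append("".join(cds[start : start + length]))
            start += length
            if i < k - 1:
                pieces.append(introns[i])
        unspliced = "".join(pieces)
        strand = "+" if gen.random() < 0.5 else "-"
        flank = "".join(_BASES[gen.integers(4, size=config.flank_len)])
        flank2 = "".join(_BASES[gen.integers(4, size=config.flank_len)])
        chrom_seq_tx = flank + unspliced + flank2
        chrom = f"chr_{gene_id}"
        span = len(unspliced)
        # transcript-oriented exon intervals within the span
        tx_coords = []
        offset = 0
        for i, length in enumerate(lengths):
            tx_coords.append((offset, offset + length))
            offset += length
            if i < k - 1:
                offset += len(introns[i])
        if strand == "+":
            genome[chrom] = chrom_seq_tx
            coords = [(config.flank_len + s, config.flank_len + e) for s, e in tx_coords]
        else:
            genome[chrom] = revcomp(chrom_seq_tx)
            total_len = len(chrom_seq_tx)
            coords = sorted(
                (total_len - (config.flank_len + e), total_len - (config.flank_len + s))
                for s, e in tx_coords
            )
        models.append(_build_model(gene_id, chrom, strand, coords, genome))
    return models, genome


# ---------------------------------------------------------------------
# SNP planting
# ---------------------------------------------------------------------

def _position_weights(
    models: Sequence[GeneModel],
    truth: SyntheticTruth,
    config_end_len: int = 69,
    spec: DomainSpec = DomainSpec(),
    hexamers: Optional[HexamerSet] = None,
):
    """Global per-position arrays (gene row, exon index, exon position,
    weight) over the plantable region; the final stop codon is excluded.
    Also returns the baseline weights with the exon-domain mechanism
    switched off (for the implied splice fraction)."""
    s_mult, e_mult, c_mult = truth.domain_multipliers
    rows = []
    for gi, model in enumerate(models):
        span_mid = math.ceil(model.gene_span / 2)
        g_before = 0
        cds_len = model.cds_length
        for i, exon in enumerate(model.exons):
            length = exon.length
            if exon.is_internal or truth.region == "all_exonic":
                p = np.arange(1, length + 1)
                d = np.minimum(p, length - p + 1)
                w = np.where(d <= spec.splice_site_max, s_mult,
                             np.where(d <= spec.end_max, e_mult, c_mult)).astype(float)
                base = np.full(length, c_mult, dtype=float)
                shared = np.ones(length)
                half3 = (g_before + p) > span_mid
                shared[half3] *= truth.gene_half_bias
                if exon.is_internal and truth.intron_size_effect != 0:
                    up_d, down_d = p - 1, length - p
                    iv = np.where(up_d < down_d, exon.upstream_intron_bp,
                                  np.where(up_d > down_d, exon.downstream_intron_bp,
                                           max(exon.upstream_intron_bp,
                                               exon.downstream_intron_bp)))
                    shared *= (1000.0 / iv) ** truth.intron_size_effect
                if exon.is_phase00:
                    shared *= truth.phase00_effect
                if exon.has_donor_AGgt:
                    shared *= truth.donor_AGgt_effect
                if truth.ese_coupling != 0 and hexamers is not None:
                    dens = ese_end_density(model.exon_seqs[i], hexamers, config_end_len)
                    shared *= 1.0 / (1.0 + truth.ese_coupling * dens)
                # exclude the terminal stop codon from plantable positions
                cds_coord = exon.cds_offset + p
                shared[cds_coord > cds_len - 3] = 0.0
                rows.append((gi, i + 1, p, w * shared, base * shared))
            g_before += length
            if exon.downstream_intron_bp is not None:
                g_before += exon.downstream_intron_bp
    gene_idx = np.concatenate([np.full(len(r[2]), r[0]) for r in rows])
    exon_idx = np.concatenate([np.full(len(r[2]), r[1]) for r in rows])
    pos = np.concatenate([r[2] for r in rows])
    w = np.concatenate([r[3] for r in rows])
    b = np.concatenate([r[4] for r in rows])
    return gene_idx, exon_idx, pos, w, b


def end_multiplier_for_fraction(
    models: Sequence[GeneModel],
    fraction: float,
    spec: DomainSpec = DomainSpec(),
    region: str = "internal_exonic",
) -> float:
    """Solve for the flank multiplier m (applied to splice-site and end
    domains, core = 1) so that an end-only placement mechanism implies
    a splice-affecting fraction of ``fraction``:
    f = (m - 1) W_f / (m W_f + W_c)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    w_f = w_c = 0
    for model in models:
        for exon in model.exons:
            if region == "internal_exonic" and not exon.is_internal:
                continue
            flank = min(exon.length, 2 * spec.end_max)
            w_f += flank
            w_c += exon.length - flank
    return (w_f + fraction * w_c) / (w_f * (1.0 - fraction))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def plant_pathogenic_snps(
    models: Sequence[GeneModel],
    truth: SyntheticTruth,
    n_snps: int,
    rng=None,
    spec: DomainSpec = DomainSpec(),
    hexamers: Optional[HexamerSet] = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant SNPs at distinct positions with probability proportional
    to the truth multipliers; returns the variant table (genomic-strand
    alleles) and the truth updated with the seed and the implied
    splice-affecting fraction (1 - sum(baseline)/sum(weights))."""
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    gen = _rng(rng)
    gene_idx, exon_idx, pos, w, b = _position_weights(
        models, truth, spec=spec, hexamers=hexamers
    )
    available = int(np.sum(w > 0))
    if n_snps > available:
        raise ValueError(f"n_snps={n_snps} exceeds {available} plantable positions")
    probs = w / w.sum()
    chosen = gen.choice(len(w), size=n_snps, replace=False, p=probs)
    records = []
    for i, ci in enumerate(sorted(chosen)):
        model = models[int(gene_idx[ci])]
        e_idx, e_pos = int(exon_idx[ci]), int(pos[ci])
        ref_tx = model.base_at(e_idx, e_pos)
        alt_tx = str(gen.choice([x for x in "ACGT" if x != ref_tx]))
        c = model.cds_coordinate(e_idx, e_pos)
        codon_i, within = (c - 1) // 3, (c - 1) % 3
        codon = model.cds_sequence[3 * codon_i : 3 * codon_i + 3]
        mutated = codon[:within] + alt_tx + codon[within + 1 :]
        if mutated in STOP_CODONS:
            consequence = "nonsense"
        else:
            consequence = "silent" if _AA[codon] == _AA[mutated] else "missense"
        # genomic coordinates and strand-adjusted alleles
        if model.strand == "+":
            s, _ = model.exon_coords[e_idx - 1]
            g_pos = s + e_pos
            ref_g, alt_g = ref_tx, alt_tx
        else:
            _, e = model.exon_coords[model.n_exons - e_idx]
            g_pos = e - e_pos + 1
            ref_g, alt_g = _COMP[ref_tx], _COMP[alt_tx]
        records.append(
            {
                "snp_id": f"snp{i + 1:06d}",
                "gene_id": model.gene_id,
                "chrom": model.chrom,
                "pos": g_pos,
                "ref": ref_g,
                "alt": alt_g,
                "consequence": consequence,
            }
        )
    implied = float(1.0 - b.sum() / w.sum())
    realized = dataclasses.replace(
        truth, implied_splice_fraction=implied, seed=seed
    )
    return pd.DataFrame(records), realized


# ---------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------

def write_fixture_bundle(
    out_dir: str | Path,
    models: Sequence[GeneModel],
    genome: dict[str, str],
    variants: pd.DataFrame,
    truth: SyntheticTruth,
    hexamers: Optional[HexamerSet] = None,
) -> dict[str, Path]:
    """Write genome FASTA, genePred TSV, variant TSV + VCF, hexamer
    list and truth JSON; re-parsing the files reproduces the in-memory
    objects field for field."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.genePred.tsv",
        "variants_tsv": out / "variants.tsv",
        "variants_vcf": out / "variants.vcf",
        "hexamers": out / "hexamers.txt",
        "truth": out / "truth.json",
    }
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()),
        paths["genome"],
        "fasta",
    )
    with open(paths["genes"], "w") as fh:
        for m in models:
            tx_start, tx_end = m.exon_coords[0][0], m.exon_coords[-1][1]
            starts = ",".join(str(s) for s, _ in m.exon_coords) + ","
            ends = ",".join(str(e) for _, e in m.exon_coords) + ","
            fh.write(
                "\t".join(
                    [
                        m.gene_id, m.chrom, m.strand,
                        str(tx_start), str(tx_end), str(tx_start), str(tx_end),
                        str(m.n_exons), starts, ends,
                    ]
                )
                + "\n"
            )
    variants.to_csv(paths["variants_tsv"], sep="\t", index=False)
    with open(paths["variants_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write(
            '##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="Consequence class">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\t.\t"
                f"GENE={row.gene_id};CONSEQUENCE={row.consequence}\n"
            )
    hx = hexamers or default_hexamer_set()
    with open(paths["hexamers"], "w") as fh:
        fh.write("\n".join(sorted(hx.motifs)) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
    return paths
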