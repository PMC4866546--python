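"""Join variants to gene models and derive per-SNP positional features.

Each pathogenic SNP is annotated with its exon, its 1-based position
within the exon, the distance to the nearest junction and the resulting
exon domain (splice_site / end / core), its exon half, its gene half
(position within the unspliced ATG->stop span) and CDS half, the size
of the nearest flanking intron (internal exons only), and the exon's
class flags (symmetric (0,0) phase, donor AGgt, acceptor agGT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .models import DomainSpec, Exon, GeneModel, classify_domain

__all__ = [
    "RawVariant",
    "SnpRecord",
    "parse_variants",
    "annotate_snp",
    "annotate_all",
    "nearest_intron_size",
    "gene_and_cds_half",
    "classify_domain",
    "records_to_frame",
]

CONSEQUENCES = {"missense", "silent", "nonsense"}


@dataclass(frozen=True)
class RawVariant:
    """One variant as read from a VCF/TSV, genomic-strand alleles."""

    snp_id: str
    gene_id: str
    chrom: str
    pos: int  # 1-based genomic
    ref: str
    alt: str
    consequence: str


@dataclass
class SnpRecord:
    """One exonic SNP with all derived positional features.

    Alleles are transcript-oriented (complemented for minus-strand
    genes).  ``d_nearest`` is the 1-based distance to the nearest exon
    junction; ``gene_half`` refers to the unspliced ATG->stop span and
    ``cds_half`` to the spliced CDS coordinate, midpoints assigned 5p.
    """

    snp_id: str
    gene_id: str
    ref: str
    alt: str
    consequence: str
    exon_index: int
    exon_position: int
    exon_length: int
    d_nearest: int
    domain: str
    exon_half: str
    gene_half: str
    cds_half: str
    nearest_intron_bp: Optional[int]
    is_internal: bool
    phase00: bool
    donor_AGgt: bool
    acceptor_agGT: bool


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base.upper()]


# ---------------------------------------------------------------------
# Input parsing
# ---------------------------------------------------------------------

_TSV_COLUMNS = ["snp_id", "gene_id", "chrom", "pos", "ref", "alt", "consequence"]


def parse_variants(
    variant_table: str | Path,
    models: Iterable[GeneModel],
    fmt: Optional[str] = None,
) -> tuple[list[RawVariant], list[RawVariant]]:
    """Read a variant TSV or VCF and bind records to gene models.

    Returns ``(exonic, non_exonic)``: records whose position falls
    inside a coding exon of their gene, and those that do not (flagged
    and excluded from exonic analyses, not an error).  TSV columns:
    snp_id, gene_id, chrom, pos, ref, alt, consequence.  VCF rows carry
    the gene id and consequence in INFO tags ``GENE`` and ``CONSEQUENCE``.
    """
    path = Path(variant_table)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    raw: list[RawVariant] = []
    if fmt == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                info = dict(rec.info)
                raw.append(
                    RawVariant(
                        snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                        gene_id=str(info["GENE"]),
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=rec.alts[0].upper(),
                        consequence=str(info.get("CONSEQUENCE", "missense")),
                    )
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: variant TSV missing columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            raw.append(
                RawVariant(
                    snp_id=row.snp_id,
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref.upper(),
                    alt=row.alt.upper(),
                    consequence=row.consequence,
                )
            )
    by_id = {m.gene_id: m for m in models}
    exonic: list[RawVariant] = []
    non_exonic: list[RawVariant] = []
    for v in raw:
        model = by_id.get(v.gene_id)
        if model is None or model.locate(v.pos) is None:
            non_exonic.append(v)
        else:
            exonic.append(v)
    return exonic, non_exonic


# ---------------------------------------------------------------------
# Per-SNP features
# ---------------------------------------------------------------------

def nearest_intron_size(exon: Exon, exon_position: int) -> int:
    """Size of the flanking intron nearest to a position in an internal
    exon; at an exact tie the LONGER of the two introns is returned."""
    if not exon.is_internal:
        raise ValueError(f"exon {exon.index} is not internal; nearest intron undefined")
    up_dist = exon_position - 1
    down_dist = exon.length - exon_position
    if up_dist < down_dist:
        return exon.upstream_intron_bp
    if up_dist > down_dist:
        return exon.downstream_intron_bp
    return max(exon.upstream_intron_bp, exon.downstream_intron_bp)


def gene_and_cds_half(model: GeneModel, variant_pos: int) -> tuple[str, str]:
    """(gene_half, cds_half) for a genomic 1-based exonic position.

    gene_half splits the unspliced ATG->stop span in two; cds_half
    splits the spliced CDS.  A position at the exact midpoint is
    assigned 5p.
    """
    g = model.gene_position(variant_pos)
    gene_half = "5p" if g <= math.ceil(model.gene_span / 2) else "3p"
    exon_index, exon_position = model.locate(variant_pos)
    c = model.cds_coordinate(exon_index, exon_position)
    cds_half = "5p" if c <= math.ceil(model.cds_length / 2) else "3p"
    return gene_half, cds_half


def annotate_snp(
    variant: RawVariant, model: GeneModel, spec: DomainSpec = DomainSpec()
) -> SnpRecord:
    """Populate every positional feature for one exonic variant."""
    loc = model.locate(variant.pos)
    if loc is None:
        raise ValueError(f"variant {variant.snp_id} is not exonic in {variant.gene_id}")
    exon_index, exon_position = loc
    genome_base = model.base_at(exon_index, exon_position)
    ref_tx = variant.ref if model.strand == "+" else _complement(variant.ref)
    alt_tx = variant.alt if model.strand == "+" else _complement(variant.alt)
    if ref_tx != genome_base:
        raise ValueError(
            f"variant {variant.snp_id}: ref allele {variant.ref!r} does not match "
            f"the genome base at {variant.chrom}:{variant.pos} "
            f"({genome_base!r} on the transcript strand of {variant.gene_id})"
        )
    exon = model.exons[exon_index - 1]
    d = min(exon_position, exon.length - exon_position + 1)
    gene_half, cds_half = gene_and_cds_half(model, variant.pos)
    return SnpRecord(
        snp_id=variant.snp_id,
        gene_id=variant.gene_id,
        ref=ref_tx,
        alt=alt_tx,
        consequence=variant.consequence,
        exon_index=exon_index,
        exon_position=exon_position,
        exon_length=exon.length,
        d_nearest=d,
        domain=classify_domain(d, spec),
        exon_half="5p" if exon_position <= math.ceil(exon.length / 2) else "3p",
        gene_half=gene_half,
        cds_half=cds_half,
        nearest_intron_bp=(
            nearest_intron_size(exon, exon_position) if exon.is_internal else None
        ),
        is_internal=exon.is_internal,
        phase00=exon.is_phase00,
        donor_AGgt=exon.has_donor_AGgt,
        acceptor_agGT=exon.has_acceptor_agGT,
    )


def annotate_all(
    variants: Iterable[RawVariant],
    models: Iterable[GeneModel],
    spec: DomainSpec = DomainSpec(),
    include_nonsense: bool = False,
) -> list[SnpRecord]:
    """Annotate every exonic variant; by default nonsense SNPs are
    dropped (their likely mode of pathology is not splice-related); an
    include-nonsense switch reruns all analyses with them retained."""
    by_id = {m.gene_id: m for m in models}
    out = []
    for v in variants:
        if not include_nonsense and v.consequence == "nonsense":
            continue
        out.append(annotate_snp(v, by_id[v.gene_id], spec))
    return out


def records_to_frame(records: Iterable[SnpRecord]) -> pd.DataFrame:
    """Per-SNP annotation table (one row per SNP, all derived columns)."""
    return pd.DataFrame([vars(r) for r in records])


def raw_variants_from_frame(df: pd.DataFrame) -> list[RawVariant]:
    """RawVariants from an in-memory variant table (same columns as the
    variant TSV: snp_id, gene_id, chrom, pos, ref, alt, consequence)."""
    return [
        RawVariant(
            snp_id=str(r.snp_id), gene_id=str(r.gene_id), chrom=str(r.chrom),
            pos=int(r.pos), ref=str(r.ref).upper(), alt=str(r.alt).upper(),
            consequence=str(r.consequence),
        )
        for r in df.itertuples(index=False)
    ]
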