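"""Pathogenic-SNP density (Dpi), ESE end density, and their correlates.

Dpi of an exon is its pathogenic SNP count divided by its length (an
exon without SNPs has Dpi = 0); half-Dpi divides each half's SNP count
by half the exon length.  ESE density of a sequence window is the
fraction of hexamer start positions (window length - 5, overlapping
matches counted) whose 6-mer belongs to the ESE set; an exon's end
density is the mean over its two terminal 69-bp windows, or a single
whole-exon window when the exon is shorter than 138 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import GeneModel
from .variants import SnpRecord

__all__ = [
    "HexamerSet",
    "DpiRecord",
    "read_hexamers",
    "ese_end_density",
    "compute_dpi",
    "build_dpi_records",
    "dpi_records_to_frame",
    "gk_gamma",
    "correlate_dpi_intron",
    "intragene_sign_test",
    "correlate_dpi_ese",
]


@dataclass(frozen=True)
class HexamerSet:
    """A named collection of ESE candidate 6-mers (uppercase ACGT)."""

    motifs: frozenset[str]
    name: str = "custom"

    def __post_init__(self) -> None:
        bad = [m for m in self.motifs if len(m) != 6 or set(m) - set("ACGT")]
        if bad:
            raise ValueError(f"invalid hexamers: {sorted(bad)[:5]}")

    def __contains__(self, item: str) -> bool:
        return item in self.motifs

    def __len__(self) -> int:
        return len(self.motifs)


def read_hexamers(path: str | Path, name: Optional[str] = None) -> HexamerSet:
    """Read a plain-text hexamer list, one uppercase 6-mer per line."""
    motifs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if line and not line.startswith("#"):
                motifs.add(line)
    return HexamerSet(frozenset(motifs), name=name or Path(path).stem)


def _window_density(seq: str, hexamers: HexamerSet) -> float:
    starts = len(seq) - 5
    hits = sum(1 for i in range(starts) if seq[i : i + 6] in hexamers)
    return hits / starts


def ese_end_density(
    exon_sequence: str, hexamers: HexamerSet, end_len: int = 69
) -> float:
    """ESE density of an exon's end regions (see module docstring)."""
    seq = exon_sequence.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    if len(seq) >= 2 * end_len:
        return 0.5 * (
            _window_density(seq[:end_len], hexamers)
            + _window_density(seq[-end_len:], hexamers)
        )
    return _window_density(seq, hexamers)


@dataclass
class DpiRecord:
    """Per-exon densities and flanking intron sizes (internal exons)."""

    gene_id: str
    exon_index: int
    exon_length: int
    snp_count: int
    dpi: float
    dpi5: float
    dpi3: float
    ese_end_density: Optional[float]
    upstream_intron_bp: int
    downstream_intron_bp: int
    flanking_intron_bp: int  # nearest relevant intron for exon-level tests


def dpi_records_to_frame(records: Sequence[DpiRecord]):
    """Per-exon table (gene, exon, dpi, half-dpi, ESE density, intron
    sizes) for TSV export."""
    import pandas as pd

    return pd.DataFrame([vars(r) for r in records])


def compute_dpi(exon_length: int, snp_count: int, snp_count_5p: int) -> tuple[float, float, float]:
    """(dpi, dpi5, dpi3) from an exon's SNP counts.

    The 5' half is positions 1..ceil(length/2); each half-Dpi divides
    by half the exon length.
    """
    if exon_length <= 0:
        raise ValueError("exon_length must be positive")
    half = exon_length / 2
    return (
        snp_count / exon_length,
        snp_count_5p / half,
        (snp_count - snp_count_5p) / half,
    )


def build_dpi_records(
    models: Sequence[GeneModel],
    records: Iterable[SnpRecord],
    hexamers: Optional[HexamerSet] = None,
    end_len: int = 69,
) -> list[DpiRecord]:
    """One DpiRecord per internal exon of every gene carrying >= 1
    annotated SNP (disease genes); zero-SNP exons get Dpi = 0.

    The exon-level flanking intron is the intron nearest the exon's
    median SNP position (the longer one on an exact tie), or the
    shorter of the two flanking introns for exons without SNPs.
    """
    per_exon: dict[tuple[str, int], list[int]] = {}
    genes_with_snps = set()
    for r in records:
        genes_with_snps.add(r.gene_id)
        per_exon.setdefault((r.gene_id, r.exon_index), []).append(r.exon_position)
    out = []
    for model in models:
        if model.gene_id not in genes_with_snps:
            continue
        for exon in model.exons:
            if not exon.is_internal:
                continue
            positions = per_exon.get((model.gene_id, exon.index), [])
            n5 = sum(1 for p in positions if p <= math.ceil(exon.length / 2))
            dpi, dpi5, dpi3 = compute_dpi(exon.length, len(positions), n5)
            if positions:
                mid = float(np.median(positions))
                up_d, down_d = mid - 1, exon.length - mid
                if up_d < down_d:
                    flank = exon.upstream_intron_bp
                elif up_d > down_d:
                    flank = exon.downstream_intron_bp
                else:
                    flank = max(exon.upstream_intron_bp, exon.downstream_intron_bp)
            else:
                flank = min(exon.upstream_intron_bp, exon.downstream_intron_bp)
            density = (
                ese_end_density(model.exon_seqs[exon.index - 1], hexamers, end_len)
                if hexamers is not None
                else None
            )
            out.append(
                DpiRecord(
                    gene_id=model.gene_id,
                    exon_index=exon.index,
                    exon_length=exon.length,
                    snp_count=len(positions),
                    dpi=dpi,
                    dpi5=dpi5,
                    dpi3=dpi3,
                    ese_end_density=density,
                    upstream_intron_bp=exon.upstream_intron_bp,
                    downstream_intron_bp=exon.downstream_intron_bp,
                    flanking_intron_bp=flank,
                )
            )
    return out


# ---------------------------------------------------------------------
# Rank association
# ---------------------------------------------------------------------

def _concordance_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    n = len(x)
    C = D = 0
    chunk = max(1, 5_000_000 // max(n, 1))
    for i in range(0, n, chunk):
        dx = np.sign(x[i : i + chunk, None] - x[None, :])
        dy = np.sign(y[i : i + chunk, None] - y[None, :])
        prod = dx * dy
        C += int(np.sum(prod > 0))
        D += int(np.sum(prod < 0))
    return C // 2, D // 2  # every unordered pair was visited twice


def gk_gamma(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Goodman-Kruskal gamma with asymptotic normal p-value.

    gamma = (C - D)/(C + D) over all pairs, tied pairs excluded; the
    p-value uses z = gamma * sqrt((C + D)/(n (1 - gamma^2))), the
    standard large-sample approximation.  Gamma is preferred over rho
    when the data carry many ties (e.g. zero-Dpi exons).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    C, D = _concordance_counts(x, y)
    if C + D == 0:
        raise ValueError("gamma undefined: all pairs tied")
    gamma = (C - D) / (C + D)
    if gamma * gamma >= 1.0:
        return gamma, 0.0
    z = gamma * math.sqrt((C + D) / (len(x) * (1.0 - gamma * gamma)))
    return gamma, float(2.0 * stats.norm.sf(abs(z)))


def correlate_dpi_intron(
    dpi_records: Sequence[DpiRecord], scope: str = "snp_bearing_only"
) -> dict:
    """Spearman correlation of Dpi against log flanking intron size.

    ``scope``: ``snp_bearing_only`` restricts to exons with >= 1 SNP
    (the primary analysis); ``all_internal`` keeps zero-Dpi exons.
    """
    if scope == "snp_bearing_only":
        recs = [r for r in dpi_records if r.snp_count > 0]
    elif scope == "all_internal":
        recs = list(dpi_records)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(recs) < 3:
        raise ValueError("need >= 3 records")
    dpi = np.array([r.dpi for r in recs])
    intron = np.log(np.array([r.flanking_intron_bp for r in recs], dtype=float))
    if np.all(dpi == dpi[0]) or np.all(intron == intron[0]):
        return {"rho": float("nan"), "p": float("nan"), "n": len(recs),
                "status": "not_computable"}
    rho, p = stats.spearmanr(dpi, intron)
    return {"rho": float(rho), "p": float(p), "n": len(recs), "status": "ok"}


def intragene_sign_test(
    dpi_records: Sequence[DpiRecord],
    min_snp_exons: int = 5,
    scope: str = "all_internal",
) -> dict:
    """Within-gene sign test of the half-Dpi vs flanking-intron trend.

    For every qualifying gene (>= ``min_snp_exons`` internal exons with
    SNPs) the Spearman rho between half-Dpi and the adjacent flanking
    intron size is computed over two points per internal exon:
    (dpi5, upstream intron) and (dpi3, downstream intron).  Genes with
    rho = 0 or undefined rho are excluded; the one-sided exact binomial
    p tests for an excess of negative correlations at p0 = 0.5.
    """
    by_gene: dict[str, list[DpiRecord]] = {}
    for r in dpi_records:
        by_gene.setdefault(r.gene_id, []).append(r)
    n_neg = n_pos = 0
    rhos: dict[str, float] = {}
    for gene_id, recs in by_gene.items():
        if sum(1 for r in recs if r.snp_count > 0) < min_snp_exons:
            continue
        if scope == "snp_bearing_only":
            recs = [r for r in recs if r.snp_count > 0]
        xs, ys = [], []
        for r in recs:
            xs.extend([r.dpi5, r.dpi3])
            ys.extend([r.upstream_intron_bp, r.downstream_intron_bp])
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            continue
        rho = stats.spearmanr(xs, ys).statistic
        if not np.isfinite(rho) or rho == 0:
            continue
        rhos[gene_id] = float(rho)
        if rho < 0:
            n_neg += 1
        else:
            n_pos += 1
    if n_neg + n_pos == 0:
        raise ValueError("no qualifying genes with a defined intragene correlation")
    p = float(stats.binomtest(n_neg, n_neg + n_pos, 0.5, alternative="greater").pvalue)
    return {"n_negative": n_neg, "n_positive": n_pos, "p": p, "rho_by_gene": rhos}


def correlate_dpi_ese(dpi_records: Sequence[DpiRecord]) -> dict:
    """Spearman and Goodman-Kruskal gamma between ESE end density and
    Dpi over all internal exons of disease genes (zero-Dpi included)."""
    recs = [r for r in dpi_records if r.ese_end_density is not None]
    if len(recs) < 3:
        raise ValueError("need >= 3 exons with an ESE density")
    density = [r.ese_end_density for r in recs]
    dpi = [r.dpi for r in recs]
    rho, rho_p = stats.spearmanr(density, dpi)
    gamma, gamma_p = gk_gamma(density, dpi)
    return {
        "rho": float(rho),
        "rho_p": float(rho_p),
        "gamma": gamma,
        "gamma_p": gamma_p,
        "n": len(recs),
    }
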