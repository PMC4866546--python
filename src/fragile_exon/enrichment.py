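"""Observed-vs-expected enrichment of pathogenic SNPs across exon
domains and exon classes, and the gene-level exon-count comparison.

The expected domain distribution is length-based: over the SNP-bearing
exons, the bp of each domain (splice-site / end / core) is summed and
divided by the total exon bp.  Enrichment per label is reported as
fo/fe = observed proportion / expected proportion (> 1 preferred,
< 1 avoided), with significance from a Pearson goodness-of-fit
chi-squared (df = number of labels - 1, no continuity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import DomainSpec, Exon, GeneModel, domain_partition
from .variants import SnpRecord

__all__ = [
    "EnrichmentResult",
    "DOMAIN_LABELS",
    "snp_bearing_exons",
    "expected_domain_distribution",
    "domain_enrichment_test",
    "domain_enrichment",
    "class_enrichment_test",
    "exon_count_comparison",
]

DOMAIN_LABELS = ("splice_site", "end", "core")


@dataclass
class EnrichmentResult:
    labels: tuple[str, ...]
    observed_counts: np.ndarray
    observed_props: np.ndarray
    expected_props: np.ndarray
    chi2: float
    df: int
    p: float
    fo_fe: np.ndarray

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "observed_counts": [int(x) for x in self.observed_counts],
            "observed_props": [float(x) for x in self.observed_props],
            "expected_props": [float(x) for x in self.expected_props],
            "chi2": float(self.chi2),
            "df": int(self.df),
            "p": float(self.p),
            "fo_fe": [float(x) for x in self.fo_fe],
        }


def snp_bearing_exons(
    records: Iterable[SnpRecord],
    models: Iterable[GeneModel],
    internal_only: bool = True,
) -> list[Exon]:
    """Unique exons carrying at least one annotated SNP."""
    by_id = {m.gene_id: m for m in models}
    seen: dict[tuple[str, int], Exon] = {}
    for r in records:
        if internal_only and not r.is_internal:
            continue
        key = (r.gene_id, r.exon_index)
        if key not in seen:
            seen[key] = by_id[r.gene_id].exons[r.exon_index - 1]
    return list(seen.values())


def expected_domain_distribution(
    exons: Sequence[Exon],
    spec: DomainSpec = DomainSpec(),
    half: Optional[str] = None,
) -> np.ndarray:
    """Length-based expected proportions over (splice_site, end, core).

    With ``half`` set, only the positions of that exon half are
    counted, distances measured to that half's own junction only.
    """
    if not exons:
        raise ValueError("expected distribution needs a non-empty exon set")
    totals = np.zeros(3, dtype=float)
    for exon in exons:
        totals += domain_partition(exon.length, spec, half=half)
    return totals / totals.sum()


def domain_enrichment_test(
    observed_counts: Sequence[int], expected_props: Sequence[float],
    labels: tuple[str, ...] = DOMAIN_LABELS,
) -> EnrichmentResult:
    """Pearson goodness-of-fit of observed SNP counts against length-
    based expected proportions, with per-label fo/fe."""
    obs = np.asarray(observed_counts, dtype=float)
    exp_p = np.asarray(expected_props, dtype=float)
    if obs.min() < 0 or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with positive total")
    if np.any((exp_p == 0) & (obs > 0)):
        raise ValueError("expected proportion 0 with positive observed count")
    total = obs.sum()
    exp = exp_p * total
    keep = exp > 0
    chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    obs_p = obs / total
    with np.errstate(divide="ignore", invalid="ignore"):
        fo_fe = np.where(exp_p > 0, obs_p / exp_p, np.nan)
    return EnrichmentResult(tuple(labels), obs.astype(int), obs_p, exp_p, chi2, df, p, fo_fe)


def _half_distance(r: SnpRecord, half: str) -> int:
    return r.exon_position if half == "5p" else r.exon_length - r.exon_position + 1


def domain_enrichment(
    records: Iterable[SnpRecord],
    models: Iterable[GeneModel],
    spec: DomainSpec = DomainSpec(),
    half: Optional[str] = None,
    internal_only: bool = True,
) -> EnrichmentResult:
    """End-to-end domain enrichment: observed counts from annotated
    SNPs, expected from the SNP-bearing exons' own domain composition.

    With ``half='5p'``/``'3p'`` only SNPs in that exon half count,
    classified by distance to that half's junction (the 5'/3' reruns
    that exclude any 5'-to-3' placement bias).
    """
    records = [r for r in records if r.is_internal or not internal_only]
    if half is not None:
        records = [r for r in records if r.exon_half == half]
    counts = np.zeros(3, dtype=int)
    index = {label: i for i, label in enumerate(DOMAIN_LABELS)}
    for r in records:
        if half is None:
            counts[index[r.domain]] += 1
        else:
            from .models import classify_domain

            counts[index[classify_domain(_half_distance(r, half), spec)]] += 1
    exons = snp_bearing_exons(records, models, internal_only=internal_only)
    expected = expected_domain_distribution(exons, spec, half=half)
    return domain_enrichment_test(counts, expected)


def class_enrichment_test(
    class_bp: int, other_bp: int, class_snps: int, other_snps: int,
    labels: tuple[str, str] = ("class", "other"),
) -> EnrichmentResult:
    """Two-label enrichment of SNPs in an exon class (e.g. donor-AGgt
    exons or symmetric (0,0) exons) against its bp share (df = 1)."""
    if min(class_bp, other_bp, class_snps, other_snps) <= 0:
        raise ValueError("all class/other bp and SNP counts must be positive")
    exp_p = class_bp / (class_bp + other_bp)
    return domain_enrichment_test(
        [class_snps, other_snps], [exp_p, 1.0 - exp_p], labels=labels
    )


def exon_count_comparison(
    disease_genes: Sequence[tuple[float, float]],
    nondisease_genes: Sequence[tuple[float, float]],
    frac: float = 0.75,
) -> dict:
    """Compare exon counts between disease and non-disease genes,
    controlling for CDS length.

    Both groups are (cds_length, exon_count) pairs.  A lowess fit of
    exon count on CDS length over the pooled genes absorbs the
    nonlinear length dependence; the residuals of the two groups are
    compared with a two-sided Mann-Whitney U test.  ``frac`` is the
    lowess smoothing span.
    """
    if len(disease_genes) < 2 or len(nondisease_genes) < 2:
        raise ValueError("each gene group needs at least 2 genes")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    dis = np.asarray(disease_genes, dtype=float)
    non = np.asarray(nondisease_genes, dtype=float)
    if dis[:, 0].min() <= 0 or non[:, 0].min() <= 0:
        raise ValueError("CDS lengths must be positive")
    x = np.concatenate([dis[:, 0], non[:, 0]])
    y = np.concatenate([dis[:, 1], non[:, 1]])
    fitted = lowess(y, x, frac=frac, return_sorted=False)
    resid = y - fitted
    r_dis, r_non = resid[: len(dis)], resid[len(dis):]
    u = stats.mannwhitneyu(r_dis, r_non, alternative="two-sided")
    return {
        "median_residual_disease": float(np.median(r_dis)),
        "median_residual_nondisease": float(np.median(r_non)),
        "U": float(u.statistic),
        "p": float(u.pvalue),
        "residuals_disease": r_dis,
        "residuals_nondisease": r_non,
        "fitted": fitted,
    }
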