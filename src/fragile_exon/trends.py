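"""Cross-species cis-motif usage metric and phase/splice-site statistics.

Because experimentally defined ESEs shape which codons are preferred
near exon junctions, the frequency of distorted codon (or amino-acid)
usage in the vicinity of exon-intron boundaries serves as a measure of
cis-splice-motif usage.  For every codon/amino acid the proportional
usage in internal exons is tabulated as a function of the distance (in
codons) from the 5' and the 3' junction, the boundary-adjacent codon
excluded, out to 34 codons; the per-species metric is the proportion of
items whose usage shows a Bonferroni-significant Spearman trend with
distance at BOTH ends.

The module also computes per-species genome-architecture parameters
(proportion of phase-zero splice sites, X = mean CDS/gene length,
N = introns per kb exon, M = mean intron size), the phase x splice-site
contingency (are AGgt donors / agGT acceptors concentrated at
phase-zero junctions?), and a trait-table export for external
phylogenetic regression tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, domain_enrichment_test
from .models import GeneModel

__all__ = [
    "SENSE_CODONS",
    "AMINO_ACIDS",
    "usage_by_distance",
    "trend_proportion_metric",
    "cis_motif_usage_metric",
    "GenomeParams",
    "genome_architecture_params",
    "phase_splice_site_contingency",
    "export_trait_table",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "TCAG"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
SENSE_CODONS = tuple(c for c in _ALL_CODONS if c not in _STOPS)


def _codon_to_aa() -> dict[str, str]:
    from Bio.Seq import Seq

    return {c: str(Seq(c).translate()) for c in SENSE_CODONS}


_CODON_AA = _codon_to_aa()
AMINO_ACIDS = tuple(sorted(set(_CODON_AA.values())))


def internal_exon_codon_lists(models: Iterable[GeneModel]) -> list[list[str]]:
    """Per internal exon, the ordered list of codons assigned to it.

    A codon spanning a junction is assigned to the exon containing at
    least two of its three bases; the terminal stop codon is dropped.
    """
    out = []
    for model in models:
        lens = model.exon_lengths
        exon_of_base = np.repeat(np.arange(len(lens)), lens)
        cds = model.cds_sequence
        n_codons = len(cds) // 3
        per_exon: dict[int, list[str]] = {}
        for ci in range(n_codons):
            codon = cds[3 * ci : 3 * ci + 3]
            if ci == n_codons - 1 and codon in _STOPS:
                continue
            owners = exon_of_base[3 * ci : 3 * ci + 3]
            counts = np.bincount(owners, minlength=len(lens))
            owner = int(np.argmax(counts))
            per_exon.setdefault(owner, []).append(codon)
        for i, exon in enumerate(model.exons):
            if exon.is_internal and i in per_exon:
                out.append(per_exon[i])
    return out


def _usage_matrix(
    codon_lists: Sequence[list[str]], unit: str, end: str, max_dist: int
) -> pd.DataFrame:
    if unit == "codon":
        items = SENSE_CODONS
        mapper = {c: c for c in SENSE_CODONS}
    elif unit == "amino_acid":
        items = AMINO_ACIDS
        mapper = _CODON_AA
    else:
        raise ValueError(f"unit must be 'codon' or 'amino_acid', got {unit!r}")
    index = {it: i for i, it in enumerate(items)}
    distances = list(range(2, max_dist + 1))
    counts = np.zeros((len(items), len(distances)), dtype=float)
    for codons in codon_lists:
        k = len(codons)
        for j, codon in enumerate(codons, start=1):
            d5, d3 = j, k - j + 1
            d = d5 if end == "5p" else d3
            # boundary-adjacent codons (either end) carry splice-site
            # signal directly and are excluded from the usage gradient
            if min(d5, d3) >= 2 and d <= max_dist and codon in mapper:
                counts[index[mapper[codon]], d - 2] += 1
    totals = counts.sum(axis=0)
    used = totals > 0
    if not used.any():
        raise ValueError("no usable exon codons at any distance")
    props = counts[:, used] / totals[used]
    return pd.DataFrame(props, index=list(items),
                        columns=[d for d, u in zip(distances, used) if u])


def usage_by_distance(
    models: Iterable[GeneModel],
    unit: str = "codon",
    end: str = "5p",
    max_dist: int = 34,
) -> pd.DataFrame:
    """Column-stochastic usage matrix (items x junction distances 2..34)
    over the internal exons of ``models``."""
    if end not in ("5p", "3p"):
        raise ValueError(f"end must be '5p' or '3p', got {end!r}")
    lists = internal_exon_codon_lists(models)
    if not lists:
        raise ValueError("no internal exons with assigned codons")
    return _usage_matrix(lists, unit, end, max_dist)


def trend_proportion_metric(
    usage_5p: pd.DataFrame,
    usage_3p: pd.DataFrame,
    alpha: float = 0.05,
    family_size: Optional[int] = None,
) -> dict:
    """Proportion of items with a Bonferroni-significant usage trend
    (two-tailed Spearman of proportional usage vs distance) at both the
    5' and the 3' end.  The Bonferroni family defaults to the item
    count (61 sense codons or 20 amino acids), applied per end.
    """
    if usage_5p.shape[1] < 3 or usage_3p.shape[1] < 3:
        raise ValueError("need >= 3 distance points per end")
    family = family_size or len(usage_5p.index)
    threshold = alpha / family
    per_item = {}
    significant = []
    for item in usage_5p.index:
        res = {}
        for label, mat in (("5p", usage_5p), ("3p", usage_3p)):
            row = mat.loc[item].to_numpy()
            d = np.asarray(mat.columns, dtype=float)
            if np.all(row == row[0]):
                res[label] = (0.0, 1.0)
            else:
                rho, p = stats.spearmanr(d, row)
                res[label] = (float(rho), float(p))
        per_item[item] = res
        if res["5p"][1] < threshold and res["3p"][1] < threshold:
            significant.append(item)
    return {
        "metric": len(significant) / family,
        "significant_items": significant,
        "per_item": per_item,
        "family_size": family,
        "alpha": alpha,
    }


def cis_motif_usage_metric(
    models: Sequence[GeneModel],
    unit: str = "codon",
    alpha: float = 0.05,
    sample_n: Optional[int] = None,
    rng: Optional[int] = None,
    max_dist: int = 34,
    family_size: Optional[int] = None,
) -> dict:
    """Per-species cis-motif usage metric.

    ``sample_n`` subsamples that many internal exons (seeded) before
    tabulating usage, so species with different exon counts are
    comparable; omitted, all internal exons are used.
    """
    lists = internal_exon_codon_lists(models)
    if not lists:
        raise ValueError("no internal exons with assigned codons")
    sampling = "all"
    if sample_n is not None and sample_n < len(lists):
        gen = np.random.default_rng(rng)
        idx = gen.choice(len(lists), size=sample_n, replace=False)
        lists = [lists[i] for i in sorted(idx)]
        sampling = f"fixed_n={sample_n}"
    u5 = _usage_matrix(lists, unit, "5p", max_dist)
    u3 = _usage_matrix(lists, unit, "3p", max_dist)
    result = trend_proportion_metric(u5, u3, alpha=alpha, family_size=family_size)
    result.update(n_exons_used=len(lists), sampling=sampling, unit=unit)
    return result


# ---------------------------------------------------------------------
# Genome architecture
# ---------------------------------------------------------------------

@dataclass
class GenomeParams:
    """Species-level splice-architecture parameters."""

    phase_zero_prop: float  # proportion of internal splice junctions at phase 0
    X: float  # mean CDS length / gene length
    N_param: float  # introns per kb exon
    M_param: float  # mean intron size (bp)


def genome_architecture_params(models: Sequence[GeneModel]) -> GenomeParams:
    if not models:
        raise ValueError("empty model set")
    phases = []
    x_ratios = []
    n_introns = 0
    exon_bp = 0
    intron_bp = 0
    for m in models:
        for exon in m.exons[:-1]:
            phases.append(exon.phase3)
        x_ratios.append(m.cds_length / m.gene_span)
        n_introns += len(m.intron_seqs)
        exon_bp += m.cds_length
        intron_bp += sum(m.intron_lengths)
    return GenomeParams(
        phase_zero_prop=float(np.mean([p == 0 for p in phases])),
        X=float(np.mean(x_ratios)),
        N_param=n_introns / (exon_bp / 1000.0),
        M_param=intron_bp / n_introns if n_introns else float("nan"),
    )


def phase_splice_site_contingency(
    models: Sequence[GeneModel], site: str = "donor_AGgt"
) -> EnrichmentResult:
    """Are class-site junctions (AGgt donors or agGT acceptors)
    distributed across boundary phases 0/1/2 as all junctions are?

    Observed = class-site junction counts per phase; expected
    proportional to the all-junction phase counts; Pearson chi-squared
    with df = 2 and per-phase fo/fe.
    """
    if site not in ("donor_AGgt", "acceptor_agGT"):
        raise ValueError(f"unknown site class {site!r}")
    all_counts = np.zeros(3, dtype=float)
    class_counts = np.zeros(3, dtype=int)
    for m in models:
        for exon in m.exons:
            if site == "donor_AGgt" and exon.donor_tetranucleotide is not None:
                all_counts[exon.phase3] += 1
                if exon.has_donor_AGgt:
                    class_counts[exon.phase3] += 1
            elif site == "acceptor_agGT" and exon.acceptor_tetranucleotide is not None:
                all_counts[exon.phase5] += 1
                if exon.has_acceptor_agGT:
                    class_counts[exon.phase5] += 1
    if np.any(all_counts == 0):
        raise ValueError("empty phase class among junctions")
    expected = all_counts / all_counts.sum()
    return domain_enrichment_test(
        class_counts, expected, labels=("phase0", "phase1", "phase2")
    )


# ---------------------------------------------------------------------
# Trait-table export
# ---------------------------------------------------------------------

def export_trait_table(
    species_results: Mapping[str, Mapping[str, float]],
    tree: str | Path,
    traits: Sequence[str],
    out: str | Path,
) -> Path:
    """Write a headerless TSV of per-species trait values (one row per
    species, columns in the requested order) for continuous-trait
    phylogenetic regression tools.

    ``tree`` is a newick file or string; species labels must match the
    tree's tip labels exactly (offenders are listed on mismatch).
    """
    import io

    from Bio import Phylo

    tree_path = Path(tree) if isinstance(tree, Path) or Path(str(tree)).exists() else None
    handle = str(tree_path) if tree_path else io.StringIO(str(tree))
    phylo = Phylo.read(handle, "newick")
    tips = {t.name for t in phylo.get_terminals()}
    species = set(species_results)
    missing_from_tree = sorted(species - tips)
    missing_from_data = sorted(tips - species)
    if missing_from_tree or missing_from_data:
        raise ValueError(
            f"species/tip mismatch: not in tree {missing_from_tree}; "
            f"no data for tips {missing_from_data}"
        )
    out = Path(out)
    with open(out, "w") as fh:
        for sp in sorted(species_results):
            values = [f"{species_results[sp][t]:.6g}" for t in traits]
            fh.write("\t".join([sp, *values]) + "\n")
    return out
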