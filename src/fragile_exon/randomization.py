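"""Matched-nucleotide pseudo-SNP randomization tests.

Each null replicate places, for every real SNP, one pseudo SNP at a
uniformly chosen qualifying position of the SAME gene carrying the SAME
reference nucleotide (this conditions the null on gene identity and
nucleotide composition, removing expression-level and base-content
confounds).  The empirical p-value over m replicates is
p = (n + 1) / (m + 1), where n is the number of replicates at least as
extreme as the observation in the stated direction.

Three tests are provided:

* gene_half_test - is the 3'/5' gene-half ratio of real SNPs larger
  than that of matched pseudo SNPs? (samples from all exonic CDS
  positions)
* intron_size_test - per replicate, are pseudo flanking introns
  mostly larger than the real SNPs' flanking introns? (internal exons
  only, per-replicate exact binomial sign test)
* exon_class_test - are real SNPs over-/under-represented in a class
  of exons (symmetric (0,0) phase, donor AGgt, acceptor agGT)?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import DomainSpec, GeneModel
from .variants import SnpRecord, nearest_intron_size

__all__ = [
    "RandomizationResult",
    "PseudoSnpSampler",
    "empirical_p",
    "gene_half_test",
    "intron_size_test",
    "exon_class_test",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def empirical_p(n: int, m: int) -> float:
    """Empirical randomization p-value (n + 1) / (m + 1)."""
    if m < 1 or not 0 <= n <= m:
        raise ValueError(f"require 0 <= n <= m, m >= 1; got n={n}, m={m}")
    return (n + 1) / (m + 1)


@dataclass
class RandomizationResult:
    statistic_name: str
    observed: float
    null_values: list[float]
    n_extreme: int
    m: int
    p: float
    direction: str
    seed: Optional[int]
    extras: dict = field(default_factory=dict)


class PseudoSnpSampler:
    """Uniform matched-nucleotide sampler over a region of each gene.

    ``region`` is ``'all_exonic'`` (every coding-exon position) or
    ``'internal_exonic'`` (internal exons only).  Per-position features
    needed by the tests (gene half, nearest flanking intron size, exon
    class flags, reference base) are precomputed once so that drawing a
    full m x n replicate matrix is a vectorized operation.
    """

    def __init__(self, models: Iterable[GeneModel], region: str = "all_exonic"):
        if region not in ("all_exonic", "internal_exonic"):
            raise ValueError(f"unknown region {region!r}")
        self.region = region
        bases, half3, intron, p00, donor, acceptor = [], [], [], [], [], []
        self._gene_pools: dict[str, list[np.ndarray]] = {}
        offset = 0
        for model in models:
            g_bases, g_feats = self._gene_positions(model)
            n_pos = len(g_bases)
            pools = []
            for b in range(4):
                pools.append(offset + np.flatnonzero(g_bases == b))
            self._gene_pools[model.gene_id] = pools
            bases.append(g_bases)
            half3.append(g_feats["half3"])
            intron.append(g_feats["intron"])
            p00.append(g_feats["phase00"])
            donor.append(g_feats["donor_AGgt"])
            acceptor.append(g_feats["acceptor_agGT"])
            offset += n_pos
        self.base = np.concatenate(bases)
        self.half3 = np.concatenate(half3)
        self.intron = np.concatenate(intron)
        self.phase00 = np.concatenate(p00)
        self.donor_AGgt = np.concatenate(donor)
        self.acceptor_agGT = np.concatenate(acceptor)

    def _gene_positions(self, model: GeneModel):
        span_mid = math.ceil(model.gene_span / 2)
        seg_bases, seg = [], {k: [] for k in ("half3", "intron", "phase00", "donor_AGgt", "acceptor_agGT")}
        g_before = 0  # unspliced transcript-oriented bp before current exon
        for i, exon in enumerate(model.exons):
            length = exon.length
            if exon.is_internal or self.region == "all_exonic":
                p = np.arange(1, length + 1)
                seq = model.exon_seqs[i]
                seg_bases.append(np.array([_BASE_INDEX.get(c, 255) for c in seq], dtype=np.uint8))
                seg["half3"].append((g_before + p) > span_mid)
                if exon.is_internal:
                    up_d, down_d = p - 1, length - p
                    iv = np.where(
                        up_d < down_d,
                        exon.upstream_intron_bp,
                        np.where(
                            up_d > down_d,
                            exon.downstream_intron_bp,
                            max(exon.upstream_intron_bp, exon.downstream_intron_bp),
                        ),
                    )
                else:
                    iv = np.full(length, -1)
                seg["intron"].append(iv)
                seg["phase00"].append(np.full(length, exon.is_phase00, dtype=bool))
                seg["donor_AGgt"].append(np.full(length, exon.has_donor_AGgt, dtype=bool))
                seg["acceptor_agGT"].append(np.full(length, exon.has_acceptor_agGT, dtype=bool))
            g_before += length
            if exon.downstream_intron_bp is not None:
                g_before += exon.downstream_intron_bp
        if not seg_bases:
            return np.empty(0, dtype=np.uint8), {k: np.empty(0) for k in seg}
        return np.concatenate(seg_bases), {k: np.concatenate(v) for k, v in seg.items()}

    def pools_for(self, records: Sequence[SnpRecord]):
        """Per-record candidate pools (flattened) for vectorized draws.

        Returns (pool, offsets, sizes, kept_records, n_skipped); records
        whose gene has no position carrying their reference base in the
        region are skipped with a warning.
        """
        pool_parts, sizes, kept = [], [], []
        n_skipped = 0
        for r in records:
            cand = self._gene_pools[r.gene_id][_BASE_INDEX[r.ref]]
            if len(cand) == 0:
                n_skipped += 1
                continue
            pool_parts.append(cand)
            sizes.append(len(cand))
            kept.append(r)
        if n_skipped:
            warnings.warn(
                f"{n_skipped} SNP(s) skipped: no position with a matching "
                f"reference base in the {self.region} region of their gene",
                stacklevel=2,
            )
        if not kept:
            raise ValueError("no SNP has any qualifying pseudo position")
        sizes_arr = np.array(sizes)
        offsets = np.concatenate([[0], np.cumsum(sizes_arr)[:-1]])
        return np.concatenate(pool_parts), offsets, sizes_arr, kept, n_skipped

    def sample_matrix(
        self, records: Sequence[SnpRecord], m: int, seed: Optional[int]
    ) -> tuple[np.ndarray, list[SnpRecord], int]:
        """(m, n) matrix of sampled global position indices, one pseudo
        SNP per kept record per replicate; replicate r uses the r-th
        deterministic child stream of ``seed``."""
        pool, offsets, sizes, kept, n_skipped = self.pools_for(records)
        children = np.random.SeedSequence(seed).spawn(m)
        rows = np.empty((m, len(kept)), dtype=np.int64)
        for r in range(m):
            rng = np.random.default_rng(children[r])
            u = rng.random(len(kept))
            rows[r] = pool[offsets + (u * sizes).astype(np.int64)]
        return rows, kept, n_skipped


def _as_seed(rng) -> Optional[int]:
    if rng is None or isinstance(rng, (int, np.integer)):
        return None if rng is None else int(rng)
    raise TypeError("pass an integer seed (or None) for reproducible substreams")


def gene_half_test(
    records: Sequence[SnpRecord],
    models: Sequence[GeneModel],
    m: int = 100,
    rng: Optional[int] = None,
    sampler: Optional[PseudoSnpSampler] = None,
) -> RandomizationResult:
    """3'/5' gene-half ratio of real SNPs vs matched pseudo SNPs.

    observed = (#real SNPs in the 3' gene half)/(#in the 5' half); a
    replicate is extreme when its pseudo ratio >= observed (a replicate
    with zero 5'-half pseudo SNPs has ratio +inf and counts extreme).
    """
    seed = _as_seed(rng)
    n5 = sum(1 for r in records if r.gene_half == "5p")
    n3 = sum(1 for r in records if r.gene_half == "3p")
    if n5 == 0 or n3 == 0:
        raise ValueError("gene-half ratio undefined: need >= 1 SNP in each half")
    observed = n3 / n5
    sampler = sampler or PseudoSnpSampler(models, region="all_exonic")
    rows, kept, n_skipped = sampler.sample_matrix(records, m, seed)
    k3 = sampler.half3[rows].sum(axis=1).astype(float)
    k5 = len(kept) - k3
    with np.errstate(divide="ignore"):
        ratios = np.where(k5 > 0, k3 / np.maximum(k5, 1), np.inf)
    n_extreme = int(np.sum(ratios >= observed))
    return RandomizationResult(
        statistic_name="gene_half_ratio_3p_over_5p",
        observed=observed,
        null_values=[float(x) for x in ratios],
        n_extreme=n_extreme,
        m=m,
        p=empirical_p(n_extreme, m),
        direction="greater",
        seed=seed,
        extras={"n_5p": n5, "n_3p": n3, "n_skipped": n_skipped},
    )


def intron_size_test(
    records: Sequence[SnpRecord],
    models: Sequence[GeneModel],
    m: int = 100,
    rng: Optional[int] = None,
    sampler: Optional[PseudoSnpSampler] = None,
) -> RandomizationResult:
    """Do pseudo SNPs land near larger flanking introns than real SNPs?

    Per replicate, A counts SNPs whose pseudo flanking intron is larger
    than the real one and B those smaller (exact ties, e.g. a pseudo SNP
    in the same exon, are excluded, the standard sign-test convention;
    counting them on either side would bias the null).  Each replicate
    gets an exact two-sided binomial p on (A, A + B).  The overall
    statistic counts replicates NOT in the expected 'pseudo larger'
    direction (A <= B), so a small empirical p means pseudo introns are
    consistently larger, i.e. real SNPs favor exons flanked by short
    introns.
    """
    seed = _as_seed(rng)
    internal = [r for r in records if r.is_internal]
    if not internal:
        raise ValueError("no comparable pairs: no SNPs in internal exons")
    sampler = sampler or PseudoSnpSampler(models, region="internal_exonic")
    rows, kept, n_skipped = sampler.sample_matrix(internal, m, seed)
    real = np.array([r.nearest_intron_bp for r in kept], dtype=float)
    pseudo = sampler.intron[rows].astype(float)
    A = (pseudo > real).sum(axis=1)
    B = (pseudo < real).sum(axis=1)
    rep_p = [
        float(stats.binomtest(int(a), int(a + b), 0.5, alternative="two-sided").pvalue)
        if a + b > 0 else 1.0
        for a, b in zip(A, B)
    ]
    n_extreme = int(np.sum(A <= B))
    return RandomizationResult(
        statistic_name="pseudo_flanking_intron_larger",
        observed=float(np.median(real)),
        null_values=[float(a) for a in A],
        n_extreme=n_extreme,
        m=m,
        p=empirical_p(n_extreme, m),
        direction="greater",
        seed=seed,
        extras={
            "per_replicate_A": [int(a) for a in A],
            "per_replicate_B": [int(b) for b in B],
            "per_replicate_binomial_p": rep_p,
            "n_pairs": len(kept),
            "n_skipped": n_skipped,
        },
    )


_DEFAULT_DIRECTIONS = {"phase00": "greater", "donor_AGgt": "less", "acceptor_agGT": "less"}


def exon_class_test(
    records: Sequence[SnpRecord],
    models: Sequence[GeneModel],
    exon_class: str = "phase00",
    direction: Optional[str] = None,
    m: int = 100,
    rng: Optional[int] = None,
    sampler: Optional[PseudoSnpSampler] = None,
) -> RandomizationResult:
    """Count of real SNPs in a class of internal exons vs matched null.

    ``exon_class`` is one of ``phase00`` (symmetric (0,0) exons, tested
    for enrichment by default), ``donor_AGgt`` or ``acceptor_agGT``
    (tested for avoidance by default)."""
    if exon_class not in _DEFAULT_DIRECTIONS:
        raise ValueError(f"unknown exon class {exon_class!r}")
    direction = direction or _DEFAULT_DIRECTIONS[exon_class]
    seed = _as_seed(rng)
    internal = [r for r in records if r.is_internal]
    observed = sum(1 for r in internal if getattr(r, exon_class))
    sampler = sampler or PseudoSnpSampler(models, region="internal_exonic")
    rows, kept, n_skipped = sampler.sample_matrix(internal, m, seed)
    flags = getattr(sampler, exon_class)
    nulls = flags[rows].sum(axis=1)
    if direction == "greater":
        n_extreme = int(np.sum(nulls >= observed))
    elif direction == "less":
        n_extreme = int(np.sum(nulls <= observed))
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    return RandomizationResult(
        statistic_name=f"snps_in_{exon_class}_exons",
        observed=float(observed),
        null_values=[float(x) for x in nulls],
        n_extreme=n_extreme,
        m=m,
        p=empirical_p(n_extreme, m),
        direction=direction,
        seed=seed,
        extras={"n_internal_snps": len(kept), "n_skipped": n_skipped},
    )
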