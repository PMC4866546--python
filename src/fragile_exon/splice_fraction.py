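"""Background-removal estimator of the splice-affecting SNP fraction.

The idea: deep exon cores (the central 100 bp of internal exons longer
than 300 bp) are assumed free of splice-disrupting mutations, so the
pathogenic SNP rate there (N SNPs over L bp) estimates the background,
splice-unrelated rate.  Extrapolating that rate over the exon-flank bp
M (all positions within the end cutoff, 69 bp by default) predicts
P = M*N/L flank SNPs; the observed excess Q - P is attributed to
splice disruption.

Two modes:

* conservative - assumes core mutations never affect splicing;
  fraction = (Q - P) / S with S all internal-exon SNPs.
* liberal - assumes a fraction (default 25%) of core-region
  mutations also affect splicing, so the background rate is
  (1 - core_splice_frac) * N/L applied to all internal-exon bp T;
  fraction = (S - T*rate) / S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .models import GeneModel
from .variants import SnpRecord

__all__ = [
    "SpliceFractionResult",
    "core_background_rate",
    "splice_affecting_fraction",
    "estimate_from_counts",
    "cutoff_sweep",
]


@dataclass
class SpliceFractionResult:
    cutoff: int
    N: int  # core-region SNPs
    L: int  # core-region bp
    core_rate: float  # (1 - core_splice_frac) * N/L in liberal mode
    M: Optional[int]  # flank bp (conservative mode)
    P: Optional[float]  # expected flank SNPs (conservative mode)
    Q: Optional[int]  # observed flank SNPs (conservative mode)
    S: int  # all internal-exon SNPs
    T: Optional[int]  # all internal-exon bp (liberal mode)
    mode: str
    core_splice_frac: float
    denominator: str
    fraction: float

    def as_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def _round_sig(x: float, sig: int = 4) -> float:
    return float(f"%.{sig}g" % x)


def _internal_records(records: Iterable[SnpRecord]) -> list[SnpRecord]:
    return [r for r in records if r.is_internal]


def _internal_exons(models: Iterable[GeneModel]):
    for m in models:
        for exon in m.exons:
            if exon.is_internal:
                yield m.gene_id, exon


def core_background_rate(
    models: Sequence[GeneModel],
    records: Iterable[SnpRecord],
    core_window: int = 100,
    min_exon: int = 300,
    liberal_adjust: float = 0.0,
) -> tuple[int, int, float]:
    """(N, L, rate): SNPs and bp in the central ``core_window`` bp of
    internal exons longer than ``min_exon``, and the background rate
    (1 - liberal_adjust) * N/L."""
    windows: dict[tuple[str, int], tuple[int, int]] = {}
    for gene_id, exon in _internal_exons(models):
        if exon.length > min_exon:
            start = (exon.length - core_window) // 2  # 0-based window start
            windows[(gene_id, exon.index)] = (start + 1, start + core_window)
    if not windows:
        raise ValueError(f"no internal exon longer than {min_exon} bp")
    L = core_window * len(windows)
    N = 0
    for r in _internal_records(records):
        w = windows.get((r.gene_id, r.exon_index))
        if w and w[0] <= r.exon_position <= w[1]:
            N += 1
    rate = (1.0 - liberal_adjust) * N / L
    return N, L, rate


def estimate_from_counts(
    N: int,
    L: int,
    S: int,
    M: Optional[int] = None,
    Q: Optional[int] = None,
    T: Optional[int] = None,
    mode: str = "conservative",
    cutoff: int = 69,
    core_splice_frac: float = 0.25,
    denominator: str = "total",
    printed_rounding: bool = False,
) -> SpliceFractionResult:
    """Run the estimator arithmetic on explicit counts.

    ``denominator`` selects the conservative-mode denominator:
    ``"total"`` divides the flank excess by S (all internal-exon SNPs),
    ``"methods"`` by N + Q.  ``printed_rounding`` rounds the liberal
    background rate to 4 significant figures and the expected count to
    an integer, mimicking fixed-precision intermediate reporting.
    """
    if S <= 0:
        raise ValueError("S (total internal-exon SNPs) must be positive")
    if mode == "conservative":
        if M is None or Q is None:
            raise ValueError("conservative mode needs flank bp M and flank SNPs Q")
        if Q > S:
            raise ValueError("flank SNPs Q cannot exceed total internal-exon SNPs S")
        rate = N / L
        P = M * rate
        denom = S if denominator == "total" else N + Q
        fraction = (Q - P) / denom
        core_splice_frac = 0.0
    elif mode == "liberal":
        if T is None:
            raise ValueError("liberal mode needs total internal-exon bp T")
        rate = (1.0 - core_splice_frac) * N / L
        if printed_rounding:
            rate = _round_sig(rate, 4)
        expected = T * rate
        if printed_rounding:
            expected = round(expected)
        P = expected
        fraction = (S - expected) / S
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if fraction < 0:
        warnings.warn(
            "negative splice-affecting fraction clamped to 0 "
            "(no flank excess over the core background rate)",
            stacklevel=2,
        )
        fraction = 0.0
    return SpliceFractionResult(
        cutoff=cutoff,
        N=N,
        L=L,
        core_rate=rate,
        M=M,
        P=P,
        Q=Q,
        S=S,
        T=T if mode == "liberal" else None,
        mode=mode,
        core_splice_frac=core_splice_frac,
        denominator=denominator if mode == "conservative" else "total",
        fraction=fraction,
    )


def splice_affecting_fraction(
    models: Sequence[GeneModel],
    records: Iterable[SnpRecord],
    cutoff: int = 69,
    mode: str = "conservative",
    core_window: int = 100,
    min_exon: int = 300,
    core_splice_frac: float = 0.25,
    denominator: str = "total",
    printed_rounding: bool = False,
) -> SpliceFractionResult:
    """Estimate the splice-affecting fraction from annotated data.

    Flank bp M counts every internal-exon position within ``cutoff`` bp
    of a junction (splice-site bp included); Q is the number of
    internal-exon SNPs at those positions.
    """
    if cutoff >= min_exon / 2:
        raise ValueError(
            f"cutoff {cutoff} reaches half the minimum core exon length {min_exon}"
        )
    internal = _internal_records(records)
    if not internal:
        raise ValueError("no SNPs in internal exons")
    N, L, _ = core_background_rate(models, internal, core_window, min_exon)
    S = len(internal)
    M = sum(min(exon.length, 2 * cutoff) for _, exon in _internal_exons(models))
    T = sum(exon.length for _, exon in _internal_exons(models))
    Q = sum(1 for r in internal if r.d_nearest <= cutoff)
    return estimate_from_counts(
        N=N, L=L, S=S, M=M, Q=Q, T=T,
        mode=mode, cutoff=cutoff, core_splice_frac=core_splice_frac,
        denominator=denominator, printed_rounding=printed_rounding,
    )


def cutoff_sweep(
    models: Sequence[GeneModel],
    records: Iterable[SnpRecord],
    cutoffs: Sequence[int] = tuple(range(50, 101, 5)),
    mode: str = "conservative",
    **kwargs,
) -> list[SpliceFractionResult]:
    """Robustness sweep of the exon-end cutoff (default 50..100 bp by
    5 bp); M and Q are recomputed per cutoff."""
    if list(cutoffs) != sorted(cutoffs) or min(cutoffs) <= 0:
        raise ValueError("cutoffs must be sorted and positive")
    records = list(records)
    return [
        splice_affecting_fraction(models, records, cutoff=c, mode=mode, **kwargs)
        for c in cutoffs
    ]
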