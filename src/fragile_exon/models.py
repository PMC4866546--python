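"""Gene models and per-exon architecture.

A :class:`GeneModel` is one protein-coding gene reduced to its coding
portion (ATG through stop, introns included), strand-normalized so that
exon 1 is always the 5'-most exon of the transcript and all sequences
read in transcript orientation.  Per-exon architecture (reading-frame
phases, junction tetranucleotides such as ``AGgt``/``agGT``, flanking
intron sizes) is derived from the model with
:func:`derive_exon_architecture`.

Positions inside exons are reported 1-based in transcript orientation;
the distance of a position to the nearest exon junction is
``d = min(p, length - p + 1)``.  Exon positions are partitioned into
three domains by that distance: splice-site (``d <= 3`` by default),
exon end (``3 < d <= 69``), and exon core (``d > 69``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DomainSpec",
    "Exon",
    "GeneModel",
    "FilterReport",
    "domain_partition",
    "classify_domain",
    "parse_gene_models",
    "apply_gene_filters",
    "derive_exon_architecture",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DomainSpec:
    """Exon-domain boundaries in bp from the nearest junction.

    ``d <= splice_site_max`` is the splice-site domain,
    ``splice_site_max < d <= end_max`` the exon-end domain, and
    ``d > end_max`` the exon core.
    """

    splice_site_max: int = 3
    end_max: int = 69

    def __post_init__(self) -> None:
        if not 0 < self.splice_site_max < self.end_max:
            raise ValueError(
                f"require 0 < splice_site_max < end_max, got "
                f"({self.splice_site_max}, {self.end_max})"
            )


def domain_partition(
    exon_length: int, spec: DomainSpec = DomainSpec(), half: Optional[str] = None
) -> tuple[int, int, int]:
    """Count exon positions per domain: (splice_site_bp, end_bp, core_bp).

    Each 1-based position ``p`` is assigned by its distance to the
    nearest junction ``d = min(p, exon_length - p + 1)``.  With
    ``half='5p'`` (or ``'3p'``) only the positions of that exon half
    are counted (split at ``ceil(length/2)``), with ``d`` measured to
    that half's own junction only.
    """
    if exon_length < 1:
        raise ValueError("exon_length must be >= 1")
    if half is None:
        splice = min(exon_length, 2 * spec.splice_site_max)
        within_end = min(exon_length, 2 * spec.end_max)
    else:
        if half == "5p":
            h = math.ceil(exon_length / 2)
        elif half == "3p":
            h = exon_length // 2
        else:
            raise ValueError(f"half must be '5p' or '3p', got {half!r}")
        splice = min(h, spec.splice_site_max)
        within_end = min(h, spec.end_max)
        exon_length = h
    return splice, within_end - splice, exon_length - within_end


def classify_domain(d: int, spec: DomainSpec = DomainSpec()) -> str:
    """Domain label for a junction distance ``d`` (1-based)."""
    if d < 1:
        raise ValueError("junction distance must be >= 1")
    if d <= spec.splice_site_max:
        return "splice_site"
    if d <= spec.end_max:
        return "end"
    return "core"


@dataclass
class Exon:
    """One coding exon with derived architecture.

    ``phase5``/``phase3`` are the reading-frame phases at the exon's
    5' and 3' boundaries (0 means the boundary falls between codons).
    Junction tetranucleotides follow the exon-uppercase / intron-
    lowercase convention: the donor of an exon ending ``...AG`` whose
    downstream intron starts ``gt...`` is ``"AGgt"``; the acceptor of
    an exon starting ``GT...`` after an intron ending ``...ag`` is
    ``"agGT"``.
    """

    index: int
    length: int
    cds_offset: int
    phase5: int
    phase3: int
    acceptor_tetranucleotide: Optional[str]
    donor_tetranucleotide: Optional[str]
    upstream_intron_bp: Optional[int]
    downstream_intron_bp: Optional[int]
    is_internal: bool

    @property
    def is_phase00(self) -> bool:
        """Symmetric (0,0) exon: phase 0 at both ends."""
        return self.phase5 == 0 and self.phase3 == 0

    @property
    def has_donor_AGgt(self) -> bool:
        return self.donor_tetranucleotide == "AGgt"

    @property
    def has_acceptor_agGT(self) -> bool:
        return self.acceptor_tetranucleotide == "agGT"


@dataclass
class GeneModel:
    """One protein-coding gene, CDS-clipped and transcript-oriented.

    ``exon_coords`` are genomic 0-based half-open intervals of the
    coding exon pieces in genomic order; ``exon_seqs``/``intron_seqs``
    are uppercase transcript-oriented sequences in transcript order
    (for minus-strand genes the genomic slices are reverse-
    complemented and the lists reversed).
    """

    gene_id: str
    chrom: str
    strand: str
    exon_coords: list[tuple[int, int]]
    exon_seqs: list[str]
    intron_seqs: list[str]
    _architecture: Optional[list[Exon]] = field(default=None, repr=False, compare=False)

    # -- basic derived quantities -------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exon_seqs)

    @property
    def exon_lengths(self) -> list[int]:
        return [len(s) for s in self.exon_seqs]

    @property
    def intron_lengths(self) -> list[int]:
        return [len(s) for s in self.intron_seqs]

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def gene_span(self) -> int:
        """Genomic bp from ATG through stop, introns included."""
        return self.exon_coords[-1][1] - self.exon_coords[0][0]

    @property
    def cds_sequence(self) -> str:
        return "".join(self.exon_seqs)

    @property
    def exons(self) -> list[Exon]:
        if self._architecture is None:
            self._architecture = derive_exon_architecture(self)
        return self._architecture

    # -- coordinate mapping -------------------------------------------
    def locate(self, genomic_pos: int) -> Optional[tuple[int, int]]:
        """Map a genomic 1-based position to (exon_index, exon_position).

        Both outputs are 1-based and transcript-oriented; returns None
        for positions outside the coding exons (intronic/UTR/etc.).
        """
        pos0 = genomic_pos - 1
        for gi, (s, e) in enumerate(self.exon_coords):
            if s <= pos0 < e:
                if self.strand == "+":
                    return gi + 1, pos0 - s + 1
                return self.n_exons - gi, e - pos0
        return None

    def gene_position(self, genomic_pos: int) -> int:
        """1-based transcript-oriented position in the unspliced ATG->stop span."""
        pos0 = genomic_pos - 1
        start, end = self.exon_coords[0][0], self.exon_coords[-1][1]
        if not start <= pos0 < end:
            raise ValueError(
                f"position {genomic_pos} outside gene span of {self.gene_id}"
            )
        return pos0 - start + 1 if self.strand == "+" else end - pos0

    def base_at(self, exon_index: int, exon_position: int) -> str:
        """Transcript-strand base at a 1-based exon position."""
        return self.exon_seqs[exon_index - 1][exon_position - 1]

    def cds_coordinate(self, exon_index: int, exon_position: int) -> int:
        """1-based transcript CDS coordinate of an exon position."""
        return sum(self.exon_lengths[: exon_index - 1]) + exon_position


# ---------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------

def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Uppercase genomic slice [start, end) from a dict of strings or a
    pyfaidx.Fasta-like mapping."""
    seq = genome[chrom]
    if isinstance(seq, str):
        piece = seq[start:end]
    else:  # pyfaidx FastaRecord supports slicing
        piece = str(seq[start:end])
    return piece.upper()


def _build_model(
    gene_id: str,
    chrom: str,
    strand: str,
    exon_coords: list[tuple[int, int]],
    genome: Mapping[str, object],
) -> GeneModel:
    if chrom not in genome:
        raise ValueError(
            f"gene {gene_id!r} references chromosome {chrom!r} absent from the genome"
        )
    chrom_len = len(genome[chrom])
    if exon_coords[0][0] < 0 or exon_coords[-1][1] > chrom_len:
        raise ValueError(
            f"gene {gene_id!r} has coordinates outside chromosome {chrom!r} "
            f"(length {chrom_len})"
        )
    exon_seqs = [_fetch(genome, chrom, s, e) for s, e in exon_coords]
    intron_seqs = [
        _fetch(genome, chrom, exon_coords[i][1], exon_coords[i + 1][0])
        for i in range(len(exon_coords) - 1)
    ]
    if strand == "-":
        exon_seqs = [revcomp(s) for s in reversed(exon_seqs)]
        intron_seqs = [revcomp(s) for s in reversed(intron_seqs)]
    return GeneModel(gene_id, chrom, strand, exon_coords, exon_seqs, intron_seqs)


def _parse_genepred_row(fields: Sequence[str]) -> tuple[str, str, str, list[tuple[int, int]]]:
    name, chrom, strand = fields[0], fields[1], fields[2]
    cds_start, cds_end = int(fields[5]), int(fields[6])
    starts = [int(x) for x in fields[8].rstrip(",").split(",")]
    ends = [int(x) for x in fields[9].rstrip(",").split(",")]
    coords = _clip_to_cds(list(zip(starts, ends)), cds_start, cds_end)
    return name, chrom, strand, coords


def _parse_bed12_row(fields: Sequence[str]) -> tuple[str, str, str, list[tuple[int, int]]]:
    chrom, start = fields[0], int(fields[1])
    name, strand = fields[3], fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    coords = _clip_to_cds(blocks, thick_start, thick_end)
    return name, chrom, strand, coords


def _clip_to_cds(
    blocks: list[tuple[int, int]], cds_start: int, cds_end: int
) -> list[tuple[int, int]]:
    out = []
    for s, e in blocks:
        s, e = max(s, cds_start), min(e, cds_end)
        if e > s:
            out.append((s, e))
    if not out:
        raise ValueError("no coding sequence within the annotated CDS bounds")
    return out


def parse_gene_models(
    annotation: str | Path,
    genome: Mapping[str, object] | str | Path,
    fmt: Optional[str] = None,
) -> list[GeneModel]:
    """Parse a genePred-like TSV or BED12 file into strand-normalized
    gene models.

    ``genome`` may be a FASTA path (read via pyfaidx), a pyfaidx.Fasta,
    or a plain ``{chrom: sequence}`` mapping.  ``fmt`` is ``'genepred'``
    or ``'bed12'``; by default it is sniffed from the column count
    (genePred has 10 columns, BED12 has 12).
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        genome = pyfaidx.Fasta(str(genome))
    models: list[GeneModel] = []
    with open(annotation) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                row_fmt = fmt or ("bed12" if len(fields) >= 12 else "genepred")
                if row_fmt == "bed12":
                    name, chrom, strand, coords = _parse_bed12_row(fields)
                else:
                    name, chrom, strand, coords = _parse_genepred_row(fields)
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{annotation}: malformed row at line {lineno}: {exc}") from exc
            models.append(_build_model(name, chrom, strand, coords, genome))
    return models


# ---------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------

FILTER_RULES = ("bad_frame", "no_ATG", "no_stop", "internal_stop", "ambiguous_N", "intronless")


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`apply_gene_filters`."""

    counts: dict[str, int]
    removed: dict[str, str]  # gene_id -> first failing rule

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def _first_failing_rule(model: GeneModel) -> Optional[str]:
    cds = model.cds_sequence
    if len(cds) % 3 != 0:
        return "bad_frame"
    if cds[:3] != "ATG":
        return "no_ATG"
    if cds[-3:] not in STOP_CODONS:
        return "no_stop"
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return "internal_stop"
    letters = set(cds)
    for s in model.intron_seqs:
        letters |= set(s)
    if letters - set("ACGT"):
        return "ambiguous_N"
    if model.n_exons < 2:
        return "intronless"
    return None


def apply_gene_filters(models: Iterable[GeneModel]) -> tuple[list[GeneModel], FilterReport]:
    """Apply the validity filters: in-frame CDS, normal start codon
    (ATG), normal stop codon, no internal stop, no ambiguous
    nucleotides, and at least one intron.  Each removed gene is charged
    to the first rule it fails (fixed rule order, deterministic report).
    """
    kept: list[GeneModel] = []
    counts = {rule: 0 for rule in FILTER_RULES}
    removed: dict[str, str] = {}
    for model in models:
        rule = _first_failing_rule(model)
        if rule is None:
            kept.append(model)
        else:
            counts[rule] += 1
            removed[model.gene_id] = rule
    return kept, FilterReport(counts, removed)


# ---------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------

def derive_exon_architecture(model: GeneModel) -> list[Exon]:
    """Populate per-exon phases, junction tetranucleotides and flanking
    intron sizes.  Requires every exon >= 2 bp and every intron >= 4 bp
    (otherwise a junction tetranucleotide is undefined)."""
    n = model.n_exons
    for i, s in enumerate(model.exon_seqs):
        if len(s) < 2:
            raise ValueError(f"{model.gene_id}: exon {i + 1} shorter than 2 bp")
    for i, s in enumerate(model.intron_seqs):
        if len(s) < 4:
            raise ValueError(f"{model.gene_id}: intron {i + 1} shorter than 4 bp")
    exons: list[Exon] = []
    offset = 0
    for i in range(n):
        seq = model.exon_seqs[i]
        length = len(seq)
        acceptor = donor = None
        up_bp = down_bp = None
        if i > 0:
            up = model.intron_seqs[i - 1]
            acceptor = up[-2:].lower() + seq[:2].upper()
            up_bp = len(up)
        if i < n - 1:
            down = model.intron_seqs[i]
            donor = seq[-2:].upper() + down[:2].lower()
            down_bp = len(down)
        exons.append(
            Exon(
                index=i + 1,
                length=length,
                cds_offset=offset,
                phase5=offset % 3,
                phase3=(offset + length) % 3,
                acceptor_tetranucleotide=acceptor,
                donor_tetranucleotide=donor,
                upstream_intron_bp=up_bp,
                downstream_intron_bp=down_bp,
                is_internal=0 < i < n - 1,
            )
        )
        offset += length
    return exons
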