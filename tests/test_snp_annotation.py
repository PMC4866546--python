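"""Per-SNP positional features: domains, halves, flanking introns."""

import math

import pytest

import fragile_exon as fx
from fragile_exon.variants import RawVariant

from conftest import build_gene

E1 = "ATG" + "GAA" * 4
I1 = "GTAAGTTTTTTTTCTTAG"
E2 = "GAAGAAGAAG"
I2 = "GTTTGTTTTTTTTTTTAG"
E3 = "AAGAA" + "TAA"


@pytest.mark.parametrize("d,label", [(1, "splice_site"), (3, "splice_site"),
                                     (4, "end"), (69, "end"), (70, "core")])
def test_domain_boundaries_inclusive(d, label):
    assert fx.classify_domain(d) == label


def test_d_nearest_and_domain_examples():
    spec = fx.DomainSpec()
    # position 100 of a 200 bp exon: min(100, 101) = 100 -> core
    assert min(100, 200 - 100 + 1) == 100
    assert fx.classify_domain(100, spec) == "core"
    assert fx.classify_domain(min(30, 100 - 30 + 1), spec) == "end"


def test_nearest_intron_tie_takes_longer():
    model, _ = build_gene([E1, E2, E3], [I1, I2])
    exon2 = model.exons[1]
    # 10 bp exon: position 1 is nearest the upstream intron
    assert fx.nearest_intron_size(exon2, 1) == len(I1)
    assert fx.nearest_intron_size(exon2, 10) == len(I2)
    # ties: up_dist == down_dist at position (length+1)/2; for 10 bp
    # there is no exact tie, so build an 11 bp exon
    model2, _ = build_gene([E1, "GAAGAAGAAGG", "AAGAAGATTGA"], [I1, I2])
    assert fx.nearest_intron_size(model2.exons[1], 6) == max(len(I1), len(I2))
    with pytest.raises(ValueError):
        fx.nearest_intron_size(model.exons[0], 1)


def test_gene_half_vs_cds_half_dissociate_with_huge_intron():
    # short first exon, huge intron 1: an exon-2 SNP early in the CDS
    # is still in the genomic 3' half of the gene span
    huge = "GT" + "T" * 496 + "AG"
    model, genome = build_gene([E1, E2, E3], [huge, I2], gene_id="huge")
    pos = model.exon_coords[1][0] + 1  # first base of exon 2 (genomic 1-based)
    gene_half, cds_half = fx.gene_and_cds_half(model, pos)
    c = model.cds_coordinate(2, 1)
    assert c < model.cds_length / 2 and cds_half == "5p"
    assert model.gene_position(pos) > model.gene_span / 2 and gene_half == "3p"


def test_midpoint_positions_assigned_5p():
    model, _ = build_gene([E1, E2, E3], [I1, I2])
    span = model.gene_span
    mid = math.ceil(span / 2)
    # walk genomic positions until we hit the midpoint of the span
    start = model.exon_coords[0][0]
    gene_half, _ = fx.gene_and_cds_half(model, start + mid) if model.locate(start + mid) else (None, None)
    for g_pos in range(start + 1, model.exon_coords[-1][1] + 1):
        if model.locate(g_pos) is None:
            continue
        gh, _ = fx.gene_and_cds_half(model, g_pos)
        assert gh == ("5p" if model.gene_position(g_pos) <= mid else "3p")


def test_annotate_rejects_ref_mismatch():
    model, _ = build_gene([E1, E2, E3], [I1, I2])
    pos = model.exon_coords[0][0] + 1
    v = RawVariant("v1", model.gene_id, model.chrom, pos, "C", "T", "missense")
    with pytest.raises(ValueError, match="ref allele"):
        fx.annotate_snp(v, model)


def test_parse_variants_flags_intronic_records(tmp_path, biased_bundle):
    models = biased_bundle.models
    m = models[0]
    intron_pos = m.exon_coords[0][1] + 1  # genomic base just inside intron 1
    tsv = tmp_path / "v.tsv"
    rows = ["snp_id\tgene_id\tchrom\tpos\tref\talt\tconsequence",
            f"x1\t{m.gene_id}\t{m.chrom}\t{intron_pos}\tA\tG\tsilent"]
    exonic_pos = m.exon_coords[0][0] + 1
    rows.append(f"x2\t{m.gene_id}\t{m.chrom}\t{exonic_pos}\tA\tG\tsilent")
    tsv.write_text("\n".join(rows) + "\n")
    exonic, non_exonic = fx.parse_variants(tsv, models)
    assert [v.snp_id for v in exonic] == ["x2"]
    assert [v.snp_id for v in non_exonic] == ["x1"]


def test_vcf_and_tsv_annotate_identically(tmp_path, biased_bundle):
    b = biased_bundle
    paths = fx.write_fixture_bundle(tmp_path, b.models, b.genome, b.variants.head(200),
                                    b.truth, b.config.hexamers)
    from_tsv, _ = fx.parse_variants(paths["variants_tsv"], b.models)
    from_vcf, _ = fx.parse_variants(paths["variants_vcf"], b.models)
    rec_tsv = fx.annotate_all(from_tsv, b.models, include_nonsense=True)
    rec_vcf = fx.annotate_all(from_vcf, b.models, include_nonsense=True)
    assert [vars(r) for r in rec_tsv] == [vars(r) for r in rec_vcf]


def test_annotation_agrees_with_brute_force_scan(biased_bundle):
    """Every derived feature recomputed from raw coordinates by an
    independent position scan over the gene's sequences."""
    b = biased_bundle
    by_id = {m.gene_id: m for m in b.models}
    spec = fx.DomainSpec()
    n_checked = 0
    for rec, raw in zip(b.records, fx.raw_variants_from_frame(b.variants)):
        if rec.snp_id != raw.snp_id:  # records drop nothing here (nonsense kept)
            continue
        m = by_id[raw.gene_id]
        # brute force: walk exons in transcript order, counting bases
        found = None
        g_before = 0
        for i, (seq, exon) in enumerate(zip(m.exon_seqs, m.exons)):
            for p in range(1, len(seq) + 1):
                # genomic coordinate of transcript position (i, p)
                if m.strand == "+":
                    gpos = m.exon_coords[i][0] + p
                else:
                    gpos = m.exon_coords[m.n_exons - 1 - i][1] - p + 1
                if gpos == raw.pos:
                    found = (i + 1, p, g_before + p)
            g_before += len(seq) + (
                m.exons[i].downstream_intron_bp or 0
            )
        assert found is not None
        e_idx, e_pos, _ = found
        assert (rec.exon_index, rec.exon_position) == (e_idx, e_pos)
        length = m.exons[e_idx - 1].length
        d = min(e_pos, length - e_pos + 1)
        assert rec.d_nearest == d
        assert rec.domain == fx.classify_domain(d, spec)
        assert rec.exon_half == ("5p" if e_pos <= math.ceil(length / 2) else "3p")
        assert rec.gene_half == (
            "5p" if m.gene_position(raw.pos) <= math.ceil(m.gene_span / 2) else "3p"
        )
        n_checked += 1
        if n_checked >= 150:
            break
    assert n_checked >= 100


def test_domain_counts_partition_internal_snps(biased_bundle):
    internal = [r for r in biased_bundle.records if r.is_internal]
    by_domain = {d: sum(1 for r in internal if r.domain == d)
                 for d in ("splice_site", "end", "core")}
    assert sum(by_domain.values()) == len(internal)
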