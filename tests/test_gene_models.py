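"""Gene-model parsing, filtering, architecture and domain partition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragile_exon as fx
from fragile_exon.models import revcomp

from conftest import build_gene

# a small fully valid toy gene: ATG + glu codons, phases engineered below
E1 = "ATG" + "GAA" * 4          # 15 bp, phase3 = 0
I1 = "GTAAGTTTTTTTTCTTAG"       # 18 bp, gt..ag
E2 = "GAAGAAGAAG"               # 10 bp, phase3 = 1
I2 = "GTTTGTTTTTTTTTTTAG"
E3 = "AAGAA" + "TAA"            # closes frame, stop


@pytest.fixture
def toy():
    return build_gene([E1, E2, E3], [I1, I2], gene_id="toy1")


def test_construction_and_internal_flags(toy):
    model, _ = toy
    assert model.n_exons == 3
    assert [e.index for e in model.exons] == [1, 2, 3]
    assert [e.is_internal for e in model.exons] == [False, True, False]
    assert model.cds_length == len(E1 + E2 + E3)
    assert model.gene_span == model.cds_length + len(I1) + len(I2)


def test_minus_strand_model_is_identical(toy):
    plus, _ = toy
    minus, _ = build_gene([E1, E2, E3], [I1, I2], gene_id="toy1", strand="-")
    assert minus.exon_seqs == plus.exon_seqs
    assert minus.intron_seqs == plus.intron_seqs
    assert [vars(a) == vars(b) for a, b in zip(minus.exons, plus.exons)]


def test_parse_genepred_roundtrip(tmp_path, toy):
    model, genome = toy
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">{model.chrom}\n{genome[model.chrom]}\n")
    ann = tmp_path / "g.genePred"
    starts = ",".join(str(s) for s, _ in model.exon_coords) + ","
    ends = ",".join(str(e) for _, e in model.exon_coords) + ","
    tx0, tx1 = model.exon_coords[0][0], model.exon_coords[-1][1]
    ann.write_text(
        f"{model.gene_id}\t{model.chrom}\t+\t{tx0}\t{tx1}\t{tx0}\t{tx1}\t3\t{starts}\t{ends}\n"
    )
    parsed = fx.parse_gene_models(ann, fasta)
    assert len(parsed) == 1
    assert parsed[0].exon_seqs == model.exon_seqs
    assert parsed[0].intron_seqs == model.intron_seqs
    assert parsed[0].exon_coords == model.exon_coords


def test_parse_errors(tmp_path, toy):
    model, genome = toy
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">{model.chrom}\n{genome[model.chrom]}\n")
    bad_chrom = tmp_path / "bad.genePred"
    bad_chrom.write_text("g1\tchr_missing\t+\t0\t30\t0\t30\t1\t0,\t30,\n")
    with pytest.raises(ValueError, match="chr_missing"):
        fx.parse_gene_models(bad_chrom, fasta)
    malformed = tmp_path / "mal.genePred"
    malformed.write_text("g1\tonly_two_columns\n")
    with pytest.raises(ValueError, match="line 1"):
        fx.parse_gene_models(malformed, fasta)


@pytest.mark.parametrize(
    "exons,rule",
    [
        (["GTG" + E1[3:], E2, E3], "no_ATG"),  # start codon not ATG
        (["ATG" + "TAA" + E1[6:], E2, E3], "internal_stop"),
        ([E1, E2, E3[:-3] + "GGG"], "no_stop"),
        ([E1, "GANGAAGAAG", E3], "ambiguous_N"),
        ([E1, E2 + "G", E3], "bad_frame"),
    ],
)
def test_gene_filters_flag_first_failing_rule(exons, rule):
    model, _ = build_gene(exons, [I1, I2])
    kept, report = fx.apply_gene_filters([model])
    assert kept == []
    assert report.removed[model.gene_id] == rule
    assert report.counts[rule] == 1


def test_gene_filters_intronless_and_valid(toy):
    single, _ = build_gene(["ATGGAAGAATAA"], [])
    model, _ = toy
    kept, report = fx.apply_gene_filters([single, model])
    assert [m.gene_id for m in kept] == [model.gene_id]
    assert report.removed[single.gene_id] == "intronless"


def test_phases_from_cumulative_cds():
    model, _ = build_gene(
        ["ATGGAAGAA", "GAAGAAGAA", "GAAGAATAA"], [I1, I2]
    )  # 9,9,9
    assert [(e.phase5, e.phase3) for e in model.exons] == [(0, 0), (0, 0), (0, 0)]
    assert model.exons[1].is_phase00
    model2, _ = build_gene(["ATGGAAGAAG", E2, "AAGAAGATTTGA"], [I1, I2])  # 10 bp first
    assert model2.exons[0].phase3 == 1
    assert model2.exons[1].phase5 == 1  # frame continuity


def test_phase_continuity_on_simulated_genes(biased_bundle):
    for model in biased_bundle.models[:20]:
        for a, b in zip(model.exons, model.exons[1:]):
            assert a.phase3 == b.phase5


def test_junction_tetranucleotide_case_convention():
    model, _ = build_gene([E1[:-2] + "AG", "GTAGAAGAAG", E3[:-4] + "ATGA"], [I1, I2])
    # exon 1 ends ...AG, intron starts gt -> donor "AGgt"
    assert model.exons[0].donor_tetranucleotide == "AGgt"
    assert model.exons[0].has_donor_AGgt
    # intron 1 ends ag, exon 2 starts GT -> acceptor "agGT"
    assert model.exons[1].acceptor_tetranucleotide == "agGT"
    assert model.exons[1].has_acceptor_agGT
    assert model.exons[1].upstream_intron_bp == len(I1)
    assert model.exons[1].downstream_intron_bp == len(I2)


def test_architecture_rejects_tiny_features():
    model, _ = build_gene([E1, E2, E3], ["GTAG", I2])  # 4 bp intron is the floor
    assert model.exons[1].upstream_intron_bp == 4
    with pytest.raises(ValueError, match="intron"):
        bad, _ = build_gene([E1, E2, E3], ["GTG", I2])
        bad.exons


@pytest.mark.parametrize(
    "length,expected",
    [(100, (6, 94, 0)), (200, (6, 132, 62)), (6, (6, 0, 0)), (7, (6, 1, 0))],
)
def test_domain_partition_examples(length, expected):
    assert fx.domain_partition(length) == expected


@settings(max_examples=200, deadline=None)
@given(st.integers(min_value=1, max_value=600))
def test_domain_partition_matches_position_enumeration(length):
    spec = fx.DomainSpec()
    counts = {"splice_site": 0, "end": 0, "core": 0}
    for p in range(1, length + 1):
        counts[fx.classify_domain(min(p, length - p + 1), spec)] += 1
    assert fx.domain_partition(length, spec) == (
        counts["splice_site"], counts["end"], counts["core"],
    )
    assert sum(fx.domain_partition(length, spec)) == length


@settings(max_examples=100, deadline=None)
@given(st.integers(min_value=1, max_value=600), st.sampled_from(["5p", "3p"]))
def test_half_partition_matches_enumeration(length, half):
    spec = fx.DomainSpec()
    h = -(-length // 2) if half == "5p" else length // 2
    counts = {"splice_site": 0, "end": 0, "core": 0}
    for d in range(1, h + 1):
        counts[fx.classify_domain(d, spec)] += 1
    assert fx.domain_partition(length, spec, half=half) == (
        counts["splice_site"], counts["end"], counts["core"],
    )


def test_revcomp_strand_invariance_of_sequences():
    seq = E1 + I1 + E2
    assert revcomp(revcomp(seq)) == seq
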