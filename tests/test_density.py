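"""Dpi, ESE end density, Goodman-Kruskal gamma and their correlations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragile_exon as fx
from fragile_exon.density import DpiRecord

from conftest import _make_bundle


# ------------------------------------------------------------------ ESE
def test_ese_density_overlapping_matches():
    hx = fx.HexamerSet(frozenset({"GAAGAA"}))
    assert fx.ese_end_density("GAAGAAGAAGAA", hx) == pytest.approx(3 / 7)


def test_ese_density_no_motifs_and_short_error():
    hx = fx.HexamerSet(frozenset({"GAAGAA"}))
    assert fx.ese_end_density("ACGT" * 50, hx) == 0.0
    with pytest.raises(ValueError):
        fx.ese_end_density("ACGTA", hx)


def test_long_exon_density_is_mean_of_two_end_windows():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    hx = fx.default_hexamer_set()
    d5 = sum(seq[i:i+6] in hx for i in range(69 - 5)) / (69 - 5)
    d3 = sum(seq[131+i:131+i+6] in hx for i in range(69 - 5)) / (69 - 5)
    assert fx.ese_end_density(seq, hx) == pytest.approx((d5 + d3) / 2)


def test_ese_density_matches_brute_force_scan():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(6, 300))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        motifs = frozenset(
            "".join(rng.choice(list("ACGT"), size=6)) for _ in range(8)
        )
        hx = fx.HexamerSet(motifs)

        def window(s):
            return sum(s[i:i+6] in motifs for i in range(len(s) - 5)) / (len(s) - 5)

        oracle = (
            0.5 * (window(seq[:69]) + window(seq[-69:])) if n >= 138 else window(seq)
        )
        assert fx.ese_end_density(seq, hx) == pytest.approx(oracle)


# ------------------------------------------------------------------ Dpi
@pytest.mark.parametrize(
    "length,n,n5,expected",
    [
        (100, 2, 1, (0.02, 0.02, 0.02)),
        (100, 0, 0, (0.0, 0.0, 0.0)),
        (100, 1, 1, (0.01, 0.02, 0.0)),
    ],
)
def test_compute_dpi_formulas(length, n, n5, expected):
    assert fx.compute_dpi(length, n, n5) == pytest.approx(expected)


def test_dpi_records_include_zero_snp_exons(biased_bundle):
    b = biased_bundle
    recs = fx.build_dpi_records(b.models, b.records, hexamers=b.config.hexamers)
    internal_total = sum(
        1 for m in b.models for e in m.exons if e.is_internal
        if any(r.gene_id == m.gene_id for r in b.records)
    )
    assert len(recs) == internal_total
    for r in recs:
        assert r.dpi == pytest.approx(r.snp_count / r.exon_length)
        assert 0.0 <= (r.ese_end_density or 0.0) <= 1.0


# ---------------------------------------------------------------- gamma
def test_gamma_perfect_orders():
    g, _ = fx.gk_gamma([1, 2, 3], [1, 2, 3])
    assert g == 1.0
    g, _ = fx.gk_gamma([1, 2, 3], [3, 2, 1])
    assert g == -1.0
    with pytest.raises(ValueError):
        fx.gk_gamma([1, 1, 1], [2, 2, 2])


@settings(max_examples=40, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=60),
    st.data(),
)
def test_gamma_equals_pair_enumeration_oracle(xs, data):
    ys = data.draw(st.lists(st.integers(min_value=0, max_value=5),
                            min_size=len(xs), max_size=len(xs)))
    C = D = 0
    for (x1, y1), (x2, y2) in itertools.combinations(zip(xs, ys), 2):
        if (x1 - x2) * (y1 - y2) > 0:
            C += 1
        elif (x1 - x2) * (y1 - y2) < 0:
            D += 1
    if C + D == 0:
        with pytest.raises(ValueError):
            fx.gk_gamma(xs, ys)
    else:
        g, _ = fx.gk_gamma(xs, ys)
        assert g == pytest.approx((C - D) / (C + D))


# ------------------------------------------------------------ correlations
@pytest.fixture(scope="module")
def short_intron_bundle():
    truth = fx.SyntheticTruth(intron_size_effect=2.0, region="internal_exonic")
    return _make_bundle(80, truth, 3000, seed=501)


def test_dpi_intron_correlation_recovers_planted_sign(short_intron_bundle, uniform_bundle):
    b = short_intron_bundle
    recs = fx.build_dpi_records(b.models, b.records)
    res = fx.correlate_dpi_intron(recs, scope="snp_bearing_only")
    assert res["status"] == "ok"
    assert res["rho"] < 0 and res["p"] < 0.05
    null = fx.correlate_dpi_intron(
        fx.build_dpi_records(uniform_bundle.models, uniform_bundle.records)
    )
    assert abs(null["rho"]) < 0.1


def test_spearman_invariant_under_monotone_transform(short_intron_bundle):
    from scipy import stats

    recs = fx.build_dpi_records(short_intron_bundle.models, short_intron_bundle.records)
    dpi = np.array([r.dpi for r in recs if r.snp_count > 0])
    intron = np.array([float(r.flanking_intron_bp) for r in recs if r.snp_count > 0])
    rho_e = stats.spearmanr(dpi, np.log(intron)).statistic
    rho_10 = stats.spearmanr(dpi, np.log10(intron)).statistic
    rho_raw = stats.spearmanr(dpi, intron).statistic
    assert rho_e == pytest.approx(rho_10) == pytest.approx(rho_raw)


def _mk_dpi(gene, idx, dpi5, dpi3, up, down, n=1):
    return DpiRecord(gene, idx, 100, n, (dpi5 + dpi3) / 2, dpi5, dpi3, None, up, down, min(up, down))


def test_intragene_sign_test_closed_form():
    # 10 genes, each with 5 internal exons in strictly inverse relation
    recs = []
    for g in range(10):
        for i in range(5):
            # larger dpi <-> smaller intron on both halves
            recs.append(_mk_dpi(f"g{g}", i + 2, 0.5 - 0.04 * i, 0.48 - 0.04 * i,
                                1000 + 100 * i, 1050 + 100 * i))
    res = fx.intragene_sign_test(recs, min_snp_exons=5)
    assert (res["n_negative"], res["n_positive"]) == (10, 0)
    assert res["p"] == pytest.approx(2 ** -10, rel=1e-9)


def test_intragene_sign_test_even_split_and_tie_exclusion():
    recs = []
    for g in range(10):
        sign = 1 if g < 5 else -1
        for i in range(5):
            recs.append(_mk_dpi(f"g{g}", i + 2, 0.1 + sign * 0.01 * i,
                                0.1 + sign * 0.011 * i, 1000 + 100 * i, 1040 + 100 * i))
    res = fx.intragene_sign_test(recs, min_snp_exons=5)
    assert res["n_negative"] == res["n_positive"] == 5
    assert res["p"] == pytest.approx(0.623, abs=0.01)
    # a gene whose Dpi never varies is excluded from the counts
    flat = [_mk_dpi("flat", i + 2, 0.1, 0.1, 1000 + i, 1100 + i) for i in range(5)]
    res2 = fx.intragene_sign_test(recs + flat, min_snp_exons=5)
    assert res2["n_negative"] + res2["n_positive"] == 10


def test_dpi_ese_negative_covariance_recovered():
    truth = fx.SyntheticTruth(ese_coupling=30.0, region="internal_exonic")
    b = _make_bundle(80, truth, 3000, seed=601)
    recs = fx.build_dpi_records(b.models, b.records, hexamers=b.config.hexamers)
    res = fx.correlate_dpi_ese(recs)
    assert res["rho"] < 0 and res["gamma"] < 0
    assert res["rho_p"] < 0.05


def test_dpi_ese_independent_placement_is_flat(uniform_bundle):
    b = uniform_bundle
    recs = fx.build_dpi_records(b.models, b.records, hexamers=b.config.hexamers)
    res = fx.correlate_dpi_ese(recs)
    assert abs(res["rho"]) < 0.1
    # rank statistics agree in sign whenever the relation is monotone
    xs = list(range(20))
    ys = [x ** 2 for x in xs]
    g, _ = fx.gk_gamma(xs, ys)
    from scipy import stats

    assert np.sign(g) == np.sign(stats.spearmanr(xs, ys).statistic) == 1
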