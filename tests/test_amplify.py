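"""Two-round amplification semantics on engineered templates."""


import pytest

from pstpcr.amplify import (
    IRAP_LIKE,
    RAPD_LIKE,
    SPECIFIC,
    AmplifyConfig,
    ProtocolWarning,
    ThermalProfile,
    anneal_efficiency,
    pst_pcr_v2,
    simulate_round1,
    simulate_round2,
)
from pstpcr.primer_design import SSPrimer, make_pst_primer
from pstpcr.seqcore import reverse_complement
from pstpcr.synth import generate_host

HYB = "CGGTGAAACGGTCGGGAAACTAGCTCT"  # 27 nt


@pytest.fixture
def ssp():
    return SSPrimer(id="s", hybridizing=HYB)


@pytest.fixture
def pst():
    return make_pst_primer("GACGTC", 10, id="p")


def clean_host(length, seed=9):
    """Random host with no walking-primer site and no SSP match."""
    host = generate_host(length, 0.45, seed).replace("GACGTC", "GACGAC")
    assert HYB not in host
    return host


def build(host, inserts):
    """Place substrings at fixed positions, overwriting the host."""
    t = list(host)
    for pos, s in inserts:
        t[pos : pos + len(s)] = list(s)
    return "".join(t)


class TestThermalProfile:
    def test_defaults_follow_protocol(self):
        p = ThermalProfile()
        assert (p.round1_linear_cycles, p.round1_exp_cycles, p.round2_cycles) == (20, 3, 28)
        assert p.round1_linear_anneal_C > p.round1_exp_anneal_C

    def test_inverted_anneal_ordering_rejected(self):
        with pytest.raises(ValueError):
            ThermalProfile(round1_linear_anneal_C=60, round1_exp_anneal_C=72)

    def test_excess_exponential_cycles_warn(self):
        with pytest.warns(ProtocolWarning):
            ThermalProfile(round1_exp_cycles=8)


class TestSpecificProducts:
    def test_worked_length_example(self, ssp, pst):
        """SSP at [100,127) extending right, palindrome at [600,606):
        total length = (606-100) + 10 + 2*19 = 554."""
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        products = pst_pcr_v2(t, ssp, pst)
        assert [p.product_class for p in products] == [SPECIFIC]
        assert products[0].total_length == 554
        assert (products[0].genomic_span.start, products[0].genomic_span.end) == (100, 616)

    def test_product_sequence_is_template_plus_adaptors(self, ssp, pst):
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        (p,) = pst_pcr_v2(t, ssp, pst, with_sequences=True)
        assert p.sequence == (
            ssp.adaptor + t[100:616] + reverse_complement(pst.adaptor)
        )

    def test_window_bound_excludes_distant_palindrome(self, ssp, pst):
        t = build(clean_host(4200), [(100, HYB), (3600, "GACGTC")])
        assert pst_pcr_v2(t, ssp, pst) == []

    def test_three_insertions_three_bands(self, ssp, pst):
        host = clean_host(12000)
        inserts, expected = [], []
        for k, (a, gap) in enumerate(zip((100, 4100, 8100), (500, 900, 1400))):
            inserts += [(a, HYB), (a + len(HYB) + gap, "GACGTC")]
            expected.append(len(HYB) + gap + 6 + 10 + 38)
        t = build(host, inserts)
        products = pst_pcr_v2(t, ssp, pst)
        assert sorted(p.total_length for p in products) == sorted(expected)

    def test_reverse_complement_template_mirrors_lengths(self, ssp, pst):
        t = build(clean_host(1500), [(100, HYB), (700, "GACGTC")])
        a = sorted(p.total_length for p in pst_pcr_v2(t, ssp, pst))
        b = sorted(p.total_length for p in pst_pcr_v2(reverse_complement(t), ssp, pst))
        assert a == b


class TestControls:
    def test_pst_only_no_products_at_default_profile(self, pst):
        t = build(clean_host(3000), [(500, "GACGTC"), (1300, "GACGTC")])
        assert pst_pcr_v2(t, pst=pst) == []

    def test_ssp_only_no_products_without_inverted_copy(self, ssp):
        t = build(clean_host(3000), [(500, HYB)])
        assert pst_pcr_v2(t, ssp=ssp) == []

    def test_inverted_ssp_copies_give_irap_product(self, ssp):
        t = build(
            clean_host(3000),
            [(500, HYB), (1300 + len(HYB), reverse_complement(HYB))],
        )
        products = pst_pcr_v2(t, ssp=ssp)
        assert [p.product_class for p in products] == [IRAP_LIKE]

    def test_proofreading_polymerase_kills_walking_products(self, ssp, pst):
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        cfg = AmplifyConfig(proofreading=True)
        assert pst_pcr_v2(t, ssp, pst, config=cfg) == []


class TestRapdThreshold:
    def template(self):
        return build(clean_host(3000), [(500, "GACGTC"), (1306, "GACGTC")])

    def test_silent_at_recommended_cycles(self, pst):
        prof = ThermalProfile(round1_exp_cycles=3)
        products = simulate_round1(self.template(), pst=pst, profile=prof)
        assert [p for p in products if p.product_class == RAPD_LIKE] == []

    def test_appears_past_threshold(self, pst):
        with pytest.warns(ProtocolWarning):
            prof = ThermalProfile(round1_linear_cycles=25, round1_exp_cycles=25)
        products = simulate_round1(self.template(), pst=pst, profile=prof)
        rapd = [p for p in products if p.product_class == RAPD_LIKE]
        assert len(rapd) == 1
        # span covers both palindromes plus both degenerate flanks
        assert rapd[0].genomic_span.start == 500 - 10
        assert rapd[0].genomic_span.end == 1306 + 6 + 10


class TestRound2:
    def test_foreign_adaptor_dropped(self, pst):
        ssp_other = SSPrimer(id="o", hybridizing=HYB, adaptor="ACGTACGTACGTACGTACG")
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        round1 = simulate_round1(t, ssp_other, pst)
        assert len(round1) == 1
        final = simulate_round2(round1, tail_primer=pst.adaptor)
        assert final == []

    def test_round2_multiplies_yield(self, ssp, pst):
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        (r1,) = simulate_round1(t, ssp, pst)
        (r2,) = simulate_round2([r1], tail_primer=ssp.adaptor)
        assert r2.relative_yield > r1.relative_yield

    def test_output_sorted_by_length_descending(self, ssp, pst):
        t = build(
            clean_host(6000),
            [(100, HYB), (900, "GACGTC"), (3100, HYB), (5000, "GACGTC")],
        )
        products = pst_pcr_v2(t, ssp, pst)
        lengths = [p.total_length for p in products]
        assert lengths == sorted(lengths, reverse=True)


class TestYieldModel:
    def test_logistic_midpoint(self):
        assert anneal_efficiency(65.0, 65.0) == pytest.approx(0.5)

    def test_raising_exp_anneal_never_raises_yield(self, ssp, pst):
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        yields = []
        for temp in (55, 60, 65):
            prof = ThermalProfile(round1_exp_anneal_C=temp)
            (p,) = pst_pcr_v2(t, ssp, pst, profile=prof)
            yields.append(p.relative_yield)
        assert yields == sorted(yields, reverse=True)

    def test_doubling_round2_cycles_squares_multiplier(self, ssp, pst):
        t = build(clean_host(1000), [(100, HYB), (600, "GACGTC")])
        (r1,) = simulate_round1(t, ssp, pst)
        (y14,) = simulate_round2([r1], ssp.adaptor, ThermalProfile(round2_cycles=14))
        (y28,) = simulate_round2([r1], ssp.adaptor, ThermalProfile(round2_cycles=28))
        m14 = y14.relative_yield / r1.relative_yield
        m28 = y28.relative_yield / r1.relative_yield
        assert m28 == pytest.approx(m14**2, rel=1e-9)
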