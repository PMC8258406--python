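"""Synthetic hosts, elements, insertions, and cohort guarantees."""

import pytest

from pstpcr.display import run_transposon_display
from pstpcr.seqcore import reverse_complement
from pstpcr.site_scan import find_ssp_sites
from pstpcr.synth import (
    AC_ELEMENT_LEN,
    TSD_LEN,
    generate_host,
    implant,
    make_element,
    ssp_for_element,
)


class TestGenerateHost:
    def test_seed_determinism(self):
        assert generate_host(10_000, 0.5, 42) == generate_host(10_000, 0.5, 42)
        assert generate_host(1000, 0.5, 1) != generate_host(1000, 0.5, 2)

    def test_gc_fraction_concentrates(self):
        host = generate_host(100_000, 0.9, 0)
        gc = sum(b in "GC" for b in host) / len(host)
        assert gc == pytest.approx(0.9, abs=0.02)

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (100, 0.0), (100, 1.5)])
    def test_invalid_parameters(self, length, gc):
        with pytest.raises(ValueError):
            generate_host(length, gc, 0)


class TestMakeElement:
    def test_default_is_ac_sized_with_tir(self):
        e = make_element(seed=3)
        s = e.element_sequence
        assert len(s) == AC_ELEMENT_LEN
        assert s[:11] == reverse_complement(s[-11:])

    def test_tag_regions_near_termini(self):
        e = make_element(seed=3)
        five, three = e.tag_regions
        assert five.end <= 200
        assert three.start >= len(e.element_sequence) - 200

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_element(length=150)

    def test_excluded_motif_absent_from_termini(self):
        e = make_element(seed=3, exclude_motifs=["GACGTC"])
        s = e.element_sequence
        assert "GACGTC" not in s[:200] and "GACGTC" not in s[-200:]

    def test_terminal_ssp_extends_across_element_end(self):
        e = make_element(seed=3)
        ssp = ssp_for_element(e, "3prime")
        sites = find_ssp_sites(e.element_sequence, ssp)
        assert len(sites) == 1 and sites[0].extension_direction == "right"


class TestImplant:
    def test_length_arithmetic(self):
        host = generate_host(10_000, 0.5, 4)
        elem = make_element(seed=5).element_sequence
        genome, records = implant(host, elem, [6000])
        assert len(genome) == 10_000 + AC_ELEMENT_LEN + TSD_LEN
        assert len(records) == 1 and records[0].final_position == 6000

    def test_target_site_duplicated(self):
        host = generate_host(10_000, 0.5, 4)
        elem = make_element(seed=5).element_sequence
        genome, (rec,) = implant(host, elem, [6000])
        left = genome[rec.final_position - TSD_LEN : rec.final_position]
        right = genome[
            rec.final_position + len(elem) : rec.final_position + len(elem) + TSD_LEN
        ]
        assert left == right == host[6000 - TSD_LEN : 6000]

    def test_no_insertions_is_identity(self):
        host = generate_host(500, 0.5, 4)
        genome, records = implant(host, "ACGT" * 100, [])
        assert genome == host and records == []

    def test_overlapping_insertions_rejected(self):
        host = generate_host(1000, 0.5, 4)
        with pytest.raises(ValueError):
            implant(host, "ACGT" * 100, [500, 503])

    def test_reverse_orientation_inserts_reverse_complement(self):
        host = generate_host(2000, 0.5, 4)
        elem = make_element(length=400, seed=5).element_sequence
        genome, (rec,) = implant(host, elem, [1000], orientations=["-"])
        inserted = genome[rec.final_position : rec.final_position + len(elem)]
        assert inserted == reverse_complement(elem)

    def test_multiple_insertions_track_final_coordinates(self):
        host = generate_host(20_000, 0.5, 4)
        elem = make_element(length=400, seed=5).element_sequence
        genome, records = implant(host, elem, [12_000, 3000])
        by_id = {r.insertion_id: r for r in records}
        grow = len(elem) + TSD_LEN
        positions = sorted(r.host_position for r in records)
        assert positions == [3000, 12_000]
        for rec in records:
            n_before = sum(p < rec.host_position for p in positions)
            assert rec.final_position == rec.host_position + n_before * grow
            assert (
                genome[rec.final_position : rec.final_position + len(elem)] == elem
            )


class TestCohort:
    def test_panel_structure(self, cohort):
        assert len(cohort.samples) == 6  # 4 lines + 2 hybrids
        hybrids = cohort.manifest[cohort.manifest["parents"] != ""]
        assert len(hybrids) == 2
        for _, row in hybrids.iterrows():
            assert len(cohort.samples[row["sample_id"]]) == 2

    def test_seed_determinism(self):
        from pstpcr.synth import make_cohort

        a = make_cohort(seed=11)
        b = make_cohort(seed=11)
        assert a.truth.equals(b.truth)
        assert a.samples["B73"][0][1] == b.samples["B73"][0][1]

    def test_hybrid_truth_is_union_of_parents(self, cohort):
        truth = cohort.truth
        for _, row in cohort.manifest.iterrows():
            if not row["parents"]:
                continue
            pa, pb = row["parents"].split(",")
            ins = set(truth[truth["sample_id"] == pa]["insertion_id"]) | set(
                truth[truth["sample_id"] == pb]["insertion_id"]
            )
            # hybrids carry both haplotypes, no rows of their own needed
            assert ins <= set(truth["insertion_id"])

    def test_every_insertion_has_in_window_palindrome(self, cohort):
        assert (cohort.truth["palindrome_distance"] >= 0).all()
        assert (
            cohort.truth["expected_band_length"] <= 3000 + 38
        ).all()

    def test_full_circle_band_recovery(self, cohort):
        """Amplifying each line recovers exactly the truth-table band for
        every implanted insertion, at the predicted length."""
        patterns = run_transposon_display(cohort.samples, cohort.ssp, cohort.pst)
        truth = cohort.truth
        for line in set(truth["sample_id"]):
            expected = sorted(
                truth[truth["sample_id"] == line]["expected_band_length"]
            )
            assert list(patterns[line].band_lengths) == expected

    def test_write_cohort_artifacts(self, cohort, tmp_path):
        from pstpcr.seqcore import read_fasta
        from pstpcr.synth import write_cohort

        write_cohort(cohort, tmp_path)
        assert (tmp_path / "truth.tsv").exists()
        assert (tmp_path / "truth.bed").exists()
        recs = read_fasta(tmp_path / "B73xMo17.fasta")
        assert len(recs) == 2  # two haplotypes
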