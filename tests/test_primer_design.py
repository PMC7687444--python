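import numpy as np
import pytest

from aspcr.diagnostics import DiagnosticSite, find_diagnostic_sites
from aspcr.errors import ConfigurationError, GapError, GeometryError
from aspcr.insilico_pcr import BindingModel, find_binding_sites
from aspcr.primer_design import (
    AssayDesign,
    Primer,
    amplicon_size,
    default_destabilizing_replacement,
    design_allele_specific_primer,
    design_assay,
    design_companion_primer,
    design_from_dict,
    design_to_dict,
    introduce_destabilizing_mismatch,
    perfect_match_primer,
    validate_design,
    write_design_json,
    write_design_tsv,
)
from aspcr.seqio import SequenceRecord, reverse_complement
from aspcr.synthetic_data import generate_alignment, paper_shaped_spec

CNR = "GGTTTCGGTCTGTTAATAGTATTTTG"
CNF = "TATCGTAACCGCACATGCATT"


def random_template(seed=0, length=574):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def reconstructed_template():
    """574 bp template carrying the printed primers' binding footprints:
    the forward primer at [32, 52] and the reverse (perfect-match form,
    engineered edit reverted) at [480, 505]."""
    tpl = random_template(seed=99)
    perfect_cnr = CNR[:-3] + "G" + CNR[-2:]
    tpl = tpl[:31] + CNF + tpl[52:]
    tpl = tpl[:479] + reverse_complement(perfect_cnr) + tpl[505:]
    return tpl


@pytest.fixture
def site480():
    return DiagnosticSite(480, "Cervus nippon", "C", frozenset("T"), True)


class TestPerfectMatchPrimer:
    def test_minus_three_prime_complements_anchor(self):
        tpl = random_template(1)
        pos = 300
        tpl = tpl[:pos - 1] + "C" + tpl[pos:]
        p = perfect_match_primer(tpl, pos, 20, "minus")
        assert p.three_prime_base == "G"
        assert (p.template_start, p.template_end) == (pos, pos + 19)
        assert p.seq == reverse_complement(tpl[pos - 1 : pos + 19])

    def test_plus_footprint_arithmetic(self):
        tpl = random_template(2)
        p = perfect_match_primer(tpl, 100, 18, "plus")
        assert (p.template_start, p.template_end) == (83, 100)
        assert p.seq == tpl[82:100]
        assert p.three_prime_base == tpl[99]

    def test_self_match_under_aligner(self):
        tpl = random_template(3)
        p = perfect_match_primer(tpl, 200, 22, "minus")
        sites = find_binding_sites(p, SequenceRecord("t", "S", tpl))
        exact = [s for s in sites if not s.mismatch_offsets]
        assert len(exact) == 1
        assert exact[0].strand == "minus"
        assert exact[0].footprint == (200, 221)
        assert exact[0].extendable

    def test_out_of_bounds(self):
        with pytest.raises(GeometryError):
            perfect_match_primer(random_template(4, 100), 95, 20, "minus")
        with pytest.raises(GeometryError):
            perfect_match_primer(random_template(4, 100), 10, 20, "plus")

    def test_gap_in_footprint(self):
        tpl = random_template(5, 100)
        tpl = tpl[:50] + "-" + tpl[51:]
        with pytest.raises(GapError):
            perfect_match_primer(tpl, 45, 20, "minus")

    def test_too_short(self):
        with pytest.raises(GeometryError):
            perfect_match_primer(random_template(6), 100, 10, "plus")


class TestDestabilizingMismatch:
    def test_paper_rule_g_to_t(self):
        assert default_destabilizing_replacement("G", "C") == "T"

    @pytest.mark.parametrize(
        "perfect,template,expected",
        [("G", "C", "T"), ("C", "G", "A"), ("T", "A", "G"), ("A", "T", "C")],
    )
    def test_rule_table(self, perfect, template, expected):
        got = default_destabilizing_replacement(perfect, template)
        assert got == expected
        # always a transversion of the perfect-match base
        purines = set("AG")
        assert (got in purines) != (perfect in purines)

    def test_edit_recorded(self, reconstructed_template, site480):
        p = perfect_match_primer(reconstructed_template, 480, 26, "minus")
        edited = introduce_destabilizing_mismatch(p, reconstructed_template, 3)
        assert edited.edits[0].original_base == "G"
        assert edited.edits[0].replacement_base == "T"
        assert edited.seq == CNR

    def test_offset_one_refused(self, reconstructed_template):
        p = perfect_match_primer(reconstructed_template, 480, 26, "minus")
        with pytest.raises(GeometryError):
            introduce_destabilizing_mismatch(p, reconstructed_template, 1)

    def test_replacement_equal_original_is_noop_error(self, reconstructed_template):
        p = perfect_match_primer(reconstructed_template, 480, 26, "minus")
        with pytest.raises(ConfigurationError):
            introduce_destabilizing_mismatch(p, reconstructed_template, 3, "G")

    def test_adds_exactly_one_mismatch(self):
        tpl = random_template(7)
        rec = SequenceRecord("t", "S", tpl)
        p = perfect_match_primer(tpl, 300, 24, "minus")
        edited = introduce_destabilizing_mismatch(p, tpl, 3)
        before = min(len(s.mismatch_offsets)
                     for s in find_binding_sites(p, rec) if s.strand == "minus")
        model = BindingModel(max_total_mismatches=3)
        after_sites = [s for s in find_binding_sites(edited, rec, model)
                       if s.strand == "minus" and s.footprint == (300, 323)]
        assert before == 0
        assert after_sites[0].mismatch_offsets == (3,)


class TestDesignAS:
    def test_reproduces_printed_reverse_primer(self, reconstructed_template, site480):
        p = design_allele_specific_primer(reconstructed_template, site480, 26, "minus")
        assert p.seq == CNR
        assert p.three_prime_base == "G"
        assert len(p.edits) == 1 and p.edits[0].offset_from_3prime == 3

    def test_synthetic_planted_site(self):
        aln, truth = generate_alignment(paper_shaped_spec(seed=5))
        site = find_diagnostic_sites(aln, "Cervus nippon")[0]
        tpl = aln.records_for("Cervus nippon")[0].seq
        p = design_allele_specific_primer(tpl, site, 26, "minus")
        assert p.three_prime_base == "G"  # complement of planted C
        assert len(p.edits) == 1
        assert p.edits[0].offset_from_3prime == 3

    def test_allele_mismatch_guard(self, reconstructed_template, site480):
        tpl = reconstructed_template[:479] + "T" + reconstructed_template[480:]
        with pytest.raises(ConfigurationError):
            design_allele_specific_primer(tpl, site480, 26, "minus")

    def test_deterministic(self, reconstructed_template, site480):
        a = design_allele_specific_primer(reconstructed_template, site480, 26, "minus")
        b = design_allele_specific_primer(reconstructed_template, site480, 26, "minus")
        assert a == b

    def test_offset_bounds(self, reconstructed_template, site480):
        with pytest.raises(ConfigurationError):
            design_allele_specific_primer(
                reconstructed_template, site480, 26, "minus", mismatch_offset=6
            )


class TestCompanion:
    def test_product_range_respected(self):
        tpl = random_template(8, 600)
        tpl = tpl[:549] + "C" + tpl[550:]
        site = DiagnosticSite(550, "X", "C", frozenset("T"), True)
        asp = design_allele_specific_primer(tpl, site, 26, "minus")
        cands = design_companion_primer(tpl, asp, product_range=(400, 500))
        assert cands
        for c in cands:
            assert 400 <= amplicon_size(c, asp) <= 500
            assert c.strand == "plus"
            assert 18 <= len(c.seq) <= 25

    def test_matches_exhaustive_enumeration(self):
        tpl = random_template(9, 400)
        tpl = tpl[:349] + "C" + tpl[350:]
        site = DiagnosticSite(350, "X", "C", frozenset("T"), True)
        asp = design_allele_specific_primer(tpl, site, 26, "minus")
        cands = design_companion_primer(tpl, asp, product_range=(150, 350))
        starts = {(c.template_start, len(c.seq)) for c in cands}
        # oracle: enumerate every admissible window independently
        from aspcr.thermo import gc_content, tm_nearest_neighbor
        expected = set()
        for L in range(18, 26):
            for start in range(1, 350 - L + 1):
                prod = 375 - start + 1
                if not 150 <= prod <= 350:
                    continue
                w = tpl[start - 1 : start + L - 1]
                tail_rc = reverse_complement(w[-5:])
                if tail_rc in w or tail_rc in asp.seq:
                    continue
                if not 55 <= tm_nearest_neighbor(w) <= 65:
                    continue
                if not 0.35 <= gc_content(w) <= 0.65:
                    continue
                expected.add((start, L))
        assert starts == expected

    def test_infeasible_geometry_empty(self):
        tpl = random_template(10, 200)
        tpl = tpl[:149] + "C" + tpl[150:]
        site = DiagnosticSite(150, "X", "C", frozenset("T"), True)
        asp = design_allele_specific_primer(tpl, site, 26, "minus")
        assert design_companion_primer(tpl, asp, product_range=(30, 40)) == []

    def test_ranking_minimizes_tm_gap(self):
        tpl = random_template(11, 600)
        tpl = tpl[:549] + "C" + tpl[550:]
        site = DiagnosticSite(550, "X", "C", frozenset("T"), True)
        asp = design_allele_specific_primer(tpl, site, 26, "minus")
        cands = design_companion_primer(tpl, asp, product_range=(200, 500))
        gaps = [abs(c.tm_c - asp.tm_c) for c in cands]
        assert gaps == sorted(gaps)


class TestAmpliconSize:
    def test_paper_geometry_474(self):
        fwd = Primer("f", "A" * 21, "plus", 32, 52)
        rev = Primer("r", "A" * 26, "minus", 480, 505)
        assert amplicon_size(fwd, rev) == 474

    def test_degenerate_overlap(self):
        fwd = Primer("f", "A" * 20, "plus", 1, 20)
        rev = Primer("r", "A" * 20, "minus", 1, 20)
        assert amplicon_size(fwd, rev) == 20

    def test_sequence_edits_irrelevant(self):
        rev1 = Primer("r", "A" * 26, "minus", 480, 505)
        rev2 = Primer("r", "C" * 26, "minus", 480, 505)
        fwd = Primer("f", "G" * 21, "plus", 32, 52)
        assert amplicon_size(fwd, rev1) == amplicon_size(fwd, rev2)

    def test_wrong_strands(self):
        fwd = Primer("f", "A" * 20, "plus", 1, 20)
        with pytest.raises(GeometryError):
            amplicon_size(fwd, fwd)


class TestValidateAndSerialize:
    @pytest.fixture
    def designed(self):
        aln, _ = generate_alignment(paper_shaped_spec(seed=6))
        site = find_diagnostic_sites(aln, "Cervus nippon")[0]
        tpl = aln.records_for("Cervus nippon")[0].seq
        return aln, design_assay(tpl, site)

    def test_pipeline_design_passes(self, designed):
        aln, assay = designed
        report = validate_design(assay, aln)
        assert report["passed"], [c for c in report["checks"] if not c["passed"]]

    def test_mutated_anchor_fails(self, designed):
        aln, assay = designed
        rev = assay.reverse
        bad_seq = rev.seq[:-1] + ("A" if rev.seq[-1] != "A" else "C")
        bad_rev = Primer(rev.name, bad_seq, rev.strand, rev.template_start,
                         rev.template_end, rev.edits, rev.tm_c, rev.gc_frac)
        bad = AssayDesign(assay.forward, bad_rev, assay.target_species,
                          assay.anchor_site, assay.product_bp)
        report = validate_design(bad, aln)
        failed = {c["name"] for c in report["checks"] if not c["passed"]}
        assert "anchor_base" in failed

    def test_tampered_product_fails_constructor(self, designed):
        _, assay = designed
        with pytest.raises(GeometryError):
            AssayDesign(assay.forward, assay.reverse, assay.target_species,
                        assay.anchor_site, assay.product_bp + 1)

    def test_json_round_trip(self, designed, tmp_path):
        import json
        _, assay = designed
        p = tmp_path / "design.json"
        write_design_json(assay, p)
        back = design_from_dict(json.loads(p.read_text()))
        assert back.forward.seq == assay.forward.seq
        assert back.reverse.seq == assay.reverse.seq
        assert back.reverse.edits == assay.reverse.edits
        assert back.product_bp == assay.product_bp

    def test_tsv_report(self, designed, tmp_path):
        _, assay = designed
        p = tmp_path / "design.tsv"
        write_design_tsv(assay, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 3
        assert lines[1].startswith("forward\t")
        assert "@-3" in lines[2]


def test_printed_primer_facts():
    """Facts assertable from the printed primer strings alone."""
    assert len(CNR) == 26
    assert len(CNF) == 21
    assert CNR[-1] == "G"          # complement of the diagnostic C
    assert CNR[-3] == "T"          # engineered antepenultimate base
    perfect = CNR[:-3] + "G" + CNR[-2:]
    assert perfect[-3] == "G"      # the perfect-match base it replaced
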