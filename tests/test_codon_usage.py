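"""Codon counting, GC3, Wright's ENC and the Nc-plot machinery."""

import numpy as np
import pytest

from rnasig import (
    CodonUsageTable,
    codon_counts,
    enc_expected,
    enc_observed,
    enc_ratio,
    family_proportions,
    family_ranking,
    gc3,
    nc_plot_data,
)
from rnasig.codon_usage import (
    CODON_BOXES,
    DEGENERACY_CLASSES,
    FAMILIES,
    GENETIC_CODE,
    CodonError,
    classify_enc_ratio,
    codon_usage_report,
)
from rnasig import reference as ref
from rnasig.synthetic import generate_orf, uniform_codon_freqs


def naive_enc(counts: dict[str, int]) -> float:
    """Independent brute-force ENC: plain loops over Wright's definitions."""
    fbar = {}
    for k in (2, 3, 4, 6):
        fs = []
        for aa, codons in FAMILIES.items():
            if len(codons) != k:
                continue
            n = sum(counts.get(c, 0) for c in codons)
            if n < 2:
                continue
            s = 0.0
            for c in codons:
                s += (counts.get(c, 0) / n) ** 2
            f = (n * s - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            fbar[k] = sum(fs) / len(fs)
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    return 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]


def orf_from_counts(counts: dict[str, int]) -> str:
    """Rebuild an ORF realizing a codon-count table exactly (order arbitrary)."""
    codons = []
    for codon, n in sorted(counts.items()):
        codons.extend([codon] * n)
    codons.remove("AUG")  # one AUG serves as the start codon
    return "AUG" + "".join(codons) + "UGA"


def test_genetic_code_family_structure():
    assert len(GENETIC_CODE) == 61
    sizes = sorted(len(c) for c in FAMILIES.values())
    assert sizes.count(1) == 2 and sizes.count(2) == 9  # Met/Trp; 9 two-fold
    assert sizes.count(3) == 1 and sizes.count(4) == 5 and sizes.count(6) == 3
    assert DEGENERACY_CLASSES[3] == ("I",)


class TestCodonCounts:
    def test_minimal_orf(self):
        t = codon_counts("AUGAAAUAA")
        assert t.counts["AUG"] == 1 and t.counts["AAA"] == 1 and t.n_codons == 2

    def test_internal_stop_named(self):
        with pytest.raises(CodonError, match="internal stop"):
            codon_counts("AUGUAAAAAUAA")

    def test_bad_frame_rejected(self):
        with pytest.raises(CodonError, match="multiple of 3"):
            codon_counts("AUGAAAU")

    def test_must_start_with_aug_and_end_with_stop(self):
        with pytest.raises(CodonError):
            codon_counts("AAAAAAUAA")
        with pytest.raises(CodonError):
            codon_counts("AUGAAAAAA")

    def test_published_codon_table_round_trip(self):
        """An ORF realizing the published counts is counted back exactly."""
        t = codon_counts(orf_from_counts(ref.ORF_CODON_COUNTS))
        assert t.counts == ref.ORF_CODON_COUNTS
        assert t.n_codons == 3419
        assert t.counts["AUG"] == 130 and t.counts["AAG"] == 111
        assert t.counts["GGA"] == 150


class TestFamilyProportions:
    def test_published_asn_proportions(self):
        props = family_proportions(ref.published_codon_usage())
        assert round(props["AAU"], 2) == 0.35 and round(props["AAC"], 2) == 0.65

    def test_single_member_family(self):
        props = family_proportions(ref.published_codon_usage())
        assert props["AUG"] == 1.0 and props["UGG"] == 1.0

    def test_absent_family_flagged_nan(self):
        t = CodonUsageTable({"AUG": 5, "AAA": 3, "AAG": 2})
        props = family_proportions(t)
        assert np.isnan(props["UGU"])

    def test_proportions_sum_to_one_per_family(self):
        props = family_proportions(ref.published_codon_usage())
        for codons in FAMILIES.values():
            assert sum(props[c] for c in codons) == pytest.approx(1.0)


class TestFamilyRanking:
    @pytest.mark.parametrize(
        "box,expected",
        [
            ("P", "A > C > U > G"),  # Pro
            ("F", "C = U"),  # Phe 45/46
            ("S:AG", "C = U"),  # Ser two-codon box 36/38
            ("Q", "G = A"),  # Gln 38/38, equal counts
            ("D", "C > U"),  # Asp 61/93
            ("G", "A > G > C > U"),  # Gly
        ],
    )
    def test_published_rankings(self, box, expected):
        assert family_ranking(ref.published_codon_usage(), box) == expected

    def test_equal_counts_tie_regardless_of_delta(self):
        t = CodonUsageTable({"CAA": 10, "CAG": 10, "AUG": 1})
        assert family_ranking(t, "Q", tie_delta=0.0) == "G = A"

    def test_absent_family_yields_empty_ranking(self):
        t = CodonUsageTable({"AUG": 1})
        assert family_ranking(t, "Q") == ""

    def test_unknown_box_rejected(self):
        with pytest.raises(CodonError):
            family_ranking(ref.published_codon_usage(), "Leu")


class TestGC3:
    def test_all_gc_ending(self):
        assert gc3("AUG" + "GCG" * 500 + "UAA") == pytest.approx(1.0, abs=0.005)
        assert gc3("AUG" + "GCG" * 500 + "UAA", synonymous_only=True) == 1.0

    def test_all_au_ending(self):
        # the obligatory start codon contributes its G third position under
        # the all-sense definition; the synonymous-only variant is exactly 0
        assert gc3("AUG" + "GCA" * 500 + "UAA") == pytest.approx(0.0, abs=0.005)
        assert gc3("AUG" + "GCA" * 500 + "UAA", synonymous_only=True) == 0.0

    def test_published_table_value(self):
        # all-sense-codon definition; the synonymous-only variant runs lower
        assert round(gc3(ref.published_codon_usage()), 2) == 0.54
        assert round(gc3(ref.published_codon_usage(), synonymous_only=True), 2) == 0.51

    def test_no_codons_rejected(self):
        with pytest.raises(CodonError):
            gc3(CodonUsageTable({}))


class TestEncObserved:
    def test_uniform_usage_approaches_61(self):
        t = CodonUsageTable({c: 1000 for c in GENETIC_CODE})
        assert enc_observed(t) == pytest.approx(61.0, abs=0.1)
        assert enc_observed(t) <= 61.0

    def test_maximal_bias_is_20(self):
        t = CodonUsageTable({codons[0]: 1000 for codons in FAMILIES.values()})
        assert enc_observed(t) == pytest.approx(20.0, abs=1e-9)

    def test_matches_independent_brute_force(self):
        rng = np.random.default_rng(11)
        freqs = rng.dirichlet(np.ones(61))
        codons = sorted(GENETIC_CODE)
        orf = generate_orf(dict(zip(codons, freqs)), 4000, seed=11)
        t = codon_counts(orf)
        assert enc_observed(t, cap=False) == pytest.approx(
            naive_enc(dict(t.counts)), rel=1e-12
        )

    def test_published_table_enc(self):
        t = ref.published_codon_usage()
        assert enc_observed(t) == pytest.approx(52.97, abs=0.01)

    def test_invariant_under_within_family_permutation(self):
        t = dict(ref.ORF_CODON_COUNTS)
        # swap counts of two Pro codons: family proportions multiset unchanged
        t["CCA"], t["CCC"] = t["CCC"], t["CCA"]
        assert enc_observed(CodonUsageTable(t)) == pytest.approx(
            enc_observed(ref.published_codon_usage())
        )

    def test_concentrating_usage_never_increases_enc(self):
        base = dict(ref.ORF_CODON_COUNTS)
        enc0 = enc_observed(ref.published_codon_usage())
        shifted = dict(base)
        shifted["GGA"] += shifted["GGU"]  # pour Gly usage into its modal codon
        shifted["GGU"] = 0
        assert enc_observed(CodonUsageTable(shifted)) <= enc0

    def test_small_sample_warns(self):
        orf = "AUG" + "AAA" * 3 + "AAG" * 2 + "GGA" * 3 + "GGG" * 2 \
            + "CUG" * 3 + "CUA" * 2 + "UAA"
        with pytest.warns(UserWarning, match="unstable"):
            enc_observed(codon_counts(orf))

    def test_ile_fallback_from_neighbor_classes(self):
        counts = {c: 50 for aa, cs in FAMILIES.items() for c in cs if aa != "I"}
        t = CodonUsageTable(counts)
        enc = enc_observed(t)  # 3-fold class empty -> mean of 2- and 4-fold
        assert 55.0 < enc <= 61.0


class TestEncExpected:
    def test_closed_form_at_half(self):
        assert enc_expected(0.5) == pytest.approx(60.5, abs=1e-12)

    def test_low_gc3_limit(self):
        assert enc_expected(1e-9) == pytest.approx(31.0, abs=1e-6)

    def test_symmetry_up_to_linear_term(self):
        for s in (0.1, 0.25, 0.4):
            assert enc_expected(s) - s == pytest.approx(enc_expected(1 - s) - (1 - s))

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.5])
    def test_domain_enforced(self, s):
        with pytest.raises(CodonError):
            enc_expected(s)


def test_enc_ratio_and_bands():
    assert enc_ratio(60.5, 60.5) == 1.0
    assert classify_enc_ratio(0.9).startswith("very weak")
    assert classify_enc_ratio(0.7) == "weak codon bias"
    t = ref.published_codon_usage()
    assert enc_ratio(enc_observed(t), enc_expected(gc3(t))) > 0.88


class TestNcPlot:
    def test_single_table_single_row(self):
        points, curve = nc_plot_data([ref.published_codon_usage()], ["MR-766"])
        assert len(points) == 1 and points.loc[0, "label"] == "MR-766"
        assert len(curve) == 99
        assert curve["enc_exp"].max() <= 62.0

    def test_identical_tables_identical_rows(self):
        points, _ = nc_plot_data([ref.published_codon_usage()] * 2, ["a", "b"])
        assert points.loc[0, "gc3"] == points.loc[1, "gc3"]
        assert points.loc[0, "enc_obs"] == points.loc[1, "enc_obs"]

    def test_empty_input_rejected(self):
        with pytest.raises(CodonError):
            nc_plot_data([])


def test_codon_usage_report_shape():
    report = codon_usage_report(ref.published_codon_usage())
    assert len(report) == 61
    assert report["count"].sum() == 3419
    met = report[report.codon == "AUG"].iloc[0]
    assert met["count"] == 130 and met["proportion"] == 1.0
    pro = report[report.codon == "CCA"].iloc[0]
    assert pro["ranking"] == "A > C > U > G"
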