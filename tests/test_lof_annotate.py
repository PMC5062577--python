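import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from koassoc import lof_annotate as lofa
from koassoc.io_formats import (GeneModel, GenotypeMatrix, Transcript,
                                VariantSite, MISSING)
from koassoc.lof_annotate import LofClass, classify_variant, hwe_exact_test


def _cls(gene, cds, v, mode="intronic2"):
    return classify_variant(v, gene, cds, mode)["t1"]


class TestClassifyVariant:
    @pytest.mark.parametrize("variant, expected", [
        (VariantSite("1", 104, "C", "T"), LofClass.nonsense),     # CAG -> TAG
        (VariantSite("1", 207, "T", "C"), LofClass.stop_loss),    # TAA -> CAA
        (VariantSite("1", 102, "TGC", "T"), LofClass.frameshift), # 2-bp deletion
        (VariantSite("1", 102, "TGCA", "T"), LofClass.not_lof),   # in-frame 3-bp
        (VariantSite("1", 110, "G", "T"), LofClass.splice_site),  # 1st intronic base
        (VariantSite("1", 200, "G", "T"), LofClass.splice_site),  # acceptor side
        (VariantSite("1", 106, "G", "A"), LofClass.not_lof),      # CAG -> CAA, benign
        (VariantSite("1", 500, "A", "T"), LofClass.not_lof),      # outside the gene
    ])
    def test_consequence_calls(self, two_exon_gene, variant, expected):
        gene, cds = two_exon_gene
        assert _cls(gene, cds, variant) is expected

    def test_exonic_junction_base_needs_flank2(self, two_exon_gene):
        gene, cds = two_exon_gene
        v = VariantSite("1", 109, "A", "G")     # last exonic base before junction
        assert _cls(gene, cds, v) is LofClass.not_lof
        assert _cls(gene, cds, v, "flank2") is LofClass.splice_site

    def test_intronic_splice_hit_under_both_modes(self, two_exon_gene):
        gene, cds = two_exon_gene
        v = VariantSite("1", 110, "G", "T")
        assert _cls(gene, cds, v) is LofClass.splice_site
        assert _cls(gene, cds, v, "flank2") is LofClass.splice_site

    def test_strand_symmetry(self, two_exon_gene, mirrored_gene):
        """Reflecting the locus onto the minus strand leaves every
        classification unchanged (coordinates mirrored, alleles complemented)."""
        plus, cds = two_exon_gene
        minus, _ = mirrored_gene
        comp = dict(zip("ACGT", "TGCA"))
        snvs = [VariantSite("1", 104, "C", "T"), VariantSite("1", 207, "T", "C"),
                VariantSite("1", 110, "G", "T"), VariantSite("1", 106, "G", "A"),
                VariantSite("1", 109, "A", "G")]
        for v in snvs:
            mirrored = VariantSite("1", 300 - (v.pos - 1), comp[v.ref], comp[v.alt])
            for mode in ("intronic2", "flank2"):
                assert (_cls(plus, cds, v, mode)
                        == _cls(minus, cds, mirrored, mode)), v

    def test_nonsense_agrees_with_translation_oracle(self, two_exon_gene):
        """An in-CDS SNV is nonsense iff translating the mutated CDS yields a
        premature stop (Biopython translation as the oracle)."""
        gene, cds = two_exon_gene
        seq = cds["t1"]
        n_aa_ref = len(Seq(seq).translate(to_stop=True))
        positions = list(range(100, 109)) + list(range(200, 209))
        for pos0 in positions:
            i = positions.index(pos0)
            for alt in "ACGT":
                if alt == seq[i]:
                    continue
                got = _cls(gene, cds, VariantSite("1", pos0 + 1, seq[i], alt))
                mutated = seq[:i] + alt + seq[i + 1:]
                premature = len(Seq(mutated).translate(to_stop=True)) < n_aa_ref
                assert (got is LofClass.nonsense) == premature, (pos0, alt)

    def test_reference_mismatch_and_length_mismatch_error(self, two_exon_gene):
        gene, cds = two_exon_gene
        with pytest.raises(ValueError, match="does not match"):
            _cls(gene, cds, VariantSite("1", 104, "G", "T"))
        with pytest.raises(ValueError, match="length"):
            _cls(gene, {"t1": "ATG"}, VariantSite("1", 104, "C", "T"))

    def test_flank2_window_contains_intronic2(self, two_exon_gene):
        gene, _ = two_exon_gene
        w_in = set()
        for s, e in lofa.splice_windows(gene.transcripts[0], "intronic2"):
            w_in.update(range(s, e))
        w_fl = set()
        for s, e in lofa.splice_windows(gene.transcripts[0], "flank2"):
            w_fl.update(range(s, e))
        assert w_in < w_fl


class TestAggregate:
    @pytest.mark.parametrize("classes, mode, expected", [
        ([LofClass.nonsense, LofClass.not_lof], "any", LofClass.nonsense),
        ([LofClass.nonsense, LofClass.not_lof], "all", LofClass.not_lof),
        ([LofClass.splice_site], "any", LofClass.splice_site),
        ([LofClass.splice_site], "all", LofClass.splice_site),
        ([LofClass.stop_loss, LofClass.frameshift], "any", LofClass.frameshift),
    ])
    def test_modes(self, classes, mode, expected):
        assert lofa.aggregate_gene_class(classes, mode) is expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            lofa.aggregate_gene_class([], "any")


def _hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Independent brute-force enumeration of the conditional HWE null."""
    from math import lgamma, exp, log
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    rare = min(na, 2 * n - na)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        probs[h] = exp(h * log(2) - lgamma(h + 1) - lgamma(hr + 1) - lgamma(hc + 1))
    tot = sum(probs.values())
    obs = probs[n_het] / tot
    return min(1.0, sum(p / tot for p in probs.values() if p / tot <= obs * (1 + 1e-12)))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_modal_het_count_gives_one(self):
        # 50/50 alleles in 100 diploids: 50 hets is the modal configuration
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("counts", [
        (57, 14, 50), (10, 5, 2), (0, 3, 12), (40, 20, 3), (1, 1, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_oracle(*counts), abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def _matrix(rows, samples):
    """rows: list of (VariantSite, [(a1, a2), ...]) -> GenotypeMatrix."""
    sites = [r[0] for r in rows]
    alle = np.array([[list(g) for g in r[1]] for r in rows], dtype=np.int8)
    phased = np.zeros((len(rows), len(samples)), dtype=bool)
    return GenotypeMatrix(sites, samples, alle, phased)


class TestQcFilter:
    def _samples(self, n, stratum="EA"):
        return pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                             "sex": "female", "stratum": stratum})

    def test_call_rate_threshold(self):
        # 94 called / 100 -> dropped; 95 -> kept (MAF kept rare)
        def make(n_called):
            gts = [(0, 1)] * 4 + [(0, 0)] * (n_called - 4) \
                + [(MISSING, MISSING)] * (100 - n_called)
            return _matrix([(VariantSite("1", 10, "A", "T"), gts)],
                           [f"S{i}" for i in range(100)])
        qc_bad = lofa.variant_qc(make(94), self._samples(100))
        assert not qc_bad["pass"].iloc[0] and "call_rate" in qc_bad["reasons"].iloc[0]
        qc_ok = lofa.variant_qc(make(95), self._samples(100))
        assert qc_ok["pass"].iloc[0]

    def test_maf_threshold_uses_called_alleles_only(self):
        gts = [(0, 1)] * 12 + [(0, 0)] * 88   # AF = 12/200 = 0.06
        gm = _matrix([(VariantSite("1", 10, "A", "T"), gts)],
                     [f"S{i}" for i in range(100)])
        qc = lofa.variant_qc(gm, self._samples(100))
        assert "maf" in qc["reasons"].iloc[0]
        assert qc["maf"].iloc[0] == pytest.approx(0.06)

    def test_hwe_profile_thresholds(self):
        # strong het deficit: p ~ 1e-7 falls between the two profiles
        counts = None
        for n_het in range(0, 30):
            n_hom = (40 - n_het) // 2
            p = hwe_exact_test(100 - n_het - n_hom, n_het, n_hom)
            if 1e-8 < p < 1e-6:
                counts = (100 - n_het - n_hom, n_het, n_hom)
                break
        assert counts is not None
        gts = ([(0, 1)] * counts[1] + [(1, 1)] * counts[2]
               + [(0, 0)] * counts[0])
        gm = _matrix([(VariantSite("1", 10, "A", "T"), gts)],
                     [f"S{i}" for i in range(100)])
        strict = lofa.variant_qc(gm, self._samples(100))
        assert "hwe" in strict["reasons"].iloc[0]
        wgs = lofa.variant_qc(gm, self._samples(100),
                              lofa.QCThresholds(hwe_p_min=1e-8))
        assert "hwe" not in wgs["reasons"].iloc[0]

    def test_order_independence(self):
        sites = [(VariantSite("1", p, "A", "T"),
                  [(0, 1)] * 3 + [(0, 0)] * 97) for p in (10, 20, 30)]
        samples = self._samples(100)
        gm_fwd = _matrix(sites, [f"S{i}" for i in range(100)])
        gm_rev = _matrix(sites[::-1], [f"S{i}" for i in range(100)])
        classes_fwd = {i: ("G", LofClass.nonsense) for i in range(3)}
        kept_f, _ = lofa.qc_filter_variants(gm_fwd, classes_fwd, samples)
        kept_r, _ = lofa.qc_filter_variants(gm_rev, classes_fwd, samples)
        assert ({lv.site for lv in kept_f} == {lv.site for lv in kept_r})

    def test_unknown_stratum_errors(self):
        gm = _matrix([(VariantSite("1", 10, "A", "T"), [(0, 1), (0, 0)])],
                     ["S0", "SX"])
        samples = self._samples(1)
        with pytest.raises(ValueError, match="stratum"):
            lofa.variant_qc(gm, samples)


def test_annotated_classes_match_generator_truth(small_cohort):
    """Classifying the synthetic cohort's variants recovers exactly the
    consequence classes the generator planted."""
    kept, qc = lofa.annotate_cohort(
        small_cohort.gm, small_cohort.models, small_cohort.cds_seqs,
        small_cohort.samples)
    truth = small_cohort.variant_truth.set_index(["chrom", "pos", "ref", "alt"])
    assert kept, "QC should keep at least some planted variants"
    for lv in kept:
        key = (lv.site.chrom, lv.site.pos, lv.site.ref, lv.site.alt)
        assert truth.loc[key, "lof_class"] == lv.lof_class.value
        assert truth.loc[key, "gene"] == lv.gene_id
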