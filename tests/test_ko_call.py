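import numpy as np
import pandas as pd
import pytest

from koassoc import ko_call, lof_annotate
from koassoc.io_formats import GenotypeMatrix, VariantSite, HAPLOID, MISSING
from koassoc.ko_call import call_gene_kos, ko_summary, KOMatrix
from koassoc.lof_annotate import LofClass, LofVariant

PAR = [("X", 60000, 2699520)]


def _build(sites_and_gts, samples, phased=None):
    sites = [s for s, _ in sites_and_gts]
    alle = np.array([[list(g) for g in gts] for _, gts in sites_and_gts],
                    dtype=np.int8)
    if phased is None:
        phased_arr = np.zeros((len(sites), len(samples)), dtype=bool)
    else:
        phased_arr = np.array(phased, dtype=bool)
    return GenotypeMatrix(sites, samples, alle, phased_arr)


def _lof(gm, gene="G", maf=0.01, strata=("EA",)):
    return [LofVariant(site=v, gene_id=gene, lof_class=LofClass.nonsense, index=i,
                       maf_by_stratum={s: maf for s in strata},
                       passing_strata=set(strata))
            for i, v in enumerate(gm.variants)]


def _samples(ids, sexes=None):
    return pd.DataFrame({"sample_id": ids,
                         "sex": sexes or ["female"] * len(ids),
                         "stratum": "EA"})


class TestCallMechanisms:
    def test_homozygous_single_site(self):
        gm = _build([(VariantSite("1", 100, "A", "T"), [(1, 1), (0, 1), (0, 0)])],
                    ["A", "B", "C"])
        kom = call_gene_kos(gm, _lof(gm), _samples(["A", "B", "C"]),
                            par_regions=PAR)
        assert kom.ko_samples("G") == {"A"}
        assert kom.calls["G"]["A"].mechanism == "homozygous"

    def test_phased_trans_yes_cis_no(self):
        sites = [(VariantSite("1", 100, "A", "T"), [(1, 0), (1, 0)]),
                 (VariantSite("1", 200, "C", "G"), [(0, 1), (1, 0)])]
        gm = _build(sites, ["trans", "cis"],
                    phased=[[True, True], [True, True]])
        kom = call_gene_kos(gm, _lof(gm), _samples(["trans", "cis"]),
                            phase_policy="use_phase", par_regions=PAR)
        assert kom.ko_samples("G") == {"trans"}
        assert kom.calls["G"]["trans"].mechanism == "compound_het"

    def test_unphased_assume_trans_if_rare(self):
        sites = [(VariantSite("1", 100, "A", "T"), [(0, 1)]),
                 (VariantSite("1", 200, "C", "G"), [(1, 0)])]
        gm = _build(sites, ["A"])
        samples = _samples(["A"])
        assert call_gene_kos(gm, _lof(gm), samples, "use_phase",
                             par_regions=PAR).n_calls() == 0
        kom = call_gene_kos(gm, _lof(gm), samples, "assume_trans_if_rare",
                            par_regions=PAR)
        assert kom.calls["G"]["A"].mechanism == "compound_het"

    def test_common_het_pair_not_assumed_trans(self):
        sites = [(VariantSite("1", 100, "A", "T"), [(0, 1)]),
                 (VariantSite("1", 200, "C", "G"), [(1, 0)])]
        gm = _build(sites, ["A"])
        lof = _lof(gm, maf=0.2)     # not rare: assumption does not apply
        kom = call_gene_kos(gm, lof, _samples(["A"]), "assume_trans_if_rare",
                            par_regions=PAR)
        assert kom.n_calls() == 0

    def test_male_hemizygous_x_nonpar_female_het_not(self):
        gm = _build([(VariantSite("X", 5_000_000, "G", "T"),
                      [(1, HAPLOID), (0, 1), (0, HAPLOID)])],
                    ["M1", "F1", "M2"])
        kom = call_gene_kos(gm, _lof(gm), _samples(
            ["M1", "F1", "M2"], ["male", "female", "male"]), par_regions=PAR)
        assert kom.ko_samples("G") == {"M1"}
        assert kom.calls["G"]["M1"].mechanism == "hemizygous"

    def test_x_par_site_not_hemizygous(self):
        gm = _build([(VariantSite("X", 100_000, "G", "T"), [(0, 1)])], ["M1"])
        kom = call_gene_kos(gm, _lof(gm), _samples(["M1"], ["male"]),
                            par_regions=PAR)
        assert kom.n_calls() == 0

    def test_male_het_x_nonpar_policy(self, caplog):
        gm = _build([(VariantSite("X", 5_000_000, "G", "T"), [(0, 1)])], ["M1"])
        samples = _samples(["M1"], ["male"])
        with caplog.at_level("WARNING"):
            kom = call_gene_kos(gm, _lof(gm), samples, par_regions=PAR,
                                x_het_policy="carrier")
        assert kom.calls["G"]["M1"].mechanism == "hemizygous"
        assert "heterozygous male" in caplog.text
        kom2 = call_gene_kos(gm, _lof(gm), samples, par_regions=PAR,
                             x_het_policy="missing")
        assert kom2.n_calls() == 0

    def test_missing_genotype_contributes_nothing(self):
        sites = [(VariantSite("1", 100, "A", "T"), [(MISSING, MISSING)]),
                 (VariantSite("1", 200, "C", "G"), [(0, 1)])]
        gm = _build(sites, ["A"])
        kom = call_gene_kos(gm, _lof(gm), _samples(["A"]),
                            "assume_trans_if_rare", par_regions=PAR)
        assert kom.n_calls() == 0

    def test_variant_failing_qc_in_stratum_ignored(self):
        gm = _build([(VariantSite("1", 100, "A", "T"), [(1, 1)])], ["A"])
        lof = _lof(gm)
        lof[0].passing_strata = {"AA"}      # sample A is in EA
        kom = call_gene_kos(gm, lof, _samples(["A"]), par_regions=PAR)
        assert kom.n_calls() == 0


class TestInvariances:
    def test_sample_and_variant_order_invariance(self, small_cohort):
        gm = small_cohort.gm
        lof, _ = lof_annotate.annotate_cohort(
            gm, small_cohort.models, small_cohort.cds_seqs, small_cohort.samples)
        kom1 = call_gene_kos(gm, lof, small_cohort.samples, "use_phase")
        rng = np.random.default_rng(0)
        order = rng.permutation(gm.n_variants)
        gm2 = GenotypeMatrix([gm.variants[i] for i in order], gm.samples,
                             gm.alleles[order], gm.phased[order])
        remap = {int(o): k for k, o in enumerate(order)}
        lof2 = [LofVariant(lv.site, lv.gene_id, lv.lof_class, remap[lv.index],
                           lv.maf_by_stratum, lv.call_rate_by_stratum,
                           lv.hwe_p_by_stratum, lv.passing_strata)
                for lv in lof]
        kom2 = call_gene_kos(gm2, lof2[::-1], small_cohort.samples, "use_phase")
        f1, f2 = kom1.to_frame(), kom2.to_frame()
        assert f1[["gene", "sample_id", "mechanism"]].equals(
            f2[["gene", "sample_id", "mechanism"]])

    def test_assume_trans_calls_superset_of_use_phase(self, small_cohort):
        """On fully phased data the unphased assumption can only add KOs
        (cis pairs are the single source of difference)."""
        gm = small_cohort.gm
        lof, _ = lof_annotate.annotate_cohort(
            gm, small_cohort.models, small_cohort.cds_seqs, small_cohort.samples)
        phased = call_gene_kos(gm, lof, small_cohort.samples, "use_phase")
        assumed = call_gene_kos(gm, lof, small_cohort.samples,
                                "assume_trans_if_rare")
        for g in phased.genes:
            assert phased.ko_samples(g) <= assumed.ko_samples(g)
        extra = {(g, s) for g in assumed.genes for s in assumed.ko_samples(g)} \
            - {(g, s) for g in phased.genes for s in phased.ko_samples(g)}
        for g, s in extra:
            assert assumed.calls[g][s].mechanism == "compound_het"


class TestSummary:
    def test_every_sample_one_homozygous_ko(self):
        n = 5
        gm = _build([(VariantSite("1", 100, "A", "T"), [(1, 1)] * n)],
                    [f"S{i}" for i in range(n)])
        kom = call_gene_kos(gm, _lof(gm), _samples([f"S{i}" for i in range(n)]),
                            par_regions=PAR)
        summ = ko_summary(kom, _samples([f"S{i}" for i in range(n)]))
        row = summ.iloc[0]
        assert row["gene_kos_per_individual"] == 1.0
        assert row["n_ko_genes"] == 1
        assert row["sharing_hist"] == f"{n}:1"

    def test_empty_matrix_all_zero(self):
        summ = ko_summary(KOMatrix(), _samples(["A", "B"]))
        assert (summ[["n_ko_genes", "n_genes_homozygous"]].to_numpy() == 0).all()

    def test_mechanism_split_matches_generator_truth(self, small_cohort):
        """The generator's own KO bookkeeping and the caller agree exactly on
        mechanisms (phased calling; cis pairs are not KOs)."""
        lof, _ = lof_annotate.annotate_cohort(
            small_cohort.gm, small_cohort.models, small_cohort.cds_seqs,
            small_cohort.samples)
        kom = call_gene_kos(small_cohort.gm, lof, small_cohort.samples,
                            "use_phase")
        called = {(r.gene, r.sample_id): r.mechanism
                  for r in kom.to_frame().itertuples()}
        # strata where every planted site of the gene survives QC
        all_pass: dict[str, set[str]] = {}
        for lv in lof:
            cur = all_pass.setdefault(lv.gene_id, set(lv.passing_strata))
            cur &= lv.passing_strata
        strat = small_cohort.samples.set_index("sample_id")["stratum"]
        n_checked = 0
        for r in small_cohort.truth.itertuples():
            key = (r.gene, r.sample_id)
            if r.mechanism == "cis_pair":
                assert called.get(key) != "compound_het"
                continue
            if strat[r.sample_id] in all_pass.get(r.gene, set()):
                assert called.get(key) == r.mechanism, key
                n_checked += 1
        assert n_checked > 10
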