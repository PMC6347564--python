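"""Site classification and the SNP/FD statistic, against enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genediv.containers import GeneModel, GenomeCallset, OutgroupTrack, SiteBlock
from genediv.diversity import (
    GeneDiversity,
    SiteClass,
    UndefinedRatioError,
    age_diversity_correlation,
    background_set,
    classify_site,
    count_genes,
    gene_counts,
    normalized_diversity,
    partition_features,
    per_site_heterozygosity,
    set_ratio,
)
from genediv.intervals import MaskTrack

ALLELES = "ACGT"


def oracle_classify(genotype, alleles_observed, outgroup, is_snv=True,
                    require_outgroup=True):
    """Independent truth-table oracle, written straight from the definitions."""
    if not is_snv or alleles_observed > 2:
        return SiteClass.EXCLUDED
    het = genotype[0] != genotype[1]
    if outgroup is None:
        if require_outgroup or not het:
            return SiteClass.NO_OUTGROUP
        return SiteClass.SNP
    if het:
        return SiteClass.SNP
    return SiteClass.FD if genotype[0] != outgroup else SiteClass.MATCH


class TestClassifySite:
    @pytest.mark.parametrize(
        "genotype,outgroup,expected",
        [
            (("A", "G"), "A", SiteClass.SNP),      # biallelic het
            (("A", "A"), "G", SiteClass.FD),       # hom differing from outgroup
            (("A", "A"), "A", SiteClass.MATCH),
            (("C", "T"), "G", SiteClass.SNP),      # het, both alleles != outgroup
            (("A", "A"), None, SiteClass.NO_OUTGROUP),
        ],
    )
    def test_examples(self, genotype, outgroup, expected):
        assert classify_site(genotype, 2, outgroup) == expected

    def test_multiallelic_and_non_snv_excluded(self):
        assert classify_site(("G", "T"), 3, "A") == SiteClass.EXCLUDED
        assert classify_site(("A", "A"), 1, "G", is_snv=False) == SiteClass.EXCLUDED

    @pytest.mark.parametrize("require_outgroup", [True, False])
    def test_exhaustive_truth_table(self, require_outgroup):
        """Full enumeration: genotype pairs x outgroup x allele count x SNV."""
        genotypes = list(itertools.combinations_with_replacement(ALLELES, 2))
        outgroups = list(ALLELES) + [None]
        for gt, og, n_all, snv in itertools.product(
            genotypes, outgroups, [1, 2, 3, 4], [True, False]
        ):
            got = classify_site(gt, n_all, og, is_snv=snv,
                                require_outgroup=require_outgroup)
            want = oracle_classify(gt, n_all, og, is_snv=snv,
                                   require_outgroup=require_outgroup)
            assert got == want, (gt, og, n_all, snv)


def build_world(site_states, start=0, chrom="chr1"):
    """site_states: list of (genotype pair, outgroup or None) at consecutive
    positions; returns callset + outgroup track."""
    n = len(site_states)
    code = {b: i for i, b in enumerate(ALLELES)}
    a1 = np.array([min(code[g[0]], code[g[1]]) for g, _ in site_states], np.int8)
    a2 = np.array([max(code[g[0]], code[g[1]]) for g, _ in site_states], np.int8)
    block = SiteBlock(
        pos=np.arange(start, start + n, dtype=np.int64),
        ref=a1.copy(),
        a1=a1,
        a2=a2,
        depth=np.full(n, 30, np.int32),
        mq=np.full(n, 40.0, np.float32),
        is_snv=np.ones(n, bool),
        n_alleles=np.where(a1 != a2, 2, 1).astype(np.int8),
    )
    og_pos = np.array([start + i for i, (_, og) in enumerate(site_states) if og],
                      np.int64)
    og_allele = np.array([code[og] for _, og in site_states if og], np.int8)
    return (
        GenomeCallset("x", {chrom: block}),
        OutgroupTrack(chroms={chrom: (og_pos, og_allele)}),
    )


class TestGeneCounts:
    def test_arithmetic(self):
        states = (
            [(("A", "G"), "A")] * 3        # 3 SNPs
            + [(("C", "C"), "T")] * 12     # 12 FDs
            + [(("A", "A"), "A")] * 5      # matches
        )
        callset, og = build_world(states)
        gene = GeneModel("g", "S", "chr1", core=(0, 20), body=(0, 20), exons=())
        mask = MaskTrack.from_intervals([("chr1", 0, 20)])
        gd = gene_counts(callset, gene, mask, og, min_callable=10)
        assert (gd.snp, gd.fd) == (3, 12)
        assert gd.ratio == pytest.approx(0.25)
        assert gd.callable_sites == 20

    def test_all_match_undefined_ratio(self):
        callset, og = build_world([(("A", "A"), "A")] * 10)
        gene = GeneModel("g", "S", "chr1", core=(0, 10), body=(0, 10), exons=())
        mask = MaskTrack.from_intervals([("chr1", 0, 10)])
        gd = gene_counts(callset, gene, mask, og)
        assert (gd.snp, gd.fd) == (0, 0)
        assert math.isnan(gd.ratio)

    def test_min_callable_boundary(self):
        gd_pass = GeneDiversity("g", callable_sites=2000, snp=1, fd=1)
        gd_fail = GeneDiversity("g", callable_sites=1999, snp=1, fd=1)
        assert gd_pass.passes_min_callable and not gd_fail.passes_min_callable

    def test_outgroup_required_by_default(self):
        states = [(("A", "G"), None), (("A", "G"), "A")]
        callset, og = build_world(states)
        gene = GeneModel("g", "S", "chr1", core=(0, 2), body=(0, 2), exons=())
        mask = MaskTrack.from_intervals([("chr1", 0, 2)])
        assert gene_counts(callset, gene, mask, og).snp == 1
        assert gene_counts(callset, gene, mask, og, require_outgroup=False).snp == 2

    def test_bulk_matches_single(self, tiny_ds):
        ds = tiny_ds
        chrom = ds.spec.chrom
        mask = ds.shared.territory
        callset = ds.callsets["ind1"]
        bulk = count_genes(callset, ds.genes, mask, ds.shared.outgroup)
        for gid in list(ds.genes)[::7]:
            single = gene_counts(callset, ds.genes[gid], mask, ds.shared.outgroup)
            row = bulk.loc[gid]
            assert (single.snp, single.fd, single.callable_sites) == (
                row["snp"], row["fd"], row["callable_sites"]
            )


class TestSetRatio:
    def frame(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "callable_sites", "snp", "fd"])
        df["passes_min_callable"] = True
        return df.set_index("gene_id")

    def test_pooled_semantics(self):
        df = self.frame([("a", 9000, 2, 10), ("b", 9000, 1, 10)])
        assert set_ratio(df, ["a", "b"]).mean_ratio == pytest.approx(0.15)

    def test_pooled_not_mean_of_ratios(self):
        df = self.frame([("a", 9000, 1, 1), ("b", 9000, 0, 99)])
        assert set_ratio(df, ["a", "b"]).mean_ratio == pytest.approx(0.01)

    def test_single_gene_set(self):
        # a one-gene "set" (the B2M-style single-gene check) is valid
        df = self.frame([("b2m", 9000, 1, 250)])
        s = set_ratio(df, ["b2m"], set_name="b2m")
        assert s.n_genes_used == 1
        assert s.mean_ratio == pytest.approx(1 / 250)

    def test_empty_members_error(self):
        df = self.frame([("a", 9000, 1, 1)])
        with pytest.raises(ValueError):
            set_ratio(df, [])

    def test_zero_fd_sum_error(self):
        df = self.frame([("a", 9000, 1, 0)])
        with pytest.raises(UndefinedRatioError):
            set_ratio(df, ["a"])

    def test_order_and_zero_gene_invariance(self):
        rows = [("a", 9000, 2, 10), ("b", 9000, 1, 30), ("c", 9000, 0, 0)]
        df = self.frame(rows)
        df_rev = self.frame(rows[::-1])
        r1 = set_ratio(df, ["a", "b"]).mean_ratio
        r2 = set_ratio(df_rev, ["b", "a", "c"]).mean_ratio  # c adds (0, 0)
        assert r1 == pytest.approx(r2)

    def test_partition_conservation(self, tiny_ds):
        # disjoint split of all genes: per-set sums add to the total
        ds = tiny_ds
        tab = count_genes(ds.callsets["ind1"], ds.genes, ds.shared.territory,
                          ds.shared.outgroup, min_callable=0)
        gids = sorted(ds.genes)
        half = len(gids) // 2
        s1 = set_ratio(tab, gids[:half])
        s2 = set_ratio(tab, gids[half:])
        assert s1.sum_snp + s2.sum_snp == int(tab["snp"].sum())
        assert s1.sum_fd + s2.sum_fd == int(tab["fd"].sum())


class TestNormalized:
    def summary(self, snp, fd, name="s"):
        from genediv.diversity import SetDiversitySummary

        return SetDiversitySummary(name, 10, snp, fd)

    def test_equal_sets_give_one(self):
        t = self.summary(15, 100)
        out = normalized_diversity(t, self.summary(30, 200))
        assert out.normalized == pytest.approx(1.0)
        assert out.log2_normalized == pytest.approx(0.0)

    def test_archaic_magnitude(self):
        out = normalized_diversity(self.summary(47, 100), self.summary(1, 100))
        assert out.normalized == pytest.approx(47.0)

    def test_log2_half(self):
        out = normalized_diversity(self.summary(5, 100), self.summary(10, 100))
        assert out.normalized == pytest.approx(0.5)
        assert out.log2_normalized == pytest.approx(-1.0)

    def test_zero_background_error(self):
        with pytest.raises(UndefinedRatioError):
            normalized_diversity(self.summary(5, 100), self.summary(0, 0))

    def test_self_normalization_identity(self, tiny_ds):
        tab = count_genes(tiny_ds.callsets["ind2"], tiny_ds.genes,
                          tiny_ds.shared.territory, tiny_ds.shared.outgroup,
                          min_callable=0)
        s = set_ratio(tab, sorted(tiny_ds.genes))
        assert normalized_diversity(s, s).normalized == pytest.approx(1.0)


class TestBackgroundSet:
    def genes(self):
        mk = lambda gid, length: GeneModel(
            gid, gid, "chr1", core=(0, length), body=(0, length), exons=()
        )
        return {"short": mk("short", 499), "edge": mk("edge", 500),
                "long": mk("long", 5000), "imm": mk("imm", 5000)}

    def test_length_boundary_and_exclusion(self):
        bg = background_set(self.genes(), immune_exclusion_ids={"imm"})
        assert bg == frozenset({"edge", "long"})

    def test_empty_background_error(self):
        with pytest.raises(ValueError):
            background_set(self.genes(), {"short", "edge", "long", "imm"})


class TestPartitionFeatures:
    def test_conservation_and_exon_snps(self, tiny_ds):
        ds = tiny_ds
        mask = ds.shared.territory
        for gid in list(ds.genes)[:5]:
            gene = ds.genes[gid]
            parts = partition_features(ds.callsets["ind1"], gene, mask,
                                       ds.shared.outgroup)
            total = gene_counts(ds.callsets["ind1"], gene, mask, ds.shared.outgroup)
            assert sum(p.snp for p in parts.values()) == total.snp
            assert sum(p.fd for p in parts.values()) == total.fd
            assert sum(p.callable_sites for p in parts.values()) == total.callable_sites

    def test_no_exons_error(self):
        gene = GeneModel("g", "S", "chr1", core=(0, 10), body=(0, 10), exons=())
        with pytest.raises(ValueError, match="exon"):
            partition_features(GenomeCallset("x", {}), gene,
                               MaskTrack.empty(), OutgroupTrack())


class TestAgeCorrelation:
    def test_perfect_correlations(self):
        assert age_diversity_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert age_diversity_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # ages (0,1,2,3), values (1,3,2,4): r = cov/sd_x sd_y
        ages = np.array([0, 1, 2, 3], float)
        vals = np.array([1, 3, 2, 4], float)
        cov = ((ages - ages.mean()) * (vals - vals.mean())).mean()
        want = cov / (ages.std() * vals.std())
        assert age_diversity_correlation(ages, vals) == pytest.approx(want)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            age_diversity_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            age_diversity_correlation([1, 1, 1], [1, 2, 3])


class TestHeterozygosity:
    def test_counts_het_snvs_only(self):
        states = [(("A", "G"), "A"), (("C", "C"), "T"), (("A", "T"), None)]
        callset, _ = build_world(states)
        mask = MaskTrack.from_intervals([("chr1", 0, 3)])
        het, n, rate = per_site_heterozygosity(callset, mask)
        assert (het, n) == (2, 3)
        assert rate == pytest.approx(2 / 3)
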