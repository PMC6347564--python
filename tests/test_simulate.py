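"""The synthetic-genome generator: structure, determinism, calibration."""

import dataclasses

import numpy as np
import pytest

from genediv.diversity import count_genes, per_site_heterozygosity, set_ratio
from genediv.filters import exclude_intervals
from genediv.simulate import (
    GeneLengthModel,
    SetDefinition,
    SyntheticSpec,
    presets,
    simulate_annotation,
    simulate_genome,
    simulate_individual,
    simulate_reference,
)


class TestAnnotation:
    def test_bodies_disjoint_including_flanks(self, tiny_annotation):
        genes, _, _ = tiny_annotation
        bodies = sorted(g.body for g in genes.values())
        for (s1, e1), (s2, e2) in zip(bodies, bodies[1:]):
            assert e1 <= s2

    def test_set_sizes(self, tiny_annotation):
        _, sets, _ = tiny_annotation
        assert len(sets.members("mhc_like")) == 5
        assert len(sets.members("innate_like")) == 8
        assert len(sets.background) == 20

    def test_mhc_set_has_14_genes_in_presets(self):
        spec = presets(seed=3)["archaic"]
        _, sets, _ = simulate_annotation(spec)
        assert len(sets.members("mhc_like")) == 14

    def test_go_markers_annotate_members(self, tiny_annotation):
        _, sets, go = tiny_annotation
        assert go.genes_for("GO:MHC0001") == sets.members("mhc_like")

    def test_deterministic(self, tiny_spec):
        a = simulate_annotation(tiny_spec)
        b = simulate_annotation(tiny_spec)
        assert a[0] == b[0] and a[1].sets == b[1].sets

    def test_genome_too_short(self):
        spec = dataclasses.replace(presets(seed=1)["archaic"], chrom_length=100_000)
        with pytest.raises(ValueError, match="too short"):
            simulate_annotation(spec)


class TestGenomeGeneration:
    def test_deterministic_callsets(self, tiny_spec, tiny_annotation):
        d1 = simulate_genome(tiny_spec, ["a"], annotation=tiny_annotation)
        d2 = simulate_genome(tiny_spec, ["a"], annotation=tiny_annotation)
        b1 = d1.callsets["a"].chroms[tiny_spec.chrom]
        b2 = d2.callsets["a"].chroms[tiny_spec.chrom]
        for col in ("pos", "a1", "a2", "depth", "mq", "is_snv", "n_alleles"):
            assert np.array_equal(getattr(b1, col), getattr(b2, col)), col

    def test_individuals_share_world_but_differ(self, tiny_ds):
        b1 = tiny_ds.callsets["ind1"].chroms[tiny_ds.spec.chrom]
        b2 = tiny_ds.callsets["ind2"].chroms[tiny_ds.spec.chrom]
        assert np.array_equal(b1.pos, b2.pos)  # same territory
        assert not np.array_equal(b1.a1, b2.a1)  # different genotypes

    def test_territory_covers_gene_bodies(self, tiny_ds):
        total = sum(g.body_length for g in tiny_ds.genes.values())
        assert tiny_ds.shared.territory.total_length() == total
        assert tiny_ds.shared.site_pos.size == total

    def test_pooled_ratio_matches_mu_over_d(self, tiny_ds):
        """Binomial expectation oracle: background pooled SNP/FD ~= mu/d."""
        spec = tiny_ds.spec
        tab = count_genes(
            tiny_ds.callsets["ind1"], tiny_ds.genes, tiny_ds.shared.territory,
            tiny_ds.shared.outgroup, min_callable=0,
        )
        bg = set_ratio(tab, tiny_ds.gene_sets.background)
        expect = spec.heterozygosity / spec.divergence
        rel_se = np.sqrt(1 / bg.sum_snp + 1 / bg.sum_fd)
        assert abs(bg.mean_ratio - expect) / expect < 3 * rel_se

    def test_elevated_set_is_elevated(self, tiny_ds):
        tab = count_genes(
            tiny_ds.callsets["ind1"], tiny_ds.genes, tiny_ds.shared.territory,
            tiny_ds.shared.outgroup, min_callable=0,
        )
        mhc = set_ratio(tab, tiny_ds.gene_sets.members("mhc_like"))
        bg = set_ratio(tab, tiny_ds.gene_sets.background)
        assert mhc.mean_ratio > 3 * bg.mean_ratio  # generated at 8x


@pytest.fixture(scope="module")
def roh_world():
    spec = SyntheticSpec(
        seed=5,
        chrom_length=1_500_000,
        n_background_genes=25,
        gene_length=GeneLengthModel(mean_core=6_000, sigma_log=0.3, min_core=1_500),
        heterozygosity=1.0e-3,
        divergence=1.2e-2,
        set_definitions=(),
        roh_fraction=0.25,
        n_roh_tracts=6,
    )
    return simulate_genome(spec, ["a1"])


class TestRoh:
    def test_roh_tracts_are_het_free(self, roh_world):
        ds = roh_world
        block = ds.callsets["a1"].chroms[ds.spec.chrom]
        in_roh = ds.shared.roh.contains(ds.spec.chrom, block.pos)
        hets = block.is_het() & block.is_snv & (block.n_alleles <= 2)
        assert not np.any(hets & in_roh)

    def test_heterozygosity_rises_after_exclusion(self, roh_world):
        ds = roh_world
        full = ds.shared.territory
        reduced = exclude_intervals(full, ds.shared.roh)
        _, _, before = per_site_heterozygosity(ds.callsets["a1"], full)
        _, _, after = per_site_heterozygosity(ds.callsets["a1"], reduced)
        assert after > before


class TestMultiplierRecovery:
    def test_ci_covers_generating_multiplier(self):
        """Set-multiplier recovery: the 95% bootstrap CI for normalized
        diversity of a 14-gene elevated set contains the generating
        multiplier in >= 90% of 100 replicate individuals (B scaled to
        2000 for runtime; the interval is the same percentile construction)."""
        from genediv._utils import derive_seed
        from genediv.resampling import bootstrap_normalized_ci
        from genediv.simulate import SyntheticDataset

        spec = SyntheticSpec(
            seed=13, chrom_length=6_000_000, n_background_genes=60,
            gene_length=GeneLengthModel(mean_core=12_000, sigma_log=0.35,
                                        min_core=2_000),
            heterozygosity=1.0e-3, divergence=1.2e-2,
            set_definitions=(
                SetDefinition("mhc_like", 14, multiplier=8.0, go_marker="GO:M"),
            ),
        )
        genes, sets, go = simulate_annotation(spec)
        shared = simulate_reference(spec, genes)
        ds = SyntheticDataset(spec, genes, sets, go, shared, {})
        hits = 0
        n_rep = 100
        for i in range(1, n_rep + 1):
            ind = str(i)
            ds.callsets[ind] = simulate_individual(shared, sets, ind)
            gt = ds.model(ind).fit(B=0, build_track=False).gene_table
            sub = lambda m: gt.loc[sorted(set(m) & set(gt.index))]
            ci = bootstrap_normalized_ci(
                sub(sets.members("mhc_like")), sub(sets.background),
                B=2000, seed=derive_seed(13, "mult-cov", i),
            )
            hits += ci.contains(8.0)
            del ds.callsets[ind]
        assert hits / n_rep >= 0.90, hits


class TestPresets:
    def test_heterozygosity_anchors(self):
        p = presets(seed=1)
        assert p["vindija"].heterozygosity == pytest.approx(1.6e-5)
        assert p["denisovan"].heterozygosity == pytest.approx(1.8e-5)

    def test_multiplier_anchors(self):
        p = presets(seed=1)
        def mult(spec, name):
            return next(s.multiplier for s in spec.set_definitions if s.name == name)
        assert mult(p["archaic"], "mhc_like") == 47.0
        assert mult(p["archaic"], "innate_like") == 1.0
        assert mult(p["african"], "mhc_like") == 7.0
        assert mult(p["non_african"], "mhc_like") == 7.0

    def test_null_immune_all_multipliers_one(self):
        spec = presets(seed=1)["null_immune"]
        assert all(s.multiplier == 1.0 for s in spec.set_definitions)

    def test_present_day_baselines_in_printed_ranges(self):
        p = presets(seed=1)
        af = p["african"].heterozygosity / p["african"].divergence
        naf = p["non_african"].heterozygosity / p["non_african"].divergence
        assert 0.154 <= af <= 0.167
        assert 0.042 <= naf <= 0.105

    def test_altai_has_roh(self):
        spec = presets(seed=1)["altai_roh"]
        tracts = spec.roh_tracts()
        covered = sum(e - s for s, e in tracts)
        assert covered == pytest.approx(0.15 * spec.chrom_length, rel=0.01)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=1, heterozygosity=0.5, divergence=0.01)
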