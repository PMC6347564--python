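"""Diversity-tail GO enrichment: exact hypergeometric oracle and null behavior."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from genediv.containers import GoAnnotation
from genediv.enrichment import (
    hypergeom_enrich,
    mean_gene_ratios,
    tail_genes,
)


def gene_frame(ratios, passes=None, fds=None):
    gids = [f"g{i:03d}" for i in range(len(ratios))]
    df = pd.DataFrame({
        "callable_sites": 9000,
        "snp": 5,
        "fd": fds if fds is not None else [10] * len(ratios),
        "ratio": ratios,
    }, index=pd.Index(gids, name="gene_id"))
    df["passes_min_callable"] = passes if passes is not None else True
    return df


class TestMeanGeneRatios:
    def test_arithmetic_mean(self):
        per = {
            "i1": gene_frame([0.1, 0.5]),
            "i2": gene_frame([0.2, 0.5]),
            "i3": gene_frame([0.3, 0.5]),
        }
        means = mean_gene_ratios(per)
        assert means["g000"] == pytest.approx(0.2)

    def test_failing_filter_anywhere_makes_ineligible(self):
        per = {
            "i1": gene_frame([0.1, 0.2]),
            "i2": gene_frame([0.1, 0.2], passes=[True, False]),
        }
        assert list(mean_gene_ratios(per).index) == ["g000"]

    def test_zero_fd_anywhere_makes_ineligible(self):
        per = {
            "i1": gene_frame([0.1, 0.2]),
            "i2": gene_frame([0.1, np.nan], fds=[10, 0]),
        }
        assert list(mean_gene_ratios(per).index) == ["g000"]


class TestTailGenes:
    def test_floor_of_five_percent(self, rng):
        means = pd.Series(rng.random(100),
                          index=[f"g{i:03d}" for i in range(100)])
        top = tail_genes(means, "top")
        assert len(top.selected_genes) == 5
        assert set(top.selected_genes) == set(means.nlargest(5).index)

    def test_bottom_side(self, rng):
        means = pd.Series(rng.random(60), index=[f"g{i:03d}" for i in range(60)])
        bottom = tail_genes(means, "bottom")
        assert len(bottom.selected_genes) == 3
        assert set(bottom.selected_genes) == set(means.nsmallest(3).index)

    def test_ties_broken_lexicographically(self):
        means = pd.Series(0.5, index=[f"g{i:03d}" for i in range(100)])
        top = tail_genes(means, "top")
        assert list(top.selected_genes) == [f"g{i:03d}" for i in range(5)]

    def test_empty_tail_errors(self):
        means = pd.Series(np.arange(19.0), index=[f"g{i}" for i in range(19)])
        with pytest.raises(ValueError):
            tail_genes(means, "top")


def exact_upper_tail(N, K, n, x):
    """Brute-force hypergeometric upper tail with exact rational arithmetic."""
    total = Fraction(0)
    for k in range(x, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
    return float(total)


def make_selection(eligible, selected, side="top"):
    from genediv.enrichment import TailSelection

    return TailSelection(side=side, tail_fraction=0.05,
                         eligible_genes=tuple(sorted(eligible)),
                         selected_genes=tuple(selected), cutoff_value=0.0)


class TestHypergeomEnrich:
    def setup_method(self):
        # the worked 100-gene instance: universe 95 (10 annotated), tail 5
        # (3 annotated) -> combined pool N=100, K=13, draw n=5, observed 3
        self.genes = [f"g{i:03d}" for i in range(100)]
        tail = self.genes[:5]
        universe = self.genes[5:]
        annotated = tail[:3] + universe[:10]
        self.tail = make_selection(tail + universe, tail)
        self.other = make_selection(tail + universe, [])
        self.ann = GoAnnotation(
            gene_to_terms={g: frozenset({"GO:X"}) for g in annotated},
            term_names={"GO:X": "category X"},
        )

    def test_matches_exact_combinatorial_oracle(self):
        res = hypergeom_enrich(self.tail, self.other, self.ann)
        r = next(x for x in res if x.go_id == "GO:X")
        assert r.tail_count == 3 and r.tail_size == 5
        assert r.p_value == pytest.approx(exact_upper_tail(100, 13, 5, 3), rel=1e-12)

    def test_absent_category_p_one(self):
        ann = GoAnnotation(gene_to_terms={g: frozenset({"GO:Y"})
                                          for g in self.genes[10:20]})
        res = hypergeom_enrich(self.tail, self.other, ann)
        r = next(x for x in res if x.go_id == "GO:Y")
        assert r.tail_count == 0
        assert r.p_value == pytest.approx(1.0)

    def test_bonferroni_cap_and_override(self):
        res = hypergeom_enrich(self.tail, self.other, self.ann, k_override=17)
        r = res[0]
        assert r.k_used == 17
        assert r.fwer == pytest.approx(min(1.0, r.p_value * 17))
        # p=0.1 with k=17 -> capped at 1
        assert min(1.0, 0.1 * 17) == 1.0

    def test_invariant_to_relabeling_and_order(self, rng):
        perm = list(self.genes)
        rng.shuffle(perm)
        relabel = dict(zip(self.genes, perm))
        tail2 = make_selection([relabel[g] for g in self.tail.eligible_genes],
                               [relabel[g] for g in self.tail.selected_genes])
        other2 = make_selection(tail2.eligible_genes, [])
        ann2 = GoAnnotation(gene_to_terms={
            relabel[g]: ts for g, ts in self.ann.gene_to_terms.items()})
        p1 = hypergeom_enrich(self.tail, self.other, self.ann)[0].p_value
        p2 = hypergeom_enrich(tail2, other2, ann2)[0].p_value
        assert p1 == pytest.approx(p2)

    def test_both_tails_excluded_from_universe(self):
        other = make_selection(self.tail.eligible_genes, self.genes[90:95],
                               side="bottom")
        res = hypergeom_enrich(self.tail, other, self.ann)
        r = res[0]
        assert r.tail_size + r.background_size == 95  # 100 - other tail

    def test_no_annotated_eligible_rejected(self):
        ann = GoAnnotation(gene_to_terms={"zzz": frozenset({"GO:Z"})})
        with pytest.raises(ValueError):
            hypergeom_enrich(self.tail, self.other, ann)


class TestPermutationNull:
    def test_p_values_conservative_under_shuffled_ratios(self):
        """With no diversity-annotation association, per-category p-values
        are stochastically >= uniform (the exact test is conservative)."""
        rng = np.random.default_rng(2024)
        genes = [f"g{i:03d}" for i in range(200)]
        ann = GoAnnotation(gene_to_terms={
            g: frozenset({f"GO:{j}"}) for j, chunk in
            enumerate(np.array_split(np.array(genes), 8)) for g in chunk
        })
        pvals = []
        for _ in range(300):
            ratios = pd.Series(rng.random(len(genes)), index=genes)
            top = tail_genes(ratios, "top")
            bottom = tail_genes(ratios, "bottom")
            for r in hypergeom_enrich(top, bottom, ann, min_category_size=2):
                pvals.append(r.p_value)
        pvals = np.asarray(pvals)
        # stochastic dominance over U(0,1): empirical CDF below the uniform's
        for q in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= q).mean() <= q + 0.02
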