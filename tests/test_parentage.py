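"""Likelihood parentage: LOD scores, simulated confidence, assignment."""

import itertools
import math

import numpy as np
import pytest

from seedshadow.core import Location, allele_frequencies, mendelian_compatible
from seedshadow.parentage import (
    AssignedParent,
    ParentageAssignment,
    ParentageConfig,
    assign_parentage,
    critical_delta,
    estimate_pas,
    single_parent_lod,
)
from seedshadow.synthetic import (
    generate_genotypes,
    generate_landscape,
    generate_offspring_and_seedcoats,
    parkia_like,
)

from conftest import make_genotype


def brute_force_locus_lod(off_call, cand_call, p, e=0.0):
    """Independent oracle: enumerate parental transmissions and population
    alleles to get the transition probability, then form the log ratio."""
    a, b = off_call
    p_off = p[a] ** 2 if a == b else 2 * p[a] * p[b]
    t = 0.0
    for transmitted in cand_call:  # each with probability 1/2
        for other, p_other in p.items():  # population allele
            if tuple(sorted((transmitted, other))) == tuple(sorted(off_call)):
                t += 0.5 * p_other
    num = (1 - e) * t + e * p_off
    return math.log(num / p_off) if num > 0 else -math.inf


class TestSingleParentLod:
    def test_heterozygote_offspring_homozygote_parent_is_zero(self):
        """(A,B) child, (A,A) parent, p_A = p_B = 0.5: ratio exactly 1."""
        off = make_genotype("o", [(1, 2)], ["L1"])
        cand = make_genotype("c", [(1, 1)], ["L1"])
        freqs = {"L1": {1: 0.5, 2: 0.5}}
        assert single_parent_lod(off, cand, freqs, e=0.0) == pytest.approx(0.0)

    def test_matches_bruteforce_enumeration(self):
        """Exhaustive check over every genotype pair at a triallelic locus."""
        p = {1: 0.5, 2: 0.3, 3: 0.2}
        freqs = {"L1": p}
        genos = list(itertools.combinations_with_replacement(p, 2))
        for off_call in genos:
            for cand_call in genos:
                for e in (0.0, 0.01):
                    got = single_parent_lod(
                        make_genotype("o", [off_call], ["L1"]),
                        make_genotype("c", [cand_call], ["L1"]),
                        freqs,
                        e=e,
                    )
                    want = brute_force_locus_lod(off_call, cand_call, p, e)
                    if math.isinf(want):
                        assert math.isinf(got) and got < 0
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_incompatible_locus_gives_minus_infinity(self):
        off = make_genotype("o", [(1, 1)], ["L1"])
        cand = make_genotype("c", [(2, 3)], ["L1"])
        lod = single_parent_lod(off, cand, {"L1": {1: 0.4, 2: 0.3, 3: 0.3}}, e=0.0)
        assert lod == -math.inf

    def test_additive_and_permutation_invariant(self, rng):
        loci = ("L1", "L2", "L3")
        freqs = {l: {1: 0.4, 2: 0.35, 3: 0.25} for l in loci}
        off = make_genotype("o", [(1, 2), (1, 1), (2, 3)], loci)
        cand = make_genotype("c", [(1, 3), (1, 2), (3, 3)], loci)
        total = single_parent_lod(off, cand, freqs)
        per_locus = sum(
            single_parent_lod(
                make_genotype("o", [off.calls[i]], [loci[i]]),
                make_genotype("c", [cand.calls[i]], [loci[i]]),
                freqs,
            )
            for i in range(3)
        )
        assert total == pytest.approx(per_locus)
        perm = [2, 0, 1]
        off_p = make_genotype("o", [off.calls[i] for i in perm], [loci[i] for i in perm])
        cand_p = make_genotype("c", [cand.calls[i] for i in perm], [loci[i] for i in perm])
        assert single_parent_lod(off_p, cand_p, freqs) == pytest.approx(total)

    def test_missing_loci_skipped(self):
        loci = ("L1", "L2")
        freqs = {l: {1: 0.5, 2: 0.5} for l in loci}
        off = make_genotype("o", [(1, 2), (0, 0)], loci)
        cand = make_genotype("c", [(1, 1), (2, 2)], loci)
        assert single_parent_lod(off, cand, freqs) == pytest.approx(0.0)

    def test_no_shared_typed_loci_is_nan_with_warning(self):
        loci = ("L1",)
        off = make_genotype("o", [(0, 0)], loci)
        cand = make_genotype("c", [(1, 1)], loci)
        with pytest.warns(UserWarning, match="no shared typed loci"):
            assert math.isnan(single_parent_lod(off, cand, {"L1": {1: 1.0}}))

    def test_true_parent_scores_above_random_nonparents(self, parkia_system, rng):
        from seedshadow.synthetic import mendelian_offspring

        genotypes = parkia_system["true_genotypes"]
        freqs = parkia_system["freqs"]
        gaps = []
        for _ in range(30):
            i, j, k = rng.choice(len(genotypes), 3, replace=False)
            child = mendelian_offspring("child", genotypes[i], genotypes[j], rng)
            gaps.append(
                single_parent_lod(child, genotypes[i], freqs)
                - single_parent_lod(child, genotypes[k], freqs)
            )
        assert np.mean(gaps) > 0


@pytest.fixture(scope="module")
def poly_freqs():
    rng = np.random.default_rng(101)
    freqs = {}
    for l in range(10):
        p = rng.dirichlet(np.ones(8))
        freqs[f"L{l:02d}"] = {a + 1: float(x) for a, x in enumerate(p)}
    return freqs


class TestCriticalDelta:
    def test_deterministic_under_seed(self, poly_freqs):
        cfg = ParentageConfig(n_candidates=30, n_confidence_sims=2000)
        assert critical_delta(poly_freqs, cfg, 13) == critical_delta(poly_freqs, cfg, 13)

    def test_full_sampling_no_error_gives_tiny_threshold(self, poly_freqs):
        cfg = ParentageConfig(
            n_candidates=30,
            proportion_sampled=1.0,
            genotyping_error=0.0,
            n_confidence_sims=2000,
        )
        assert critical_delta(poly_freqs, cfg, 17) == pytest.approx(0.0, abs=0.5)

    def test_sparser_sampling_raises_threshold(self, poly_freqs):
        base = dict(n_candidates=60, genotyping_error=0.01, n_confidence_sims=4000)
        t_sparse = critical_delta(
            poly_freqs, ParentageConfig(proportion_sampled=0.15, **base), 19
        )
        t_dense = critical_delta(
            poly_freqs, ParentageConfig(proportion_sampled=0.99, **base), 19
        )
        assert t_sparse > t_dense


@pytest.fixture(scope="module")
def pas_population():
    cfg = parkia_like(n_loci=10, alleles_per_locus=8, adult_density_per_ha=2.0, seed=61)
    adults, _ = generate_landscape(cfg, 61)
    true_g, _, _ = generate_genotypes(adults, cfg, 62)
    offspring_g, _, recs, truth = generate_offspring_and_seedcoats(
        adults, true_g, cfg, n_offspring=150, rng=63
    )
    freqs = allele_frequencies(true_g + offspring_g)
    locations = {a.id: a.location for a in adults}
    locations.update({r.id: r.location for r in recs})
    return {
        "adults": adults,
        "adult_genotypes": true_g,
        "offspring": offspring_g,
        "truth": truth,
        "freqs": freqs,
        "locations": locations,
    }


class TestAssignment:
    def test_low_typed_offspring_excluded(self, pas_population):
        cfg = ParentageConfig(n_candidates=30, min_typed_loci=6, n_confidence_sims=500)
        loci = pas_population["offspring"][0].loci
        sparse = make_genotype("sparse", [(1, 1)] * 3 + [(0, 0)] * 7, loci)
        asn, n_excluded = assign_parentage(
            [sparse] + pas_population["offspring"][:5],
            pas_population["adult_genotypes"],
            pas_population["freqs"],
            cfg,
            seed=3,
            threshold=0.0,
        )
        assert n_excluded == 1
        assert all(a.offspring_id != "sparse" for a in asn)

    def test_error_free_assignments_hit_truth(self, pas_population):
        """At the simulated strict threshold ≥95% of assignments are correct."""
        cfg = ParentageConfig(
            n_candidates=len(pas_population["adult_genotypes"]),
            proportion_sampled=0.99,
            genotyping_error=0.0,
            n_confidence_sims=4000,
        )
        asn, _ = assign_parentage(
            pas_population["offspring"],
            pas_population["adult_genotypes"],
            pas_population["freqs"],
            cfg,
            seed=5,
        )
        truth = {r.offspring_id: (r.mother_id, r.father_id) for r in pas_population["truth"].rows}
        n_total = n_correct = 0
        for a in asn:
            for parent in a.parents:
                n_total += 1
                n_correct += parent.parent_id in truth[a.offspring_id]
        assert n_total > 50
        assert n_correct / n_total >= 0.95 - 3 * math.sqrt(0.05 * 0.95 / n_total)

    def test_incompatible_candidates_never_assigned(self, pas_population):
        """At e = 0 a Mendelian exclusion is absolute."""
        cfg = ParentageConfig(
            n_candidates=len(pas_population["adult_genotypes"]),
            genotyping_error=0.0,
            n_confidence_sims=500,
        )
        asn, _ = assign_parentage(
            pas_population["offspring"],
            pas_population["adult_genotypes"],
            pas_population["freqs"],
            cfg,
            seed=7,
            threshold=0.0,
        )
        genos = {g.sample_id: g for g in pas_population["adult_genotypes"]}
        offs = {g.sample_id: g for g in pas_population["offspring"]}
        for a in asn:
            for parent in a.parents:
                assert mendelian_compatible(offs[a.offspring_id], genos[parent.parent_id]) == 0


class TestEstimatePas:
    def _assignment(self, oid, parents):
        return ParentageAssignment(
            offspring_id=oid,
            parents=tuple(AssignedParent(parent_id=p, lod=1.0, delta=1.0) for p in parents),
        )

    def test_700m_filter_drops_far_parent(self):
        cfg = ParentageConfig(n_candidates=5)
        locations = {
            "off": Location(0, 0),
            "near": Location(100, 0),
            "far": Location(900, 0),
        }
        sample, n_removed = estimate_pas(
            [self._assignment("off", ["near", "far"])], locations, cfg
        )
        assert sample.values == [100.0]
        assert n_removed == 1

    def test_no_assignments_is_an_error(self):
        with pytest.raises(ValueError, match="no assigned"):
            estimate_pas([self._assignment("off", [])], {"off": Location(0, 0)},
                         ParentageConfig(n_candidates=5))

    def test_both_parents_both_counted(self):
        cfg = ParentageConfig(n_candidates=5)
        locations = {
            "off": Location(0, 0),
            "p1": Location(100, 0),
            "p2": Location(0, 250),
        }
        sample, _ = estimate_pas([self._assignment("off", ["p1", "p2"])], locations, cfg)
        assert sorted(sample.values) == [100.0, 250.0]
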