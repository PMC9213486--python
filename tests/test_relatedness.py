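"""ANI / AAI / TETRA relatedness, species calls, MAG filtering, dereplication."""

import numpy as np
import pytest

from oracles import transitive_closure_clusters
from sipseq import relatedness, seqgen
from sipseq.relatedness import (
    GenomeRecord,
    RelatednessResult,
    aai,
    ani,
    dereplicate,
    quality_filter,
    quality_report,
    same_species,
    tetra,
    tetra_correlation,
)


def genome(gid, seq, comp=None, cont=None):
    return GenomeRecord(gid, {"c1": seq}, completeness=comp, contamination=cont)


class TestANI:
    def test_identical_genomes_100(self):
        g = genome("a", seqgen.random_genome(30_000, 0.5, 1))
        res = ani(g, genome("b", g.contigs["c1"]))
        assert res.ani == pytest.approx(100.0)

    def test_substitution_recovery(self):
        # 60 kb genome at 5 % substitutions: ANI ~ 95
        base = seqgen.random_genome(60_000, 0.5, 2)
        res = ani(genome("a", base), genome("b", seqgen.mutate_nt(base, 0.05, 3)))
        assert res.ani == pytest.approx(95.0, abs=0.5)
        assert res.ani_fragments_used > 100

    def test_unrelated_genomes_undefined(self):
        a = genome("a", seqgen.random_genome(20_000, 0.5, 4))
        b = genome("b", seqgen.random_genome(20_000, 0.5, 5))
        res = ani(a, b)
        assert res.ani is None and res.reason

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            ani(GenomeRecord("a", {}), genome("b", "ACGT" * 300))


class TestAAI:
    def test_identical_proteomes(self):
        p = seqgen.random_proteome(20, 120, seed=1)
        res = aai(p, p)
        assert res.aai == pytest.approx(100.0) and res.rbh_count == 20

    def test_symmetric_exactly(self):
        p = seqgen.random_proteome(15, 100, seed=2)
        q = {k: seqgen.mutate_protein(v, 0.15, seed=i) for i, (k, v) in enumerate(p.items())}
        assert aai(p, q).aai == aai(q, p).aai

    def test_substitution_recovery(self):
        p = seqgen.random_proteome(40, 150, seed=3)
        q = {f"m_{k}": seqgen.mutate_protein(v, 0.10, seed=i) for i, (k, v) in enumerate(p.items())}
        res = aai(p, q)
        assert res.aai == pytest.approx(90.0, abs=1.0)
        assert res.rbh_count == 40

    def test_unrelated_proteomes_undefined(self):
        res = aai(seqgen.random_proteome(5, 80, seed=8), seqgen.random_proteome(5, 80, seed=9))
        assert res.aai is None and res.rbh_count == 0


class TestTetra:
    def test_self_correlation_is_one(self):
        g = genome("a", seqgen.random_genome(50_000, 0.45, 1))
        assert tetra_correlation(g, g) == pytest.approx(1.0)

    def test_reverse_complement_invariant(self):
        from sipseq.alignkit import reverse_complement

        g = genome("a", seqgen.random_genome(40_000, 0.55, 2))
        grc = genome("arc", reverse_complement(g.contigs["c1"]))
        assert np.allclose(tetra(g), tetra(grc))

    def test_signature_length_and_contig_order_invariance(self):
        s1 = seqgen.random_genome(20_000, 0.5, 3)
        s2 = seqgen.random_genome(20_000, 0.6, 4)
        g12 = GenomeRecord("x", {"a": s1, "b": s2})
        g21 = GenomeRecord("y", {"b": s2, "a": s1})
        z12, z21 = tetra(g12), tetra(g21)
        assert z12.shape == (256,)
        assert np.allclose(z12, z21)

    def test_independent_genomes_weak_correlation(self):
        rs = [tetra_correlation(
            genome("a", seqgen.random_genome(100_000, 0.5, 2 * s)),
            genome("b", seqgen.random_genome(100_000, 0.5, 2 * s + 1)),
        ) for s in range(5)]
        assert all(abs(r) < 0.3 for r in rs)

    def test_ambiguous_windows_skipped(self):
        g = genome("a", "ACGT" * 3000 + "NNNN" + "ACGT" * 3000)
        z = tetra(g)
        assert np.isfinite(z).all()


class TestSpeciesCall:
    @pytest.mark.parametrize(
        "ani_val, same",
        [(99.99, True), (82.6, False), (95.0, True)],  # inclusive boundary
    )
    def test_ani_rule(self, ani_val, same):
        res = RelatednessResult("a", "b", ani=ani_val)
        assert same_species(res).same_species is same

    def test_aai_fallback(self):
        assert same_species(RelatednessResult("a", "b", aai=99.3)).same_species
        assert not same_species(RelatednessResult("a", "b", aai=58.7)).same_species

    def test_both_undefined_uncallable(self):
        with pytest.raises(ValueError):
            same_species(RelatednessResult("a", "b"))


class TestQualityFilter:
    @pytest.mark.parametrize(
        "comp, cont, kept",
        [
            (86.9, 4.8, True),
            (70.7, 0.0, True),
            (70.0, 1.0, False),  # strict boundary at 70
            (99.8, 4.1, True),
            (90.0, 5.0, False),  # strict boundary at 5
        ],
    )
    def test_strict_thresholds(self, comp, cont, kept):
        r = genome("g", "ACGT", comp=comp, cont=cont)
        assert (r in quality_filter([r])) is kept

    def test_missing_metadata_excluded_with_reason(self):
        r = genome("g", "ACGT")
        assert quality_filter([r]) == []
        report = quality_report([r])
        assert report.loc[0, "reason"] == "missing quality metadata"


class TestDereplicate:
    def test_best_of_identical_pair_retained(self):
        seq = seqgen.random_genome(15_000, 0.5, 1)
        a = genome("a", seq, comp=90.0, cont=0.0)
        b = genome("b", seq, comp=80.0, cont=0.0)
        result = dereplicate([a, b])
        assert result.representative_ids == ["a"]

    def test_all_undefined_ani_all_retained(self):
        recs = [genome(f"g{i}", seqgen.random_genome(5_000, 0.5, i), comp=90.0, cont=0.0) for i in range(3)]
        result = dereplicate(recs)
        assert sorted(result.representative_ids) == ["g0", "g1", "g2"]

    def test_clusters_match_transitive_closure(self, rng):
        ids = [f"m{i}" for i in range(10)]
        recs = [genome(i, "ACGT" * 100, comp=float(80 + k), cont=0.0) for k, i in enumerate(ids)]
        pw = {}
        for i in range(10):
            for j in range(i + 1, 10):
                pw[(ids[i], ids[j])] = 99.0 if rng.random() < 0.25 else 80.0
        result = dereplicate(recs, pairwise_ani=pw)
        linked = lambda x, y: pw.get((x, y), pw.get((y, x), 0.0)) >= 95.0
        expected = transitive_closure_clusters(ids, linked)
        assert {frozenset(c) for c in result.clusters} == expected
        # one representative per cluster, each the top scorer (ties by id)
        for cluster, rep in zip(result.clusters, result.representatives):
            by_id = {r.id: r for r in recs}
            best = min(cluster, key=lambda g: (-by_id[g].score, g))
            assert rep.id == best

    def test_representatives_subset_of_quality_filtered(self):
        seq = seqgen.random_genome(12_000, 0.5, 7)
        recs = [
            genome("keep", seq, comp=95.0, cont=1.0),
            genome("drop", seqgen.mutate_nt(seq, 0.01, 8), comp=60.0, cont=1.0),
        ]
        kept = quality_filter(recs)
        result = dereplicate(kept)
        assert set(result.representative_ids) <= {r.id for r in kept}
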