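"""Subtype permutation comparison: exact cases, invariants, calibration."""

import numpy as np
import pytest
from scipy import stats

import mocolo as m


@pytest.fixture(scope="module")
def world():
    syn = m.make_genome(
        m.GenomeSpec(chromosome_length=300_000, background_g=0.25), seed=41
    )
    hosts, _ = m.make_features(
        syn, m.FeatureSpec(150, 400), m.FeatureSpec(10, 25), seed=41
    )
    return syn, hosts


def two_chrom_world():
    """Hosts on chr1 only, so chr2 placements are exactly disjoint."""
    syn = m.make_genome(
        m.GenomeSpec(n_chromosomes=2, chromosome_length=100_000), seed=42
    )
    starts = np.arange(50) * 1500 + 100
    hosts = m.MotifLibrary.from_arrays(
        np.array(["chr1"] * 50, dtype=object), starts, starts + 400,
        genome=syn.genome,
    )
    return syn, hosts


class TestNormalizedOverlap:
    def test_by_pivot_fraction(self, world):
        _, hosts = world
        # query = copies of the first 6 of 10 pivot motifs
        pivot = hosts.subset(range(10))
        query = hosts.subset(range(6))
        assert m.normalized_overlap(pivot, query, "by_pivot") == 0.6

    def test_identical_gives_one_disjoint_gives_zero(self, world):
        _, hosts = world
        assert m.normalized_overlap(hosts, hosts, "by_pivot") == 1.0
        syn2, hosts2 = two_chrom_world()
        far = m.MotifLibrary.from_arrays(
            np.array(["chr2"] * 5, dtype=object),
            np.arange(5) * 1000, np.arange(5) * 1000 + 25,
        )
        assert m.normalized_overlap(hosts2, far, "by_pivot") == 0.0
        assert m.normalized_overlap(hosts2, far, "by_subtype") == 0.0

    def test_empty_library_error(self, world):
        _, hosts = world
        with pytest.raises(ValueError, match="non-empty"):
            m.normalized_overlap(hosts, m.MotifLibrary())

    def test_invariant_under_duplication(self, world):
        syn, hosts = world
        q = m.make_subtyped_query(
            syn, hosts, {"A": m.SubtypeSpec(40, 25, 0.5)}, seed=43
        )
        doubled = q.subset(list(range(40)) * 2)
        assert m.normalized_overlap(hosts, q, "by_pivot") == m.normalized_overlap(
            hosts, doubled, "by_pivot"
        )


class TestCompareSubtypes:
    def test_identical_copies_give_p_one(self, world):
        syn, hosts = world
        q = m.make_subtyped_query(
            syn, hosts, {"A": m.SubtypeSpec(50, 25, 1.0)}, seed=44
        )
        result = m.compare_subtypes(
            hosts, {"A": q, "B": q}, n_permutations=49,
            mode="by_subtype", seed=45,
        )
        assert result.pairs["p_value"].iloc[0] == 1.0
        assert result.pairs["observed_diff"].iloc[0] == 0.0

    def test_inside_vs_disjoint_is_exactly_min_p(self):
        syn, hosts = two_chrom_world()
        rng = np.random.default_rng(46)
        host_pick = rng.integers(0, 50, size=50)
        offsets = rng.integers(0, 400 - 25 + 1, size=50)
        s_in = hosts.starts[host_pick] + offsets
        s_out = rng.integers(0, 100_000 - 25, size=50)
        query = m.MotifLibrary.from_arrays(
            np.array(["chr1"] * 50 + ["chr2"] * 50, dtype=object),
            np.concatenate([s_in, s_out]),
            np.concatenate([s_in, s_out]) + 25,
            subtypes=["inside"] * 50 + ["disjoint"] * 50,
            genome=syn.genome,
        )
        result = m.compare_subtypes(
            hosts, query, n_permutations=99, mode="by_subtype", seed=47
        )
        assert result.pairs["p_value"].iloc[0] == pytest.approx(0.01)
        assert result.pairs["observed_diff"].iloc[0] == pytest.approx(1.0)

    def test_three_subtypes_make_three_pairs(self, world):
        syn, hosts = world
        q = m.make_subtyped_query(
            syn, hosts,
            {"MR": m.SubtypeSpec(40, 25, 0.9),
             "DR": m.SubtypeSpec(40, 25, 0.5),
             "Z": m.SubtypeSpec(40, 25, 0.1)},
            seed=48,
        )
        result = m.compare_subtypes(
            hosts, q, n_permutations=49, mode="by_subtype", seed=49
        )
        assert len(result.pairs) == 3
        assert set(result.pairs.columns) >= {
            "subtype_a", "subtype_b", "observed_diff", "p_value", "q_value"
        }
        # planted ordering of proportions is recovered
        props = result.proportions
        assert props["MR"] > props["DR"] > props["Z"]

    def test_zero_motif_subtype_named_in_error(self, world):
        _, hosts = world
        with pytest.raises(ValueError, match="'B' has zero motifs"):
            m.compare_subtypes(
                hosts, {"A": hosts.subset(range(5)), "B": m.MotifLibrary()},
                n_permutations=9,
            )

    def test_permutation_preserves_sizes_and_pool(self, world):
        # label permutation must repartition the exact pooled multiset
        syn, hosts = world
        q = m.make_subtyped_query(
            syn, hosts,
            {"A": m.SubtypeSpec(30, 25, 0.2), "B": m.SubtypeSpec(20, 25, 0.2)},
            seed=50,
        )
        groups = m.partition_by_subtype(q)
        assert groups["A"].count == 30 and groups["B"].count == 20
        pooled = sorted(
            zip(q.chroms.tolist(), q.starts.tolist(), q.ends.tolist())
        )
        rng = np.random.default_rng(51)
        perm = rng.permutation(50)
        relabeled = [groups["A"], groups["B"]]
        merged = m.MotifLibrary.from_arrays(
            np.concatenate([g.chroms for g in relabeled]),
            np.concatenate([g.starts for g in relabeled]),
            np.concatenate([g.ends for g in relabeled]),
        )
        pa, pb = merged.subset(perm[:30]), merged.subset(perm[30:])
        assert pa.count == 30 and pb.count == 20
        re_pooled = sorted(
            zip(
                np.concatenate([pa.chroms, pb.chroms]).tolist(),
                np.concatenate([pa.starts, pb.starts]).tolist(),
                np.concatenate([pa.ends, pb.ends]).tolist(),
            )
        )
        assert re_pooled == pooled

    def test_rank_calibration_under_exchangeable_subtypes(self, world):
        # The randomized PIT of the permutation rank is Uniform(0,1) when
        # the two subtypes are exchangeable; the reported (add-one, folded)
        # p-value is conservative on ties, so it is checked one-sidedly.
        syn, hosts = world
        us = []
        rej = 0
        vrng = np.random.default_rng(52)
        n_data = 120
        for d in range(n_data):
            q = m.make_subtyped_query(
                syn, hosts,
                {"A": m.SubtypeSpec(80, 25, 0.0), "B": m.SubtypeSpec(80, 25, 0.0)},
                seed=6000 + d,
            )
            r = m.compare_subtypes(
                hosts, q, n_permutations=99, mode="by_subtype", seed=7000 + d
            )
            obs = abs(r.pairs["observed_diff"].iloc[0])
            null = np.abs(r.null_diffs[("A", "B")])
            n_gt = int((null > obs + 1e-12).sum())
            n_eq = int((np.abs(null - obs) <= 1e-12).sum())
            us.append((n_gt + vrng.random() * (1 + n_eq)) / 100.0)
            rej += r.pairs["p_value"].iloc[0] <= 0.05
        assert stats.kstest(us, "uniform").pvalue > 0.01
        # validity: reported p rejects at most nominally (binomial 99% upper)
        assert rej <= stats.binom.ppf(0.995, n_data, 0.05)


class TestPivotResimulation:
    def test_degenerate_genome_reduces_to_plain_permutation(self):
        # every pivot motif spans its whole chromosome: within-chromosome
        # simulation has a single placement, so resimulation changes nothing
        g = m.Genome({"c1": "ACGTACGT" * 10, "c2": "GGGGCCCC" * 10})
        pivot = m.MotifLibrary.from_arrays(
            np.array(["c1", "c2"], dtype=object), [0, 0], [80, 80], genome=g
        )
        rng = np.random.default_rng(53)
        qs = rng.integers(0, 60, size=30)
        query = m.MotifLibrary.from_arrays(
            np.array(["c1"] * 15 + ["c2"] * 15, dtype=object), qs, qs + 10,
            subtypes=["A"] * 15 + ["B"] * 15, genome=g,
        )
        plain = m.compare_subtypes(
            pivot, query, n_permutations=29, mode="by_subtype", seed=54
        )
        resim = m.compare_subtypes_with_pivot_resimulation(
            pivot, query, g,
            sim_config=m.SimulationConfig(
                match_g_content=False, within_chromosome=True
            ),
            n_permutations=29, mode="by_subtype", seed=54,
        )
        assert resim.resimulated_pivot
        assert plain.pairs["p_value"].iloc[0] == resim.pairs["p_value"].iloc[0]
        assert np.allclose(
            plain.null_diffs[("A", "B")], resim.null_diffs[("A", "B")]
        )

    def test_identical_subtypes_p_one(self, world):
        syn, hosts = world
        q = m.make_subtyped_query(
            syn, hosts, {"A": m.SubtypeSpec(30, 25, 0.8)}, seed=55
        )
        result = m.compare_subtypes_with_pivot_resimulation(
            hosts, {"A": q, "B": q}, syn.genome,
            sim_config=m.SimulationConfig(match_g_content=False),
            n_permutations=29, mode="by_subtype", seed=56,
        )
        assert result.pairs["p_value"].iloc[0] == 1.0

    def test_planted_ordering_recovered(self, world):
        syn, hosts = world
        q = m.make_subtyped_query(
            syn, hosts,
            {"MR": m.SubtypeSpec(60, 25, 0.9),
             "DR": m.SubtypeSpec(60, 25, 0.5),
             "Z": m.SubtypeSpec(60, 25, 0.1)},
            seed=57,
        )
        result = m.compare_subtypes_with_pivot_resimulation(
            hosts, q, syn.genome,
            sim_config=m.SimulationConfig(match_g_content=False),
            n_permutations=49, mode="by_subtype", seed=58,
        )
        props = result.proportions
        assert props["MR"] > props["DR"] > props["Z"]
        mr_z = result.pairs.set_index(["subtype_a", "subtype_b"]).loc[
            ("MR", "Z"), "p_value"
        ]
        assert mr_z <= 0.05
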