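"""Analytics: statistics, differential reaction fingerprints, k-NN map, SSN."""

import itertools
import random

import numpy as np
import pytest

from mitekit import align, analytics, fixtures
from mitekit.analytics import (FingerprintParams, compute_stats,
                               knn_reaction_map, reaction_fingerprint,
                               reaction_symmetric_difference,
                               sequence_similarity_network)
from mitekit.model import Dataset


class TestStats:
    def test_fixture_coverage_by_construction(self, dataset):
        st = compute_stats(dataset)
        # spec: n=10, mibig 0.89, rhea 0.15, neither 0.07 -> 9/2/1 entries
        assert st.n_active == 10 and st.n_retired == 0
        assert st.pct_mibig == 90
        assert st.pct_rhea == 20
        assert st.pct_neither == 10

    def test_rule_and_example_floors(self, dataset, bot):
        st = compute_stats(Dataset(list(dataset) + bot.entries))
        assert st.n_rules >= st.n_active
        assert st.n_examples >= st.n_rules

    def test_empty_dataset_reports_not_available(self):
        st = compute_stats(Dataset([]))
        assert st.n_active == 0 and st.n_datapoints == 0
        assert st.pct_mibig is None and "NA" in st.to_tsv()

    def test_taxon_rollup_counts_supplied_lineages(self, dataset):
        lineages = {acc: ("Bacteria" if i % 2 else "Fungi")
                    for i, acc in enumerate(dataset.accessions)}
        st = compute_stats(dataset, lineages)
        assert st.taxon_rollup == {"Bacteria": 5, "Fungi": 5}


PHENOL_A = "Oc1ccc(CC)cc1"
PHENOL_B = "Oc1ccc(CCN)cc1"


def jaccard_sim(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


class TestReactionFingerprint:
    def test_identity_reaction_is_zero_vector(self):
        fp = reaction_fingerprint("CCO", ["CCO"])
        assert not fp.bits.any()

    def test_deterministic_for_fixed_seed(self):
        p = FingerprintParams(seed=11)
        fp1 = reaction_fingerprint(PHENOL_A, ["COc1ccc(CC)cc1"], p)
        fp2 = reaction_fingerprint(PHENOL_A, ["COc1ccc(CC)cc1"], p)
        assert np.array_equal(fp1.bits, fp2.bits)

    def test_similar_reactions_closer_than_dissimilar(self):
        # two O-methylations of different phenols vs a chlorination of one;
        # oracle: the raw symmetric-difference identifier sets, before hashing
        methyl_a = (PHENOL_A, ["COc1ccc(CC)cc1"])
        methyl_b = (PHENOL_B, ["COc1ccc(CCN)cc1"])
        chloro_a = (PHENOL_A, ["CCc1ccc(O)c(Cl)c1"])
        raw = {name: set(reaction_symmetric_difference(s, p))
               for name, (s, p) in
               {"ma": methyl_a, "mb": methyl_b, "ca": chloro_a}.items()}
        assert jaccard_sim(raw["ma"], raw["mb"]) > jaccard_sim(raw["ma"], raw["ca"])
        fps = {name: reaction_fingerprint(s, p)
               for name, (s, p) in
               {"ma": methyl_a, "mb": methyl_b, "ca": chloro_a}.items()}
        assert (fps["ma"].jaccard_distance(fps["mb"])
                < fps["ma"].jaccard_distance(fps["ca"]))

    def test_zero_vector_iff_identical_identifier_multisets(self):
        fp = reaction_fingerprint(PHENOL_A, ["COc1ccc(CC)cc1"])
        diff = reaction_symmetric_difference(PHENOL_A, ["COc1ccc(CC)cc1"])
        assert bool(fp.bits.any()) == bool(diff)


def brute_force_knn_edges(fps, names, k):
    n = len(fps)
    dist = [[fps[i].jaccard_distance(fps[j]) for j in range(n)] for i in range(n)]
    rank = {name: i for i, name in enumerate(sorted(names))}
    edges = set()
    for i in range(n):
        neighbours = sorted((dist[i][j], rank[names[j]], j)
                            for j in range(n) if j != i)[:k]
        for _, _, j in neighbours:
            edges.add((min(names[i], names[j]), max(names[i], names[j])))
    return edges


@pytest.fixture(scope="module")
def entry_fps(dataset, bot):
    combined = Dataset(list(dataset) + bot.entries)
    return analytics.sample_entry_fingerprints(combined)


class TestKnnMap:
    def test_identical_fingerprints_connect_at_distance_zero(self):
        fp = reaction_fingerprint(PHENOL_A, ["COc1ccc(CC)cc1"])
        g = knn_reaction_map([fp, fp, fp], k=1, names=["a", "b", "c"])
        assert g.graph.number_of_edges() >= 2
        assert all(w == 0.0 for _, _, w in g.edges)
        assert g.orphan_fraction == 0.0

    def test_k_equals_n_minus_one_gives_complete_graph(self, entry_fps):
        fps, names = entry_fps
        g = knn_reaction_map(fps, k=len(fps) - 1, names=names)
        n = len(fps)
        assert g.graph.number_of_edges() == n * (n - 1) // 2

    @pytest.mark.parametrize("k", [1, 3])
    def test_agrees_with_brute_force_oracle(self, entry_fps, k):
        fps, names = entry_fps
        g = knn_reaction_map(fps, k=k, names=names)
        assert {(u, v) for u, v, _ in g.edges} == brute_force_knn_edges(fps, names, k)

    def test_invalid_k_rejected(self, entry_fps):
        fps, names = entry_fps
        with pytest.raises(ValueError):
            knn_reaction_map(fps, k=len(fps), names=names)


class TestSSN:
    def test_identical_pair_one_edge_no_orphans(self):
        seqs = {"A": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
                "B": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"}
        g = sequence_similarity_network(seqs, 0.7)
        assert len(g.edges) == 1 and g.orphan_fraction == 0.0

    def test_unrelated_pair_all_orphans(self):
        rng = random.Random(17)
        seqs = {name: "".join(rng.choice(fixtures.AMINO_ACIDS) for _ in range(100))
                for name in ("A", "B")}
        identity, _ = align.local_identity(seqs["A"], seqs["B"])
        assert identity < 0.7  # premise, checked against the aligner directly
        g = sequence_similarity_network(seqs, 0.7)
        assert len(g.edges) == 0 and g.orphan_fraction == 1.0

    def test_two_families_form_two_cliques(self, bundle):
        # default spec: two 5-member families mutated at 5% per site
        g = sequence_similarity_network(bundle.sequences, 0.7)
        names = sorted(bundle.sequences)
        fam1, fam2 = set(names[:5]), set(names[5:])
        for fam in (fam1, fam2):
            for a, b in itertools.combinations(sorted(fam), 2):
                assert g.graph.has_edge(a, b)
        assert not any(g.graph.has_edge(a, b)
                       for a in fam1 for b in fam2)
        assert g.orphan_fraction == 0.0

    def test_raising_threshold_never_adds_edges(self, bundle):
        low = sequence_similarity_network(bundle.sequences, 0.5)
        high = sequence_similarity_network(bundle.sequences, 0.9)
        low_edges = {(u, v) for u, v, _ in low.edges}
        high_edges = {(u, v) for u, v, _ in high.edges}
        assert high_edges <= low_edges

    def test_edge_list_export_is_sorted_tsv(self, bundle):
        g = sequence_similarity_network(bundle.sequences, 0.7)
        lines = g.to_edge_tsv().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        body = [tuple(line.split("\t")[:2]) for line in lines[1:]]
        assert body == sorted(body)
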