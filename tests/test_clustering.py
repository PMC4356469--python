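"""Identity definition, dereplication, and greedy centroid clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbiotag.clustering import (
    Phylotype,
    UniqueSequence,
    dereplicate,
    greedy_cluster,
    pairwise_identity,
    validate_membership,
)
from symbiotag.readprep import TaggedRead
from symbiotag.simdata import generate_references, generate_run

from conftest import small_config


def _mutate_at(seq: str, positions) -> str:
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = sub[out[p]]
    return "".join(out)


def _seq(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_force_optimal_identities(a: str, b: str) -> set[float]:
    """Enumerate every global alignment of two short strings and return the
    identities (matches / columns) of all score-optimal ones.

    Scoring: match +1, mismatch -1, gap -2.  Independent oracle for
    pairwise_identity on tiny inputs.
    """
    best_score = -np.inf
    best: set[float] = set()

    def recurse(i, j, score, matches, columns):
        nonlocal best_score, best
        if i == len(a) and j == len(b):
            if score > best_score:
                best_score, best = score, {matches / columns}
            elif score == best_score:
                best.add(matches / columns)
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            recurse(i + 1, j + 1, score + (1 if hit else -1),
                    matches + hit, columns + 1)
        if i < len(a):
            recurse(i + 1, j, score - 2, matches, columns + 1)
        if j < len(b):
            recurse(i, j + 1, score - 2, matches, columns + 1)

    recurse(0, 0, 0.0, 0, 1e-12)
    return best


class TestPairwiseIdentity:
    def test_identical(self):
        s = _seq(300)
        assert pairwise_identity(s, s) == 1.0

    def test_single_substitution(self):
        s = _seq(300)
        assert pairwise_identity(s, _mutate_at(s, [150])) == pytest.approx(299 / 300)

    def test_gapped_example(self):
        # optimal alignment ACG-T / ACGGT: 5 columns, 4 matches
        assert pairwise_identity("ACGT", "ACGGT") == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_three_substitutions_exercises_aligner_path(self):
        s = _seq(300, seed=3)
        m = _mutate_at(s, [10, 150, 290])
        assert pairwise_identity(s, m) == pytest.approx(297 / 300)

    @given(
        a=st.text(alphabet="ACG", min_size=1, max_size=6),
        b=st.text(alphabet="ACG", min_size=1, max_size=6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_alignment_oracle(self, a, b):
        got = pairwise_identity(a, b)
        optima = brute_force_optimal_identities(a, b)
        assert any(abs(got - x) < 1e-9 for x in optima)
        assert pairwise_identity(b, a) == got  # symmetry


class TestDereplicate:
    @staticmethod
    def _reads(spec):
        return {
            lib: [TaggedRead(f"{lib}{i}", b, np.full(len(b), 30))
                  for i, b in enumerate(bases)]
            for lib, bases in spec.items()
        }

    def test_groups_and_counts(self):
        uniques = dereplicate(self._reads({"lib1": ["AAA"] * 3, "lib2": ["CCC"]}))
        assert [(u.bases, u.abundance, u.counts) for u in uniques] == [
            ("AAA", 3, {"lib1": 3}),
            ("CCC", 1, {"lib2": 1}),
        ]

    def test_empty(self):
        assert dereplicate({}) == []

    def test_lexicographic_tie_break(self):
        uniques = dereplicate(self._reads({"lib1": ["CCC", "AAA", "CCC", "AAA"]}))
        assert [u.bases for u in uniques] == ["AAA", "CCC"]

    def test_cross_library_aggregation(self):
        uniques = dereplicate(self._reads({"a": ["GGG"], "b": ["GGG", "GGG"]}))
        (u,) = uniques
        assert u.abundance == 3 and u.counts == {"a": 1, "b": 2}


def _uniques(*items):
    return [UniqueSequence(bases=b, abundance=n, counts={"s": n}) for b, n in items]


class TestGreedyCluster:
    def test_near_identical_pair_merges(self):
        a = _seq(1000, seed=1)
        b = _mutate_at(a, [5, 250, 700])  # identity 0.997
        (p,) = greedy_cluster(_uniques((a, 10), (b, 3)))
        assert p.total_abundance == 13
        assert p.representative == a

    def test_distant_pair_stays_apart(self):
        a = _seq(300, seed=2)
        b = _mutate_at(a, [10, 50, 90, 130, 170, 210])  # identity 0.98
        assert len(greedy_cluster(_uniques((a, 10), (b, 3)))) == 2

    def test_greedy_chain_order_dependence(self):
        """A-B and B-C within threshold but A-C below: C is orphaned because
        comparisons run against the founding centroid A only."""
        a = _seq(1000, seed=4)
        b = _mutate_at(a, [10, 210, 410, 610, 810])            # A-B 0.995
        c = _mutate_at(b, [110, 310, 510, 710, 860, 960])      # B-C 0.994
        assert pairwise_identity(a, c) == pytest.approx(0.989)
        clusters = greedy_cluster(_uniques((a, 10), (b, 5), (c, 2)))
        sizes = sorted(len(p.members) for p in clusters)
        assert sizes == [1, 2]
        big = max(clusters, key=lambda p: len(p.members))
        assert {m.bases for m in big.members} == {a, b}

    def test_representative_most_abundant_member(self):
        a = _seq(500, seed=5)
        b = _mutate_at(a, [100])
        (p,) = greedy_cluster(_uniques((b, 7), (a, 3)))
        assert p.representative == b
        assert p.centroid == b
        # abundance tie: lexicographically smaller sequence wins
        first, second = sorted([a, b])
        (p2,) = greedy_cluster(_uniques((first, 5), (second, 5)))
        assert p2.representative == first

    def test_prefix_truncation_joins_length_variants(self):
        a = _seq(400, seed=6)
        clusters = greedy_cluster(_uniques((a, 5), (a[:300], 2), (a[:251], 1)))
        assert len(clusters) == 1

    def test_conservation_and_membership(self):
        rng = np.random.default_rng(0)
        base = _seq(400, seed=7)
        seqs = [
            _mutate_at(base, rng.choice(400, size=rng.integers(0, 8), replace=False))
            for _ in range(20)
        ]
        uniques = dereplicate(
            {"s": [TaggedRead(f"r{i}", b, np.full(len(b), 30))
                   for i, b in enumerate(seqs)]}
        )
        clusters = greedy_cluster(uniques)
        assert sum(p.total_abundance for p in clusters) == len(seqs)
        validate_membership(clusters)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        """Greedy result equals an independent brute-force scan (<= 10 seqs)."""
        rng = np.random.default_rng(seed)
        ref_a = _seq(300, seed=seed)
        ref_b = _mutate_at(ref_a, rng.choice(300, size=15, replace=False))
        pool = []
        for i in range(int(rng.integers(2, 11))):
            ref = ref_a if rng.random() < 0.5 else ref_b
            n_mut = int(rng.integers(0, 5))
            mut = _mutate_at(ref, rng.choice(300, size=n_mut, replace=False))
            cut = int(rng.integers(250, 301))
            pool.append((mut[:cut], int(rng.integers(1, 9))))
        uniques = []
        seen = set()
        for b, n in pool:
            if b not in seen:
                seen.add(b)
                uniques.append(UniqueSequence(b, n, {"s": n}))
        uniques.sort(key=lambda u: (-u.abundance, u.bases))

        # independent oracle: plain greedy scan over pairwise_identity
        oracle_centroids, oracle_members = [], []
        for u in uniques:
            for idx, c in enumerate(oracle_centroids):
                L = min(len(u.bases), len(c))
                if pairwise_identity(u.bases[:L], c[:L]) >= 0.99:
                    oracle_members[idx].append(u.bases)
                    break
            else:
                oracle_centroids.append(u.bases)
                oracle_members.append([u.bases])

        clusters = greedy_cluster(uniques)
        got = sorted(sorted(m.bases for m in p.members) for p in clusters)
        assert got == sorted(sorted(ms) for ms in oracle_members)


class TestRecoveryFromSimulation:
    def test_error_free_run_recovers_references_exactly(self):
        cfg = small_config(per_base_error_rate=0.0, tag_switch_prob=0.0)
        run = generate_run(cfg, generate_references(cfg))
        from symbiotag.readprep import demultiplex, quality_filter

        bins, _ = demultiplex(run.reads, run.samples)
        filtered = {k: quality_filter(v) for k, v in bins.items()}
        clusters = greedy_cluster(dereplicate(filtered))
        present = set(run.truth["origin_phylotype"])
        assert len(clusters) == len(present)
        refs = [r.sequence for r in run.references]
        for p in clusters:
            assert any(ref.startswith(p.representative) for ref in refs)
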