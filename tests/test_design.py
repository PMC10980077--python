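"""Simulated annealing, constraints, clustering and baselines."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mutenc.design import (
    DesignConfig,
    DesignError,
    blosum_distance_matrix,
    cluster_and_select,
    legal_mutation_set,
    random_baseline_variants,
    run_simulated_annealing,
    temperature_schedule,
)
from mutenc.simulate import SimParams, make_toy_structure, total_energy
from mutenc.structures import build_contact_graph
from mutenc.variants import AA_ALPHABET, Substitution, Variant, apply_variant


@pytest.fixture(scope="module")
def toy8():
    s = make_toy_structure(8, seed=9)
    graph = build_contact_graph(s)
    p = SimParams.random(seed=9, coupling_scale=0.0)  # additive objective
    return s, graph, p


def additive_score_fn(s, graph, p):
    return lambda seq: -total_energy(seq, p, graph)


@pytest.fixture(scope="module")
def observed_cfg(toy8):
    s, _, _ = toy8
    rng = np.random.default_rng(0)
    allowed = set()
    while len(allowed) < 12:
        pos = int(rng.integers(len(s.sequence)))
        aa = AA_ALPHABET[rng.integers(20)]
        if aa != s.sequence[pos]:
            allowed.add((pos, aa))
    return DesignConfig(
        n_mutations=2, constraint="observed", allowed_mutations=frozenset(allowed),
        n_runs=10, n_steps=2000, seed=0,
    )


class TestSchedule:
    def test_log_spaced_endpoints(self):
        cfg = DesignConfig(n_steps=10000)
        t = temperature_schedule(cfg)
        assert t[0] == pytest.approx(10.0)
        assert t[-1] == pytest.approx(0.01)
        # log-spaced: constant ratio between consecutive steps
        ratios = t[1:] / t[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_metropolis_limit_at_low_temperature(self):
        # a worsening move of -1 at T = 1e-9 is accepted with prob exp(-1e9)
        assert np.exp(-1.0 / 1e-9) == 0.0


class TestSimulatedAnnealing:
    def test_finds_exhaustive_optimum(self, toy8, observed_cfg):
        """Best-seen design equals the brute-force optimum 2-mutant in >= 9/10
        seeded runs under an additive objective."""
        s, graph, p = toy8
        score_fn = additive_score_fn(s, graph, p)
        legal = legal_mutation_set(s.sequence, observed_cfg)
        best_score = -np.inf
        for a, b in itertools.combinations(legal, 2):
            if a[0] == b[0]:
                continue
            subs = tuple(sorted(
                Substitution(pos, s.sequence[pos], aa) for pos, aa in (a, b)
            ))
            sc = score_fn(apply_variant(s.sequence, Variant(subs=subs)))
            if sc > best_score:
                best_score, best_variant = sc, Variant(subs=subs)
        hits = 0
        for run in range(10):
            _, best, bscore, _ = run_simulated_annealing(
                score_fn, s.sequence, observed_cfg, run_seed=run
            )
            hits += best == best_variant
        assert hits >= 9

    def test_every_state_satisfies_constraint(self, toy8, observed_cfg):
        s, graph, p = toy8
        allowed = observed_cfg.allowed_mutations
        seen = []

        def spy_fn(seq):
            seen.append(seq)
            return -total_energy(seq, p, graph)

        run_simulated_annealing(spy_fn, s.sequence, observed_cfg, run_seed=1)
        assert len(seen) >= observed_cfg.n_steps
        for seq in seen:
            muts = {(i, seq[i]) for i in range(len(seq)) if seq[i] != s.sequence[i]}
            assert len(muts) == observed_cfg.n_mutations
            assert muts <= allowed

    def test_unobserved_mode_excludes_allowed_set(self, toy8, observed_cfg):
        s, graph, p = toy8
        from dataclasses import replace

        cfg = replace(observed_cfg, constraint="unobserved", n_steps=200)
        seen = []

        def spy_fn(seq):
            seen.append(seq)
            return 0.0

        run_simulated_annealing(spy_fn, s.sequence, cfg, run_seed=2)
        for seq in seen:
            muts = {(i, seq[i]) for i in range(len(seq)) if seq[i] != s.sequence[i]}
            assert not muts & observed_cfg.allowed_mutations

    def test_constant_score_accepts_everything(self, toy8, observed_cfg):
        s, _, _ = toy8
        from dataclasses import replace

        cfg = replace(observed_cfg, n_steps=500)
        _, _, _, traj = run_simulated_annealing(lambda seq: 0.0, s.sequence, cfg, run_seed=3)
        assert traj["accepted"].all()

    def test_acceptance_declines_with_temperature(self, toy8, observed_cfg):
        """Acceptance rate in the hottest schedule quartile exceeds the coldest
        (rank test across several runs)."""
        s, graph, p = toy8
        score_fn = additive_score_fn(s, graph, p)
        hot, cold = [], []
        q = observed_cfg.n_steps // 4
        for run in range(8):
            _, _, _, traj = run_simulated_annealing(score_fn, s.sequence, observed_cfg, run_seed=100 + run)
            hot.append(traj["accepted"][:q].mean())
            cold.append(traj["accepted"][-q:].mean())
        assert mannwhitneyu(hot, cold, alternative="greater").pvalue < 0.01

    def test_infeasible_constraint_raises(self, toy8):
        s, _, _ = toy8
        cfg = DesignConfig(
            n_mutations=3, constraint="observed",
            allowed_mutations=frozenset({(0, "C"), (0, "D"), (1, "C")}),
            n_steps=10,
        )
        with pytest.raises(DesignError):
            run_simulated_annealing(lambda seq: 0.0, s.sequence, cfg, run_seed=0)


class TestBlosumDistance:
    def test_identity_zero_symmetry_nonnegative(self):
        seqs = ["ACDEF", "ACDEF", "WYKLH", "ACDEH"]
        d = blosum_distance_matrix(seqs)
        assert d[0, 1] == 0.0
        np.testing.assert_allclose(d, d.T)
        assert (d >= 0).all()
        assert d[0, 2] > d[0, 3] > 0

    def test_matches_hand_formula_on_pair(self):
        from Bio.Align import substitution_matrices

        bl = substitution_matrices.load("BLOSUM62")
        x, y = "AC", "AD"
        expected = sum(
            (bl[a, a] + bl[b, b]) / 2.0 - bl[a, b] for a, b in zip(x, y)
        )
        d = blosum_distance_matrix([x, y])
        assert d[0, 1] == pytest.approx(expected)


class TestClusterAndSelect:
    def make_blobs(self, base_seq, sizes=(150, 150, 150), n_centers=3, seed=0):
        """Blobs of designs tightly clustered around distant 2-mutant centers."""
        rng = np.random.default_rng(seed)
        length = len(base_seq)
        centers = [((0, "W"), (1, "Y")), ((4, "C"), (5, "D")), ((8, "K"), (9, "E"))]
        designs = []
        for (c, size) in zip(centers[:n_centers], sizes):
            for _ in range(size):
                muts = list(c)
                # jitter: re-draw the second mutation among 2 similar options
                if rng.random() < 0.5:
                    pos, aa = muts[1]
                    alt = {"Y": "F", "D": "E", "E": "D"}.get(aa, aa)
                    muts[1] = (pos, alt)
                subs = tuple(sorted(
                    Substitution(p, base_seq[p], a) for p, a in muts if base_seq[p] != a
                ))
                designs.append(Variant(subs=subs))
        return designs

    def test_three_blob_selection(self):
        base = "GAVLKEQSTM"
        designs = self.make_blobs(base, sizes=(200, 150, 150))
        report = cluster_and_select(designs, base, n_clusters=3, min_cluster_size=50, n_select=2)
        assert len(report.selected) == 2
        # first selected cluster is the largest blob
        first_positions = {s.position for s in report.selected[0].subs}
        assert first_positions == {0, 1}
        # greedy check: second representative maximizes distance to the first
        seqs = [apply_variant(base, v) for v in designs]
        d = blosum_distance_matrix(seqs)
        reps = report.representatives
        first = report.selected_clusters[0]
        others = [k for k in reps if k != first]
        dists = {k: d[reps[first], reps[k]] for k in others}
        assert report.selected_clusters[1] == max(dists, key=dists.get)

    def test_small_cluster_never_represented(self):
        base = "GAVLKEQSTM"
        designs = self.make_blobs(base, sizes=(200, 150, 50))
        with pytest.warns(UserWarning, match="survive"):
            report = cluster_and_select(
                designs, base, n_clusters=3, min_cluster_size=100, n_select=3
            )
        for v in report.selected:
            assert {s.position for s in v.subs} != {8, 9}

    def test_representative_minimizes_mean_distance(self):
        base = "GAVLKEQSTM"
        designs = self.make_blobs(base)
        report = cluster_and_select(designs, base, n_clusters=3, min_cluster_size=50, n_select=3)
        seqs = [apply_variant(base, v) for v in designs]
        d = blosum_distance_matrix(seqs)
        for k, rep in report.representatives.items():
            members = np.where(report.labels == k)[0]
            means = d[np.ix_(members, members)].mean(axis=1)
            assert d[np.ix_([rep], members)].mean() == pytest.approx(means.min())


class TestRandomBaselines:
    def test_observed_mode_uses_only_allowed(self, toy8, observed_cfg):
        s, _, _ = toy8
        vs = random_baseline_variants(s.sequence, observed_cfg, n=50, seed=0)
        for v in vs:
            assert len(v.subs) == 2
            assert len({x.position for x in v.subs}) == 2
            assert {(x.position, x.mut_aa) for x in v.subs} <= observed_cfg.allowed_mutations

    def test_unobserved_mode_avoids_allowed(self, toy8, observed_cfg):
        s, _, _ = toy8
        from dataclasses import replace

        cfg = replace(observed_cfg, constraint="unobserved", n_mutations=5)
        vs = random_baseline_variants(s.sequence, cfg, n=50, seed=1)
        for v in vs:
            assert len(v.subs) == 5
            assert not {(x.position, x.mut_aa) for x in v.subs} & observed_cfg.allowed_mutations
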