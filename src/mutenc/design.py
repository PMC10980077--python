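"""Simulated-annealing sequence design with clustering-based selection.

Designs are fixed-cardinality variants (exactly ``n_mutations`` substitutions)
optimized against any sequence-scoring function by Metropolis Monte Carlo
under a log-spaced temperature schedule (default 10^1 down to 10^-2).  A
proposal redraws a Poisson-distributed number of the current mutations
(clipped to [1, n_mutations]) and refills from the constraint-legal mutation
set without replacement, so every visited state satisfies the constraint.

Constraints are defined over (position, mutant amino acid) pairs: *observed*
designs reuse only mutations from a supplied allowed set (e.g. those present
in a small training set); *unobserved* designs exclude that set entirely.

The pool of per-run solutions is reduced to a handful of diverse candidates by
complete-linkage agglomerative clustering under a BLOSUM62-derived distance
d(x, y) = Σ_i (B(x_i,x_i) + B(y_i,y_i) − 2 B(x_i,y_i)) / 2 (zero iff the
sequences are identical), dropping clusters below a minimum size, then
greedily selecting cluster representatives starting from the largest cluster
and repeatedly adding the representative farthest (on average) from those
already selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .variants import AA_ALPHABET, Substitution, Variant, apply_variant


class DesignError(ValueError):
    pass


@dataclass
class DesignConfig:
    n_mutations: int = 5
    constraint: str = "observed"  # "observed" | "unobserved"
    allowed_mutations: frozenset = frozenset()  # of (position, mut_aa)
    n_runs: int = 10_000
    n_steps: int = 10_000
    t_start: float = 10.0
    t_end: float = 1e-2
    proposal_lambda: float = 1.0
    report: str = "final"  # cluster "final" or "best" states
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_start > self.t_end > 0):
            raise DesignError("need t_start > t_end > 0")
        if self.constraint not in ("observed", "unobserved"):
            raise DesignError(f"unknown constraint {self.constraint!r}")
        self.allowed_mutations = frozenset(
            (int(p), str(a)) for p, a in self.allowed_mutations
        )


def temperature_schedule(cfg: DesignConfig) -> np.ndarray:
    """Log-spaced temperatures from t_start to t_end inclusive, one per step."""
    return np.logspace(np.log10(cfg.t_start), np.log10(cfg.t_end), cfg.n_steps)


def legal_mutation_set(base_seq: str, cfg: DesignConfig) -> list[tuple[int, str]]:
    """(position, mutant) pairs satisfying the constraint mode."""
    all_muts = {
        (pos, aa)
        for pos, wt in enumerate(base_seq)
        for aa in AA_ALPHABET
        if aa != wt
    }
    if cfg.constraint == "observed":
        legal = set(cfg.allowed_mutations) & all_muts
    else:
        legal = all_muts - set(cfg.allowed_mutations)
    return sorted(legal)


def _sample_mutations(
    legal: list, n: int, rng: np.random.Generator, existing: list | None = None
) -> list:
    """Draw mutations without replacement until n distinct positions are held."""
    chosen = list(existing or [])
    held = {p for p, _ in chosen}
    order = rng.permutation(len(legal))
    for k in order:
        if len(chosen) == n:
            break
        pos, aa = legal[k]
        if pos not in held:
            chosen.append((pos, aa))
            held.add(pos)
    if len(chosen) < n:
        raise DesignError(
            "constraint set cannot form the requested number of mutations "
            "at distinct positions"
        )
    return chosen


def _to_variant(base_seq: str, muts, base_id: str = "") -> Variant:
    subs = tuple(
        sorted(Substitution(p, base_seq[p], a) for p, a in muts)
    )
    return Variant(base_id=base_id, subs=subs)


def run_simulated_annealing(
    score_fn,
    base_seq: str,
    cfg: DesignConfig,
    run_seed: int = 0,
):
    """One annealing run; returns (final, best, best_score, trajectory).

    ``trajectory`` records per-step temperature and acceptance for diagnostic
    tests (acceptance of Δ ≥ 0 moves is unconditional; worse moves are accepted
    with probability exp(Δ/T)).
    """
    rng = np.random.default_rng(run_seed)
    legal = legal_mutation_set(base_seq, cfg)
    temps = temperature_schedule(cfg)
    current = _sample_mutations(legal, cfg.n_mutations, rng)
    current_score = float(score_fn(apply_variant(base_seq, _to_variant(base_seq, current))))
    best, best_score = list(current), current_score
    accepted = np.zeros(cfg.n_steps, dtype=bool)
    for step, temp in enumerate(temps):
        n_change = min(max(int(rng.poisson(cfg.proposal_lambda)), 1), cfg.n_mutations)
        n_keep = cfg.n_mutations - n_change
        keep_idx = rng.permutation(cfg.n_mutations)[:n_keep]
        kept = [current[i] for i in keep_idx]
        proposal = _sample_mutations(legal, cfg.n_mutations, rng, existing=kept)
        prop_score = float(
            score_fn(apply_variant(base_seq, _to_variant(base_seq, proposal)))
        )
        delta = prop_score - current_score
        if delta >= 0 or rng.random() < np.exp(delta / temp):
            current, current_score = proposal, prop_score
            accepted[step] = True
            if current_score > best_score:
                best, best_score = list(current), current_score
    trajectory = {"temperature": temps, "accepted": accepted}
    return (
        _to_variant(base_seq, current),
        _to_variant(base_seq, best),
        best_score,
        trajectory,
    )


def design_sequences(score_fn, base_seq: str, cfg: DesignConfig):
    """All annealing runs; returns (reported variants, per-run records)."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(2**31, size=cfg.n_runs)
    records = []
    reported = []
    for seed in seeds:
        final, best, best_score, _ = run_simulated_annealing(
            score_fn, base_seq, cfg, run_seed=int(seed)
        )
        final_score = float(score_fn(apply_variant(base_seq, final)))
        records.append(
            {
                "run_seed": int(seed),
                "final": final,
                "final_score": final_score,
                "best": best,
                "best_score": best_score,
            }
        )
        reported.append(best if cfg.report == "best" else final)
    return reported, records


# ---------------------------------------------------------------------------
# BLOSUM62 distance, clustering and greedy representative selection
# ---------------------------------------------------------------------------

_BLOSUM = None


def _blosum62():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices

        _BLOSUM = substitution_matrices.load("BLOSUM62")
    return _BLOSUM


def blosum_distance_matrix(seqs: list[str], raw_similarity: bool = False) -> np.ndarray:
    """Pairwise distances under the quadratic-form BLOSUM62 dissimilarity.

    With ``raw_similarity`` the (shifted) negative alignment score is used
    instead: d = max_similarity − Σ B(x_i, y_i).
    """
    bl = _blosum62()
    alpha = bl.alphabet
    index = {a: i for i, a in enumerate(alpha)}
    b = np.asarray(bl)
    codes = np.array([[index[a] for a in s] for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    diag = b[codes, codes]  # (n, L) of B(a, a)
    for i in range(n):
        bij = b[codes[i][None, :], codes]  # (n, L) of B(x_i, y_j) per position
        if raw_similarity:
            d[i] = -bij.sum(axis=1)
        else:
            d[i] = ((diag[i][None, :] + diag) / 2.0 - bij).sum(axis=1)
    if raw_similarity:
        d -= d.min()
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class DesignReport:
    variants: list  # one per run (final or best states per config)
    labels: np.ndarray  # cluster assignment per design
    cluster_sizes: dict
    representatives: dict  # cluster label -> design index
    selected_clusters: list
    selected: list  # the selected representative Variants
    records: list = field(default_factory=list)


def cluster_and_select(
    designs: list[Variant],
    base_seq: str,
    n_clusters: int = 20,
    min_cluster_size: int = 100,
    n_select: int = 5,
    min_cluster_frac: float | None = None,
) -> DesignReport:
    """Complete-linkage clustering of designs and greedy diverse selection.

    Clusters smaller than ``min_cluster_size`` (or ``min_cluster_frac`` of the
    designs, if given) are dropped.  Each surviving cluster is represented by
    its member with the lowest mean distance to co-members; selection starts
    from the largest cluster and repeatedly adds the cluster whose
    representative is farthest on average from those already selected.
    """
    from sklearn.cluster import AgglomerativeClustering

    if len(designs) < n_clusters:
        raise DesignError("need at least n_clusters designs")
    seqs = [apply_variant(base_seq, v) for v in designs]
    d = blosum_distance_matrix(seqs)
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="complete"
    ).fit_predict(d)

    threshold = (
        int(np.ceil(min_cluster_frac * len(designs)))
        if min_cluster_frac is not None
        else min_cluster_size
    )
    sizes = {int(k): int((labels == k).sum()) for k in np.unique(labels)}
    surviving = [k for k, s in sizes.items() if s >= threshold]
    if len(surviving) < n_select:
        warnings.warn(
            f"only {len(surviving)} clusters survive the size filter; "
            f"reporting all of them",
            stacklevel=2,
        )
    reps = {}
    for k in surviving:
        members = np.where(labels == k)[0]
        mean_dist = d[np.ix_(members, members)].mean(axis=1)
        reps[k] = int(members[np.argmin(mean_dist)])

    selected: list[int] = []
    remaining = set(surviving)
    if surviving:
        first = max(surviving, key=lambda k: (sizes[k], -k))
        selected.append(first)
        remaining.discard(first)
    while remaining and len(selected) < n_select:
        def mean_to_selected(k):
            return float(np.mean([d[reps[k], reps[s]] for s in selected]))
        nxt = max(sorted(remaining), key=mean_to_selected)
        selected.append(nxt)
        remaining.discard(nxt)

    return DesignReport(
        variants=list(designs),
        labels=labels,
        cluster_sizes=sizes,
        representatives=reps,
        selected_clusters=selected,
        selected=[designs[reps[k]] for k in selected],
    )


def random_baseline_variants(
    base_seq: str, cfg: DesignConfig, n: int, seed: int = 0
) -> list[Variant]:
    """Random fixed-cardinality variants from the constraint-legal mutation set."""
    rng = np.random.default_rng(seed)
    legal = legal_mutation_set(base_seq, cfg)
    return [
        _to_variant(base_seq, _sample_mutations(legal, cfg.n_mutations, rng))
        for _ in range(n)
    ]
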