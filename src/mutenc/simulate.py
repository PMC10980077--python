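"""Synthetic biophysics simulator: toy structures, energies, attribute tables.

A seeded stand-in for a molecular-mechanics scoring pipeline.  Variant
sequences are scored with a known additive-plus-contact-epistatic energy on
the structure's Cβ contact graph:

    E(seq) = sum_i [ h(a_i) + b(a_i) * deg_i ] + sum_{(i,j) in edges} J(a_i, a_j)

with per-amino-acid field energies ``h``, burial weights ``b`` (scaled by
contact-graph degree) and a symmetric 20×20 contact-pair coupling ``J``.  The
three summands form a component vector c = (field, burial, pair); each named
score term k in the 60-term catalog is a fixed mixture ``A_k · c`` plus
optional Gaussian observation noise, and ``total_score`` is the plain sum of
components.  Because the pair term is the only interaction, setting J ≡ 0
makes every variant effect exactly additive — the ground truth that the
epistasis statistics and extrapolation benchmarks are validated against.

Optional binding terms are computed analogously from interface-restricted
parameters (g, J_b) over a designated interface residue set, emulating
energy-of-binding attributes without modeling a second chain.

Experimental sequence–function datasets are fabricated from the same energy:
latent fitness −E, an optional monotone sigmoid link, Gaussian assay noise,
wild-type normalization to 0 and rounding to 7 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import ContactGraph, ProteinStructure, build_contact_graph
from .variants import (
    AA_ALPHABET,
    Variant,
    apply_variant,
    parse_variant,
    sample_subvariants,
)

# ---------------------------------------------------------------------------
# Score-term catalog: 20 full-atom terms, 13 centroid terms, 27 filter terms.
# Five of these (dslf_fa13, linear_chainbreak, overlap_chainbreak,
# filter_total_score, res_count_all) are emitted but excluded before training,
# leaving 55 training tasks.  The three chainbreak/disulfide terms are
# identically zero here, and res_count_all is the constant sequence length, so
# the exclusion rules operate on columns that genuinely carry no signal.
# ---------------------------------------------------------------------------

FULLATOM_TERMS = [
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "fa_intra_sol_xover4",
    "lk_ball_wtd", "fa_elec", "pro_close", "hbond_sr_bb", "hbond_lr_bb",
    "hbond_bb_sc", "hbond_sc", "dslf_fa13", "omega", "fa_dun", "p_aa_pp",
    "yhh_planarity", "ref", "rama_prepro", "total_score",
]
CENTROID_TERMS = [
    "env", "pair", "cbeta", "vdw", "rg", "cenpack", "hs_pair", "ss_pair",
    "rsigma", "sheet", "linear_chainbreak", "overlap_chainbreak",
    "centroid_total_score",
]
FILTER_TERMS = [
    "filter_total_score", "res_count_all", "buried_np", "buried_np_per_res",
    "buried_over_exposed", "buried_minus_exposed", "contact_all",
    "contact_core_scn", "contact_core_sasa", "degree", "degree_core_scn",
    "exposed_hydrophobics", "exposed_np_afilmvwy", "exposed_polars",
    "exposed_total", "holes", "mismatch_probability", "n_charged",
    "n_hydrophobic", "n_hydrophobic_noa", "n_polar_core", "one_core_each",
    "pack", "ss_contributes_core", "ss_sc", "total_hydrophobic", "total_sasa",
]
FULL_CATALOG = FULLATOM_TERMS + CENTROID_TERMS + FILTER_TERMS  # 60 names

EXCLUDED_TERMS = [
    "dslf_fa13",
    "linear_chainbreak",
    "overlap_chainbreak",
    "filter_total_score",
    "res_count_all",
]
ZERO_TERMS = ["dslf_fa13", "linear_chainbreak", "overlap_chainbreak"]

BINDING_TERMS = [
    "complex_normalized", "dg_cross", "dg_separated", "dg_separated_per_dsasa",
    "dsasa_hphobic", "dsasa_int", "dsasa_polar", "delta_unsat_hbonds",
    "hbond_e_fraction", "hbonds_int", "nres_int", "packstat",
    "per_residue_energy_int", "sc_value", "side1_normalized", "side1_score",
    "side2_score",
]

assert len(FULL_CATALOG) == 60 and len(set(FULL_CATALOG)) == 60
assert len(BINDING_TERMS) == 17 and len(set(BINDING_TERMS)) == 17

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class SimulatorError(ValueError):
    pass


@dataclass
class SimParams:
    """Ground-truth energy parameters and term-mixing weights (see module docs)."""

    h: np.ndarray  # (20,) field energies
    b: np.ndarray  # (20,) burial weights
    J: np.ndarray  # (20, 20) symmetric contact couplings
    A: np.ndarray  # (60, 3) term mixing rows
    sigma: np.ndarray  # (60,) per-term observation noise sd
    interface: frozenset = frozenset()
    g: np.ndarray | None = None  # (20,) interface field energies
    J_b: np.ndarray | None = None  # (20, 20) symmetric interface couplings
    A_bind: np.ndarray | None = None  # (17, 2) binding-term mixing rows
    sigma_bind: np.ndarray | None = None  # (17,)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.J, self.J.T):
            raise SimulatorError("J must be symmetric")
        if self.J_b is not None and not np.allclose(self.J_b, self.J_b.T):
            raise SimulatorError("J_b must be symmetric")
        if np.any(self.sigma < 0):
            raise SimulatorError("sigma must be >= 0")

    @classmethod
    def random(
        cls,
        seed: int = 0,
        interface=(),
        noise_scale: float = 0.05,
        coupling_scale: float = 1.0,
    ) -> "SimParams":
        """Draw all parameter tables once from seeded standard normals.

        Mixing rows are L1-normalized so every term lives on the shared energy
        scale; rows for the identically-zero terms are zeroed.
        """
        rng = np.random.default_rng(seed)
        h = rng.normal(size=20)
        b = rng.normal(scale=0.3, size=20)
        J = rng.normal(scale=coupling_scale, size=(20, 20))
        J = (J + J.T) / 2.0
        A = rng.normal(size=(len(FULL_CATALOG), 3))
        A /= np.abs(A).sum(axis=1, keepdims=True)
        sigma = np.full(len(FULL_CATALOG), noise_scale)
        for term in ZERO_TERMS:
            k = FULL_CATALOG.index(term)
            A[k] = 0.0
            sigma[k] = 0.0
        g = rng.normal(size=20)
        J_b = rng.normal(scale=coupling_scale, size=(20, 20))
        J_b = (J_b + J_b.T) / 2.0
        A_bind = rng.normal(size=(len(BINDING_TERMS), 2))
        A_bind /= np.abs(A_bind).sum(axis=1, keepdims=True)
        sigma_bind = np.full(len(BINDING_TERMS), noise_scale)
        return cls(
            h=h, b=b, J=J, A=A, sigma=sigma, interface=frozenset(interface),
            g=g, J_b=J_b, A_bind=A_bind, sigma_bind=sigma_bind, seed=seed,
        )


def make_toy_structure(
    length: int, seed: int = 0, style: str = "globule", id: str | None = None
) -> ProteinStructure:
    """Deterministic toy backbone: a collapsed random walk (globule) or a line.

    Globule style steps 3.8 Å per residue with a center-of-mass pull chosen so
    the 8 Å contact graph has a protein-like mean degree (roughly 2–10 for
    lengths 20–100).  Chain style spaces residues 5 Å along the x-axis, giving
    a path contact graph.
    """
    if length < 1:
        raise SimulatorError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
    if style == "chain":
        coords = np.zeros((length, 3))
        coords[:, 0] = 5.0 * np.arange(length)
    elif style == "globule":
        # uniform packing in a ball whose radius scales as n^(1/3); the
        # density (one residue per ~300 A^3) and a 3.8 A clash distance put
        # the 8 A contact graph in the protein-like 2-10 mean-degree band
        radius = 4.17 * length ** (1.0 / 3.0)
        coords = np.zeros((length, 3))
        placed = 0
        while placed < length:
            cand = rng.normal(size=3)
            cand *= radius * rng.random() ** (1.0 / 3.0) / np.linalg.norm(cand)
            if placed == 0 or (
                np.linalg.norm(coords[:placed] - cand, axis=1).min() >= 3.8
            ):
                coords[placed] = cand
                placed += 1
    else:
        raise SimulatorError(f"unknown style {style!r}")
    return ProteinStructure(
        id=id or f"toy_{style}_{length}_{seed}", sequence=seq, coords=coords
    )


def _seq_to_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=int)
    except KeyError as exc:  # pragma: no cover
        raise SimulatorError(f"non-canonical amino acid {exc}") from exc


def energy_components(
    seq: str, p: SimParams, graph: ContactGraph, degrees: np.ndarray | None = None
) -> np.ndarray:
    """Return (field, burial, pair) component sums for one sequence."""
    a = _seq_to_indices(seq)
    if degrees is None:
        degrees = graph.degree()
    fielde = float(p.h[a].sum())
    burial = float((p.b[a] * degrees).sum())
    pair = float(sum(p.J[a[i], a[j]] for i, j in graph.edges))
    return np.array([fielde, burial, pair])


def binding_components(seq: str, p: SimParams, graph: ContactGraph) -> np.ndarray:
    """(interface field, interface pair) sums restricted to the interface set."""
    if p.g is None or p.J_b is None:
        raise SimulatorError("binding parameters not set")
    a = _seq_to_indices(seq)
    iface = p.interface
    fielde = float(sum(p.g[a[i]] for i in iface))
    pair = float(
        sum(p.J_b[a[i], a[j]] for i, j in graph.edges if i in iface and j in iface)
    )
    return np.array([fielde, pair])


def total_energy(seq: str, p: SimParams, graph: ContactGraph) -> float:
    return float(energy_components(seq, p, graph).sum())


def score_variants(
    s: ProteinStructure,
    p: SimParams,
    variants: list[Variant],
    with_binding: bool = False,
    noise: bool = True,
    seed: int | None = None,
    graph: ContactGraph | None = None,
) -> pd.DataFrame:
    """Score variants into an attribute table (base_pdb, variant, 60[+17] terms).

    Noiseless mode is an exact deterministic function of sequence.  The noisy
    mode draws one standard-normal per (variant, term), scaled by the term's
    sigma, from ``seed`` (defaults to ``p.seed``).
    """
    if graph is None:
        graph = build_contact_graph(s)
    degrees = graph.degree()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    terms = list(FULL_CATALOG) + (list(BINDING_TERMS) if with_binding else [])
    rows = np.empty((len(variants), len(terms)))
    names = []
    i_total = FULL_CATALOG.index("total_score")
    i_filter_total = FULL_CATALOG.index("filter_total_score")
    i_rescount = FULL_CATALOG.index("res_count_all")
    for r, v in enumerate(variants):
        seq = apply_variant(s.sequence, v)
        c = energy_components(seq, p, graph, degrees)
        vals = p.A @ c
        vals[i_total] = c.sum()
        if noise:
            vals = vals + rng.normal(size=len(FULL_CATALOG)) * p.sigma
        vals[i_filter_total] = vals[i_total]
        vals[i_rescount] = float(len(seq))
        if with_binding:
            cb = binding_components(seq, p, graph)
            bvals = p.A_bind @ cb
            if noise:
                bvals = bvals + rng.normal(size=len(BINDING_TERMS)) * p.sigma_bind
            vals = np.concatenate([vals, bvals])
        else:
            vals = vals[: len(FULL_CATALOG)]
        rows[r] = vals
        names.append(v.to_string())
    out = pd.DataFrame(rows, columns=terms)
    out.insert(0, "variant", names)
    out.insert(0, "base_pdb", s.id)
    return out


def inject_faults(
    table: pd.DataFrame,
    r_nan: float = 0.0,
    r_dup: float = 0.0,
    r_out: float = 0.0,
    seed: int = 0,
    outlier_magnitude: float = 1e4,
) -> pd.DataFrame:
    """Corrupt an attribute table for preprocessing tests and demos.

    Each row independently: with probability ``r_nan`` one random term becomes
    NaN; with probability ``r_dup`` the row is duplicated (appended); with
    probability ``r_out`` a huge offset is added to ``total_score`` (and its
    filter copy).  Rows are marked in a boolean ``injected_outlier`` column so
    recovery can be measured.
    """
    rng = np.random.default_rng(seed)
    out = table.copy().reset_index(drop=True)
    term_cols = [c for c in out.columns if c not in ("base_pdb", "variant")]
    out["injected_outlier"] = False
    n = len(out)
    nan_rows = np.where(rng.random(n) < r_nan)[0]
    for r in nan_rows:
        col = term_cols[rng.integers(len(term_cols))]
        out.loc[r, col] = np.nan
    dup_rows = np.where(rng.random(n) < r_dup)[0]
    out_rows = np.where(rng.random(n) < r_out)[0]
    for r in out_rows:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.loc[r, "total_score"] += sign * outlier_magnitude
        if "filter_total_score" in out.columns:
            out.loc[r, "filter_total_score"] = out.loc[r, "total_score"]
        out.loc[r, "injected_outlier"] = True
    if len(dup_rows):
        out = pd.concat([out, out.iloc[dup_rows]], ignore_index=True)
    return out


@dataclass
class ExperimentalDataset:
    """Variant/score table for one base protein; wild type normalized to 0."""

    df: pd.DataFrame  # columns: variant, score
    base_seq: str
    base_id: str = ""

    def __post_init__(self) -> None:
        if not {"variant", "score"} <= set(self.df.columns):
            raise SimulatorError("dataset needs 'variant' and 'score' columns")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def variants(self) -> list[Variant]:
        return [
            parse_variant(t, self.base_seq, base_id=self.base_id)
            for t in self.df["variant"]
        ]

    def sequences(self) -> list[str]:
        return [apply_variant(self.base_seq, v) for v in self.variants()]

    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    def n_subs(self) -> np.ndarray:
        return np.array(
            [0 if not t else t.count(",") + 1 for t in self.df["variant"]]
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, base_seq: str, base_id: str = "") -> "ExperimentalDataset":
        df = pd.read_csv(path, dtype={"variant": str}, keep_default_na=False)
        df["score"] = pd.to_numeric(df["score"])
        return cls(df=df, base_seq=base_seq, base_id=base_id)


def make_experimental_dataset(
    s: ProteinStructure,
    p: SimParams,
    n: int,
    max_subs: int = 2,
    assay_noise: float = 0.1,
    link: str = "identity",
    seed: int = 0,
    include_wildtype: bool = True,
    graph: ContactGraph | None = None,
) -> ExperimentalDataset:
    """Fabricate a sequence–function dataset with known ground truth.

    Latent fitness is −E(seq), optionally squashed by a logistic link centered
    on the wild-type latent value (scale = latent sd over the sample, mimicking
    a saturating assay), plus Gaussian assay noise.  Scores are normalized so
    the wild type's realized score is exactly 0 and rounded to 7 decimals.
    """
    if n < 1:
        raise SimulatorError("n must be >= 1")
    if graph is None:
        graph = build_contact_graph(s)
    variants = sample_subvariants(
        s.sequence, n, max_subs=max_subs, seed=seed, base_id=s.id
    )[:n]
    if include_wildtype:
        variants = [Variant(base_id=s.id)] + variants
    rng = np.random.default_rng(seed)
    latent = np.array(
        [-total_energy(apply_variant(s.sequence, v), p, graph) for v in variants]
    )
    wt_latent = -total_energy(s.sequence, p, graph)
    if link == "sigmoid":
        scale = latent.std() or 1.0
        latent = 1.0 / (1.0 + np.exp(-(latent - wt_latent) / scale))
        wt_latent = 0.5
    elif link != "identity":
        raise SimulatorError(f"unknown link {link!r}")
    scores = latent + rng.normal(scale=assay_noise, size=len(variants))
    if include_wildtype:
        wt_realized = scores[0]
    else:
        wt_realized = wt_latent
    scores = np.round(scores - wt_realized, 7)
    df = pd.DataFrame({"variant": [v.to_string() for v in variants], "score": scores})
    return ExperimentalDataset(df=df, base_seq=s.sequence, base_id=s.id)
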