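"""Variant representation, parsing and variant-space generation.

A *variant* is a set of single-residue amino-acid substitutions applied to a
named base (wild-type) protein sequence.  Variants are written as
comma-separated ``<wt><pos><mut>`` tokens, e.g. ``"G41L,V54G"``.  Positions
are 0-based internally; parsers accept an explicit ``offset`` for 1-based
published strings.  The empty string denotes the wild type.

Two generators cover the variant spaces used for pretraining data:
:func:`enumerate_variants` (exhaustive singles / singles+doubles) and
:func:`sample_subvariants`, which repeatedly draws a random ``max_subs``-order
variant and expands all of its lower-order sub-variants until a target count
is reached.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

_TOKEN_RE = re.compile(r"^([A-Za-z*])(\d+)([A-Za-z*])$")


class VariantError(ValueError):
    """Malformed variant string or variant/sequence inconsistency."""


@dataclass(frozen=True, order=True)
class Substitution:
    """One amino-acid substitution: ``wt_aa`` at 0-based ``position`` -> ``mut_aa``."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_SET or self.mut_aa not in AA_SET:
            raise VariantError(
                f"non-canonical amino acid in {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise VariantError(
                f"substitution {self.wt_aa}{self.position}{self.mut_aa} is synonymous"
            )
        if self.position < 0:
            raise VariantError(f"negative position {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class Variant:
    """An ordered, position-distinct set of substitutions against one base protein."""

    base_id: str = ""
    subs: tuple[Substitution, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        positions = [s.position for s in self.subs]
        if sorted(positions) != positions:
            object.__setattr__(self, "subs", tuple(sorted(self.subs)))
            positions = sorted(positions)
        if len(set(positions)) != len(positions):
            raise VariantError(f"duplicate positions in variant {positions}")

    @property
    def n_subs(self) -> int:
        return len(self.subs)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.subs)

    def is_wildtype(self) -> bool:
        return not self.subs

    def to_string(self, one_based: bool = False) -> str:
        off = 1 if one_based else 0
        return ",".join(f"{s.wt_aa}{s.position + off}{s.mut_aa}" for s in self.subs)

    def __str__(self) -> str:
        return self.to_string()


def parse_variant(
    text: str, base_seq: str, offset: int = 0, base_id: str = ""
) -> Variant:
    """Parse a comma-separated substitution string against ``base_seq``.

    ``offset`` is subtracted from each printed position (pass 1 for 1-based
    strings).  The wild-type letter of every token must agree with
    ``base_seq``; duplicate (position, mutation) tokens are collapsed, but two
    different mutations at one position are an error.
    """
    if offset not in (0, 1):
        raise VariantError(f"offset must be 0 or 1, got {offset}")
    text = text.strip()
    if not text:
        return Variant(base_id=base_id)
    subs: dict[int, Substitution] = {}
    for token in text.split(","):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if m is None:
            raise VariantError(f"malformed substitution token {token!r}")
        wt, pos_s, mut = m.group(1).upper(), m.group(2), m.group(3).upper()
        pos = int(pos_s) - offset
        if pos < 0 or pos >= len(base_seq):
            raise VariantError(f"position {pos} out of range for token {token!r}")
        if base_seq[pos] != wt:
            raise VariantError(
                f"token {token!r}: wild-type letter {wt} does not match "
                f"base sequence {base_seq[pos]} at 0-based position {pos}"
            )
        sub = Substitution(pos, wt, mut)
        prior = subs.get(pos)
        if prior is not None and prior != sub:
            raise VariantError(f"conflicting substitutions at position {pos}")
        subs[pos] = sub
    return Variant(base_id=base_id, subs=tuple(sorted(subs.values())))


def apply_variant(base_seq: str, v: Variant) -> str:
    """Return the mutated sequence; wild-type letters are re-checked."""
    chars = list(base_seq)
    for s in v.subs:
        if s.position >= len(base_seq):
            raise VariantError(f"position {s.position} out of range")
        if chars[s.position] != s.wt_aa:
            raise VariantError(
                f"substitution {s} inconsistent with base sequence "
                f"({chars[s.position]} at {s.position})"
            )
        chars[s.position] = s.mut_aa
    return "".join(chars)


def _single_subs(base_seq: str) -> list[Substitution]:
    out = []
    for pos, wt in enumerate(base_seq):
        for mut in AA_ALPHABET:
            if mut != wt:
                out.append(Substitution(pos, wt, mut))
    return out


def enumerate_variants(base_seq: str, order: int, base_id: str = "") -> list[Variant]:
    """All 1-substitution (order 1) or 1- and 2-substitution (order 2) variants.

    Counts: order 1 gives ``L*19`` variants, order 2 adds ``C(L,2)*19**2``.
    """
    if order not in (1, 2):
        raise VariantError(f"order must be 1 or 2, got {order}")
    singles = _single_subs(base_seq)
    out = [Variant(base_id=base_id, subs=(s,)) for s in singles]
    if order == 2:
        by_pos: dict[int, list[Substitution]] = {}
        for s in singles:
            by_pos.setdefault(s.position, []).append(s)
        for i, j in itertools.combinations(sorted(by_pos), 2):
            for a in by_pos[i]:
                for b in by_pos[j]:
                    out.append(Variant(base_id=base_id, subs=(a, b)))
    return out


def variant_space_size(length: int, max_subs: int) -> int:
    """Exact number of 1..max_subs-substitution variants of a length-L sequence."""
    return sum(math.comb(length, k) * 19**k for k in range(1, max_subs + 1))


def _random_variant(
    base_seq: str, n_subs: int, rng: np.random.Generator, base_id: str
) -> Variant:
    positions = np.sort(rng.choice(len(base_seq), size=n_subs, replace=False))
    subs = []
    for pos in positions:
        wt = base_seq[pos]
        choices = [a for a in AA_ALPHABET if a != wt]
        subs.append(Substitution(int(pos), wt, choices[rng.integers(len(choices))]))
    return Variant(base_id=base_id, subs=tuple(subs))


def sample_subvariants(
    base_seq: str,
    n_target: int,
    max_subs: int = 5,
    seed: int = 0,
    base_id: str = "",
) -> list[Variant]:
    """Sub-variants sampling: grow a duplicate-free variant list to ``n_target``.

    Each iteration draws a uniformly random ``max_subs``-substitution variant
    and enumerates every non-empty subset of its substitutions (the variant
    itself plus all lower-order sub-variants), keeping those not seen before.
    When the final iteration overshoots, the fresh batch is truncated in a
    seeded random order.  If the full 1..max_subs variant space holds fewer
    than ``n_target`` variants, the full space is returned.
    """
    if n_target < 1:
        raise VariantError("n_target must be >= 1")
    if max_subs < 1 or max_subs > len(base_seq):
        raise VariantError("need 1 <= max_subs <= len(base_seq)")
    space = variant_space_size(len(base_seq), max_subs)
    if n_target >= space:
        # exhaustive fallback; only reachable for small spaces
        out = []
        for k in range(1, max_subs + 1):
            for positions in itertools.combinations(range(len(base_seq)), k):
                pools = [
                    [Substitution(p, base_seq[p], a) for a in AA_ALPHABET if a != base_seq[p]]
                    for p in positions
                ]
                for combo in itertools.product(*pools):
                    out.append(Variant(base_id=base_id, subs=combo))
        return out

    rng = np.random.default_rng(seed)
    seen: set[tuple[Substitution, ...]] = set()
    out: list[Variant] = []
    while len(out) < n_target:
        parent = _random_variant(base_seq, max_subs, rng, base_id)
        fresh: list[Variant] = []
        for k in range(1, max_subs + 1):
            for combo in itertools.combinations(parent.subs, k):
                if combo not in seen:
                    seen.add(combo)
                    fresh.append(Variant(base_id=base_id, subs=combo))
        need = n_target - len(out)
        if len(fresh) > need:
            order = rng.permutation(len(fresh))[:need]
            fresh = [fresh[i] for i in sorted(order)]
        out.extend(fresh)
    return out


def read_variant_csv(path) -> list[str]:
    """Read a single-column ``variant`` CSV; wild type is the empty string."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "variant" not in df.columns:
        raise VariantError("variant CSV must have a 'variant' column")
    return df["variant"].tolist()


def write_variant_csv(path, variants, one_based: bool = False) -> None:
    strings = [
        v.to_string(one_based=one_based) if isinstance(v, Variant) else str(v)
        for v in variants
    ]
    pd.DataFrame({"variant": strings}).to_csv(path, index=False)
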