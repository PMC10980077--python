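"""Protein structures, Cβ contact graphs and relative-distance maps.

The transformer's relative position embeddings consume an integer
relative-distance map.  In 1D mode the distance between sequence positions
``i`` and ``j`` is the signed offset ``j - i`` clipped to ±8.  In 3D mode the
structure is reduced to an undirected contact graph — an edge whenever the
residues' Cβ atoms (Cα for glycine or any residue lacking a Cβ) lie within
8 Å — and the distance is the shortest-path length in that graph, clipped at
3, so 0 = self, 1 = direct contact, 2 = second shell, 3 = everything else.
Disconnected pairs fall in the catch-all bucket 3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

CONTACT_THRESHOLD_A = 8.0
CLIP_1D = 8
CLIP_3D = 3


class StructureError(ValueError):
    """Unusable or inconsistent structural input."""


@dataclass
class ProteinStructure:
    """Per-residue representative coordinates (Cβ, Cα fallback), in Å."""

    id: str
    sequence: str
    coords: np.ndarray  # (L, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactGraph:
    n: int
    edges: frozenset  # of (i, j) tuples with i < j

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n), dtype=int)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a


@dataclass
class RelativeDistanceMap:
    mode: str  # "1d" or "3d"
    clip: int
    values: np.ndarray  # (n, n) int

    @property
    def n_classes(self) -> int:
        """Number of distinct distance buckets (size of the embedding table)."""
        return 2 * self.clip + 1 if self.mode == "1d" else self.clip + 1

    def index_map(self) -> np.ndarray:
        """Distances shifted to non-negative embedding-table indices."""
        return self.values + (self.clip if self.mode == "1d" else 0)


def load_structure(
    pdb_text: str,
    expected_seq: str | None = None,
    chain: str | None = None,
    id: str = "structure",
) -> ProteinStructure:
    """Parse a PDB record into one representative coordinate per residue.

    Uses the Cβ atom, falling back to Cα for glycine or incomplete residues.
    Hetero records and waters are ignored.  If ``chain`` is None the file must
    contain exactly one chain.  ``expected_seq`` enforces an exact sequence
    match.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure(id, io.StringIO(pdb_text))))
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) != 1:
            raise StructureError(
                f"structure has chains {sorted(chains)}; pass a chain selector"
            )
        chain_obj = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise StructureError(f"chain {chain!r} not found (have {sorted(chains)})")
        chain_obj = chains[chain]

    letters = []
    coords = []
    for res in chain_obj:
        if res.id[0] != " ":
            continue  # hetero/water
        name = res.get_resname().upper()
        if name not in protein_letters_3to1:
            raise StructureError(f"non-standard residue {name} at {res.id}")
        if "CB" in res:
            atom = res["CB"]
        elif "CA" in res:
            atom = res["CA"]
        else:
            raise StructureError(f"residue {name} {res.id} has neither CB nor CA")
        letters.append(protein_letters_3to1[name])
        coords.append(atom.get_coord())
    if not letters:
        raise StructureError("no standard residues found")
    seq = "".join(letters)
    if expected_seq is not None and seq != expected_seq:
        raise StructureError(
            f"parsed sequence does not match expected sequence "
            f"({seq!r} vs {expected_seq!r})"
        )
    return ProteinStructure(id=id, sequence=seq, coords=np.asarray(coords, dtype=float))


def build_contact_graph(
    s: ProteinStructure, threshold_A: float = CONTACT_THRESHOLD_A
) -> ContactGraph:
    """Edge between residues iff coordinate distance <= threshold (inclusive)."""
    n = len(s)
    if n == 1:
        return ContactGraph(n=1, edges=frozenset())
    d = squareform(pdist(s.coords))
    ii, jj = np.where(np.triu(d <= threshold_A, k=1))
    return ContactGraph(n=n, edges=frozenset(zip(ii.tolist(), jj.tolist())))


def relative_distances_1d(length: int, clip: int = CLIP_1D) -> RelativeDistanceMap:
    idx = np.arange(length)
    values = np.clip(idx[None, :] - idx[:, None], -clip, clip)
    return RelativeDistanceMap(mode="1d", clip=clip, values=values)


def relative_distances_3d(
    s: ProteinStructure,
    clip: int = CLIP_3D,
    graph: ContactGraph | None = None,
    threshold_A: float = CONTACT_THRESHOLD_A,
) -> RelativeDistanceMap:
    """Shortest-path lengths on the contact graph, clipped; unreachable -> clip."""
    if graph is None:
        graph = build_contact_graph(s, threshold_A)
    n = graph.n
    adj = csr_matrix(graph.adjacency())
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    d[~np.isfinite(d)] = clip
    values = np.minimum(d, clip).astype(int)
    return RelativeDistanceMap(mode="3d", clip=clip, values=values)


def relative_distances(
    s, mode: str, clip: int | None = None, **kwargs
) -> RelativeDistanceMap:
    """Dispatch on mode: ``s`` is a length (1D) or a ProteinStructure (3D)."""
    mode = mode.lower()
    if mode == "1d":
        length = len(s) if isinstance(s, ProteinStructure) else int(s)
        return relative_distances_1d(length, clip if clip is not None else CLIP_1D)
    if mode == "3d":
        if not isinstance(s, ProteinStructure):
            raise StructureError("3D relative distances require a ProteinStructure")
        return relative_distances_3d(s, clip if clip is not None else CLIP_3D, **kwargs)
    raise StructureError(f"unknown relative-distance mode {mode!r}")


def structure_to_pdb(s: ProteinStructure) -> str:
    """Minimal single-chain PDB text with one CB pseudo-atom per residue.

    Round-trips through :func:`load_structure`; used to export toy structures.
    """
    from Bio.Data.IUPACData import protein_letters_1to3

    lines = []
    for i, (aa, xyz) in enumerate(zip(s.sequence, s.coords)):
        resname = protein_letters_1to3[aa].upper()
        atom = "CA" if aa == "G" else "CB"
        # strict fixed columns: name [12:16], resname [17:20], chain [21],
        # resseq [22:26], xyz [30:54], occ/b [54:66], element [76:78]
        lines.append(
            f"ATOM  {i + 1:5d}  {atom:<3s} {resname:<3s} A{i + 1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
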