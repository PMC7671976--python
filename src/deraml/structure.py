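"""Residue contact graphs from protein structures.

The structural encoding used throughout the package is a residue contact
graph: one node per residue (1-based author numbering, one-letter amino
acid, a representative side-chain coordinate) and an undirected edge
between every residue pair whose representative atoms lie within a distance
threshold. The representative atom is C-beta, falling back to C-alpha for
glycine — the common contact-map convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .variants import AA_INDEX, PointMutation, Variant

DEFAULT_CONTACT_THRESHOLD = 8.0  # Angstrom


@dataclass(frozen=True)
class ResidueGraph:
    """Residues with coordinates plus undirected contact edges.

    ``positions`` are strictly unique 1-based residue numbers; ``edges``
    maps an unordered position pair ``(i, j)`` with ``i < j`` to the
    Euclidean distance in Angstrom between the representative coordinates.
    """

    positions: tuple[int, ...]
    amino_acids: tuple[str, ...]
    coordinates: np.ndarray  # (n, 3) float
    edges: Mapping[tuple[int, int], float]
    threshold: float
    _pos_index: dict[int, int] = field(repr=False, default_factory=dict)
    _adjacency: dict[int, tuple[int, ...]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("residue positions must be unique")
        if len(self.positions) != len(self.amino_acids):
            raise ValueError("positions and amino acids differ in length")
        for aa in self.amino_acids:
            if aa not in AA_INDEX:
                raise ValueError(f"unknown amino acid {aa!r}")
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (len(self.positions), 3):
            raise ValueError("coordinates must be (n_residues, 3)")
        object.__setattr__(self, "coordinates", coords)
        for (i, j), d in self.edges.items():
            if i == j:
                raise ValueError("self-edges are not allowed")
            if i > j:
                raise ValueError("edges must be stored with i < j")
            if d > self.threshold + 1e-9:
                raise ValueError(f"edge ({i},{j}) distance {d} exceeds threshold {self.threshold}")
        self._pos_index.update({p: k for k, p in enumerate(self.positions)})
        adj: dict[int, list[int]] = {p: [] for p in self.positions}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        self._adjacency.update({p: tuple(sorted(n)) for p, n in adj.items()})

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    def index_of(self, position: int) -> int:
        try:
            return self._pos_index[position]
        except KeyError:
            raise KeyError(f"position {position} not in graph") from None

    def amino_acid_at(self, position: int) -> str:
        return self.amino_acids[self.index_of(position)]

    def coordinate_of(self, position: int) -> np.ndarray:
        return self.coordinates[self.index_of(position)]

    def neighbors(self, position: int) -> tuple[int, ...]:
        self.index_of(position)
        return self._adjacency.get(position, ())

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    # -- validation of mutations ------------------------------------------

    def validate_mutation(self, mutation: PointMutation) -> None:
        aa = self.amino_acid_at(mutation.position)
        if aa != mutation.wt:
            raise ValueError(
                f"mutation {mutation} claims wild-type {mutation.wt} but the "
                f"graph has {aa} at position {mutation.position}"
            )

    def validate_variant(self, variant: Variant) -> None:
        for m in variant:
            self.validate_mutation(m)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "residues": [
                {"position": int(p), "aa": a, "xyz": [float(x) for x in c]}
                for p, a, c in zip(self.positions, self.amino_acids, self.coordinates)
            ],
            "edges": [
                {"i": int(i), "j": int(j), "distance": float(d)}
                for (i, j), d in sorted(self.edges.items())
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ResidueGraph":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = source
        payload = json.loads(text)
        residues = payload["residues"]
        return cls(
            positions=tuple(r["position"] for r in residues),
            amino_acids=tuple(r["aa"] for r in residues),
            coordinates=np.array([r["xyz"] for r in residues], dtype=float),
            edges={(e["i"], e["j"]): e["distance"] for e in payload["edges"]},
            threshold=payload["threshold"],
        )


# -- construction ----------------------------------------------------------

ResidueCoordinates = Sequence[tuple[int, str, np.ndarray]]


def build_contact_graph(
    coords: ResidueCoordinates,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> ResidueGraph:
    """Connect residue pairs whose representative atoms are within ``threshold``.

    ``coords`` is a sequence of ``(position, amino_acid, xyz)`` triples in
    any order; the graph stores them sorted by position, so construction is
    invariant to input ordering.
    """
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    entries = sorted(coords, key=lambda t: t[0])
    positions = tuple(int(p) for p, _, _ in entries)
    aas = tuple(a for _, a, _ in entries)
    xyz = np.array([np.asarray(c, dtype=float) for _, _, c in entries]).reshape(len(entries), 3)
    edges: dict[tuple[int, int], float] = {}
    if len(entries) > 1:
        dmat = squareform(pdist(xyz))
        ii, jj = np.nonzero(np.triu(dmat <= threshold, k=1))
        for a, b in zip(ii, jj):
            edges[(positions[a], positions[b])] = float(dmat[a, b])
    return ResidueGraph(positions=positions, amino_acids=aas, coordinates=xyz,
                        edges=edges, threshold=float(threshold))


def read_structure(path: str | Path, chain: str) -> list[tuple[int, str, np.ndarray]]:
    """Representative residue coordinates from a single-model PDB file.

    Returns ``(author_position, one_letter_aa, xyz)`` triples for every
    standard amino-acid residue of ``chain``, using the C-beta atom (C-alpha
    for glycine). Residues with insertion codes are rejected; residues
    lacking both C-beta and C-alpha are skipped with a warning.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    chains = {c.id: c for c in model}
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not found; available: {sorted(chains)}")
    out: list[tuple[int, str, np.ndarray]] = []
    for residue in chains[chain]:
        het, seqnum, icode = residue.id
        if het != " ":
            continue  # waters, ligands
        resname = residue.get_resname().strip().upper()
        if resname not in protein_letters_3to1:
            continue
        if icode.strip():
            raise ValueError(f"insertion-coded residue {resname}{seqnum}{icode} is not supported")
        aa = protein_letters_3to1[resname]
        atom = None
        if aa != "G" and "CB" in residue:
            atom = residue["CB"]
        elif "CA" in residue:
            atom = residue["CA"]
        elif "CB" in residue:
            atom = residue["CB"]
        if atom is None:
            warnings.warn(f"residue {resname}{seqnum} lacks CB and CA; skipped", stacklevel=2)
            continue
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]  # first altloc
        out.append((int(seqnum), aa, atom.get_coord().astype(float)))
    return out


def active_site_shell(
    graph: ResidueGraph,
    centers: Iterable[int],
    radius: float,
) -> set[int]:
    """Positions within ``radius`` Angstrom of any center position.

    Mirrors the mutagenesis-targeting rule of picking residues in close
    vicinity of the active site; the centers themselves are always included
    (radius 0 returns exactly the centers).
    """
    centers = list(centers)
    if not centers:
        raise ValueError("at least one center position is required")
    center_xyz = np.array([graph.coordinate_of(c) for c in centers])
    d = np.linalg.norm(graph.coordinates[:, None, :] - center_xyz[None, :, :], axis=2)
    within = d.min(axis=1) <= radius
    shell = {p for p, w in zip(graph.positions, within) if w}
    shell.update(centers)
    return shell
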