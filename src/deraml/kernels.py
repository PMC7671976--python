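"""Contact-graph kernels between enzyme variants.

The similarity between two variants u, v on a residue graph G = (P, E) with
a substitution model s and an edge mix lambda is the raw kernel

    k(u, v) = (1 - lambda) * sum_i s(a_i, b_i)
              + lambda * sum_{(i,j) in E} s(a_i, b_i) * s(a_j, b_j)

where a_i / b_i is the amino acid occupying position i in u / v (the wild
type unless mutated). The node term compares residue content position by
position; the edge term compares residue *pairs* across every structural
contact, so mutations are weighed in the context of their 3D neighbourhood.
Reported similarities are cosine-normalized,
``k(u,v) / sqrt(k(u,u) k(v,v))``, giving a unit diagonal.

Because variants differ from the wild type in at most three positions, all
kernels are evaluated as corrections to precomputed wild-type sums; the
cost per variant pair is independent of protein length, which is what makes
screening tens of thousands of candidates against a 131-variant training
set cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structure import ResidueGraph
from .substitution import PSD_TOLERANCE, SubstitutionModel, load_substitution_models
from .variants import AA_INDEX, Variant, check_duplicate_free

DEFAULT_EDGE_MIX = 0.5


@dataclass(frozen=True)
class KernelDefinition:
    """One candidate kernel: a substitution model plus the node/edge mix."""

    model: SubstitutionModel
    edge_mix: float = DEFAULT_EDGE_MIX

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_mix <= 1.0:
            raise ValueError("edge_mix (lambda) must lie in [0, 1]")

    @property
    def name(self) -> str:
        return self.model.name


@dataclass(frozen=True)
class KernelMatrix:
    """A (cross-)Gram matrix of normalized variant similarities."""

    row_index: tuple[str, ...]
    col_index: tuple[str, ...]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError("kernel matrix shape does not match its index")
        object.__setattr__(self, "values", v)

    @property
    def is_square(self) -> bool:
        return self.row_index == self.col_index

    def min_eigenvalue(self) -> float:
        if not self.is_square:
            raise ValueError("eigenvalues are defined for square Gram matrices only")
        return float(np.linalg.eigvalsh(self.values).min())


def _mutation_arrays(variant: Variant, graph: ResidueGraph) -> tuple[np.ndarray, np.ndarray]:
    """(graph index, mutant amino-acid index) arrays for a variant."""
    gidx = np.empty(len(variant), dtype=np.intp)
    aidx = np.empty(len(variant), dtype=np.intp)
    for k, m in enumerate(variant):
        gidx[k] = graph.index_of(m.position)
        aidx[k] = AA_INDEX[m.mut]
    return gidx, aidx


class KernelComputer:
    """Kernel evaluations for one (graph, kernel definition) pair.

    Precomputes the wild-type node sum, edge sum and per-position
    neighbour sums once, so that every subsequent pair evaluation touches
    only the mutated positions.
    """

    def __init__(self, graph: ResidueGraph, definition: KernelDefinition):
        self.graph = graph
        self.definition = definition
        S = definition.model.matrix
        self._S = S
        self._lam = definition.edge_mix
        n = len(graph)
        self._wt_idx = np.array([AA_INDEX[a] for a in graph.amino_acids], dtype=np.intp)
        self._s0 = S[self._wt_idx, self._wt_idx]  # self-similarity of each wild-type residue
        self._S0 = float(self._s0.sum())
        # neighbour wild-type self-similarity sums and the wild-type edge sum
        nsum = np.zeros(n)
        E0 = 0.0
        self._edge_index_pairs: list[tuple[int, int]] = []
        for (pi, pj) in graph.edges:
            i, j = graph.index_of(pi), graph.index_of(pj)
            nsum[i] += self._s0[j]
            nsum[j] += self._s0[i]
            E0 += self._s0[i] * self._s0[j]
            self._edge_index_pairs.append((i, j))
        self._edge_set = {(min(i, j), max(i, j)) for i, j in self._edge_index_pairs}
        self._nsum = nsum
        self._E0 = E0
        self._k_wt = (1.0 - self._lam) * self._S0 + self._lam * E0
        if self._k_wt <= 0:
            raise ValueError("wild-type self-kernel is non-positive; check the substitution model")

    # -- scalar path -------------------------------------------------------

    def raw_pair(self, u: Variant, v: Variant) -> float:
        """Un-normalized kernel via wild-type delta corrections."""
        S, lam = self._S, self._lam
        occupied: dict[int, list[int]] = {}
        for variant, slot in ((u, 0), (v, 1)):
            gidx, aidx = _mutation_arrays(variant, self.graph)
            for g, a in zip(gidx, aidx):
                occupied.setdefault(int(g), [int(self._wt_idx[g]), int(self._wt_idx[g])])[slot] = int(a)
        node = self._S0
        edge = self._E0
        deltas: dict[int, float] = {}
        for g, (a, b) in occupied.items():
            d = S[a, b] - self._s0[g]
            deltas[g] = d
            node += d
            edge += d * self._nsum[g]
        touched = sorted(deltas)
        for x in range(len(touched)):
            for y in range(x + 1, len(touched)):
                i, j = touched[x], touched[y]
                if (i, j) in self._edge_set:
                    edge += deltas[i] * deltas[j]
        return (1.0 - lam) * node + lam * edge

    def raw_self(self, v: Variant) -> float:
        return self.raw_pair(v, v)

    def pair(self, u: Variant, v: Variant) -> float:
        """Cosine-normalized kernel value."""
        return self.raw_pair(u, v) / np.sqrt(self.raw_self(u) * self.raw_self(v))

    # -- vectorized path ---------------------------------------------------

    def _encode(self, variants: Sequence[Variant]) -> list[tuple[np.ndarray, np.ndarray]]:
        return [_mutation_arrays(v, self.graph) for v in variants]

    def self_vector(self, variants: Sequence[Variant]) -> np.ndarray:
        """Raw self-kernels k(v, v) for a variant list."""
        S, lam = self._S, self._lam
        out = np.empty(len(variants))
        for idx, (gidx, aidx) in enumerate(self._encode(variants)):
            node = self._S0
            edge = self._E0
            d = S[aidx, aidx] - self._s0[gidx]
            node += d.sum()
            edge += (d * self._nsum[gidx]).sum()
            for x in range(len(gidx)):
                for y in range(x + 1, len(gidx)):
                    i, j = int(gidx[x]), int(gidx[y])
                    if (min(i, j), max(i, j)) in self._edge_set:
                        edge += d[x] * d[y]
            out[idx] = (1.0 - lam) * node + lam * edge
        return out

    def cross_raw(self, rows: Sequence[Variant], cols: Sequence[Variant]) -> np.ndarray:
        """Raw kernel matrix k(rows x cols), vectorized over variant pairs.

        The pair kernel decomposes into per-variant scalars plus
        corrections at shared mutated positions and at structural contacts
        between mutated positions; each correction is applied as a grouped
        array update, so the cost scales with the number of library
        positions and their contact edges, not with len(rows)*len(cols)
        times protein length.
        """
        S, lam = self._S, self._lam
        enc_r = self._encode(rows)
        enc_c = self._encode(cols)
        nr, nc = len(rows), len(cols)

        def per_variant_scalars(enc):
            nodeA = np.zeros(len(enc))
            edgeB = np.zeros(len(enc))
            for idx, (gidx, aidx) in enumerate(enc):
                d = S[aidx, self._wt_idx[gidx]] - self._s0[gidx]
                nodeA[idx] = d.sum()
                edgeB[idx] = (d * self._nsum[gidx]).sum()
            return nodeA, edgeB

        nodeA_r, edgeB_r = per_variant_scalars(enc_r)
        nodeA_c, edgeB_c = per_variant_scalars(enc_c)

        K = (1.0 - lam) * (self._S0 + nodeA_r[:, None] + nodeA_c[None, :]) \
            + lam * (self._E0 + edgeB_r[:, None] + edgeB_c[None, :])

        # group mutations by graph position
        def by_position(enc, n):
            table: dict[int, tuple[list[int], list[int]]] = {}
            for idx, (gidx, aidx) in enumerate(enc):
                for g, a in zip(gidx, aidx):
                    table.setdefault(int(g), ([], []))[0].append(idx)
                    table[int(g)][1].append(int(a))
            return {g: (np.array(i, dtype=np.intp), np.array(a, dtype=np.intp))
                    for g, (i, a) in table.items()}

        rows_at = by_position(enc_r, nr)
        cols_at = by_position(enc_c, nc)

        # shared-position corrections to the node and neighbour-sum terms
        def eps_block(g: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            ri, ra = rows_at[g]
            ci, ca = cols_at[g]
            w = self._wt_idx[g]
            eps = S[np.ix_(ra, ca)] - S[ra, w][:, None] - S[w, ca][None, :] + self._s0[g]
            return ri, ci, eps

        shared = sorted(set(rows_at) & set(cols_at))
        for g in shared:
            ri, ci, eps = eps_block(g)
            K[np.ix_(ri, ci)] += ((1.0 - lam) + lam * self._nsum[g]) * eps

        # Delta_i * Delta_j over contact edges between mutated positions
        if lam > 0.0:
            used = set(rows_at) | set(cols_at)
            lib_edges = [(i, j) for (i, j) in self._edge_set if i in used and j in used]

            def delta_matrix(g: int) -> np.ndarray:
                du = np.zeros(nr)
                dv = np.zeros(nc)
                w = self._wt_idx[g]
                if g in rows_at:
                    ri, ra = rows_at[g]
                    du[ri] = S[ra, w] - self._s0[g]
                if g in cols_at:
                    ci, ca = cols_at[g]
                    dv[ci] = S[w, ca] - self._s0[g]
                D = du[:, None] + dv[None, :]
                if g in rows_at and g in cols_at:
                    ri, ci, eps = eps_block(g)
                    D[np.ix_(ri, ci)] += eps
                return D

            for (i, j) in lib_edges:
                K += lam * (delta_matrix(i) * delta_matrix(j))
        return K

    def cross(self, rows: Sequence[Variant], cols: Sequence[Variant]) -> np.ndarray:
        """Cosine-normalized cross kernel matrix."""
        K = self.cross_raw(rows, cols)
        sr = self.self_vector(rows)
        sc = self.self_vector(cols)
        return K / np.sqrt(np.outer(sr, sc))


# -- public operations -----------------------------------------------------


def variant_kernel(
    v1: Variant,
    v2: Variant,
    graph: ResidueGraph,
    model: SubstitutionModel,
    edge_mix: float = DEFAULT_EDGE_MIX,
) -> float:
    """Normalized contact-graph kernel between two variants."""
    graph.validate_variant(v1)
    graph.validate_variant(v2)
    return KernelComputer(graph, KernelDefinition(model, edge_mix)).pair(v1, v2)


def _psd_clip_normalized(K: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues, then cosine-renormalize the diagonal.

    Congruence with a positive diagonal preserves positive
    semidefiniteness, so the result is PSD with an exactly unit diagonal.
    """
    K = 0.5 * (K + K.T)
    w, v = np.linalg.eigh(K)
    if w.min() < -PSD_TOLERANCE:
        K = (v * np.clip(w, 0.0, None)) @ v.T
        K = 0.5 * (K + K.T)
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    np.fill_diagonal(K, 1.0)
    return K


def gram_matrix(
    variants: Sequence[Variant],
    graph: ResidueGraph,
    model: SubstitutionModel,
    edge_mix: float = DEFAULT_EDGE_MIX,
) -> KernelMatrix:
    """Normalized, PSD-corrected Gram matrix over a duplicate-free variant set."""
    if len(variants) == 0:
        raise ValueError("variant set must be nonempty")
    names = tuple(check_duplicate_free(variants))
    comp = KernelComputer(graph, KernelDefinition(model, edge_mix))
    K = _psd_clip_normalized(comp.cross(variants, variants))
    return KernelMatrix(row_index=names, col_index=names, values=K, name=model.name)


def combine_kernels(grams: Sequence[KernelMatrix], weights: Sequence[float]) -> KernelMatrix:
    """Entrywise convex combination of Gram matrices sharing one index."""
    if len(grams) != len(weights):
        raise ValueError("one weight per Gram matrix is required")
    w = np.asarray(weights, dtype=float)
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    first = grams[0]
    for g in grams[1:]:
        if g.row_index != first.row_index or g.col_index != first.col_index:
            raise ValueError("Gram matrices must share the same variant index")
    values = sum(wi * g.values for wi, g in zip(w, grams))
    return KernelMatrix(row_index=first.row_index, col_index=first.col_index,
                        values=values, name="+".join(g.name for g in grams))


class KernelBank:
    """A set of candidate kernels over one residue graph.

    Wraps one :class:`KernelComputer` per kernel definition and exposes the
    Gram/cross-Gram computations the multiple-kernel-learning model needs.
    """

    def __init__(self, graph: ResidueGraph, definitions: Iterable[KernelDefinition]):
        self.graph = graph
        self.definitions = tuple(definitions)
        if not self.definitions:
            raise ValueError("kernel bank needs at least one kernel definition")
        self._computers = [KernelComputer(graph, d) for d in self.definitions]

    @classmethod
    def default(cls, graph: ResidueGraph, edge_mix: float = DEFAULT_EDGE_MIX) -> "KernelBank":
        return cls(graph, (KernelDefinition(m, edge_mix) for m in load_substitution_models()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def gram_matrices(self, variants: Sequence[Variant]) -> list[KernelMatrix]:
        names = tuple(check_duplicate_free(variants))
        out = []
        for d, comp in zip(self.definitions, self._computers):
            K = _psd_clip_normalized(comp.cross(variants, variants))
            out.append(KernelMatrix(row_index=names, col_index=names, values=K, name=d.name))
        return out

    def cross_matrices(
        self,
        rows: Sequence[Variant],
        cols: Sequence[Variant],
        only: Sequence[str] | None = None,
    ) -> dict[str, np.ndarray]:
        """Normalized cross kernels, keyed by kernel name.

        ``only`` restricts computation to the named kernels (e.g. those
        with non-negligible learned weight).
        """
        wanted = set(only) if only is not None else None
        out: dict[str, np.ndarray] = {}
        for d, comp in zip(self.definitions, self._computers):
            if wanted is not None and d.name not in wanted:
                continue
            out[d.name] = comp.cross(rows, cols)
        return out
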