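"""Amino-acid substitution models used as node/edge kernels.

Each model is a symmetric 20x20 similarity over the standard amino acids
(row/column order ACDEFGHIKLMNPQRSTVWY). Two families are packaged:

* matrix-derived — log-odds exchangeability matrices (BLOSUM62, and the
  structure-alignment-derived Johnson-Overington matrix standing for the
  "interaction" family) rescaled linearly to [0, 1];
* property-derived — Gaussian radial similarities
  ``exp(-(p_i - p_j)^2 / (2 sigma^2))`` over published per-residue scalar
  scales (Miyazawa contact energies, Kyte-Doolittle hydrophobicity,
  Zamyatnin residue volumes, formal side-chain charge), with the bandwidth
  ``sigma`` set to the scale's standard deviation over the 20 residues;

plus the identity (Kronecker delta) model. Every matrix is projected to the
positive-semidefinite cone by clipping negative eigenvalues at zero, so any
Gram matrix assembled from them is a valid covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants import AMINO_ACIDS, AA_INDEX

PSD_TOLERANCE = 1e-8

# Residue side-chain volumes in cubic Angstrom (Zamyatnin, 1972).
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Formal side-chain charge near neutral pH; histidine carries a small
# fractional protonation.
RESIDUE_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
RESIDUE_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})


@dataclass(frozen=True)
class SubstitutionModel:
    """A named symmetric 20x20 amino-acid similarity matrix."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError(f"substitution matrix {self.name} is not symmetric")
        object.__setattr__(self, "matrix", m)

    def similarity(self, a: str, b: str) -> float:
        return float(self.matrix[AA_INDEX[a], AA_INDEX[b]])

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


def _clip_psd(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    matrix = 0.5 * (matrix + matrix.T)
    w, v = np.linalg.eigh(matrix)
    if w.min() >= 0.0:
        return matrix
    clipped = (v * np.clip(w, 0.0, None)) @ v.T
    return 0.5 * (clipped + clipped.T)


def _rescale_unit(matrix: np.ndarray) -> np.ndarray:
    lo, hi = matrix.min(), matrix.max()
    return (matrix - lo) / (hi - lo)


def radial_similarity(scale: dict[str, float], name: str, sigma: float | None = None) -> SubstitutionModel:
    """Gaussian similarity over a scalar residue property scale.

    ``sigma`` defaults to the standard deviation of the scale over the 20
    amino acids, which places typical property differences about one
    bandwidth apart.
    """
    values = np.array([scale[a] for a in AMINO_ACIDS], dtype=float)
    if sigma is None:
        sigma = float(values.std())
    if sigma <= 0:
        raise ValueError("property scale is constant; no similarity can be derived")
    d2 = (values[:, None] - values[None, :]) ** 2
    return SubstitutionModel(name=name, matrix=np.exp(-d2 / (2.0 * sigma**2)))


def _biopython_matrix(name: str) -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    out = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return 0.5 * (out + out.T)


def _protparam_scale(key: str) -> dict[str, float]:
    from Bio.SeqUtils import ProtParamData

    scales = {"miyazawa": ProtParamData.mi, "kyte_doolittle": ProtParamData.kd}
    return dict(scales[key])


def load_substitution_models(psd_correct: bool = True) -> list[SubstitutionModel]:
    """The packaged bank of amino-acid substitution models.

    Returns seven named models: identity, exchangeability (BLOSUM62),
    interaction (Johnson-Overington, structure-derived), contact_energy
    (Miyazawa contact-energy scale), packing_volume (Zamyatnin),
    hydrophobicity (Kyte-Doolittle) and charge. Matrix-derived models are
    rescaled to [0, 1] before PSD correction.
    """
    models = [
        SubstitutionModel("identity", np.eye(20)),
        SubstitutionModel("exchangeability", _rescale_unit(_biopython_matrix("BLOSUM62"))),
        SubstitutionModel("interaction", _rescale_unit(_biopython_matrix("JOHNSON"))),
        radial_similarity(_protparam_scale("miyazawa"), "contact_energy"),
        radial_similarity(RESIDUE_VOLUME, "packing_volume"),
        radial_similarity(_protparam_scale("kyte_doolittle"), "hydrophobicity"),
        radial_similarity(RESIDUE_CHARGE, "charge"),
    ]
    if psd_correct:
        models = [SubstitutionModel(m.name, _clip_psd(m.matrix)) for m in models]
    for m in models:
        if np.any(np.diag(m.matrix) <= 0):
            raise AssertionError(f"model {m.name} lost positive self-similarity")
        if m.min_eigenvalue < -PSD_TOLERANCE:
            raise AssertionError(f"model {m.name} is not PSD after correction")
    return models
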