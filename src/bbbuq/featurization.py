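"""Molecular representations and chemical-space machinery.

Two representations feed the classifiers: ECFP4 — extended-connectivity
fingerprints of radius 2, hashed to 2048 binary bits, the community default
for nearest-neighbour Tanimoto analysis — and a physicochemical descriptor
panel (the toolkit's full 2D descriptor list, ~210 values). Tanimoto
similarity over fingerprints drives both the chemical-space overlap profile
between datasets and the fingerprint-distance applicability-domain score.

A rule-based permeability score (e.g. the published "BBB score") is exposed
as a pluggable scoring function thresholded at 4; its piecewise component
functions are supplied by the caller, not hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .exceptions import EmptyReference, LengthMismatch, MissingPka, UnparseableStructure

BBB_SCORE_THRESHOLD = 4.0

_DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in Descriptors._descList)


@dataclass
class Fingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: np.ndarray  # uint8 0/1 vector
    radius: int = 2

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]


@dataclass
class DescriptorVector:
    """Real-valued descriptor panel; non-finite entries imputed to 0."""

    values: np.ndarray
    names: tuple[str, ...]
    imputed: tuple[str, ...] = ()


@dataclass
class BBBScoreInput:
    """Descriptors consumed by rule-based permeability scores."""

    mw: float
    hba: int
    hbd: int
    tpsa: float
    n_aromatic_rings: int
    pka: float | None = None


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparseableStructure(f"cannot parse SMILES: {smiles!r}")
    return mol


def compute_ecfp4(smiles_std: str, n_bits: int = 2048) -> Fingerprint:
    """ECFP4 (Morgan radius 2) binary fingerprint. Deterministic."""
    mol = _mol_from_smiles(smiles_std)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return Fingerprint(bits=gen.GetFingerprintAsNumPy(mol), radius=2)


def fingerprint_matrix(smiles_list, n_bits: int = 2048) -> np.ndarray:
    """Stack ECFP4 fingerprints into an (n, n_bits) uint8 matrix."""
    return np.vstack([compute_ecfp4(s, n_bits).bits for s in smiles_list])


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B| on bit sets; 0 by convention when both are empty."""
    if a.n_bits != b.n_bits:
        raise LengthMismatch(f"{a.n_bits} vs {b.n_bits}")
    inter = int(np.sum((a.bits & b.bits) > 0))
    union = int(np.sum((a.bits | b.bits) > 0))
    if union == 0:
        return 0.0
    return inter / union


def _tanimoto_matrix(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities between rows of two 0/1 matrices."""
    q = query.astype(np.float64)
    r = reference.astype(np.float64)
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return sim


def max_similarity_profile(
    query: list[Fingerprint] | np.ndarray,
    reference: list[Fingerprint] | np.ndarray,
    exclude_self: bool = False,
) -> np.ndarray:
    """Per query molecule, the max Tanimoto similarity over a reference set.

    With ``exclude_self`` and query == reference this yields the internal
    nearest-neighbour profile of a dataset (self-pairs skipped by index).
    """
    qmat = query if isinstance(query, np.ndarray) else np.vstack([f.bits for f in query])
    rmat = reference if isinstance(reference, np.ndarray) else np.vstack([f.bits for f in reference])
    if rmat.shape[0] == 0 or (exclude_self and rmat.shape[0] < 2):
        raise EmptyReference("reference set too small")
    if qmat.shape[1] != rmat.shape[1]:
        raise LengthMismatch(f"{qmat.shape[1]} vs {rmat.shape[1]}")
    sim = _tanimoto_matrix(qmat, rmat)
    if exclude_self:
        if qmat.shape[0] != rmat.shape[0]:
            raise LengthMismatch("exclude_self requires query == reference")
        np.fill_diagonal(sim, -1.0)
    return sim.max(axis=1)


def compute_pcp_descriptors(smiles_std: str) -> DescriptorVector:
    """Full 2D physicochemical descriptor panel of the toolkit.

    Descriptors that fail or return non-finite values on edge-case molecules
    are imputed to 0 and flagged by name. Pure function of the SMILES.
    """
    mol = _mol_from_smiles(smiles_std)
    raw = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
    values = np.array([raw[name] for name in _DESCRIPTOR_NAMES], dtype=np.float64)
    bad = ~np.isfinite(values)
    imputed = tuple(n for n, b in zip(_DESCRIPTOR_NAMES, bad) if b)
    values[bad] = 0.0
    return DescriptorVector(values=values, names=_DESCRIPTOR_NAMES, imputed=imputed)


def descriptor_matrix(smiles_list) -> np.ndarray:
    """Stack descriptor panels into an (n, d) float matrix."""
    return np.vstack([compute_pcp_descriptors(s).values for s in smiles_list])


def descriptor_names() -> tuple[str, ...]:
    return _DESCRIPTOR_NAMES


def compute_bbb_score_input(smiles_std: str, pka: float | None = None) -> BBBScoreInput:
    """Collect the descriptors rule-based permeability scores consume.

    pKa is accepted as a user-supplied value (its computation requires
    external tooling); all other descriptors come from the 2D structure.
    """
    mol = _mol_from_smiles(smiles_std)
    return BBBScoreInput(
        mw=Descriptors.MolWt(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        n_aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        pka=pka,
    )


def bbb_score_classify(x: BBBScoreInput, score_fn) -> tuple[float, str]:
    """Apply a pluggable additive permeability score; positive iff score >= 4.

    ``score_fn`` maps a :class:`BBBScoreInput` to a real score. It may raise
    :class:`MissingPka` if it needs a pKa that was not supplied.
    """
    score = float(score_fn(x))
    label = "positive" if score >= BBB_SCORE_THRESHOLD else "negative"
    return score, label


def require_pka(x: BBBScoreInput) -> float:
    """Helper for score functions that cannot run without a pKa."""
    if x.pka is None:
        raise MissingPka("score function requires a pKa value")
    return x.pka
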