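"""Synthetic chemistry fixtures: libraries, noisy labels, corrupted tables.

The generator emulates the shape of the public permeability benchmarks
without their pharmacology:

* a combinatorial library of drug-like aromatic scaffolds decorated with
  common substituents, pre-standardized by construction;
* binary labels from a smooth descriptor rule — low TPSA and low molecular
  weight favour permeability, as for real CNS drugs — thresholded at the
  quantile that reproduces the ~3:1 BBB+:BBB− imbalance of the public
  benchmark (positive fraction 0.76), then flipped with Bernoulli noise
  whose probability is concentrated near the rule boundary. Labels thus
  behave like a logistic function of the descriptors and a trained model's
  errors cluster at the boundary, so uncertainty-vs-error correlation
  exists by construction;
* a corruption pass that injects exactly the defect classes curation must
  repair: salt/solvent companions, invalid SMILES, exact duplicates and
  stereo-variant duplicates, with a truth map for closure testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors, Descriptors
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .curation import POSITIVE, NEGATIVE, MoleculeRecord, RawEntry, standardize_structure
from .exceptions import ExhaustedCombinations, UnattainableImbalance

#: two-site aromatic scaffold templates ({A}/{B} attach to aromatic carbons)
DEFAULT_SCAFFOLDS = (
    "c1cc({A})ccc1{B}",
    "c1cc({A})cc({B})c1",
    "c1cc({A})cnc1{B}",
    "c1cc({A})c2cc({B})ccc2c1",
    "c1cc({A})sc1{B}",
    "c1cc({A})oc1{B}",
    "c1cc({A})ccc1-c1ccc({B})cc1",
    "c1cc({A})ccc1Cc1ccc({B})cc1",
    "c1cc({A})ccc1C(=O)Nc1ccc({B})cc1",
    "c1cc({A})ccc1S(=O)(=O)Nc1ccc({B})cc1",
)

#: substituents valid when attached to an aromatic carbon
DEFAULT_SUBSTITUENTS = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC",
    "N", "NC", "N(C)C", "C#N", "C(F)(F)F", "[N+](=O)[O-]", "C(=O)O",
    "C(=O)OC", "C(=O)N", "C(=O)NC", "S(=O)(=O)N", "CO", "C(C)O", "SC", "C=C",
)


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic benchmark."""

    n_molecules: int = 2000
    scaffolds: tuple = DEFAULT_SCAFFOLDS
    substituents: tuple = DEFAULT_SUBSTITUENTS
    label_noise: float = 0.1
    imbalance_target: float = 0.76  # BBB+ fraction of the public benchmark
    seed: int = 0
    # corruption rates (fractions of the clean set)
    salt_rate: float = 0.1
    invalid_rate: float = 0.05
    duplicate_rate: float = 0.05
    stereo_rate: float = 0.05
    conflict_rate: float = 0.0


def generate_library(cfg: FixtureConfig) -> list[str]:
    """Enumerate n distinct, parseable, pre-standardized SMILES.

    Scaffold × substituent × substituent combinations are standardized and
    deduplicated, then deterministically shuffled by the seed and truncated.
    """
    seen: dict[str, None] = {}
    for scaffold, a, b in itertools.product(cfg.scaffolds, cfg.substituents, cfg.substituents):
        smi = scaffold.replace("{A}", a).replace("{B}", b)
        if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - templates are valid
            continue
        std = standardize_structure(smi)
        seen.setdefault(std, None)
    pool = list(seen)
    if cfg.n_molecules > len(pool):
        raise ExhaustedCombinations(f"need {cfg.n_molecules}, space has {len(pool)}")
    rng = np.random.default_rng(cfg.seed)
    rng.shuffle(pool)
    return pool[: cfg.n_molecules]


def _rule_score(smiles: str) -> float:
    """Smooth permeability-likeness score: high for small, apolar molecules."""
    mol = Chem.MolFromSmiles(smiles)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    mw = Descriptors.MolWt(mol)
    return -(tpsa / 90.0 + mw / 400.0)


#: width (in SD units of the rule score) of the boundary-noise kernel
NOISE_KERNEL_WIDTH = 0.5


def assign_synthetic_labels(smiles: list[str], cfg: FixtureConfig):
    """Rule-based labels with boundary-concentrated Bernoulli flips.

    The rule score is thresholded at the quantile that yields the target
    positive fraction. Each label is then flipped with probability
    proportional to a Gaussian kernel of the molecule's margin (distance of
    its rule score from the threshold, in SD units), normalized so the
    *marginal* flip rate equals ``label_noise``. Flips therefore concentrate
    near the rule boundary — labels behave like a logistic function of the
    descriptors — so a trained model's errors are uncertainty-correlated by
    construction; flips are roughly symmetric about the threshold, leaving
    the positive fraction at the target. Returns (labels, truth) where truth
    records the noiseless rule and flip mask for tests.
    """
    if not 0.0 <= cfg.label_noise < 0.5:
        raise UnattainableImbalance("label_noise must be in [0, 0.5)")
    if not 0.0 < cfg.imbalance_target < 1.0:
        raise UnattainableImbalance(f"target {cfg.imbalance_target} not in (0, 1)")
    scores = np.array([_rule_score(s) for s in smiles])
    threshold = float(np.quantile(scores, 1.0 - cfg.imbalance_target))
    rule_labels = scores >= threshold
    margin = (scores - threshold) / max(float(scores.std()), 1e-12)
    kernel = np.exp(-((margin / NOISE_KERNEL_WIDTH) ** 2))
    if cfg.label_noise > 0.0:
        c = cfg.label_noise / kernel.mean()
        p_flip = np.minimum(c * kernel, 0.5)
        if p_flip.mean() < cfg.label_noise - 1e-9:  # capping starved the rate
            raise UnattainableImbalance(
                f"label_noise {cfg.label_noise} unreachable with boundary kernel"
            )
    else:
        p_flip = np.zeros_like(kernel)
    rng = np.random.default_rng(cfg.seed + 1)
    flips = rng.random(len(smiles)) < p_flip
    labels = rule_labels ^ flips
    truth = {
        "rule": "tpsa_mw_linear",
        "description": "positive iff -(TPSA/90 + MW/400) >= threshold",
        "threshold": threshold,
        "scores": scores,
        "rule_labels": rule_labels.astype(int),
        "flip_probability": p_flip,
        "flip_mask": flips,
    }
    return labels.astype(int), truth


def make_benchmark_records(cfg: FixtureConfig) -> tuple[list[MoleculeRecord], dict]:
    """Clean, labeled fixture dataset as curated records."""
    smiles = generate_library(cfg)
    labels, truth = assign_synthetic_labels(smiles, cfg)
    records = [
        MoleculeRecord(
            identifier=f"syn{i:05d}",
            smiles_raw=s,
            smiles_std=s,
            label=POSITIVE if y else NEGATIVE,
            label_source="annotated",
        )
        for i, (s, y) in enumerate(zip(smiles, labels))
    ]
    return records, truth


_SALT_COMPANIONS = ("Cl", "O", "[Na+].[Cl-]", "OC(=O)C(=O)O", "O.O")


def _stereo_variant(smiles: str) -> str | None:
    """A stereo-annotated SMILES of the same constitution, if any centre exists."""
    mol = Chem.MolFromSmiles(smiles)
    opts = StereoEnumerationOptions(maxIsomers=2, onlyUnassigned=True)
    for iso in EnumerateStereoisomers(mol, opts):
        iso_smi = Chem.MolToSmiles(iso)
        if iso_smi != Chem.MolToSmiles(mol):
            return iso_smi
    return None


def corrupt_records(records: list[MoleculeRecord], cfg: FixtureConfig):
    """Inject curation defects into a clean record set.

    Returns (raw_entries, truth) where truth holds the clean canonical-key
    set and the exact injected counts so tests can assert the curation
    report recovers them. Labels travel as annotated BBB+/BBB− strings.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(records)
    entries: list[RawEntry] = []
    n_mixtures = 0
    salt_mask = rng.random(n) < cfg.salt_rate
    for rec, salted in zip(records, salt_mask):
        smi = rec.smiles_raw
        if salted:
            smi = smi + "." + _SALT_COMPANIONS[int(rng.integers(len(_SALT_COMPANIONS)))]
            n_mixtures += 1
        entries.append(
            RawEntry(
                identifier=rec.identifier,
                smiles=smi,
                label_raw="BBB+" if rec.label == POSITIVE else "BBB-",
            )
        )

    # invalid SMILES entries
    n_invalid = int(round(cfg.invalid_rate * n))
    garbage = ("C1CC", "notasmiles", "C(", "Xx12", "c1ccccc")
    for j in range(n_invalid):
        entries.append(
            RawEntry(
                identifier=f"bad{j:04d}",
                smiles=garbage[j % len(garbage)],
                label_raw="BBB+",
            )
        )

    # exact duplicates
    n_dup = int(round(cfg.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    for j, i in enumerate(dup_idx):
        entries.append(
            RawEntry(
                identifier=f"dup{j:04d}",
                smiles=records[i].smiles_raw,
                label_raw="BBB+" if records[i].label == POSITIVE else "BBB-",
            )
        )

    # stereo-variant duplicates (fall back to exact copies when achiral)
    n_stereo_req = int(round(cfg.stereo_rate * n))
    n_stereo = 0
    order = rng.permutation(n)
    for i in order:
        if n_stereo >= n_stereo_req:
            break
        variant = _stereo_variant(records[i].smiles_raw) or records[i].smiles_raw
        entries.append(
            RawEntry(
                identifier=f"ste{n_stereo:04d}",
                smiles=variant,
                label_raw="BBB+" if records[i].label == POSITIVE else "BBB-",
            )
        )
        n_stereo += 1

    # label conflicts: duplicate with the opposite label (off by default)
    n_conflict = int(round(cfg.conflict_rate * n))
    conflict_idx = rng.choice(n, size=n_conflict, replace=False) if n_conflict else []
    conflict_keys = set()
    for j, i in enumerate(conflict_idx):
        conflict_keys.add(records[i].smiles_std)
        entries.append(
            RawEntry(
                identifier=f"cfl{j:04d}",
                smiles=records[i].smiles_raw,
                label_raw="BBB-" if records[i].label == POSITIVE else "BBB+",
            )
        )

    truth = {
        "clean_keys": {r.smiles_std for r in records},
        "n_clean": n,
        "n_mixtures": n_mixtures,
        "n_invalid": n_invalid,
        "n_duplicates": n_dup + n_stereo,
        "n_conflict_groups": len(conflict_keys),
        "conflict_keys": conflict_keys,
    }
    return entries, truth
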