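"""Self-contained synthetic datasets with the statistical structure the
framework assumes.

Molecules are assembled from a small grammar of valence-valid fragments
(acyclic and ring pieces over C/N/O/F/S/Cl), joined by single bonds at
atoms with free valence.  A linear "true" HFE is defined on descriptor
counts; the synthetic physics model predicts truth plus a structured,
feature-expressible residual; "experimental" labels add Gaussian noise
with a per-record uncertainty tag (a default sigma for most records and
an inflated tail for a minority).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from rdkit import Chem

from .dataset_io import MoleculeRecord
from .gb_physics import GBSystem, INTRINSIC_RADII

#: (SMILES, weight) fragment grammar; all fragments are valence-valid and
#: joinable through any atom with free valence.
DEFAULT_GRAMMAR = (
    ("C", 6.0), ("CC", 4.0), ("CCC", 2.0), ("C(C)C", 1.0),
    ("O", 3.0), ("CO", 2.0), ("C=O", 1.5), ("C(=O)O", 1.0),
    ("N", 2.0), ("CN", 1.5), ("C#N", 0.5),
    ("F", 1.0), ("Cl", 1.0), ("S", 0.8),
    ("c1ccccc1", 2.0), ("c1ccncc1", 0.8), ("c1ccoc1", 0.5), ("c1ccsc1", 0.4),
    ("C1CCCCC1", 0.8), ("C1CCOC1", 0.4),
)

#: truth coefficients, kcal/mol per descriptor
DEFAULT_TRUTH = {
    "intercept": 1.5,
    "heavy": -0.18,
    "O": -1.5,
    "N": -1.2,
    "aromatic_rings": -1.0,
}


@dataclass
class SyntheticSpec:
    n_molecules: int = 100
    seed: int = 0
    grammar: tuple = DEFAULT_GRAMMAR
    truth_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    residual_amplitude: float = 1.5  # kcal/mol
    noise_sigma: float = 0.3  # kcal/mol
    high_uncertainty_fraction: float = 0.10
    high_uncertainty_factor: float = 3.0
    min_heavy: int = 2
    max_heavy: int = 24

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not self.grammar:
            raise ValueError("empty fragment grammar")
        for smi, w in self.grammar:
            if Chem.MolFromSmiles(smi) is None or w <= 0:
                raise ValueError(f"invalid grammar entry ({smi!r}, {w})")


def _attachable_atoms(mol: Chem.Mol) -> list:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetTotalNumHs() > 0 and a.GetSymbol() not in ("F", "Cl", "Br", "I")]


def _join(mol_a: Chem.Mol, mol_b: Chem.Mol, rng: np.random.Generator) -> Optional[Chem.Mol]:
    """Bond a random attachable atom of A to one of B with a single bond."""
    sites_a = _attachable_atoms(mol_a)
    sites_b = _attachable_atoms(mol_b)
    if not sites_a or not sites_b:
        return None
    ia = int(rng.choice(sites_a))
    ib = int(rng.choice(sites_b))
    combo = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    combo.AddBond(ia, mol_a.GetNumAtoms() + ib, Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def _sample_molecule(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    frags = [Chem.MolFromSmiles(s) for s, _ in spec.grammar]
    weights = np.array([w for _, w in spec.grammar], dtype=float)
    weights /= weights.sum()
    # skew the size distribution toward small molecules (database-like)
    target = int(np.clip(round(rng.triangular(spec.min_heavy, spec.min_heavy + 2,
                                              spec.max_heavy + 1)), spec.min_heavy,
                         spec.max_heavy))
    for _ in range(50):  # retry loop: some join attempts fail
        mol = Chem.Mol(frags[int(rng.choice(len(frags), p=weights))])
        stalled = 0
        while mol.GetNumHeavyAtoms() < target and stalled < 10:
            frag = frags[int(rng.choice(len(frags), p=weights))]
            if mol.GetNumHeavyAtoms() + frag.GetNumHeavyAtoms() > spec.max_heavy:
                stalled += 1
                continue
            joined = _join(mol, frag, rng)
            if joined is None:
                stalled += 1
                continue
            mol = joined
        if mol.GetNumHeavyAtoms() >= spec.min_heavy:
            return Chem.MolToSmiles(mol)
    raise RuntimeError("fragment grammar failed to produce a molecule")


def descriptor_counts(smiles: str) -> dict:
    mol = Chem.MolFromSmiles(smiles)
    return {
        "heavy": mol.GetNumHeavyAtoms(),
        "O": sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "O"),
        "N": sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N"),
        "aromatic_atoms": sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        "aromatic_rings": sum(
            1 for ring in mol.GetRingInfo().AtomRings()
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
        ),
    }


def true_hfe(smiles: str, coefficients: dict) -> float:
    counts = descriptor_counts(smiles)
    value = coefficients.get("intercept", 0.0)
    for name, coef in coefficients.items():
        if name != "intercept":
            value += coef * counts.get(name, 0)
    return value


def structured_residual(smiles: str, amplitude: float) -> float:
    """Physics-model error as a function of descriptors the networks can
    see (oxygen count, aromatic-atom count, heavy-atom count).  Scaled so
    its root-mean-square over typical grammar samples is about `amplitude`."""
    c = descriptor_counts(smiles)
    raw = 0.55 * c["O"] + 0.18 * c["aromatic_atoms"] - 0.12 * c["heavy"] + 0.35
    return amplitude * raw


def generate_synthetic_dataset(spec: SyntheticSpec) -> Tuple[list, dict]:
    """Returns (records, truth map).  Deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    records, truth = [], {}
    n_tail = int(round(spec.high_uncertainty_fraction * spec.n_molecules))
    tail = set(rng.choice(spec.n_molecules, size=n_tail, replace=False).tolist())
    for k in range(spec.n_molecules):
        smiles = _sample_molecule(spec, rng)
        mid = f"syn-{k:05d}"
        t = true_hfe(smiles, spec.truth_coefficients)
        resid = structured_residual(smiles, spec.residual_amplitude)
        sigma = spec.noise_sigma * (spec.high_uncertainty_factor if k in tail else 1.0)
        expt = t + rng.normal(0.0, sigma) if sigma > 0 else t
        rec = MoleculeRecord(
            id=mid, smiles=smiles, name=f"synthetic-{k}",
            expt_hfe=float(expt), expt_uncertainty=float(sigma),
            calc_hfe=float(t + resid),
            physics_pred={"synthetic": float(t + resid)},
        )
        records.append(rec)
        truth[mid] = float(t)
    return records, truth


def make_toy_gb_system(kind: str, **params) -> GBSystem:
    """Small exact geometries for physics oracle tests."""
    if kind == "single_ion":
        q = params.get("q", 1.0)
        R = params.get("R", 2.0)
        return GBSystem(coords=[[0.0, 0.0, 0.0]], charges=[q], intrinsic_radii=[R])
    if kind == "diatomic":
        d = params.get("d", 3.0)
        q = params.get("q", 0.5)
        R = params.get("R", 1.5)
        return GBSystem(
            coords=[[-d / 2, 0.0, 0.0], [d / 2, 0.0, 0.0]],
            charges=[q, -q], intrinsic_radii=[R, R],
        )
    if kind == "linear_chain":
        n = params.get("n", 3)
        d = params.get("d", 1.5)
        R = params.get("R", 1.5)
        q = params.get("q", 0.3)
        return GBSystem(
            coords=[[i * d, 0.0, 0.0] for i in range(n)],
            charges=[q * (-1) ** i for i in range(n)],
            intrinsic_radii=[R] * n,
        )
    raise ValueError(f"unknown toy system kind {kind!r}")


def default_benchmark(seed: int = 7, n_train: int = 400, n_val: int = 80,
                      n_test: int = 80, residual_amplitude: float = 1.5,
                      noise_sigma: float = 0.3) -> Tuple[list, dict]:
    """The standard synthetic benchmark: 400/80/80 with a learnable
    residual of ~1.5 kcal/mol amplitude and 0.3 kcal/mol label noise."""
    spec = SyntheticSpec(
        n_molecules=n_train + n_val + n_test,
        seed=seed,
        residual_amplitude=residual_amplitude,
        noise_sigma=noise_sigma,
        high_uncertainty_fraction=0.0,
    )
    return generate_synthetic_dataset(spec)
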