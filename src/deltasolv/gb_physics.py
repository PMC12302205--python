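"""Generalized Born polar solvation energy and the derived atom features.

The polar solvation free energy is computed as a double sum over atom
pairs of ``q_i q_j (1/f_ij + alpha*beta/A)`` with the usual prefactor
``-(1/2) (1/eps_in - 1/eps_out) / (1 + beta*alpha)``, where ``beta =
eps_in/eps_out`` and ``A`` is the electrostatic size of the solute.  The
pair function f uses the canonical exponential form

    f(r, Ri, Rj) = sqrt(r^2 + Ri*Rj * exp(-r^2 / (4*Ri*Rj)))

Effective Born radii come from pairwise descreening: the inverse intrinsic
radius minus, for each neighbor, the exact analytic integral of 1/r^4 over
the part of the neighbor sphere outside the atom's own sphere, clamped so
R_i never drops below the intrinsic radius.

The per-atom diagonal self-energies and inverse Born radii double as the
physics-based node features; inverse interatomic distances are the
physics-based edge feature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .dataset_io import MoleculeRecord, ValidationError

#: kcal*Angstrom/(mol*e^2)
COULOMB_K = 332.06
#: dimensionless constant multiplying beta/A in the pair term
DEFAULT_ALPHA = 0.571412

#: Bondi-style intrinsic radii (Angstrom) per heavy element.
INTRINSIC_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}


@dataclass
class GBParameters:
    eps_in: float = 1.0
    eps_out: float = 78.5
    alpha: float = DEFAULT_ALPHA
    coulomb_k: float = COULOMB_K

    def __post_init__(self):
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def beta(self) -> float:
        return self.eps_in / self.eps_out


@dataclass
class GBSystem:
    coords: np.ndarray  # (n, 3) Angstrom
    charges: np.ndarray  # (n,) elementary charges
    intrinsic_radii: np.ndarray  # (n,) Angstrom
    born_radii: Optional[np.ndarray] = None  # (n,) Angstrom
    electrostatic_size: Optional[float] = None  # Angstrom

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.intrinsic_radii = np.asarray(self.intrinsic_radii, dtype=float)
        if np.any(self.intrinsic_radii <= 0):
            raise ValueError("intrinsic radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    def populate(self) -> "GBSystem":
        """Fill in Born radii and electrostatic size if absent."""
        if self.born_radii is None:
            self.born_radii = effective_born_radii(self)
        if self.electrostatic_size is None:
            self.electrostatic_size = electrostatic_size(self)
        return self


@dataclass
class GBEnergy:
    total: float  # kcal/mol
    pair_terms: np.ndarray  # (n, n) symmetric, kcal/mol; diagonal = self terms

    @property
    def self_energies(self) -> np.ndarray:
        return np.diag(self.pair_terms)


# -- partial charges -----------------------------------------------------------

def assign_partial_charges(record: MoleculeRecord, method: str = "gasteiger") -> np.ndarray:
    """Per-heavy-atom partial charges with hydrogen charges condensed in.

    ``gasteiger`` runs an electronegativity-equalization scheme on the
    molecule with explicit hydrogens, then folds each hydrogen's charge
    into its bonded heavy atom.  ``from_structure`` takes the record's own
    charge list verbatim.  Heavy-atom order follows the record's canonical
    atom ranking.
    """
    from .featurization import heavy_atom_order

    if method == "from_structure":
        if record.charges is None:
            raise ValidationError(f"record {record.id!r}: no charges in structure data")
        return np.asarray(record.charges, dtype=float)
    if method != "gasteiger":
        raise ValueError(f"unknown charge method {method!r}")

    mol = record.mol()
    molH = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(molH)
    raw = np.array([float(a.GetProp("_GasteigerCharge")) for a in molH.GetAtoms()])
    raw = np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0)
    condensed = np.zeros(mol.GetNumAtoms())
    for atom in molH.GetAtoms():
        idx = atom.GetIdx()
        if atom.GetAtomicNum() == 1:
            heavy = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() != 1]
            if heavy:
                condensed[heavy[0]] += raw[idx]
        else:
            condensed[idx] += raw[idx]
    # renormalize any residual drift onto all atoms so the total is exact
    formal = float(Chem.GetFormalCharge(mol))
    drift = condensed.sum() - formal
    condensed -= drift / len(condensed)
    order = heavy_atom_order(mol)
    return condensed[order]


# -- effective Born radii ------------------------------------------------------

def _descreen_integral(d: np.ndarray, rho_i: np.ndarray, s: np.ndarray) -> np.ndarray:
    """(1/4pi) * integral of |x - x_i|^-4 over the part of a sphere of
    radius `s` centered at distance `d` that lies outside the sphere of
    radius `rho_i` around atom i.  Exact closed form.
    """
    U = d + s
    L = np.maximum(np.abs(d - s), rho_i)
    out = np.zeros_like(d)
    mask = U > L
    if np.any(mask):
        dm, sm, Lm, Um = d[mask], s[mask], L[mask], U[mask]
        term = (
            (1.0 / Lm - 1.0 / Um)
            + ((dm * dm - sm * sm) / (4.0 * dm)) * (1.0 / (Um * Um) - 1.0 / (Lm * Lm))
            + (1.0 / (2.0 * dm)) * np.log(Lm / Um)
        )
        out[mask] = 0.5 * term
    return out


def effective_born_radii(system: GBSystem) -> np.ndarray:
    """Pairwise-descreening estimate of the effective Born radii."""
    xyz = system.coords
    rho = system.intrinsic_radii
    n = system.n_atoms
    if n == 1:
        return rho.copy()
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0.0):
        raise ValueError("two distinct atoms share identical coordinates")
    inv_R = 1.0 / rho.copy()
    for i in range(n):
        others = np.arange(n) != i
        contrib = _descreen_integral(
            dist[i, others], np.full(others.sum(), rho[i]), rho[others]
        )
        inv_R[i] -= contrib.sum()
    R = np.where(inv_R > 0, 1.0 / np.maximum(inv_R, 1e-12), np.inf)
    return np.maximum(R, rho)


# -- electrostatic size --------------------------------------------------------

def electrostatic_size(system: GBSystem) -> float:
    """Electrostatic size A: the capacitance of the union-of-spheres
    conductor, estimated from the inverse of the potential-coefficient
    matrix (P_ii = 1/rho_i, P_ij = 1/d_ij).

    Exact for a single sphere (A = rho); rotation/translation invariant;
    strictly increasing under uniform scaling of the coordinates.
    """
    n = system.n_atoms
    if n == 0:
        raise ValueError("empty system")
    rho = system.intrinsic_radii
    if n == 1:
        return float(rho[0])
    xyz = system.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    off = 1.0 / np.maximum(dist, 1e-12)
    # for overlapping spheres, cap the mutual coefficient just below the
    # geometric mean of the self terms so P stays positive definite
    limit = 0.999 / np.sqrt(np.outer(rho, rho))
    off = np.minimum(off, limit)
    P = np.where(np.eye(n, dtype=bool), 1.0 / rho, off)
    cap_matrix = np.linalg.pinv(P)
    A = float(cap_matrix.sum())
    return max(A, float(rho.max()))


# -- pair function and energy --------------------------------------------------

def gb_pair_function(r, R_i, R_j):
    """Canonical exponential pair function, symmetric in (R_i, R_j)."""
    r = np.asarray(r, dtype=float)
    R_i = np.asarray(R_i, dtype=float)
    R_j = np.asarray(R_j, dtype=float)
    if np.any(r < 0) or np.any(R_i <= 0) or np.any(R_j <= 0):
        raise ValueError("require r >= 0 and positive Born radii")
    prod = R_i * R_j
    return np.sqrt(r * r + prod * np.exp(-(r * r) / (4.0 * prod)))


def gb_polar_energy(system: GBSystem, params: Optional[GBParameters] = None) -> GBEnergy:
    """Polar solvation energy with full symmetric pair decomposition."""
    params = params or GBParameters()
    if system.born_radii is None:
        raise ValueError("system.born_radii not set; call system.populate()")
    A = system.electrostatic_size
    if A is None:
        raise ValueError("system.electrostatic_size not set; call system.populate()")
    q = system.charges
    R = system.born_radii
    xyz = system.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    f = gb_pair_function(dist, R[:, None], R[None, :])
    beta = params.beta
    alpha = params.alpha
    pref = -0.5 * params.coulomb_k * (1.0 / params.eps_in - 1.0 / params.eps_out)
    pref /= 1.0 + beta * alpha
    pair = pref * np.outer(q, q) * (1.0 / f + alpha * beta / A)
    return GBEnergy(total=float(pair.sum()), pair_terms=pair)


# -- molecule-level feature pipeline -------------------------------------------

def embed_coordinates(record: MoleculeRecord, seed: Optional[int] = None) -> np.ndarray:
    """Heavy-atom 3D coordinates: the record's structure if present,
    otherwise a deterministic ETKDG conformer (seed derived from the id)."""
    from .featurization import heavy_atom_order

    mol = record.mol()
    order = heavy_atom_order(mol)
    if record.coords is not None:
        heavy = [(x, y, z) for el, x, y, z in record.coords if el != "H"]
        return np.array(heavy, dtype=float)
    if seed is None:
        seed = (hash(record.id) % (2**31 - 1)) or 1
    molH = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(molH, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molH, params) != 0:
            raise ValidationError(f"record {record.id!r}: 3D embedding failed")
    conf = molH.GetConformer()
    xyz = np.array(
        [
            [conf.GetAtomPosition(a.GetIdx()).x,
             conf.GetAtomPosition(a.GetIdx()).y,
             conf.GetAtomPosition(a.GetIdx()).z]
            for a in molH.GetAtoms()
            if a.GetAtomicNum() != 1
        ]
    )
    return xyz[order]


@dataclass
class AtomFeatureTable:
    """Per-atom physics features in canonical heavy-atom order."""

    mol_id: str
    charges: np.ndarray
    born_radii: np.ndarray
    inv_born_radii: np.ndarray
    self_energies: np.ndarray
    coords: np.ndarray


def compute_gb_features(
    record: MoleculeRecord,
    params: Optional[GBParameters] = None,
    charge_method: str = "gasteiger",
) -> AtomFeatureTable:
    """Charges, Born radii, and GB self-energies for one molecule."""
    from .featurization import heavy_atom_order

    mol = record.mol()
    order = heavy_atom_order(mol)
    symbols = [mol.GetAtomWithIdx(int(i)).GetSymbol() for i in order]
    rho = np.array([INTRINSIC_RADII[s] for s in symbols])
    xyz = embed_coordinates(record)
    charges = assign_partial_charges(record, method=charge_method)
    system = GBSystem(coords=xyz, charges=charges, intrinsic_radii=rho).populate()
    energy = gb_polar_energy(system, params)
    return AtomFeatureTable(
        mol_id=record.id,
        charges=charges,
        born_radii=system.born_radii,
        inv_born_radii=1.0 / system.born_radii,
        self_energies=energy.self_energies,
        coords=xyz,
    )


def write_feature_csv(tables: Sequence[AtomFeatureTable], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "atom_index", "charge_e", "born_radius_A",
                         "inv_born_radius_invA", "self_energy_kcal_mol"])
        for t in tables:
            for k in range(len(t.charges)):
                writer.writerow([t.mol_id, k, t.charges[k], t.born_radii[k],
                                 t.inv_born_radii[k], t.self_energies[k]])
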