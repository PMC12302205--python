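"""Heavy-atom molecular graphs with chemistry- and physics-based features.

Node feature layout (chem block, 24 entries): element identity one-hot
(9), heavy-atom degree one-hot (6, degrees 0-5), attached-hydrogen count
one-hot (5, 0-4), hybridization one-hot (3: sp, sp2, sp3; all-zero for
other states), aromaticity bit (1).  Physics block (2 entries): partial
charge and inverse effective Born radius, both min-max normalized.

Edge feature layout: bond-type one-hot (4: single, double, triple,
aromatic), plus normalized inverse distance when physics features are on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .dataset_io import ELEMENTS, MoleculeRecord, ValidationError

CHEM_NODE_DIM = 24
PHYS_NODE_DIM = 2
BOND_TYPES = ("single", "double", "triple", "aromatic")

_HYBRIDIZATIONS = {
    Chem.HybridizationType.SP: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP3: 2,
}
_BOND_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def heavy_atom_order(mol: Chem.Mol) -> list:
    """Deterministic node ordering: canonical atom ranking of the molecule."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])
    return order


@dataclass
class FeatureConfig:
    feature_set: str = "chem"  # chem | phys | all
    include_edge_features: bool = True

    def __post_init__(self):
        if self.feature_set not in ("chem", "phys", "all"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")

    @property
    def node_dim(self) -> int:
        return {"chem": CHEM_NODE_DIM, "phys": PHYS_NODE_DIM,
                "all": CHEM_NODE_DIM + PHYS_NODE_DIM}[self.feature_set]

    @property
    def edge_dim(self) -> int:
        if not self.include_edge_features:
            return 0
        return 4 if self.feature_set == "chem" else 5

    @property
    def needs_physics(self) -> bool:
        return self.feature_set in ("phys", "all")


class Normalizer:
    """Per-feature (min, max) bounds fitted on a training partition.

    Transform maps the training range onto [0, 1]; out-of-range values at
    inference are clamped.  A degenerate (constant) feature maps to 0.
    """

    def __init__(self):
        self.bounds: dict = {}

    @property
    def fitted(self) -> bool:
        return bool(self.bounds)

    def fit(self, named_values: dict) -> "Normalizer":
        for name, values in named_values.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                raise ValueError(f"no values to fit for feature {name!r}")
            self.bounds[name] = (float(values.min()), float(values.max()))
        return self

    def transform(self, name: str, value):
        if name not in self.bounds:
            raise ValueError(f"normalizer not fitted for feature {name!r}")
        lo, hi = self.bounds[name]
        if hi <= lo:
            return np.zeros_like(np.asarray(value, dtype=float))
        return np.clip((np.asarray(value, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def fit_normalizer(feature_values: dict) -> Normalizer:
    """Fit bounds from a mapping of feature name -> list of raw values."""
    return Normalizer().fit(feature_values)


@dataclass
class MolecularGraph:
    mol_id: str
    n_nodes: int
    node_features: np.ndarray  # (n_nodes, d)
    edges: np.ndarray  # (n_edges, 2), each undirected bond stored once
    edge_features: np.ndarray  # (n_edges, edge_dim)
    y: Optional[float] = None  # experimental HFE, kcal/mol
    y_phys: Optional[float] = None  # physics prediction, kcal/mol
    meta: dict = field(default_factory=dict)

    @property
    def node_dim(self) -> int:
        return self.node_features.shape[1]

    def directed_edges(self) -> np.ndarray:
        """Both directions of every bond, for message passing."""
        if len(self.edges) == 0:
            return np.zeros((0, 2), dtype=int)
        return np.vstack([self.edges, self.edges[:, ::-1]])


def chem_node_vector(element: str, degree: int, n_hydrogens: int,
                     hybridization: str, aromatic: bool) -> np.ndarray:
    """24-entry chemistry node block (one-hot blocks in layout order)."""
    if element not in ELEMENTS:
        raise ValidationError(f"element {element!r} outside vocabulary")
    if not 0 <= degree <= 5:
        raise ValidationError(f"degree {degree} out of range 0-5")
    if not 0 <= n_hydrogens <= 4:
        raise ValidationError(f"attached-H count {n_hydrogens} out of range 0-4")
    v = np.zeros(CHEM_NODE_DIM)
    v[ELEMENTS.index(element)] = 1.0
    v[9 + degree] = 1.0
    v[15 + n_hydrogens] = 1.0
    hyb_index = {"sp": 0, "sp2": 1, "sp3": 2}.get(hybridization)
    if hyb_index is not None:
        v[20 + hyb_index] = 1.0
    v[23] = 1.0 if aromatic else 0.0
    return v


def phys_node_vector(charge: float, inv_born_radius: float,
                     normalizer: Normalizer) -> np.ndarray:
    if not normalizer.fitted:
        raise ValueError("normalizer is not fitted")
    return np.array([
        float(normalizer.transform("charge", charge)),
        float(normalizer.transform("inv_born_radius", inv_born_radius)),
    ])


def edge_vector(bond_type: str, distance: Optional[float],
                config: FeatureConfig, normalizer: Optional[Normalizer] = None) -> np.ndarray:
    if bond_type not in BOND_TYPES:
        raise ValidationError(f"unknown bond type {bond_type!r}")
    onehot = np.zeros(4)
    onehot[BOND_TYPES.index(bond_type)] = 1.0
    if config.feature_set == "chem" or not config.include_edge_features:
        return onehot
    if distance is None or distance <= 0:
        raise ValidationError("positive distance required for physics edge features")
    if normalizer is None or not normalizer.fitted:
        raise ValueError("normalizer required for physics edge features")
    inv_d = float(normalizer.transform("inv_distance", 1.0 / distance))
    return np.append(onehot, inv_d)


def _atom_chem_vector(atom: Chem.Atom) -> np.ndarray:
    hyb = {0: "sp", 1: "sp2", 2: "sp3"}.get(
        _HYBRIDIZATIONS.get(atom.GetHybridization(), -1), "other"
    )
    return chem_node_vector(
        element=atom.GetSymbol(),
        degree=atom.GetDegree(),
        n_hydrogens=min(atom.GetTotalNumHs(), 4),
        hybridization=hyb,
        aromatic=atom.GetIsAromatic(),
    )


def featurize_molecule(
    record: MoleculeRecord,
    config: FeatureConfig,
    normalizer: Optional[Normalizer] = None,
    gb_features=None,
) -> MolecularGraph:
    """Build the heavy-atom graph for one record.

    `gb_features` is an AtomFeatureTable (charges, inverse Born radii,
    coordinates in canonical order); required when the config includes
    physics features.
    """
    mol = record.mol()
    order = heavy_atom_order(mol)
    pos_of = {orig: new for new, orig in enumerate(order)}
    n = mol.GetNumAtoms()

    blocks = []
    if config.feature_set in ("chem", "all"):
        chem = np.stack([_atom_chem_vector(mol.GetAtomWithIdx(int(i))) for i in order])
        blocks.append(chem)
    if config.needs_physics:
        if gb_features is None:
            raise ValueError(f"record {record.id!r}: physics features requested but gb_features missing")
        if normalizer is None or not normalizer.fitted:
            raise ValueError("fitted normalizer required for physics features")
        phys = np.stack([
            phys_node_vector(gb_features.charges[k], gb_features.inv_born_radii[k], normalizer)
            for k in range(n)
        ])
        blocks.append(phys)
    node_features = np.concatenate(blocks, axis=1)

    edges, edge_feats = [], []
    for bond in mol.GetBonds():
        i = pos_of[bond.GetBeginAtomIdx()]
        j = pos_of[bond.GetEndAtomIdx()]
        a, b = (i, j) if i < j else (j, i)
        edges.append((a, b))
        if config.include_edge_features:
            bt = BOND_TYPES[_BOND_INDEX.get(bond.GetBondType(), 0)]
            dist = None
            if config.needs_physics:
                xyz = gb_features.coords
                dist = float(np.linalg.norm(xyz[a] - xyz[b]))
            edge_feats.append(edge_vector(bt, dist, config, normalizer))
    edges = np.array(sorted(edges), dtype=int) if edges else np.zeros((0, 2), dtype=int)
    if config.include_edge_features and edge_feats:
        edge_features = np.stack([f for _, f in _sorted_edge_feats(mol, pos_of, edge_feats)])
    else:
        edge_features = np.zeros((len(edges), config.edge_dim))

    return MolecularGraph(
        mol_id=record.id,
        n_nodes=n,
        node_features=node_features,
        edges=edges,
        edge_features=edge_features,
        y=record.expt_hfe,
        meta={"feature_set": config.feature_set},
    )


def _sorted_edge_feats(mol, pos_of, edge_feats):
    keys = []
    for bond in mol.GetBonds():
        i = pos_of[bond.GetBeginAtomIdx()]
        j = pos_of[bond.GetEndAtomIdx()]
        keys.append((min(i, j), max(i, j)))
    return sorted(zip(keys, edge_feats))


def collect_numeric_features(records: Sequence[MoleculeRecord], gb_tables: dict) -> dict:
    """Raw numeric feature values over a partition, for normalizer fitting."""
    charges, inv_R, inv_d = [], [], []
    for r in records:
        t = gb_tables[r.id]
        charges.extend(t.charges.tolist())
        inv_R.extend(t.inv_born_radii.tolist())
        mol = r.mol()
        order = heavy_atom_order(mol)
        pos_of = {orig: new for new, orig in enumerate(order)}
        for bond in mol.GetBonds():
            i, j = pos_of[bond.GetBeginAtomIdx()], pos_of[bond.GetEndAtomIdx()]
            d = float(np.linalg.norm(t.coords[i] - t.coords[j]))
            inv_d.append(1.0 / d)
    return {"charge": charges, "inv_born_radius": inv_R, "inv_distance": inv_d}
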