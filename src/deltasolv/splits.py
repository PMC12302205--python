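"""Train/validation/test partitioning policies.

Three policies at a 6:1:1 ratio: stratified random sampling over HFE
quantile bins, an extreme-|HFE| held-out test set, and a scaffold-grouped
split in which every molecule sharing a Bemis-Murcko framework lands in
one partition.  All policies are deterministic given a seed, with ties
broken by ascending compound id.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .dataset_io import MoleculeRecord, ValidationError

DEFAULT_RATIOS = (6, 1, 1)
DEFAULT_N_BINS = 8

PARTITIONS = ("train", "val", "test")


@dataclass
class DataSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    policy: str
    seed: int
    metadata: dict = field(default_factory=dict)

    def partitions(self) -> dict:
        return {"train": self.train_ids, "val": self.val_ids, "test": self.test_ids}

    def all_ids(self) -> set:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "policy": self.policy,
                "seed": self.seed,
                "train": self.train_ids,
                "val": self.val_ids,
                "test": self.test_ids,
                "metadata": self.metadata,
            }
        )

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "partition"])
            for name, ids in self.partitions().items():
                for cid in ids:
                    writer.writerow([cid, name])

    def restrict(self, keep_ids) -> "DataSplit":
        """New split containing only `keep_ids` (used to filter after splitting)."""
        keep = set(keep_ids)
        return DataSplit(
            train_ids=[i for i in self.train_ids if i in keep],
            val_ids=[i for i in self.val_ids if i in keep],
            test_ids=[i for i in self.test_ids if i in keep],
            policy=self.policy,
            seed=self.seed,
            metadata={**self.metadata, "filtered": True},
        )


def _check_ratios(ratios) -> tuple:
    ratios = tuple(ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be three positive numbers, got {ratios}")
    return ratios


def _allocate(ids: list, ratios: tuple, rng: np.random.Generator) -> tuple:
    """Shuffle one bin and allocate to len(ratios) partitions: floor
    proportions, then leftovers round-robin in partition order."""
    ids = sorted(ids)  # canonical order before shuffling, for reproducibility
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    total = sum(ratios)
    counts = [int(len(ids) * r / total) for r in ratios]
    leftover = len(ids) - sum(counts)
    for k in range(leftover):
        counts[k % len(ratios)] += 1
    out, pos = [], 0
    for c in counts:
        out.append(shuffled[pos:pos + c])
        pos += c
    return tuple(out)


def _quantile_bins(values: np.ndarray, n_bins: int) -> list:
    """Indices grouped into `n_bins` near-equal quantile bins by value."""
    order = np.argsort(values, kind="stable")
    return [list(chunk) for chunk in np.array_split(order, n_bins)]


def stratified_split(
    records: Sequence[MoleculeRecord],
    ratios=DEFAULT_RATIOS,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> DataSplit:
    """Quantile-binned stratified random split on the experimental HFE."""
    ratios = _check_ratios(ratios)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(records) < 3:
        raise ValueError("need at least as many records as partitions")
    records = sorted(records, key=lambda r: r.id)
    values = np.array([r.expt_hfe for r in records])
    rng = np.random.default_rng(seed)
    parts = {name: [] for name in PARTITIONS}
    edges = []
    for bin_idx in _quantile_bins(values, n_bins):
        bin_ids = [records[i].id for i in bin_idx]
        if not bin_ids:
            continue
        edges.append((float(values[bin_idx].min()), float(values[bin_idx].max())))
        tr, va, te = _allocate(bin_ids, ratios, rng)
        parts["train"] += tr
        parts["val"] += va
        parts["test"] += te
    return DataSplit(
        train_ids=sorted(parts["train"]),
        val_ids=sorted(parts["val"]),
        test_ids=sorted(parts["test"]),
        policy="stratified",
        seed=seed,
        metadata={"n_bins": n_bins, "bin_ranges": edges},
    )


def hfe_extreme_split(
    records: Sequence[MoleculeRecord],
    test_size: int = 80,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> DataSplit:
    """Largest-|HFE| records form the test set; the rest split 6:1."""
    if test_size <= 0 or test_size >= len(records):
        raise ValueError(f"test_size must be in (0, {len(records)}), got {test_size}")
    ranked = sorted(records, key=lambda r: (-abs(r.expt_hfe), r.id))
    test = ranked[:test_size]
    rest = ranked[test_size:]
    cutoff = min(abs(r.expt_hfe) for r in test)
    # remaining records divided 6:1 into train/val with the same quantile binning
    rest_sorted = sorted(rest, key=lambda r: r.id)
    values = np.array([r.expt_hfe for r in rest_sorted])
    rng = np.random.default_rng(seed)
    train_ids, val_ids = [], []
    for bin_idx in _quantile_bins(values, n_bins):
        bin_ids = [rest_sorted[i].id for i in bin_idx]
        if not bin_ids:
            continue
        tr, va = _allocate(bin_ids, (6, 1), rng)
        train_ids += tr
        val_ids += va
    return DataSplit(
        train_ids=sorted(train_ids),
        val_ids=sorted(val_ids),
        test_ids=sorted(r.id for r in test),
        policy="hfe_extreme",
        seed=seed,
        metadata={"test_size": test_size, "abs_hfe_cutoff": cutoff, "n_bins": n_bins},
    )


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko framework SMILES; empty for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def scaffold_split(
    records: Sequence[MoleculeRecord],
    ratios=DEFAULT_RATIOS,
    seed: int = 0,
) -> DataSplit:
    """Scaffold-grouped split.

    Acyclic molecules are distributed 6:1:1 at random; scaffold groups are
    assigned whole, largest first, each to the partition currently furthest
    below its target share of ring-containing molecules.
    """
    ratios = _check_ratios(ratios)
    records = sorted(records, key=lambda r: r.id)
    rng = np.random.default_rng(seed)
    acyclic, groups = [], {}
    scaffold_of = {}
    for r in records:
        scaf = murcko_scaffold(r.smiles)
        scaffold_of[r.id] = scaf
        if scaf == "":
            acyclic.append(r.id)
        else:
            groups.setdefault(scaf, []).append(r.id)

    parts = {name: [] for name in PARTITIONS}
    tr, va, te = _allocate(acyclic, ratios, rng)
    parts["train"] += tr
    parts["val"] += va
    parts["test"] += te

    n_ring = sum(len(g) for g in groups.values())
    total = sum(ratios)
    targets = {name: n_ring * r / total for name, r in zip(PARTITIONS, ratios)}
    filled = {name: 0 for name in PARTITIONS}
    for scaf, ids in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        deficits = {name: targets[name] - filled[name] for name in PARTITIONS}
        dest = max(PARTITIONS, key=lambda name: deficits[name])
        parts[dest] += ids
        filled[dest] += len(ids)

    return DataSplit(
        train_ids=sorted(parts["train"]),
        val_ids=sorted(parts["val"]),
        test_ids=sorted(parts["test"]),
        policy="scaffold",
        seed=seed,
        metadata={
            "n_acyclic": len(acyclic),
            "n_ring": n_ring,
            "n_scaffolds": len(groups),
            "scaffold_of": scaffold_of,
        },
    )


def make_split(
    records: Sequence[MoleculeRecord],
    policy: str,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
    test_size: int = 80,
    ratios=DEFAULT_RATIOS,
) -> DataSplit:
    if policy == "stratified":
        return stratified_split(records, ratios=ratios, n_bins=n_bins, seed=seed)
    if policy == "hfe_extreme":
        return hfe_extreme_split(records, test_size=test_size, n_bins=n_bins, seed=seed)
    if policy == "scaffold":
        return scaffold_split(records, ratios=ratios, seed=seed)
    raise ValueError(f"unknown split policy {policy!r}")
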