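"""Reading the FreeSolv-dialect database text and record-level filters.

The database dialect: lines starting with ``#`` are header comments; data
lines are semicolon-delimited with at least seven fields::

    compound id; SMILES; iupac name; expt (kcal/mol); expt uncertainty;
    calc (kcal/mol); calc uncertainty; [reference/notes ...]

Trailing fields beyond the seven parsed ones are ignored.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Heavy-atom element vocabulary (the one-hot identity alphabet).
ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

#: Default absolute uncertainty cutoff, kcal/mol.
UNCERTAINTY_CUTOFF = 0.6
#: |HFE| above which the relative-uncertainty rule applies, kcal/mol.
HFE_REGIME_CUTOFF = 6.0
#: Relative-uncertainty cutoff (fraction).
RELATIVE_CUTOFF = 0.10


class ParseError(ValueError):
    """Malformed database line."""


class ValidationError(ValueError):
    """Record violates a domain invariant (e.g. element outside vocabulary)."""


@dataclass
class MoleculeRecord:
    """One database entry: identifiers, label, uncertainty, physics data."""

    id: str
    smiles: str
    name: str = ""
    expt_hfe: float = 0.0
    expt_uncertainty: float = 0.0
    calc_hfe: Optional[float] = None
    coords: Optional[list] = None  # list of (element, x, y, z) for heavy atoms
    charges: Optional[list] = None  # per-heavy-atom partial charges, if provided
    physics_pred: dict = field(default_factory=dict)

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValidationError(f"record {self.id!r}: unparseable SMILES {self.smiles!r}")
        return m

    def heavy_atom_count(self) -> int:
        return self.mol().GetNumHeavyAtoms()


@dataclass
class FilterReport:
    kept: list
    removed: list  # list of (id, reason)

    @property
    def removed_ids(self) -> list:
        return [rid for rid, _ in self.removed]

    def to_json(self) -> str:
        return json.dumps({"kept": self.kept, "removed": [list(t) for t in self.removed]})


def _validate_elements(record: MoleculeRecord) -> None:
    mol = record.mol()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            continue
        if sym not in ELEMENTS:
            raise ValidationError(
                f"record {record.id!r}: element {sym!r} outside the supported vocabulary"
            )
    if record.expt_uncertainty < 0:
        raise ValidationError(f"record {record.id!r}: negative uncertainty")
    if record.coords is not None:
        n_heavy = sum(1 for el, *_ in record.coords if el != "H")
        if n_heavy != mol.GetNumHeavyAtoms():
            raise ValidationError(
                f"record {record.id!r}: coords heavy-atom count {n_heavy} "
                f"!= SMILES heavy-atom count {mol.GetNumHeavyAtoms()}"
            )


def parse_freesolv(text: str, validate: bool = True) -> list:
    """Parse raw FreeSolv-dialect file contents into records (order kept)."""
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(";")]
        if len(fields) < 7:
            raise ParseError(f"line {lineno}: expected >= 7 semicolon-delimited fields, got {len(fields)}")
        cid, smiles, name = fields[0], fields[1], fields[2]
        try:
            expt = float(fields[3])
            expt_unc = float(fields[4])
            calc = float(fields[5])
            float(fields[6])  # calc uncertainty: parsed for validation, not stored
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric energy field ({exc})") from None
        rec = MoleculeRecord(
            id=cid, smiles=smiles, name=name,
            expt_hfe=expt, expt_uncertainty=expt_unc, calc_hfe=calc,
        )
        if validate:
            _validate_elements(rec)
        records.append(rec)
    return records


def serialize_freesolv(records: Iterable[MoleculeRecord]) -> str:
    """Write records back out in the same dialect (seven fields)."""
    lines = ["# id; SMILES; name; expt (kcal/mol); d(expt); calc (kcal/mol); d(calc)"]
    for r in records:
        calc = r.calc_hfe if r.calc_hfe is not None else 0.0
        lines.append(
            f"{r.id}; {r.smiles}; {r.name}; {r.expt_hfe!r}; {r.expt_uncertainty!r}; {calc!r}; 0.0"
        )
    return "\n".join(lines) + "\n"


def filter_low_uncertainty(records: Sequence[MoleculeRecord]) -> FilterReport:
    """Remove high-uncertainty records.

    Below |HFE| of 6 kcal/mol a record is removed iff its uncertainty
    exceeds 0.6 kcal/mol; at or above, iff its relative uncertainty
    exceeds 10%.  Boundary values survive (strict inequalities).
    """
    kept, removed = [], []
    for r in records:
        if abs(r.expt_hfe) < HFE_REGIME_CUTOFF:
            bad = r.expt_uncertainty > UNCERTAINTY_CUTOFF
        else:
            bad = r.expt_uncertainty / abs(r.expt_hfe) > RELATIVE_CUTOFF
        if bad:
            removed.append((r.id, "high_uncertainty"))
        else:
            kept.append(r.id)
    return FilterReport(kept=kept, removed=removed)


def drop_single_heavy_atom(records: Sequence[MoleculeRecord]) -> FilterReport:
    """Remove molecules whose graph has a single node (one heavy atom)."""
    kept, removed = [], []
    for r in records:
        if r.heavy_atom_count() == 1:
            removed.append((r.id, "single_heavy_atom"))
        else:
            kept.append(r.id)
    return FilterReport(kept=kept, removed=removed)


def apply_filters(records: Sequence[MoleculeRecord]) -> FilterReport:
    """Both record-level filters combined into one report."""
    unc = filter_low_uncertainty(records)
    by_id = {r.id: r for r in records}
    surviving = [by_id[i] for i in unc.kept]
    single = drop_single_heavy_atom(surviving)
    return FilterReport(kept=single.kept, removed=unc.removed + single.removed)


def attach_physics_predictions(
    records: Sequence[MoleculeRecord],
    table: Mapping[str, float],
    model_name: str,
) -> Sequence[MoleculeRecord]:
    """Annotate records with a named physics model's predictions (in place)."""
    ids = {r.id for r in records}
    unknown = sorted(set(table) - ids)
    if unknown:
        raise ValidationError(f"physics table contains unknown ids: {unknown}")
    for r in records:
        if r.id in table:
            r.physics_pred[model_name] = float(table[r.id])
    return records


def read_prediction_table(path) -> dict:
    """Two-column CSV (id, kcal/mol) with header; duplicate ids are an error."""
    table: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return table
        for row in reader:
            if not row:
                continue
            cid, value = row[0].strip(), float(row[1])
            if cid in table:
                raise ValidationError(f"duplicate id {cid!r} in prediction table")
            table[cid] = value
    return table


def write_records_csv(records: Sequence[MoleculeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        models = sorted({m for r in records for m in r.physics_pred})
        writer.writerow(["id", "smiles", "name", "expt_hfe", "expt_uncertainty", "calc_hfe"] + models)
        for r in records:
            writer.writerow(
                [r.id, r.smiles, r.name, r.expt_hfe, r.expt_uncertainty, r.calc_hfe]
                + [r.physics_pred.get(m, "") for m in models]
            )


def locate_freesolv(explicit=None):
    """Find a user-supplied FreeSolv v0.52 database file, or None.

    Checked in order: an explicit path argument, the FREESOLV_PATH
    environment variable, then ``data/freesolv_v0.52.txt``,
    ``data/database.txt`` and ``database.txt`` relative to the working
    directory.  The file is never downloaded.
    """
    import os

    candidates = []
    if explicit:
        candidates.append(Path(explicit))
    env = os.environ.get("FREESOLV_PATH")
    if env:
        candidates.append(Path(env))
    candidates += [Path("data/freesolv_v0.52.txt"), Path("data/database.txt"),
                   Path("database.txt")]
    for path in candidates:
        if path.is_file():
            return path
    return None


# -- optional 3D structures ---------------------------------------------------

def load_structure_file(path) -> Chem.Mol:
    path = Path(path)
    if path.suffix.lower() == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    elif path.suffix.lower() in (".sdf", ".mol"):
        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
    else:
        raise ValidationError(f"unsupported structure format: {path.suffix}")
    if mol is None:
        raise ValidationError(f"could not read structure file {path}")
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        pass  # tolerate partial sanitization; we only need coords + elements
    return mol


def attach_structures(records: Sequence[MoleculeRecord], directory) -> int:
    """Match SDF/MOL2 files in `directory` to records by filename stem.

    Heavy-atom order is reconciled against the record's canonical atom
    ranking through an RDKit substructure match; ambiguity (no match) is
    an error.  Returns the number of records annotated.
    """
    from .featurization import heavy_atom_order

    directory = Path(directory)
    by_id = {r.id: r for r in records}
    n = 0
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".sdf", ".mol", ".mol2"):
            continue
        rec = by_id.get(path.stem)
        if rec is None:
            continue
        mol3d = load_structure_file(path)
        ref = rec.mol()
        heavy3d = Chem.RemoveHs(Chem.Mol(mol3d), sanitize=False)
        match = heavy3d.GetSubstructMatch(ref)
        if not match or len(match) != ref.GetNumAtoms():
            raise ValidationError(f"record {rec.id!r}: structure does not match SMILES connectivity")
        conf = heavy3d.GetConformer()
        order = heavy_atom_order(ref)
        coords = []
        for ref_idx in order:
            pos = conf.GetAtomPosition(match[ref_idx])
            coords.append((ref.GetAtomWithIdx(ref_idx).GetSymbol(), pos.x, pos.y, pos.z))
        rec.coords = coords
        n += 1
    return n
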