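"""Molecule ingestion, normalization, descriptors and drug-likeness profiling.

This module covers the structure-handling front end of the pipeline:
reading SMILES/SDF libraries, keeping the largest fragment of salts and
adducts, stereo-aware deduplication, a small panel of 2D molecular
descriptors, and Lipinski Rule-of-Five profiling.

Descriptor conventions
----------------------
* ``hba`` / ``hbd`` are Lipinski's original N+O and NH+OH counts, not
  pharmacophore-style acceptor/donor definitions.
* ``alogp`` is the Crippen/Wildman additive atom-contribution logP.
* ``n_rotatable`` uses RDKit's default rotatable-bond pattern
  (non-ring single bonds between non-terminal heavy atoms, amides
  excluded).
* ``n_rings`` is the SSSR ring count.
* ``fpsa`` is a topological fractional polar surface area: the Labute
  approximate-surface-area contribution of N and O atoms divided by the
  total Labute surface area, which keeps the value in [0, 1].
* ``n_chiral_c`` counts *assigned* stereocenters on carbon only;
  unassigned or merely potential centers are not counted, since library
  entries are expected to carry explicit stereoconfigurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

logger = logging.getLogger(__name__)

# RDKit is chatty about kekulization/stereo on real-world libraries; parse
# failures are reported through our own logging instead.
RDLogger.DisableLog("rdApp.*")

#: Column order of the full descriptor table (CSV output).
DESCRIPTOR_COLUMNS = [
    "alogp",
    "mw",
    "n_rotatable",
    "n_rings",
    "n_aromatic_rings",
    "hba",
    "hbd",
    "fpsa",
    "n_chiral_c",
    "n_carbon",
    "f_chirality",
]

#: The 8-descriptor panel used for chemical-space PCA, in fixed order.
PCA_DESCRIPTOR_COLUMNS = [
    "alogp",
    "mw",
    "hbd",
    "hba",
    "n_rotatable",
    "n_rings",
    "n_aromatic_rings",
    "fpsa",
]

RO5_MW_LIMIT = 500.0
RO5_HBA_LIMIT = 10
RO5_HBD_LIMIT = 5
RO5_ALOGP_LIMIT = 5.0


@dataclass
class MoleculeRecord:
    """A single library entry: identifier, RDKit molecule, source tag."""

    id: str
    mol: Chem.Mol
    source: str = ""

    def __post_init__(self) -> None:
        if self.mol is None or self.mol.GetNumAtoms() == 0:
            raise ValueError(f"record {self.id!r} has an empty structure")


@dataclass(frozen=True)
class DescriptorVector:
    """Per-molecule 2D descriptors (the library-profiling panel)."""

    alogp: float
    mw: float
    n_rotatable: int
    n_rings: int
    n_aromatic_rings: int
    hba: int
    hbd: int
    fpsa: float
    n_chiral_c: int
    n_carbon: int
    f_chirality: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Ro5Report:
    """Rule-of-Five criterion flags for one molecule (strict < comparisons)."""

    flag_mw: bool
    flag_hba: bool
    flag_hbd: bool
    flag_alogp: bool

    @property
    def n_satisfied(self) -> int:
        return int(self.flag_mw) + int(self.flag_hba) + int(self.flag_hbd) + int(self.flag_alogp)

    @property
    def pass_strict(self) -> bool:
        return self.n_satisfied == 4

    @property
    def pass_relaxed(self) -> bool:
        return self.n_satisfied >= 3


@dataclass
class LibrarySummary:
    """Descriptor statistics and Rule-of-Five category counts for a library.

    ``except_X`` counts molecules satisfying the three criteria other than
    X, irrespective of X itself — so every ``except_X`` is at least
    ``all_satisfied``.
    """

    n_molecules: int
    descriptor_stats: pd.DataFrame  # rows: descriptors; cols: mean/sd/median/min/max
    all_satisfied: int
    except_mw: int
    except_acceptors: int
    except_donors: int
    except_alogp: int
    at_least_three: int

    def ro5_counts(self) -> dict:
        return {
            "all_satisfied": self.all_satisfied,
            "except_mw": self.except_mw,
            "except_acceptors": self.except_acceptors,
            "except_donors": self.except_donors,
            "except_alogp": self.except_alogp,
            "at_least_three": self.at_least_three,
        }


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_library(path: str | Path, format: str = "smiles", source: str | None = None) -> list[MoleculeRecord]:
    """Read a molecule library from a SMILES list or an SDF file.

    SMILES files hold one record per line: ``SMILES [whitespace] id``; a
    missing id is auto-numbered. Unparsable entries are logged with their
    line/record number and skipped.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        On an unknown format or if no record parses at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("smiles", "sdf"):
        raise ValueError(f"unknown format {format!r}; expected 'smiles' or 'sdf'")
    tag = source if source is not None else path.name

    records: list[MoleculeRecord] = []
    n_skipped = 0
    if format == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"MOL{lineno:06d}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    n_skipped += 1
                    logger.warning("line %d: could not parse SMILES %r — skipped", lineno, smiles)
                    continue
                records.append(MoleculeRecord(id=mol_id, mol=mol, source=tag))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                logger.warning("SDF record %d: could not parse — skipped", idx + 1)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"MOL{idx + 1:06d}"
            records.append(MoleculeRecord(id=mol_id, mol=mol, source=tag))

    if not records:
        raise ValueError(f"no parsable records in {path} ({n_skipped} entries skipped)")
    if n_skipped:
        logger.info("read %d records from %s (%d skipped)", len(records), path, n_skipped)
    return records


# ---------------------------------------------------------------------------
# normalization & deduplication
# ---------------------------------------------------------------------------

def structure_key(mol: Chem.Mol) -> str:
    """Stereo-aware canonical structure key (InChIKey).

    Falls back to the canonical isomeric SMILES for the rare structures the
    InChI algorithm rejects; both keys are collision-safe for dedup purposes.
    """
    try:
        key = Chem.MolToInchiKey(mol)
    except Exception:
        key = ""
    if not key:
        key = "SMI:" + Chem.MolToSmiles(mol)
    return key


def largest_fragment(record: MoleculeRecord) -> MoleculeRecord:
    """Keep only the largest connected fragment (salt/adduct stripping).

    The fragment with the most heavy atoms wins; ties go to the larger
    molecular weight, then to the lexicographically smallest canonical
    SMILES. Single-fragment input is returned unchanged.
    """
    frags = Chem.GetMolFrags(record.mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return record
    best = max(
        frags,
        key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m), _neg_lex(Chem.MolToSmiles(m))),
    )
    return MoleculeRecord(id=record.id, mol=best, source=record.source)


class _neg_lex(str):
    """Orders strings in reverse so that ``max`` picks the lexicographically smallest."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def deduplicate(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], list[tuple[str, list[str]]]]:
    """Remove duplicate structures, keeping the first occurrence in input order.

    Duplicates are detected by the stereo-aware :func:`structure_key`, so
    enantiomers of the same skeleton are distinct and both survive.

    Returns the deduplicated records and a report of ``(kept_id,
    removed_ids)`` pairs (one entry per key that had duplicates).
    """
    if not records:
        raise ValueError("deduplicate: empty record list")
    kept: list[MoleculeRecord] = []
    by_key: dict[str, MoleculeRecord] = {}
    removed: dict[str, list[str]] = {}
    for rec in records:
        key = structure_key(rec.mol)
        if key in by_key:
            removed.setdefault(key, []).append(rec.id)
        else:
            by_key[key] = rec
            kept.append(rec)
    report = [(by_key[k].id, ids) for k, ids in removed.items()]
    return kept, report


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def _fractional_polar_surface(mol: Chem.Mol) -> float:
    contribs, h_contrib = rdMolDescriptors._CalcLabuteASAContribs(mol)
    total = float(sum(contribs)) + float(h_contrib)
    if total <= 0:
        return 0.0
    polar = sum(c for c, atom in zip(contribs, mol.GetAtoms()) if atom.GetSymbol() in ("N", "O"))
    return float(polar) / total


def _chiral_carbon_count(mol: Chem.Mol) -> int:
    centers = Chem.FindMolChiralCenters(mol, includeUnassigned=False, useLegacyImplementation=False)
    return sum(1 for idx, _ in centers if mol.GetAtomWithIdx(idx).GetSymbol() == "C")


def compute_descriptors(record: MoleculeRecord) -> DescriptorVector:
    """Compute the descriptor panel for one molecule."""
    mol = record.mol
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"record {record.id!r}: structure has no heavy atoms")
    n_carbon = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    n_chiral_c = _chiral_carbon_count(mol)
    return DescriptorVector(
        alogp=float(Crippen.MolLogP(mol)),
        mw=float(Descriptors.MolWt(mol)),
        n_rotatable=int(Lipinski.NumRotatableBonds(mol)),
        n_rings=int(rdMolDescriptors.CalcNumRings(mol)),
        n_aromatic_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        hba=int(Lipinski.NOCount(mol)),
        hbd=int(Lipinski.NHOHCount(mol)),
        fpsa=_fractional_polar_surface(mol),
        n_chiral_c=n_chiral_c,
        n_carbon=n_carbon,
        f_chirality=(n_chiral_c / n_carbon) if n_carbon > 0 else 0.0,
    )


def f_chirality(record: MoleculeRecord) -> float:
    """Fraction of carbons that are assigned stereocenters.

    Raises
    ------
    ValueError
        For carbon-free molecules, where the fraction is undefined.
    """
    n_carbon = sum(1 for a in record.mol.GetAtoms() if a.GetSymbol() == "C")
    if n_carbon == 0:
        raise ValueError(f"record {record.id!r}: F-chirality undefined for a carbon-free molecule")
    return _chiral_carbon_count(record.mol) / n_carbon


def descriptor_table(records: Iterable[MoleculeRecord]) -> pd.DataFrame:
    """Descriptor panel for a whole library, indexed by molecule id."""
    rows = {}
    for rec in records:
        rows[rec.id] = compute_descriptors(rec).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=DESCRIPTOR_COLUMNS)
    df.index.name = "id"
    return df


# ---------------------------------------------------------------------------
# Rule of Five
# ---------------------------------------------------------------------------

def ro5_evaluate(dv: DescriptorVector) -> Ro5Report:
    """Lipinski Rule-of-Five flags: MW < 500 Da, HBA < 10, HBD < 5, AlogP < 5.

    All comparisons are strict, so a molecule sitting exactly on a bound
    fails that criterion.
    """
    return Ro5Report(
        flag_mw=dv.mw < RO5_MW_LIMIT,
        flag_hba=dv.hba < RO5_HBA_LIMIT,
        flag_hbd=dv.hbd < RO5_HBD_LIMIT,
        flag_alogp=dv.alogp < RO5_ALOGP_LIMIT,
    )


def ro5_table(descriptors: pd.DataFrame) -> pd.DataFrame:
    """Vectorized Rule-of-Five report for a descriptor table."""
    flags = pd.DataFrame(
        {
            "flag_mw": descriptors["mw"] < RO5_MW_LIMIT,
            "flag_hba": descriptors["hba"] < RO5_HBA_LIMIT,
            "flag_hbd": descriptors["hbd"] < RO5_HBD_LIMIT,
            "flag_alogp": descriptors["alogp"] < RO5_ALOGP_LIMIT,
        },
        index=descriptors.index,
    )
    flags["n_satisfied"] = flags.sum(axis=1).astype(int)
    flags["pass_strict"] = flags["n_satisfied"] == 4
    flags["pass_relaxed"] = flags["n_satisfied"] >= 3
    return flags


def library_summary(descriptors: pd.DataFrame) -> LibrarySummary:
    """Per-descriptor statistics plus Rule-of-Five category counts.

    The ``except_X`` categories count molecules satisfying the three
    criteria other than X whatever the value of X, which makes each
    category a superset of the fully compliant set.
    """
    if descriptors.empty:
        raise ValueError("library_summary: empty descriptor table")
    flags = ro5_table(descriptors)
    stats = pd.DataFrame(
        {
            "mean": descriptors.mean(),
            "sd": descriptors.std(ddof=1),
            "median": descriptors.median(),
            "min": descriptors.min(),
            "max": descriptors.max(),
        }
    )
    f_mw, f_hba = flags["flag_mw"], flags["flag_hba"]
    f_hbd, f_logp = flags["flag_hbd"], flags["flag_alogp"]
    return LibrarySummary(
        n_molecules=len(descriptors),
        descriptor_stats=stats,
        all_satisfied=int((f_mw & f_hba & f_hbd & f_logp).sum()),
        except_mw=int((f_hba & f_hbd & f_logp).sum()),
        except_acceptors=int((f_mw & f_hbd & f_logp).sum()),
        except_donors=int((f_mw & f_hba & f_logp).sum()),
        except_alogp=int((f_mw & f_hba & f_hbd).sum()),
        at_least_three=int((flags["n_satisfied"] >= 3).sum()),
    )
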