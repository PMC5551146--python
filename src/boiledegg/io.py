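"""Reading, validation and serialization of compound tables.

A compound table is a CSV/TSV file with one row per chemical. Required
columns are ``id`` and ``smiles``; ``name``, ``chem_class``, ``measured_fa``,
``role`` and ``parent_id`` are recognised when present, and a column mapping
can be supplied for files with different headers. Rows whose SMILES does not
parse are never dropped silently: they are logged at WARNING level and
accounted for in :class:`CompoundTable.n_rejected`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

#: recognised chemical classes; free-text labels are accepted as well
KNOWN_CLASSES = (
    "organochlorine",
    "organophosphorus",
    "pyrethroid",
    "carbamate",
    "triazine",
    "miscellaneous",
)

ROLES = ("parent", "oxon_metabolite", "other")


class CompoundError(ValueError):
    """A compound record violates an invariant (bad SMILES, bad Fa, dup id)."""


@dataclass(frozen=True)
class Compound:
    """One input molecule.

    Parameters
    ----------
    id:
        Short unique label within a table.
    smiles:
        SMILES string; must parse to a graph with at least one heavy atom.
    measured_fa:
        Optional measured fraction absorbed, in [0, 1].
    role:
        ``parent``, ``oxon_metabolite`` or ``other``; used by the
        parent/oxon comparison.
    """

    id: str
    smiles: str
    name: str = ""
    chem_class: str = "miscellaneous"
    measured_fa: float | None = None
    role: str = "other"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise CompoundError(f"compound {self.id!r}: SMILES parse failure: {self.smiles!r}")
        if self.measured_fa is not None and not (0.0 <= self.measured_fa <= 1.0):
            raise CompoundError(f"compound {self.id!r}: measured_fa {self.measured_fa} outside [0, 1]")
        if self.role not in ROLES:
            raise CompoundError(f"compound {self.id!r}: unknown role {self.role!r}")

    def mol(self) -> Chem.Mol:
        """RDKit molecule for the (unstandardized) SMILES."""
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class CompoundTable:
    """An ordered collection of compounds plus parse provenance."""

    compounds: list[Compound]
    source: str = "<memory>"
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.compounds)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.compounds],
                "name": [c.name for c in self.compounds],
                "chem_class": [c.chem_class for c in self.compounds],
                "smiles": [c.smiles for c in self.compounds],
                "measured_fa": [c.measured_fa for c in self.compounds],
                "role": [c.role for c in self.compounds],
                "parent_id": [c.parent_id for c in self.compounds],
            }
        )


#: default multi-fragment / stereo policy used throughout the package
@dataclass(frozen=True)
class StandardizationPolicy:
    keep_largest_fragment: bool = True
    drop_stereo: bool = True


DEFAULT_POLICY = StandardizationPolicy()


def standardize_structure(smiles: str, policy: StandardizationPolicy = DEFAULT_POLICY) -> str:
    """Return a canonical SMILES under the package's standardization policy.

    The default policy keeps the largest organic fragment of multi-fragment
    inputs (ties broken toward the fragment containing carbon, then
    lexicographically), preserves formal charges, and removes stereochemistry
    annotations (no implemented descriptor is stereo-dependent). The
    operation is idempotent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundError(f"SMILES parse failure: {smiles!r}")
    if policy.keep_largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if len(frags) > 1:
            def key(m: Chem.Mol) -> tuple:
                has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
                return (m.GetNumHeavyAtoms(), has_c, Chem.MolToSmiles(m))
            mol = max(frags, key=key)
    if policy.drop_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


_COLUMN_ALIASES = {
    "id": ("id", "identifier", "compound_id"),
    "name": ("name", "compound", "pesticide"),
    "chem_class": ("chem_class", "class", "chemical_class"),
    "smiles": ("smiles", "canonical_smiles"),
    "measured_fa": ("measured_fa", "fa", "fraction_absorbed"),
    "role": ("role",),
    "parent_id": ("parent_id", "parent"),
}


def _resolve_columns(header: Sequence[str], mapping: Mapping[str, str] | None) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    for field_name, aliases in _COLUMN_ALIASES.items():
        if mapping and field_name in mapping:
            if mapping[field_name] not in header:
                raise KeyError(f"mapped column {mapping[field_name]!r} not in file header")
            resolved[field_name] = mapping[field_name]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[field_name] = lower[alias]
                break
    for required in ("id", "smiles"):
        if required not in resolved:
            raise KeyError(f"required column {required!r} (or an alias) missing from header {list(header)}")
    return resolved


def read_compound_table(
    path: str | Path,
    format: str | None = None,
    column_mapping: Mapping[str, str] | None = None,
) -> CompoundTable:
    """Read a CSV/TSV compound table.

    Every row either becomes a :class:`Compound` or is recorded as a
    rejection (row number, reason); ``rows_in == n_accepted + n_rejected``.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if format not in ("csv", "tsv"):
        raise ValueError(f"unsupported format {format!r}")
    frame = pd.read_csv(path, sep="\t" if format == "tsv" else ",", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(frame.columns), column_mapping)

    compounds: list[Compound] = []
    rejections: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(frame.columns, row))
        cid = rec[cols["id"]].strip()
        try:
            if not cid:
                raise CompoundError("empty id")
            if cid in seen:
                raise CompoundError(f"duplicate id {cid!r}")
            fa_raw = rec.get(cols.get("measured_fa", ""), "").strip() if "measured_fa" in cols else ""
            compound = Compound(
                id=cid,
                smiles=rec[cols["smiles"]].strip(),
                name=rec.get(cols.get("name", ""), cid).strip() or cid,
                chem_class=(rec.get(cols.get("chem_class", ""), "") or "miscellaneous").strip(),
                measured_fa=float(fa_raw) if fa_raw else None,
                role=(rec.get(cols.get("role", ""), "") or "other").strip(),
                parent_id=(rec.get(cols.get("parent_id", ""), "").strip() or None) if "parent_id" in cols else None,
            )
        except (CompoundError, ValueError) as exc:
            reason = "parse failure" if "SMILES parse failure" in str(exc) else str(exc)
            logger.warning("%s row %d rejected: %s", path.name, i, reason)
            rejections.append((i, reason))
            continue
        seen.add(cid)
        compounds.append(compound)
    return CompoundTable(compounds=compounds, source=str(path), rejections=rejections)


#: fixed column order of the results CSV written by :func:`write_results`
RESULT_COLUMNS = (
    "id",
    "name",
    "chem_class",
    "mw",
    "wlogp",
    "tpsa",
    "n_heavy",
    "n_aromatic_heavy",
    "n_rotatable",
    "n_hba",
    "n_hbd",
    "frac_csp3",
    "molar_refractivity",
    "n_NO",
    "mv_mean_vdw",
    "mp_mean_polarizability",
    "gi_label",
    "bbb_label",
)


def write_results(table: CompoundTable, predictions: pd.DataFrame, path: str | Path) -> Path:
    """Write one row per compound (descriptors + labels) in a fixed column order.

    ``predictions`` must align 1:1 with ``table`` by ``id`` (same order).
    """
    path = Path(path)
    ids = table.ids()
    if list(predictions["id"]) != ids:
        raise ValueError("predictions are not aligned 1:1 with the compound table")
    out = predictions.copy()
    out["name"] = [c.name for c in table.compounds]
    out["chem_class"] = [c.chem_class for c in table.compounds]
    cols = [c for c in RESULT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format="%.4f")
    return path


def compounds_from_records(records: Iterable[Mapping], source: str = "<records>") -> CompoundTable:
    """Build a table from dict-like records (convenience for programmatic use)."""
    compounds = []
    rejections: list[tuple[int, str]] = []
    for i, rec in enumerate(records, start=1):
        try:
            compounds.append(Compound(**rec))
        except CompoundError as exc:
            logger.warning("record %d rejected: %s", i, exc)
            rejections.append((i, str(exc)))
    return CompoundTable(compounds=compounds, source=source, rejections=rejections)


def with_standardized_smiles(table: CompoundTable, policy: StandardizationPolicy = DEFAULT_POLICY) -> CompoundTable:
    """Return a copy of the table with every SMILES standardized."""
    return CompoundTable(
        compounds=[replace(c, smiles=standardize_structure(c.smiles, policy)) for c in table.compounds],
        source=table.source,
        rejections=list(table.rejections),
    )
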