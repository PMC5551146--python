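"""Physicochemical descriptor panel for one molecule.

The two descriptors the egg classifier runs on are the Wildman–Crippen
octanol/water partition coefficient (WLogP), an atom-contribution sum over
the published 68-type table, and the Ertl topological polar surface area
(tPSA), a fragment-contribution sum over polar atoms. Both are computed with
RDKit's implementations of those published methods. The rest of the panel
(molecular weight, atom counts, rotatable bonds, H-bond donors/acceptors,
Csp3 fraction, Wildman–Crippen molar refractivity, N+O count) follows the
conventions documented below; the carbon-scaled mean atomic van der Waals
volume and polarizability are simple atomic-constant surrogates for
externally computed values and are flagged as such.

Operational definitions
-----------------------
- rotatable bonds: non-ring single bonds between two non-terminal heavy
  atoms, amide C–N excluded (RDKit default definition).
- HBA / HBD: Lipinski-style N/O-based perception (RDKit ``Lipinski``
  module); the source web tool's exact rules are not published, so a fixed
  documented convention is used instead.
- Csp3 fraction: sp3-hybridised carbons / total carbons; defined as 0 for
  carbon-free molecules (logged).
- tPSA: the ``include_sp`` flag toggles the extended sulfur/phosphorus
  fragment contributions. This matters for every phosphorothioate (P=S)
  pesticide; the package default is to include them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Mapping

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

logger = logging.getLogger(__name__)

MolLike = Chem.Mol | str


@dataclass(frozen=True)
class DescriptorVector:
    """Computed physicochemical panel for one molecule."""

    mw: float                      # g/mol, implicit hydrogens included
    wlogp: float                   # Wildman-Crippen logP (dimensionless)
    tpsa: float                    # Ertl topological polar surface area, A^2
    n_heavy: int
    n_aromatic_heavy: int
    n_rotatable: int
    n_hba: int
    n_hbd: int
    frac_csp3: float
    molar_refractivity: float      # Wildman-Crippen MR, cm^3/mol
    n_NO: int                      # nitrogen + oxygen atom count
    mv_mean_vdw: float | None = None           # carbon-scaled, surrogate
    mp_mean_polarizability: float | None = None  # carbon-scaled, surrogate
    xlogp3: float | None = None    # optional, externally supplied
    logs_silicos: float | None = None  # optional, externally supplied

    def __post_init__(self) -> None:
        assert self.mw > 0 and self.tpsa >= 0
        assert 0.0 <= self.frac_csp3 <= 1.0
        assert 0 <= self.n_aromatic_heavy <= self.n_heavy
        assert 0 <= self.n_NO <= self.n_heavy

    def as_dict(self) -> dict[str, float | int | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_mol(molecule: MolLike) -> Chem.Mol:
    if not isinstance(molecule, Chem.Mol):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"SMILES parse failure: {molecule!r}")
        molecule = mol
    # round-trip through the canonical SMILES so atom ordering (and hence
    # every contribution sum) is bit-identical across input dialects
    return Chem.MolFromSmiles(Chem.MolToSmiles(molecule))


def compute_wlogp(molecule: MolLike) -> float:
    """Wildman–Crippen logP: sum of per-atom contributions (implicit H included)."""
    return float(Crippen.MolLogP(_as_mol(molecule)))


def compute_tpsa(molecule: MolLike, include_sp: bool = True) -> float:
    """Ertl topological polar surface area in Å².

    ``include_sp`` toggles the extended sulfur/phosphorus fragment
    contributions; apolar molecules return 0.
    """
    return float(rdMolDescriptors.CalcTPSA(_as_mol(molecule), includeSandP=include_sp))


def compute_counts(molecule: MolLike) -> dict[str, float | int]:
    """Atom/bond count block of the panel (see module docstring for rules)."""
    mol = _as_mol(molecule)
    n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    if n_carbon == 0:
        logger.warning("molecule without carbon: frac_csp3 defined as 0")
        frac = 0.0
    else:
        frac = float(rdMolDescriptors.CalcFractionCSP3(mol))
    return {
        "n_heavy": mol.GetNumHeavyAtoms(),
        "n_aromatic_heavy": sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        "n_rotatable": int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "n_hba": int(Lipinski.NumHAcceptors(mol)),
        "n_hbd": int(Lipinski.NumHDonors(mol)),
        "n_NO": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)),
        "frac_csp3": frac,
    }


def compute_mw_mr(molecule: MolLike) -> tuple[float, float]:
    """Molecular weight (standard atomic masses, implicit H counted) and
    Wildman–Crippen molar refractivity."""
    mol = _as_mol(molecule)
    return float(Descriptors.MolWt(mol)), float(Crippen.MolMR(mol))


# Carbon-scaled atomic constants (van der Waals volume, polarizability),
# standard descriptor-handbook tables; surrogate for externally computed
# whole-molecule means, not bit-compatible with commercial engines.
VDW_VOLUME_SCALED: Mapping[int, float] = {
    1: 0.299, 5: 0.702, 6: 1.000, 7: 0.695, 8: 0.512, 9: 0.410,
    14: 1.524, 15: 1.181, 16: 1.088, 17: 1.035, 35: 1.384, 53: 1.728,
}
POLARIZABILITY_SCALED: Mapping[int, float] = {
    1: 0.379, 5: 1.722, 6: 1.000, 7: 0.625, 8: 0.456, 9: 0.316,
    14: 3.059, 15: 2.063, 16: 1.648, 17: 1.239, 35: 1.733, 53: 3.040,
}


def compute_mean_atomic_props(molecule: MolLike) -> tuple[float, float]:
    """Mean carbon-scaled atomic van der Waals volume and polarizability.

    The mean runs over all atoms including explicit hydrogens; elements
    without a tabulated constant are excluded from the mean and logged.
    Surrogate values: an all-carbon skeleton without hydrogens gives exactly
    1.0 by the scaling definition.
    """
    mol = Chem.AddHs(_as_mol(molecule))
    mv, mp = [], []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z not in VDW_VOLUME_SCALED:
            logger.warning("no tabulated atomic constants for element Z=%d; excluded from mean", z)
            continue
        mv.append(VDW_VOLUME_SCALED[z])
        mp.append(POLARIZABILITY_SCALED[z])
    if not mv:
        raise ValueError("no atoms with tabulated constants")
    return sum(mv) / len(mv), sum(mp) / len(mp)


def compute_descriptors(
    molecule: MolLike,
    include_sp: bool = True,
    with_mean_atomic: bool = True,
    xlogp3: float | None = None,
    logs_silicos: float | None = None,
) -> DescriptorVector:
    """Compute the full panel for one standardized molecule."""
    mol = _as_mol(molecule)
    mw, mr = compute_mw_mr(mol)
    counts = compute_counts(mol)
    wlogp = compute_wlogp(mol)
    tpsa = compute_tpsa(mol, include_sp=include_sp)
    if not (math.isfinite(wlogp) and math.isfinite(tpsa)):
        raise ValueError("non-finite descriptor value")
    mv = mp = None
    if with_mean_atomic:
        mv, mp = compute_mean_atomic_props(mol)
    return DescriptorVector(
        mw=mw,
        wlogp=wlogp,
        tpsa=tpsa,
        molar_refractivity=mr,
        mv_mean_vdw=mv,
        mp_mean_polarizability=mp,
        xlogp3=xlogp3,
        logs_silicos=logs_silicos,
        **counts,
    )
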