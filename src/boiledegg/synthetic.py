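"""Ground-truth-bearing synthetic inputs.

Two generators make every pipeline stage testable without the published
corpus:

* :func:`generate_descriptor_cloud` samples bare (tPSA, WLogP) points with
  known region membership relative to the two ellipses — inside both,
  intestinal-only, brain-only, outside both — so classifier label recovery
  and class-summary percentages have an exact counting oracle. The
  brain-only region is the thin sliver of the yolk protruding from the
  white at near-zero tPSA (the lindane regime), so it is sampled
  parametrically inside the brain ellipse rather than by box rejection.
* :func:`generate_smiles_library` assembles valid SMILES from a small
  fragment grammar (halogenated rings, phosphorothioate/phosphate heads,
  carbamate, triazine and cyclopropanecarboxylate cores) tagged with
  synthetic class labels, optionally with parent → oxon pairs produced by
  the P=S → P=O substitution. Class proportions default to those of the
  pesticide corpus the package targets (30:99:42:74:31:62 across the six
  classes). No attempt is made at chemical realism beyond valence-valid
  fragments.

All randomness flows through one seeded ``numpy`` generator; identical
spec + seed reproduces identical output, byte-for-byte after serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from .egg import EggModel, EllipseModel, classify_points, load_model
from .io import Compound, CompoundTable, standardize_structure

REGIONS = ("both", "intestinal_only", "brain_only", "outside")

#: corpus-like class proportions used when no explicit counts are requested
DEFAULT_CLASS_WEIGHTS: Mapping[str, int] = {
    "organochlorine": 30,
    "organophosphorus": 99,
    "pyrethroid": 42,
    "carbamate": 74,
    "triazine": 31,
    "miscellaneous": 62,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Requested composition of a synthetic descriptor cloud."""

    n_both: int = 10
    n_intestinal_only: int = 10
    n_brain_only: int = 0
    n_outside: int = 10
    seed: int = 0
    jitter: float = 0.25  # bounding-box padding fraction for 'outside' sampling

    def __post_init__(self) -> None:
        if min(self.n_both, self.n_intestinal_only, self.n_brain_only, self.n_outside) < 0:
            raise ValueError("region counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_intestinal_only + self.n_brain_only + self.n_outside


def _sample_in_ellipse(rng: np.random.Generator, e: EllipseModel, n: int) -> np.ndarray:
    """Uniform points inside an ellipse via the polar square-root map."""
    r = np.sqrt(rng.random(n))
    t = rng.random(n) * 2.0 * math.pi
    u = e.semi_axis_tpsa * r * np.cos(t)
    v = e.semi_axis_wlogp * r * np.sin(t)
    c, s = math.cos(e.rotation), math.sin(e.rotation)
    return np.column_stack([e.center_tpsa + c * u - s * v, e.center_wlogp + s * u + c * v])


def _region_mask(pts: np.ndarray, model: EggModel, region: str) -> np.ndarray:
    qi = model.intestinal.quadratic_form(pts[:, 0], pts[:, 1])
    qb = model.brain.quadratic_form(pts[:, 0], pts[:, 1])
    gi, bbb = qi <= 1.0, qb <= 1.0
    return {
        "both": gi & bbb,
        "intestinal_only": gi & ~bbb,
        "brain_only": ~gi & bbb,
        "outside": ~gi & ~bbb,
    }[region]


def generate_descriptor_cloud(
    spec: SyntheticSpec,
    model: EggModel | None = None,
    max_batches: int = 400,
) -> pd.DataFrame:
    """Labelled (tPSA, WLogP) points with exact per-region counts.

    Rejection sampling is bounded: if a region cannot be filled within
    ``max_batches`` proposal batches (e.g. a requested region is
    geometrically empty for the given model) a ``RuntimeError`` is raised
    rather than looping forever.
    """
    model = model or load_model()
    rng = np.random.default_rng(spec.seed)
    want = {
        "both": spec.n_both,
        "intestinal_only": spec.n_intestinal_only,
        "brain_only": spec.n_brain_only,
        "outside": spec.n_outside,
    }
    white, yolk = model.intestinal, model.brain
    lo_x = min(white.center_tpsa - white.semi_axis_tpsa, yolk.center_tpsa - yolk.semi_axis_tpsa)
    hi_x = max(white.center_tpsa + white.semi_axis_tpsa, yolk.center_tpsa + yolk.semi_axis_tpsa)
    lo_y = min(white.center_wlogp - white.semi_axis_wlogp, yolk.center_wlogp - yolk.semi_axis_wlogp)
    hi_y = max(white.center_wlogp + white.semi_axis_wlogp, yolk.center_wlogp + yolk.semi_axis_wlogp)
    pad_x, pad_y = spec.jitter * (hi_x - lo_x), spec.jitter * (hi_y - lo_y)

    frames = []
    for region, n in want.items():
        if n == 0:
            continue
        got: list[np.ndarray] = []
        n_got = 0
        for _ in range(max_batches):
            batch = max(4 * n, 256)
            if region == "both":
                pts = _sample_in_ellipse(rng, yolk, batch)  # yolk is mostly inside the white
            elif region == "intestinal_only":
                pts = _sample_in_ellipse(rng, white, batch)
            elif region == "brain_only":
                pts = _sample_in_ellipse(rng, yolk, batch)
            else:
                pts = np.column_stack(
                    [
                        rng.uniform(lo_x - pad_x, hi_x + pad_x, batch),
                        rng.uniform(lo_y - pad_y, hi_y + pad_y, batch),
                    ]
                )
            pts = pts[pts[:, 0] >= 0.0]  # tPSA is non-negative by definition
            keep = pts[_region_mask(pts, model, region)]
            if len(keep):
                got.append(keep)
                n_got += len(keep)
            if n_got >= n:
                break
        else:
            raise RuntimeError(
                f"could not draw {n} points in region {region!r} within the proposal budget; "
                "the region may be empty for this ellipse model"
            )
        pts = np.concatenate(got)[:n]
        frames.append(
            pd.DataFrame(
                {
                    "tpsa": pts[:, 0],
                    "wlogp": pts[:, 1],
                    "region": region,
                    "gi_label": "high" if region in ("both", "intestinal_only") else "low",
                    "bbb_label": "yes" if region in ("both", "brain_only") else "no",
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["tpsa", "wlogp", "region", "gi_label", "bbb_label"])
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"pt-{i:05d}" for i in range(len(out))])
    return out


def recover_labels(cloud: pd.DataFrame, model: EggModel | None = None) -> pd.DataFrame:
    """Run the classifier on a cloud's bare points (for label-recovery checks)."""
    model = model or load_model()
    return classify_points(cloud["tpsa"], cloud["wlogp"], model)


# --------------------------------------------------------------------------
# SMILES fragment grammar


def oxonize(smiles: str) -> str:
    """P=S → P=O substitution (the oxidative desulfuration forming an oxon).

    Exactly one terminal thiophosphoryl sulfur is replaced; molecules
    without a P=S group raise ``ValueError``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES parse failure: {smiles!r}")
    rw = Chem.RWMol(mol)
    for bond in rw.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if {a.GetAtomicNum(), b.GetAtomicNum()} == {15, 16}:
            s = a if a.GetAtomicNum() == 16 else b
            if s.GetDegree() == 1:
                s.SetAtomicNum(8)
                out = rw.GetMol()
                Chem.SanitizeMol(out)
                return Chem.MolToSmiles(out)
    raise ValueError(f"no thiophosphoryl (P=S) group in {smiles!r}")


_HALO = ("Cl", "Cl", "Br", "F")
_ALKYL = ("C", "CC", "CCC", "C(C)C")
_ARYL = ("c1ccccc1", "c1ccc(Cl)cc1", "c1ccc(C)cc1", "c1ccc([N+](=O)[O-])cc1", "c1ccc(OC)cc1")
_AMINE = ("NC", "NCC", "NC(C)C", "N(C)C")

_TEMPLATES: Mapping[str, tuple[str, ...]] = {
    "organochlorine": (
        "Clc1ccc({h})cc1Cl",
        "Clc1cc(Cl)c({h})c(Cl)c1",
        "ClC1CC({h})C(Cl)C(Cl)C1Cl",
        "Clc1ccc(C(c2ccc({h})cc2)C(Cl)Cl)cc1",
        "Oc1c(Cl)cc({h})c(Cl)c1Cl",
    ),
    "organophosphorus": (
        "{a1}OP(=S)(O{a2})O{ar}",
        "{a1}OP(=S)(O{a2})S{a3}",
        "{a1}OP(=O)(O{a2})O{ar}",
        "{a1}P(=S)(O{a2})S{ar}",
    ),
    "carbamate": (
        "CNC(=O)O{ar}",
        "CN(C)C(=O)O{ar}",
        "CCN(CC)C(=O)S{a1}",
        "CNC(=O)ON=C(C)S{a1}",
    ),
    "triazine": (
        "{s1}c1nc({m1})nc({m2})n1",
        "Clc1nc({m1})nc({m2})n1",
    ),
    "pyrethroid": (
        "CC1(C)C(C=C({h})Cl)C1C(=O)OC{ar}",
        "CC1(C)C(C=C(C)C)C1C(=O)OC{ar}",
        "CC1(C)C(C=C({h})Cl)C1C(=O)OC(C#N){ar}",
    ),
    "miscellaneous": (
        "OC(=O)CO{ar}",
        "CC(=O)N{ar}",
        "CN(C)C(=O)N{ar}",
        "OC(=O)C(C)O{ar}",
    ),
}


def _instantiate(rng: np.random.Generator, template: str) -> str:
    pick = lambda options: options[int(rng.integers(len(options)))]
    return template.format(
        h=pick(_HALO),
        a1=pick(_ALKYL),
        a2=pick(_ALKYL),
        a3=pick(_ALKYL),
        ar=pick(_ARYL),
        s1=pick(("Cl", "SC", "OC")),
        m1=pick(_AMINE),
        m2=pick(_AMINE),
    )


def _allocate(n: int, weights: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder allocation of n items to weighted classes."""
    total = sum(weights.values())
    raw = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_smiles_library(
    n: int | None = None,
    seed: int = 0,
    class_counts: Mapping[str, int] | None = None,
    n_oxon_pairs: int = 0,
) -> CompoundTable:
    """Generate ``n`` valid, class-labelled synthetic compounds.

    When ``class_counts`` is given it fixes the per-class counts exactly
    (and ``n`` is ignored); otherwise ``n`` compounds are allocated across
    the six classes in corpus-like proportions. ``n_oxon_pairs``
    thiophosphoryl organophosphorus parents (if available) additionally
    emit an oxon-metabolite row via :func:`oxonize`; oxon rows are appended
    beyond ``n``.
    """
    if class_counts is None:
        if n is None or n < 1:
            raise ValueError("need n >= 1 or explicit class_counts")
        class_counts = _allocate(n, DEFAULT_CLASS_WEIGHTS)
    rng = np.random.default_rng(seed)
    compounds: list[Compound] = []
    op_parents: list[int] = []
    i = 0
    for chem_class in sorted(class_counts):
        templates = _TEMPLATES[chem_class]
        for _ in range(class_counts[chem_class]):
            template = templates[int(rng.integers(len(templates)))]
            smiles = standardize_structure(_instantiate(rng, template))
            cid = f"syn-{i:04d}"
            compounds.append(
                Compound(id=cid, name=f"synthetic {chem_class} {i}", chem_class=chem_class, smiles=smiles, role="parent")
            )
            if chem_class == "organophosphorus" and "=S" in smiles.replace("(=S)", "=S"):
                op_parents.append(len(compounds) - 1)
            i += 1
    thio = [j for j in op_parents if "P" in compounds[j].smiles and "S" in compounds[j].smiles]
    for j in thio[:n_oxon_pairs]:
        parent = compounds[j]
        try:
            oxon_smiles = standardize_structure(oxonize(parent.smiles))
        except ValueError:
            continue
        compounds.append(
            Compound(
                id=f"{parent.id}-oxon",
                name=f"{parent.name} oxon",
                chem_class=parent.chem_class,
                smiles=oxon_smiles,
                role="oxon_metabolite",
                parent_id=parent.id,
            )
        )
    return CompoundTable(compounds=compounds, source=f"<synthetic seed={seed}>")
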