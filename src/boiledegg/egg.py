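"""Two-ellipse (BOILED-Egg) permeation classifier in (tPSA, WLogP) space.

A molecule is plotted at (tPSA, WLogP). Membership in the large "white"
ellipse predicts high human intestinal absorption (fraction absorbed
Fa ≥ 0.30); membership in the smaller "yolk" ellipse predicts brain
permeation (LogBB ≥ 0). The two regions are not mutually exclusive — the
yolk lies almost entirely inside the white — so both tests are evaluated
independently. Ellipse geometry is loaded from a versioned YAML config,
never hard-coded; a checksum of the config accompanies every output for
provenance.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .descriptors import DescriptorVector, compute_descriptors
from .io import CompoundTable

GI_HIGH, GI_LOW = "high", "low"
BBB_YES, BBB_NO = "yes", "no"


@dataclass(frozen=True)
class EllipseModel:
    """One ellipse in (tPSA, WLogP) space."""

    name: str
    center_tpsa: float
    center_wlogp: float
    semi_axis_tpsa: float
    semi_axis_wlogp: float
    rotation: float  # radians, tilt of the tPSA semi-axis
    interpretation: str = ""

    def __post_init__(self) -> None:
        if self.semi_axis_tpsa <= 0 or self.semi_axis_wlogp <= 0:
            raise ValueError(f"ellipse {self.name!r}: semi-axes must be positive")
        if not (-math.pi / 2 < self.rotation <= math.pi / 2):
            raise ValueError(f"ellipse {self.name!r}: rotation outside (-pi/2, pi/2]")

    def quadratic_form(self, tpsa, wlogp):
        """(u/a)^2 + (v/b)^2 in the rotated principal frame; <= 1 is inside."""
        dx = np.asarray(tpsa, dtype=float) - self.center_tpsa
        dy = np.asarray(wlogp, dtype=float) - self.center_wlogp
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.semi_axis_tpsa) ** 2 + (v / self.semi_axis_wlogp) ** 2

    def outline(self, n: int = 256) -> np.ndarray:
        """Sampled boundary polyline, shape (n, 2) as (tpsa, wlogp)."""
        t = np.linspace(0.0, 2.0 * math.pi, n)
        u = self.semi_axis_tpsa * np.cos(t)
        v = self.semi_axis_wlogp * np.sin(t)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.column_stack([self.center_tpsa + c * u - s * v, self.center_wlogp + s * u + c * v])


@dataclass(frozen=True)
class EggModel:
    """The intestinal + brain ellipse pair plus boundary convention."""

    intestinal: EllipseModel
    brain: EllipseModel
    boundary_inclusive: bool = True
    config_checksum: str = ""
    version: int = 1


def point_in_ellipse(tpsa: float, wlogp: float, ellipse: EllipseModel, inclusive: bool = True) -> bool:
    """True iff the point lies inside the ellipse (boundary counts as inside
    when ``inclusive``). Non-finite coordinates are a classification error."""
    if not (math.isfinite(tpsa) and math.isfinite(wlogp)):
        raise ValueError(f"non-finite point ({tpsa}, {wlogp})")
    q = float(ellipse.quadratic_form(tpsa, wlogp))
    return q <= 1.0 if inclusive else q < 1.0


def load_model(path: str | Path | None = None) -> EggModel:
    """Load an egg model from YAML; the bundled published geometry by default."""
    if path is None:
        raw = (resources.files("boiledegg") / "data" / "boiled_egg.yaml").read_bytes()
    else:
        raw = Path(path).read_bytes()
    cfg = yaml.safe_load(raw)
    to_rad = math.radians if cfg.get("rotation_units", "degrees") == "degrees" else float
    ellipses = {}
    for name in ("intestinal", "brain"):
        e = cfg["ellipses"][name]
        ellipses[name] = EllipseModel(
            name=name,
            center_tpsa=float(e["center"][0]),
            center_wlogp=float(e["center"][1]),
            semi_axis_tpsa=float(e["semi_axis_tpsa"]),
            semi_axis_wlogp=float(e["semi_axis_wlogp"]),
            rotation=to_rad(float(e["rotation"])),
            interpretation=e.get("interpretation", ""),
        )
    return EggModel(
        intestinal=ellipses["intestinal"],
        brain=ellipses["brain"],
        boundary_inclusive=bool(cfg.get("boundary_inclusive", True)),
        config_checksum=hashlib.sha256(raw).hexdigest()[:16],
        version=int(cfg.get("version", 1)),
    )


@dataclass(frozen=True)
class PermeationPrediction:
    """Two-label prediction for one compound."""

    compound_id: str
    tpsa: float
    wlogp: float
    gi_label: str  # "high" | "low"
    bbb_label: str  # "yes" | "no"


def classify_permeation(d: DescriptorVector, model: EggModel, compound_id: str = "") -> PermeationPrediction:
    """Assign GI and BBB labels from the two independent ellipse tests."""
    inc = model.boundary_inclusive
    gi = point_in_ellipse(d.tpsa, d.wlogp, model.intestinal, inclusive=inc)
    bbb = point_in_ellipse(d.tpsa, d.wlogp, model.brain, inclusive=inc)
    return PermeationPrediction(
        compound_id=compound_id,
        tpsa=d.tpsa,
        wlogp=d.wlogp,
        gi_label=GI_HIGH if gi else GI_LOW,
        bbb_label=BBB_YES if bbb else BBB_NO,
    )


def classify_table(
    table: CompoundTable,
    model: EggModel | None = None,
    include_sp: bool = True,
    with_mean_atomic: bool = True,
) -> pd.DataFrame:
    """Descriptor panel + egg labels for every compound of a table.

    Returns one row per compound with the full panel, ``gi_label`` and
    ``bbb_label``. Output metadata (tPSA setting, model checksum) is attached
    under ``frame.attrs``.
    """
    model = model or load_model()
    rows = []
    for c in table:
        d = compute_descriptors(c.mol(), include_sp=include_sp, with_mean_atomic=with_mean_atomic)
        pred = classify_permeation(d, model, compound_id=c.id)
        rows.append(
            {
                "id": c.id,
                "name": c.name,
                "chem_class": c.chem_class,
                "role": c.role,
                "parent_id": c.parent_id,
                **d.as_dict(),
                "gi_label": pred.gi_label,
                "bbb_label": pred.bbb_label,
            }
        )
    if rows:
        frame = pd.DataFrame(rows)
    else:
        from dataclasses import fields as dc_fields

        from .descriptors import DescriptorVector

        frame = pd.DataFrame(
            columns=["id", "name", "chem_class", "role", "parent_id"]
            + [f.name for f in dc_fields(DescriptorVector)]
            + ["gi_label", "bbb_label"]
        )
    frame.attrs["tpsa_includes_sp"] = include_sp
    frame.attrs["model_checksum"] = model.config_checksum
    return frame


def egg_plot_data(predictions: pd.DataFrame, model: EggModel, n_arc: int = 256) -> dict:
    """Serializable plot specification: ellipse outlines, points, axis ranges."""
    if len(predictions) == 0:
        raise ValueError("need at least one prediction to plot")
    pts = predictions[["tpsa", "wlogp"]].to_numpy(dtype=float)
    outlines = {
        "intestinal": model.intestinal.outline(n_arc).tolist(),
        "brain": model.brain.outline(n_arc).tolist(),
    }
    all_x = np.concatenate([pts[:, 0], model.intestinal.outline(8)[:, 0]])
    all_y = np.concatenate([pts[:, 1], model.intestinal.outline(8)[:, 1]])
    pad_x = 0.05 * (all_x.max() - all_x.min() + 1.0)
    pad_y = 0.05 * (all_y.max() - all_y.min() + 1.0)
    return {
        "outlines": outlines,
        "points": pts.tolist(),
        "ids": list(predictions["id"]) if "id" in predictions else [],
        "xlim": [float(all_x.min() - pad_x), float(all_x.max() + pad_x)],
        "ylim": [float(all_y.min() - pad_y), float(all_y.max() + pad_y)],
        "xlabel": "tPSA (Å²)",
        "ylabel": "WLogP",
        "model_checksum": model.config_checksum,
    }


def plot_egg(predictions: pd.DataFrame, model: EggModel, path: str | Path) -> Path:
    """Render the egg plot (grey intestinal region, yellow brain region,
    one black dot per compound) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = egg_plot_data(predictions, model)
    fig, ax = plt.subplots(figsize=(7, 5))
    white = np.asarray(spec["outlines"]["intestinal"])
    yolk = np.asarray(spec["outlines"]["brain"])
    ax.fill(white[:, 0], white[:, 1], color="0.85", zorder=1, label="high GI absorption")
    ax.fill(yolk[:, 0], yolk[:, 1], color="gold", zorder=2, label="brain-permeant")
    pts = np.asarray(spec["points"])
    ax.scatter(pts[:, 0], pts[:, 1], s=12, c="black", zorder=3)
    ax.set_xlim(spec["xlim"])
    ax.set_ylim(spec["ylim"])
    ax.set_xlabel(spec["xlabel"])
    ax.set_ylabel(spec["ylabel"])
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def classify_points(
    tpsa: Sequence[float] | np.ndarray,
    wlogp: Sequence[float] | np.ndarray,
    model: EggModel,
) -> pd.DataFrame:
    """Vectorised labelling of bare (tPSA, WLogP) points (no molecules needed)."""
    tpsa = np.asarray(tpsa, dtype=float)
    wlogp = np.asarray(wlogp, dtype=float)
    if not (np.isfinite(tpsa).all() and np.isfinite(wlogp).all()):
        raise ValueError("non-finite point coordinates")
    qi = model.intestinal.quadratic_form(tpsa, wlogp)
    qb = model.brain.quadratic_form(tpsa, wlogp)
    inc = model.boundary_inclusive
    gi = qi <= 1.0 if inc else qi < 1.0
    bbb = qb <= 1.0 if inc else qb < 1.0
    return pd.DataFrame(
        {
            "tpsa": tpsa,
            "wlogp": wlogp,
            "gi_label": np.where(gi, GI_HIGH, GI_LOW),
            "bbb_label": np.where(bbb, BBB_YES, BBB_NO),
        }
    )
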