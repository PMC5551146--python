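"""Ellipse-membership classifier: geometry oracles, labels, plot data."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boiledegg import (
    classify_permeation,
    classify_points,
    classify_table,
    compute_descriptors,
    egg_plot_data,
    load_model,
    plot_egg,
    point_in_ellipse,
)
from boiledegg.egg import EllipseModel
from boiledegg.io import compounds_from_records

TILTED = EllipseModel(
    name="tilted", center_tpsa=50.0, center_wlogp=2.0,
    semi_axis_tpsa=30.0, semi_axis_wlogp=3.0, rotation=math.radians(20.0),
)


def brute_force_inside(x, y, e: EllipseModel) -> bool:
    """Independent membership formula: rotate into the principal frame with
    an explicit rotation matrix, then compare against the axis equation."""
    R = np.array([[math.cos(-e.rotation), -math.sin(-e.rotation)],
                  [math.sin(-e.rotation), math.cos(-e.rotation)]])
    u, v = R @ np.array([x - e.center_tpsa, y - e.center_wlogp])
    return (u / e.semi_axis_tpsa) ** 2 + (v / e.semi_axis_wlogp) ** 2 <= 1.0


def test_center_is_inside(model):
    for e in (model.intestinal, model.brain, TILTED):
        assert point_in_ellipse(e.center_tpsa, e.center_wlogp, e)


def test_displacement_beyond_semi_axis_is_outside():
    e = EllipseModel(name="t", center_tpsa=10, center_wlogp=1, semi_axis_tpsa=5, semi_axis_wlogp=2, rotation=0.0)
    assert not point_in_ellipse(10 + 5.001, 1.0, e)
    assert not point_in_ellipse(10.0, 1 + 2.001, e)
    # exactly on the boundary counts as inside by default, not with inclusive=False
    assert point_in_ellipse(15.0, 1.0, e)
    assert not point_in_ellipse(15.0, 1.0, e, inclusive=False)


@pytest.mark.parametrize("ellipse_name", ["intestinal", "brain", "tilted"])
def test_membership_matches_brute_force_grid(model, ellipse_name):
    """Dense 200x200 rasterization: implementation vs independent formula."""
    e = {"intestinal": model.intestinal, "brain": model.brain, "tilted": TILTED}[ellipse_name]
    xs = np.linspace(e.center_tpsa - 1.5 * e.semi_axis_tpsa, e.center_tpsa + 1.5 * e.semi_axis_tpsa, 200)
    ys = np.linspace(e.center_wlogp - 1.5 * e.semi_axis_wlogp, e.center_wlogp + 1.5 * e.semi_axis_wlogp, 200)
    disagreements = sum(
        point_in_ellipse(x, y, e) != brute_force_inside(x, y, e) for x in xs for y in ys
    )
    assert disagreements == 0


def test_non_finite_point_is_classification_error(model):
    with pytest.raises(ValueError):
        point_in_ellipse(float("nan"), 1.0, model.intestinal)
    with pytest.raises(ValueError):
        classify_points([1.0, float("inf")], [0.0, 0.0], model)


@given(
    x=st.floats(-50, 250), y=st.floats(-8, 12),
    t=st.floats(0.0, 1.0),
    which=st.sampled_from(["intestinal", "brain", "tilted"]),
)
def test_radial_shrink_never_leaves_ellipse(x, y, t, which):
    """Moving a point radially toward the center never flips inside → outside."""
    model = load_model()
    e = {"intestinal": model.intestinal, "brain": model.brain, "tilted": TILTED}[which]
    if point_in_ellipse(x, y, e):
        sx = e.center_tpsa + t * (x - e.center_tpsa)
        sy = e.center_wlogp + t * (y - e.center_wlogp)
        assert point_in_ellipse(sx, sy, e)


@pytest.mark.parametrize(
    "smiles,gi,bbb",
    [
        ("ClC1C(Cl)C(Cl)C(Cl)C(Cl)C1Cl", "low", "yes"),   # lindane: the GI-low/BBB-yes sliver
        ("CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl", "high", "no"),  # chlorpyrifos parent
        ("CCOP(=O)(OCC)Oc1nc(Cl)c(Cl)cc1Cl", "high", "yes"),  # chlorpyrifos-oxon
        ("C[n+]1ccc(-c2cc[n+](C)cc2)cc1", "low", "no"),   # paraquat
    ],
)
def test_reference_compound_labels(model, smiles, gi, bbb):
    pred = classify_permeation(compute_descriptors(smiles), model)
    assert (pred.gi_label, pred.bbb_label) == (gi, bbb)


def test_classification_order_and_dialect_invariance(model):
    recs = [
        {"id": "a", "smiles": "c1ccccc1O"},
        {"id": "b", "smiles": "OC1=CC=CC=C1"},  # same molecule, Kekulé dialect
        {"id": "c", "smiles": "CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl"},
    ]
    fwd = classify_table(compounds_from_records(recs), model).set_index("id")
    rev = classify_table(compounds_from_records(recs[::-1]), model).set_index("id")
    for cid in ("a", "b", "c"):
        assert fwd.loc[cid, "gi_label"] == rev.loc[cid, "gi_label"]
        assert fwd.loc[cid, "bbb_label"] == rev.loc[cid, "bbb_label"]
    assert fwd.loc["a", "gi_label"] == fwd.loc["b", "gi_label"]
    assert fwd.loc["a", "wlogp"] == fwd.loc["b", "wlogp"]


def test_model_loaded_from_config_with_checksum(model):
    assert model.config_checksum and len(model.config_checksum) == 16
    assert model.boundary_inclusive
    # geometry invariants from the config contract
    for e in (model.intestinal, model.brain):
        assert e.semi_axis_tpsa > 0 and e.semi_axis_wlogp > 0
        assert -math.pi / 2 < e.rotation <= math.pi / 2


def test_invalid_ellipse_rejected():
    with pytest.raises(ValueError):
        EllipseModel(name="bad", center_tpsa=0, center_wlogp=0, semi_axis_tpsa=-1, semi_axis_wlogp=1, rotation=0.0)


def test_egg_plot_data_and_render(tmp_path, model):
    recs = [{"id": "center", "smiles": "CCO"}]
    preds = classify_table(compounds_from_records(recs), model)
    spec = egg_plot_data(preds, model)
    assert set(spec["outlines"]) == {"intestinal", "brain"}
    assert len(spec["outlines"]["intestinal"]) == 256
    assert spec["xlim"][0] < spec["points"][0][0] < spec["xlim"][1]
    out = plot_egg(preds, model, tmp_path / "egg.svg")
    assert out.is_file() and out.stat().st_size > 0
    with pytest.raises(ValueError):
        egg_plot_data(preds.iloc[:0], model)
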