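"""Confrontation of predicted and measured human intestinal absorption.

Literature Fa values are curated per compound: a range reported for one
ingested dose collapses to its median (midpoint), several studies/doses
average to their mean, and the final value is dichotomised at the
Fa ≥ 0.30 cutoff (boundary counts as high). Published inequality-only
values ("Fa > 0.48", "Fa ≤ 0.05") are accepted when the bound alone decides
the label — every bound in the curated pesticide set does. Accuracy is the
percentage of compounds whose predicted and measured labels agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

FA_CUTOFF = 0.30

HIGH, LOW = "high", "low"

#: qualifiers accepted for single literature values
_QUALIFIERS = ("=", ">", ">=", "<", "<=")


class CurationError(ValueError):
    """Measured-Fa entries cannot be curated into a label."""


@dataclass(frozen=True)
class FaEntry:
    """One per-study literature value: a point value, a range, or a bound."""

    value: float | None = None
    lo: float | None = None
    hi: float | None = None
    qualifier: str = "="

    def resolve(self) -> float:
        """Collapse to a single Fa value (range → median)."""
        if self.lo is not None or self.hi is not None:
            if self.lo is None or self.hi is None or not (0.0 <= self.lo <= self.hi <= 1.0):
                raise CurationError(f"invalid range ({self.lo}, {self.hi})")
            return 0.5 * (self.lo + self.hi)
        if self.value is None or not (0.0 <= self.value <= 1.0):
            raise CurationError(f"invalid Fa value {self.value}")
        return self.value


@dataclass(frozen=True)
class MeasuredAbsorption:
    compound_id: str
    fa_values: tuple[float, ...]
    fa_final: float
    measured_label: str
    from_bound: bool = False


def _bound_label(value: float, qualifier: str) -> str | None:
    """Label decided by an inequality bound alone, or None if indecisive."""
    if qualifier in (">", ">=") and value >= FA_CUTOFF:
        return HIGH
    if qualifier == "<" and value <= FA_CUTOFF:
        return LOW
    if qualifier == "<=" and value < FA_CUTOFF:
        return LOW
    return None


def curate_measured_fa(
    compound_id: str,
    entries: Sequence[FaEntry | float | tuple[float, float]],
    qualifier: str = "=",
) -> MeasuredAbsorption:
    """Curate per-study Fa entries into a final value and high/low label.

    ``entries`` may mix plain floats, ``(lo, hi)`` ranges and
    :class:`FaEntry` objects. A ``qualifier`` other than ``"="`` is only
    meaningful for a single entry and must decide the label by itself.
    """
    if not entries:
        raise CurationError(f"{compound_id}: no measured Fa entries")
    norm: list[FaEntry] = []
    for e in entries:
        if isinstance(e, FaEntry):
            norm.append(e)
        elif isinstance(e, tuple):
            norm.append(FaEntry(lo=e[0], hi=e[1]))
        else:
            norm.append(FaEntry(value=float(e)))
    if qualifier not in _QUALIFIERS:
        raise CurationError(f"{compound_id}: unknown qualifier {qualifier!r}")
    values = tuple(e.resolve() for e in norm)
    fa_final = sum(values) / len(values) if len(values) > 1 else values[0]
    if qualifier != "=":
        if len(values) != 1:
            raise CurationError(f"{compound_id}: an inequality bound needs a single entry")
        label = _bound_label(fa_final, qualifier)
        if label is None:
            raise CurationError(
                f"{compound_id}: bound '{qualifier} {fa_final}' does not decide the high/low label"
            )
        return MeasuredAbsorption(compound_id, values, fa_final, label, from_bound=True)
    label = HIGH if fa_final >= FA_CUTOFF else LOW
    return MeasuredAbsorption(compound_id, values, fa_final, label)


@dataclass(frozen=True)
class AccuracyResult:
    n_total: int
    n_concordant: int
    discordant: tuple[str, ...] = field(default=())

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_concordant / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_concordant": self.n_concordant,
            "accuracy_pct": self.accuracy,
            "discordant": list(self.discordant),
        }


def confront(
    measured: Iterable[MeasuredAbsorption],
    predictions: pd.DataFrame | Mapping[str, str],
) -> AccuracyResult:
    """Count agreement between measured high/low labels and predicted GI labels.

    ``predictions`` is either the frame from :func:`boiledegg.egg.classify_table`
    (``id`` + ``gi_label`` columns) or a plain id → label mapping. Every
    measured compound must have a prediction.
    """
    if isinstance(predictions, pd.DataFrame):
        pred_map = dict(zip(predictions["id"].astype(str), predictions["gi_label"]))
    else:
        pred_map = dict(predictions)
    measured = list(measured)
    if not measured:
        raise ValueError("no measured compounds")
    discordant = []
    for m in measured:
        if m.compound_id not in pred_map:
            raise KeyError(f"no prediction for measured compound {m.compound_id!r}")
        if pred_map[m.compound_id] != m.measured_label:
            discordant.append(m.compound_id)
    return AccuracyResult(
        n_total=len(measured),
        n_concordant=len(measured) - len(discordant),
        discordant=tuple(sorted(discordant)),
    )


def measured_from_frame(frame: pd.DataFrame) -> list[MeasuredAbsorption]:
    """Curate a measured-Fa table (columns: id, fa, fa_qualifier) row by row."""
    out = []
    for _, row in frame.iterrows():
        out.append(
            curate_measured_fa(
                str(row["id"]),
                [float(row["fa"])],
                qualifier=str(row.get("fa_qualifier", "=") or "="),
            )
        )
    return out
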