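"""Cohort-level aggregation and descriptor-association statistics.

Two kinds of outputs:

* per-class summaries of the predicted GI/BBB labels (counts and
  percentages, with class-level percentages conventionally printed to the
  integer and corpus-level ones to one decimal);
* per-descriptor two-group comparisons between predicted permeant and
  non-permeant compounds, by the classical pooled-variance Student's t test
  (two-sided, significance at p < 0.05, no multiple-testing correction —
  the faithful-reproduction convention of the analysis this package
  implements). Welch's unequal-variance variant is available behind a flag
  for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: descriptor columns compared between groups by default (internally computable panel)
DEFAULT_PARAMETERS = (
    "mw",
    "mv_mean_vdw",
    "mp_mean_polarizability",
    "n_heavy",
    "n_aromatic_heavy",
    "frac_csp3",
    "n_rotatable",
    "n_hba",
    "n_hbd",
    "molar_refractivity",
    "tpsa",
    "n_NO",
)


@dataclass(frozen=True)
class ClassSummary:
    chem_class: str
    n_total: int
    n_gi_high: int
    n_bbb_yes: int

    @property
    def pct_gi_high(self) -> float:
        return 100.0 * self.n_gi_high / self.n_total

    @property
    def pct_bbb_yes(self) -> float:
        return 100.0 * self.n_bbb_yes / self.n_total


def summarize_by_class(predictions: pd.DataFrame, class_column: str = "chem_class") -> pd.DataFrame:
    """One row per chemical class plus an ``all`` row.

    ``pct_*`` columns carry unrounded percentages; ``pct_*_printed`` applies
    the reporting convention (integer for classes, one decimal for the
    ``all`` row). Empty classes are excluded with a warning.
    """
    req = {class_column, "gi_label", "bbb_label"}
    if not req.issubset(predictions.columns):
        raise KeyError(f"predictions must carry columns {sorted(req)}")
    rows: list[dict] = []
    for cls, sub in predictions.groupby(class_column, sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby drops empty groups
            logger.warning("class %r empty; excluded", cls)
            continue
        rows.append(_summary_row(str(cls), sub, printed_decimals=0))
    rows.append(_summary_row("all", predictions, printed_decimals=1))
    return pd.DataFrame(rows)


def _summary_row(label: str, sub: pd.DataFrame, printed_decimals: int) -> dict:
    s = ClassSummary(
        chem_class=label,
        n_total=len(sub),
        n_gi_high=int((sub["gi_label"] == "high").sum()),
        n_bbb_yes=int((sub["bbb_label"] == "yes").sum()),
    )
    fmt = f"{{:.{printed_decimals}f}}"
    return {
        "chem_class": s.chem_class,
        "n_total": s.n_total,
        "n_gi_high": s.n_gi_high,
        "pct_gi_high": s.pct_gi_high,
        "n_bbb_yes": s.n_bbb_yes,
        "pct_bbb_yes": s.pct_bbb_yes,
        "pct_gi_high_printed": fmt.format(round(s.pct_gi_high, printed_decimals)),
        "pct_bbb_yes_printed": fmt.format(round(s.pct_bbb_yes, printed_decimals)),
    }


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one descriptor."""

    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    flagged: bool = False  # degenerate case (zero variance in both groups)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _student_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float, bool]:
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), False


def compare_groups(
    frame: pd.DataFrame,
    group_labels: Sequence[str] | pd.Series,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    group_a: str | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-parameter Student's t comparison between two labelled groups.

    ``group_labels`` must take exactly two distinct values (e.g.
    ``permeant`` / ``non-permeant``). ``group_a`` fixes which label is
    reported first; by default the labels are taken in sorted order.
    Parameters with fewer than two finite values in either group are skipped
    with a warning.
    """
    labels = pd.Series(list(group_labels), index=frame.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    if group_a is not None:
        uniq = [group_a] + [u for u in uniq if u != group_a]
    la, lb = uniq
    rows = []
    for param in parameters:
        if param not in frame.columns:
            logger.warning("parameter %r absent; skipped", param)
            continue
        col = pd.to_numeric(frame[param], errors="coerce")
        a = col[labels == la].dropna().to_numpy(dtype=float)
        b = col[labels == lb].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("parameter %r: fewer than 2 finite values in a group; skipped", param)
            continue
        t, p, flagged = _student_t(a, b, welch)
        c = GroupComparison(
            parameter=param,
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
            t=t, p=p, flagged=flagged,
        )
        rows.append(
            {
                "parameter": c.parameter,
                "group_a": la, "mean_a": c.mean_a, "sd_a": c.sd_a, "n_a": c.n_a,
                "group_b": lb, "mean_b": c.mean_b, "sd_b": c.sd_b, "n_b": c.n_b,
                "t": c.t, "p": c.p, "significant": c.significant, "flagged": c.flagged,
            }
        )
    return pd.DataFrame(rows)


def pooled_t_statistic(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Closed-form pooled-variance Student t and two-sided p.

    Kept as an explicit formula (pooled s², t = Δmean / (s·√(1/n₁+1/n₂)),
    df = n₁+n₂−2) so callers can cross-check the table-driven route.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def oxon_comparison(
    predictions: pd.DataFrame,
    pairing: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Parent vs oxon-metabolite brain-permeation table.

    ``predictions`` must contain both parents and their oxon metabolites.
    The pairing is either given explicitly (parent id → oxon id) or read
    from the ``role``/``parent_id`` columns. Returns the paired table
    (parent name, parent bbb label, oxon bbb label) and the percentage of
    brain-permeant oxons. Unpaired oxons are an error listing the offenders.
    """
    by_id = predictions.set_index("id", drop=False)
    if pairing is None:
        if "role" not in predictions.columns:
            raise ValueError("no pairing given and no 'role' column present")
        oxons = predictions[predictions["role"] == "oxon_metabolite"]
        missing = [str(r["id"]) for _, r in oxons.iterrows() if not r.get("parent_id")]
        if missing:
            raise ValueError(f"oxon metabolites without parent_id: {missing}")
        pairing = {str(r["parent_id"]): str(r["id"]) for _, r in oxons.iterrows()}
    unknown = [pid for pid in pairing if pid not in by_id.index] + [
        oid for oid in pairing.values() if oid not in by_id.index
    ]
    if unknown:
        raise ValueError(f"pairing references unknown compound ids: {sorted(set(unknown))}")
    rows = []
    for pid, oid in pairing.items():
        rows.append(
            {
                "parent_id": pid,
                "parent_name": by_id.loc[pid, "name"],
                "parent_bbb": by_id.loc[pid, "bbb_label"],
                "oxon_id": oid,
                "oxon_bbb": by_id.loc[oid, "bbb_label"],
            }
        )
    table = pd.DataFrame(rows).sort_values("parent_name").reset_index(drop=True)
    pct_oxon_yes = 100.0 * (table["oxon_bbb"] == "yes").mean()
    return table, float(pct_oxon_yes)
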