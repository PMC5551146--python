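"""Bundled curated datasets.

Two small tables ship with the package so the headline analyses run
offline:

* ``oxon_pairs`` — 15 thiophosphoryl organophosphorus pesticides and their
  15 oxon metabolites (the P=S → P=O bioactivation products), for the
  parent-versus-oxon brain-permeation comparison.
* ``measured_fa`` — 25 pesticides with a curated measured human fraction
  absorbed (point values or literature bounds with their qualifier), for
  the predicted-versus-measured confrontation.

Fa values and their qualifiers are transcribed from published human
pharmacokinetics curation; the structures are the standard public
structures of these well-characterised pesticides (curated offline, no
live database lookup), each checked against its known molecular formula.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io import CompoundTable, read_compound_table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("boiledegg") / "data" / name))


def load_oxon_pairs() -> CompoundTable:
    """15 organophosphorus parents + their 15 oxon metabolites."""
    table = read_compound_table(_data_path("oxon_pairs.csv"))
    assert table.n_rejected == 0
    return table


def load_measured_fa() -> tuple[CompoundTable, pd.DataFrame]:
    """25 pesticides with measured human Fa.

    Returns the compound table and the raw measured-Fa frame (columns
    ``id``, ``fa``, ``fa_qualifier``, ...) for
    :func:`boiledegg.confrontation.measured_from_frame`.
    """
    path = _data_path("measured_fa.csv")
    table = read_compound_table(path)
    assert table.n_rejected == 0
    frame = pd.read_csv(path)
    return table, frame
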