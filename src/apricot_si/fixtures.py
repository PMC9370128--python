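"""Packaged reference datasets.

The package ships four transcribed reference tables:

* ``compiled_si_table1`` — 103 self-incompatible / unclassified cultivars
  with their incompatibility-group genotypes,
* ``compiled_sc_table2`` — 153 self-compatible cultivars,
* ``study66`` — the 66-cultivar study subset (the ``source == "study"``
  rows of the two compilations),
* ``panel`` — the five-assay genotyping primer panel, and
* ``registry`` — the historical genotype → incompatibility-group register
  (Roman-numeral groups I–XXVI present in the compilation, plus the
  group-0 singleton genotypes).
"""

from __future__ import annotations

from importlib import resources

from .core import CultivarRecord, GroupRegistry, PrimerAssayDef
from .io import read_cultivar_table, read_panel, read_registry

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = ("study66", "compiled_si_table1", "compiled_sc_table2", "panel", "registry")

_FILES = {
    "compiled_si_table1": "table1_incompatible.csv",
    "compiled_sc_table2": "table2_compatible.csv",
    "panel": "panel.csv",
    "registry": "registry.csv",
}


def _path(filename: str):
    return resources.files("apricot_si.data").joinpath(filename)


def load_fixture(
    which: str,
) -> list[CultivarRecord] | list[PrimerAssayDef] | GroupRegistry:
    """Load one packaged dataset by name (see :data:`FIXTURES`)."""
    if which == "study66":
        # study subset preserves table order: Table 1 study rows then Table 2
        records = [
            r
            for name in ("compiled_si_table1", "compiled_sc_table2")
            for r in load_fixture(name)
        ]
        return [r for r in records if r.source == "study"]
    if which not in _FILES:
        raise ValueError(f"unknown fixture {which!r}; choose from {FIXTURES}")
    path = _path(_FILES[which])
    with path.open("r", encoding="utf-8", newline="") as fh:
        if which == "panel":
            return read_panel(fh)
        if which == "registry":
            return read_registry(fh)
        return read_cultivar_table(fh)
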