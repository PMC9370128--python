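#!/usr/bin/env python
"""Export the packaged reference tables as plain CSVs.

Writes the two cultivar compilations (103 self-incompatible /
unclassified, 153 self-compatible), the 66-cultivar study subset, the
genotyping primer panel and the incompatibility-group registry to
results/fixtures/ and prints their record counts.
"""

from pathlib import Path

from apricot_si.fixtures import FIXTURES, load_fixture
from apricot_si.io import write_cultivar_table, write_panel, write_registry

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in FIXTURES:
        data = load_fixture(name)
        path = OUT / f"{name}.csv"
        if name == "panel":
            write_panel(data, path)
        elif name == "registry":
            write_registry(data, path)
        else:
            write_cultivar_table(data, path)
        print(f"{name:22s} {len(data):4d} entries -> {path}")


if __name__ == "__main__":
    main()
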