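#!/usr/bin/env python
"""Self-(in)compatibility classification and incompatibility groups.

Classifies the 66-cultivar study cohort (re-deriving the two
microscopy-resolved Sc/S8 calls from simulated pistil observations),
allocates the compiled self-incompatible cultivars to their
cross-incompatibility groups, and writes the study cohort's donor ×
pistil pollinizer matrix. Outputs under results/.
"""

import json
from pathlib import Path

from apricot_si.compat import assign_groups, pollinizer_matrix
from apricot_si.fixtures import load_fixture
from apricot_si.workflow import previous_group_assignment, study_classification

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    study = study_classification(seed=SEED)
    counts = {k.value: v for k, v in sorted(study.counts.items(), key=lambda kv: kv[0].value)}
    print("study cohort classification:", counts)
    for name, genotype in study.resolved_genotypes.items():
        print(f"  microscopy-resolved: {name} -> {genotype}")
    (OUT / "study_classification.json").write_text(
        json.dumps(
            {
                "counts": counts,
                "calls": {
                    n: {"call": c.call.value, "basis": c.basis.value}
                    for n, c in study.calls.items()
                },
            },
            indent=2,
            ensure_ascii=False,
        ),
        encoding="utf-8",
    )

    table1 = load_fixture("compiled_si_table1")
    registry = load_fixture("registry")
    full = assign_groups(table1, registry)
    prev = previous_group_assignment()
    print(
        f"group allocation: {len(full.groups)} compiled cultivars assigned "
        f"({len(prev.groups)} from previous studies), "
        f"{len(full.unclassified)} unclassified"
    )
    (OUT / "group_assignment.json").write_text(
        json.dumps(
            {
                "assigned": full.groups,
                "unclassified": full.unclassified,
                "n_assigned_previous_studies": len(prev.groups),
            },
            indent=2,
            ensure_ascii=False,
        ),
        encoding="utf-8",
    )

    matrix = pollinizer_matrix(load_fixture("study66"))
    matrix.to_csv(OUT / "pollinizer_matrix_study66.csv")
    frac_f = (matrix.values == "F").mean()
    print(
        f"pollinizer matrix: {matrix.shape[0]}x{matrix.shape[1]} verdicts, "
        f"{100 * frac_f:.0f}% fully compatible"
    )


if __name__ == "__main__":
    main()
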