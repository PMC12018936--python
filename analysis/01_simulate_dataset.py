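#!/usr/bin/env python
"""Generate the synthetic crocodyliform dataset every later step consumes.

Emulates the study's data structure at desk scale: a fossil-rich birth-death
tree, a discrete morphological matrix with ordered morphoclines / missing /
polymorphic scores, FAD-LAD tip ages, extant head-width & total-length
specimens, and fossil head widths with the true total lengths withheld.
Also writes the molecular-scaffold constraint: the true tree restricted to
its extant tips.

Writes results/synthetic/{matrix.tnt, true_tree.nwk, scaffold.nwk, ages.csv,
extant.csv, fossil.csv, truth.json}.
"""

import json
from pathlib import Path

from paleocroc import io_formats as io
from paleocroc import synthetic_data as S
from paleocroc.parsimony import restrict_tree

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = S.paper_like_preset(SEED)
    tree, ages = S.simulate_tree(cfg)
    matrix = S.simulate_matrix(tree, cfg)
    records, fossil_hw, truth = S.simulate_allometry(tree, cfg)

    io.write_tnt_matrix(matrix, OUT / "matrix.tnt")
    io.write_newick(tree, OUT / "true_tree.nwk")
    io.write_age_table(ages, OUT / "ages.csv")
    io.write_allometry_table(records, OUT / "extant.csv")
    io.write_allometry_table(
        [io.AllometryRecord(t, "1", hw) for t, hw in sorted(fossil_hw.items())],
        OUT / "fossil.csv",
    )
    extant_taxa = frozenset({r.taxon for r in records})
    scaffold = restrict_tree(tree, extant_taxa)
    io.write_newick(scaffold, OUT / "scaffold.nwk", branch_lengths=False)
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    n_missing = sum(not c for row in matrix.cells for c in row)
    print(f"matrix: {matrix.n_taxa} taxa x {matrix.n_chars} characters "
          f"({sum(matrix.ordered)} ordered, "
          f"{100 * n_missing / (matrix.n_taxa * matrix.n_chars):.0f}% missing)")
    print(f"tips: {len(extant_taxa)} extant, {len(fossil_hw)} fossil")
    print(f"allometry: {len(records)} extant specimens; "
          f"truth slope={truth['slope']}, lambda={truth['lam']}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
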