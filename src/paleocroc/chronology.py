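"""Minimum-branch-length (mbl) time calibration of a cladogram.

Given a rooted topology and first/last appearance ages for every tip, each
node is first dated to the oldest age among its descendant tips and then
pushed back so that every branch is at least ``min_branch`` Myr long.  The
result is the pointwise-minimal assignment of node ages satisfying

* node age >= oldest descendant tip age, and
* parent age >= child age + ``min_branch``,

with every tip held exactly at its assigned age.  Ages are Ma before
present, branch durations Myr.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

TOL = 1e-9


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationConfig:
    """Calibration settings.

    ``min_branch``: minimum branch duration, Myr (5 for the body-size
    analysis tree, 1 for display trees).  ``tip_age_rule``: which point of
    the FAD-LAD range dates each tip; first appearances (FAD) by default.
    """

    min_branch: float = 5.0
    tip_age_rule: str = "FAD"

    def __post_init__(self) -> None:
        if not self.min_branch > 0:
            raise ValueError("min_branch must be > 0")
        if self.tip_age_rule not in ("FAD", "LAD", "midpoint"):
            raise ValueError("tip_age_rule must be FAD, LAD or midpoint")


def tip_ages_from_table(ages: pd.DataFrame, rule: str = "FAD") -> dict[str, float]:
    """Per-taxon point age (Ma) from a FAD/LAD table under *rule*."""
    out: dict[str, float] = {}
    for _, row in ages.iterrows():
        fad, lad = float(row["fad"]), float(row["lad"])
        if rule == "FAD":
            age = fad
        elif rule == "LAD":
            age = lad
        else:
            age = 0.5 * (fad + lad)
        out[str(row["taxon"])] = age
    return out


def calibrate_mbl(
    topology: dendropy.Tree,
    ages: pd.DataFrame | dict[str, float],
    config: CalibrationConfig | None = None,
) -> dendropy.Tree:
    """Time-calibrate *topology* with the mbl rule.

    Returns a copy of the tree with ``node.age`` (Ma) set on every node and
    ``edge.length`` set to the branch duration (Myr).  Polytomies are
    calibrated as-is.  Raises :class:`CalibrationError` naming the tip if an
    age is missing.
    """
    if config is None:
        config = CalibrationConfig()
    tip_age = (
        tip_ages_from_table(ages, config.tip_age_rule)
        if isinstance(ages, pd.DataFrame)
        else dict(ages)
    )
    tree = topology.clone(depth=1)
    m = config.min_branch
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            if label not in tip_age:
                raise CalibrationError(f"no age for tip {label!r}")
            nd.age = float(tip_age[label])
        else:
            nd.age = max(c.age + m for c in nd.child_nodes())
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
    tree.seed_node.edge.length = None
    return tree


def validate_time_tree(tree: dendropy.Tree, min_branch: float) -> None:
    """Raise CalibrationError if the time-tree invariants are violated."""
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.parent_node.age < nd.age - TOL:
            raise CalibrationError("parent younger than child")
        if nd.edge.length is None or nd.edge.length < min_branch - TOL:
            raise CalibrationError("branch shorter than the configured minimum")
        if abs((nd.parent_node.age - nd.age) - nd.edge.length) > 1e-6:
            raise CalibrationError("edge length inconsistent with node ages")
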