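"""Body-size categories, ancestral-state reconstruction and size reduction.

Total lengths are binned into the four study categories (upper-inclusive
bounds, cm): small (0, 150], medium (150, 400], large (400, 700], gigantic
(700, inf).  Finer, fixed-width bins (50 cm by default) serve ancestral-state
plotting of mean total length.

Ancestral bins are reconstructed by ordered (Wagner) parsimony, adjacent
bins one step apart; the binary osmoregulation character (saltwater-tolerant
vs freshwater-only, coded from salt-gland, isotopic and occurrence proxies)
by Fitch parsimony.  Both return full MPR sets per node.  Parsimony ASR is
branch-length-free, so the "equal branch length" display convention of the
source figures needs no special handling here.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import dendropy

from .io_formats import MISSING, CharacterMatrix
from .parsimony import CostModel, mpr_states

logger = logging.getLogger(__name__)

SIZE_BIN_NAMES = ("small", "medium", "large", "gigantic")
#: upper bound of each category, cm (upper-inclusive)
SIZE_BIN_UPPER = (150.0, 400.0, 700.0, math.inf)

SALTWATER = "saltwater_tolerant"
FRESHWATER = "freshwater_only"
UNKNOWN = "unknown"


class SizeError(ValueError):
    pass


def classify_size(tl_cm: float) -> str:
    """Size category of a total length in cm (upper-inclusive bounds)."""
    if not tl_cm > 0:
        raise SizeError(f"total length must be positive, got {tl_cm}")
    for name, upper in zip(SIZE_BIN_NAMES, SIZE_BIN_UPPER):
        if tl_cm <= upper:
            return name
    raise AssertionError("unreachable")


def size_bin_index(tl_cm: float) -> int:
    return SIZE_BIN_NAMES.index(classify_size(tl_cm))


def fine_bin_index(tl_cm: float, width_cm: float = 50.0) -> int:
    """Index of the fixed-width bin holding *tl_cm* (upper-inclusive)."""
    if not tl_cm > 0:
        raise SizeError(f"total length must be positive, got {tl_cm}")
    return max(int(math.ceil(tl_cm / width_cm)) - 1, 0)


def fine_bin_bounds(index: int, width_cm: float = 50.0) -> tuple[float, float]:
    return (index * width_cm, (index + 1) * width_cm)


def fine_bin_label(index: int, width_cm: float = 50.0) -> str:
    lo, hi = fine_bin_bounds(index, width_cm)
    return f"{lo:g}-{hi:g}"


def _single_char_matrix(
    tree: dendropy.Tree, states: Mapping[str, int], n_states: int, ordered: bool
) -> CharacterMatrix:
    taxa = sorted(
        (lf.taxon.label if lf.taxon else lf.label) for lf in tree.leaf_node_iter()
    )
    cells = []
    for t in taxa:
        if t in states and states[t] is not None:
            s = int(states[t])
            if not 0 <= s < n_states:
                raise SizeError(f"state {s} for {t!r} outside 0..{n_states - 1}")
            cells.append([frozenset([s])])
        else:
            cells.append([MISSING])
    return CharacterMatrix(taxa=taxa, cells=cells, ordered=[ordered])


def asr_bins(
    tree: dendropy.Tree, bins: Mapping[str, int], n_bins: int | None = None
) -> dict[dendropy.Node, frozenset[int]]:
    """Ordered-parsimony MPR sets of bin indices for every node of *tree*.

    Taxa absent from *bins* are treated as missing and contribute nothing.
    """
    usable = {t: b for t, b in bins.items() if b is not None}
    if not usable:
        raise SizeError("empty trait set: no taxon has a bin")
    if n_bins is None:
        n_bins = max(usable.values()) + 1
    matrix = _single_char_matrix(tree, usable, n_bins, ordered=True)
    costs = CostModel(n_states=(n_bins,), ordered=(True,))
    return mpr_states(tree, matrix, costs, 0)


def asr_binary(
    tree: dendropy.Tree, states: Mapping[str, str]
) -> dict[dendropy.Node, frozenset[int]]:
    """Fitch MPR sets for the binary osmoregulation character.

    Input states are ``saltwater_tolerant`` / ``freshwater_only`` /
    ``unknown`` (treated as missing).  Returned sets contain 0
    (freshwater-only) and/or 1 (saltwater-tolerant).
    """
    coded: dict[str, int] = {}
    for taxon, s in states.items():
        if s == SALTWATER:
            coded[taxon] = 1
        elif s == FRESHWATER:
            coded[taxon] = 0
        elif s == UNKNOWN:
            continue
        else:
            raise SizeError(f"unknown osmoregulation state {s!r} for {taxon!r}")
    if not coded:
        raise SizeError("all osmoregulation states unknown")
    matrix = _single_char_matrix(tree, coded, 2, ordered=False)
    costs = CostModel(n_states=(2,), ordered=(False,))
    return mpr_states(tree, matrix, costs, 0)


def reduction_percent(
    ancestral_bin: tuple[float, float], descendant_bin: tuple[float, float]
) -> tuple[float, float]:
    """(min %, max %) total-length reduction from an ancestral to a descendant bin.

    Both percentages reference the ancestral bin's upper bound:
    ``min = (1 - upper_desc / upper_anc) * 100`` and
    ``max = (1 - lower_desc / upper_anc) * 100``.  Bins must have finite
    bounds (the open-ended gigantic bin is rejected).  A descendant bin
    extending above the ancestral upper bound yields a negative minimum,
    reported as 0 with a logged note.
    """
    a_lo, a_hi = ancestral_bin
    d_lo, d_hi = descendant_bin
    for v in (a_lo, a_hi, d_lo, d_hi):
        if not math.isfinite(v) or v < 0:
            raise SizeError("bins must have finite non-negative bounds")
    if a_hi <= 0 or a_hi < a_lo or d_hi < d_lo:
        raise SizeError("bin bounds must satisfy 0 <= lower <= upper, upper > 0")
    # round away float noise well below any meaningful precision
    min_pct = round((1.0 - d_hi / a_hi) * 100.0, 10)
    max_pct = round((1.0 - d_lo / a_hi) * 100.0, 10)
    if min_pct < 0:
        logger.info(
            "descendant bin extends above ancestral bin (%s -> %s); min reduction clamped to 0",
            ancestral_bin,
            descendant_bin,
        )
        min_pct = 0.0
    return (min_pct, max_pct)
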