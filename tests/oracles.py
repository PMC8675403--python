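"""Independent oracles used to cross-check the implementation.

These deliberately take different computational routes from the package:
pairwise enumeration instead of category-count algebra for agreement, and
exact rational arithmetic for crosswalk conservation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import pandas as pd


def fleiss_kappa_pairwise(panel: pd.DataFrame) -> tuple[float, float, float]:
    """Fleiss' kappa by brute-force enumeration of rater pairs.

    Observed agreement is the mean over items of the fraction of rater
    pairs that agree; chance agreement is the sum of squared overall
    category proportions.  Returns (kappa, observed, expected).
    """
    values = panel.to_numpy()
    n_items, n_raters = values.shape
    pair_fractions = []
    for row in values:
        pairs = list(combinations(row, 2))
        pair_fractions.append(sum(1 for a, b in pairs if a == b) / len(pairs))
    p_bar = sum(pair_fractions) / n_items
    flat = [v for row in values for v in row]
    p_e = sum((flat.count(c) / len(flat)) ** 2 for c in set(flat))
    kappa = (p_bar - p_e) / (1 - p_e)
    return kappa, p_bar, p_e


def recode_exact(wf: pd.DataFrame, xwalk: pd.DataFrame) -> dict[str, Fraction]:
    """Crosswalk recoding in exact rational arithmetic (no rounding)."""
    counts = dict(zip(wf["code4"], wf["jobholders"]))
    out: dict[str, Fraction] = {}
    for row in xwalk.itertuples(index=False):
        w = Fraction(str(row.weight))
        out[row.target] = out.get(row.target, Fraction(0)) + w * counts[row.source]
    return out
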