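"""Inter-rater agreement on the exposure ratings.

Chance-corrected agreement between the expert raters is measured with
Fleiss' kappa: for items rated by a fixed number of raters ``n``,

    P_i  = (sum_j n_ij^2 - n) / (n (n - 1))      per-item agreement
    Pbar = mean_i P_i                            observed agreement
    Pe   = sum_j p_j^2                           expected (chance) agreement
    kappa = (Pbar - Pe) / (1 - Pe)

where ``n_ij`` counts raters assigning category ``j`` to item ``i`` and
``p_j`` is the overall share of assignments in category ``j``.

Agreement is computed on the likelihood axis by default.  The conditional
rating scheme makes frequency/intensity agreement misleading (both are
missing whenever a rater sees no exposure), so those axes are only
available behind an explicit opt-in and are restricted to items every
rater actually rated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import code2_of

logger = logging.getLogger("jemforge")


class DegenerateMarginError(ValueError):
    """All assignments fall in one category but agreement is imperfect.

    The Fleiss expected agreement is then 1 and kappa is undefined (0/0
    with a nonzero numerator is impossible; Pbar < 1 with Pe = 1 gives
    -inf, which carries no information about the raters).
    """


class UnequalRaterCountError(ValueError):
    """Some items were rated by a different number of raters."""


@dataclass(frozen=True)
class AgreementResult:
    """Fleiss' kappa and its components for one rating panel."""

    kappa: float
    n_items: int
    n_raters: int
    observed_agreement: float
    expected_agreement: float
    disagreement_codes: frozenset[str]
    n_excluded: int = 0


def make_panel(
    ratings: pd.DataFrame,
    axis: str = "likelihood",
    round: int | None = 2,
    allow_conditional_axes: bool = False,
) -> pd.DataFrame:
    """Pivot a long ratings table into an item x rater panel for one axis.

    Frequency/intensity panels are only built with
    ``allow_conditional_axes=True``: agreement on the conditional axes is
    computed over the subset of items that *every* rater rated, which
    changes its meaning and is easy to misread.
    """
    if axis != "likelihood" and not allow_conditional_axes:
        raise ValueError(
            f"agreement on {axis!r} requires allow_conditional_axes=True "
            "(conditional axes are rated only when likelihood is 1)"
        )
    df = ratings if round is None else ratings[ratings["round"] == round]
    if df.empty:
        raise ValueError(f"no ratings for round {round}")
    panel = df.pivot(index="code4", columns="rater_id", values=axis)
    if axis != "likelihood":
        complete = panel.notna().all(axis=1)
        logger.info(
            "%s panel: restricting to %d/%d items rated by all raters",
            axis, int(complete.sum()), len(panel),
        )
        panel = panel[complete]
    return panel


def fleiss_kappa(
    panel: pd.DataFrame,
    categories: tuple[int, ...] | None = None,
    on_missing: str = "drop",
) -> AgreementResult:
    """Fleiss' kappa for an item x rater panel of categorical levels.

    Items with missing entries are excluded (with a logged count) when
    ``on_missing="drop"``; with ``on_missing="raise"`` they are an error
    listing the offending items, so the caller must drop or impute
    explicitly.  Silent imputation is never performed — it would bias
    kappa.

    ``categories`` must cover every observed level; it defaults to the
    levels observed in the panel.
    """
    if on_missing not in ("drop", "raise"):
        raise ValueError("on_missing must be 'drop' or 'raise'")
    incomplete = panel.isna().any(axis=1)
    n_excluded = int(incomplete.sum())
    if n_excluded:
        if on_missing == "raise":
            raise UnequalRaterCountError(
                f"items with missing ratings: {sorted(panel.index[incomplete])}"
            )
        logger.info("fleiss_kappa: excluding %d items with missing ratings", n_excluded)
        panel = panel[~incomplete]
    if panel.empty:
        raise ValueError("no complete items to compute agreement on")
    n_items, n_raters = panel.shape
    if n_raters < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")

    values = panel.to_numpy()
    observed = sorted({int(v) for v in values.ravel()})
    if categories is None:
        cats = observed
    else:
        cats = sorted(int(c) for c in categories)
        uncovered = set(observed) - set(cats)
        if uncovered:
            raise ValueError(f"categories {cats} do not cover observed levels {sorted(uncovered)}")

    # n_ij: raters assigning category j to item i
    counts = np.stack([(values == c).sum(axis=1) for c in cats], axis=1)
    p_i = (np.square(counts).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    p_e = float(np.square(p_j).sum())

    disagreeing = frozenset(panel.index[(counts > 0).sum(axis=1) >= 2].astype(str))

    if p_e >= 1.0 - 1e-15:
        if abs(p_bar - 1.0) < 1e-15:
            kappa = 1.0
        else:
            raise DegenerateMarginError(
                "all assignments fall in a single category yet agreement is "
                f"imperfect (Pbar={p_bar:.6f}); kappa is undefined"
            )
    else:
        kappa = (p_bar - p_e) / (1.0 - p_e)

    return AgreementResult(
        kappa=kappa,
        n_items=n_items,
        n_raters=n_raters,
        observed_agreement=p_bar,
        expected_agreement=p_e,
        disagreement_codes=disagreeing,
        n_excluded=n_excluded,
    )


def count_disagreements_by_group(
    result: AgreementResult, codes: pd.DataFrame
) -> pd.DataFrame:
    """Localise rater disagreement on the 2-digit occupation groups.

    ``codes`` is the code universe (a DataFrame with a ``code4`` column).
    Returns one row per 2-digit group with ``n_disagreeing``, ``n_total``
    and ``fraction``; the numerators sum to ``len(result.disagreement_codes)``.
    """
    universe = codes["code4"].astype(str)
    unknown = sorted(result.disagreement_codes - set(universe))
    if unknown:
        raise KeyError(f"disagreement codes not in the code universe: {unknown}")
    df = pd.DataFrame({"code4": universe})
    df["code2"] = code2_of(df["code4"])
    df["disagrees"] = df["code4"].isin(result.disagreement_codes)
    out = (
        df.groupby("code2")
        .agg(n_disagreeing=("disagrees", "sum"), n_total=("code4", "size"))
        .reset_index()
    )
    out["n_disagreeing"] = out["n_disagreeing"].astype(int)
    out["fraction"] = out["n_disagreeing"] / out["n_total"]
    return out


def bootstrap_kappa_ci(
    panel: pd.DataFrame,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    categories: tuple[int, ...] | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for kappa, resampling items with replacement.

    Offered as an optional extra; replicates whose resample is degenerate
    (a single category with imperfect agreement) are skipped.
    """
    rng = np.random.default_rng(seed)
    complete = panel[panel.notna().all(axis=1)]
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(complete), size=len(complete))
        try:
            stats.append(fleiss_kappa(complete.iloc[idx], categories=categories).kappa)
        except DegenerateMarginError:
            continue
    if not stats:
        raise ValueError("all bootstrap replicates were degenerate")
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
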