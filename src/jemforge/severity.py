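"""Compound severity scoring and grouped exposure summaries.

The compound severity of one occupation code is the product of its three
consensus ratings, likelihood x frequency x intensity.  Under the rating
scheme's conditional structure the attainable values are exactly
{0, 1, 2, 3, 4, 6, 8, 9, 12}; 12 (likelihood 1, daily >1 h, indoors poorly
ventilated) is the worst possible exposure.

Summaries aggregate the per-code JEM over a grouping — the 2-digit
occupation groups, or socio-economic (NS-SEC analytic) classes supplied as
an external code -> class mapping.  Group mean severity is an unweighted
mean over codes; a workforce-weighted variant is available behind an
explicit ``weights`` argument to keep the two readings distinct.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping

import pandas as pd

from .core import DEFAULT_SCHEME, RatingScheme, code2_of


def compound_severity(
    likelihood: int, frequency: int, intensity: int,
    scheme: RatingScheme = DEFAULT_SCHEME,
) -> int:
    """likelihood x frequency x intensity for one code (0 when unexposed)."""
    for axis, value in zip(("likelihood", "frequency", "intensity"),
                           (likelihood, frequency, intensity)):
        if value not in scheme.levels(axis):
            raise ValueError(f"illegal {axis} level {value}")
    return likelihood * frequency * intensity


def legal_triples(scheme: RatingScheme = DEFAULT_SCHEME) -> list[tuple[int, int, int]]:
    """All (likelihood, frequency, intensity) triples the conditional scheme admits.

    Likelihood 0 forces frequency = intensity = 0; likelihood 1 pairs with
    every nonzero frequency and intensity level.
    """
    triples = [(0, 0, 0)]
    triples += [
        (1, f, i)
        for f, i in product(scheme.rated_levels("frequency"),
                            scheme.rated_levels("intensity"))
    ]
    return triples


def severity_image(scheme: RatingScheme = DEFAULT_SCHEME) -> frozenset[int]:
    """The set of severity values attainable over all legal triples."""
    return frozenset(l * f * i for l, f, i in legal_triples(scheme))


def summarize_by_group(
    jem: pd.DataFrame,
    grouping: Mapping[str, object] | pd.Series | None = None,
    weights: Mapping[str, int] | pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate a JEM over groups of codes.

    ``grouping`` maps code4 -> group id (e.g. an NS-SEC analytic class
    1–8); when omitted, codes are grouped by their 2-digit parent group.
    Every code in the JEM must be covered.  ``weights`` (optional) maps
    code4 -> jobholder count for a workforce-weighted mean severity,
    reported in a separate column.

    Returns ``(per_group, overall)``: one row per group with n_codes,
    n_likely, fraction_likely and mean_severity, plus an overall dict with
    the whole-JEM likely count/fraction and mean severity with its range.
    """
    df = jem.loc[:, ["code4", "likelihood", "severity"]].copy()
    df["code4"] = df["code4"].astype(str)
    if grouping is None:
        df["group_id"] = code2_of(df["code4"])
    else:
        gmap = pd.Series(grouping)
        gmap.index = gmap.index.astype(str)
        missing = sorted(set(df["code4"]) - set(gmap.index))
        if missing:
            raise KeyError(f"codes missing from grouping: {missing}")
        df["group_id"] = df["code4"].map(gmap)

    df["likely"] = df["likelihood"].astype(int) == 1
    per_group = (
        df.groupby("group_id")
        .agg(
            n_codes=("code4", "size"),
            n_likely=("likely", "sum"),
            mean_severity=("severity", "mean"),
        )
        .reset_index()
    )
    per_group["n_likely"] = per_group["n_likely"].astype(int)
    per_group["fraction_likely"] = per_group["n_likely"] / per_group["n_codes"]
    per_group = per_group.loc[:, ["group_id", "n_codes", "n_likely", "fraction_likely", "mean_severity"]]

    if weights is not None:
        wmap = pd.Series(weights)
        wmap.index = wmap.index.astype(str)
        missing = sorted(set(df["code4"]) - set(wmap.index))
        if missing:
            raise KeyError(f"codes missing from weights: {missing}")
        df["w"] = df["code4"].map(wmap).astype(float)
        df["ws"] = df["w"] * df["severity"].astype(float)
        wsum = df.groupby("group_id").agg(w=("w", "sum"), ws=("ws", "sum"))
        per_group = per_group.merge(
            (wsum["ws"] / wsum["w"]).rename("weighted_mean_severity").reset_index(),
            on="group_id",
        )

    overall = {
        "n_codes": int(len(df)),
        "n_likely": int(df["likely"].sum()),
        "fraction_likely": float(df["likely"].mean()),
        "mean_severity": float(df["severity"].mean()),
        "min_severity": int(df["severity"].min()),
        "max_severity": int(df["severity"].max()),
    }
    return per_group, overall


def top_severity_codes(jem: pd.DataFrame) -> pd.DataFrame:
    """Codes ordered by compound severity, worst first.

    Sorted by severity descending with ties broken by code4 ascending, so
    the ranking is fully deterministic.  The head of the frame is the
    subset at the attainable maximum.
    """
    if jem.empty:
        raise ValueError("JEM is empty")
    out = jem.loc[:, ["code4", "severity"]].copy()
    out["code4"] = out["code4"].astype(str)
    out["severity"] = out["severity"].astype(int)
    return out.sort_values(["severity", "code4"], ascending=[False, True]).reset_index(drop=True)


def codes_at_severity(jem: pd.DataFrame, value: int) -> list[str]:
    """All codes whose compound severity equals ``value``, sorted."""
    sel = jem.loc[jem["severity"].astype(int) == value, "code4"].astype(str)
    return sorted(sel)
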