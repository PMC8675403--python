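"""Workforce counts, classification crosswalks and exposure cross-tabulation.

Jobholder counts per 4-digit occupation code (official labour-market
extracts round them to the nearest 100) are recoded between classification
versions via an explicit weighted crosswalk, joined to the JEM, and
aggregated into the frequency x intensity cross-tabulation from which the
headline exposure estimates are read: the number of workers in jobs rated
likely to involve SHS exposure, their share of all jobs held, and the
lower bound implied by the likelihood threshold (at least ``min_prevalence``
of jobholders in a likely code are exposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import DEFAULT_SCHEME, RatingScheme

logger = logging.getLogger("jemforge")

WORKFORCE_COLUMNS = ("code4", "scheme_version", "jobholders")


class CrosswalkError(ValueError):
    """A crosswalk is unusable: unmapped codes or weights not summing to 1."""


def read_workforce(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a workforce CSV (code4, scheme_version, jobholders)."""
    df = pd.read_csv(path, dtype={"code4": str})
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in WORKFORCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"workforce file {path} lacks columns {missing}")
    df = df.loc[:, list(WORKFORCE_COLUMNS)].copy()
    df["code4"] = df["code4"].astype(str)
    df["jobholders"] = df["jobholders"].astype(int)
    validate_workforce(df)
    return df


def validate_workforce(wf: pd.DataFrame, rounded_extract: bool = False) -> None:
    """Structural checks: unique codes per version, non-negative counts,
    and (for rounded extracts) counts that are multiples of 100."""
    dup = wf.loc[wf.duplicated(subset=["code4", "scheme_version"]), "code4"]
    if not dup.empty:
        raise ValueError(f"duplicate code4 within a version: {sorted(dup.unique())}")
    if (wf["jobholders"] < 0).any():
        raise ValueError("negative jobholder counts")
    if rounded_extract and (wf["jobholders"] % 100 != 0).any():
        bad = wf.loc[wf["jobholders"] % 100 != 0, "code4"].tolist()
        raise ValueError(f"rounded extract has counts not multiple of 100: {bad}")


def read_crosswalk(path, default_equal_split: bool = True) -> pd.DataFrame:
    """Read a crosswalk CSV (source, target[, weight]).

    A file without a weight column is completed with an equal split across
    each source's targets — loudly, because silent assumptions about
    occupational recoding materially change counts.
    """
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"crosswalk file {path} lacks column {col!r}")
    if "weight" not in df.columns:
        if not default_equal_split:
            raise CrosswalkError(f"crosswalk file {path} has no weight column")
        logger.warning(
            "crosswalk %s has no weight column: assuming an EQUAL SPLIT "
            "across each source's targets", path,
        )
        df["weight"] = 1.0 / df.groupby("source")["source"].transform("size")
    df["weight"] = df["weight"].astype(float)
    return df.loc[:, ["source", "target", "weight"]]


def recode_workforce(
    wf: pd.DataFrame,
    xwalk: pd.DataFrame,
    target_version: str = "SOC2020",
) -> pd.DataFrame:
    """Recode workforce counts to another classification version.

    Each target code receives the weight-mixed sum of its source counts;
    sums are rounded half-to-even to whole workers.  The residual drift of
    the total against the exact (unrounded) total is logged, never hidden.
    """
    bad_w = (xwalk["weight"] <= 0) | (xwalk["weight"] > 1)
    if bad_w.any():
        raise CrosswalkError(
            f"weights outside (0, 1]: sources {sorted(xwalk.loc[bad_w, 'source'].unique())}"
        )
    wsum = xwalk.groupby("source")["weight"].sum()
    off = wsum[(wsum - 1.0).abs() > 1e-9]
    if not off.empty:
        raise CrosswalkError(
            f"crosswalk weights do not sum to 1 for sources: {sorted(off.index)}"
        )
    unmapped = sorted(set(wf["code4"]) - set(xwalk["source"]))
    if unmapped:
        raise CrosswalkError(f"source codes missing from crosswalk: {unmapped}")

    merged = wf.merge(xwalk, left_on="code4", right_on="source", how="left")
    merged["mass"] = merged["jobholders"] * merged["weight"]
    exact = merged.groupby("target")["mass"].sum()
    counts = exact.map(lambda x: int(round(x)))  # round() is half-to-even
    drift = int(counts.sum()) - int(wf["jobholders"].sum())
    if drift:
        logger.info("recode_workforce: rounding drift of %+d workers on total %d",
                    drift, int(wf["jobholders"].sum()))
    out = pd.DataFrame({
        "code4": counts.index.astype(str),
        "scheme_version": target_version,
        "jobholders": counts.to_numpy(dtype=int),
    }).sort_values("code4").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Exposure cross-tabulation
# ---------------------------------------------------------------------------


def _legal_cells(scheme: RatingScheme) -> list[tuple[int, int]]:
    cells = [(0, 0)]
    cells += [
        (f, i)
        for f in scheme.rated_levels("frequency")
        for i in scheme.rated_levels("intensity")
    ]
    return cells


@dataclass(frozen=True)
class ExposureCrossTab:
    """Jobholder counts by (frequency, intensity) of potential exposure.

    Only structurally possible cells exist: (0, 0) — all workers in codes
    with likelihood 0 — and every (frequency >= 1, intensity >= 1)
    combination.  Frequency 0 with nonzero intensity (and vice versa)
    cannot occur under the conditional rating scheme and is absent.
    """

    cells: Mapping[tuple[int, int], int]
    scheme: RatingScheme = field(default=DEFAULT_SCHEME, compare=False)

    def __post_init__(self) -> None:
        legal = _legal_cells(self.scheme)
        illegal = set(self.cells) - set(legal)
        if illegal:
            raise ValueError(f"structurally impossible cells: {sorted(illegal)}")
        if any(v < 0 for v in self.cells.values()):
            raise ValueError("negative cell counts")
        # normalise: every legal cell present, absent cells are 0
        object.__setattr__(
            self, "cells", {c: int(self.cells.get(c, 0)) for c in legal}
        )

    def cell(self, frequency: int, intensity: int) -> int:
        return int(self.cells.get((frequency, intensity), 0))

    @property
    def grand_total(self) -> int:
        return int(sum(self.cells.values()))

    def row_total(self, frequency: int) -> int:
        return int(sum(v for (f, _), v in self.cells.items() if f == frequency))

    def col_total(self, intensity: int) -> int:
        return int(sum(v for (_, i), v in self.cells.items() if i == intensity))

    @property
    def exposed_total(self) -> int:
        """Workers in codes rated likely to involve exposure (everything
        outside the (0, 0) cell)."""
        return self.grand_total - self.cell(0, 0)

    def to_frame(self) -> pd.DataFrame:
        """The familiar table layout: frequency rows x intensity columns
        with marginal totals; impossible cells are left empty."""
        freqs = self.scheme.frequency_levels
        ints = self.scheme.intensity_levels
        data = {}
        for i in ints:
            data[i] = [
                self.cell(f, i) if (f, i) in _legal_cells(self.scheme) else pd.NA
                for f in freqs
            ]
        df = pd.DataFrame(data, index=list(freqs))
        df.index.name = "frequency"
        df.columns.name = "intensity"
        df["Total"] = [self.row_total(f) for f in freqs]
        totals = [self.col_total(i) for i in ints] + [self.grand_total]
        df.loc["Total"] = totals
        return df


def cross_tabulate(
    jem: pd.DataFrame,
    wf: pd.DataFrame,
    scheme: RatingScheme = DEFAULT_SCHEME,
) -> ExposureCrossTab:
    """Aggregate jobholder counts into the frequency x intensity table.

    Each code's jobholders land in the cell of its consensus (frequency,
    intensity); codes with likelihood 0 land in (0, 0).  The JEM and the
    workforce table must cover the same code universe — codes present on
    one side only are an error listing them, because silently dropping
    either ratings or workers would corrupt the totals.
    """
    jem_codes = set(jem["code4"].astype(str))
    wf_codes = set(wf["code4"].astype(str))
    only_wf = sorted(wf_codes - jem_codes)
    only_jem = sorted(jem_codes - wf_codes)
    if only_wf or only_jem:
        raise KeyError(
            f"code universes differ: in workforce only {only_wf}; in JEM only {only_jem}"
        )
    merged = jem.merge(wf.loc[:, ["code4", "jobholders"]], on="code4")
    cells: dict[tuple[int, int], int] = {c: 0 for c in _legal_cells(scheme)}
    for row in merged.itertuples(index=False):
        if int(row.likelihood) == 0:
            key = (0, 0)
        else:
            key = (int(row.frequency), int(row.intensity))
        cells[key] += int(row.jobholders)
    return ExposureCrossTab(cells=cells, scheme=scheme)


@dataclass(frozen=True)
class ExposedEstimate:
    """Headline workforce exposure figures derived from the crosstab."""

    n_in_exposed_jobs: int
    share_of_jobs: float
    lower_bound_exposed: float
    min_prevalence: float


def exposed_worker_estimates(
    ct: ExposureCrossTab, min_prevalence: float = 0.10
) -> ExposedEstimate:
    """Workers in likely-exposed jobs, their share of all jobs, and the
    lower bound on exposed workers implied by the likelihood threshold.

    A code rated likely means at least ``min_prevalence`` (default 10%) of
    its jobholders are exposed, so ``min_prevalence x n_in_exposed_jobs``
    is a floor on the number of exposed workers.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    if ct.grand_total == 0:
        raise ValueError("empty cross-tabulation")
    n_exposed_jobs = ct.exposed_total
    return ExposedEstimate(
        n_in_exposed_jobs=n_exposed_jobs,
        share_of_jobs=n_exposed_jobs / ct.grand_total,
        lower_bound_exposed=min_prevalence * n_exposed_jobs,
        min_prevalence=min_prevalence,
    )


def indoor_exposure_share(
    ct: ExposureCrossTab,
    numerator_cells: Iterable[tuple[int, int]] = ((3, 3),),
    indoor_intensities: Iterable[int] = (3,),
) -> tuple[int, int, float]:
    """Share of workers in given cells among all workers with indoor exposure.

    Which intensity levels count as "indoors" is a reporting choice
    (level 3 only, or levels 2–3); both denominators are computable here
    and neither is privileged.  Returns (numerator, denominator, share).
    """
    num = int(sum(ct.cell(f, i) for f, i in numerator_cells))
    den = int(sum(v for (_, i), v in ct.cells.items() if i in set(indoor_intensities)))
    if den == 0:
        raise ValueError("no workers at the chosen indoor intensity levels")
    return num, den, num / den
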