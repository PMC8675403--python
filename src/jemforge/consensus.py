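"""Consensus adjudication: many raters' scores -> one JEM record per code.

After the second round of independent rating, remaining conflicts are
resolved mechanically, axis by axis, likelihood first:

* all raters agree -> that value (``unanimous``);
* three raters, two agree -> the repeated value (``majority``);
* only two raters rated the axis -> the higher (worse) value
  (``higher_of_two``), reading the ordinal scales worst-last;
* three raters, all distinct (cannot arise on the binary likelihood
  axis) -> the policy decides; the default takes the median with a logged
  warning and a ``tiebreak`` provenance flag, a strict policy raises.

Frequency and intensity are resolved only when the consensus likelihood is
1, and only over the raters who actually rated those axes (raters who saw
no exposure contribute nothing to them).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import AXES, DEFAULT_SCHEME, RatingScheme

logger = logging.getLogger("jemforge")

PROVENANCES = ("unanimous", "majority", "higher_of_two", "tiebreak")


@dataclass(frozen=True)
class ConsensusPolicy:
    """How to adjudicate an axis rated differently by all three raters.

    ``tiebreak_three_distinct``:
      * ``"median"`` — take the middle value, log a warning, flag the
        provenance as ``tiebreak`` (default; the median respects the
        ordinal scale and assumes least);
      * ``"flag_and_median"`` — as ``"median"``; kept as a distinct name so
        configs can state explicitly that flagged tiebreaks are expected;
      * ``"error"`` — strict mode, raise instead.

    Likelihood is always resolved before frequency/intensity: the
    conditional scheme makes the latter meaningless until the former is
    settled.
    """

    tiebreak_three_distinct: str = "median"

    def __post_init__(self) -> None:
        if self.tiebreak_three_distinct not in ("median", "error", "flag_and_median"):
            raise ValueError(
                f"unknown tiebreak policy {self.tiebreak_three_distinct!r}"
            )


class TiebreakError(ValueError):
    """Three distinct ratings under the strict consensus policy."""


class MissingAxisError(ValueError):
    """Consensus likelihood is 1 but no rater supplied a conditional axis."""


def resolve_axis(
    values: Sequence[int],
    policy: ConsensusPolicy = ConsensusPolicy(),
    axis: str = "",
    scheme: RatingScheme = DEFAULT_SCHEME,
) -> tuple[int, str]:
    """Resolve 1–3 ratings of one axis into a consensus (level, provenance).

    ``axis`` (if given) enables level-legality checking and better
    messages.  The order of ``values`` never matters.
    """
    vals = [int(v) for v in values]
    if not vals:
        raise MissingAxisError(f"no ratings for axis {axis or '?'}")
    if len(vals) > 3:
        raise ValueError(f"at most 3 raters supported, got {len(vals)}")
    if axis:
        legal = scheme.levels(axis)
        bad = [v for v in vals if v not in legal]
        if bad:
            raise ValueError(f"illegal level(s) {bad} for axis {axis}")

    distinct = set(vals)
    if len(distinct) == 1:
        return vals[0], "unanimous"
    if len(vals) == 2:
        return max(vals), "higher_of_two"
    if len(distinct) == 2:  # three raters, two agree
        return statistics.mode(vals), "majority"
    # three raters, three distinct values
    if policy.tiebreak_three_distinct == "error":
        raise TiebreakError(f"three distinct ratings {sorted(vals)} on axis {axis or '?'}")
    logger.warning(
        "three distinct ratings %s on axis %s: taking the median", sorted(vals), axis or "?"
    )
    return int(statistics.median(vals)), "tiebreak"


def build_jem(
    ratings: pd.DataFrame,
    policy: ConsensusPolicy = ConsensusPolicy(),
    scheme: RatingScheme = DEFAULT_SCHEME,
    round: int | None = 2,
) -> pd.DataFrame:
    """Resolve a validated round of ratings into one JEM record per code.

    Returns a DataFrame with columns code4, likelihood, frequency,
    intensity, severity and a provenance column per axis.  Codes whose
    consensus likelihood is 1 but for which no rater supplied a frequency
    (or intensity) rating are an error — a level cannot be fabricated.
    """
    df = ratings if round is None else ratings[ratings["round"] == round]
    if df.empty:
        raise ValueError(f"no ratings for round {round}")

    records: list[dict] = []
    missing_axis: list[str] = []
    for code4, grp in df.groupby("code4", sort=True):
        rec: dict = {"code4": str(code4)}
        lk_values = grp["likelihood"].dropna().astype(int).tolist()
        try:
            lk, lk_prov = resolve_axis(lk_values, policy, axis="likelihood", scheme=scheme)
        except MissingAxisError:
            missing_axis.append(f"{code4} (likelihood)")
            continue
        rec["likelihood"], rec["likelihood_provenance"] = lk, lk_prov
        if lk == 0:
            # nobody exposed: the conditional axes are forced to 0; all
            # (zero) contributing ratings trivially agree
            for axis in ("frequency", "intensity"):
                rec[axis], rec[f"{axis}_provenance"] = 0, "unanimous"
        else:
            for axis in ("frequency", "intensity"):
                axis_values = grp[axis].dropna().astype(int).tolist()
                if not axis_values:
                    missing_axis.append(f"{code4} ({axis})")
                    rec = None
                    break
                rec[axis], rec[f"{axis}_provenance"] = resolve_axis(
                    axis_values, policy, axis=axis, scheme=scheme
                )
            if rec is None:
                continue
        rec["severity"] = rec["likelihood"] * rec["frequency"] * rec["intensity"]
        records.append(rec)

    if missing_axis:
        raise MissingAxisError(
            "consensus likelihood is 1 but no rater rated the axis for: "
            + ", ".join(missing_axis)
        )

    jem = pd.DataFrame.from_records(records)
    cols = [
        "code4", "likelihood", "frequency", "intensity", "severity",
        "likelihood_provenance", "frequency_provenance", "intensity_provenance",
    ]
    return jem.loc[:, cols]
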