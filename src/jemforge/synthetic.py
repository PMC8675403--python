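"""Synthetic inputs for every stage of the JEM pipeline.

Two kinds of data live here:

1. A parametric simulator (``SimulationConfig`` + ``simulate_*``) that
   generates a universe of 4-digit occupation codes nested in 2-digit
   groups, a latent "true" JEM, noisy rater panels at a controllable error
   rate, lognormal workforce counts rounded to the nearest 100, and a
   mixed identity/merge/split classification crosswalk.  Identical config
   and seed give byte-identical outputs.

2. Deterministic synthetic stand-ins for the published UK 2020 SHS-JEM
   artefacts (``synthetic_uk_jem``, ``synthetic_uk_workforce``) and the
   printed UK jobholder cross-tabulation (``uk_jobholder_crosstab_2020``).
   The deposited per-code JEM table is not redistributed here; the
   stand-in is *constructed* to match every summary margin reported for
   it, so the parsing/summarising/tabulating code paths can be exercised
   against known headline figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RATING_COLUMNS, code2_of
from .workforce import ExposureCrossTab

# ---------------------------------------------------------------------------
# Parametric simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults mirror the UK 2020 setting: 412 four-digit codes in 26
    two-digit groups, three raters, a 20.4% prevalence of likely-exposed
    codes.  The frequency/intensity laws (over the rated levels 1–4 and
    1–3) echo the published JEM's distribution of likely codes over the
    cross-tabulation cells; the lognormal workforce law gives a mean code
    size near 110 000 jobholders, matching a ~46M national workforce.

    ``rater_error`` is the per-axis probability that a rater deviates from
    the latent truth; ``deviation_kernel`` is ``"adjacent"`` (one step on
    the ordinal scale, reflecting at the ends — expert disagreement on
    ordinal exposure scales is overwhelmingly between neighbouring levels)
    or ``"uniform"`` (any other legal level, for worst-case tests).
    """

    n_codes: int = 412
    n_groups: int = 26
    n_raters: int = 3
    prevalence_likely: float = 0.204
    rater_error: float = 0.1
    deviation_kernel: str = "adjacent"
    frequency_law: tuple[float, ...] = (0.12, 0.30, 0.54, 0.04)
    intensity_law: tuple[float, ...] = (0.36, 0.20, 0.44)
    workforce_mu: float = 11.1
    workforce_sigma: float = 1.0
    crosswalk_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_groups <= 89:
            raise ValueError("n_groups must be in [1, 89] (two-digit groups)")
        if self.n_codes < self.n_groups:
            raise ValueError("need at least one code per group")
        if self.n_codes > 99 * self.n_groups:
            raise ValueError("at most 99 codes per two-digit group")
        if not 0 <= self.prevalence_likely <= 1:
            raise ValueError("prevalence_likely must be in [0, 1]")
        if not 0 <= self.rater_error < 1:
            raise ValueError("rater_error must be in [0, 1)")
        if self.deviation_kernel not in ("adjacent", "uniform"):
            raise ValueError("deviation_kernel must be 'adjacent' or 'uniform'")
        for name, law, k in (("frequency_law", self.frequency_law, 4),
                             ("intensity_law", self.intensity_law, 3)):
            if len(law) != k or abs(sum(law) - 1.0) > 1e-9 or any(p < 0 for p in law):
                raise ValueError(f"{name} must be {k} non-negative probabilities summing to 1")
        if abs(sum(self.crosswalk_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.crosswalk_mix):
            raise ValueError("crosswalk_mix must be 3 proportions summing to 1")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_truth(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent code universe and true JEM.

    Codes are partitioned near-evenly over 2-digit groups numbered from
    10.  Each code is likely-exposed with probability
    ``prevalence_likely``; likely codes draw frequency/intensity from the
    config's categorical laws, others are (0, 0, 0).

    Returns ``(codes, truth)``: the universe (code4, code2, title,
    scheme_version) and the latent JEM (code4, likelihood, frequency,
    intensity, severity).
    """
    rng = _rng(config, 0)
    base, rem = divmod(config.n_codes, config.n_groups)
    code4s: list[str] = []
    for g in range(config.n_groups):
        code2 = str(10 + g)
        n_in_group = base + (1 if g < rem else 0)
        code4s += [f"{code2}{k:02d}" for k in range(1, n_in_group + 1)]
    codes = pd.DataFrame({
        "code4": code4s,
        "code2": [c[:2] for c in code4s],
        "title": [f"Synthetic occupation {c}" for c in code4s],
        "scheme_version": "SOC2020",
    })

    likely = rng.random(config.n_codes) < config.prevalence_likely
    freq = np.where(
        likely, rng.choice([1, 2, 3, 4], size=config.n_codes, p=config.frequency_law), 0
    )
    inten = np.where(
        likely, rng.choice([1, 2, 3], size=config.n_codes, p=config.intensity_law), 0
    )
    truth = pd.DataFrame({
        "code4": code4s,
        "likelihood": likely.astype(int),
        "frequency": freq.astype(int),
        "intensity": inten.astype(int),
    })
    truth["severity"] = truth["likelihood"] * truth["frequency"] * truth["intensity"]
    return codes, truth


def _perturb(value: int, lo: int, hi: int, kernel: str, rng: np.random.Generator) -> int:
    """One erroneous rating: a neighbouring level (reflecting at the scale
    ends) or a uniform draw over the other legal levels."""
    if kernel == "adjacent":
        step = 1 if rng.random() < 0.5 else -1
        out = value + step
        if out < lo:
            out = lo + 1
        elif out > hi:
            out = hi - 1
        return out
    others = [v for v in range(lo, hi + 1) if v != value]
    return int(rng.choice(others))


def simulate_raters(
    truth: pd.DataFrame, config: SimulationConfig, round: int = 2
) -> pd.DataFrame:
    """Noisy independent rater panel over the latent truth.

    Each rater reports the true level with probability ``1 - rater_error``
    per axis, else a deviated level from the kernel.  The likelihood axis
    (binary) deviates by a symmetric flip.  The conditional structure is
    enforced: a rater reporting likelihood 0 reports nothing else; a rater
    who erroneously reports likelihood 1 for a truly unexposed code must
    still commit to legal frequency/intensity levels, drawn from the
    config's laws.
    """
    rng = _rng(config, 1)
    eps = config.rater_error
    rows: list[tuple] = []
    for r in range(1, config.n_raters + 1):
        rater_id = f"r{r}"
        for rec in truth.itertuples(index=False):
            lk = int(rec.likelihood)
            if rng.random() < eps:
                lk = 1 - lk
            if lk == 0:
                rows.append((rater_id, rec.code4, round, 0, pd.NA, pd.NA))
                continue
            if int(rec.likelihood) == 1:
                fr, it = int(rec.frequency), int(rec.intensity)
                if rng.random() < eps:
                    fr = _perturb(fr, 1, 4, config.deviation_kernel, rng)
                if rng.random() < eps:
                    it = _perturb(it, 1, 3, config.deviation_kernel, rng)
            else:  # spurious exposure: invent a plausible profile
                fr = int(rng.choice([1, 2, 3, 4], p=config.frequency_law))
                it = int(rng.choice([1, 2, 3], p=config.intensity_law))
            rows.append((rater_id, rec.code4, round, 1, fr, it))
    df = pd.DataFrame(rows, columns=list(RATING_COLUMNS))
    for axis in ("likelihood", "frequency", "intensity"):
        df[axis] = df[axis].astype("Int64")
    return df


def simulate_workforce_and_crosswalk(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Source-version workforce counts, a mixed crosswalk, and a
    socio-economic class mapping.

    The crosswalk maps source codes (an older classification version) onto
    the truth's target codes with a configurable mix of identity (1->1),
    merge (2 sources -> 1 target, weight 1 each) and split (1 source -> 2
    targets, complementary weights) mappings.  Workforce counts are
    lognormal, rounded to the nearest 100 (the convention of official
    labour-market extracts).  The class mapping assigns each 2-digit group
    a synthetic socio-economic class 1–8.
    """
    rng = _rng(config, 2)
    targets = list(truth["code4"].astype(str))
    order = rng.permutation(len(targets))
    shuffled = [targets[i] for i in order]

    p_id, p_merge, p_split = config.crosswalk_mix
    n = len(shuffled)
    n_split_targets = 2 * int(p_split * n / 2)   # splits consume targets in pairs
    n_merge_targets = int(p_merge * n)

    split_targets = shuffled[:n_split_targets]
    merge_targets = shuffled[n_split_targets:n_split_targets + n_merge_targets]
    identity_targets = shuffled[n_split_targets + n_merge_targets:]

    taken = set(targets)
    fresh = (f"{k:04d}" for k in range(10_000))

    def new_code() -> str:
        for c in fresh:
            if c not in taken:
                taken.add(c)
                return c
        raise RuntimeError("exhausted 4-digit code space")

    xw_rows: list[tuple[str, str, float]] = []
    for code in identity_targets:
        xw_rows.append((code, code, 1.0))
    for t1, t2 in zip(split_targets[0::2], split_targets[1::2]):
        src = new_code()
        w = float(np.round(rng.uniform(0.2, 0.8), 3))
        xw_rows.append((src, t1, w))
        xw_rows.append((src, t2, 1.0 - w))
    for tgt in merge_targets:
        xw_rows.append((new_code(), tgt, 1.0))
        xw_rows.append((new_code(), tgt, 1.0))
    xwalk = pd.DataFrame(xw_rows, columns=["source", "target", "weight"])

    sources = sorted(xwalk["source"].unique())
    counts = rng.lognormal(config.workforce_mu, config.workforce_sigma, size=len(sources))
    counts = (np.round(counts / 100) * 100).astype(int)
    wf = pd.DataFrame({
        "code4": sources,
        "scheme_version": "SOC2010",
        "jobholders": counts,
    })

    groups = sorted(set(code2_of(truth["code4"].astype(str))))
    group_class = {g: int(rng.integers(1, 9)) for g in groups}
    nssec = pd.DataFrame({
        "code4": targets,
        "nssec_class": [group_class[c[:2]] for c in targets],
    })
    return wf, xwalk.sort_values(["source", "target"]).reset_index(drop=True), nssec


def write_fixtures(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Simulate everything and write the five CSV inputs plus the truth.

    Files: codes.csv, ratings.csv, workforce.csv (source version),
    crosswalk.csv, nssec_map.csv, truth_jem.csv.  Returns name -> path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    codes, truth = simulate_truth(config)
    ratings = simulate_raters(truth, config)
    wf, xwalk, nssec = simulate_workforce_and_crosswalk(truth, config)
    paths = {}
    for name, df in [
        ("codes", codes), ("ratings", ratings), ("workforce", wf),
        ("crosswalk", xwalk), ("nssec_map", nssec), ("truth_jem", truth),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Synthetic stand-ins for the published UK 2020 artefacts
# ---------------------------------------------------------------------------

#: The UK 2020 jobholder counts by (frequency, intensity) of potential SHS
#: exposure, typed from the published cross-tabulation (counts of persons).
UK_CROSSTAB_CELLS_2020: dict[tuple[int, int], int] = {
    (0, 0): 35_729_200,
    (1, 2): 17_900,
    (1, 3): 1_587_800,
    (2, 1): 83_500,
    (2, 2): 408_800,
    (2, 3): 2_706_700,
    (3, 1): 3_037_700,
    (3, 2): 904_600,
    (3, 3): 789_000,
    (4, 3): 884_700,
}


def uk_jobholder_crosstab_2020() -> ExposureCrossTab:
    """The published UK 2020 frequency x intensity jobholder table."""
    return ExposureCrossTab(cells=dict(UK_CROSSTAB_CELLS_2020))


# Group structure of the stand-in JEM: 2-digit group -> (n_codes, n_likely,
# cells of its likely codes).  The named groups carry the likely-fractions
# reported for the UK JEM: skilled agricultural trades 5/5, skilled
# construction 11/12, elementary administration & service 16/26, elementary
# trades 4/8, caring personal service 7/16, and the office groups 0/20 and
# 0/28; cell placements follow the reported exposure profiles (agricultural
# work: frequent but outdoor; in-home care: daily, indoors).
_STANDIN_CONSTRAINED: dict[str, tuple[int, list[tuple[int, int]]]] = {
    "21": (28, []),                                            # science/eng professionals
    "22": (24, [(2, 3)] * 3 + [(1, 3)] * 2),                   # health professionals
    "41": (20, []),                                            # administrative
    "51": (5, [(3, 1)] * 5),                                   # skilled agricultural
    "53": (12, [(3, 1)] * 8 + [(2, 1)] * 2 + [(3, 2)]),        # skilled construction
    "61": (16, [(4, 3)] * 3 + [(3, 3)] * 2 + [(2, 3)] * 2),    # caring personal service
    "91": (8, [(3, 1)] * 2 + [(2, 3)] * 2),                    # elementary trades
    "92": (26, [(3, 2)] * 4 + [(2, 3)] * 6 + [(3, 3)] * 3 + [(2, 2)] * 2 + [(1, 3)]),
}
_STANDIN_OTHER_GROUPS = ("11", "12", "23", "24", "31", "32", "33", "34", "35",
                         "42", "52", "54", "62", "63", "71", "72", "81", "82")
# cells for the 36 likely codes spread 2-per-group over the other 18 groups
_STANDIN_OTHER_CELLS = ([(3, 1)] * 13 + [(3, 2)] * 5 + [(3, 3)] * 3
                        + [(2, 3)] * 5 + [(2, 2)] * 3 + [(1, 3)] * 5 + [(1, 2)] * 2)
# codes of the caring group; includes the three maximal-severity occupations
_CARING_CODES = [f"61{k:02d}" for k in range(1, 14)] + ["6116", "6135", "6137"]
_CARING_LIKELY = ["6116", "6135", "6137", "6101", "6102", "6103", "6104"]


def synthetic_uk_jem() -> pd.DataFrame:
    """Synthetic stand-in for the deposited UK 2020 SHS-JEM.

    This is NOT the published per-code table (which is distributed as
    journal supplementary material); it is a synthetic reconstruction
    constrained to reproduce every summary margin reported for it:

    * 412 four-digit codes in 26 two-digit groups, 84 (20.4%) rated likely;
    * mean compound severity exactly 1.0, range 0–12;
    * exactly three codes at the maximal severity 12 — 6116 (nannies and
      au pairs), 6135 (care workers and home carers), 6137 (care escorts);
    * the reported group likely-fractions (5/5, 11/12, 16/26, 4/8, 7/16,
      0/20, 0/28);
    * per-cell code counts consistent with the published jobholder
      cross-tabulation, so pairing it with ``synthetic_uk_workforce``
      reproduces that table cell for cell.

    Per-code ratings other than these constraints are arbitrary; the
    stand-in is deterministic.
    """
    records: list[dict] = []

    def add(code4: str, cell: tuple[int, int] | None) -> None:
        if cell is None:
            lk, fr, it = 0, 0, 0
        else:
            lk, (fr, it) = 1, cell
        records.append({
            "code4": code4,
            "title": f"Synthetic occupation {code4}",
            "likelihood": lk, "frequency": fr, "intensity": it,
            "severity": lk * fr * it,
        })

    for code2, (n_codes, cells) in sorted(_STANDIN_CONSTRAINED.items()):
        if code2 == "61":
            likely_cells = dict(zip(_CARING_LIKELY, cells))
            for code4 in _CARING_CODES:
                add(code4, likely_cells.get(code4))
        else:
            group_codes = [f"{code2}{k:02d}" for k in range(1, n_codes + 1)]
            for j, code4 in enumerate(group_codes):
                add(code4, cells[j] if j < len(cells) else None)

    other_cells = list(_STANDIN_OTHER_CELLS)
    for g, code2 in enumerate(_STANDIN_OTHER_GROUPS):
        n_codes = 16 if code2 in ("11", "12", "23") else 15
        cells = [other_cells.pop(0), other_cells.pop(0)]
        for j, code4 in enumerate(f"{code2}{k:02d}" for k in range(1, n_codes + 1)):
            add(code4, cells[j] if j < 2 else None)
    assert not other_cells

    jem = pd.DataFrame.from_records(records).sort_values("code4").reset_index(drop=True)
    for axis in ("likelihood", "frequency", "intensity"):
        jem[axis] = jem[axis].astype("Int64")
    return jem


def synthetic_uk_workforce(jem: pd.DataFrame | None = None) -> pd.DataFrame:
    """Synthetic jobholder counts matched to ``synthetic_uk_jem``.

    The published per-cell jobholder totals are divided over the stand-in
    codes falling in each cell, in multiples of 100 (the rounding
    convention of the source extracts), so the cross-tabulation of the
    stand-in JEM with these counts equals the published table exactly.
    """
    if jem is None:
        jem = synthetic_uk_jem()
    by_cell: dict[tuple[int, int], list[str]] = {}
    for row in jem.itertuples(index=False):
        cell = (0, 0) if int(row.likelihood) == 0 else (int(row.frequency), int(row.intensity))
        by_cell.setdefault(cell, []).append(str(row.code4))

    rows: list[tuple[str, str, int]] = []
    for cell, codes in by_cell.items():
        total_units = UK_CROSSTAB_CELLS_2020[cell] // 100
        base, rem = divmod(total_units, len(codes))
        for j, code4 in enumerate(sorted(codes)):
            rows.append((code4, "SOC2020", (base + (1 if j < rem else 0)) * 100))
    wf = pd.DataFrame(rows, columns=["code4", "scheme_version", "jobholders"])
    return wf.sort_values("code4").reset_index(drop=True)
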