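"""Derivation of analysis traits from raw common-garden measurements.

Twelve traits are carried through the quantitative-genetic analysis:

========  =====================================================  =========
name      definition                                             unit
========  =====================================================  =========
H         stem height                                            cm
D         stem diameter at 22 cm above ground                    mm
VI        volume index, D^2 * H (after unit harmonization)       cm^3
CD        crown diameter, mean of two perpendicular readings     cm
NB        number of branches on the main stem                    count
NSyll     sylleptic branch count, log(x+1) transformed           log count
RNB       relative number of branches, NB / H                    1/cm
RCD       relative canopy depth, (I_high - I_low) / H            fraction
d13C      carbon isotope ratio vs. the Pee Dee Belemnite std     per mil
BF        bud flush date                                         Julian day
BS        bud set date                                           Julian day
I20       electrolyte-leakage injury index after -20 C freeze    percent
========  =====================================================  =========

All functions accept scalars or numpy/pandas array-likes and vectorize
element-wise.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gardenqg.exceptions import DegenerateInputError

#: Columns of the derived-trait table, in canonical order.
TRAIT_NAMES = [
    "H",
    "D",
    "VI",
    "CD",
    "NB",
    "NSyll_log",
    "RNB",
    "RCD",
    "d13C",
    "BF",
    "BS",
    "I20",
]

#: The eight growth / branching traits entering the PCA preprocessing step.
GROWTH_BRANCH_TRAITS = ["H", "D", "VI", "CD", "NB", "NSyll_log", "RNB", "RCD"]

#: Design/key columns expected in phenotype tables.
DESIGN_COLUMNS = ["block", "population", "genotype"]


def delta13c(r_sample, r_standard):
    """Carbon isotope ratio in per mil relative to a standard.

    delta13C = (R_sample - R_standard) / R_standard * 1000, with R the
    13C:12C ratio of the combusted sample and of the Pee Dee Belemnite
    standard respectively.

    Raises
    ------
    DegenerateInputError
        If any standard ratio is <= 0.
    """
    r_sa = np.asarray(r_sample, dtype=float)
    r_sd = np.asarray(r_standard, dtype=float)
    if np.any(r_sd <= 0):
        raise DegenerateInputError("standard isotope ratio must be positive")
    out = (r_sa - r_sd) / r_sd * 1000.0
    return out.item() if out.ndim == 0 else out


def injury_index(l_t, l_k, l_0, l_d):
    """Flint index of freezing injury (percent) from electrolyte leakage.

    I = 100 (R_t - R_0) / (1 - R_0) with R_t = L_t / L_k the relative
    conductivity of the frozen sample (leachate over heat-killed leachate)
    and R_0 = L_0 / L_d the same for the unfrozen control.  Values are
    passed through un-clamped: measurement noise can yield slightly
    negative indices and those are informative for downstream variance
    components.

    Raises
    ------
    DegenerateInputError
        If a heat-kill conductivity is <= 0 or a control relative
        conductivity reaches 1 (degenerate control).
    """
    l_t = np.asarray(l_t, dtype=float)
    l_k = np.asarray(l_k, dtype=float)
    l_0 = np.asarray(l_0, dtype=float)
    l_d = np.asarray(l_d, dtype=float)
    if np.any(l_k <= 0) or np.any(l_d <= 0):
        raise DegenerateInputError("heat-kill conductivities must be positive")
    r_t = l_t / l_k
    r_0 = l_0 / l_d
    if np.any(r_0 >= 1):
        raise DegenerateInputError(
            "control relative conductivity R_0 >= 1: injury index undefined"
        )
    out = 100.0 * (r_t - r_0) / (1.0 - r_0)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class ScoringWindow:
    """First and last phenology scoring visits, as days of year.

    Events already past at the first visit are recorded one week before it;
    events still pending at the last visit are recorded one week after it.
    """

    first: int
    last: int

    def __post_init__(self):
        if self.last < self.first:
            raise ValueError("scoring window: last visit before first visit")


def julian_day(date) -> int:
    """Day of year counted from December 31 (January 1 -> 1)."""
    if isinstance(date, (_dt.date, _dt.datetime, pd.Timestamp)):
        return int(pd.Timestamp(date).dayofyear)
    return int(date)


def to_julian_day(date, window: ScoringWindow | None = None, censored: str | None = None):
    """Convert a phenology event date to a (possibly censored) Julian day.

    Parameters
    ----------
    date
        Calendar date (datetime/date/Timestamp) or day-of-year integer.
        For a censored record, pass the relevant visit date.
    window
        Scoring window; required when `censored` is given or when the
        boundary rule should apply to out-of-window days.
    censored
        ``"left"`` — event had already occurred at the first visit, recorded
        as ``window.first - 7``; ``"right"`` — event had not occurred by the
        last visit, recorded as ``window.last + 7``; ``None`` — observed.
    """
    doy = julian_day(date)
    if censored is not None:
        if window is None:
            raise ValueError("censored records require a scoring window")
        if censored == "left":
            return window.first - 7
        if censored == "right":
            return window.last + 7
        raise ValueError(f"unknown censoring code: {censored!r}")
    if window is not None:
        if doy < window.first:
            return window.first - 7
        if doy > window.last:
            return window.last + 7
    return doy


def derive_growth(
    H,
    D,
    CD_ns,
    CD_ew,
    I_high,
    I_low,
    NB,
    NSyll,
    *,
    diameter_unit: str = "mm",
) -> pd.DataFrame:
    """Derive the growth and branching traits from raw measurements.

    Heights and crown/insertion measures are in cm; the stem diameter is in
    ``diameter_unit`` (``"mm"`` by default, converted to cm) so the volume
    index VI = D^2 * H is reported in cm^3 throughout.

    Returns a DataFrame with columns H, D, VI, CD, NB, NSyll_log, RNB, RCD.
    D is reported back on its original scale; only VI uses the harmonized
    unit.
    """
    H = np.atleast_1d(np.asarray(H, dtype=float))
    if np.any(H <= 0):
        raise DegenerateInputError("height must be positive for ratio traits")
    D = np.atleast_1d(np.asarray(D, dtype=float))
    if diameter_unit == "mm":
        d_cm = D / 10.0
    elif diameter_unit == "cm":
        d_cm = D
    else:
        raise ValueError(f"unknown diameter unit: {diameter_unit!r}")
    I_high = np.atleast_1d(np.asarray(I_high, dtype=float))
    I_low = np.atleast_1d(np.asarray(I_low, dtype=float))
    if np.any(I_high < I_low):
        raise DegenerateInputError("highest insertion below lowest insertion")
    NB = np.atleast_1d(np.asarray(NB, dtype=float))
    NSyll = np.atleast_1d(np.asarray(NSyll, dtype=float))
    out = pd.DataFrame(
        {
            "H": H,
            "D": D,
            "VI": d_cm**2 * H,
            "CD": (
                np.atleast_1d(np.asarray(CD_ns, dtype=float))
                + np.atleast_1d(np.asarray(CD_ew, dtype=float))
            ) / 2.0,
            "NB": NB,
            "NSyll_log": np.log(NSyll + 1.0),
            "RNB": NB / H,
            "RCD": (I_high - I_low) / H,
        }
    )
    return out


def derive_traits(
    raw: pd.DataFrame,
    *,
    bf_window: ScoringWindow | None = None,
    bs_window: ScoringWindow | None = None,
    diameter_unit: str = "mm",
) -> pd.DataFrame:
    """Derive the full 12-trait table from a ramet-level raw table.

    Expected raw columns: the design keys (block, population, genotype),
    growth measures (H, D, CD_ns, CD_ew, I_high, I_low, NB, NSyll),
    isotope ratios (R_sa, R_sd), conductivities (L_t, L_k, L_0, L_d) —
    either single columns or replicate columns suffixed _1.._k whose Flint
    indices are averaged — and bud dates (BF_date, BS_date as days of year
    or dates, with optional BF_censored / BS_censored codes).
    Missing raw cells propagate to missing derived traits.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table lacks design columns: {missing}")
    out = raw[DESIGN_COLUMNS].copy()
    growth = derive_growth(
        raw["H"], raw["D"], raw["CD_ns"], raw["CD_ew"],
        raw["I_high"], raw["I_low"], raw["NB"], raw["NSyll"],
        diameter_unit=diameter_unit,
    )
    growth.index = raw.index
    out = pd.concat([out, growth], axis=1)
    out["d13C"] = delta13c(raw["R_sa"], raw["R_sd"])

    # injury: average Flint indices over replicate shoot-segment
    # determinations when replicate columns are present
    reps = sorted(
        int(c.rsplit("_", 1)[1])
        for c in raw.columns
        if c.startswith("L_t_") and c.rsplit("_", 1)[1].isdigit()
    )
    if reps:
        vals = [
            injury_index(
                raw[f"L_t_{i}"], raw[f"L_k_{i}"], raw[f"L_0_{i}"], raw[f"L_d_{i}"]
            )
            for i in reps
        ]
        out["I20"] = np.mean(np.column_stack(vals), axis=1)
    else:
        out["I20"] = injury_index(raw["L_t"], raw["L_k"], raw["L_0"], raw["L_d"])

    for trait, date_col, window in (
        ("BF", "BF_date", bf_window),
        ("BS", "BS_date", bs_window),
    ):
        cens = raw.get(f"{trait}_censored")
        out[trait] = [
            np.nan
            if pd.isna(d)
            else to_julian_day(
                d, window, None if cens is None or pd.isna(cens.iloc[i]) else cens.iloc[i]
            )
            for i, d in enumerate(raw[date_col])
        ]
    return out[DESIGN_COLUMNS + TRAIT_NAMES]
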