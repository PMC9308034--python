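"""Physician capacity estimation from opening hours and quarterly contacts.

Each physician's observed load ``N`` is the number of distinct patients seen
per quarter (averaged over the quarters present in the data).  The maximum
capacity ``C`` is estimated from opening hours: within each specialty,
physicians are binned by weekly opening hours (bin width 5 h, half-open
intervals [0,5), [5,10), ...); within each bin the median ``N`` of the top
``c``% busiest physicians is assigned to everyone in the bin as their
capacity.  Finally ``C`` is floored at the physician's own ``N`` so nobody
starts over capacity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network import parse_contact_dates


def quarterly_patient_counts(contacts: pd.DataFrame) -> pd.Series:
    """Distinct patients per physician per quarter, averaged over quarters.

    Only quarters in which the physician saw at least one patient enter the
    average; the result is rounded to the nearest integer.
    """
    dates = parse_contact_dates(contacts)
    quarters = dates.dt.to_period("Q")
    per_quarter = (
        contacts.assign(_q=quarters)
        .groupby(["physician_id", "_q"], observed=True)["patient_id"]
        .nunique()
    )
    mean = per_quarter.groupby("physician_id").mean()
    return mean.round().astype(int).rename("N")


def top_fraction_median(values: np.ndarray, c: float) -> float:
    """Median of the top-``c``% largest values; set size ceil(c/100*n), min 1."""
    values = np.sort(np.asarray(values, dtype=float))
    k = max(1, math.ceil(c / 100.0 * values.size))
    return float(np.median(values[-k:]))


def estimate_capacity(
    profiles: pd.DataFrame,
    bin_hours: float = 5.0,
    c: float = 10.0,
) -> pd.DataFrame:
    """Assign maximum capacities ``C`` to a profile table.

    ``profiles`` needs columns ``physician_id``, ``specialty``,
    ``opening_hours`` (NaN allowed) and ``N``.  Returns a copy with an added
    integer column ``C`` satisfying ``C >= N``.  Physicians with missing
    opening hours receive the median ``C`` of their specialty (computed over
    the binned physicians); a specialty with no opening-hour information at
    all is treated as a single bin.
    """
    if not 0 < c <= 100:
        raise ConfigurationError(f"c must be in (0, 100], got {c}")
    if bin_hours <= 0:
        raise ConfigurationError("bin_hours must be positive")
    out = profiles.copy()
    hours = pd.to_numeric(out["opening_hours"], errors="coerce")
    if (hours.dropna() < 0).any():
        raise ConfigurationError("opening hours must be non-negative")
    out["_bin"] = np.floor(hours / bin_hours)

    C = pd.Series(np.nan, index=out.index)
    for spec, group in out.groupby("specialty", observed=True):
        binned = group[group["_bin"].notna()]
        if binned.empty:
            # no opening-hour data for this specialty: one bin for everyone
            C.loc[group.index] = top_fraction_median(
                group["N"].to_numpy(), c)
            continue
        for _, sub in binned.groupby("_bin"):
            C.loc[sub.index] = top_fraction_median(sub["N"].to_numpy(), c)
        missing = group.index.difference(binned.index)
        if len(missing):
            C.loc[missing] = float(np.median(C.loc[binned.index]))
    out["C"] = np.maximum(np.round(C).astype(int), out["N"].astype(int))
    return out.drop(columns="_bin")


def build_profiles(
    contacts: pd.DataFrame,
    physicians: pd.DataFrame,
    bin_hours: float = 5.0,
    c: float = 10.0,
) -> pd.DataFrame:
    """Merge quarterly loads and capacity estimates into one profile table.

    Physicians without any recorded visit get ``N = 0``.  Returns columns
    ``physician_id``, ``specialty``, ``municipality_id``, ``opening_hours``,
    ``N``, ``C``.
    """
    counts = quarterly_patient_counts(contacts)
    profiles = physicians[["physician_id", "specialty", "municipality_id",
                           "opening_hours"]].copy()
    profiles["N"] = profiles["physician_id"].map(counts).fillna(0).astype(int)
    return estimate_capacity(profiles, bin_hours=bin_hours, c=c)
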