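"""Synthetic administrative visit-record generator.

Real physician-claims data are access-restricted, so this module generates the
three tables the rest of the package consumes with the statistical structure
such data exhibit:

``municipalities``
    gazetteer of 5-digit municipality IDs with coordinates; the first digit of
    the ID encodes the federal state (at most 9 states).
``physicians``
    one row per (physician, specialty, municipality) combination with weekly
    opening hours and a latent log-normal popularity used by the visit model.
``contacts``
    roughly one year of patient visits; each patient has a home municipality
    and chooses physicians with probability decaying exponentially in distance
    (a gravity model), which together with the log-normal popularity produces
    heavy-tailed per-physician patient loads.

All draws are keyed off ``SynthConfig.seed`` so a configuration maps to
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: The 13 outpatient specialties modelled, by their customary abbreviations
#: (general practice, ophthalmology, surgery, dermatology, gynaecology and
#: obstetrics, otorhinolaryngology, internal medicine, paediatrics, neurology,
#: orthopaedics, psychiatry, radiology, urology).
SPECIALTIES: tuple[str, ...] = (
    "GP", "OPH", "SRG", "DER", "OBGYN", "ENT", "IM",
    "PED", "NEU", "ORTH", "PSY", "RAD", "URO",
)

# Bounding box (lat_min, lat_max, lon_min, lon_max) of the synthetic country;
# roughly the extent of a small alpine country, ~600 km east-west.
_BOX = (46.4, 49.0, 9.5, 17.2)


@dataclasses.dataclass
class SynthConfig:
    """Parameters of the synthetic-data generator.

    Defaults are sized for a desk-scale system: 9 federal states, 13
    specialties, a few hundred physicians and a few thousand patients over
    one year of visits.

    Parameters
    ----------
    n_municipalities
        Number of municipalities, spread as evenly as possible over states.
    n_states
        Number of federal states (at most 9; the state is the leading digit
        of the 5-digit municipality ID).
    n_physicians_per_specialty
        Physicians generated for each specialty label.
    specialties
        Specialty labels; defaults to the 13 standard abbreviations.
    n_patients
        Number of patients generating visits.
    visits_per_patient_mean
        Mean of the Poisson number of visits per patient over the period.
    period_days
        Length of the observation period in days.
    locality_scale_km
        e-folding distance (km) of the patient–physician affinity kernel;
        smaller values make visits more local.
    opening_hours_range
        (low, high) bounds of uniformly drawn weekly opening hours.
    seed
        Master seed; all three tables derive from it deterministically.
    """

    n_municipalities: int = 90
    n_states: int = 9
    n_physicians_per_specialty: int = 30
    specialties: Sequence[str] = SPECIALTIES
    n_patients: int = 12000
    visits_per_patient_mean: float = 13.0
    period_days: int = 365
    locality_scale_km: float = 30.0
    opening_hours_range: tuple[float, float] = (15.0, 45.0)
    seed: int = 0
    start_date: str = "2018-01-01"

    def __post_init__(self) -> None:
        if not 1 <= self.n_states <= 9:
            raise ConfigurationError(
                "n_states must be in 1..9 (the state is one leading digit), "
                f"got {self.n_states}"
            )
        for name in ("n_municipalities", "n_physicians_per_specialty",
                     "n_patients", "period_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_municipalities < self.n_states:
            raise ConfigurationError("need at least one municipality per state")
        if self.visits_per_patient_mean <= 0:
            raise ConfigurationError("visits_per_patient_mean must be positive")
        if self.locality_scale_km < 0:
            raise ConfigurationError("locality_scale_km must be non-negative")
        lo, hi = self.opening_hours_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("opening_hours_range must satisfy 0 <= lo <= hi")
        if not self.specialties:
            raise ConfigurationError("specialties must be non-empty")
        if len(set(self.specialties)) != len(self.specialties):
            raise ConfigurationError("specialty labels must be unique")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    # one independent stream per table keeps tables stable if only a later
    # stage's parameters change
    return np.random.default_rng([cfg.seed, stream])


def generate_municipalities(cfg: SynthConfig) -> pd.DataFrame:
    """Generate the municipality gazetteer.

    States are spatially contiguous Gaussian clusters around centres laid out
    on a grid inside the bounding box.  Each municipality additionally gets a
    Zipf-like ``weight`` (a population-size proxy) that the physician and
    patient generators use, producing urban/rural heterogeneity.

    Returns a DataFrame with columns ``municipality_id`` (5-digit string,
    leading digit = state), ``lat``, ``lon``, ``weight``.
    """
    rng = _rng(cfg, 0)
    lat_min, lat_max, lon_min, lon_max = _BOX
    lat = rng.uniform(lat_min, lat_max, cfg.n_municipalities)
    lon = rng.uniform(lon_min, lon_max, cfg.n_municipalities)

    # states tile the country contiguously: equal-count longitude bands,
    # each split by latitude — like federal states sharing borders rather
    # than sitting on isolated islands
    base, extra = divmod(cfg.n_municipalities, cfg.n_states)
    counts = [base + (1 if s < extra else 0) for s in range(cfg.n_states)]
    ncols = math.ceil(math.sqrt(cfg.n_states))
    col_of_state = [s % ncols for s in range(cfg.n_states)]

    by_lon = np.argsort(lon, kind="stable")
    rows = []
    cursor = 0
    for col in range(ncols):
        states_here = [s for s in range(cfg.n_states) if col_of_state[s] == col]
        band_n = sum(counts[s] for s in states_here)
        band = by_lon[cursor:cursor + band_n]
        cursor += band_n
        band = band[np.argsort(lat[band], kind="stable")]
        offset = 0
        for s in states_here:
            for k, idx in enumerate(band[offset:offset + counts[s]]):
                rows.append((f"{s + 1}{k + 1:04d}", lat[idx], lon[idx]))
            offset += counts[s]
    table = pd.DataFrame(rows, columns=["municipality_id", "lat", "lon"])
    table = table.sort_values("municipality_id", kind="stable",
                              ignore_index=True)
    # Zipf-like size weights (rank^-0.9 over a random permutation) scaled by
    # a log-normal per-state urbanisation factor: states differ
    # systematically in how much population, and hence how many physicians
    # and patients, they attract — the urban/rural heterogeneity real
    # federal states exhibit
    ranks = rng.permutation(len(table)) + 1
    weight = ranks.astype(float) ** -0.9
    state_factor = rng.lognormal(0.0, 0.8, cfg.n_states)
    state_idx = table["municipality_id"].str[0].astype(int) - 1
    weight = weight * state_factor[state_idx]
    table["weight"] = weight / weight.sum()
    return table


def generate_physicians(cfg: SynthConfig, municipalities: pd.DataFrame) -> pd.DataFrame:
    """Generate the physician attribute table.

    Municipality assignment follows the gazetteer size weights; weekly
    opening hours are uniform over ``opening_hours_range``; ``popularity``
    is log-normal so per-physician patient loads come out heavy-tailed.
    """
    rng = _rng(cfg, 1)
    weights = municipalities["weight"].to_numpy()
    weights = weights / weights.sum()
    rows = []
    idx = 0
    for spec in cfg.specialties:
        muni = rng.choice(
            municipalities["municipality_id"].to_numpy(),
            size=cfg.n_physicians_per_specialty, p=weights,
        )
        lo, hi = cfg.opening_hours_range
        hours = rng.uniform(lo, hi, cfg.n_physicians_per_specialty)
        popularity = rng.lognormal(0.0, 0.75, cfg.n_physicians_per_specialty)
        for k in range(cfg.n_physicians_per_specialty):
            idx += 1
            rows.append((f"D{idx:05d}", spec, muni[k],
                         round(hours[k], 1), popularity[k]))
    return pd.DataFrame(
        rows,
        columns=["physician_id", "specialty", "municipality_id",
                 "opening_hours", "popularity"],
    )


def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return 6371.0088 * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def generate_contacts(
    cfg: SynthConfig,
    municipalities: pd.DataFrame,
    physicians: pd.DataFrame,
) -> pd.DataFrame:
    """Generate the visit-record table.

    Each patient draws a home municipality (size-weighted), a Poisson number
    of visits, and for every visit a physician with probability proportional
    to ``popularity * exp(-distance / locality_scale_km)``.  With
    ``locality_scale_km == 0`` only physicians in the home municipality are
    eligible (falling back to the nearest municipality with physicians when
    the home one has none).  Visit dates are i.i.d. uniform over the period.

    Returns a DataFrame with columns ``patient_id``, ``physician_id``,
    ``date`` (datetime), ``municipality_id`` (the physician's).
    """
    if physicians.empty:
        raise ConfigurationError("physician table is empty")
    rng = _rng(cfg, 2)

    muni_ids = municipalities["municipality_id"].to_numpy()
    muni_pos = {m: k for k, m in enumerate(muni_ids)}
    lat = municipalities["lat"].to_numpy()
    lon = municipalities["lon"].to_numpy()
    dist = _haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])

    phys_muni = np.array([muni_pos[m] for m in physicians["municipality_id"]])
    popularity = physicians["popularity"].to_numpy()

    # per-home-municipality categorical weights over physicians
    d_home_phys = dist[:, phys_muni]                     # (n_muni, n_phys)
    if cfg.locality_scale_km == 0.0:
        kernel = (d_home_phys == 0.0).astype(float)
    else:
        kernel = np.exp(-d_home_phys / cfg.locality_scale_km)
    weights = popularity[None, :] * kernel
    row_sums = weights.sum(axis=1)
    for m in np.flatnonzero(row_sums == 0.0):
        near = d_home_phys[m] == d_home_phys[m].min()
        weights[m, near] = popularity[near]
        row_sums[m] = weights[m].sum()
    weights /= row_sums[:, None]

    home_w = municipalities["weight"].to_numpy()
    home = rng.choice(len(muni_ids), size=cfg.n_patients, p=home_w / home_w.sum())
    n_visits = rng.poisson(cfg.visits_per_patient_mean, cfg.n_patients)

    # draw all visits of patients sharing a home municipality in one call
    patient_col = np.repeat(np.arange(cfg.n_patients), n_visits)
    phys_col = np.empty(int(n_visits.sum()), dtype=int)
    visit_home = np.repeat(home, n_visits)
    for m in np.unique(visit_home):
        mask = visit_home == m
        phys_col[mask] = rng.choice(len(popularity), size=int(mask.sum()),
                                    p=weights[m])
    offsets = rng.integers(0, cfg.period_days, size=phys_col.size)

    start = pd.Timestamp(cfg.start_date)
    phys_ids = physicians["physician_id"].to_numpy()
    phys_muni_ids = physicians["municipality_id"].to_numpy()
    contacts = pd.DataFrame({
        "patient_id": np.char.add("P", np.char.zfill(
            patient_col.astype(str), 6)),
        "physician_id": phys_ids[phys_col],
        "date": start + pd.to_timedelta(offsets, unit="D"),
        "municipality_id": phys_muni_ids[phys_col],
    })
    return contacts.sort_values(
        ["patient_id", "date", "physician_id"], kind="stable"
    ).reset_index(drop=True)


def generate_dataset(cfg: SynthConfig):
    """Generate (municipalities, physicians, contacts) in one call."""
    municipalities = generate_municipalities(cfg)
    physicians = generate_physicians(cfg, municipalities)
    contacts = generate_contacts(cfg, municipalities, physicians)
    return municipalities, physicians, contacts


def write_tables(
    municipalities: pd.DataFrame,
    physicians: pd.DataFrame,
    contacts: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write the three tables as headered CSV with ISO-8601 dates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    municipalities.to_csv(outdir / "municipalities.csv", index=False)
    physicians.to_csv(outdir / "physicians.csv", index=False)
    out = contacts.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(outdir / "contacts.csv", index=False)
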