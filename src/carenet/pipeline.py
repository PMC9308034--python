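"""End-to-end orchestration: tables -> network -> capacity -> simulation ->
indicators, with input validation, reproducible seeding and a run manifest.

A run is described by a YAML/JSON config with the blocks

``synthetic``      SynthConfig fields (mutually exclusive with ``inputs``)
``inputs``         paths to contacts.csv / physicians.csv / municipalities.csv
``network``        {window_days}
``params``         SimulationParams fields (s, c, d, p, alpha, seed, ...)
``scenario``       "removal" (default) or "shock"
``shock_fraction`` percentage of physicians removed at once (default 15)
``specialties``    subset to simulate (default: all present)
``output_dir``     where results are written
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacity import build_profiles
from .errors import ConfigurationError, ValidationError
from .indicators import (benefit_scores, critical_limits, regional_levels,
                         resilience_curves, risk_scores,
                         score_resilience_regression)
from .network import (build_sharing_network, parse_contact_dates,
                      specialty_layer, threshold_network, write_edgelist,
                      write_graphml, write_node_table)
from .simulation import (RemovalTrajectory, ShockResult, SimulationParams,
                         compile_system, run_removal_ensemble,
                         run_shock_ensemble)
from .synth import SynthConfig, generate_dataset

_MUNI_RE = re.compile(r"^\d{5}$")

_CONTACT_COLS = ["patient_id", "physician_id", "date", "municipality_id"]
_PHYS_COLS = ["physician_id", "specialty", "municipality_id", "opening_hours"]
_MUNI_COLS = ["municipality_id", "lat", "lon"]


def validate_tables(
    contacts: pd.DataFrame,
    physicians: pd.DataFrame,
    municipalities: pd.DataFrame,
    period: tuple[str, int] | None = None,
) -> None:
    """Schema and referential-integrity checks; raises before any simulation.

    Rejects missing columns, non-5-digit municipality IDs, negative opening
    hours, unknown physician/municipality references, unparseable dates and
    (when ``period`` = (start, days) is given) dates outside the period.
    """
    for name, table, cols in (("contacts", contacts, _CONTACT_COLS),
                              ("physicians", physicians, _PHYS_COLS),
                              ("municipalities", municipalities, _MUNI_COLS)):
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValidationError(f"{name} table lacks columns {missing}")
    muni_ids = municipalities["municipality_id"].astype(str)
    bad = muni_ids[~muni_ids.str.match(_MUNI_RE)]
    if len(bad):
        raise ValidationError(
            f"municipality IDs must be 5 digits, e.g. {bad.iloc[0]!r}")
    for name, table in (("physicians", physicians), ("contacts", contacts)):
        ids = table["municipality_id"].astype(str)
        unknown = set(ids) - set(muni_ids)
        if unknown:
            raise ValidationError(
                f"{name} reference unknown municipalities: {sorted(unknown)[:5]}")
    hours = pd.to_numeric(physicians["opening_hours"], errors="coerce")
    if (hours.dropna() < 0).any():
        raise ValidationError("negative opening hours in physician table")
    unknown_phys = set(contacts["physician_id"]) - set(physicians["physician_id"])
    if unknown_phys:
        raise ValidationError(
            f"contacts reference unknown physicians: {sorted(unknown_phys)[:5]}")
    dates = parse_contact_dates(contacts)
    if period is not None:
        start = pd.Timestamp(period[0])
        end = start + pd.Timedelta(days=int(period[1]))
        outside = (dates < start) | (dates >= end)
        if outside.any():
            row = int(np.flatnonzero(outside.to_numpy())[0])
            raise ValidationError(
                f"visit date outside configured period at row {row}: "
                f"{dates.iloc[row].date()}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    return cfg


def _load_tables(cfg: dict):
    if "synthetic" in cfg and "inputs" in cfg:
        raise ConfigurationError("config must give either 'synthetic' or "
                                 "'inputs', not both")
    if "synthetic" in cfg:
        scfg = SynthConfig(**(cfg["synthetic"] or {}))
        municipalities, physicians, contacts = generate_dataset(scfg)
        period = (scfg.start_date, scfg.period_days)
        return contacts, physicians, municipalities, period
    if "inputs" not in cfg:
        raise ConfigurationError("config needs a 'synthetic' or 'inputs' block")
    paths = cfg["inputs"]
    try:
        contacts = pd.read_csv(paths["contacts"],
                               dtype={"municipality_id": str,
                                      "physician_id": str, "patient_id": str})
        physicians = pd.read_csv(paths["physicians"],
                                 dtype={"municipality_id": str,
                                        "physician_id": str})
        municipalities = pd.read_csv(paths["municipalities"],
                                     dtype={"municipality_id": str})
    except (KeyError, FileNotFoundError) as exc:
        raise ValidationError(f"cannot load input tables: {exc}") from exc
    period = None
    if "period" in cfg:
        period = (cfg["period"]["start"], cfg["period"]["days"])
    return contacts, physicians, municipalities, period


def ensemble_to_frame(trajectories: list[RemovalTrajectory]) -> pd.DataFrame:
    """Stack an ensemble into one long table with a ``replicate`` column."""
    frames = []
    for rep, traj in enumerate(trajectories):
        frame = traj.to_frame()
        frame.insert(0, "replicate", rep)
        frame["n_physicians"] = traj.n_physicians
        frame["total_patients"] = traj.total_patients
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def ensemble_from_frame(df: pd.DataFrame) -> list[RemovalTrajectory]:
    """Inverse of :func:`ensemble_to_frame`."""
    out = []
    for _, sub in df.groupby("replicate"):
        states = sorted(sub["state"].astype(str).unique())
        steps = int(sub["step"].max()) + 1
        arrays = {}
        for name in ("free_capacity", "located", "lost"):
            piv = (sub[sub["observable"] == name]
                   .pivot(index="step", columns="state", values="value")
                   .reindex(index=range(steps), columns=states))
            arrays[name] = piv.to_numpy(dtype=np.int64)
        frac = (sub.drop_duplicates("step").sort_values("step")
                ["frac_removed"].to_numpy(dtype=float))
        out.append(RemovalTrajectory(
            state_labels=[str(s) for s in states], frac_removed=frac,
            free_capacity=arrays["free_capacity"], located=arrays["located"],
            lost=arrays["lost"], removed_ids=[],
            n_physicians=int(sub["n_physicians"].iloc[0]),
            total_patients=int(sub["total_patients"].iloc[0])))
    return out


def shock_ensemble_to_frame(results: list[ShockResult]) -> pd.DataFrame:
    frames = []
    for rep, res in enumerate(results):
        frame = res.to_frame()
        frame.insert(0, "replicate", rep)
        frame["total_patients"] = res.total_patients
        frame["n_removed"] = res.n_removed
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> Path:
    """Run the full stress-test pipeline described by a config.

    Writes, under ``output_dir``: the input tables (when synthetic), network
    exports, per-specialty trajectory/curve/limit/score tables, an aggregate
    ``summary.json`` and a ``manifest.json`` recording the config snapshot,
    per-replicate seeds and input checksums.  Returns the output directory.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(cfg.get("output_dir", "carenet_output"))

    contacts, physicians, municipalities, period = _load_tables(cfg)
    validate_tables(contacts, physicians, municipalities, period)

    params = SimulationParams(**(cfg.get("params") or {}))
    window = int((cfg.get("network") or {}).get("window_days", 91))
    scenario = cfg.get("scenario", "removal")
    if scenario not in ("removal", "shock"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")

    outdir.mkdir(parents=True, exist_ok=True)
    input_dir = outdir / "inputs"
    input_dir.mkdir(exist_ok=True)
    from .synth import write_tables
    write_tables(municipalities, physicians, contacts, input_dir)

    net = build_sharing_network(contacts, window_days=window,
                                physicians=physicians)
    net = threshold_network(net, p=params.p, d=params.d,
                            municipalities=municipalities)
    write_edgelist(net, outdir / "network_edges.csv")
    write_node_table(net, outdir / "network_nodes.csv")
    write_graphml(net, outdir / "network.graphml")

    profiles = build_profiles(contacts, physicians, c=params.c)
    profiles.to_csv(outdir / "profiles.csv", index=False)

    specialties = cfg.get("specialties") or sorted(
        physicians["specialty"].unique())
    summary: list[dict] = []
    limit_rows, score_rows = [], []
    for spec in specialties:
        layer = specialty_layer(net, spec)
        sub_prof = profiles[profiles["specialty"] == spec]
        system = compile_system(layer, sub_prof, municipalities)
        sdir = outdir / f"specialty_{spec}"
        sdir.mkdir(exist_ok=True)

        risk = risk_scores(layer, sub_prof)
        benefit = benefit_scores(profiles, spec)
        states = sub_prof.set_index("physician_id")["municipality_id"].astype(
            str).str[0]
        scores = pd.DataFrame({"risk": risk, "benefit": benefit,
                               "state": states})
        scores.to_csv(sdir / "scores.csv")
        risk_levels = regional_levels(scores["risk"], scores["state"])
        benefit_levels = regional_levels(scores["benefit"], scores["state"])

        if scenario == "shock":
            n_rep = int(cfg.get("shock_ensemble_size", 10))
            results = run_shock_ensemble(
                system, params, float(cfg.get("shock_fraction", 15.0)),
                n_replicates=n_rep)
            shock_ensemble_to_frame(results).to_csv(
                sdir / "shock_trajectories.csv", index=False)
            for st in risk_levels.index:
                summary.append({
                    "specialty": spec, "state": st,
                    "pct_risk_above": float(risk_levels.get(st, np.nan)),
                    "pct_benefit_above": float(benefit_levels.get(st, np.nan)),
                })
            continue

        trajectories = run_removal_ensemble(system, params)
        ensemble_to_frame(trajectories).to_csv(
            sdir / "trajectories.csv", index=False)
        curves = resilience_curves(trajectories)
        curves.to_frame().to_csv(sdir / "curves.csv", index=False)
        limits = critical_limits(curves)
        limits.to_csv(sdir / "limits.csv", index=False)

        mean_by_state = scores.groupby("state")[["risk", "benefit"]].mean()
        for _, row in limits.iterrows():
            st = row["state"]
            limit_rows.append({"specialty": spec, "state": st,
                               "L_FC": row["L_FC"], "L_LP": row["L_LP"]})
            if st in mean_by_state.index:
                score_rows.append({
                    "specialty": spec, "state": st,
                    "risk": mean_by_state.loc[st, "risk"],
                    "benefit": mean_by_state.loc[st, "benefit"]})
            summary.append({
                "specialty": spec, "state": st,
                "L_FC": float(row["L_FC"]), "L_LP": float(row["L_LP"]),
                "pct_risk_above": float(risk_levels.get(st, np.nan)),
                "pct_benefit_above": float(benefit_levels.get(st, np.nan)),
            })

    if scenario == "removal" and limit_rows:
        reg_data = pd.merge(pd.DataFrame(limit_rows),
                            pd.DataFrame(score_rows),
                            on=["specialty", "state"])
        regressions = {}
        for target in ("L_FC", "L_LP"):
            try:
                res = score_resilience_regression(
                    reg_data.rename(columns={target: "L"}))
            except ValidationError:
                continue
            regressions[target] = {
                "r_mean": res.r_mean, "r_sd": res.r_sd,
                "b_mean": res.b_mean, "b_sd": res.b_sd,
                "per_specialty": res.per_specialty.to_dict("records"),
            }
        if regressions:
            (outdir / "regression.json").write_text(
                json.dumps(regressions, indent=2, default=float))

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))

    n_rep = (params.ensemble_size if scenario == "removal"
             else int(cfg.get("shock_ensemble_size", 10)))
    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": _jsonable(cfg),
        "params": dataclasses.asdict(params),
        "replicate_seeds": [params.seed + k for k in range(n_rep)],
        "input_checksums": {
            f.name: _sha256(f) for f in sorted(input_dir.glob("*.csv"))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
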