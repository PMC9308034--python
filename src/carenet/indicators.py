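"""Regional resilience indicators and per-physician risk/benefit scores.

From scenario-(i) trajectory ensembles this module derives, per federal
state, the mean ± SD curves of relative remaining free capacity and of the
cumulative lost-patient fraction versus the fraction of physicians removed,
and the two critical limits

* ``L_FC`` — fraction of physicians removed when the remaining free capacity
  first drops below 20% of its initial value,
* ``L_LP`` — fraction removed when cumulative lost patients first exceed 1%
  of the state's patients,

with linear interpolation between recorded removal steps.  Per physician it
computes the risk score

    R_i = < min((N_j + N_i * w_j) / C_j, 1) >_j,

the mean clamped load of i's network neighbours j if i's patients were
redistributed along the normalised sharing weights w_j (sum_j w_j = 1), and
the benefit score B_i, the initial free capacity min–max normalised within
the specialty.  Regional levels report the percentage of a state's
physicians scoring strictly above the nationwide mean, and an OLS regression
relates the critical limits to state-level mean scores.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .simulation import RemovalTrajectory


@dataclasses.dataclass
class ResilienceCurves:
    """Ensemble mean ± SD of state-level observables over removal steps.

    Free capacity is relative to the state's initial free capacity, lost
    patients relative to the state's initial patients (states starting with
    zero of either carry NaN rows).
    """

    state_labels: list[str]
    frac_removed: np.ndarray   # (steps,)
    fc_mean: np.ndarray        # (steps, n_states)
    fc_sd: np.ndarray
    lost_mean: np.ndarray
    lost_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, mean, sd in (("free_capacity", self.fc_mean, self.fc_sd),
                               ("lost", self.lost_mean, self.lost_sd)):
            for step in range(mean.shape[0]):
                for j, st in enumerate(self.state_labels):
                    rows.append((step, self.frac_removed[step], st, name,
                                 mean[step, j], sd[step, j]))
        return pd.DataFrame(rows, columns=["step", "frac_removed", "state",
                                           "observable", "mean", "sd"])


def resilience_curves(trajectories: list[RemovalTrajectory]) -> ResilienceCurves:
    """Aggregate a scenario-(i) ensemble into relative mean ± SD curves."""
    if not trajectories:
        raise ValidationError("empty trajectory ensemble")
    first = trajectories[0]
    steps = first.frac_removed.size
    for t in trajectories:
        if t.frac_removed.size != steps or t.state_labels != first.state_labels:
            raise ValidationError("trajectories are not aligned")

    fc = np.stack([t.free_capacity for t in trajectories]).astype(float)
    lost = np.stack([t.lost for t in trajectories]).astype(float)
    init_fc = fc[:, 0, :]
    init_pat = (np.stack([t.located for t in trajectories])
                .astype(float)[:, 0, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        fc_rel = np.where(init_fc[:, None, :] > 0,
                          fc / init_fc[:, None, :], np.nan)
        lost_rel = np.where(init_pat[:, None, :] > 0,
                            lost / init_pat[:, None, :], np.nan)
    return ResilienceCurves(
        state_labels=list(first.state_labels),
        frac_removed=first.frac_removed.copy(),
        fc_mean=fc_rel.mean(axis=0), fc_sd=fc_rel.std(axis=0),
        lost_mean=lost_rel.mean(axis=0), lost_sd=lost_rel.std(axis=0))


def _first_crossing(x: np.ndarray, y: np.ndarray, limit: float,
                    below: bool) -> tuple[float, bool]:
    """Smallest x where y crosses the limit (strictly below/above), linearly
    interpolated between recorded steps; (1.0, True) when never crossed."""
    hit = y < limit if below else y > limit
    idx = np.flatnonzero(hit & ~np.isnan(y))
    if idx.size == 0:
        return 1.0, True
    i = int(idx[0])
    if i == 0:
        return float(x[0]), False
    y0, y1 = y[i - 1], y[i]
    strictly_before = (y0 > limit) if below else (y0 < limit)
    if not strictly_before or y0 == y1:
        # the curve sat exactly at the limit: first recorded step beyond it
        return float(x[i]), False
    t = (y0 - limit) / (y0 - y1)
    return float(x[i - 1] + t * (x[i] - x[i - 1])), False


def critical_limits(
    curves: ResilienceCurves,
    fc_limit: float = 0.20,
    lp_limit: float = 0.01,
) -> pd.DataFrame:
    """Per-state critical removal fractions ``L_FC`` and ``L_LP``.

    ``L_FC``: mean remaining free capacity first < ``fc_limit``;
    ``L_LP``: mean cumulative lost fraction first > ``lp_limit``.  A limit
    never crossed yields 1.0 with the matching ``*_censored`` flag set.
    """
    rows = []
    for j, st in enumerate(curves.state_labels):
        l_fc, fc_cens = _first_crossing(curves.frac_removed,
                                        curves.fc_mean[:, j], fc_limit,
                                        below=True)
        l_lp, lp_cens = _first_crossing(curves.frac_removed,
                                        curves.lost_mean[:, j], lp_limit,
                                        below=False)
        rows.append((st, l_fc, fc_cens, l_lp, lp_cens))
    return pd.DataFrame(rows, columns=["state", "L_FC", "L_FC_censored",
                                       "L_LP", "L_LP_censored"])


# ---------------------------------------------------------------------------
# per-physician scores

def risk_scores(net: nx.Graph, profiles: pd.DataFrame) -> pd.Series:
    """Risk score R_i per physician of the (layered) network.

    w_j = a_ij / sum_k a_ik over i's neighbours; R_i is the neighbour mean
    of min((N_j + N_i*w_j)/C_j, 1).  Isolated physicians have no neighbours
    to absorb their patients, so their score is undefined (NaN) and excluded
    from aggregates.
    """
    prof = profiles.set_index("physician_id")
    out = {}
    for i in net.nodes:
        nbrs = list(net.adj[i])
        if not nbrs:
            out[i] = np.nan
            continue
        w = np.array([float(net.adj[i][j].get("weight", 1)) for j in nbrs])
        w = w / w.sum()
        N_i = float(prof.loc[i, "N"])
        N_j = prof.loc[nbrs, "N"].to_numpy(dtype=float)
        C_j = prof.loc[nbrs, "C"].to_numpy(dtype=float)
        if np.any(C_j <= 0):
            bad = [j for j, c in zip(nbrs, C_j) if c <= 0]
            raise ValidationError(f"neighbour capacity must be positive: {bad[:5]}")
        out[i] = float(np.mean(np.minimum((N_j + N_i * w) / C_j, 1.0)))
    return pd.Series(out, name="risk").rename_axis("physician_id")


def benefit_scores(
    profiles: pd.DataFrame,
    specialty: str | None = None,
) -> pd.Series:
    """Benefit score B_i: initial free capacity C−N, min–max normalised to
    [0, 1] within each specialty (all scores 0 when a specialty's free
    capacities are all equal)."""
    prof = profiles if specialty is None else \
        profiles[profiles["specialty"] == specialty]
    if prof.empty:
        raise ValidationError(f"no physicians with specialty {specialty!r}")
    out = pd.Series(np.nan, index=prof["physician_id"], name="benefit")
    for _, sub in prof.groupby("specialty", observed=True):
        vals = (sub["C"] - sub["N"]).astype(float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:   # degenerate: every physician identical
            out.loc[sub["physician_id"]] = 0.0
        else:
            out.loc[sub["physician_id"]] = ((vals - lo) / (hi - lo)).to_numpy()
    return out.rename_axis("physician_id")


def regional_levels(scores: pd.Series, states: pd.Series) -> pd.Series:
    """Percentage of each state's physicians scoring strictly above the
    nationwide mean score (NaN scores are excluded throughout)."""
    df = pd.DataFrame({"score": scores, "state": states}).dropna(subset=["score"])
    if df.empty:
        raise ValidationError("no scores to aggregate")
    nationwide = df["score"].mean()
    return (df.groupby("state")["score"]
              .apply(lambda s: 100.0 * float((s > nationwide).sum()) / s.size)
              .rename("pct_above_average"))


# ---------------------------------------------------------------------------
# score-vs-resilience regression

@dataclasses.dataclass
class RegressionResult:
    """Per-specialty OLS of a critical limit on state-level mean scores,
    L ~ r * risk + b * benefit + const, with cross-specialty summaries."""

    per_specialty: pd.DataFrame   # specialty, r, b, intercept, rank_deficient
    r_mean: float
    r_sd: float
    b_mean: float
    b_sd: float


def score_resilience_regression(data: pd.DataFrame) -> RegressionResult:
    """Fit the limit-vs-scores regression per specialty.

    ``data`` has one row per (specialty, state) with columns ``specialty``,
    ``state``, ``L`` (the critical limit), ``risk`` and ``benefit``
    (state-level mean scores).  Specialties need >= 4 states of complete
    data; a rank-deficient design is flagged and its coefficients left NaN.
    """
    rows = []
    for spec, sub in data.dropna(
            subset=["L", "risk", "benefit"]).groupby("specialty", observed=True):
        if len(sub) < 4:
            raise ValidationError(
                f"specialty {spec!r} has only {len(sub)} complete states; "
                "need >= 4")
        X = sm.add_constant(sub[["risk", "benefit"]].to_numpy(), has_constant="add")
        if np.linalg.matrix_rank(X) < 3:
            rows.append((spec, np.nan, np.nan, np.nan, True))
            continue
        fit = sm.OLS(sub["L"].to_numpy(), X).fit()
        const, r, b = fit.params
        rows.append((spec, float(r), float(b), float(const), False))
    per = pd.DataFrame(rows, columns=["specialty", "r", "b", "intercept",
                                      "rank_deficient"])
    ok = per[~per["rank_deficient"]]
    return RegressionResult(
        per_specialty=per,
        r_mean=float(ok["r"].mean()) if len(ok) else float("nan"),
        r_sd=float(ok["r"].std(ddof=1)) if len(ok) > 1 else float("nan"),
        b_mean=float(ok["b"].mean()) if len(ok) else float("nan"),
        b_sd=float(ok["b"].std(ddof=1)) if len(ok) > 1 else float("nan"))
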