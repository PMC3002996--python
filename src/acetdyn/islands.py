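"""Probe-level acetylation calls against the control-probe null.

Control probes are designed to be un-acetylated and give an empirical null
for the background signal of each array day. Each gene-assigned probe is
compared against that null with a one-sided upper-tail test (acetylation is
signal *above* background); per-day Benjamini-Hochberg control then decides
which probes are called "acetylated". Per-gene transition summaries between
days (fraction of probes staying un-acetylated / staying acetylated)
quantify whether the *location* of acetylation signal moves over time.

The null is moment-based and robust: per-day median location and
MAD-derived scale, with the day scale shrunk toward the pooled cross-day
scale,

    scale_day = lam * sigma_day + (1 - lam) * sigma_pooled,
    lam = n_day / (n_day + N0),   N0 = 50 control probes,

so a day with few controls borrows strength from the other days while a
well-measured day keeps its own variability estimate. All signals (probe
and control) are replicate-averaged before testing, so probe and null
distributions live on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAD_TO_SIGMA = 1.4826  # consistency factor for a Gaussian
SHRINK_PRIOR_N = 50.0
_MIN_SCALE = 1e-12


@dataclass
class NullModel:
    """Per-day location/scale of the control-probe background."""

    days: tuple[int, ...]
    location: dict[int, float]
    scale: dict[int, float]          # shrunken, used for testing
    day_scale: dict[int, float]      # raw per-day MAD sigma
    pooled_scale: float
    lam: dict[int, float]


@dataclass
class StateMatrix:
    """Per-probe acetylation calls for every gene and day.

    ``calls`` is a long DataFrame (gene_id, probe_id, day, signal, p, q,
    acetylated) at the chosen FDR level.
    """

    calls: pd.DataFrame
    days: tuple[int, ...]
    fdr: float

    def gene_matrix(self, gene_id: str) -> pd.DataFrame:
        """Boolean probes x days matrix for one gene."""
        sub = self.calls[self.calls["gene_id"] == gene_id]
        return sub.pivot(index="probe_id", columns="day", values="acetylated")


def _replicate_mean(probe_table: pd.DataFrame) -> pd.DataFrame:
    return (
        probe_table.groupby(["probe_id", "day"], dropna=False, observed=True)
        .agg(gene_id=("gene_id", "first"), signal=("signal", "mean"))
        .reset_index()
    )


def fit_null(probe_table: pd.DataFrame, min_controls: int = 50) -> NullModel:
    """Fit the background model from control probes (rows without gene_id).

    Requires at least ``min_controls`` control probes on every day.
    """
    controls = probe_table[probe_table["gene_id"].isna()]
    if controls.empty:
        raise ValueError("probe table contains no control probes")
    avg = _replicate_mean(controls)
    days = tuple(sorted(avg["day"].unique()))
    loc, raw, lam, scale = {}, {}, {}, {}
    centered_all = []
    n_by_day = {}
    for day in days:
        x = avg.loc[avg["day"] == day, "signal"].to_numpy()
        if len(x) < min_controls:
            raise ValueError(
                f"day {day}: only {len(x)} control probes (< {min_controls})"
            )
        loc[day] = float(np.median(x))
        raw[day] = float(MAD_TO_SIGMA * np.median(np.abs(x - loc[day])))
        centered_all.append(x - loc[day])
        n_by_day[day] = len(x)
    pooled = np.concatenate(centered_all)
    pooled_scale = float(MAD_TO_SIGMA * np.median(np.abs(pooled)))
    for day in days:
        lam[day] = n_by_day[day] / (n_by_day[day] + SHRINK_PRIOR_N)
        scale[day] = max(lam[day] * raw[day] + (1 - lam[day]) * pooled_scale, _MIN_SCALE)
    return NullModel(days=days, location=loc, scale=scale, day_scale=raw,
                     pooled_scale=pooled_scale, lam=lam)


def call_states(probe_table: pd.DataFrame, null_model: NullModel,
                fdr: float = 0.10) -> StateMatrix:
    """One-sided upper-tail calls with per-day Benjamini-Hochberg control.

    A probe is acetylated on a day iff its BH-adjusted p-value (within that
    day, across all gene-assigned probes) is <= ``fdr``.
    """
    if not (0 < fdr < 1):
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    genic = probe_table[probe_table["gene_id"].notna()]
    avg = _replicate_mean(genic)
    missing = set(avg["day"].unique()) - set(null_model.days)
    if missing:
        raise ValueError(f"null model lacks day(s) {sorted(missing)}")
    parts = []
    for day in sorted(avg["day"].unique()):
        sub = avg[avg["day"] == day].copy()
        z = (sub["signal"] - null_model.location[day]) / null_model.scale[day]
        sub["p"] = stats.norm.sf(z)
        sub["q"] = stats.false_discovery_control(sub["p"], method="bh")
        sub["acetylated"] = sub["q"] <= fdr
        parts.append(sub)
    calls = pd.concat(parts, ignore_index=True)[
        ["gene_id", "probe_id", "day", "signal", "p", "q", "acetylated"]
    ]
    return StateMatrix(calls=calls, days=tuple(sorted(avg["day"].unique())), fdr=fdr)


def _summarize(counts: pd.DataFrame, min_state_count: int) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        p_stay_ac = counts["stay_ac"] / counts["n_ac"]
        p_stay_unac = counts["stay_unac"] / counts["n_unac"]
    out = pd.DataFrame({
        "n_ac": counts["n_ac"].astype(int),
        "n_unac": counts["n_unac"].astype(int),
        "p_stay_ac": p_stay_ac,
        "p_stay_unac": p_stay_unac,
    })
    out["discarded"] = (
        np.minimum(out["n_ac"], out["n_unac"]) < min_state_count
    )
    return out


def transition_summary(state_matrix: StateMatrix, day_a: int, day_b: int,
                       min_state_count: int = 3) -> pd.DataFrame:
    """Per-gene probe-state persistence between two days.

    p_stay_ac   = #(acetylated on both days)   / #(acetylated on day_a)
    p_stay_unac = #(un-acetylated on both days)/ #(un-acetylated on day_a)

    Genes with fewer than ``min_state_count`` probes in either state on
    ``day_a`` are flagged ``discarded`` (their estimates are unstable).
    """
    for d in (day_a, day_b):
        if d not in state_matrix.days:
            raise ValueError(f"day {d} not in state matrix (has {state_matrix.days})")
    calls = state_matrix.calls
    wide = calls[calls["day"].isin([day_a, day_b])].pivot_table(
        index=["gene_id", "probe_id"], columns="day", values="acetylated",
        aggfunc="first",
    ).dropna()
    a = wide[day_a].astype(bool)
    b = wide[day_b].astype(bool)
    df = pd.DataFrame({
        "gene_id": wide.index.get_level_values("gene_id"),
        "ac_a": a.to_numpy(),
        "stay_ac": (a & b).to_numpy(),
        "stay_unac": (~a & ~b).to_numpy(),
    })
    counts = df.groupby("gene_id").agg(
        n_ac=("ac_a", "sum"),
        stay_ac=("stay_ac", "sum"),
        stay_unac=("stay_unac", "sum"),
        n_probes=("ac_a", "size"),
    )
    counts["n_unac"] = counts["n_probes"] - counts["n_ac"]
    return _summarize(counts, min_state_count)


def pooled_transition_summary(state_matrix: StateMatrix,
                              min_state_count: int = 3) -> pd.DataFrame:
    """Transition summary pooling all consecutive day pairs, assuming the
    state-change distribution is the same between all time points."""
    days = state_matrix.days
    if len(days) < 2:
        raise ValueError("need at least two days to pool transitions")
    pooled = None
    for day_a, day_b in zip(days, days[1:]):
        calls = state_matrix.calls
        wide = calls[calls["day"].isin([day_a, day_b])].pivot_table(
            index=["gene_id", "probe_id"], columns="day", values="acetylated",
            aggfunc="first",
        ).dropna()
        a = wide[day_a].astype(bool)
        b = wide[day_b].astype(bool)
        df = pd.DataFrame({
            "gene_id": wide.index.get_level_values("gene_id"),
            "ac_a": a.to_numpy(),
            "stay_ac": (a & b).to_numpy(),
            "stay_unac": (~a & ~b).to_numpy(),
        })
        counts = df.groupby("gene_id").agg(
            n_ac=("ac_a", "sum"),
            stay_ac=("stay_ac", "sum"),
            stay_unac=("stay_unac", "sum"),
            n_probes=("ac_a", "size"),
        )
        counts["n_unac"] = counts["n_probes"] - counts["n_ac"]
        pooled = counts if pooled is None else pooled.add(counts, fill_value=0)
    return _summarize(pooled, min_state_count)
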