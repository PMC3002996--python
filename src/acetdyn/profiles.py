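"""Binned TSS acetylation profiles, peak finding and peak stability.

Genes are probed at varying positions, so raw profiles are not directly
comparable. Mapping every gene onto a fixed 14-vector — mean above-background
signal in 0.5 kb bins spanning -3.5..+3.5 kb around the TSS — makes profiles
comparable while keeping most of the quantitative variation. A *peak* is the
smallest contiguous run of bins that contains the profile maximum and covers
at least a given fraction (default 30%) of the total binned signal.

Bins are half-open, 0-based internally (bin k covers
[-3500 + 500k, -3500 + 500(k+1)) bp); outputs report them 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .islands import NullModel, _replicate_mean

BIN_WIDTH_BP = 500.0
WINDOW_BP = 3500.0
N_BINS = int(2 * WINDOW_BP / BIN_WIDTH_BP)  # 14


class PeakCategory(str, Enum):
    IDENTICAL = "identical"
    CONTAINED = "contained"
    OVERLAPPING = "overlapping"
    DISJOINT = "disjoint"
    UNDEFINED = "undefined"  # one of the profiles had no peak


@dataclass(frozen=True)
class PeakRegion:
    """Inclusive bin interval [lo, hi] (0-based) around the profile maximum."""

    gene_id: str
    day: int
    lo: int
    hi: int
    covered_fraction: float

    def as_1based(self) -> tuple[int, int]:
        return self.lo + 1, self.hi + 1


def bin_index(offset_bp: np.ndarray) -> np.ndarray:
    """Map TSS offsets to bin indices 0..13 (offsets outside the window -> -1).

    The right window edge (+3500) is folded into the last bin so the closed
    window maps onto exactly N_BINS half-open bins.
    """
    off = np.asarray(offset_bp, dtype=float)
    idx = np.floor((off + WINDOW_BP) / BIN_WIDTH_BP).astype(int)
    idx[off == WINDOW_BP] = N_BINS - 1
    idx[(off < -WINDOW_BP) | (off > WINDOW_BP)] = -1
    return idx


def bin_profile(gene_probes: pd.DataFrame, null_model: NullModel, day: int) -> np.ndarray:
    """14-bin mean above-background profile for one gene on one day.

    Every probe contributes its signal minus the day's null location, floored
    at zero; the bin value is the mean of those contributions over the probes
    in the bin. Bins with no probes (or none above background) are zero.
    Replicates are averaged first.
    """
    sub = gene_probes[gene_probes["day"] == day]
    if "replicate" in sub.columns and sub["replicate"].nunique() > 1:
        sub = _replicate_mean(sub)
        sub = sub.merge(
            gene_probes[["probe_id", "offset_bp"]].drop_duplicates("probe_id"),
            on="probe_id",
        )
    profile = np.zeros(N_BINS)
    if sub.empty:
        return profile
    above = np.maximum(sub["signal"].to_numpy() - null_model.location[day], 0.0)
    idx = bin_index(sub["offset_bp"].to_numpy())
    for k in range(N_BINS):
        mask = idx == k
        if mask.any():
            profile[k] = above[mask].mean()
    return profile


def bin_all(probe_table: pd.DataFrame, null_model: NullModel) -> pd.DataFrame:
    """Binned profiles for every gene and day.

    Returns a DataFrame indexed by (gene_id, day) with columns bin_01..bin_14.
    """
    genic = probe_table[probe_table["gene_id"].notna()]
    avg = _replicate_mean(genic).merge(
        genic[["probe_id", "offset_bp"]].drop_duplicates("probe_id"), on="probe_id"
    )
    days = sorted(avg["day"].unique())
    loc = np.array([null_model.location[d] for d in days])
    day_pos = avg["day"].map({d: i for i, d in enumerate(days)}).to_numpy()
    above = np.maximum(avg["signal"].to_numpy() - loc[day_pos], 0.0)
    idx = bin_index(avg["offset_bp"].to_numpy())
    ok = idx >= 0
    frame = pd.DataFrame({
        "gene_id": avg["gene_id"].to_numpy()[ok],
        "day": avg["day"].to_numpy()[ok],
        "bin": idx[ok],
        "above": above[ok],
    })
    means = frame.groupby(["gene_id", "day", "bin"], observed=True)["above"].mean()
    wide = means.unstack("bin", fill_value=0.0)
    wide = wide.reindex(columns=range(N_BINS), fill_value=0.0)
    wide.columns = [f"bin_{k + 1:02d}" for k in range(N_BINS)]
    # genes absent on some day (no probes in window) get all-zero rows
    full_index = pd.MultiIndex.from_product(
        [wide.index.get_level_values("gene_id").unique(), days],
        names=["gene_id", "day"],
    )
    return wide.reindex(full_index, fill_value=0.0)


def _tss_distance(k: int) -> float:
    """Distance of bin k's centre from the TSS."""
    centre = -WINDOW_BP + BIN_WIDTH_BP * (k + 0.5)
    return abs(centre)


def _argmax_tss(profile: np.ndarray) -> int:
    """Argmax with ties broken toward the TSS, then leftward."""
    best = profile.max()
    cands = np.flatnonzero(profile == best)
    return int(min(cands, key=lambda k: (_tss_distance(k), k)))


def find_peak(profile: np.ndarray, coverage: float = 0.30,
              gene_id: str = "", day: int = 0) -> PeakRegion | None:
    """Smallest contiguous bin interval containing the argmax that carries at
    least ``coverage`` of the total signal.

    Grown greedily from the argmax: at each step the neighbouring bin with
    the larger signal is added; ties are broken toward the TSS, then
    leftward. Returns ``None`` for an all-zero profile.
    """
    profile = np.asarray(profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        return None
    lo = hi = _argmax_tss(profile)
    acc = profile[lo]
    while acc < coverage * total - 1e-12:
        left = profile[lo - 1] if lo > 0 else -np.inf
        right = profile[hi + 1] if hi < len(profile) - 1 else -np.inf
        if left > right:
            grow_left = True
        elif right > left:
            grow_left = False
        else:  # tie: toward TSS, then leftward
            dl, dr = _tss_distance(lo - 1), _tss_distance(hi + 1)
            grow_left = dl < dr or (dl == dr)
        if grow_left:
            lo -= 1
            acc += profile[lo]
        else:
            hi += 1
            acc += profile[hi]
    return PeakRegion(gene_id=gene_id, day=day, lo=lo, hi=hi,
                      covered_fraction=float(acc / total))


def peak_stability(peak_a: PeakRegion | None, peak_b: PeakRegion | None,
                   mismatch_tol: int = 0) -> PeakCategory:
    """Classify how two peak intervals relate.

    With ``mismatch_tol`` t, each endpoint may differ by up to t bins before
    a category degrades: *identical* if both endpoints agree within t;
    *contained* if one interval lies within the other expanded by t;
    *overlapping* if they intersect after expansion by t; else *disjoint*.
    """
    if peak_a is None or peak_b is None:
        return PeakCategory.UNDEFINED
    t = mismatch_tol
    a, b = (peak_a.lo, peak_a.hi), (peak_b.lo, peak_b.hi)
    if abs(a[0] - b[0]) <= t and abs(a[1] - b[1]) <= t:
        return PeakCategory.IDENTICAL
    def contained(x, y):  # x inside y expanded by t
        return y[0] - t <= x[0] and x[1] <= y[1] + t
    if contained(a, b) or contained(b, a):
        return PeakCategory.CONTAINED
    if a[0] <= b[1] + t and b[0] <= a[1] + t:
        return PeakCategory.OVERLAPPING
    return PeakCategory.DISJOINT


def delta_profile(profile_t: np.ndarray, profile_0: np.ndarray) -> np.ndarray:
    """Per-bin acetylation change between two days of the same gene."""
    profile_t = np.asarray(profile_t, dtype=float)
    profile_0 = np.asarray(profile_0, dtype=float)
    if profile_t.shape != profile_0.shape:
        raise ValueError("profiles have mismatched shapes")
    return profile_t - profile_0


def quantile_band_summary(delta_profiles: np.ndarray,
                          quantiles: tuple[float, ...] = (0.10, 0.25, 0.75, 0.90)
                          ) -> pd.DataFrame:
    """Per-bin empirical quantiles over a group of genes' change profiles.

    ``delta_profiles`` is genes x bins; returns a quantile x bin DataFrame
    (linear interpolation). Visualizes how broadly a group gains or loses
    signal across the window.
    """
    arr = np.asarray(delta_profiles, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise ValueError("empty gene group")
    q = np.quantile(arr, quantiles, axis=0, method="linear")
    return pd.DataFrame(q, index=[f"q{int(100 * x)}" for x in quantiles],
                        columns=[f"bin_{k + 1:02d}" for k in range(arr.shape[1])])


def peak_table(binned: pd.DataFrame, coverage: float = 0.30) -> pd.DataFrame:
    """Peaks for every (gene, day) row of a ``bin_all`` table (1-based bins)."""
    rows = []
    for (gene, day), values in binned.iterrows():
        pk = find_peak(values.to_numpy(), coverage=coverage, gene_id=gene, day=day)
        if pk is None:
            rows.append((gene, day, np.nan, np.nan, np.nan))
        else:
            lo1, hi1 = pk.as_1based()
            rows.append((gene, day, lo1, hi1, pk.covered_fraction))
    return pd.DataFrame(rows, columns=["gene_id", "day", "bin_lo", "bin_hi",
                                       "covered_fraction"])
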