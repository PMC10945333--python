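"""Statistics of per-vessel vascular events.

Operates on event tables with one row per sonicated vessel (see
:data:`mbcav.simulate.events.EVENT_COLUMNS`): occurrence rates normalized by
the vessels in each (pressure group × caliber bin) cell, conditional
probabilities along the activation → fate → RBC-leakage chain, the empirical
extravasation-timing CDF, bifurcation-proximity fractions, and the
optical–acoustic (RBC leakage vs broadband IC power) correlation summary.

Percentages are reported to the nearest integer percent where a rounded
presentation is requested; raw fractions are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mbcav.simulate.counts import EventCountTable

#: Default caliber bin edges (µm), expressing the diameters singled out in
#: the observations (5-300 µm range, 56/70/100/180 µm thresholds).
DEFAULT_CALIBER_EDGES = (5.0, 10.0, 20.0, 40.0, 70.0, 100.0, 180.0, 300.0)

#: Event predicates evaluated on an event-table DataFrame.
EVENT_PREDICATES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "activation": lambda df: df["activation"].astype(bool),
    "extravasation": lambda df: df["fate"] == "extravasated",
    "rbc_leakage": lambda df: df["rbc_leakage"] != "none",
    "flow_reversal": lambda df: df["flow_reversal"] != "none",
}

NETWORK_PRESSURE_GROUPS = {
    "low": frozenset({0.5, 1.0}),
    "intermediate": frozenset({2.0}),
    "high": frozenset({3.0}),
}
SINGLE_VESSEL_PRESSURE_GROUPS = {
    "low": frozenset({1.0}),
    "intermediate": frozenset({2.0, 2.5}),
    "high": frozenset({3.0, 3.5}),
}


@dataclass(frozen=True)
class GroupingScheme:
    """Pressure-group and caliber-bin assignment for event tables."""

    pressure_groups: Mapping[str, frozenset[float]] = field(
        default_factory=lambda: dict(NETWORK_PRESSURE_GROUPS)
    )
    caliber_edges: tuple[float, ...] | None = DEFAULT_CALIBER_EDGES

    @classmethod
    def network(cls, caliber_edges=DEFAULT_CALIBER_EDGES) -> "GroupingScheme":
        return cls(dict(NETWORK_PRESSURE_GROUPS), caliber_edges)

    @classmethod
    def single_vessel(cls, caliber_edges=DEFAULT_CALIBER_EDGES) -> "GroupingScheme":
        return cls(dict(SINGLE_VESSEL_PRESSURE_GROUPS), caliber_edges)

    def assign_pressure_group(self, pressures: pd.Series) -> pd.Series:
        lookup: dict[float, str] = {}
        for label, members in self.pressure_groups.items():
            for p in members:
                if p in lookup:
                    raise ValueError(f"pressure {p} in more than one group")
                lookup[p] = label
        out = pressures.map(lookup)
        if out.isna().any():
            bad = sorted(pressures[out.isna()].unique())
            raise ValueError(f"pressures outside all groups: {bad}")
        return out

    def assign_caliber_bin(self, diameters: pd.Series) -> pd.Series:
        if self.caliber_edges is None:
            return pd.Series("all", index=diameters.index)
        edges = np.asarray(self.caliber_edges, dtype=float)
        binned = pd.cut(diameters, edges, include_lowest=True)
        if binned.isna().any():
            bad = diameters[binned.isna()]
            raise ValueError(
                f"{bad.size} diameters outside the caliber bins "
                f"[{edges[0]:g}, {edges[-1]:g}] µm (e.g. {bad.iloc[0]!r})"
            )
        return binned.astype(str)


def percent(fraction: float) -> int:
    """Nearest-integer percentage of a fraction (presentation rounding)."""
    return int(round(100.0 * fraction))


# ---------------------------------------------------------------------------
# rates and conditional probabilities

def event_rate_histograms(
    records: pd.DataFrame,
    scheme: GroupingScheme | None = None,
    event_types: Sequence[str] = tuple(EVENT_PREDICATES),
) -> pd.DataFrame:
    """Event rates per (event type × pressure group × caliber bin).

    Rate = event count / total vessels in the cell.  Cells with zero vessels
    are flagged (``defined=False``) rather than divided.
    """
    scheme = scheme or GroupingScheme()
    if records.empty:
        return pd.DataFrame(
            columns=["event_type", "pressure_group", "caliber_bin",
                     "count", "total", "rate", "defined"]
        )
    df = records.copy()
    df["_group"] = scheme.assign_pressure_group(df["pressure_mpa"])
    df["_bin"] = scheme.assign_caliber_bin(df["diameter_um"])

    totals = df.groupby(["_group", "_bin"], observed=False).size()
    rows = []
    for event in event_types:
        flags = EVENT_PREDICATES[event](df)
        counts = df[flags].groupby(["_group", "_bin"], observed=False).size()
        for (group, cbin), total in totals.items():
            count = int(counts.get((group, cbin), 0))
            rows.append(
                {
                    "event_type": event,
                    "pressure_group": group,
                    "caliber_bin": cbin,
                    "count": count,
                    "total": int(total),
                    "rate": count / total if total > 0 else np.nan,
                    "defined": total > 0,
                }
            )
    return pd.DataFrame(rows)


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else np.nan


def _conditional_block(df: pd.DataFrame, label: str) -> dict:
    act = df["activation"].astype(bool)
    n = len(df)
    n_act = int(act.sum())
    n_ext = int((df["fate"] == "extravasated").sum())
    n_rem = int((df["fate"] == "remained").sum())
    n_unc = int((df["fate"] == "unclear").sum())
    leak = df["rbc_leakage"] != "none"
    n_leak = int(leak.sum())
    n_leak_ext = int((leak & (df["fate"] == "extravasated")).sum())
    n_leak_rem = int((leak & (df["fate"] == "remained")).sum())
    n_trans_rev = int((df["flow_reversal"] == "transient").sum())
    return {
        "group": label,
        "n_vessels": n,
        "n_activations": n_act,
        "n_extravasated": n_ext,
        "n_remained": n_rem,
        "n_unclear": n_unc,
        "n_leakage": n_leak,
        "p_activation": _safe_ratio(n_act, n),
        "p_extravasated_given_activation": _safe_ratio(n_ext, n_act),
        "p_remained_given_activation": _safe_ratio(n_rem, n_act),
        "p_unclear_given_activation": _safe_ratio(n_unc, n_act),
        "p_leakage_given_activation": _safe_ratio(n_leak, n_act),
        "p_leakage_given_extravasated": _safe_ratio(n_leak_ext, n_ext),
        "p_leakage_given_remained": _safe_ratio(n_leak_rem, n_rem),
        "p_transient_reversal_given_activation": _safe_ratio(n_trans_rev, n_act),
    }


def conditional_rates(
    records: pd.DataFrame, by: str = "pressure_mpa"
) -> pd.DataFrame:
    """Conditional event probabilities per group and pooled.

    Fate probabilities are conditioned on all activations (the "unclear"
    fate is a separate outcome column, not excluded from the activation
    denominator); leakage-given-fate probabilities condition on the fate
    counts only.  Denominators are reported alongside every rate; undefined
    ratios (zero denominator) are NaN.
    """
    blocks = [
        _conditional_block(sub, str(key))
        for key, sub in records.groupby(by, observed=False)
    ]
    blocks.append(_conditional_block(records, "pooled"))
    return pd.DataFrame(blocks)


def conditional_rates_from_counts(counts: EventCountTable) -> pd.DataFrame:
    """Conditional rates computed from the packaged observed tallies."""
    counts.consistency_check()
    return conditional_rates(
        counts.expand_to_records(), by="pressure_mpa"
    )


# ---------------------------------------------------------------------------
# extravasation timing

@dataclass
class TimingCDF:
    """Empirical CDF of extravasation times (seconds from onset)."""

    times: np.ndarray | None = None
    bins: list[tuple[float, float, float]] | None = None  # (lo, hi, mass)

    REPORT_TIMES = (0.1e-3, 0.5e-3, 1e-3, 5e-3)

    @classmethod
    def from_times(cls, times: np.ndarray) -> "TimingCDF":
        t = np.asarray(times, dtype=float)
        t = t[~np.isnan(t)]
        if np.any(t < 0):
            raise ValueError("extravasation times must be non-negative")
        if t.size == 0:
            raise ValueError("no extravasation times supplied")
        return cls(times=np.sort(t))

    @classmethod
    def from_histogram(cls, bins) -> "TimingCDF":
        bins = [tuple(map(float, b)) for b in bins]
        mass = sum(b[2] for b in bins)
        if not np.isclose(mass, 1.0, atol=1e-6):
            raise ValueError("histogram mass must sum to 1")
        return cls(bins=sorted(bins))

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "TimingCDF":
        return cls.from_times(records["extravasation_time_s"].to_numpy())

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.times is not None:
            return np.searchsorted(self.times, t, side="right") / self.times.size
        out = np.zeros(t.shape if t.shape else (1,))
        for lo, hi, mass in self.bins:
            frac = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
            out = out + mass * frac
        return out if t.shape else float(out[0])

    def report(self) -> dict[float, float]:
        """Cumulative fractions at 0.1, 0.5, 1 and 5 ms."""
        return {t: float(np.asarray(self(t))) for t in self.REPORT_TIMES}


def extravasation_timing_cdf(
    source: pd.DataFrame | np.ndarray | Sequence | EventCountTable,
) -> TimingCDF:
    """Build the timing CDF from records, raw times, or packaged tallies."""
    if isinstance(source, EventCountTable):
        return TimingCDF.from_histogram(source.timing_histogram)
    if isinstance(source, pd.DataFrame):
        return TimingCDF.from_records(source)
    return TimingCDF.from_times(np.asarray(source, dtype=float))


# ---------------------------------------------------------------------------
# bifurcation proximity

def bifurcation_proximity(
    records: pd.DataFrame,
    threshold_um: float = 50.0,
    event_types: Sequence[str] = ("activation", "extravasation", "rbc_leakage"),
) -> dict:
    """Fraction of event-bearing vessels within ``threshold_um`` of a
    branching point (centroid-of-event to centerline-crossing distance).

    Rows without a recorded distance are excluded from the fractions and
    tallied in the coverage note.  Reported overall, per event type, and
    split by arteriole/venule.
    """
    dist = records["bifurcation_distance_um"]
    any_event = np.zeros(len(records), dtype=bool)
    per_type = {}
    for event in event_types:
        flags = EVENT_PREDICATES[event](records).to_numpy()
        any_event |= flags
        valid = flags & dist.notna().to_numpy()
        per_type[event] = {
            "fraction_within": _safe_ratio(
                int((dist[valid] <= threshold_um).sum()), int(valid.sum())
            ),
            "n_events": int(valid.sum()),
        }
    valid_any = any_event & dist.notna().to_numpy()
    by_type = {}
    for vtype, sub in records[valid_any].groupby("vessel_type", observed=False):
        by_type[vtype] = _safe_ratio(
            int((sub["bifurcation_distance_um"] <= threshold_um).sum()), len(sub)
        )
    return {
        "threshold_um": threshold_um,
        "overall": _safe_ratio(
            int((dist[valid_any] <= threshold_um).sum()), int(valid_any.sum())
        ),
        "per_event_type": per_type,
        "by_vessel_type": by_type,
        "n_events_missing_distance": int((any_event & dist.isna()).sum()),
    }


# ---------------------------------------------------------------------------
# optical–acoustic correlation

SIZE_GROUPS = {"5-20": (5.0, 20.0), "20-50": (20.0, 50.0), ">=50": (50.0, np.inf)}


def fov_leakage_fractions(
    records: pd.DataFrame,
    size_groups: Mapping[str, tuple[float, float]] = None,
) -> pd.DataFrame:
    """Per-FOV, per-size-group fraction of vessels with RBC leakage."""
    size_groups = size_groups or SIZE_GROUPS
    rows = []
    for fov, sub in records.groupby("fov_id", observed=False):
        for label, (lo, hi) in size_groups.items():
            sel = sub[(sub["diameter_um"] >= lo) & (sub["diameter_um"] < hi)]
            if len(sel) == 0:
                continue
            rows.append(
                {
                    "fov_id": fov,
                    "size_group": label,
                    "n_vessels": len(sel),
                    "leakage_fraction": float(
                        (sel["rbc_leakage"] != "none").mean()
                    ),
                }
            )
    return pd.DataFrame(rows)


def leakage_vs_ic_correlation(
    fov_summaries: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank correlation of per-FOV RBC-leakage fraction against broadband IC
    power, per vessel-size group, with a permutation p-value.

    ``fov_summaries`` needs columns ``size_group``, ``ic_power`` and
    ``leakage_fraction`` (one row per FOV × size group).  Groups with fewer
    than 3 FOVs are flagged not computed.  A rank (Spearman) statistic is
    used because no linear or threshold-like pattern is assumed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, sub in fov_summaries.groupby("size_group", observed=False):
        x = sub["ic_power"].to_numpy(dtype=float)
        y = sub["leakage_fraction"].to_numpy(dtype=float)
        if len(sub) < 3:
            rows.append(
                {"size_group": label, "n_fovs": len(sub), "rho": np.nan,
                 "p_permutation": np.nan, "computed": False}
            )
            continue
        rho = float(stats.spearmanr(x, y).statistic)
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        # vectorized permutations of the y ranks
        perm = np.argsort(rng.random((n_permutations, yr.size)), axis=1)
        perm_rhos = (yc[perm] @ xc) / denom
        p = (1 + np.sum(np.abs(perm_rhos) >= abs(rho) - 1e-12)) / (
            n_permutations + 1
        )
        rows.append(
            {"size_group": label, "n_fovs": len(sub), "rho": rho,
             "p_permutation": float(p), "computed": True}
        )
    return pd.DataFrame(rows)
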