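"""Packaged observed event counts and their record-level expansion.

The study's vascular-network acquisitions yielded printed tallies of vessels
and vascular events per pressure group (microbubble activation, bubble fate,
RBC leakage, flow-reversal recovery) plus an extravasation-timing histogram.
These are shipped as a JSON fixture so the event-statistics module can be
exercised and regression-tested without any raw data.

Counts the source did not print directly (the 2 MPa vessel total and fate
split, the 3 MPa "unclear" count) are reconstructed by subtraction from
printed totals and flagged ``derived`` in the JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd

from mbcav.simulate.events import EVENT_COLUMNS


@dataclass(frozen=True)
class EventCountTable:
    """Immutable view of the packaged per-pressure event tallies."""

    data: dict[str, Any]

    @property
    def total_vessels(self) -> int:
        return int(self.data["total_vessels"])

    @property
    def total_activations(self) -> int:
        return int(self.data["total_activations"])

    @property
    def pressures(self) -> list[float]:
        return sorted(float(p) for p in self.data["pressure_groups"])

    def group(self, pressure: float) -> dict[str, Any]:
        return self.data["pressure_groups"][f"{float(pressure):.1f}"]

    @property
    def timing_histogram(self) -> list[tuple[float, float, float]]:
        """(low s, high s, fraction) bins of extravasation times."""
        return [
            (lo * 1e-3, hi * 1e-3, frac)
            for lo, hi, frac in self.data["timing_histogram_ms"]
        ]

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.pressures:
            g = self.group(p)
            rows.append({"pressure_mpa": p, **{k: g[k] for k in g if k != "derived"}})
        return pd.DataFrame(rows)

    def consistency_check(self) -> None:
        """Verify the bookkeeping identities of the tallies."""
        df = self.as_dataframe()
        if int(df["vessels"].sum()) != self.total_vessels:
            raise AssertionError("per-pressure vessel counts do not sum to total")
        if int(df["activations"].sum()) != self.total_activations:
            raise AssertionError("per-pressure activations do not sum to total")
        fates = df["remained"] + df["extravasated"] + df["unclear"]
        if not (fates == df["activations"]).all():
            raise AssertionError("fate counts do not sum to activations")
        totals = self.data["totals"]
        if int(df["extravasated"].sum()) != totals["extravasated"]:
            raise AssertionError("extravasation totals inconsistent")
        if int(df["remained"].sum()) != totals["remained"]:
            raise AssertionError("remained totals inconsistent")

    def expand_to_records(self) -> pd.DataFrame:
        """Deterministically expand the tallies into one row per vessel.

        The expansion reproduces every packaged count exactly.  Quantities
        the tallies do not constrain are reconstructed conservatively:
        leakage is routed through extravasated rows first (split 13/109/213
        across 1/2/3 MPa so the pooled 335-of-348 total holds) with the
        remainder on unclear-fate rows; sustained flow reversals are placed
        on leaking rows (sustained reversals were always accompanied by
        sustained leakage); 2 MPa transient-reversal count (not printed) is
        interpolated at 118.  Vessel geometry (diameters, bifurcation
        distances) is not part of the tallies and is left missing.
        """
        ext_leak = {1.0: 13, 2.0: 109, 3.0: 213}
        transient_rev = {1.0: 35, 2.0: 118, 3.0: 160}
        # pooled timing allocation over the 348 extravasations: largest-
        # remainder rounding of the histogram fractions (13 / 209 / 126)
        timing_counts = _largest_remainder(
            [frac for _, _, frac in self.timing_histogram],
            int(self.data["totals"]["extravasated"]),
        )
        midpoints = [0.5 * (lo + hi) for lo, hi, _ in self.timing_histogram]
        time_pool = np.repeat(midpoints, timing_counts).tolist()

        blocks = []
        vessel_id = 0
        for p in self.pressures:
            g = self.group(p)
            n = g["vessels"]
            n_ext, n_unc, n_rem = g["extravasated"], g["unclear"], g["remained"]
            n_act = g["activations"]
            n_leak = g["rbc_leakage"]
            n_ext_leak = ext_leak[p]
            n_unc_leak = n_leak - n_ext_leak
            if not 0 <= n_unc_leak <= n_unc:
                raise AssertionError("leakage split exceeds unclear-fate rows")

            fate = np.array(
                ["extravasated"] * n_ext
                + ["unclear"] * n_unc
                + ["remained"] * n_rem
                + ["n/a"] * (n - n_act),
                dtype=object,
            )
            activation = fate != "n/a"
            leak = np.zeros(n, dtype=bool)
            leak[:n_ext_leak] = True
            leak[n_ext : n_ext + n_unc_leak] = True

            n_trans = transient_rev[p]
            n_sust = n_act - n_trans
            reversal = np.full(n, "none", dtype=object)
            leak_idx = np.flatnonzero(leak)
            reversal[leak_idx[:n_sust]] = "sustained"
            remaining = np.flatnonzero(activation & (reversal == "none"))
            reversal[remaining] = "transient"

            leakage = np.full(n, "none", dtype=object)
            leakage[leak & (reversal == "sustained")] = "sustained"
            leakage[leak & (reversal != "sustained")] = "transient"

            times = np.full(n, np.nan)
            times[:n_ext] = time_pool[:n_ext]
            del time_pool[:n_ext]

            blocks.append(
                pd.DataFrame(
                    {
                        "vessel_id": np.arange(vessel_id, vessel_id + n),
                        "fov_id": -1,
                        "embryo_id": -1,
                        "pressure_mpa": p,
                        "diameter_um": np.nan,
                        "vessel_type": "unknown",
                        "bifurcation_distance_um": np.nan,
                        "scale": "network",
                        "activation": activation,
                        "fate": fate,
                        "extravasation_time_s": times,
                        "rbc_leakage": leakage,
                        "flow_reversal": reversal,
                    }
                )
            )
            vessel_id += n
        table = pd.concat(blocks, ignore_index=True)[EVENT_COLUMNS]
        table.attrs["source"] = "packaged_observed_counts"
        return table


def _largest_remainder(fractions: list[float], total: int) -> list[int]:
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts.tolist()


def packaged_observed_counts() -> EventCountTable:
    """Load the packaged observed event tallies."""
    text = (
        resources.files("mbcav").joinpath("data/event_counts.json").read_text()
    )
    return EventCountTable(json.loads(text))
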