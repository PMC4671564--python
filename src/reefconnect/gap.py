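"""Protection gap analysis and scenario comparison.

Overlays a selected (high-connectivity) reef portfolio on the existing MPA
layer and reports, per marine ecoregion and in total, how much of the
selected reef area is already protected. A selected unit's protected area
is its stored area-weighted MPA overlap, not a binary in/out call.
Percentages are computed on unrounded sums and formatted to two decimals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .seascape import ReefUnit

__all__ = ["compute_gap_table", "compare_scenarios"]


def compute_gap_table(
    units: list[ReefUnit],
    selected,
    ecoregion_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-ecoregion (plus TOTAL) protection status of the selected reefs.

    Columns: total reef area, selected reef area, selected area inside the
    existing MPA network, and the percentage of selected area protected
    (0.00 when nothing is selected in an ecoregion). The unprotected share
    is the complement of the TOTAL percentage.
    """
    selected = set(int(getattr(s, "unit_id", s)) for s in selected)
    known = {u.unit_id for u in units}
    unknown = selected - known
    if unknown:
        raise ValueError(f"selection references unknown units: {sorted(unknown)}")
    rows = {}
    for u in units:
        key = u.ecoregion_id
        r = rows.setdefault(key, {"total_reef_km2": 0.0, "selected_reef_km2": 0.0, "selected_in_mpa_km2": 0.0})
        r["total_reef_km2"] += u.total_reef_area_km2
        if u.unit_id in selected:
            r["selected_reef_km2"] += u.total_reef_area_km2
            r["selected_in_mpa_km2"] += u.mpa_reef_area_km2
    recs = []
    for key in sorted(rows):
        r = rows[key]
        name = ecoregion_names.get(key, str(key)) if ecoregion_names else str(key)
        recs.append({"ecoregion": name, **r})
    total = {
        "ecoregion": "TOTAL",
        "total_reef_km2": sum(r["total_reef_km2"] for r in rows.values()),
        "selected_reef_km2": sum(r["selected_reef_km2"] for r in rows.values()),
        "selected_in_mpa_km2": sum(r["selected_in_mpa_km2"] for r in rows.values()),
    }
    recs.append(total)
    df = pd.DataFrame(recs)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(
            df["selected_reef_km2"] > 0,
            100.0 * df["selected_in_mpa_km2"] / df["selected_reef_km2"],
            0.0,
        )
    df["pct_selected_in_mpa"] = np.round(pct, 2)
    return df


def compare_scenarios(
    selected_a, selected_b, units: list[ReefUnit] | None = None
) -> dict:
    """Overlap report between two selected unit sets.

    Reports shared / only-A / only-B unit counts (and reef areas when the
    unit table is supplied) and the Jaccard index of the two sets; two empty
    selections are identical, Jaccard 1.
    """
    a = set(int(getattr(s, "unit_id", s)) for s in selected_a)
    b = set(int(getattr(s, "unit_id", s)) for s in selected_b)
    union = a | b
    jaccard = len(a & b) / len(union) if union else 1.0
    area = {u.unit_id: u.total_reef_area_km2 for u in units} if units else {}

    def tot(ids):
        return sum(area.get(i, 0.0) for i in ids) if area else float("nan")

    return {
        "shared_units": len(a & b),
        "only_a_units": len(a - b),
        "only_b_units": len(b - a),
        "shared_area_km2": tot(a & b),
        "only_a_area_km2": tot(a - b),
        "only_b_area_km2": tot(b - a),
        "jaccard": jaccard,
    }
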