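"""Jurisdictional summaries of the averaged connectivity matrix.

Reduces settled-larvae amounts between reef units to the quantities managers
compare across Exclusive Economic Zones: larvae received and contributed per
EEZ (total and excluding within-EEZ settlement), within-EEZ retention, the
per-EEZ contribution ratio, per-unit local retention, and the EEZ-by-EEZ
exchange matrix. All summaries operate on the same post-threshold averaged
matrix consumed by the centrality and reserve-selection stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dispersal import ConnectivityMatrix
from .seascape import ReefUnit

__all__ = [
    "local_retention",
    "eez_exchange_totals",
    "contribution_ratio",
    "eez_matrix",
]


def local_retention(matrix: ConnectivityMatrix) -> pd.Series:
    """Per-unit local retention: diagonal settled amount over released.

    Units with zero release have undefined retention, reported as NaN.
    """
    diag = np.diag(matrix.settled)
    with np.errstate(invalid="ignore", divide="ignore"):
        ret = np.where(matrix.released > 0, diag / matrix.released, np.nan)
    return pd.Series(ret, index=pd.Index(matrix.unit_ids, name="unit_id"), name="local_retention")


def _eez_ids(units: list[ReefUnit], matrix: ConnectivityMatrix) -> np.ndarray:
    by_id = {u.unit_id: u.eez_id for u in units}
    try:
        return np.array([by_id[i] for i in matrix.unit_ids])
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"unit {e} missing from the unit table") from None


def eez_exchange_totals(
    matrix: ConnectivityMatrix, units: list[ReefUnit]
) -> pd.DataFrame:
    """Received/contributed settled larvae per EEZ, with external variants.

    For each EEZ: ``received_total`` sums settlement into its units from any
    source, ``contributed_total`` sums settlement of larvae its units
    released anywhere; the ``_external`` variants drop source/destination
    pairs inside the same EEZ, and ``retained_within_eez`` is the within-EEZ
    block sum. ``contribution_ratio`` (external over total contribution,
    retention included in the denominator) is NaN when nothing settles.
    """
    eez = _eez_ids(units, matrix)
    S = matrix.settled
    zones = np.unique(eez)
    rows = []
    for z in zones:
        src = eez == z
        dst = eez == z
        received = S[:, dst].sum()
        contributed = S[src, :].sum()
        within = S[np.ix_(src, dst)].sum()
        rows.append(
            {
                "eez_id": z,
                "received_total": received,
                "contributed_total": contributed,
                "received_external": received - within,
                "contributed_external": contributed - within,
                "retained_within_eez": within,
                "contribution_ratio": (contributed - within) / contributed
                if contributed > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("eez_id")


def contribution_ratio(summary: pd.DataFrame) -> pd.Series:
    """Externally contributed share of each EEZ's contributed larvae."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            summary["contributed_total"] > 0,
            summary["contributed_external"] / summary["contributed_total"],
            np.nan,
        )
    return pd.Series(ratio, index=summary.index, name="contribution_ratio")


def eez_matrix(matrix: ConnectivityMatrix, units: list[ReefUnit]) -> pd.DataFrame:
    """EEZ-by-EEZ settled-larvae exchange matrix (rows: source, cols: destination)."""
    eez = _eez_ids(units, matrix)
    zones = np.unique(eez)
    out = np.zeros((len(zones), len(zones)))
    for a, za in enumerate(zones):
        for b, zb in enumerate(zones):
            out[a, b] = matrix.settled[np.ix_(eez == za, eez == zb)].sum()
    return pd.DataFrame(out, index=pd.Index(zones, name="source_eez"), columns=pd.Index(zones, name="dest_eez"))
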