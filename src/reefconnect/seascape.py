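"""Synthetic seascape generation.

Builds the gridded inputs the connectivity analysis assumes: a time-varying
2-D surface current field, a reef-habitat grid aggregated into contiguous
reef units (planning units), jurisdiction (EEZ) and ecoregion labels, a
smooth threat-derived cost surface, and an existing-MPA coverage layer.

Currents are an analytic wind-driven double gyre rather than archived ocean
model output: the field is closed-form and linear in its amplitude, which
makes transport behaviour exactly testable. Reef habitat is generated as
compact blobs of reef-bearing cells on an 8 km grid (the resolution at which
regional reef maps are commonly rasterised); contiguous reef cells are
grouped into reef units with 8-neighbour (queen) adjacency, since diagonal
reef chains are ecologically continuous at this cell size.

Grid convention: 0-based (row, col), row 0 at the north edge; cell centres
are used for centroids and distances.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = [
    "SeascapeConfig",
    "CurrentField",
    "HabitatGrid",
    "ReefUnit",
    "ConfigurationError",
    "GenerationError",
    "generate_current_field",
    "generate_habitat_and_units",
    "label_reef_units",
    "cost_surface",
    "assign_jurisdictions_and_cost",
    "generate_mpa_layer",
    "generate_seascape",
    "seascape_to_netcdf",
    "seascape_from_netcdf",
    "units_to_dataframe",
    "units_from_dataframe",
    "units_to_csv",
    "units_from_csv",
    "units_to_geojson",
]

# 8-neighbour (queen) structuring element used to group reef cells into units
QUEEN = np.ones((3, 3), dtype=bool)


class ConfigurationError(ValueError):
    """Invalid seascape configuration."""


class GenerationError(RuntimeError):
    """Seascape generation failed (e.g. nowhere to seed reef habitat)."""


@dataclass(frozen=True)
class SeascapeConfig:
    """Parameters of the synthetic seascape.

    Defaults describe a modest regional domain: a 40x40 grid of 8 km cells
    (320 km square), daily current fields over a 30-day cycle with a peak
    surface speed of 0.3 m/s (typical of Caribbean surface currents), a
    dozen reef clusters with per-cell reef areas of 5-64 km^2, six marine
    jurisdictions and four ecoregions, and 25% of reef area inside MPAs.
    """

    grid_rows: int = 40
    grid_cols: int = 40
    cell_size_km: float = 8.0
    n_timesteps: int = 30
    timestep_hours: float = 24.0
    gyre_amplitude: float = 0.3
    n_reef_clusters: int = 12
    reef_area_range_km2: tuple[float, float] = (5.0, 64.0)
    n_eez: int = 6
    n_ecoregions: int = 4
    mpa_fraction: float = 0.25
    cost_range: tuple[float, float] = (1.0, 10.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell_size_km must be positive")
        if self.n_timesteps < 1 or self.timestep_hours <= 0:
            raise ConfigurationError("time axis must be positive")
        if self.gyre_amplitude < 0:
            raise ConfigurationError("gyre_amplitude must be >= 0")
        if self.n_reef_clusters < 1:
            raise ConfigurationError("n_reef_clusters must be positive")
        lo, hi = self.reef_area_range_km2
        if not (0 < lo <= hi):
            raise ConfigurationError("reef_area_range_km2 must satisfy 0 < min <= max")
        if hi > self.cell_size_km**2 + 1e-12:
            raise ConfigurationError("per-cell reef area cannot exceed the cell area")
        if self.n_eez < 1 or self.n_ecoregions < 1:
            raise ConfigurationError("n_eez and n_ecoregions must be >= 1")
        if not 0.0 <= self.mpa_fraction <= 1.0:
            raise ConfigurationError("mpa_fraction must be in [0, 1]")
        clo, chi = self.cost_range
        if not (0 <= clo <= chi):
            raise ConfigurationError("cost_range must satisfy 0 <= min <= max")


@dataclass
class CurrentField:
    """Gridded surface velocities (m/s) on a (time, row, col) grid.

    ``u`` is eastward (increasing column), ``v`` is northward (decreasing
    row, since row 0 is the north edge). Velocities are zero over land.
    """

    u: np.ndarray
    v: np.ndarray
    cell_size_km: float
    timestep_hours: float
    land_mask: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.u.shape != self.v.shape or self.u.ndim != 3:
            raise ValueError("u and v must be (time, row, col) arrays of equal shape")
        if self.land_mask.shape != self.u.shape[1:]:
            raise ValueError("land_mask shape must match the spatial grid")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("velocities must be finite")
        if self.land_mask.any():
            if np.abs(self.u[:, self.land_mask]).max() > 0 or np.abs(self.v[:, self.land_mask]).max() > 0:
                raise ValueError("velocities must be zero over land")

    @property
    def n_timesteps(self) -> int:
        return self.u.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[1:]

    def at_hour(self, t_hours: float) -> tuple[np.ndarray, np.ndarray]:
        """Velocity field in effect at simulation hour ``t_hours``.

        Fields shorter than the simulated duration are cycled periodically.
        """
        idx = int(t_hours // self.timestep_hours) % self.n_timesteps
        return self.u[idx], self.v[idx]


@dataclass
class HabitatGrid:
    """Reef area per cell (km^2) plus the land mask, on the model grid."""

    reef_area_km2: np.ndarray
    land_mask: np.ndarray
    cell_size_km: float = 8.0

    def __post_init__(self) -> None:
        self.reef_area_km2 = np.asarray(self.reef_area_km2, dtype=np.float64)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.reef_area_km2.shape != self.land_mask.shape:
            raise ValueError("reef_area and land_mask shapes differ")
        if (self.reef_area_km2 < 0).any():
            raise ValueError("reef areas must be nonnegative")
        if self.land_mask.any() and self.reef_area_km2[self.land_mask].max() > 0:
            raise ValueError("reef area must be zero on land")
        if self.reef_area_km2.max(initial=0.0) > self.cell_size_km**2 + 1e-9:
            raise ValueError("per-cell reef area exceeds the cell area")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reef_area_km2.shape


@dataclass
class ReefUnit:
    """A contiguous cluster of reef-bearing cells treated as one planning unit."""

    unit_id: int
    member_cells: list[tuple[int, int]]
    total_reef_area_km2: float
    centroid: tuple[float, float]
    eez_id: int = -1
    ecoregion_id: int = -1
    unit_cost: float = 0.0
    mpa_reef_area_km2: float = 0.0


def generate_current_field(config: SeascapeConfig) -> CurrentField:
    """Analytic double-gyre velocity field, optionally time-modulated.

    The streamfunction is psi = A sin(pi f(x, t)) sin(pi y) on the unit
    domain x in [0, 2], y in [0, 1], with the standard time-dependent gyre
    boundary f(x, t); one modulation cycle spans the full time axis. The
    field is linear in ``gyre_amplitude`` (given in m/s), so doubling the
    amplitude exactly doubles every speed; amplitude 0 gives a still ocean.
    """
    R, C = config.grid_rows, config.grid_cols
    nt = config.n_timesteps
    # cell-centre coordinates on the canonical double-gyre domain
    x = 2.0 * (np.arange(C) + 0.5) / C
    y = (np.arange(R) + 0.5) / R
    X = np.broadcast_to(x, (R, C))
    Y = np.broadcast_to(y[:, None], (R, C))

    A = config.gyre_amplitude / np.pi  # peak |u| = gyre_amplitude
    eps = 0.25 if nt > 1 else 0.0
    period_h = nt * config.timestep_hours
    u = np.empty((nt, R, C))
    v = np.empty((nt, R, C))
    for k in range(nt):
        t_h = k * config.timestep_hours
        e = eps * np.sin(2.0 * np.pi * t_h / period_h)
        f = e * X**2 + (1.0 - 2.0 * e) * X
        dfdx = 2.0 * e * X + (1.0 - 2.0 * e)
        u[k] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * Y)
        # psi increases northward in y; rows run southward, but v is stored
        # as the northward component so the sign convention is unchanged
        v[k] = np.pi * A * np.cos(np.pi * f) * dfdx * np.sin(np.pi * Y)

    land = np.zeros((R, C), dtype=bool)  # open-ocean domain
    u[:, land] = 0.0
    v[:, land] = 0.0
    return CurrentField(
        u=u,
        v=v,
        cell_size_km=config.cell_size_km,
        timestep_hours=config.timestep_hours,
        land_mask=land,
    )


def label_reef_units(habitat: HabitatGrid) -> tuple[np.ndarray, list[ReefUnit]]:
    """Group contiguous reef cells (queen adjacency) into reef units.

    Returns the integer label grid (0 = no reef) and the unit list with
    1-based ids, areas and unweighted cell-centre centroids.
    """
    labels, n = ndimage.label(habitat.reef_area_km2 > 0, structure=QUEEN)
    units: list[ReefUnit] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        cells = list(zip(rows.tolist(), cols.tolist()))
        area = float(habitat.reef_area_km2[rows, cols].sum())
        centroid = (float(rows.mean()), float(cols.mean()))
        units.append(
            ReefUnit(
                unit_id=lab,
                member_cells=cells,
                total_reef_area_km2=area,
                centroid=centroid,
            )
        )
    return labels, units


def _seed_positions(rng: np.random.Generator, ocean: np.ndarray, n: int, min_sep: int) -> list[tuple[int, int]]:
    """Rejection-sample n ocean cells pairwise at least min_sep apart (Chebyshev)."""
    cand = np.argwhere(ocean)
    if len(cand) == 0:
        raise GenerationError("cannot seed reef clusters: no ocean cells")
    seeds: list[tuple[int, int]] = []
    for _ in range(20000):
        if len(seeds) == n:
            break
        r, c = cand[rng.integers(len(cand))]
        if all(max(abs(r - sr), abs(c - sc)) >= min_sep for sr, sc in seeds):
            seeds.append((int(r), int(c)))
    if len(seeds) < n:
        raise GenerationError(
            f"could only place {len(seeds)} of {n} reef clusters with separation {min_sep}"
        )
    return seeds


def generate_habitat_and_units(
    config: SeascapeConfig,
    land_mask: np.ndarray | None = None,
) -> tuple[HabitatGrid, list[ReefUnit]]:
    """Seed compact reef blobs and group them into contiguous reef units.

    Each of ``n_reef_clusters`` blobs grows by random accretion within a
    2-cell radius of its seed; seeds are kept far enough apart that blobs
    cannot touch, so the generator yields exactly ``n_reef_clusters`` units
    on grids large enough to place them. Per-cell reef areas are sampled
    uniformly from ``reef_area_range_km2``.
    """
    R, C = config.grid_rows, config.grid_cols
    if land_mask is None:
        land_mask = np.zeros((R, C), dtype=bool)
    land_mask = np.asarray(land_mask, dtype=bool)
    ocean = ~land_mask
    rng = np.random.default_rng([config.rng_seed, 1])

    max_radius = 2
    seeds = _seed_positions(rng, ocean, config.n_reef_clusters, min_sep=2 * max_radius + 2)

    reef = np.zeros((R, C), dtype=bool)
    for sr, sc in seeds:
        blob = {(sr, sc)}
        target = int(rng.integers(4, 2 * (2 * max_radius + 1) ** 2 // 3))
        for _ in range(200):
            if len(blob) >= target:
                break
            br, bc = list(blob)[rng.integers(len(blob))]
            dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
            nr, nc = br + dr, bc + dc
            if (
                0 <= nr < R
                and 0 <= nc < C
                and ocean[nr, nc]
                and max(abs(nr - sr), abs(nc - sc)) <= max_radius
            ):
                blob.add((int(nr), int(nc)))
        for r, c in blob:
            reef[r, c] = True

    lo, hi = config.reef_area_range_km2
    area = np.zeros((R, C))
    area[reef] = rng.uniform(lo, hi, size=int(reef.sum()))
    area = np.minimum(area, config.cell_size_km**2)
    habitat = HabitatGrid(reef_area_km2=area, land_mask=land_mask, cell_size_km=config.cell_size_km)
    _, units = label_reef_units(habitat)
    return habitat, units


def cost_surface(config: SeascapeConfig) -> np.ndarray:
    """Smooth synthetic threat surface in ``cost_range``, seeded from the config."""
    R, C = config.grid_rows, config.grid_cols
    rng = np.random.default_rng([config.rng_seed, 2])
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    rr = np.arange(R)[:, None] / max(R, 1)
    cc = np.arange(C)[None, :] / max(C, 1)
    s = 0.5 * (1.0 + np.sin(2 * np.pi * cc + ph1) * np.cos(2 * np.pi * rr + ph2))
    lo, hi = config.cost_range
    return lo + (hi - lo) * s


def assign_jurisdictions_and_cost(
    units: list[ReefUnit], config: SeascapeConfig
) -> list[ReefUnit]:
    """Label units with EEZ / ecoregion ids and a threat-derived cost.

    EEZs are longitude (column) bands and ecoregions latitude (row) bands of
    the unit centroid; the unit cost is the mean of the smooth synthetic
    threat surface over the unit's member cells, emulating averaging a
    cumulative-threat raster over each reef unit.
    """
    if not units:
        raise ValueError("units must be non-empty")
    if config.n_eez < 1 or config.n_ecoregions < 1:
        raise ConfigurationError("n_eez and n_ecoregions must be >= 1")
    surf = cost_surface(config)
    out = []
    for u in units:
        eez = min(int(u.centroid[1] / config.grid_cols * config.n_eez), config.n_eez - 1)
        eco = min(
            int(u.centroid[0] / config.grid_rows * config.n_ecoregions),
            config.n_ecoregions - 1,
        )
        rows = [r for r, _ in u.member_cells]
        cols = [c for _, c in u.member_cells]
        cost = float(surf[rows, cols].mean()) if u.member_cells else float(surf.mean())
        out.append(dataclasses.replace(u, eez_id=eez, ecoregion_id=eco, unit_cost=cost))
    return out


def generate_mpa_layer(units: list[ReefUnit], config: SeascapeConfig) -> list[ReefUnit]:
    """Assign existing-MPA reef coverage totalling ~mpa_fraction of reef area.

    Units are visited in a seeded random order and covered in full until the
    regional quota is reached; only the unit that crosses the quota receives
    partial coverage, so the protected total matches the quota exactly.
    """
    if not 0.0 <= config.mpa_fraction <= 1.0:
        raise ConfigurationError("mpa_fraction must be in [0, 1]")
    rng = np.random.default_rng([config.rng_seed, 3])
    order = rng.permutation(len(units))
    total = sum(u.total_reef_area_km2 for u in units)
    quota = config.mpa_fraction * total
    covered = np.zeros(len(units))
    remaining = quota
    for idx in order:
        if remaining <= 0:
            break
        take = min(units[idx].total_reef_area_km2, remaining)
        covered[idx] = take
        remaining -= take
    return [
        dataclasses.replace(u, mpa_reef_area_km2=float(covered[i]))
        for i, u in enumerate(units)
    ]


def generate_seascape(
    config: SeascapeConfig,
) -> tuple[CurrentField, HabitatGrid, list[ReefUnit]]:
    """Full seascape: currents, habitat, labelled/cost/MPA-annotated units."""
    currents = generate_current_field(config)
    habitat, units = generate_habitat_and_units(config)
    if units:
        units = assign_jurisdictions_and_cost(units, config)
        units = generate_mpa_layer(units, config)
    return currents, habitat, units


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def seascape_to_netcdf(currents: CurrentField, habitat: HabitatGrid, path) -> None:
    """Write currents + habitat as one NetCDF file (dims time, row, col)."""
    ds = xr.Dataset(
        {
            "u": (("time", "row", "col"), currents.u),
            "v": (("time", "row", "col"), currents.v),
            "reef_area": (("row", "col"), habitat.reef_area_km2),
            "land_mask": (("row", "col"), currents.land_mask.astype(np.int8)),
        },
        attrs={
            "cell_size_km": currents.cell_size_km,
            "timestep_hours": currents.timestep_hours,
            "origin_row_km": currents.origin[0],
            "origin_col_km": currents.origin[1],
        },
    )
    ds.to_netcdf(path, engine="scipy")


def seascape_from_netcdf(path) -> tuple[CurrentField, HabitatGrid]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
        land = ds["land_mask"].values.astype(bool)
        currents = CurrentField(
            u=ds["u"].values,
            v=ds["v"].values,
            cell_size_km=float(ds.attrs["cell_size_km"]),
            timestep_hours=float(ds.attrs["timestep_hours"]),
            land_mask=land,
            origin=(float(ds.attrs["origin_row_km"]), float(ds.attrs["origin_col_km"])),
        )
        habitat = HabitatGrid(
            reef_area_km2=ds["reef_area"].values,
            land_mask=land,
            cell_size_km=float(ds.attrs["cell_size_km"]),
        )
    return currents, habitat


UNIT_COLUMNS = [
    "unit_id",
    "eez_id",
    "ecoregion_id",
    "total_reef_area_km2",
    "unit_cost",
    "mpa_reef_area_km2",
    "centroid_row",
    "centroid_col",
]


def units_to_dataframe(units: list[ReefUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "eez_id": u.eez_id,
                "ecoregion_id": u.ecoregion_id,
                "total_reef_area_km2": u.total_reef_area_km2,
                "unit_cost": u.unit_cost,
                "mpa_reef_area_km2": u.mpa_reef_area_km2,
                "centroid_row": u.centroid[0],
                "centroid_col": u.centroid[1],
            }
            for u in units
        ],
        columns=UNIT_COLUMNS,
    )


def units_from_dataframe(df: pd.DataFrame) -> list[ReefUnit]:
    missing = set(UNIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"unit table is missing columns: {sorted(missing)}")
    return [
        ReefUnit(
            unit_id=int(r.unit_id),
            member_cells=[],
            total_reef_area_km2=float(r.total_reef_area_km2),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            eez_id=int(r.eez_id),
            ecoregion_id=int(r.ecoregion_id),
            unit_cost=float(r.unit_cost),
            mpa_reef_area_km2=float(r.mpa_reef_area_km2),
        )
        for r in df.itertuples()
    ]


def units_to_csv(units: list[ReefUnit], path) -> None:
    units_to_dataframe(units).to_csv(path, index=False)


def units_from_csv(path) -> list[ReefUnit]:
    return units_from_dataframe(pd.read_csv(path))


def units_to_geojson(units: list[ReefUnit], cell_size_km: float, grid_rows: int, path=None) -> dict:
    """Unit footprints as a GeoJSON FeatureCollection (km coordinates, y north-up)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for u in units:
        cells = [
            box(
                c * cell_size_km,
                (grid_rows - 1 - r) * cell_size_km,
                (c + 1) * cell_size_km,
                (grid_rows - r) * cell_size_km,
            )
            for r, c in u.member_cells
        ]
        geom = unary_union(cells) if cells else None
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom) if geom is not None else None,
                "properties": {
                    "unit_id": u.unit_id,
                    "eez_id": u.eez_id,
                    "ecoregion_id": u.ecoregion_id,
                    "total_reef_area_km2": u.total_reef_area_km2,
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
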