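"""Reserve selection: Marxan-style objective and simulated annealing.

A planning problem scores a candidate set of reef planning units with the
four-term objective

    sum(cost of selected units)
    + BLM * sum(boundary values crossing the selection edge)
    + sum over features of SPF * penalty for any unmet target
    + cost-threshold penalty (optional)

Boundary entries may be *asymmetric* connectivity values: every directed
entry whose two endpoints differ in selection status contributes once, so
both lost exports and unprotected imports are penalized. The feature
penalty is SPF x (shortfall/target) x a base penalty equal to the cost of a
greedy cover that meets the target from scratch, keeping the term
commensurate with unit costs. The optional cost-threshold term ramps
linearly over annealing progress and multiplies the cost excess.

Optimization is single-unit-flip simulated annealing (adaptive initial
temperature from sampled flip deltas, geometric cooling) followed by
best-improvement 1-flip local search, repeated over independent runs to
produce a best solution and per-unit selection frequencies. The inner loop
is compiled with numba; the pure-Python ``objective_score`` is the reference
implementation the kernels are held to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .dispersal import ConnectivityMatrix
from .seascape import ReefUnit

__all__ = [
    "Feature",
    "PlanningProblem",
    "Solution",
    "SelectionFrequency",
    "ParseError",
    "build_distance_boundary",
    "build_connectivity_boundary",
    "build_problem",
    "objective_score",
    "crossing_value",
    "simulated_annealing",
    "iterative_improvement",
    "run_scenario",
    "stratify_features",
    "calibrate_blm",
    "write_problem",
    "read_problem",
]

STATUS_FREE = 0
STATUS_LOCKED_IN = 2
STATUS_LOCKED_OUT = 3


class ParseError(ValueError):
    """Malformed planning-problem file."""


@dataclass(frozen=True)
class Feature:
    """A conservation feature: a per-unit amount with a target and penalty factor."""

    feature_id: int
    name: str
    target: float
    spf: float


@dataclass
class PlanningProblem:
    """Planning units, features, targets and (possibly asymmetric) boundaries."""

    unit_ids: np.ndarray
    cost: np.ndarray
    status: np.ndarray
    features: list[Feature]
    amounts: np.ndarray  # (n_units, n_features)
    bound_id1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bound_id2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bound_value: np.ndarray = field(default_factory=lambda: np.empty(0))
    blm: float = 0.0
    cost_threshold: tuple[float, float, float] | None = None  # (threshold, pen_start, pen_end)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        self.cost = np.asarray(self.cost, dtype=np.float64)
        self.status = np.asarray(self.status, dtype=np.int64)
        self.amounts = np.asarray(self.amounts, dtype=np.float64)
        self.bound_id1 = np.asarray(self.bound_id1, dtype=np.int64)
        self.bound_id2 = np.asarray(self.bound_id2, dtype=np.int64)
        self.bound_value = np.asarray(self.bound_value, dtype=np.float64)
        n = len(self.unit_ids)
        if len(np.unique(self.unit_ids)) != n:
            raise ValueError("unit ids must be unique")
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != len(fids):
            raise ValueError("feature ids must be unique")
        if self.cost.shape != (n,) or self.status.shape != (n,):
            raise ValueError("cost/status must align with unit_ids")
        if (self.cost < 0).any():
            raise ValueError("unit costs must be nonnegative")
        if self.amounts.shape != (n, len(self.features)):
            raise ValueError("amounts must be (n_units, n_features)")
        if (self.amounts < 0).any():
            raise ValueError("feature amounts must be nonnegative")
        known = set(self.unit_ids.tolist())
        for arr in (self.bound_id1, self.bound_id2):
            bad = set(arr.tolist()) - known
            if bad:
                raise ValueError(f"boundary entries reference unknown units: {sorted(bad)}")
        if (self.bound_value < 0).any():
            raise ValueError("boundary values must be nonnegative")
        self._index = {int(u): i for i, u in enumerate(self.unit_ids)}
        # achievability warning: targets with everything selected
        tot = self.amounts.sum(axis=0)
        for f, t in zip(self.features, tot):
            if f.target > t + 1e-12:
                warnings.warn(
                    f"feature {f.name!r}: target {f.target} exceeds total amount {t}",
                    stacklevel=2,
                )
        self._base_penalties: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit_id: int) -> int:
        return self._index[int(unit_id)]

    def base_penalties(self) -> np.ndarray:
        """Per-feature base penalty: cost of a greedy cover meeting the target.

        Units are added in decreasing amount-per-cost order (zero-cost units
        first) until the target is met; the summed cost anchors the penalty
        for missing that feature entirely.
        """
        if self._base_penalties is None:
            out = np.zeros(len(self.features))
            for fi, f in enumerate(self.features):
                if f.target <= 0:
                    continue
                a = self.amounts[:, fi]
                usable = a > 0
                if not usable.any():
                    continue
                with np.errstate(divide="ignore"):
                    ratio = np.where(self.cost > 0, a / np.maximum(self.cost, 1e-300), np.inf)
                order = np.argsort(-ratio[usable], kind="stable")
                idx = np.nonzero(usable)[0][order]
                got = 0.0
                spent = 0.0
                for i in idx:
                    got += a[i]
                    spent += self.cost[i]
                    if got >= f.target:
                        break
                out[fi] = spent
            self._base_penalties = out
        return self._base_penalties


@dataclass
class Solution:
    """A selected unit set with its objective breakdown and target status."""

    selected: tuple[int, ...]
    cost_term: float
    boundary_term: float
    penalty_term: float
    threshold_term: float
    total: float
    feature_held: dict[int, float]
    feature_met: dict[int, bool]

    def to_dataframe(self, problem: PlanningProblem) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "unit_id": problem.unit_ids,
                "selected": [int(u in sel) for u in problem.unit_ids.tolist()],
            }
        )


@dataclass
class SelectionFrequency:
    """How often each unit entered the selected set across repetitions."""

    unit_ids: np.ndarray
    counts: np.ndarray
    n_repetitions: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.counts, index=pd.Index(self.unit_ids, name="unit_id"), name="selection_frequency"
        )


# ---------------------------------------------------------------------------
# boundary builders
# ---------------------------------------------------------------------------

def build_distance_boundary(
    units: list[ReefUnit], cell_size_km: float = 8.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reversed min-max-scaled Euclidean centroid distances as boundary values.

    All unordered unit pairs are scaled to [0, 1] by their distance and
    reversed (1 - scaled): the nearest pair gets the largest value. With all
    pairwise distances equal the scaling is degenerate and every pair gets
    value 1 (with a warning). Entries are symmetric; one row per pair.
    """
    if len(units) < 2:
        raise ValueError("need at least two units for a distance boundary")
    ids = np.array([u.unit_id for u in units], dtype=np.int64)
    pts = np.array([u.centroid for u in units]) * cell_size_km
    i, j = np.triu_indices(len(units), k=1)
    d = np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
    dmin, dmax = float(d.min()), float(d.max())
    if dmax - dmin <= 0:
        warnings.warn("all pairwise distances equal; boundary values degenerate to 1")
        vals = np.ones_like(d)
    else:
        vals = 1.0 - (d - dmin) / (dmax - dmin)
    return ids[i], ids[j], vals


def build_connectivity_boundary(
    matrix: ConnectivityMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed connection strengths max-scaled to [0, 1] as boundary values.

    Strong connections already mean "close", so no reversal is applied; the
    asymmetry of the matrix is preserved (value i->j may differ from j->i)
    and zero/self connections are omitted.
    """
    S = matrix.settled
    off = ~np.eye(S.shape[0], dtype=bool)
    pos = (S > 0) & off
    if not pos.any():
        warnings.warn("connectivity matrix has no off-diagonal connections")
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0)
    smax = S[pos].max()
    src, dst = np.nonzero(pos)
    ids = np.asarray(matrix.unit_ids, dtype=np.int64)
    return ids[src], ids[dst], S[src, dst] / smax


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def crossing_value(problem: PlanningProblem, selected) -> float:
    """Raw boundary value crossing the selection edge (before the BLM weight)."""
    if len(problem.bound_value) == 0:
        return 0.0
    sel = np.zeros(problem.n_units, dtype=bool)
    for u in selected:
        sel[problem.index_of(u)] = True
    i1 = np.array([problem.index_of(u) for u in problem.bound_id1.tolist()])
    i2 = np.array([problem.index_of(u) for u in problem.bound_id2.tolist()])
    return float(problem.bound_value[sel[i1] != sel[i2]].sum())


def objective_score(
    problem: PlanningProblem, selected, progress: float = 1.0
) -> Solution:
    """Score a selection with the four-term objective (reference implementation)."""
    selected = set(int(u) for u in selected)
    unknown = selected - set(problem.unit_ids.tolist())
    if unknown:
        raise ValueError(f"selection references unknown units: {sorted(unknown)}")
    for u, st in zip(problem.unit_ids.tolist(), problem.status):
        if st == STATUS_LOCKED_IN and u not in selected:
            raise ValueError(f"locked-in unit {u} missing from selection")
        if st == STATUS_LOCKED_OUT and u in selected:
            raise ValueError(f"locked-out unit {u} present in selection")

    sel_idx = np.array(sorted(problem.index_of(u) for u in selected), dtype=np.int64)
    cost_term = float(problem.cost[sel_idx].sum()) if len(sel_idx) else 0.0
    boundary_term = problem.blm * crossing_value(problem, selected)

    base = problem.base_penalties()
    held = (
        problem.amounts[sel_idx].sum(axis=0)
        if len(sel_idx)
        else np.zeros(len(problem.features))
    )
    penalty_term = 0.0
    feature_held: dict[int, float] = {}
    feature_met: dict[int, bool] = {}
    for fi, f in enumerate(problem.features):
        feature_held[f.feature_id] = float(held[fi])
        met = held[fi] >= f.target - 1e-12
        feature_met[f.feature_id] = bool(met)
        if not met and f.target > 0:
            shortfall = f.target - held[fi]
            penalty_term += f.spf * (shortfall / f.target) * base[fi]

    threshold_term = 0.0
    if problem.cost_threshold is not None:
        thr, p0, p1 = problem.cost_threshold
        ramp = p0 + (p1 - p0) * progress
        threshold_term = ramp * max(0.0, cost_term - thr)

    total = cost_term + boundary_term + penalty_term + threshold_term
    return Solution(
        selected=tuple(sorted(selected)),
        cost_term=cost_term,
        boundary_term=boundary_term,
        penalty_term=penalty_term,
        threshold_term=threshold_term,
        total=total,
        feature_held=feature_held,
        feature_met=feature_met,
    )


# ---------------------------------------------------------------------------
# numba kernels (must agree with objective_score; tested against it)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _flip_delta(u, new_val, sel, cost, amounts, targets, pen_scale, blm,
                inc_ptr, inc_other, inc_val, cost_tot, held,
                thr_on, thr, ramp):
    sgn = 1.0 if new_val == 1 else -1.0
    d = sgn * cost[u]
    db = 0.0
    for k in range(inc_ptr[u], inc_ptr[u + 1]):
        if sel[inc_other[k]] != new_val:
            db += inc_val[k]
        else:
            db -= inc_val[k]
    d += blm * db
    for f in range(amounts.shape[1]):
        a = amounts[u, f]
        if a > 0.0 and targets[f] > 0.0:
            h0 = held[f]
            h1 = h0 + sgn * a
            s0 = targets[f] - h0
            s1 = targets[f] - h1
            p0 = pen_scale[f] * (s0 / targets[f]) if s0 > 1e-12 else 0.0
            p1 = pen_scale[f] * (s1 / targets[f]) if s1 > 1e-12 else 0.0
            d += p1 - p0
    if thr_on:
        e0 = cost_tot - thr
        e1 = cost_tot + sgn * cost[u] - thr
        t0 = ramp * e0 if e0 > 0.0 else 0.0
        t1 = ramp * e1 if e1 > 0.0 else 0.0
        d += t1 - t0
    return d


@njit(cache=True)
def _anneal(sel, cost, amounts, targets, pen_scale, blm,
            inc_ptr, inc_other, inc_val,
            proposals, uniforms, t0, log_final_ratio,
            thr_on, thr, pstart, pend, best_sel):
    n_iter = proposals.shape[0]
    cost_tot = 0.0
    for i in range(sel.shape[0]):
        if sel[i] == 1:
            cost_tot += cost[i]
    held = np.zeros(targets.shape[0])
    for f in range(targets.shape[0]):
        s = 0.0
        for i in range(sel.shape[0]):
            if sel[i] == 1:
                s += amounts[i, f]
        held[f] = s
    best_sel[:] = sel[:]
    cur_delta = 0.0
    best_delta = 0.0
    for k in range(n_iter):
        progress = k / n_iter
        T = t0 * np.exp(log_final_ratio * progress)
        ramp = pstart + (pend - pstart) * progress
        u = proposals[k]
        new_val = 1 - sel[u]
        d = _flip_delta(u, new_val, sel, cost, amounts, targets, pen_scale,
                        blm, inc_ptr, inc_other, inc_val, cost_tot, held,
                        thr_on, thr, ramp)
        if d < 0.0 or (T > 0.0 and uniforms[k] < np.exp(-d / T)):
            sel[u] = new_val
            sgn = 1.0 if new_val == 1 else -1.0
            cost_tot += sgn * cost[u]
            for f in range(targets.shape[0]):
                held[f] += sgn * amounts[u, f]
            cur_delta += d
            if cur_delta < best_delta - 1e-12:
                best_delta = cur_delta
                best_sel[:] = sel[:]


@njit(cache=True)
def _improve(sel, free_units, cost, amounts, targets, pen_scale, blm,
             inc_ptr, inc_other, inc_val, thr_on, thr, ramp):
    cost_tot = 0.0
    for i in range(sel.shape[0]):
        if sel[i] == 1:
            cost_tot += cost[i]
    held = np.zeros(targets.shape[0])
    for f in range(targets.shape[0]):
        s = 0.0
        for i in range(sel.shape[0]):
            if sel[i] == 1:
                s += amounts[i, f]
        held[f] = s
    for _ in range(100000):
        best_d = -1e-9
        best_u = -1
        for fi in range(free_units.shape[0]):
            u = free_units[fi]
            new_val = 1 - sel[u]
            d = _flip_delta(u, new_val, sel, cost, amounts, targets, pen_scale,
                            blm, inc_ptr, inc_other, inc_val, cost_tot, held,
                            thr_on, thr, ramp)
            if d < best_d:
                best_d = d
                best_u = u
        if best_u < 0:
            break
        new_val = 1 - sel[best_u]
        sel[best_u] = new_val
        sgn = 1.0 if new_val == 1 else -1.0
        cost_tot += sgn * cost[best_u]
        for f in range(targets.shape[0]):
            held[f] += sgn * amounts[best_u, f]


def _kernel_arrays(problem: PlanningProblem):
    n = problem.n_units
    i1 = np.array([problem.index_of(u) for u in problem.bound_id1.tolist()], dtype=np.int64)
    i2 = np.array([problem.index_of(u) for u in problem.bound_id2.tolist()], dtype=np.int64)
    deg = np.zeros(n, dtype=np.int64)
    for a, b in zip(i1, i2):
        deg[a] += 1
        deg[b] += 1
    inc_ptr = np.zeros(n + 1, dtype=np.int64)
    inc_ptr[1:] = np.cumsum(deg)
    inc_other = np.zeros(inc_ptr[-1], dtype=np.int64)
    inc_val = np.zeros(inc_ptr[-1])
    fill = inc_ptr[:-1].copy()
    for a, b, v in zip(i1, i2, problem.bound_value):
        inc_other[fill[a]] = b
        inc_val[fill[a]] = v
        fill[a] += 1
        inc_other[fill[b]] = a
        inc_val[fill[b]] = v
        fill[b] += 1
    targets = np.array([f.target for f in problem.features])
    pen_scale = np.array([f.spf for f in problem.features]) * problem.base_penalties()
    if problem.cost_threshold is not None:
        thr_on, thr, p0, p1 = True, *problem.cost_threshold
    else:
        thr_on, thr, p0, p1 = False, 0.0, 0.0, 0.0
    return inc_ptr, inc_other, inc_val, targets, pen_scale, thr_on, thr, p0, p1


def _initial_selection(problem: PlanningProblem, rng: np.random.Generator) -> np.ndarray:
    sel = np.zeros(problem.n_units, dtype=np.int8)
    sel[problem.status == STATUS_LOCKED_IN] = 1
    free = problem.status == STATUS_FREE
    sel[free] = (rng.random(int(free.sum())) < 0.5).astype(np.int8)
    return sel


def simulated_annealing(
    problem: PlanningProblem, iterations: int = 100_000, seed: int = 0
) -> Solution:
    """One annealing run plus best-improvement local search.

    Starts from a random selection of the free units, proposes single-unit
    flips, and accepts worsening moves with probability exp(-delta/T) under
    geometric cooling from an adaptive initial temperature (90th percentile
    of |delta| over 1000 sampled flips) to 1e-4 of it. The best selection
    seen is kept and polished by iterative improvement, so the result is
    never worse than the initial random selection. Deterministic per seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    sel = _initial_selection(problem, rng)
    free_units = np.nonzero(problem.status == STATUS_FREE)[0].astype(np.int64)
    if len(free_units) == 0:
        return objective_score(problem, problem.unit_ids[sel.astype(bool)])
    (inc_ptr, inc_other, inc_val, targets, pen_scale,
     thr_on, thr, p0, p1) = _kernel_arrays(problem)

    # adaptive initial temperature from sampled flip deltas
    cost_tot = float(problem.cost[sel.astype(bool)].sum())
    held = problem.amounts[sel.astype(bool)].sum(axis=0)
    sample = rng.choice(free_units, size=min(1000, 8 * len(free_units)))
    deltas = np.array(
        [
            abs(
                _flip_delta(
                    int(u), 1 - int(sel[u]), sel, problem.cost, problem.amounts,
                    targets, pen_scale, problem.blm, inc_ptr, inc_other, inc_val,
                    cost_tot, held, thr_on, thr, p0,
                )
            )
            for u in sample
        ]
    )
    t0 = max(float(np.percentile(deltas, 90)), 1e-12)

    proposals = free_units[rng.integers(0, len(free_units), size=iterations)]
    uniforms = rng.random(iterations)
    best_sel = np.zeros_like(sel)
    _anneal(
        sel, problem.cost, problem.amounts, targets, pen_scale, problem.blm,
        inc_ptr, inc_other, inc_val, proposals, uniforms, t0, float(np.log(1e-4)),
        thr_on, thr, p0, p1, best_sel,
    )
    _improve(
        best_sel, free_units, problem.cost, problem.amounts, targets, pen_scale,
        problem.blm, inc_ptr, inc_other, inc_val, thr_on, thr, p1,
    )
    return objective_score(problem, problem.unit_ids[best_sel.astype(bool)])


def iterative_improvement(problem: PlanningProblem, solution: Solution) -> Solution:
    """Apply best single-unit flips while any flip strictly lowers the total."""
    sel = np.zeros(problem.n_units, dtype=np.int8)
    for u in solution.selected:
        sel[problem.index_of(u)] = 1
    free_units = np.nonzero(problem.status == STATUS_FREE)[0].astype(np.int64)
    (inc_ptr, inc_other, inc_val, targets, pen_scale,
     thr_on, thr, p0, p1) = _kernel_arrays(problem)
    _improve(
        sel, free_units, problem.cost, problem.amounts, targets, pen_scale,
        problem.blm, inc_ptr, inc_other, inc_val, thr_on, thr, p1,
    )
    return objective_score(problem, problem.unit_ids[sel.astype(bool)])


def run_scenario(
    problem: PlanningProblem,
    n_reps: int = 100,
    iterations: int = 100_000,
    seed: int = 0,
) -> tuple[Solution, SelectionFrequency]:
    """Repeat annealing runs; return the best solution and selection frequency.

    Repetition seeds derive deterministically from ``seed``; objective ties
    between repetitions go to the earliest repetition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    best: Solution | None = None
    counts = np.zeros(problem.n_units, dtype=np.int64)
    for s in rep_seeds:
        sol = simulated_annealing(problem, iterations=iterations, seed=int(s))
        for u in sol.selected:
            counts[problem.index_of(u)] += 1
        if best is None or sol.total < best.total - 1e-12:
            best = sol
    freq = SelectionFrequency(
        unit_ids=problem.unit_ids.copy(), counts=counts, n_repetitions=n_reps
    )
    return best, freq


def stratify_features(
    problem: PlanningProblem,
    units: list[ReefUnit],
    by_ecoregion: bool = True,
    target_fraction: float = 0.30,
) -> PlanningProblem:
    """Split each feature into per-ecoregion features with in-stratum targets.

    Each stratum feature keeps the parent's SPF, zeroes amounts outside its
    ecoregion, and targets ``target_fraction`` of the stratum's total amount
    (so targets must be met within every ecoregion). Strata holding none of
    a feature are omitted with a warning.
    """
    if not by_ecoregion:
        return problem
    eco = {u.unit_id: u.ecoregion_id for u in units}
    missing = [int(u) for u in problem.unit_ids.tolist() if u not in eco]
    if missing:
        raise ValueError(f"units without ecoregion labels: {missing}")
    eco_per_unit = np.array([eco[int(u)] for u in problem.unit_ids.tolist()])
    regions = np.unique(eco_per_unit)
    new_features: list[Feature] = []
    new_amounts = []
    fid = 1
    for fi, f in enumerate(problem.features):
        for reg in regions:
            mask = eco_per_unit == reg
            amt = np.where(mask, problem.amounts[:, fi], 0.0)
            tot = float(amt.sum())
            if tot <= 0:
                warnings.warn(
                    f"feature {f.name!r} absent from ecoregion {reg}; stratum omitted"
                )
                continue
            new_features.append(
                Feature(
                    feature_id=fid,
                    name=f"{f.name}_eco{reg}",
                    target=target_fraction * tot,
                    spf=f.spf,
                )
            )
            new_amounts.append(amt)
            fid += 1
    return PlanningProblem(
        unit_ids=problem.unit_ids.copy(),
        cost=problem.cost.copy(),
        status=problem.status.copy(),
        features=new_features,
        amounts=np.column_stack(new_amounts) if new_amounts else np.zeros((problem.n_units, 0)),
        bound_id1=problem.bound_id1.copy(),
        bound_id2=problem.bound_id2.copy(),
        bound_value=problem.bound_value.copy(),
        blm=problem.blm,
        cost_threshold=problem.cost_threshold,
    )


def build_problem(
    units: list[ReefUnit],
    feature_amounts: dict[str, np.ndarray],
    target_fraction: float = 0.30,
    spf: float = 10.0,
    blm: float = 0.17,
    boundary: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    cost_threshold: tuple[float, float, float] | None = None,
) -> PlanningProblem:
    """Assemble a PlanningProblem from annotated reef units.

    ``feature_amounts`` maps feature names to per-unit amount vectors
    (aligned with ``units``); each feature targets ``target_fraction`` of
    its regional total. Defaults mirror common regional practice: 30%
    targets, SPF 10, BLM 0.17.
    """
    ids = np.array([u.unit_id for u in units], dtype=np.int64)
    cost = np.array([u.unit_cost for u in units])
    feats = []
    amts = []
    for k, (name, vec) in enumerate(feature_amounts.items(), start=1):
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != ids.shape:
            raise ValueError(f"feature {name!r} amounts misaligned with units")
        feats.append(
            Feature(feature_id=k, name=name, target=target_fraction * float(vec.sum()), spf=spf)
        )
        amts.append(vec)
    b1, b2, bv = boundary if boundary is not None else (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0),
    )
    return PlanningProblem(
        unit_ids=ids,
        cost=cost,
        status=np.zeros(len(ids), dtype=np.int64),
        features=feats,
        amounts=np.column_stack(amts) if amts else np.zeros((len(ids), 0)),
        bound_id1=b1,
        bound_id2=b2,
        bound_value=bv,
        blm=blm,
        cost_threshold=cost_threshold,
    )


def calibrate_blm(
    problem: PlanningProblem,
    blm_candidates,
    n_reps: int = 10,
    iterations: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cost / boundary trade-off table over candidate BLM values.

    Runs the full scenario at each candidate BLM and reports the best
    solution's cost term and raw crossing boundary value; the caller picks
    the knee of the trade-off.
    """
    blm_candidates = list(blm_candidates)
    if not blm_candidates:
        raise ValueError("blm_candidates must be non-empty")
    rows = []
    for b in blm_candidates:
        p = PlanningProblem(
            unit_ids=problem.unit_ids.copy(),
            cost=problem.cost.copy(),
            status=problem.status.copy(),
            features=list(problem.features),
            amounts=problem.amounts.copy(),
            bound_id1=problem.bound_id1.copy(),
            bound_id2=problem.bound_id2.copy(),
            bound_value=problem.bound_value.copy(),
            blm=float(b),
            cost_threshold=problem.cost_threshold,
        )
        best, _ = run_scenario(p, n_reps=n_reps, iterations=iterations, seed=seed)
        rows.append(
            {
                "blm": float(b),
                "cost_term": best.cost_term,
                "boundary_crossing": crossing_value(p, best.selected),
                "total": best.total,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Marxan-dialect I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{fname}: missing columns {missing}")


def write_problem(problem: PlanningProblem, directory) -> None:
    """Write pu/spec/puvspr/bound tables plus run parameters (BLM, threshold)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"id": problem.unit_ids, "cost": problem.cost, "status": problem.status}
    ).to_csv(d / "pu.csv", index=False)
    pd.DataFrame(
        {
            "id": [f.feature_id for f in problem.features],
            "target": [f.target for f in problem.features],
            "spf": [f.spf for f in problem.features],
            "name": [f.name for f in problem.features],
        }
    ).to_csv(d / "spec.csv", index=False)
    rows = []
    for ui, uid in enumerate(problem.unit_ids.tolist()):
        for f, amt in zip(problem.features, problem.amounts[ui]):
            if amt > 0:
                rows.append({"species": f.feature_id, "pu": uid, "amount": amt})
    pd.DataFrame(rows, columns=["species", "pu", "amount"]).sort_values(
        ["pu", "species"]
    ).to_csv(d / "puvspr.csv", index=False)
    pd.DataFrame(
        {
            "id1": problem.bound_id1,
            "id2": problem.bound_id2,
            "boundary": problem.bound_value,
        }
    ).to_csv(d / "bound.csv", index=False)
    with open(d / "input.dat", "w") as fh:
        fh.write(f"BLM {problem.blm}\n")
        if problem.cost_threshold is not None:
            thr, a, b = problem.cost_threshold
            fh.write(f"COSTTHRESH {thr}\nTHRESHPEN1 {a}\nTHRESHPEN2 {b}\n")


def read_problem(directory) -> PlanningProblem:
    """Read a problem written by :func:`write_problem` (round-trip identity)."""
    d = Path(directory)
    pu = pd.read_csv(d / "pu.csv")
    _require_columns(pu, ["id", "cost", "status"], "pu.csv")
    spec_df = pd.read_csv(d / "spec.csv")
    _require_columns(spec_df, ["id", "target", "spf", "name"], "spec.csv")
    puvspr = pd.read_csv(d / "puvspr.csv")
    _require_columns(puvspr, ["species", "pu", "amount"], "puvspr.csv")
    bound = pd.read_csv(d / "bound.csv")
    _require_columns(bound, ["id1", "id2", "boundary"], "bound.csv")

    ids = pu["id"].to_numpy(np.int64)
    known = set(ids.tolist())
    fidx = {int(f): k for k, f in enumerate(spec_df["id"].tolist())}
    uidx = {int(u): k for k, u in enumerate(ids.tolist())}
    amounts = np.zeros((len(ids), len(fidx)))
    for line, row in enumerate(puvspr.itertuples(), start=2):
        if int(row.pu) not in uidx:
            raise ParseError(f"puvspr.csv line {line}: unknown planning unit {row.pu}")
        if int(row.species) not in fidx:
            raise ParseError(f"puvspr.csv line {line}: unknown feature {row.species}")
        amounts[uidx[int(row.pu)], fidx[int(row.species)]] = float(row.amount)
    for line, row in enumerate(bound.itertuples(), start=2):
        for uid in (row.id1, row.id2):
            if int(uid) not in known:
                raise ParseError(f"bound.csv line {line}: unknown planning unit {uid}")

    blm = 0.0
    cost_threshold = None
    input_dat = d / "input.dat"
    if input_dat.exists():
        kv = {}
        for ln in input_dat.read_text().splitlines():
            parts = ln.split()
            if len(parts) == 2:
                kv[parts[0]] = float(parts[1])
        blm = kv.get("BLM", 0.0)
        if "COSTTHRESH" in kv:
            cost_threshold = (kv["COSTTHRESH"], kv.get("THRESHPEN1", 0.0), kv.get("THRESHPEN2", 0.0))

    features = [
        Feature(
            feature_id=int(r.id), name=str(r.name), target=float(r.target), spf=float(r.spf)
        )
        for r in spec_df.itertuples()
    ]
    return PlanningProblem(
        unit_ids=ids,
        cost=pu["cost"].to_numpy(np.float64),
        status=pu["status"].to_numpy(np.int64),
        features=features,
        amounts=amounts,
        bound_id1=bound["id1"].to_numpy(np.int64),
        bound_id2=bound["id2"].to_numpy(np.int64),
        bound_value=bound["boundary"].to_numpy(np.float64),
        blm=blm,
        cost_threshold=cost_threshold,
    )
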