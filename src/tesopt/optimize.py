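"""Box-constrained least-squares montage optimization.

The designed field ``E_designed`` is a unit vector ``e0`` at every element
of the target set T and zero on the rest of the deep region.  For a
candidate electrode subset with montages stacked in ``E_dataset`` the
per-montage current ratios ``w`` solve

    minimize  || E_dataset w - E_designed ||_2
    subject to |w_m| <= 2,

i.e. no montage may carry more than twice the base injection current (1 mA
per montage by default), which keeps the current from concentrating on a
single electrode.  Subsets of size k are searched exhaustively (C(n, k)
candidates); after normalizing the solution so the volume-averaged field
magnitude in the target equals 0.4 V/m — an estimated stimulation
threshold — subsets whose per-electrode current exceeds the 4 mA safety
cap are excluded, and the minimum-RMSE feasible subset wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import lsq_linear

from .leadfield import (
    LeadFieldBank,
    LeadFieldDataset,
    MontageSet,
    build_dataset,
    enumerate_montages,
)
from .phantom import VoxelHeadModel

__all__ = [
    "DesignField",
    "WeightSolution",
    "ElectrodeCurrentVector",
    "OptimizationResult",
    "build_design_field",
    "solve_weights",
    "rmse",
    "electrode_currents",
    "normalize_to_level",
    "optimize_electrode_subset",
]


@dataclass
class DesignField:
    """Target array: unit vector ``e0`` on T, zero on the complement."""

    vector: np.ndarray  # (3N,)
    target_elements: np.ndarray  # indices into the dataset's elements
    e0: np.ndarray

    @property
    def n_target(self) -> int:
        return len(self.target_elements)


def build_design_field(
    dataset: LeadFieldDataset, target_mask: np.ndarray, e0_direction
) -> DesignField:
    """Construct the designed field for a dataset.

    ``target_mask`` is a boolean voxel mask; dataset elements inside it form
    T.  ``e0_direction`` is normalized to unit length.
    """
    e0 = np.asarray(e0_direction, dtype=float)
    n = np.linalg.norm(e0)
    if n == 0:
        raise ValueError("e0 direction must be nonzero")
    e0 = e0 / n
    in_t = dataset.element_mask(target_mask)
    t_idx = np.flatnonzero(in_t)
    if t_idx.size == 0:
        raise ValueError("target set T is empty for this dataset")
    vec = np.zeros(3 * dataset.n_elements)
    rows = (3 * t_idx[:, None] + np.arange(3)).ravel()
    vec[rows] = np.tile(e0, t_idx.size)
    return DesignField(vector=vec, target_elements=t_idx, e0=e0)


@dataclass
class WeightSolution:
    """Per-montage current ratios with the box bound and fit diagnostics."""

    w: np.ndarray
    bound: float
    cost: float  # 0.5 * ||Aw - b||^2 as reported by the solver
    rmse: float
    status: str
    kkt_ok: bool

    def __post_init__(self) -> None:
        if np.any(np.abs(self.w) > self.bound + 1e-9):
            raise ValueError("weight solution violates the box bound")


def rmse(dataset: LeadFieldDataset, w: np.ndarray, design: DesignField) -> float:
    """Root-mean-square misfit averaged over all 3N Cartesian components."""
    r = dataset.matrix @ np.asarray(w, dtype=float) - design.vector
    return float(np.sqrt(np.mean(r * r)))


def solve_weights(
    dataset: LeadFieldDataset, design: DesignField, bound: float = 2.0
) -> WeightSolution:
    """Solve the box-constrained least-squares problem for current ratios.

    Uses a deterministic bounded least-squares solver (BVLS, with a
    trust-region fallback); optimality is checked via the KKT conditions
    (zero projected gradient on inactive bounds).
    """
    A = dataset.matrix
    b = design.vector
    if A.shape[0] != b.shape[0]:
        raise ValueError("dataset and design field are dimensionally inconsistent")
    try:
        res = lsq_linear(A, b, bounds=(-bound, bound), method="bvls", tol=1e-12)
    except Exception:
        res = lsq_linear(A, b, bounds=(-bound, bound), method="trf", tol=1e-12)
    if not res.success:
        res_trf = lsq_linear(A, b, bounds=(-bound, bound), method="trf", tol=1e-12)
        if res_trf.success or res_trf.cost < res.cost:
            res = res_trf
    w = np.clip(res.x, -bound, bound)

    g = A.T @ (A @ w - b)
    scale = max(np.abs(g).max(), 1.0)
    inactive = np.abs(w) < bound - 1e-9
    kkt_ok = bool(np.all(np.abs(g[inactive]) <= 1e-6 * scale)) if inactive.any() else True
    return WeightSolution(
        w=w,
        bound=bound,
        cost=float(res.cost),
        rmse=rmse(dataset, w, design),
        status="converged" if res.success else "not-converged",
        kkt_ok=kkt_ok,
    )


@dataclass
class ElectrodeCurrentVector:
    """Signed net injected current per electrode (A); sums to zero."""

    electrodes: tuple[int, ...]
    currents_a: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return {e: float(c) for e, c in zip(self.electrodes, self.currents_a)}

    @property
    def max_abs_ma(self) -> float:
        return float(np.abs(self.currents_a).max() * 1e3)

    @property
    def total_ma(self) -> float:
        """Total delivered current (sum of positive electrode currents), mA."""
        return float(self.currents_a[self.currents_a > 0].sum() * 1e3)


def electrode_currents(
    w: np.ndarray, montages: MontageSet, base_current: float | None = None
) -> ElectrodeCurrentVector:
    """Net per-electrode current: signed sum of montage currents.

    Each montage m contributes ``+w_m * base`` at its anode and ``-w_m *
    base`` at its cathode.
    """
    w = np.asarray(w, dtype=float)
    if w.size != len(montages):
        raise ValueError("weights and montages are not aligned")
    elecs = montages.electrodes
    pos = {e: i for i, e in enumerate(elecs)}
    currents = np.zeros(len(elecs))
    for wm, m in zip(w, montages):
        base = base_current if base_current is not None else m.base_current
        currents[pos[m.anode]] += wm * base
        currents[pos[m.cathode]] -= wm * base
    return ElectrodeCurrentVector(electrodes=elecs, currents_a=currents)


@dataclass
class OptimizationResult:
    """Outcome of the exhaustive subset search for one k."""

    electrodes: tuple[int, ...]
    montage_set: MontageSet
    weights: WeightSolution
    rmse: float
    scale: float
    currents: ElectrodeCurrentVector  # after normalization
    target_mean_v_per_m: float  # volume-averaged |E| in target after normalization
    feasible: bool
    mode: str
    k: int
    level: float


def _target_rows(
    bank: LeadFieldBank,
    full_dataset_volume: LeadFieldDataset,
    target_mask: np.ndarray,
) -> np.ndarray:
    """Rows of the volumetric dataset belonging to target voxels (3|T|, m)."""
    in_t = full_dataset_volume.element_mask(target_mask)
    t_idx = np.flatnonzero(in_t)
    rows = (3 * t_idx[:, None] + np.arange(3)).ravel()
    return full_dataset_volume.matrix[rows]


def _target_average(target_rows: np.ndarray, w: np.ndarray) -> float:
    """Volume-averaged field magnitude (V/m) over target voxels for weights w."""
    e = (target_rows @ w).reshape(-1, 3)
    return float(np.linalg.norm(e, axis=1).mean())


def normalize_to_level(
    result: OptimizationResult,
    target_rows: np.ndarray,
    level: float = 0.4,
) -> OptimizationResult:
    """Scale a solution so the volume-averaged target field equals ``level``.

    ``target_rows`` holds the volumetric dataset rows of the target voxels
    (normalization always uses the volumetric target even in surface mode).
    Weights and per-electrode currents are scaled by the same factor; the
    operation is idempotent.
    """
    avg = _target_average(target_rows, result.weights.w * result.scale)
    if avg <= 0:
        raise ValueError("combined field vanishes in the target; cannot normalize")
    s = level / avg
    scale = result.scale * s
    currents = electrode_currents(result.weights.w * scale, result.montage_set)
    return replace(
        result,
        scale=scale,
        currents=currents,
        target_mean_v_per_m=_target_average(target_rows, result.weights.w * scale),
        level=level,
    )


def optimize_electrode_subset(
    bank: LeadFieldBank,
    model: VoxelHeadModel,
    k: int,
    mode: str = "surface",
    region: str = "deep",
    e0_direction=(0.0, 1.0, 0.0),
    bound: float = 2.0,
    cap_ma: float | None = 4.0,
    cap_total: bool = False,
    level: float = 0.4,
    base_current: float = 1e-3,
    full_dataset: LeadFieldDataset | None = None,
    target_rows: np.ndarray | None = None,
) -> OptimizationResult:
    """Exhaustive minimum-RMSE search over all C(n, k) electrode subsets.

    Every subset is scored by its box-constrained least-squares RMSE; after
    normalization to the target ``level`` (0.4 V/m volume average), subsets
    whose per-electrode current exceeds ``cap_ma`` (or whose total delivered
    current exceeds it, when ``cap_total`` is set) are infeasible.  The
    minimum-RMSE feasible subset is returned, ties broken lexicographically;
    if no subset is feasible the minimum-RMSE result is returned flagged
    ``feasible=False``.  ``cap_ma=None`` disables the cap.

    ``full_dataset`` / ``target_rows`` may be passed to reuse the all-montage
    dataset across calls with different k.
    """
    n = len(bank.layout)
    if not 2 <= k <= n:
        raise ValueError(f"k must be between 2 and {n}, got {k}")

    all_montages = enumerate_montages(range(n), base_current=base_current)
    col = {(m.anode, m.cathode): j for j, m in enumerate(all_montages)}
    if full_dataset is None:
        full_dataset = build_dataset(bank, all_montages, model, region, mode=mode)
    if target_rows is None:
        if mode == "volume" and region == "deep":
            vol_ds = full_dataset
        else:
            vol_ds = build_dataset(bank, all_montages, model, "deep", mode="volume")
        target_rows = _target_rows(bank, vol_ds, model.masks["target"])

    design = build_design_field(full_dataset, model.masks["target"], e0_direction)

    best_feasible: OptimizationResult | None = None
    best_any: OptimizationResult | None = None
    for subset in itertools.combinations(range(n), k):
        mset = enumerate_montages(subset, base_current=base_current)
        idx = [col[(m.anode, m.cathode)] for m in mset]
        ds = full_dataset.subset_columns(idx)
        sol = solve_weights(ds, design, bound=bound)
        result = OptimizationResult(
            electrodes=subset,
            montage_set=mset,
            weights=sol,
            rmse=sol.rmse,
            scale=1.0,
            currents=electrode_currents(sol.w, mset),
            target_mean_v_per_m=_target_average(target_rows[:, idx], sol.w),
            feasible=True,
            mode=mode,
            k=k,
            level=level,
        )
        try:
            result = normalize_to_level(
                replace(result, currents=result.currents), target_rows[:, idx], level=level
            )
        except ValueError:
            result = replace(result, feasible=False)
        if result.feasible and cap_ma is not None:
            used = result.currents.total_ma if cap_total else result.currents.max_abs_ma
            if used > cap_ma:
                result = replace(result, feasible=False)

        key = (result.rmse, subset)
        if best_any is None or key < (best_any.rmse, best_any.electrodes):
            best_any = result
        if result.feasible and (
            best_feasible is None or key < (best_feasible.rmse, best_feasible.electrodes)
        ):
            best_feasible = result

    return best_feasible if best_feasible is not None else best_any
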