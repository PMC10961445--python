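"""Group-level field mapping on a template surface.

Each subject's deep-region surface, carrying per-vertex field strength of
their optimized montage, is registered to a template surface by affine
iterative-closest-point (ICP), max-normalized to [0, 1], and projected to
the template by nearest-neighbour lookup.  Vertexwise means and relative
standard deviations (SD/mean) across subjects summarize how robust a
stimulation pattern is over anatomical variability.  A group montage is the
electrode subset most frequently selected across subjects, driven with the
mean of per-subject current ratios re-optimized on that common subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .optimize import DesignField, OptimizationResult, solve_weights

__all__ = [
    "AffineTransform",
    "TemplateFieldMap",
    "GroupResult",
    "GroupMontage",
    "register_affine_icp",
    "project_to_template",
    "group_statistics",
    "select_group_montage",
]


@dataclass
class AffineTransform:
    """x -> A x + t with invertible linear part (mm)."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: x -> self(other(x))."""
        return AffineTransform(
            linear=self.linear @ other.linear,
            translation=self.linear @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vecs = vecs[:, order]
    # deterministic sign: largest-magnitude component of each axis positive
    for i in range(3):
        j = np.argmax(np.abs(vecs[:, i]))
        if vecs[j, i] < 0:
            vecs[:, i] = -vecs[:, i]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return c, vecs


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine map src -> dst."""
    X = np.hstack([src, np.ones((len(src), 1))])
    sol, _, rank, _ = np.linalg.lstsq(X, dst, rcond=None)
    if rank < 4:
        raise ValueError("degenerate point configuration for affine fit")
    return AffineTransform(linear=sol[:3].T, translation=sol[3])


def register_affine_icp(
    source_vertices: np.ndarray,
    template_vertices: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    return_history: bool = False,
):
    """Affine ICP registering a source surface onto a template.

    ICP is run from two deterministic initializations — centroid
    translation only, and centroid plus principal-axes alignment (with a
    fixed sign convention) — and the lower-residual fit wins; for
    near-spherical surfaces the principal axes are noise-driven, so the
    plain centroid start is the safer of the two.  Each iteration matches
    every transformed source vertex to its nearest template vertex and
    refits the affine map by least squares; the mean squared residual is
    non-increasing across iterations.  Stops when the improvement drops
    below ``tol`` (relative) or after ``max_iter`` iterations.
    """
    src = np.asarray(source_vertices, dtype=float)
    dst = np.asarray(template_vertices, dtype=float)
    if len(src) < 4 or len(dst) < 4:
        raise ValueError("need at least 4 vertices on both surfaces")
    if np.linalg.matrix_rank(src - src.mean(axis=0)) < 3:
        raise ValueError("source surface is degenerate (coplanar)")

    cs, vs = _principal_axes(src)
    cd, vd = _principal_axes(dst)
    R0 = vd @ vs.T
    inits = [
        AffineTransform(linear=np.eye(3), translation=cd - cs),
        AffineTransform(linear=R0, translation=cd - R0 @ cs),
    ]

    tree = cKDTree(dst)
    best: tuple[float, AffineTransform, list[float]] | None = None
    for transform in inits:
        history: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            moved = transform.apply(src)
            d, nn = tree.query(moved)
            mse = float(np.mean(d * d))
            history.append(mse)
            if prev - mse < tol * max(prev, 1e-30):
                break
            prev = mse
            transform = _fit_affine(src, dst[nn])
        if best is None or history[-1] < best[0]:
            best = (history[-1], transform, history)
    if return_history:
        return best[1], best[2]
    return best[1]


@dataclass
class TemplateFieldMap:
    """Max-normalized field strengths sampled on the template vertices."""

    values: np.ndarray  # in [0, 1]
    subject: str
    template_n_vertices: int

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("template map values must lie in [0, 1]")


def project_to_template(
    individual_vertices: np.ndarray,
    individual_values: np.ndarray,
    transform: AffineTransform,
    template_vertices: np.ndarray,
    subject: str = "",
) -> TemplateFieldMap:
    """Project an individual field map onto the template.

    The individual strengths are normalized by their maximum; every
    template vertex takes the value of the nearest affine-transformed
    individual vertex.
    """
    vals = np.asarray(individual_values, dtype=float)
    if vals.size == 0:
        raise ValueError("individual map is empty")
    vmax = vals.max()
    if vmax <= 0:
        raise ValueError("individual map has no positive values")
    vals = vals / vmax
    moved = transform.apply(np.asarray(individual_vertices, dtype=float))
    _, nn = cKDTree(moved).query(np.asarray(template_vertices, dtype=float))
    return TemplateFieldMap(
        values=vals[nn], subject=subject, template_n_vertices=len(template_vertices)
    )


@dataclass
class GroupResult:
    """Vertexwise group mean and relative SD of normalized field strength."""

    mean: np.ndarray
    relative_sd: np.ndarray  # NaN where mean == 0 (undefined)
    n_subjects: int


def group_statistics(maps: list[TemplateFieldMap]) -> GroupResult:
    """Vertexwise mean and relative SD (population SD / mean) over subjects."""
    if len(maps) < 2:
        raise ValueError("need at least two subject maps")
    n_vertices = maps[0].template_n_vertices
    if any(m.template_n_vertices != n_vertices for m in maps):
        raise ValueError("maps are defined on different templates")
    stack = np.stack([m.values for m in maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)  # population SD
    rel = np.full(n_vertices, np.nan)
    defined = mean > 0
    rel[defined] = sd[defined] / mean[defined]
    return GroupResult(mean=mean, relative_sd=rel, n_subjects=len(maps))


@dataclass
class GroupMontage:
    """Most frequently selected subset with mean per-montage current ratios."""

    electrodes: tuple[int, ...]
    frequency: int
    n_subjects: int
    mean_ratios: np.ndarray
    per_subject_ratios: np.ndarray  # (n_subjects, m)


def select_group_montage(
    results: list[OptimizationResult],
    subject_problems: list[tuple] | None = None,
) -> GroupMontage:
    """Pick the group electrode subset and average the current ratios.

    The subset chosen by the most subjects wins (ties lexicographic).
    ``subject_problems`` supplies, per subject, the all-montage dataset and
    design field so subjects whose individual optimum differs are re-solved
    on the group subset; the mean is taken over all subjects.  Without it,
    only the subjects who selected the group subset contribute.
    """
    if not results:
        raise ValueError("no subject results")
    counts: dict[tuple[int, ...], int] = {}
    for r in results:
        counts[r.electrodes] = counts.get(r.electrodes, 0) + 1
    group_subset = min(counts, key=lambda s: (-counts[s], s))
    frequency = counts[group_subset]

    ref = next(r for r in results if r.electrodes == group_subset)
    group_montages = ref.montage_set

    ratios = []
    for i, r in enumerate(results):
        if r.electrodes == group_subset:
            ratios.append(r.weights.w)
        elif subject_problems is not None:
            full_ds, design = subject_problems[i]
            col = {
                (m.anode, m.cathode): j for j, m in enumerate(full_ds.montage_set)
            }
            idx = [col[(m.anode, m.cathode)] for m in group_montages]
            sol = solve_weights(full_ds.subset_columns(idx), design, bound=r.weights.bound)
            ratios.append(sol.w)
    per_subject = np.stack(ratios)
    return GroupMontage(
        electrodes=group_subset,
        frequency=frequency,
        n_subjects=len(results),
        mean_ratios=per_subject.mean(axis=0),
        per_subject_ratios=per_subject,
    )
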