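"""Synthetic layered-sphere head phantoms.

The phantom is a concentric five-layer sphere (skin, skull, CSF, gray
matter, white matter) rasterized on a regular voxel grid, with one spherical
deep "target" nucleus and optional decoy nuclei embedded in the white
matter, and 19 scalp electrode patches at idealized 10-20 positions.  It
stands in for segmented MRI head models so that every downstream stage
(forward solve, lead fields, montage optimization, group analysis) can be
exercised without external data.  An ensemble of randomly perturbed
phantoms emulates inter-subject anatomical and conductivity variability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._electrodes1020 import (
    ELECTRODE_DIRECTIONS,
    ELECTRODE_NAMES,
    REFERENCE_HEAD_RADIUS_MM,
)

__all__ = [
    "ConductivityTable",
    "PhantomConfig",
    "VoxelHeadModel",
    "ElectrodeLayout",
    "default_conductivity_table",
    "build_phantom",
    "perturb_config",
]

# Tissue label codes used in the phantom label volume (0 = exterior air).
LABELS = {
    "skin": 1,
    "skull": 2,
    "CSF": 3,
    "gray_matter": 4,
    "white_matter": 5,
    "target": 6,
    "decoy": 7,
}


class ConductivityTable(dict):
    """Mapping tissue name -> electrical conductivity in S/m.

    All values must be strictly positive and finite; applying the table to a
    model whose labels are not all covered raises ``KeyError``.
    """

    def __init__(self, values: dict[str, float]):
        for name, sigma in values.items():
            sigma = float(sigma)
            if not np.isfinite(sigma) or sigma <= 0:
                raise ValueError(f"conductivity for {name!r} must be positive and finite, got {sigma}")
        super().__init__({k: float(v) for k, v in values.items()})

    def scaled(self, factors: dict[str, float]) -> "ConductivityTable":
        """Return a copy with per-tissue multiplicative factors applied."""
        out = dict(self)
        for name, f in factors.items():
            if name in out:
                out[name] = out[name] * float(f)
        return ConductivityTable(out)


#: Measured tissue conductivities (S/m) of the full head-model inventory.
#: White matter is 70% of gray matter by construction.
_TABLE_VALUES = {
    "amygdala": 0.2,
    "blood": 0.7,
    "bone_cancellous": 0.027,
    "bone_cortical": 0.008,
    "brainstem": 0.14,
    "caudate": 0.2,
    "cerebellum_gray_matter": 0.2,
    "cerebellum_white_matter": 0.2,
    "CSF": 1.8,
    "fat": 0.08,
    "gray_matter": 0.2,
    "hippocampus": 0.2,
    "intervertebral_disk": 0.1,
    "muscle": 0.16,
    "nucleus_accumbens": 0.2,
    "putamen": 0.2,
    "skin": 0.1,
    "thalamus": 0.2,
    "vitreous_humor": 1.5,
    "white_matter": 0.14,
}

# Alternative values quoted in the narrative description of the conductivity
# assignment (skin/blood differ from the tabulated set).
_TEXT_OVERRIDES = {"skin": 0.08, "blood": 0.2}


def default_conductivity_table(variant: str = "table") -> ConductivityTable:
    """Return the default tissue conductivity table (S/m).

    Parameters
    ----------
    variant:
        ``"table"`` (default) uses the tabulated measured values;
        ``"text"`` substitutes the narrative values (skin 0.08, blood 0.2).
    """
    values = dict(_TABLE_VALUES)
    if variant == "text":
        values.update(_TEXT_OVERRIDES)
    elif variant != "table":
        raise ValueError(f"unknown conductivity variant {variant!r}")
    return ConductivityTable(values)


def _phantom_conductivities(table: ConductivityTable) -> dict[str, float]:
    """Conductivities for the phantom's own tissue names.

    The target and decoy nuclei get the deep gray-nucleus value (accumbens /
    putamen class), the skull layer the compact-bone value.
    """
    return {
        "skin": table["skin"],
        "skull": table["bone_cortical"],
        "CSF": table["CSF"],
        "gray_matter": table["gray_matter"],
        "white_matter": table["white_matter"],
        "target": table["nucleus_accumbens"],
        "decoy": table["putamen"],
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and material parameters of a layered-sphere phantom.

    Radii are outer radii of the skin, skull, CSF, gray-matter and
    white-matter layers, strictly decreasing, in mm.  The target nucleus
    (and any decoys) must lie entirely inside the white-matter sphere.
    ``electrode_side_mm`` is the physical sponge side (3 cm); when
    ``scale_electrodes_to_head`` is set the footprint on the phantom scalp
    is scaled by (outer radius / 92 mm) so its angular size matches the
    device on an adult head.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 1.0
    radii_mm: tuple[float, float, float, float, float] = (22.0, 20.5, 19.0, 17.5, 14.0)
    target_center_mm: tuple[float, float, float] = (4.0, 3.0, 0.0)
    target_radius_mm: float = 4.0
    # decoy radius deliberately differs from the target's so the deep-region
    # surface has no point symmetry (keeps template registration well-posed)
    decoy_centers_mm: tuple[tuple[float, float, float], ...] = ((-4.0, -3.0, 0.0),)
    decoy_radius_mm: float = 5.0
    electrode_side_mm: float = 30.0
    electrode_sheet_mm: float = 1.0
    scale_electrodes_to_head: bool = True
    conductivity_variant: str = "table"
    conductivity_scale: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        r = np.asarray(self.radii_mm, dtype=float)
        if r.size != 5 or not np.all(np.diff(r) < 0):
            raise ValueError("layer radii must be 5 strictly decreasing values (skin inward)")
        if np.linalg.norm(self.target_center_mm) + self.target_radius_mm >= r[-1]:
            raise ValueError("target nucleus must lie entirely inside the white-matter sphere")
        for c in self.decoy_centers_mm:
            if np.linalg.norm(c) + self.decoy_radius_mm >= r[-1]:
                raise ValueError("decoy nucleus must lie entirely inside the white-matter sphere")
        half_extent = min(s * self.voxel_mm for s in self.shape) / 2.0
        if r[0] > half_extent:
            raise ValueError(
                f"grid too small: outer radius {r[0]} mm exceeds half-extent {half_extent} mm"
            )

    def conductivities(self) -> ConductivityTable:
        table = default_conductivity_table(self.conductivity_variant)
        base = ConductivityTable(_phantom_conductivities(table))
        return base.scaled(dict(self.conductivity_scale))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("shape", "radii_mm", "target_center_mm"):
            raw[key] = tuple(raw[key])
        raw["decoy_centers_mm"] = tuple(tuple(c) for c in raw["decoy_centers_mm"])
        raw["conductivity_scale"] = tuple((k, v) for k, v in raw["conductivity_scale"])
        return cls(**raw)


@dataclass
class VoxelHeadModel:
    """Labeled voxel volume conductor.

    ``labels`` holds one integer tissue code per voxel (0 = exterior);
    ``masks`` exposes the named regions downstream stages rely on:
    ``target`` (the nucleus to stimulate), ``deep`` (target plus decoys),
    ``gray_matter`` and ``white_matter``.
    """

    labels: np.ndarray
    voxel_mm: float
    conductivity: ConductivityTable
    label_names: dict[int, str]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = [l for l in present if self.label_names.get(l) not in self.conductivity]
        if missing:
            raise ValueError(f"labels without conductivity: {missing}")

    @property
    def conductor_mask(self) -> np.ndarray:
        return self.labels > 0

    def sigma_volume(self) -> np.ndarray:
        """Per-voxel conductivity in S/m (0 outside the conductor)."""
        sigma = np.zeros(self.labels.shape, dtype=np.float64)
        for code, name in self.label_names.items():
            sigma[self.labels == code] = self.conductivity[name]
        return sigma

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.labels.shape, dtype=float) * self.voxel_mm / 2.0

    def voxel_centers_mm(self, idx: np.ndarray) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * self.voxel_mm

    def save_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


@dataclass
class ElectrodeLayout:
    """Scalp electrode patches as node sets on the lattice surface.

    ``patch_nodes[i]`` are flat node indices (into the (nx+1, ny+1, nz+1)
    corner lattice) through which electrode ``i`` injects current; patches
    are pairwise disjoint by construction.
    """

    names: tuple[str, ...]
    centers_mm: np.ndarray
    patch_nodes: tuple[np.ndarray, ...]
    node_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names_or_indices) -> "ElectrodeLayout":
        """Layout restricted to the given electrodes (order preserved)."""
        idx = [self.index(e) if isinstance(e, str) else int(e) for e in names_or_indices]
        return ElectrodeLayout(
            names=tuple(self.names[i] for i in idx),
            centers_mm=self.centers_mm[idx],
            patch_nodes=tuple(self.patch_nodes[i] for i in idx),
            node_shape=self.node_shape,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "node_shape": list(self.node_shape),
            "electrodes": [
                {
                    "name": n,
                    "center_mm": [float(x) for x in c],
                    "nodes": [int(v) for v in p],
                }
                for n, c, p in zip(self.names, self.centers_mm, self.patch_nodes)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeLayout":
        raw = json.loads(Path(path).read_text())
        return cls(
            names=tuple(e["name"] for e in raw["electrodes"]),
            centers_mm=np.array([e["center_mm"] for e in raw["electrodes"]]),
            patch_nodes=tuple(np.array(e["nodes"], dtype=np.int64) for e in raw["electrodes"]),
            node_shape=tuple(raw["node_shape"]),
        )


def _rasterize(config: PhantomConfig) -> tuple[np.ndarray, dict[int, str]]:
    shape = config.shape
    h = config.voxel_mm
    center = np.asarray(shape, dtype=float) * h / 2.0
    ii, jj, kk = np.indices(shape)
    pos = np.stack([(ii + 0.5) * h, (jj + 0.5) * h, (kk + 0.5) * h], axis=-1)
    r = np.linalg.norm(pos - center, axis=-1)

    labels = np.zeros(shape, dtype=np.int16)
    # paint outside-in so inner layers overwrite outer ones
    layer_order = ["skin", "skull", "CSF", "gray_matter", "white_matter"]
    for name, radius in zip(layer_order, config.radii_mm):
        labels[r <= radius] = LABELS[name]
    tc = center + np.asarray(config.target_center_mm)
    rt = np.linalg.norm(pos - tc, axis=-1)
    labels[rt <= config.target_radius_mm] = LABELS["target"]
    for c in config.decoy_centers_mm:
        rd = np.linalg.norm(pos - (center + np.asarray(c)), axis=-1)
        labels[rd <= config.decoy_radius_mm] = LABELS["decoy"]
    names = {code: name for name, code in LABELS.items()}
    return labels, names


def _surface_nodes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices and integer (i,j,k) coordinates of boundary lattice nodes.

    A corner node is on the conductor surface when between 1 and 7 of its
    (up to) 8 adjacent voxels are conductor.
    """
    cond = (labels > 0).astype(np.int8)
    padded = np.pad(cond, 1)
    # count of conductor voxels adjacent to each node of the corner lattice
    count = np.zeros(tuple(s + 1 for s in labels.shape), dtype=np.int8)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                count += padded[
                    di : di + labels.shape[0] + 1,
                    dj : dj + labels.shape[1] + 1,
                    dk : dk + labels.shape[2] + 1,
                ]
    surf = (count > 0) & (count < 8)
    coords = np.argwhere(surf)
    flat = np.ravel_multi_index(coords.T, count.shape)
    return flat, coords


def _build_layout(config: PhantomConfig, labels: np.ndarray) -> ElectrodeLayout:
    h = config.voxel_mm
    node_shape = tuple(s + 1 for s in labels.shape)
    center = np.asarray(labels.shape, dtype=float) * h / 2.0
    outer_r = config.radii_mm[0]

    side = config.electrode_side_mm
    if config.scale_electrodes_to_head:
        side = side * outer_r / REFERENCE_HEAD_RADIUS_MM

    flat, coords = _surface_nodes(labels)
    pos = coords * h - center  # node positions relative to head centre
    pos_unit = pos / np.maximum(np.linalg.norm(pos, axis=1, keepdims=True), 1e-12)

    dirs = np.stack([ELECTRODE_DIRECTIONS[n] for n in ELECTRODE_NAMES])
    # Voronoi ownership on the sphere keeps patches disjoint even if the
    # requested footprint is large for the phantom radius.
    owner = np.argmax(pos_unit @ dirs.T, axis=1)

    patch_nodes: list[np.ndarray] = []
    centers = []
    half_arc = (side / 2.0) / outer_r  # geodesic half-side in radians
    for e, name in enumerate(ELECTRODE_NAMES):
        d = dirs[e]
        centers.append(center + d * outer_r)
        # local tangent frame at the electrode centre
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(ref, d)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        sel = owner == e
        pn = pos_unit[sel]
        w = pn @ d
        a = np.arctan2(pn @ u, np.maximum(w, 1e-9))
        b = np.arctan2(pn @ v, np.maximum(w, 1e-9))
        inside = (w > 0) & (np.abs(a) <= half_arc) & (np.abs(b) <= half_arc)
        cand_idx = np.flatnonzero(sel)[inside]
        if cand_idx.size == 0:
            raise ValueError(f"electrode {name}: no surface nodes under the patch")
        # one node per tangent-grid cell: keeps the areal injection density
        # uniform despite the staircase surface
        ca = np.rint(a[inside] * outer_r / h).astype(np.int64)
        cb = np.rint(b[inside] * outer_r / h).astype(np.int64)
        radial = np.linalg.norm(pos[cand_idx], axis=1)
        order = np.lexsort((-radial, cb, ca))
        cells = np.stack([ca, cb], axis=1)[order]
        keep = np.ones(len(order), dtype=bool)
        keep[1:] = np.any(cells[1:] != cells[:-1], axis=1)
        chosen = cand_idx[order][keep]
        patch_nodes.append(np.sort(flat[chosen]))

    return ElectrodeLayout(
        names=ELECTRODE_NAMES,
        centers_mm=np.asarray(centers),
        patch_nodes=tuple(patch_nodes),
        node_shape=node_shape,
    )


def build_phantom(config: PhantomConfig | None = None) -> tuple[VoxelHeadModel, ElectrodeLayout]:
    """Rasterize the layered-sphere phantom and place the 19 electrodes.

    Deterministic given the config.  Returns the voxel model (with region
    masks ``target``, ``deep``, ``gray_matter``, ``white_matter``) and the
    electrode layout.
    """
    if config is None:
        config = PhantomConfig()
    config.validate()
    labels, label_names = _rasterize(config)
    model = VoxelHeadModel(
        labels=labels,
        voxel_mm=config.voxel_mm,
        conductivity=config.conductivities(),
        label_names=label_names,
    )
    model.masks = {
        "target": labels == LABELS["target"],
        "deep": (labels == LABELS["target"]) | (labels == LABELS["decoy"]),
        "gray_matter": labels == LABELS["gray_matter"],
        "white_matter": labels == LABELS["white_matter"],
    }
    if not model.masks["target"].any():
        raise ValueError("target nucleus rasterized to zero voxels; increase resolution")
    layout = _build_layout(config, labels)
    return model, layout


def perturb_config(
    config: PhantomConfig,
    seed: int,
    radii_frac: float = 0.05,
    conductivity_frac: float = 0.10,
    center_jitter_vox: float = 2.0,
) -> PhantomConfig:
    """Random per-subject perturbation of a phantom config.

    Radii are jittered by +/-``radii_frac`` (then re-sorted and separated so
    they stay strictly decreasing), tissue conductivities by
    +/-``conductivity_frac``, and the target centre by up to
    ``center_jitter_vox`` voxels per axis (clipped so the nucleus stays
    inside the white matter).  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    r = np.asarray(config.radii_mm, dtype=float)
    r = r * (1.0 + rng.uniform(-radii_frac, radii_frac, size=r.size))
    r = np.sort(r)[::-1]
    min_gap = max(0.5 * config.voxel_mm, 0.25)
    for i in range(1, r.size):  # enforce strict decrease
        r[i] = min(r[i], r[i - 1] - min_gap)
    half_extent = min(s * config.voxel_mm for s in config.shape) / 2.0
    r[0] = min(r[0], half_extent)

    jit = rng.uniform(-center_jitter_vox, center_jitter_vox, size=3) * config.voxel_mm
    tc = np.asarray(config.target_center_mm, dtype=float) + jit
    max_off = r[-1] - config.target_radius_mm - config.voxel_mm
    n = np.linalg.norm(tc)
    if n > max_off:
        tc = tc * (max_off / n)

    tissues = sorted(config.conductivities())
    factors = tuple(
        (t, float(1.0 + rng.uniform(-conductivity_frac, conductivity_frac))) for t in tissues
    )

    new = dataclasses.replace(
        config,
        radii_mm=tuple(float(x) for x in r),
        target_center_mm=tuple(float(x) for x in tc),
        conductivity_scale=factors,
        seed=int(seed),
    )
    new.validate()
    return new
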