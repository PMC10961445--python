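"""Shared fixtures: small phantoms and precomputed lead-field banks.

Heavy objects (forward-solve banks, the default-resolution subject run, the
perturbed-phantom group run) are session-scoped so the whole suite pays for
each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tesopt.leadfield import compute_lead_fields, enumerate_montages, extract_target_surface
from tesopt.optimize import _target_rows, build_design_field
from tesopt.phantom import ConductivityTable, PhantomConfig, VoxelHeadModel, build_phantom
from tesopt.pipeline import GroupSettings, PipelineConfig, run_group_pipeline, run_subject
from tesopt.spfd import InjectionPattern, assemble_system


def toy_phantom_config(**overrides) -> PhantomConfig:
    """32^3 phantom: full layer stack at reduced radii, two deep nuclei."""
    kwargs = dict(
        shape=(32, 32, 32),
        voxel_mm=1.0,
        radii_mm=(14.5, 13.5, 12.5, 11.5, 9.5),
        target_center_mm=(2.5, 2.0, 0.0),
        target_radius_mm=3.0,
        decoy_centers_mm=((-2.5, -2.0, 0.0),),
        decoy_radius_mm=3.5,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def toy_config() -> PhantomConfig:
    return toy_phantom_config()


@pytest.fixture(scope="session")
def toy_setup(toy_config):
    """Toy phantom with its assembled system and full 19-electrode bank."""
    model, layout = build_phantom(toy_config)
    system = assemble_system(model)
    bank = compute_lead_fields(model, layout, system=system)
    return {"config": toy_config, "model": model, "layout": layout, "system": system, "bank": bank}


@pytest.fixture(scope="session")
def toy_surface_dataset(toy_setup):
    from tesopt.leadfield import build_dataset

    model, bank = toy_setup["model"], toy_setup["bank"]
    montages = enumerate_montages(range(len(toy_setup["layout"])))
    surface = extract_target_surface(model, "deep")
    dataset = build_dataset(bank, montages, model, "deep", mode="surface", surface=surface)
    design = build_design_field(dataset, model.masks["target"], (0.0, 1.0, 0.0))
    vol = build_dataset(bank, montages, model, "deep", mode="volume")
    target_rows = _target_rows(bank, vol, model.masks["target"])
    return {
        "dataset": dataset,
        "design": design,
        "volume_dataset": vol,
        "target_rows": target_rows,
        "surface": surface,
    }


@pytest.fixture(scope="session")
def six_electrode_bank(toy_setup):
    """Bank over a 6-electrode sub-layout for exhaustive-search oracles."""
    model, layout, system = toy_setup["model"], toy_setup["layout"], toy_setup["system"]
    sub = layout.subset(["F3", "F4", "T7", "T8", "O1", "Cz"])
    return compute_lead_fields(model, sub, system=system)


@pytest.fixture(scope="session")
def default_run():
    """Full subject run on the default 48^3 phantom (k=2)."""
    cfg = PipelineConfig()
    return run_subject(cfg)


@pytest.fixture(scope="session")
def group_run():
    """Group pipeline over 10 perturbed toy phantoms, k=2."""
    cfg = PipelineConfig(
        phantom=toy_phantom_config(),
        group=GroupSettings(n_subjects=10, k=2, master_seed=7),
    )
    return run_group_pipeline(cfg)


def asymmetric_blob(n: int = 500, radius: float = 10.0) -> np.ndarray:
    """Star-shaped surface point cloud with no rotational or mirror
    symmetry, so affine registration onto it has a unique optimum."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    u = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    bump = 1.0 + 0.25 * u[:, 0] + 0.15 * u[:, 1] + 0.07 * u[:, 2] + 0.12 * u[:, 0] * u[:, 1]
    return radius * bump[:, None] * u


def homogeneous_box_model(n: int = 16, sigma: float = 1.0, voxel_mm: float = 1.0) -> VoxelHeadModel:
    labels = np.ones((n, n, n), dtype=np.int16)
    return VoxelHeadModel(labels, voxel_mm, ConductivityTable({"medium": sigma}), {1: "medium"})


def slab_injection(system, current_a: float = 1e-3) -> InjectionPattern:
    """Uniform current density on the x=0 face, returned on the opposite face.

    Nodal currents are weighted by each node's area share (1/4 at corners,
    1/2 on edges) so the discrete solution is the exact linear profile.
    """
    node_shape = system.node_shape
    nid = np.arange(system.n_nodes).reshape(node_shape)

    def weights(n):
        w = np.ones(n)
        w[0] = w[-1] = 0.5
        return w

    W = np.outer(weights(node_shape[1]), weights(node_shape[2])).ravel()
    cur = current_a * W / W.sum()
    return InjectionPattern(
        np.concatenate([nid[0].ravel(), nid[-1].ravel()]),
        np.concatenate([cur, -cur]),
    )
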