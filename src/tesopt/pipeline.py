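"""End-to-end pipelines tying phantom, solver, optimizer and group stages.

A single master seed fans out to per-subject seeds through
``numpy.random.SeedSequence`` so any subject's run can be reproduced in
isolation; with a fixed master seed the whole pipeline is deterministic.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .group import (
    GroupMontage,
    GroupResult,
    group_statistics,
    project_to_template,
    register_affine_icp,
    select_group_montage,
)
from .leadfield import (
    LeadFieldDataset,
    build_dataset,
    enumerate_montages,
    extract_target_surface,
)
from .optimize import (
    OptimizationResult,
    _target_rows,
    build_design_field,
    optimize_electrode_subset,
)
from .phantom import PhantomConfig, build_phantom, perturb_config
from .spfd import assemble_system
from .leadfield import compute_lead_fields

logger = logging.getLogger("tesopt")

__all__ = [
    "SolverSettings",
    "OptimizationSettings",
    "GroupSettings",
    "PipelineConfig",
    "run_individual_pipeline",
    "run_group_pipeline",
    "subject_seeds",
]


@dataclass(frozen=True)
class SolverSettings:
    tol: float = 1e-6
    max_iter: int = 20_000
    backend: str = "auto"


@dataclass(frozen=True)
class OptimizationSettings:
    k_values: tuple[int, ...] = (2,)
    mode: str = "surface"
    region: str = "deep"
    bound: float = 2.0
    cap_ma: float | None = 4.0
    cap_total: bool = False
    level: float = 0.4
    e0_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    base_current: float = 1e-3


@dataclass(frozen=True)
class GroupSettings:
    n_subjects: int = 10
    k: int = 2
    radii_frac: float = 0.05
    conductivity_frac: float = 0.10
    center_jitter_vox: float = 2.0
    master_seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    solver: SolverSettings = field(default_factory=SolverSettings)
    optimization: OptimizationSettings = field(default_factory=OptimizationSettings)
    group: GroupSettings = field(default_factory=GroupSettings)
    reference_electrode: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        if self.solver.tol <= 0:
            raise ValueError("solver tolerance must be positive")
        if any(k < 2 for k in self.optimization.k_values):
            raise ValueError("every k must be >= 2")
        if self.optimization.mode not in ("volume", "surface"):
            raise ValueError("mode must be 'volume' or 'surface'")
        if self.group.n_subjects < 1:
            raise ValueError("subject count must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        ph = raw.get("phantom", {})
        for key in ("shape", "radii_mm", "target_center_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        if "decoy_centers_mm" in ph:
            ph["decoy_centers_mm"] = tuple(tuple(c) for c in ph["decoy_centers_mm"])
        if "conductivity_scale" in ph:
            ph["conductivity_scale"] = tuple((k, v) for k, v in ph["conductivity_scale"])
        opt = raw.get("optimization", {})
        for key in ("k_values", "e0_direction"):
            if key in opt:
                opt[key] = tuple(opt[key])
        return cls(
            phantom=PhantomConfig(**ph),
            solver=SolverSettings(**raw.get("solver", {})),
            optimization=OptimizationSettings(**opt),
            group=GroupSettings(**raw.get("group", {})),
            reference_electrode=raw.get("reference_electrode", 0),
        )


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic per-subject seeds derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_subjects, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass
class SubjectRun:
    """All per-subject artifacts the group stage needs."""

    config: PhantomConfig
    model: object
    layout: object
    bank: object
    surface: object
    dataset: LeadFieldDataset  # all-montage dataset in the configured mode
    design: object
    target_rows: np.ndarray
    results: dict[int, OptimizationResult]


def _result_payload(result: OptimizationResult, layout) -> dict:
    names = layout.names
    return {
        "schema_version": 1,
        "k": result.k,
        "mode": result.mode,
        "electrodes": [names[e] for e in result.electrodes],
        "montages": [
            {"anode": names[m.anode], "cathode": names[m.cathode]}
            for m in result.montage_set
        ],
        "weights": [float(w) for w in result.weights.w],
        "currents_ma": {
            names[e]: float(c * 1e3) for e, c in result.currents.as_dict().items()
        },
        "rmse": float(result.rmse),
        "scale": float(result.scale),
        "target_mean_v_per_m": float(result.target_mean_v_per_m),
        "feasible": bool(result.feasible),
    }


def _write_weights_csv(path: Path, result: OptimizationResult, layout) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["anode", "cathode", "weight", "scaled_weight"])
        for m, w in zip(result.montage_set, result.weights.w):
            writer.writerow(
                [layout.names[m.anode], layout.names[m.cathode], f"{w:.10g}", f"{w * result.scale:.10g}"]
            )


def run_subject(
    config: PipelineConfig,
    phantom_config: PhantomConfig | None = None,
    k_values: tuple[int, ...] | None = None,
) -> SubjectRun:
    """Phantom -> lead fields -> dataset -> subset optimization for one head."""
    pc = phantom_config if phantom_config is not None else config.phantom
    opt = config.optimization
    ks = k_values if k_values is not None else opt.k_values

    model, layout = build_phantom(pc)
    system = assemble_system(model)
    bank = compute_lead_fields(
        model,
        layout,
        reference_index=config.reference_electrode,
        base_current=opt.base_current,
        tol=config.solver.tol,
        backend=config.solver.backend,
        system=system,
    )
    logger.info(
        "subject seed=%s: %d lead-field solves, max residual %.2e",
        pc.seed,
        len(layout) - 1,
        max(bank.residuals),
    )

    all_montages = enumerate_montages(range(len(layout)), base_current=opt.base_current)
    surface = extract_target_surface(model, opt.region, depth_mm=1.0)
    dataset = build_dataset(
        bank, all_montages, model, opt.region, mode=opt.mode, surface=surface
    )
    if opt.mode == "volume" and opt.region == "deep":
        vol_ds = dataset
    else:
        vol_ds = build_dataset(bank, all_montages, model, "deep", mode="volume")
    target_rows = _target_rows(bank, vol_ds, model.masks["target"])
    design = build_design_field(dataset, model.masks["target"], opt.e0_direction)

    results: dict[int, OptimizationResult] = {}
    for k in ks:
        results[k] = optimize_electrode_subset(
            bank,
            model,
            k,
            mode=opt.mode,
            region=opt.region,
            e0_direction=opt.e0_direction,
            bound=opt.bound,
            cap_ma=opt.cap_ma,
            cap_total=opt.cap_total,
            level=opt.level,
            base_current=opt.base_current,
            full_dataset=dataset,
            target_rows=target_rows,
        )
        logger.info(
            "subject seed=%s k=%d: best subset %s rmse=%.4g feasible=%s",
            pc.seed,
            k,
            results[k].electrodes,
            results[k].rmse,
            results[k].feasible,
        )
    return SubjectRun(
        config=pc,
        model=model,
        layout=layout,
        bank=bank,
        surface=surface,
        dataset=dataset,
        design=design,
        target_rows=target_rows,
        results=results,
    )


def run_individual_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> dict[int, OptimizationResult]:
    """Full single-subject pipeline; writes artifacts when ``outdir`` given."""
    config.validate()
    run = run_subject(config)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        run.model.save_nifti(out / "model.nii.gz")
        run.layout.to_json(out / "layout.json")
        run.config.to_yaml(out / "phantom_config.yaml")
        (out / "conductivity.json").write_text(json.dumps(dict(run.model.conductivity), indent=1))
        run.surface.save_ply(out / "deep_surface.ply")
        run.dataset.save(out / "dataset")
        payload = {str(k): _result_payload(r, run.layout) for k, r in run.results.items()}
        (out / "result.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        for k, r in run.results.items():
            _write_weights_csv(out / f"weights_k{k}.csv", r, run.layout)
    return run.results


@dataclass
class GroupPipelineOutput:
    template_vertices: np.ndarray
    template_target_vertex: np.ndarray  # True where the vertex belongs to the target nucleus
    maps: list
    group: GroupResult
    montage: GroupMontage
    group_montage_map: GroupResult  # group stats when all subjects share the montage
    subject_results: list[OptimizationResult]


def _surface_strengths(run: SubjectRun, w_scaled: np.ndarray, montage_idx) -> np.ndarray:
    """|E| per surface vertex for given scaled weights on dataset columns."""
    e = (run.dataset.matrix[:, montage_idx] @ w_scaled).reshape(-1, 3)
    return np.linalg.norm(e, axis=1)


def run_group_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> GroupPipelineOutput:
    """Per-subject optimization on perturbed phantoms plus group averaging.

    The template is the unperturbed base phantom's deep-region surface.
    Subject surfaces are ICP-registered to it; max-normalized field
    strengths are projected by nearest neighbour and averaged.  The group
    montage (most frequent subset, mean re-optimized ratios) is then applied
    to every subject to produce the shared-montage group map.
    """
    config.validate()
    g = config.group
    if g.n_subjects < 2:
        raise ValueError("group pipeline needs at least 2 subjects")
    opt = config.optimization

    base_model, _ = build_phantom(config.phantom)
    template = extract_target_surface(base_model, opt.region, depth_mm=1.0)
    tmpl_vertices = template.vertices_mm
    tmpl_target = base_model.masks["target"][
        tuple(
            np.clip(
                np.floor(template.samples_mm / base_model.voxel_mm).astype(np.int64),
                0,
                np.asarray(base_model.labels.shape) - 1,
            ).T
        )
    ]

    seeds = subject_seeds(g.master_seed, g.n_subjects)
    runs: list[SubjectRun] = []
    maps = []
    transforms = []
    for seed in seeds:
        pc = perturb_config(
            config.phantom,
            seed,
            radii_frac=g.radii_frac,
            conductivity_frac=g.conductivity_frac,
            center_jitter_vox=g.center_jitter_vox,
        )
        run = run_subject(config, phantom_config=pc, k_values=(g.k,))
        runs.append(run)
        result = run.results[g.k]
        col = {
            (m.anode, m.cathode): j for j, m in enumerate(run.dataset.montage_set)
        }
        idx = [col[(m.anode, m.cathode)] for m in result.montage_set]
        strengths = _surface_strengths(run, result.weights.w * result.scale, idx)
        transform = register_affine_icp(run.surface.vertices_mm, tmpl_vertices)
        transforms.append(transform)
        maps.append(
            project_to_template(
                run.surface.vertices_mm,
                strengths,
                transform,
                tmpl_vertices,
                subject=f"seed-{seed}",
            )
        )

    group = group_statistics(maps)
    results = [run.results[g.k] for run in runs]
    problems = [(run.dataset, run.design) for run in runs]
    montage = select_group_montage(results, subject_problems=problems)

    # apply the shared montage with mean ratios to every subject
    shared_maps = []
    for run, transform in zip(runs, transforms):
        col = {(m.anode, m.cathode): j for j, m in enumerate(run.dataset.montage_set)}
        ref = next(r for r in results if r.electrodes == montage.electrodes)
        idx = [col[(m.anode, m.cathode)] for m in ref.montage_set]
        strengths = _surface_strengths(run, montage.mean_ratios, idx)
        if strengths.max() <= 0:
            continue
        shared_maps.append(
            project_to_template(
                run.surface.vertices_mm, strengths, transform, tmpl_vertices
            )
        )
    shared = group_statistics(shared_maps)

    out = GroupPipelineOutput(
        template_vertices=tmpl_vertices,
        template_target_vertex=tmpl_target,
        maps=maps,
        group=group,
        montage=montage,
        group_montage_map=shared,
        subject_results=results,
    )
    if outdir is not None:
        outp = Path(outdir)
        outp.mkdir(parents=True, exist_ok=True)
        template.save_ply(outp / "template.ply")
        names = runs[0].layout.names
        summary = {
            "schema_version": 1,
            "n_subjects": g.n_subjects,
            "k": g.k,
            "group_montage": {
                "electrodes": [names[e] for e in montage.electrodes],
                "frequency": montage.frequency,
                "mean_ratios": [float(x) for x in montage.mean_ratios],
                "per_subject_ratios": montage.per_subject_ratios.tolist(),
            },
            "mean_map_mean": float(group.mean.mean()),
            "relative_sd_defined_vertices": int(np.sum(~np.isnan(group.relative_sd))),
        }
        (outp / "group_result.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        np.savez_compressed(
            outp / "group_maps.npz",
            mean=group.mean,
            relative_sd=group.relative_sd,
            shared_mean=shared.mean,
            shared_relative_sd=shared.relative_sd,
            target_vertex=tmpl_target,
        )
    return out
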