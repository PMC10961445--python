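# tesopt

Montage optimization for multichannel transcranial electrical stimulation
(mc-tES) on voxel volume conductors, with synthetic layered head phantoms
for end-to-end testing.

## The problem

Transcranial electrical stimulation injects weak currents through scalp
electrodes; the induced electric field (EF) in the brain is the physical
agent of stimulation. Targeting a *deep* brain structure (accumbens,
amygdala, putamen, ...) is hard: tissue inhomogeneity spreads the current,
and the best electrode montage differs between heads. `tesopt` implements
a fast optimization pipeline for multichannel montages:

1. **Forward model.** The head is a passive volume conductor,
   ∇·(σ∇φ) = 0. On a labeled voxel grid the scalar-potential
   finite-difference (SPFD) method places φ on voxel corner nodes and a
   conductance on every lattice edge (the mean conductivity of the voxels
   sharing the edge, times the voxel size); Kirchhoff's current law gives a
   sparse symmetric system solved to a relative residual below 10⁻⁶. The
   per-voxel EF is **E** = −∇φ from corner-edge differences, with
   magnitudes capped at the 99.9th percentile to suppress staircase
   artifacts.
2. **Lead fields.** A montage is an anode–cathode pair from 19 scalp
   electrodes at 10–20 positions (C(19,2) = 171 montages). Because the
   system is linear, one solve per electrode against a fixed reference
   (k − 1 solves) spans every montage field by superposition:
   **E**(a,c) = **L**(a) − **L**(c).
3. **Optimization dataset.** `E_dataset` stacks the three Cartesian EF
   components of every element of the deep region, one column per montage —
   either every voxel (*volume* mode) or sampling points 1 mm inside the
   region's boundary mesh (*surface* mode, an order of magnitude fewer
   elements; the element count grows as O(h⁻²) instead of O(h⁻³) as the
   resolution h is refined).
4. **Constrained least squares.** The designed field `E_designed` is a unit
   vector **e₀** on the target set T and zero elsewhere. Per-montage
   current ratios solve min‖E_dataset·w − E_designed‖₂ subject to
   |w_m| ≤ 2 (no montage may carry more than twice the 1 mA base current).
   All C(19,k) electrode subsets are searched exhaustively; after scaling
   the solution so the volume-averaged target field is 0.4 V/m (an
   estimated stimulation threshold), subsets needing more than 4 mA at any
   electrode are excluded, and the minimum-RMSE feasible subset wins, where
   RMSE = ‖E_dataset·w − E_designed‖ / √(3N).
5. **Group level.** Individual deep-region surfaces are registered to a
   template by affine iterative-closest-point, max-normalized EF strengths
   are projected by nearest neighbour, and vertexwise means and relative
   SDs summarize robustness across heads. A *group montage* — the subset
   most subjects selected, driven with mean re-optimized current ratios —
   lets one montage serve a whole cohort.

Everything runs on synthetic phantoms: concentric skin / skull / CSF /
gray / white spheres with an embedded target nucleus, a decoy nucleus, and
19 electrode patches; a perturbation generator emulates inter-subject
variability. No external data is needed.

## Worked example

```bash
python - <<'EOF'
from tesopt.pipeline import PipelineConfig
from tesopt.phantom import PhantomConfig
cfg = PipelineConfig(phantom=PhantomConfig(
    shape=(32,32,32), radii_mm=(14.5,13.5,12.5,11.5,9.5),
    target_center_mm=(2.5,2.0,0.0), target_radius_mm=3.0,
    decoy_centers_mm=((-2.5,-2.0,0.0),), decoy_radius_mm=3.5))
cfg.to_yaml('toy.yaml')
EOF
tesopt optimize --config toy.yaml --k 2 --k 3 --out run/
```

prints

```
k=2: subset (6, 11) rmse=0.18884 max|I|=0.118 mA feasible=True
k=3: subset (0, 1, 11) rmse=0.16349 max|I|=0.13 mA feasible=True
```

For k = 2 the winning montage is F8–T8 (electrode indices 6 and 11): a
single right-lateral pair best reproduces a unit anterior field in the
right-anterior target nucleus, with misfit RMSE 0.189 (in units of the
designed field, over all 3N dataset components). Adding a third electrode
(Fp1–Fp2–T8) lowers the RMSE to 0.163 — more electrodes never fit worse.
`max|I|` is the largest per-electrode current after the solution is scaled
so the volume-averaged target field is 0.4 V/m; both montages stay far
below the 4 mA safety cap, so both are feasible. `run/result.json` holds
the montages, signed per-electrode currents (mA), weights and the
normalization scale; `run/weights_k2.csv` the per-montage ratios.

Other subcommands: `tesopt phantom` (write the labeled NIfTI model and
electrode layout), `tesopt solve` (one montage's field volume),
`tesopt leadfields` (the full dataset), `tesopt group` (ensemble analysis),
`tesopt report` (summarize a result directory).

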