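# arcdmd

Dynamic conformal arc (DCA) planning for lung SBRT with **deformable margin
delineation (DMD)** — a dose-driven edit of the aperture-fitting target that
recovers near-VMAT conformity from a simple conformal arc — implemented
end-to-end on synthetic thoracic phantoms, with no commercial treatment
planning system.

## The problem

In stereotactic body radiotherapy of early-stage lung tumors, a dynamic
conformal arc shapes the MLC to the planning target volume's (PTV)
beam's-eye-view silhouette at every gantry angle of a 340° arc.  It is fast
to plan and deliver, but on non-spherical targets it is poorly conformal:
after the prescription isodose is normalized to cover 95 % of the PTV,
tissue just outside the PTV in the rotation plane receives ≥ 100 % of the
prescription ("hot" sleeves), while the cranio-caudal target tips stay
below it ("cold" spots).

The DMD method fixes this without inverse optimization.  From a
conventional DCA dose distribution it identifies

* **hot** voxels — dose ≥ Rx, outside the PTV, inside the body, and
* **cold** voxels — dose < Rx, inside the PTV,

then deforms the *aperture-fitting* target: local shrinkage next to hot
regions, local expansion next to cold regions.  The MLC is refitted to the
deformed target (PTV-DMD), dose is recomputed, and the prescription is
re-normalized to 95 % coverage of the **original** PTV — so coverage is
preserved by construction and only conformity changes.  The loop repeats
until the misdose volumes are negligible or an iteration cap, and returns
the round with the best conformity index.

Plan quality is scored with the standard SBRT index suite:

```
CI         = V_Rx / V_PTV                      (RTOG conformity index, ideal 1)
CI_Paddick = TV_PIV² / (TV · PIV)              (conformity number, ideal 1)
R50%       = V_50%Rx / V_PTV                   (gradient index)
D2cm       = max dose ≥ 2 cm from the PTV, % of Rx
HI         = (D2% − D98%) / D50%               (homogeneity)
CΔ         = (V_PI − PTV_PI) / V_PTV           (external index)
```

plus lung V20 Gy, V2.5 Gy and mean lung dose, paired Wilcoxon signed-rank
comparisons, and Spearman correlations of CΔ with CI and CI_Paddick.

Because no clinical data ship with the package, a phantom generator
produces the study conditions: elliptical body, low-density lungs, and
tumors (sphere / ellipsoid / bilobed / capped cylinder) with ITV volumes
log-uniform on 0.56–69.39 cc, PTV = ITV + 5 mm, and 3×18 / 5×11 / 8×7.5 Gy
fractionation.  Dose comes from a declared simplified engine (exact
radiological path length by Siddon ray tracing, Gaussian penumbra, FFF-like
radial profile, inverse square); see `docs/methods.md` for its assumptions
and limits.

## Worked example

```bash
arcdmd phantom --out demo/case --seed 11 --preset coarse
# case000: ITV 1.05 cc PTV 4.51 cc -> demo/case

arcdmd plan dmd --phantom demo/case --out demo/dmd --cp-spacing 10
# best iteration 5: CI 1.102 (baseline 2.156), CΔ 0.150 (baseline 1.204)
```

The first command voxelizes a random thoracic case (here a small 1.05 cc
tumor — small targets are where a conformal arc is least conformal on a
3 mm grid).  The second plans a conventional 340° DCA (the "baseline"),
then runs the deformation loop: the conventional plan puts more than twice
the PTV volume inside the prescription isodose (CI 2.16) and exposes
healthy tissue at 1.2 PTV-volumes at full dose (CΔ 1.20); five deformation
rounds shrink that to CI 1.10 and CΔ 0.15 while `iterations.csv` shows the
PTV coverage fraction pinned at 0.95 in every round.  Per-iteration
metrics, the final plan, dose grid, and the deformed target mask (NIfTI)
are written to `demo/dmd/`.

The same comparison over a whole cohort:

```bash
arcdmd cohort --n 10 --seed 42 --out results/cohort
```

writes `cohort.csv` (one row per case and arm), `summary.csv` (mean ± SD
per arm with paired Wilcoxon p-values) and `correlations.json`.  On this
synthetic cohort the deformation arm improves the mean conformity index
from ≈ 1.5 to ≈ 1.1, the conformity number from ≈ 0.62 to ≈ 0.85, and the
external index from ≈ 0.58 to ≈ 0.13 (p ≈ 0.002), with CΔ correlating
positively with CI and negatively with CI_Paddick — the behaviour the
method is designed to produce.

## Layout

```
src/arcdmd/
  phantom.py      synthetic thoracic phantoms, cohort sampler, NIfTI/YAML IO
  geometry.py     arcs, beam's-eye-view projection (exact DDA), MLC fitting
  dose_engine.py  simplified arc dose model with per-control-point caching
  planning.py     conventional DCA plans, DVH, 95 % coverage normalization
  dmd.py          hot/cold regions, morphological target deformation, DMD loop
  metrics.py      CI, CI_Paddick, R50%, D2cm, HI, CΔ, lung dose metrics
  report.py       cohort runner, exact Wilcoxon signed-rank, Spearman
  cli.py          `arcdmd` command-line interface
```
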