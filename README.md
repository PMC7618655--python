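# kneealign

Automated knee-alignment measurement for AP knee radiographs:

* **Two-stage landmark localization** — a global attention-gated hourglass
  network detects two reference points (the tibial plateau corners), which
  fix the position, orientation and scale of a similarity reference frame;
  a local hourglass then localizes the full landmark set inside that frame,
  and the results are mapped back to image coordinates.
* **Anatomical tibiofemoral angle (aTFA)** — signed varus/valgus angle
  (valgus positive) computed from named landmark subsets by two recipes:
  `FTS` (femoral + tibial shaft pair midpoints) and `FNTS` (femoral shaft
  midpoint + femoral notch midpoint for the femur).
* **Evaluation suite** — relative point-to-point / point-to-curve
  localization errors (percent of the tibial-plateau reference length) and
  method-agreement statistics: ICC(2,1) with 95% CI, mean absolute
  difference, and Bland–Altman bias ± limits of agreement.
* **Synthetic phantom generator** — radiograph-like left-knee phantoms
  with exact landmark ground truth and a configurable true aTFA, used to
  exercise the whole pipeline end to end.

The networks (hourglass with attention gates on the skip connections, wing
loss, Adam) run on a small pure-numpy reverse-mode autodiff core, so the
package trains desk-scale models on a single CPU in minutes with no deep
learning framework dependency.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which trains both stages on
200 synthetic phantoms and checks the end-to-end gates (median rP2P < 5%,
aTFA MAD < 2° on 50 held-out phantoms); the full run takes a few minutes
on one CPU.

## CLI

All commands accept `--seed` and `--log-level` and write a reproducibility
record (config snapshot + seed + version) next to their outputs.

```sh
# 1. synthesize a dataset (PNG images + PTS landmark files + manifest CSV)
kneealign synth --n 200 --seed 1 --out runs/data

# 2. train the two stages
kneealign train-global --manifest runs/data/manifest.csv --out-model runs/models/global --epochs 20
kneealign train-local  --manifest runs/data/manifest.csv --out-model runs/models/local  --epochs 28

# 3. localize landmarks (single image or batch over a manifest)
kneealign localize --manifest runs/data/manifest.csv \
    --global-model runs/models/global --local-model runs/models/local \
    --schema runs/data/schema.yaml --out runs/preds

# 4. measure the aTFA from a PTS file
kneealign measure --pts runs/preds/phantom_0000.pts --schema runs/data/schema.yaml --method both

# 5. localization + agreement report
kneealign evaluate --manifest runs/data/manifest.csv --predictions runs/preds --out runs/report
```

The end-to-end desk-scale experiment (generate, train both stages,
evaluate) is also available programmatically:

```python
from kneealign.experiment import DeskScaleConfig, run_desk_scale

result = run_desk_scale(DeskScaleConfig(seed=1), "runs/desk")
print(result.localization_table)
print(result.agreement_table)
```

## Package layout

| module | contents |
| --- | --- |
| `kneealign.geometry` | points, landmark sets/schemas, similarity-transform algebra |
| `kneealign.phantom` | synthetic left-knee phantom generator + dataset writer |
| `kneealign.nn` | autodiff core, attention-gated hourglass, heatmap encode/decode, wing loss, training loop |
| `kneealign.localizer` | global search → reference frame → local search → map back |
| `kneealign.alignment` | FTS / FNTS aTFA measurement |
| `kneealign.evaluation` | rP2P/rP2C metrics, ICC/MAD/Bland–Altman, run-level report |
| `kneealign.io` | PNG/DICOM reading, PTS dialect, schema files, manifests, laterality flip |
| `kneealign.cli` | `kneealign` command group tying the pipeline together |
| `kneealign.experiment` | desk-scale end-to-end experiment driver |

## File formats

* **PTS** — `version: 1` / `n_points: K` / `{` / K lines of `x y` / `}`.
* **Schema** — YAML mapping role names (shaft pairs, notch pair, plateau
  corners) to landmark indices.
* **Manifest** — CSV with `id, image, pts, true_atfa, laterality` columns.
* **Checkpoints** — `.npz` parameter archive + self-describing JSON sidecar.

Coordinates are 0-based pixels, origin at the top-left pixel centre,
x = column, y = row (y-down). Laterality is metadata (right knees are
mirrored to left before processing), never inferred from pixels.
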