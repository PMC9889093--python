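# clearquant

Quantifying immunostaining quality in cleared, thick tissue.

Tissue clearing lets fluorescence microscopes image hundreds of micrometres
into intact tissue, but antibody staining degrades with depth: diffusing
antibody is consumed by binding sites near the cut surface before it reaches
the core. Judging which clearing/staining protocol stains "better" by eye is
unreliable — display settings and background differences swamp real effects.
`clearquant` is an analysis pipeline for Z-stacks of antibody-stained cleared
tissue that turns each stack into objective per-depth quality metrics and
compares protocols statistically, with the analyst blinded to condition
identity. It is aimed at labs benchmarking clearing and immunohistochemistry
(IHC) protocols on thick (0.5–1 mm) sections.

## What it computes

For a stack *I(x, y, z)* and a binary segmentation mask *M* (computed
internally, or imported from an external pixel classifier such as Ilastik):

- per plane *z*: the stained-voxel fraction
  *f(z) = |M ∩ plane z| / |plane z|*, the signal
  *S(z) = mean I over M*, the noise *N(z) = mean I outside M*, and
  *SNR(z) = S/N*;
- the **normalized staining-quality score**: each per-plane value divided by
  the single maximum over all conditions sharing a fluorophore, giving a
  [0, 1] heatmap comparable across protocols;
- the **half-max depth** *z*<sub>½</sub>: the depth, measured from the
  detected tissue surface, at which the staining metric first falls to half
  of its maximum (linearly interpolated between planes) — the headline
  penetration statistic;
- per-condition replicate summaries (mean ± SEM, N = 3 by default) and
  two-tailed two-sample t-tests against a designated baseline protocol,
  labeled `*` (p < 0.05), `**` (p < 0.01) or `ns`.

Because real benchmark imagery is large and external, the package ships a
first-class synthetic generator: scenes of sphere-like (nuclei), tube-like
(vessels) or filament-like (astrocyte processes) features whose staining is
attenuated with depth by a sigmoid front, an exponential decay, or a 1D
reaction–diffusion simulation of antibody depletion
(∂c/∂t = D ∂²c/∂z² − k c (B − b), ∂b/∂t = k c (B − b)). Every rendered stack
records its true half-depth, so recovery, ranking and test calibration can be
validated end to end.

## Worked example

Simulate three protocols (true half-depths 150, 250 and 80 µm, 3 replicates
each), write them as multipage TIFFs with a manifest, and run the full
pipeline:

```python
import yaml
from pathlib import Path
import clearquant as cq
from clearquant.io import run_pipeline

cfg = {
    "scene": {"shape": [32, 32, 100]},     # 100 planes x 5 um = 500 um deep
    "replicates": 3,
    "conditions": [
        {"label": "baseline", "baseline": True,
         "attenuation": {"kind": "sigmoid", "d_half_um": 150.0}},
        {"label": "long-incubation",
         "attenuation": {"kind": "sigmoid", "d_half_um": 250.0}},
        {"label": "harsh-delipidation",
         "attenuation": {"kind": "sigmoid", "d_half_um": 80.0}},
    ],
}
out = Path("demo_out"); out.mkdir(exist_ok=True)
entries = []
for s in cq.generate_condition_set(cfg, seed=1):
    p = out / f"{s.condition_id}_{s.replicate_id}.tif"
    cq.write_stack(s.stack, p)
    entries.append({"path": str(p), "condition_id": s.condition_id,
                    "replicate_id": s.replicate_id, "plane_spacing_um": 5.0,
                    "baseline": s.condition_id == "baseline"})
(out / "manifest.yaml").write_text(yaml.safe_dump({"samples": entries}))

report = run_pipeline(cq.load_manifest(out / "manifest.yaml"), out / "results")
print(report["summary"].to_string(index=False))
```

Output:

```
fluorophore_group          condition  baseline  n    mean_um   sem_um           t  df  p_vs_baseline label
              ch0           baseline      True  3 150.822185 0.073202         NaN NaN            NaN
              ch0    long-incubation     False  3 250.926036 0.070123  987.509709 4.0   6.309323e-12    **
              ch0 harsh-delipidation     False  3  81.068770 0.034785 -860.656318 4.0   1.093524e-11    **
```

Each condition's mean half-max depth lands within ~1 µm of its true
penetration depth; the longer-incubation protocol penetrates significantly
deeper than baseline and the harsh protocol significantly shallower. The run
directory also contains per-sample depth-profile CSVs
(`depth_um, fraction, signal, noise, snr`), a per-fluorophore normalized
heatmap matrix, and `run_log.json` recording every default applied.

The same steps are available from the shell:

```bash
clearquant simulate --config sim.yaml --out demo_out --seed 1
clearquant run-all --manifest demo_out/manifest.yaml --out demo_out/results
clearquant segment --in stack.tif --method otsu --out mask.tif
clearquant blind --manifest demo_out/manifest.yaml --seed 3 --out codes.csv
```

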