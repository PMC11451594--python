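# nucleomech

Quantitative analysis of the **nuclear mechanophenotype** in cultured
cells — the coupled changes in nuclear envelope tension, nuclear
geometry, nucleoplasmic rheology, stiffness, condensate formation and
chromatin occupancy that accompany cell-state transitions in pluripotent
stem cells.

The package implements six measurement pipelines that are usually
scattered across ImageJ macros, instrument software and ad-hoc scripts,
plus a synthetic-data generator that produces every input modality with
exactly known ground truth, so each pipeline is validated end-to-end by
parameter recovery:

| Module | Measures | Core statistic |
| --- | --- | --- |
| `fluctuations` | envelope tautness from fast time-lapse movies | sd of envelope position about its temporal mean, per normal, after bleach + rotational-drift correction |
| `morphometry` | 3D nuclear geometry from label masks | volume, z-height, marching-cubes surface area, surface/volume |
| `rheology` | nucleoplasm crowding from nanoparticle (GEM) tracks | aggregate time-averaged MSD; fit MSD = 4·D_eff·t^b |
| `condensates` | condensate formation and localization | cluster:nucleus mean-intensity enrichment; DNA-at-cluster; erosion-ring peripheral profile; N/C ratio |
| `afm` | apparent Young's modulus from force-indentation | baseline / contact point / bending correction; Hertz (sphere) or Sneddon–Bilodeau (pyramid) fit, ν = 0.5, δ ≤ 500 nm |
| `genomics` | occupancy redistribution between conditions | reproducibility/size/signal filters, 1-kb merging, blacklist, TSS±1 kb classes, log2 reference scaling, Ward clustering (cutoff 7) |
| `simulate` | all of the above, with ground truth | OU envelope movies, exact fBm tracks, exact-enrichment condensate images, digitized ellipsoids, implicit-contact force curves, planted peak tables |

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

Simulate a fluctuating-envelope movie with a known stationary amplitude
of 0.1 μm and recover it through the full pipeline:

```python
from nucleomech import SimConfig
from nucleomech.simulate import gen_boundary_movie
from nucleomech.fluctuations import NucleusMovie, quantify_nucleus

cfg = SimConfig(seed=1, frame_interval=0.15)   # 150 ms/frame
movie, truth = gen_boundary_movie(cfg, n_angles=16, n_frames=2000,
                                  sigma=0.1, tau=1.0)
res = quantify_nucleus(NucleusMovie(movie, 0.15, 0.1), n_normals=8)
print(f"recovered amplitude: {res.nucleus_mean_std:.4f} um")
```

```
recovered amplitude: 0.1012 um
```

The estimate sits within ~1% of the 0.1 μm ground truth: the standard
deviation of the envelope position about its mean, averaged over eight
automatically placed normals, recovers the stationary amplitude of the
underlying Ornstein–Uhlenbeck boundary process.

The same round-trip pattern works from the shell:

```bash
nucleomech simulate tracks --out data/ --seed 42
nucleomech gems --tracks data/tracks.csv --out gems/
# -> D_eff=0.5141 um^2/s^b, b=1.020     (truth: D=0.5, b=1)
```

Subcommands: `simulate`, `fluctuations`, `morpho`, `gems`,
`condensates`, `afm`, `peaks` (see `nucleomech <cmd> --help`).

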