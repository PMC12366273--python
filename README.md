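# gradientchip

Design and quantification tools for counter-current growth-factor gradients
in microfluidic hydrogel co-culture chips — the kind of device that grows
vascularised adipose tissue by feeding vasculogenic media from one end of a
hydrogel culture compartment and adipogenic media from the other.

The package answers two questions for such a chip:

1. **How far does each media supplement actually act?**  Each growth factor
   is modelled in the 2D culture compartment by diffusion with first-order
   half-life decay,

   &nbsp;&nbsp;&nbsp;&nbsp;∂C/∂t = D (∂²C/∂x² + ∂²C/∂y²) + kC,&nbsp;&nbsp;
   k = ln(½)/t_½ < 0,

   with the media channels as Dirichlet boundary segments whose
   concentration itself decays between media exchanges (media sits in the
   channels for 2–3 days).  A region is called *bioactive* for a factor when
   C ≥ EC50, and the design metrics report the bioactive area fraction, the
   maximum bioactive distance from the fed end, its timing, and the
   *limiting factor* of each medium — the supplement whose reach is
   shortest.

2. **What do the resulting cultures look like, quantitatively?**  Skeleton
   morphometry of fluorescent vessel networks (junction and endpoint
   counts, total length with corrected chain weights, total area, diameter
   from the distance transform) and lipid coverage of brightfield images
   (dark-band threshold, whole field / length-thirds / 370 µm bins), with
   time-lapse subsampling support.

Because real micrographs of these cultures are rarely shareable, a
synthetic-data module generates ground-truthed vessel networks, lipid
droplet images and rise–decline–plateau time-lapse stacks so that every
analysis stage is testable end to end.

## Worked example

```python
import gradientchip as gc

analysis = gc.run_distribution_analysis()   # 2-day single-loading run
print(analysis.to_table().to_string(index=False))
print(analysis.limiting)
```

prints (distances in mm from each factor's fed end, times in hours):

```
 factor fed_end  ec50_ng_ml  max_distance_mm  time_of_max_h
  FGF-a    left        0.30             3.85           2.00
    EGF    left        0.10             4.85          14.50
  FGF-b    left        0.10             7.90           8.00
  IGF-1    left        5.00             2.65           0.50
   VEGF    left        1.70             2.90           0.50
    DEX   right        1.90             4.40          13.50
insulin   right       33.70             7.90           4.00

{'stromal': 'FGF-a', 'vascular': 'IGF-1', 'adipogenic_initiation': 'DEX', ...}
```

Reading this: IGF-1 (24 min half-life) barely reaches past its own 2.6 mm
feeding channel before decaying below its EC50, so it confines vasculogenic
stimulation to one end of the chip; FGF-β and insulin stay bioactive over
the whole 7.9 mm compartment.  IGF-1, FGF-α and DEX are the limiting
factors of the vascular, stromal and adipogenic media.

The `examples/` directory has one short script per capability (reservoir
decay and feeding schedules, the distribution design run, vessel
morphometry, lipid coverage, time-lapse trend recovery); each prints the
numbers it computes and a line on what they mean.  A thin CLI wraps the
same functions:

```bash
gradientchip design-report -o out/           # distribution table + profiles
gradientchip simulate -o out/ --duration-days 31
gradientchip vessel-metrics images/ -o metrics.csv --pixel-size 4
gradientchip lipid-coverage image.png -o coverage.csv
gradientchip synth network -o data/ --seed 1
```

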