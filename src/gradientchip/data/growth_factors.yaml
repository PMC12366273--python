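# Default growth-factor transport/decay/potency parameters and media
# compositions for the gradient chip model.
#
# Units: supplemented_conc, ec50 in ng/mL; molecular_weight in g/mol;
# diffusivity in um^2/s; half_life in s.
factors:
  FGF-a:
    supplemented_conc: 5.0
    molecular_weight: 15800.0
    diffusivity: 100.0
    half_life: 4320.0
    ec50: 0.3
    group: stromal
  EGF:
    supplemented_conc: 5.0
    molecular_weight: 6400.0
    diffusivity: 21.0
    half_life: 25200.0
    ec50: 0.1
    group: stromal
  FGF-b:
    supplemented_conc: 5.0
    molecular_weight: 17100.0
    diffusivity: 92.0
    half_life: 90000.0
    ec50: 0.1
    group: stromal
  IGF-1:
    supplemented_conc: 15.0
    molecular_weight: 7600.0
    diffusivity: 159.0
    half_life: 1440.0
    ec50: 5.0
    group: vascular
  VEGF:
    supplemented_conc: 5.0
    molecular_weight: 38200.0
    diffusivity: 200.0
    half_life: 3600.0
    ec50: 1.7
    group: vascular
  DEX:
    supplemented_conc: 392.0
    molecular_weight: 392.0
    diffusivity: 10.8
    half_life: 16200.0
    ec50: 1.9
    group: adipogenic
  insulin:
    supplemented_conc: 1000.0
    molecular_weight: 5808.0
    diffusivity: 200.0
    half_life: 108000.0
    ec50: 33.7
    group: adipogenic

# EGF and FGF-b are supplemented in both the stromal (MSC) and vascular (EC)
# media. The adipogenic initiation/maturation compositions are proprietary and
# approximated by their two identifiable modelled factors (IBMX has no
# published transport/decay parameters and is not modelled).
media:
  stromal:
    FGF-a: 5.0
    EGF: 5.0
    FGF-b: 5.0
  vascular:
    IGF-1: 15.0
    VEGF: 5.0
    EGF: 5.0
    FGF-b: 5.0
  adipogenic_initiation:
    DEX: 392.0
    insulin: 1000.0
  adipogenic_maturation:
    DEX: 392.0
    insulin: 1000.0
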