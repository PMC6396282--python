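# melanocycle

Kinetic simulation of the melanopsin photocycle and quantification of
intrinsically photosensitive retinal ganglion cell (ipRGC) light responses.

ipRGCs signal ambient light continuously for minutes to hours, which
requires their photopigment melanopsin to be deactivated and regenerated in
an ongoing cycle. Two adaptor proteins divide that labor: β-arrestin 2
terminates signaling of the light-activated, phosphorylated receptor, and
β-arrestin 1 primes the deactivated receptor for chromophore exchange back
to the dark state. `melanocycle` is for researchers who want to explore the
consequences of that division quantitatively: it simulates populations of
ipRGCs with genotype-resolved photocycle kinetics (wild type, single-
arrestin knockouts, phosphosite mutants, C-terminal truncation, arrestin
overexpression, 11-*cis*-retinal supplementation) down to spike trains, raw
multielectrode-array-like voltage traces, pupil traces and pup locomotion
tracks — and it implements the matching analysis pipeline: robust-SD spike
detection, peristimulus response metrics with a 2-SD onset criterion,
light-response adaptation maps (LRAMs), adaptation-rate statistics, subtype
clustering, negative-phototaxis and pupillometry quantification.

## The model

Total pigment is tracked across five pools,

    dark --σ·Φ(t)--> active --k_phos--> phospho_active
    phospho_active --k_d2eff--> arr_bound --k_r1eff--> dark
    active, phospho_active --k_spont--> spent --k_turnover--> dark

with effective rates resolved per genotype:

    k_d2eff = (k_deact2·arr2 + k_deact_cross·arr1)·binding_scale·deact_accel
    k_r1eff =  k_regen1·arr1 + k_regen_cross·arr2 + retinal_supply_rate

Firing follows `r(t) = r_base + r_max·Hill(lowpass(D) − θ)` with drive
`D = gain·(active + ε·phospho_active)`, and spikes are drawn by Poisson
thinning with an absolute refractory period. See `docs/methods.md` for the
full account, including the default calibration and its limitations.

## Worked example

Simulate 30 wild-type and 30 β-arrestin-2-knockout cells under the standard
repetition protocol (0.1/1/10/60-s pulses of 480-nm light at
5×10¹² photons cm⁻² s⁻¹, five repetitions each, 3-min dark gaps), then
quantify the 60-s responses:

```python
import numpy as np
import melanocycle as mc
from melanocycle.metrics import response_table
from melanocycle.adaptation import adaptation_rate

proto = mc.protocol_repetition()
for name in ["WT", "barr2_ko"]:
    res = mc.simulate_population(proto, genotype=mc.genotype(name),
                                 pop=mc.PopulationConfig(n_cells=30, seed=42))
    tab = response_table(res.trains, proto)
    t60 = tab[np.isclose(tab.stimulus_duration_s, 60.0)]
    st = adaptation_rate(tab)
    print(f"{name}: latency {t60.latency_s.mean():.2f} s, "
          f"post-OFF {t60.post_off_duration_s.mean():.1f} s, "
          f"slope {st.mean_slope:.2f} ± {st.sem_slope:.2f} s/rep "
          f"(p={st.p_slope_vs_zero:.2g})")
```

```
WT: latency 1.84 s, post-OFF 2.7 s, slope -0.33 ± 0.24 s/rep (p=0.18)
barr2_ko: latency 1.70 s, post-OFF 47.5 s, slope -0.13 ± 0.20 s/rep (p=0.52)
```

The knockout responds slightly faster (less pigment is pulled out of the
signaling states while the response builds), persists ~45 s beyond light
OFF instead of ~3 s (deactivation is left to the weak cross-pathway), and —
like the wild type — shows no significant rundown across five repetitions
of the same stimulus, because β-arrestin-1-mediated regeneration restores
the dark pool during the 3-min gaps. Repeating this with `barr1_ko` shows
the converse phenotype: normal first responses, then a steep negative
adaptation slope as unregenerated pigment accumulates.

The same stages are available from the shell:

```bash
melanocycle simulate --protocol protocol_repetition --cells 30 --seed 42 --out sim.h5
melanocycle detect   --in raw.csv --out spikes.csv
melanocycle metrics  --spikes spikes.csv --protocol protocol_repetition --out metrics.csv
melanocycle lram     --metrics metrics.csv --out lram.csv --plot lram.png
melanocycle pipeline --config cfg.json --seed 42 --out run1/
```

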