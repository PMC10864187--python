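# thermalplex

Design and analysis toolkit for **temperature-multiplexed DNA probe
imaging** ("thermal-plex"): fluidic-free sequential fluorescence imaging
in which each target is assigned a *thermal channel* — a designed
temperature window in which exactly one probe set fluoresces after a
brief on-scope heating spike.

It is written for two audiences: probe designers, who need to pick
barcode/quencher melting temperatures, generate orthogonal domain
sequences, and verify that a channel panel has high yield and low
crosstalk before ordering oligos; and imaging analysts, who need to turn
the resulting multi-round spot images into per-cell count matrices and
covariation statistics.

## The model

A thermal probe set couples a fluorophore-carrying **imager** strand to a
target-bound **barcode** domain (duplex melting temperature *T*<sub>mb</sub>)
and prehybridizes a **quencher** strand to the imager
(*T*<sub>mq</sub> < *T*<sub>mb</sub>). Each duplex is a two-state system
with nearest-neighbor thermodynamics (ΔH, ΔS from the unified NN table,
or back-derived from a stated Tm), bound under the free-ligand convention

θ(T) = cK(T) / (1 + cK(T)),  K(T) = exp(−(ΔH − TΔS)/(RT)),
T<sub>m</sub> = ΔH / (ΔS + R ln c)

Fluorescence requires the imager bound and the quencher gone, so the
**thermal spectrum** is

signal(T) = θ<sub>barcode</sub>(T) · (1 − θ<sub>quencher</sub>(T))

summarized by the signal temperature *T*<sub>s</sub> (argmax), yield
(maximum) and width *W* (FWHM). Channel panels are selected on the
(*T*<sub>mb</sub>, *T*<sub>mq</sub>) design plane under yield ≥ 0.8 and
pairwise spike-crosstalk ≤ 0.12 with the lowest channel above the 37 °C
wash floor. Melt-off/rebinding kinetics follow
dθ/dt = k<sub>on</sub>c(1−θ) − k<sub>off</sub>(T(t))θ with
k<sub>off</sub> = k<sub>on</sub>/K(T). Image quantification follows
standard smFISH practice (max Z-projection, threshold + 8-connected
components, greedy one-to-one colocalization, per-cell counts on label
masks), and covariation analysis clusters targets on the Pearson
correlation distance 1 − r with average linkage.

## Worked example

```python
from thermalplex import ThermalProbeSet, thermal_spectrum

probe = ThermalProbeSet.from_tms("apc", tmb_C=61.0, tmq_C=53.0)
spec = thermal_spectrum(probe)
print(f"Ts = {spec.ts_C:.1f} C, yield = {spec.signal_yield:.3f}, "
      f"W = {spec.width_C:.1f} C")
```

prints

```
Ts = 57.2 C, yield = 0.910, W = 8.5 C
```

i.e. a probe whose quencher melts at 53 °C and whose barcode melts at
61 °C fluoresces maximally after a spike to about 57 °C, recovering 91%
of the unquenched signal over an 8.5 °C-wide window. Designing a full
panel from the shell:

```sh
thermalplex design --out design_out/        # greedy channel selection
thermalplex scan --out scan_out/            # yield/Ts/width heatmaps
```

The greedy floor-up search over the default 40–80 °C × 35–75 °C grid
returns six channels at 37.6/44.1/50.7/57.1/64.1/71.6 °C, covering the
five printed design temperatures 39/48/57/65/72 °C within 3 °C each.

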