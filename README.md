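# coromix

Mixing assessment of coronary infusion catheters for continuous-infusion
thermodilution.

Continuous-infusion thermodilution estimates absolute coronary blood flow
and microvascular resistance from the steady temperature of
room-temperature saline infused continuously into a coronary artery
through a microcatheter.  The measurement is only valid if saline and
blood mix completely within the first centimetres downstream of the
catheter tip.  `coromix` quantifies that mixing and compares two catheter
topologies in an idealized 4 mm × 70 mm coronary segment:

* **side-hole** — a monorail infusion catheter with four ~100 µm side
  holes and the 0.36 mm pressure/temperature wire inside its lumen;
* **end-hole** — a conventional microcatheter with a single end hole and
  the wire alongside.

The package is aimed at interventional-physiology and biomedical
engineering groups who need a reproducible, scriptable version of the
assessment: a desk-scale pulsatile scalar-transport simulator standing in
for full 3D CFD, the cross-section mixing statistics, the pullback
deviation analysis, and the projectional pass/fail classifier.

## The quantities

With blood at temperature `Tb` entering at flow `Qb` and infusate at `Ti`
injected at rate `Qi`, perfect mixing gives the dilution fraction and
mixed-cup temperature

    P* = Qi / (Qb + Qi),        Tmix = Tb − P* (Tb − Ti).

At a cross-section distal of the injection site, with time-averaged
temperatures `T_m,k` at `n` sample points spread uniformly by area
(points at the wire excluded):

* **SD_t** = sqrt( Σ_k (T_m,k − T̄)² / n ) — 0 means the section is
  thermally uniform;
* dilution probability **P** = (Tb − T)/(Tb − Ti) per point;
* entropy ratio **E** = [ (1/n) Σ_k (−P_k ln P_k) ] / (−P* ln P*) — a
  Shannon-entropy homogeneity index equal to 1 when every point sits at
  the perfect-mixing fraction, not calculable when no infusate has
  reached the section (all P_k = 0).

Along the vessel, a sensor pullback from 6 cm distal back to the tip is
smoothed (2 s rolling mean), normalized to N = 1000 points, expressed as
the percentage deviation from the pullback-mean temperature
(ΔT_rel,i = (T_i − T̄)/T̄ · 100%), and summarized by the percentage of
points deviating more than 15% and 20%.  Finally, a projected
(line-of-sight averaged) dilution image is classified PASS/FAIL by the
coefficient of variation across the diameter within 1–3 cm of the tip —
an operational version of the visual ink-cloud criterion.

## Worked example

```python
import coromix as cm

protocols = [p for p in cm.cfd_combinations() if p.coronary_flow_mean == 150]
for p in protocols:
    field = cm.simulate(p, resolution=cm.COARSE)
    for station in (1.2, 4.4):
        m = cm.station_measures(field, station)
        e = f"{m.entropy_ratio:.3f}" if m.calculable else "NA"
        print(f"{p.catheter.value:9s} {station:.1f} cm  "
              f"SD_t={m.sd_t:.3f} C  E={e}  (n={m.n_used})")
```

prints

```
SIDE_HOLE 1.2 cm  SD_t=0.006 C  E=1.067  (n=112)
SIDE_HOLE 4.4 cm  SD_t=0.002 C  E=0.982  (n=112)
END_HOLE  1.2 cm  SD_t=0.968 C  E=0.545  (n=124)
END_HOLE  4.4 cm  SD_t=0.790 C  E=0.512  (n=124)
```

For the medium-flow protocol (150 mL/min coronary flow, 15 mL/min
infusion) the side-hole catheter is already near-homogeneous 1.2 cm past
the injection site (SD_t ≈ 0.01 °C, E ≈ 1), while the end-hole catheter
leaves an unmixed cold core: cross-section spreads two orders of
magnitude larger and an entropy ratio far below 1 even at 4.4 cm.  `n` is
the number of unmasked sample points (the wire footprint differs between
the geometries).

The same comparison from a shell, with all artifacts (CSV tables,
deviation profiles, verdicts, provenance metadata) written to a
directory:

```
coromix report --combo MED:15 --outdir out/
coromix pullback --trace-csv my_recording.csv     # analyze a recorded trace
```

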