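# vectornav

Route simulation for vector-navigating migratory birds, plus the
circular-statistics toolkit used to analyse orientation-cage (Emlen
funnel) experiments.

A bird that reaches its wintering grounds by flying an inherited compass
course — *vector navigation* — traces a route whose shape depends on the
compass it consults.  `vectornav` simulates four mechanisms from a
common departure point on a spherical Earth:

* **geographic loxodrome** — constant true heading (rhumb line);
* **magnetic loxodrome** — constant course relative to magnetic north,
  so the track bends with the declination field;
* **time-compensated sun compass with the clock fixed at departure** —
  heading offset from the sun azimuth evaluated at the departure-site
  sunset instant; approximates the great circle (orthodrome);
* **magnetoclinic compass** — the course keeps the *apparent* magnetic
  inclination γ′ constant, tan γ′ = tan γ / cos β, with γ the local dip
  and β the course relative to the magnetic meridian; includes the
  two-phase variant that first follows the isocline (constant-dip
  contour) to a switch point.

The geomagnetic field comes from a vendored reference-field coefficient
table (definitive epochs 2005-2010, degree 13); the solar ephemeris is a
standard low-precision almanac algorithm.  The statistics module
implements the mean vector (α, r), Rayleigh test, 95% confidence arcs,
Watson's two-sample U², Mardia's one-way classification (F) and
concentration-homogeneity tests, chi-square contingency tests, and von
Mises utilities (κ = A⁻¹(r)); the cage pipeline applies the study's
inclusion rule (activity and concentration scores ≥ 1, sum ≥ 3), one
bearing per bird per diagram, and every reported group and pairwise
comparison.  A synthetic-data generator emulates cage records with the
published group parameters so the whole pipeline is testable without any
data download.

The default departure point is the Kanaryarmiut Field Station in the
Yukon-Kuskokwim Delta, SW Alaska (61°21′ N, 165°08′ W), where dunlins
(*Calidris alpina*) of two races stage in autumn before crossing to the
Pacific Northwest or to East Asia.  See `docs/methods.md` for the models
and their assumptions.

## Worked example

```python
from datetime import date
from vectornav import (STUDY_SITE, GeoPosition, FieldModelConfig, field_at,
                       isocline_heading, rhumb_course, solve_initial_direction,
                       rayleigh_test)

field = FieldModelConfig()
fv = field_at(STUDY_SITE, 2005.67, field)
print(f"declination {fv.declination:.1f} deg E, inclination {fv.inclination:.1f} deg")
print(f"rhumb to southern Japan: {rhumb_course(STUDY_SITE, GeoPosition(31.0, 130.5)):.0f} deg")
print(f"magnetoclinic NW departure: {isocline_heading(STUDY_SITE, 2005.67, 'NW', field):.0f} deg")
sun = solve_initial_direction("sun_compass", STUDY_SITE, date(2005, 9, 1),
                              GeoPosition(31.0, 130.5), field)
print(f"sun-compass departure to southern Japan: {sun:.0f} deg")
res = rayleigh_test(16, 0.61)
print(f"adult group Rayleigh: Z = {res.statistic:.2f}, p = {res.p_value:.4f}")
```

prints

```
declination 13.2 deg E, inclination 72.3 deg
rhumb to southern Japan: 235 deg
magnetoclinic NW departure: 284 deg
sun-compass departure to southern Japan: 262 deg
adult group Rayleigh: Z = 5.95, p = 0.0016
```

Reading this: at the study site the field dips steeply (72.3°) and
points 13.2° east of true north.  A bird bound for southern Japan holds
235° under a star/geographic compass, 262° under a clock-fixed sun
compass (the orthodrome bends poleward of the rhumb), while a
magnetoclinic bird can only leave along the local isocline — toward the
north-west (284°) for the East-Asian route.  The Rayleigh test confirms
the adult cage sample (n = 16, r = 0.61) is strongly directed
(p < 0.002).

The same operations are available from a CLI, e.g.

```sh
vectornav simulate-route --mechanism magnetoclinic --branch SE \
    --switch-lon -158 --onward 150 --out route      # GeoJSON + CSV
vectornav synthesize --seed 1 --out records.csv
vectornav analyze-cage --input records.csv --out results
```

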