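# tavisim

A desk-scale simulator of **transcatheter aortic valve implantation (TAVI)**
for computational cardiovascular biomechanics: it deploys parameterised
stent frames into synthetic, patient-like aortic roots with an explicit
quasi-static finite-element scheme and computes the three outcome
predictors used to compare such simulations against clinical imaging —

* the **projected stent diameter** at the valve level (what fluoroscopy
  measures; deployed frames are not circular, so the x-ray view matters),
* **paravalvular-leak (PVL) channels**: gaps between device and
  implantation site that are continuous along the device's sealing range
  (the full frame for balloon-expandable devices, the proximal 12 mm skirt
  for self-expandable ones), located by aortic sinus (NCC/RCC/LCC),
* regional **maximum principal strain** of the root below the coronary
  ostia — highest in the NCC–RCC sector where the left bundle branch runs —
  as a proxy for conduction-disturbance (pacemaker) risk.

It is aimed at researchers prototyping TAVI outcome metrics, device
parameter studies, and teaching: everything runs on a laptop in minutes per
case, from one config file, with no patient data.  The package also ships
the printed per-patient outcome tables of a published 28-patient
retrospective cohort (14 balloon-expandable, 14 self-expandable cases) as
plain-text fixtures and recomputes their summary statistics.

## What is inside

| module | content |
| --- | --- |
| `tavisim.anatomy` | parametric aortic root: LVOT, annulus (z = 0), three-lobed Valsalva sinuses, ascending aorta, native leaflets, calcific deposits with exact volume targeting |
| `tavisim.devices` | diamond-cell beam-lattice frames: balloon-expandable 23/26/29 mm (elastoplastic Co-Cr), self-expandable 26/29 mm (superelastic Nitinol, hourglass profile, 12 mm skirt) |
| `tavisim.materials` | linear-elastic tissue cards, radial-return elastoplasticity, and a flag-shaped 1-D superelastic law with full strain recovery |
| `tavisim.solver` | explicit quasi-static dynamics: corotational beams with fiber-integrated constitutive updates, CST membranes, penalty contact, KE/strain-energy quasi-static gate |
| `tavisim.protocols` | crimping, balloon valvuloplasty, positioning rules (1/3-below-annulus, ≤ 6 mm depth), balloon expansion, sheath release |
| `tavisim.metrics` | projected diameter, cylindrical gap map + leak-channel detection, Green–Lagrange strain report |
| `tavisim.cohort` | cohort outcome tables and their summary statistics |
| `tavisim.config` / `tavisim.cli` | one-file run configuration, `tavisim` command-line tool, VTK/STL I/O |

The model is documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Crimp a 26 mm self-expandable frame to its 6 mm delivery diameter, release
it inside a calcified synthetic root, and read off the three predictors:

```python
from tavisim.anatomy import AnatomyParams, build_anatomy
from tavisim.devices import build_self_expandable
from tavisim.protocols import Procedure, ProtocolParams
from tavisim.solver import SolverSettings

root = build_anatomy(AnatomyParams(
    annulus_diameter=24.5, n_theta=28, axial_spacing=2.2,
    calcium_volume=726.0,        # cohort-average calcific load, mm^3
    calcium_leaflets=(1,),       # one bulky nodule on the RCC leaflet
    seed=2,
))
proc = Procedure(
    build_self_expandable(26), anatomy=root,
    params=ProtocolParams(run_bav=False,
                          stage_durations={"crimp": 0.5, "release": 1.2}),
    with_balloon=False,
    settings=SolverSettings(mass_scaling_factor=1e6, damping=10.0),
)
proc.crimp()                 # rigid coaxial cylinder down to 6 mm
proc.position_stent()        # skirt 4 mm below the annulus plane
proc.release_sheath()        # 80 mm pull-back, inflow expands first
res = proc.result()

print(round(res.projected_diameter(), 1), "mm")   # 19.9 mm
pvl = res.pvl_report()
print(pvl.present, sorted(pvl.sinuses()))          # True ['NCC', 'RCC']
sr = res.strain_report()
print(round(sr.average_below_ostia, 2), "%")      # 1.05 %
```

The projected diameter (~20 mm for a 26 mm device in a stenotic root) falls
in the fluoroscopic range the cohort tables report for that size; the
undersized deployment leaks — the gap field is strongest in the RCC sector,
where the calcific nodule keeps the leaflet tented off the frame — and the
sub-coronary strain average is the conduction-risk statistic.  Releasing
the same frame in a smaller (23.5 mm annulus) root seals the skirt and
reports no PVL.

The same case runs from the shell:

```bash
tavisim run --config case.yaml --seed 2 --out results/case1
tavisim cohort          # printed cohort statistics, recomputed
```

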