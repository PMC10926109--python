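# twomass — vocal fold vertical mobility and source–filter interaction

`twomass` is a lumped-element voice-production toolkit built around one
question: how does the ability of the vocal folds to move **vertically**
(in the superior–inferior direction) change their coupling to the
acoustic resonances of the airways?

Each vocal fold is modeled as two masses (a heavier lower body
m₁ = 0.17 g and a lighter upper cover m₂ = 0.03 g) suspended on 2-D
spring–damper elements, so each mass moves both medially–laterally (y)
and vertically (x):

    m_i r̈_i + η_i ∘ ṙ_i + k_i ∘ r_i + k_c (r_i − r_j) = F_i ,   i,j ∈ {1,2}

with element-wise products `∘`, horizontal stiffnesses k₁y = 150 N/m and
k₂y = 40 N/m, coupling spring k_c = 20 N/m, and damping
η_i = ζ_i · 2√(m_i k_i) (ζ₁ = 0.1, ζ₂ = 0.6). The single control knob is
the **vertical-to-horizontal stiffness ratio**

    Q = k_ix / k_iy ,

which stiffens the vertical springs while leaving the horizontal
dynamics untouched: raising Q progressively restrains vertical motion.

Around this mechanical core the package provides:

- **eigenmodes** — the in-vacuo generalized eigenproblem of the 4-DOF
  system, its frequency table over Q, and the horizontal/vertical mode
  labeling (the lowest vertical mode crosses the second horizontal mode
  between Q = 2 and Q = 3);
- **glottal geometry** — the medial surface built from two cylinders
  joined by their common tangent, closed at rest at both mass levels;
- **glottal flow** — quasi-steady Bernoulli flow with separation at the
  minimum glottal area, and pressure-force integration over the surface
  (the per-mass vertical force components are the entrainment
  diagnostic);
- **tract acoustics** — Kelly–Lochbaum transmission lines for the
  150 mm subglottal and 175 mm supraglottal ducts, a constant-pressure
  inlet chamber, an open-end radiation load, and monopole far-field
  sampling at 160 mm;
- **simulator** — the coupled fixed-step loop (flow solved against the
  instantaneous acoustic load of both lines, so the tract feeds back on
  the source) driven by a 2000 Pa lung pressure, plus Q sweeps;
- **analysis** — F0, SPL, Welch spectra, a subharmonic index, best
  rational p:q lock between F0 and a resonance, and Poincaré-section
  regime classification (limit cycle vs torus/subharmonic).

The coupled flow model is a deliberately reduced-order surrogate for
full 3-D compressible flow simulation — see `docs/methods.md` for what
it does and does not capture.

## Worked example

The eigenfrequency table over the standard Q sweep:

```sh
$ twomass modes
Q     1.5    2.0    3.0    5.0    7.0    10.0   15.0    100.0
mode
1     153.2  153.2  153.2  153.2  153.2  153.2  153.2   153.2
2     187.0  215.3  229.2  229.2  229.2  229.2  229.2   229.2
3     229.2  229.2  262.7  337.7  398.6  475.5  581.3  1496.0
4     262.9  292.8  345.3  431.8  503.8  595.8  723.7   1842.4
```

Modes 1 and 2 at high Q are purely horizontal (they never move with Q);
the two vertical modes stiffen as √Q and overtake the second horizontal
mode between Q = 2 and Q = 3.

A coupled simulation and its re-analysis:

```sh
$ twomass run --out demo.csv --duration 0.45 --transient-discard 0.1 --Q 2 --wav demo.wav
running: Q = 2.0, p_lung = 2000.0 Pa, duration = 0.45 s, dt = 2.5e-05 s
wrote demo.csv (14000 samples)
wrote demo.wav

$ twomass analyze demo.csv
     f0_hz    spl_db   amp_y1   amp_y2   amp_x1   amp_x2      regime  subharmonic_index
196.359133 77.885872 0.000583 0.000322 0.000207 0.000092 limit_cycle       1.868524e-07
```

The folds self-oscillate near 196 Hz with a mean horizontal amplitude
of 0.58 mm on the lower mass; the vertical amplitudes (`amp_x*`, in m)
collapse by two orders of magnitude when the run is repeated with
`--Q 100`, while the horizontal amplitude barely changes — the
vertical-restraint effect the package exists to study. In Python the
same run is

```python
from twomass import SimulationConfig, ModelParams, run, sweep_Q

result = run(SimulationConfig(params=ModelParams(Q=2.0)))
table = sweep_Q(SimulationConfig(), [1.5, 2, 3, 5, 7, 10, 15, 100])
```

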