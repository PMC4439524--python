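# itdfreq

Analysis tools for **frequency-dependent interaural time differences
(ITDs)** — for auditory neuroscientists studying how binaural neurons and
natural acoustics deviate from the textbook picture of a single, fixed
interaural delay per sound direction.

Low-frequency sound localization relies on the ITD. In idealized accounts
the ITD of a source is one number, and a binaural neuron (MSO → IC) is
tuned to one best delay at every frequency. In reality both sides of that
picture are frequency-dependent: a neuron's best ITD drifts with tone
frequency, and the acoustical ITD of a fixed source direction drifts with
frequency too, because of head diffraction and early ground reflections.
`itdfreq` implements the full analysis chain that quantifies both effects
and the coincidence-detection mechanism that can link them.

## The core statistics

**Neural side.** A cell's best phase BP(f) — the circular mean phase of
its spikes relative to a binaural-beat cycle at tone frequency *f* — is
regressed on frequency as a line in phase space,

    BP(f) ≈ CP + CD · f   (phases in cycles)

by minimizing the sync-rate-weighted circular objective

    E(CP, CD) = Σ_f SR(f) · d(BP(f), CP + CD·f),
    d(x, y) = ½ [1 − cos 2π(x − y)],

with SR = rate × vector strength. The intercept CP (cycles) is the
*characteristic phase*, the slope CD (ms) the *characteristic delay*; a
pure time delay has CP = 0. The minimization is a grid scan over CP ∈
[−0.5, 0.5] cycles × CD ∈ [−2, 2] ms followed by Newton descent. Fit
quality is an unweighted mean circular residual in [0, 1], with a
surrogate (uniform-BP) test for linearity.

**Acoustical side.** A rigid-sphere head model (analytic partial-wave
solution, optional image-source ground reflection with a flow-resistivity
impedance) yields interaural phase difference spectra IPD(f). From these:

    ITD_g(f) = dIPD/df          (group ITD — envelope delay)
    ITD_p(f) = ⟨IPD(f)⟩ / f     (phase ITD — fine-structure delay)
    IDI(f)   = f · (ITD_p − ITD_g)   (interaural diffraction index)

and, within cell-like frequency bands BW(F) = F/Q(F), *acoustical* CP and
CD computed by the same circular-linear regression used for cells.

**Mechanism.** Coincidences between two phase-locked auditory-nerve
fibers with slightly mismatched characteristic frequencies (CFs),
counted while one train is shifted by an internal delay, produce
"pseudobinaural" ITD curves whose best phases feed the same CP/CD
analysis — showing that sub-0.1-octave cochlear mistuning generates the
frequency-dependent tuning and the inverse CP–CD relationship.

All animal-recording inputs are replaced by seeded synthetic generators
(`itdfreq.synthetic`) with controlled CP/CD, phase locking, tuning and
cochlear phase, so every stage is testable end to end.

## Worked example

Fit CP/CD to a synthetic cell generated with CP = 0.27 cycles and
CD = −0.102 ms (5 s binaural beats, 10 repetitions per tone):

```python
import numpy as np
from itdfreq.circstats import phase_point_stats, screen_points
from itdfreq.cpcd import PhaseFrequencyCurve, fit_cpcd
from itdfreq.synthetic import ModelCellSpec, generate_cell_responses

spec = ModelCellSpec("cell01", cp=0.27, cd=-0.102, cf=900.0, seed=42)
responses = generate_cell_responses(spec)
points = screen_points([phase_point_stats(r) for r in responses], alpha=0.001)
curve = PhaseFrequencyCurve(
    "cell01",
    np.array([p.tone_freq for p in points]),
    np.array([p.bp for p in points]),
    np.array([p.sr for p in points]),
)
fit = fit_cpcd(curve, linearity_surrogates=1999, seed=0)
print(f"{len(points)} of {len(responses)} frequency points pass the Rayleigh screen")
print(f"CP = {fit.cp:+.3f} cycles   CD = {fit.cd:+.3f} ms")
print(f"residual = {fit.residual:.4f}   linearity p = {fit.linearity_p:.4g}")
```

prints

```
8 of 9 frequency points pass the Rayleigh screen
CP = +0.267 cycles   CD = -0.097 ms
residual = 0.0003   linearity p = 0.0005
```

The 9th tone (3 kHz) loses phase locking and is screened out; the fit
recovers the generating parameters to within the beat-sampling noise. The
same pipeline is available from the shell:

```
itdfreq simulate --kind cells --n 20 --seed 1 --out spikes.csv
itdfreq fit-cpcd --spikes spikes.csv --out fits.csv --seed 1
itdfreq population-test --fits fits.csv --spikes spikes.csv --seed 1
itdfreq acoustics --model sphere+ground --azimuths 15,45,75 --out ipd.csv
```

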