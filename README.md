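# groovesync

Analysis pipeline for studying **groove** — the pleasurable urge to move to
music — and its relationship to **auditory–motor synchronization**. The
package takes head-movement recordings (11 optical markers at 100 Hz, or a
synthetic stand-in with known ground truth), reduces them to a neck-angle
magnitude signal, quantifies movement–music phase locking at two metrical
timescales, and runs the inferential layer a movement-science study of this
design needs: factorial ANOVA (parametric and aligned-rank), condition-wise
correlations, random-intercept mixed models, and an observed-variable path
analysis with multi-group invariance testing.

It is aimed at researchers in sensorimotor neuroscience and music cognition
who want a tested, reproducible implementation of this analysis chain, plus
a synthetic-data generator that doubles as a test bed for estimator
recovery.

## The measures and models

**Phase-locking value.** Movement is compared with a canonical reference
oscillation at a target frequency *f* (2 Hz is the beat at 120 bpm, 1 Hz a
slower metrical level). After band-pass filtering (*f* ± 0.3 Hz, zero-phase
Butterworth) the instantaneous phase φ_motion(t) is extracted with the
Hilbert transform and compared with the reference phase φ_ref(t):

    PLV = | (1/N) Σ_t exp( i · (φ_motion(t) − φ_ref(t)) ) |

PLV is 0 for no phase consistency and 1 for perfect locking, and is
invariant to constant phase offsets and amplitude scaling.

**Kinematics.** Marker trajectories are trimmed to the 16-s stimulus
window, low-pass filtered (4th-order Butterworth, 5 Hz, forward–backward),
joint centers are computed from marker geometry, the head-segment rotation
relative to the torso is decomposed into three components, and the
Euclidean norm of the three angle components gives the one-dimensional
movement signal.

**Path model.** The structural system over endogenous y = (Pleasure, Urge,
PLV1, PLV2) and exogenous syncopation dummies x = (Middle, High; Low as
reference) is y = B y + Γ x + ζ with Cov(ζ) = Ψ and Cov(x) = Φ, implying

    Σ(θ) = [ (I−B)⁻¹(ΓΦΓ′+Ψ)(I−B)⁻ᵀ   (I−B)⁻¹ΓΦ ;  ΦΓ′(I−B)⁻ᵀ   Φ ]

Estimation minimizes F_ML = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − p with
analytic gradients; T = (N−1)·F_ML, with CFI, TLI, RMSEA and SRMR against
the independence baseline, and multi-group fitting with equality
constraints and stepwise constraint release for invariance testing.

## Worked example

`examples/` contains one short script per capability. For instance, the
kinematics round trip (`python examples/03_kinematics_roundtrip.py`) drives
the body template with a known 10°, 2-Hz neck oscillation and recovers it
from the marker trajectories alone:

```
driving amplitude:   9.980 deg at 2.000 Hz
recovered amplitude: 9.974 deg at 2.000 Hz
relative amplitude error: 0.07%
```

and the path model (`python examples/05_path_model.py`) fits the embodied
groove–synchrony system per movement condition on a synthetic dataset:

```
    Free: chi2(7) =   2.46, CFI = 1.000, TLI = 1.019, RMSEA = 0.000, SRMR = 0.017 -> good fit
  Static: chi2(7) =  10.41, CFI = 0.993, TLI = 0.985, RMSEA = 0.043, SRMR = 0.032 -> good fit
 Dynamic: chi2(7) =  11.12, CFI = 0.993, TLI = 0.984, RMSEA = 0.047, SRMR = 0.032 -> good fit
...
invariance test (all paths equal across conditions): delta chi2(14) = 7.26, p = 0.924
```

Here chi2(df) is the covariance-structure test statistic (small is good),
the four indices grade global fit, and the invariance test correctly finds
no condition differences because the generator used one parameter set for
all conditions.

A full synthetic study (simulate → measure synchrony → analyze → report)
runs from the shell:

```sh
groovesync run-all --seed 1 --out runs/demo
groovesync plv --input angle.csv --freq 2 --bandwidth 0.3 --edge-trim 1.0
```

## Layout

- `src/groovesync/simulate.py` — synthetic designs, phase-coupled movement,
  ratings DGP with retained ground truth
- `src/groovesync/kinematics.py` — markers → joint centers → neck angles
- `src/groovesync/synchrony.py` — band-pass, Hilbert phase, PLV
- `src/groovesync/scoring.py` — questionnaire composites, trial table
- `src/groovesync/stats.py` — ANOVA/ART, correlations, mixed model
- `src/groovesync/sem.py` — path-analysis engine, multi-group invariance
- `src/groovesync/pipeline.py`, `cli.py` — orchestration and the
  `groovesync` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
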