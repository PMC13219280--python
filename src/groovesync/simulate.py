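"""Synthetic study generator: factorial design, phase-coupled head movement, ratings.

This module emulates the study conditions of a seated music-listening
experiment: 30 participants, 3 syncopation levels x 3 rhythmic patterns per
level x 3 movement conditions (27 trials each), 16-s stimuli at 120 bpm, head
movement captured at 100 Hz, and two groove ratings (Urge-to-Move, Pleasure)
on a 0-6 scale.  Everything is generated from a known data-generating process
so that downstream estimators can be tested for parameter recovery, and the
ground truth is retained beside every simulated dataset.

Movement is synthesized as a neck-angle signal with sinusoidal components at
the metrical frequencies (1 Hz and 2 Hz) whose phase coupling is controlled
by a von Mises concentration parameter; ratings come from a structural path
model over (syncopation dummies, Pleasure, Urge, PLV1, PLV2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, special

from .kinematics import (
    HEAD_MARKERS,
    MARKER_NAMES,
    AngleSeries,
    MarkerFrameSeries,
    MissingMarkerError,
)
from scipy.spatial.transform import Rotation

ENDOGENOUS = ("pleasure", "urge", "plv1", "plv2")
EXOGENOUS = ("sync_mid", "sync_high")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design parameters of the simulated study."""

    n_participants: int = 30
    syncopation_levels: tuple[str, ...] = ("Low", "Middle", "High")
    patterns_per_level: int = 3
    movement_conditions: tuple[str, ...] = ("Free", "Static", "Dynamic")
    tempo_bpm: float = 120.0
    trial_duration_s: float = 16.0
    sampling_rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.patterns_per_level <= 0:
            raise ValueError("counts must be positive")
        if len(set(self.syncopation_levels)) != len(self.syncopation_levels):
            raise ValueError("duplicate syncopation labels")
        if len(set(self.movement_conditions)) != len(self.movement_conditions):
            raise ValueError("duplicate movement-condition labels")
        if not self.syncopation_levels or not self.movement_conditions:
            raise ValueError("factor levels must be non-empty")
        if min(self.tempo_bpm, self.trial_duration_s, self.sampling_rate_hz) <= 0:
            raise ValueError("tempo, duration and sampling rate must be positive")

    @property
    def beat_frequency_hz(self) -> float:
        """Beat-level frequency: 2 Hz at the default 120 bpm."""
        return self.tempo_bpm / 60.0

    @property
    def trials_per_participant(self) -> int:
        return (
            len(self.syncopation_levels)
            * self.patterns_per_level
            * len(self.movement_conditions)
        )


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """One row per participant x condition x level x pattern.

    The first section is always the first movement condition (participants
    complete it before knowing movement is of interest); the order of the
    remaining sections alternates across participants (0-based even
    participant index: listed order; odd: reversed).  Stimulus order within a
    section is shuffled deterministically under the design seed.
    """
    rng = np.random.default_rng(spec.seed)
    first, *rest = spec.movement_conditions
    stimuli = [
        (level, pattern)
        for level in spec.syncopation_levels
        for pattern in range(1, spec.patterns_per_level + 1)
    ]
    rows = []
    for p in range(1, spec.n_participants + 1):
        sections = [first] + (rest if (p - 1) % 2 == 0 else rest[::-1])
        for section_idx, condition in enumerate(sections, start=1):
            order = rng.permutation(len(stimuli))
            for trial_idx, stim_idx in enumerate(order, start=1):
                level, pattern = stimuli[stim_idx]
                rows.append(
                    {
                        "participant": p,
                        "section": section_idx,
                        "movement": condition,
                        "syncopation": level,
                        "pattern": pattern,
                        "trial_in_section": trial_idx,
                    }
                )
    table = pd.DataFrame(rows)
    if len(table) != spec.n_participants * spec.trials_per_participant:
        raise AssertionError("design cardinality violated")
    return table


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MovementSimParams:
    """Controls of the synthetic neck-angle signal.

    Amplitudes are in degrees.  ``kappa_*`` are von Mises concentrations of
    the phase jitter at each metrical component (``inf`` means perfectly
    locked); larger kappa means tighter phase coupling and a higher expected
    PLV (the mean resultant length I1(kappa)/I0(kappa)).  When
    ``phase_drift_sd`` is positive the jitter is instead a phase random walk
    with that per-sample standard deviation (radians).  ``baseline_deg`` is
    the postural offset of the angle magnitude; by default it is chosen large
    enough that the signal never rectifies at zero.
    """

    amplitude_1hz: float = 1.5
    amplitude_2hz: float = 3.0
    kappa_1hz: float = 4.0
    kappa_2hz: float = 4.0
    broadband_noise_sd: float = 0.3
    phase_drift_sd: float = 0.0
    baseline_deg: float | None = None
    jitter_timescale_s: float = 8.0

    def __post_init__(self) -> None:
        if self.amplitude_1hz < 0 or self.amplitude_2hz < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.kappa_1hz < 0 or self.kappa_2hz < 0:
            raise ValueError("kappa must be non-negative")
        if self.broadband_noise_sd < 0 or self.phase_drift_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.jitter_timescale_s <= 0:
            raise ValueError("jitter timescale must be positive")


def mean_resultant_length(kappa: float) -> float:
    """Expected resultant length of von Mises(0, kappa): I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if math.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    # ive = exp(-kappa) * iv avoids overflow for large kappa
    return float(special.ive(1, kappa) / special.ive(0, kappa))


def kappa_for_plv(target_plv: float) -> float:
    """Invert the Bessel-function ratio: concentration giving a target PLV."""
    p = float(np.clip(target_plv, 1e-4, 0.9995))
    return float(optimize.brentq(lambda k: mean_resultant_length(k) - p, 1e-6, 2e4))


def simulate_phase_samples(
    frequency_hz: float,
    kappa: float,
    n: int,
    sampling_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Phase samples ``2*pi*f*t_i + eps_i`` with iid von Mises(0, kappa) jitter.

    This is the controlled input of the PLV statistic: the resultant length of
    the jitter converges to I1(kappa)/I0(kappa).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    base = 2 * np.pi * frequency_hz * np.arange(n) / sampling_rate
    if math.isinf(kappa):
        return base
    return base + rng.vonmises(0.0, kappa, size=n)


def _vonmises_quantiles(u: np.ndarray, kappa: float) -> np.ndarray:
    """von Mises(0, kappa) quantile function via a tabulated CDF."""
    x = np.linspace(-np.pi, np.pi, 4097)
    pdf = np.exp(kappa * (np.cos(x) - 1.0))
    cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(x))))
    cdf /= cdf[-1]
    return np.interp(u, cdf, x)


def _slow_vonmises_jitter(
    kappa: float, n: int, sampling_rate: float, timescale_s: float, rng
) -> np.ndarray:
    """Stationary phase jitter with exact von Mises marginal and slow dynamics.

    A unit-variance Gaussian AR(1) process with correlation time
    ``timescale_s`` is mapped through the Gaussian CDF and the von Mises
    quantile function.  The marginal is von Mises(0, kappa) at every sample,
    so the circular mean over a long record converges to I1(kappa)/I0(kappa),
    while the jitter varies slowly enough to pass the narrow analysis band of
    the PLV pipeline (see the methods note).
    """
    if math.isinf(kappa):
        return np.zeros(n)
    rho = math.exp(-1.0 / (sampling_rate * timescale_s))
    innovations = rng.standard_normal(n) * math.sqrt(1.0 - rho * rho)
    innovations[0] = rng.standard_normal()
    g = signal.lfilter([1.0], [1.0, -rho], innovations)
    u = np.clip(special.ndtr(g), 1e-12, 1 - 1e-12)
    if kappa < 1e-8:
        return 2 * np.pi * (u - 0.5)
    return _vonmises_quantiles(u, kappa)


def simulate_neck_angle(
    params: MovementSimParams,
    duration_s: float,
    sampling_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_jitter: bool = False,
):
    """Synthesize the neck angular-magnitude signal of one trial.

    theta(t) = baseline + A1*sin(2*pi*1*t + eps1(t)) + A2*sin(2*pi*2*t + eps2(t)) + noise

    with slowly varying von Mises phase jitter (or a phase random walk when
    ``phase_drift_sd > 0``).  The baseline offset keeps the magnitude
    non-negative so the downstream norm does not rectify the oscillation.
    With ``return_jitter=True`` the realized jitter series are also returned,
    for oracle comparisons against the measured PLV.
    """
    if duration_s <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = round(duration_s * sampling_rate)
    t = np.arange(n) / sampling_rate
    baseline = params.baseline_deg
    if baseline is None:
        baseline = (
            params.amplitude_1hz
            + params.amplitude_2hz
            + max(1.0, 6.0 * params.broadband_noise_sd)
        )
    theta = np.full(n, float(baseline))
    jitter: dict[float, np.ndarray] = {}
    for freq, amp, kappa in (
        (1.0, params.amplitude_1hz, params.kappa_1hz),
        (2.0, params.amplitude_2hz, params.kappa_2hz),
    ):
        if params.phase_drift_sd > 0:
            eps = np.cumsum(rng.normal(0.0, params.phase_drift_sd, size=n))
        else:
            eps = _slow_vonmises_jitter(
                kappa, n, sampling_rate, params.jitter_timescale_s, rng
            )
        jitter[freq] = eps
        if amp > 0:
            theta += amp * np.sin(2 * np.pi * freq * t + eps)
    if params.broadband_noise_sd > 0:
        theta += rng.normal(0.0, params.broadband_noise_sd, size=n)
    series = AngleSeries(np.maximum(theta, 0.0), sampling_rate)
    if return_jitter:
        return series, jitter
    return series


# ---------------------------------------------------------------------------
# body template / forward kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BodyTemplate:
    """Rest positions (metres) of the 11 markers for a seated participant.

    The neck pivot is derived from the rest pose with the same joint-center
    convention used by the kinematics module, so forward and inverse passes
    agree by construction.
    """

    rest_positions: dict[str, tuple[float, float, float]]
    neck_projection_fraction: float = 0.0

    def __post_init__(self) -> None:
        missing = set(MARKER_NAMES) - set(self.rest_positions)
        if missing:
            raise MissingMarkerError(f"template missing markers: {sorted(missing)}")

    def rest(self, name: str) -> np.ndarray:
        return np.asarray(self.rest_positions[name], dtype=float)

    @property
    def neck_pivot(self) -> np.ndarray:
        ear_mid = 0.5 * (self.rest("ear_L") + self.rest("ear_R"))
        return ear_mid + self.neck_projection_fraction * (self.rest("C7") - ear_mid)


def default_body_template() -> BodyTemplate:
    """Anatomically plausible seated rest pose.

    Axes: x lateral (right positive), y anterior, z vertical.  The head-top
    marker sits 15 cm above the ear midpoint; the thoracolumbar center lies
    directly below the neck pivot so the rest pose is the neutral (zero-angle)
    orientation.
    """
    return BodyTemplate(
        rest_positions={
            "head_top": (0.0, 0.0, 0.85),
            "ear_L": (-0.07, 0.0, 0.70),
            "ear_R": (0.07, 0.0, 0.70),
            "sternum_up": (0.0, 0.06, 0.55),
            "acromion_L": (-0.18, 0.0, 0.55),
            "acromion_R": (0.18, 0.0, 0.55),
            "rib_low_L": (-0.12, 0.03, 0.25),
            "rib_low_R": (0.12, 0.03, 0.25),
            "C7": (0.0, -0.06, 0.58),
            "T8": (0.0, 0.005, 0.35),
            "T12": (0.0, -0.005, 0.22),
        }
    )


def forward_kinematics(
    angle: AngleSeries,
    template: BodyTemplate | None = None,
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
    sway_amplitude_m: float = 0.0,
    sway_frequency_hz: float = 0.25,
) -> MarkerFrameSeries:
    """Drive the head segment by the angle series, about the neck pivot.

    Head markers are rigidly rotated about ``axis`` (default: the lateral
    axis, i.e. flexion/extension nodding) by the angle magnitude; torso
    markers stay at their rest positions, optionally with a small slow
    anterior-posterior sway.  The inverse pass (kinematics module) recovers
    the driving angle, enabling round-trip testing.
    """
    template = template if template is not None else default_body_template()
    axis_v = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis_v)
    if nrm < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    axis_v = axis_v / nrm
    pivot = template.neck_pivot
    n = angle.n_samples
    rot = Rotation.from_rotvec(np.outer(np.deg2rad(angle.values), axis_v))
    positions = np.empty((n, len(MARKER_NAMES), 3))
    sway = np.zeros((n, 3))
    if sway_amplitude_m > 0:
        sway[:, 1] = sway_amplitude_m * np.sin(
            2 * np.pi * sway_frequency_hz * angle.times
        )
    for j, name in enumerate(MARKER_NAMES):
        rest = template.rest(name)
        if name in HEAD_MARKERS:
            positions[:, j, :] = pivot + rot.apply(rest - pivot)
        else:
            positions[:, j, :] = rest + sway
    return MarkerFrameSeries(positions, angle.sampling_rate, MARKER_NAMES)


# ---------------------------------------------------------------------------
# ratings DGP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingDGP:
    """Structural data-generating process for ratings and coupling.

    ``paths`` maps ``(source, target)`` to a raw-scale coefficient, with
    sources/targets drawn from ``{sync_mid, sync_high, pleasure, urge, plv1,
    plv2}``.  Feedback paths (PLV -> ratings) make the system simultaneous;
    it is then solved through ``(I - B)^{-1}``, which must exist.  Composite
    scores are clipped to ``rating_bounds`` after noise; the unclipped latent
    values are retained in the ground truth so recovery tests are not biased
    by censoring.
    """

    intercepts: dict[str, float]
    paths: dict[tuple[str, str], float]
    random_intercept_sd: dict[str, float]
    residual_sd: dict[str, float]
    rating_bounds: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self) -> None:
        for name in ENDOGENOUS:
            if name not in self.intercepts:
                raise ValueError(f"missing intercept for {name}")
        for (src, dst), _ in self.paths.items():
            if dst not in ENDOGENOUS:
                raise ValueError(f"path target {dst} is not endogenous")
            if src not in ENDOGENOUS + EXOGENOUS:
                raise ValueError(f"unknown path source {src}")
            if src == dst:
                raise ValueError("self-loops are not allowed")
        for d in (self.random_intercept_sd, self.residual_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("SDs must be non-negative")

    def b_matrix(self) -> np.ndarray:
        """Endogenous-to-endogenous coefficient matrix B (target row, source column)."""
        b = np.zeros((len(ENDOGENOUS), len(ENDOGENOUS)))
        for (src, dst), coef in self.paths.items():
            if src in ENDOGENOUS:
                b[ENDOGENOUS.index(dst), ENDOGENOUS.index(src)] = coef
        return b

    def gamma_matrix(self) -> np.ndarray:
        g = np.zeros((len(ENDOGENOUS), len(EXOGENOUS)))
        for (src, dst), coef in self.paths.items():
            if src in EXOGENOUS:
                g[ENDOGENOUS.index(dst), EXOGENOUS.index(src)] = coef
        return g

    @property
    def is_recursive(self) -> bool:
        """True when the endogenous system is acyclic (sequential generation)."""
        b = self.b_matrix() != 0
        order = list(range(len(ENDOGENOUS)))
        remaining = set(order)
        while remaining:
            free = [i for i in remaining if not any(b[i, j] for j in remaining if j != i)]
            if not free:
                return False
            remaining -= set(free)
        return True


def default_rating_dgp(feedback: bool = False) -> RatingDGP:
    """Study-condition DGP: inverted-U syncopation effects, Pleasure -> Urge,
    Urge -> coupling at both timescales; optional negative PLV feedback."""
    paths = {
        ("sync_mid", "pleasure"): 0.8,
        ("sync_high", "pleasure"): -1.0,
        ("sync_mid", "urge"): 0.6,
        ("sync_high", "urge"): -0.9,
        ("pleasure", "urge"): 0.55,
        ("urge", "plv1"): 0.015,
        ("urge", "plv2"): 0.035,
    }
    if feedback:
        paths[("plv1", "urge")] = -0.4
        paths[("plv2", "pleasure")] = -0.3
    return RatingDGP(
        intercepts={"pleasure": 3.3, "urge": 1.4, "plv1": 0.12, "plv2": 0.18},
        paths=paths,
        random_intercept_sd={"pleasure": 0.5, "urge": 0.5, "plv1": 0.03, "plv2": 0.05},
        residual_sd={"pleasure": 0.9, "urge": 0.8, "plv1": 0.06, "plv2": 0.08},
    )


@dataclass
class GroundTruth:
    """Generating parameters retained beside a simulated dataset.

    Never merged into analysis-facing tables; recovery tests read it directly.
    """

    dgp: RatingDGP
    latent: pd.DataFrame
    participant_intercepts: pd.DataFrame
    seed: int | None

    def coupling_by_trial(self) -> pd.DataFrame:
        """Per-trial latent (unclipped, noiseless-measurement) coupling values."""
        return self.latent[["plv1", "plv2"]].copy()


def simulate_ratings(
    design: pd.DataFrame,
    dgp: RatingDGP | None = None,
    coupling_by_trial: pd.DataFrame | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate Urge/Pleasure (and PLV columns) from the structural DGP.

    Recursive systems are generated sequentially in causal order; systems
    with feedback are solved simultaneously through ``(I - B)^{-1}``.  When
    ``coupling_by_trial`` provides plv1/plv2 values (e.g. measured from
    simulated movement), those are used as the coupling variables instead of
    being generated.
    """
    dgp = dgp if dgp is not None else default_rating_dgp()
    rng = rng if rng is not None else np.random.default_rng(seed)
    table = design.copy()
    from .scoring import add_syncopation_dummies

    table = add_syncopation_dummies(table)

    n = len(table)
    x = table[["sync_mid", "sync_high"]].to_numpy(dtype=float)
    b = dgp.b_matrix()
    g = dgp.gamma_matrix()
    k = len(ENDOGENOUS)

    participants = pd.unique(table["participant"])
    b_i = pd.DataFrame(
        {
            name: rng.normal(0.0, dgp.random_intercept_sd.get(name, 0.0), len(participants))
            for name in ENDOGENOUS
        },
        index=pd.Index(participants, name="participant"),
    )
    rand = b_i.loc[table["participant"]].to_numpy()
    resid = np.column_stack(
        [rng.normal(0.0, dgp.residual_sd.get(name, 0.0), n) for name in ENDOGENOUS]
    )
    const = np.array([dgp.intercepts[name] for name in ENDOGENOUS])
    # u: everything except the endogenous feedback terms
    u = const[None, :] + x @ g.T + rand + resid

    fixed = {}
    if coupling_by_trial is not None:
        for col in ("plv1", "plv2"):
            if col in coupling_by_trial:
                fixed[ENDOGENOUS.index(col)] = np.asarray(
                    coupling_by_trial[col], dtype=float
                )

    y = np.zeros((n, k))
    free_idx = [i for i in range(k) if i not in fixed]
    for i, vals in fixed.items():
        if len(vals) != n:
            raise ValueError("coupling_by_trial length mismatch")
        y[:, i] = vals
    if dgp.is_recursive or fixed:
        # sequential generation in causal order (fixed columns act as givens)
        b_eff = b.copy()
        remaining = list(free_idx)
        resolved = set(fixed)
        guard = 0
        while remaining:
            progressed = False
            for i in list(remaining):
                deps = [j for j in range(k) if b_eff[i, j] != 0 and j not in resolved]
                if not deps:
                    y[:, i] = u[:, i] + y @ b_eff[i, :]
                    resolved.add(i)
                    remaining.remove(i)
                    progressed = True
            guard += 1
            if not progressed:
                raise ValueError(
                    "feedback among non-fixed endogenous variables requires a "
                    "simultaneous solve; remove coupling_by_trial or break the loop"
                )
            if guard > k + 1:
                raise AssertionError("generation did not terminate")
    else:
        eye_b = np.eye(k) - b
        if abs(np.linalg.det(eye_b)) < 1e-12:
            raise ValueError("(I - B) is singular; the feedback system has no solution")
        y = np.linalg.solve(eye_b, u.T).T

    latent = table[["participant", "movement", "syncopation", "pattern"]].copy()
    for i, name in enumerate(ENDOGENOUS):
        latent[name] = y[:, i]

    lo, hi = dgp.rating_bounds
    clipped = 0
    for name in ("urge", "pleasure"):
        col = y[:, ENDOGENOUS.index(name)]
        clipped += int(np.sum((col < lo) | (col > hi)))
        table[name] = np.clip(col, lo, hi)
    for name in ("plv1", "plv2"):
        col = y[:, ENDOGENOUS.index(name)]
        clipped += int(np.sum((col < 0) | (col > 1)))
        table[name] = np.clip(col, 0.0, 1.0)
    if clipped / (4 * n) > 0.20:
        warnings.warn(
            f"{clipped / (4 * n):.0%} of generated scores were clipped; "
            "the DGP is poorly scaled",
            stacklevel=2,
        )

    truth = GroundTruth(
        dgp=dgp,
        latent=latent,
        participant_intercepts=b_i,
        seed=seed,
    )
    return table, truth
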