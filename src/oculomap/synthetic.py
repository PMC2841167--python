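"""Synthetic face stimuli, observers and gaze data.

Every pipeline stage is exercised against data from this module: it
renders face-like grayscale stimuli (oval + darker landmark patches +
smooth per-identity variation), draws scanpaths from parametric
observer profiles (a mixture over facial landmarks with Gamma fixation
durations), renders those plans into 1000 Hz sample streams whose
saccade kinematics exceed the detector thresholds, and assembles whole
two-group experiments with aperture-dependent behavioural accuracy.

All randomness flows through an explicit seed; identical seeds give
byte-identical output at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .events import Event, EventSequence, GazeRecording
from .spotlight import DEFAULT_LAYOUT, Landmark

__all__ = [
    "ObserverProfile",
    "ExperimentDesign",
    "ScanStep",
    "ScanPlan",
    "WC_PROFILE",
    "NOSE_PROFILE",
    "make_face_image",
    "make_face_set",
    "sample_scanpath",
    "plan_to_events",
    "synthesize_trial_samples",
    "simulate_experiment",
    "SimulatedExperiment",
]


# --------------------------------------------------------------------------
# observer profiles


@dataclass(frozen=True)
class ObserverProfile:
    """Generative fixation-strategy parameters.

    ``landmark_weights`` is a mixture over facial landmarks; each
    fixation picks a landmark and lands at its centre plus isotropic
    Gaussian scatter of SD ``spread_deg``.  Fixation durations are
    Gamma(shape, scale) ms, truncated below at ``min_fix_ms`` so that
    planted fixations stay above the detector's resolution.  Blinks
    occur at ``blink_rate`` per second.
    """

    landmark_weights: Mapping[str, float]
    spread_deg: float = 0.5
    fix_dur_shape: float = 4.0
    fix_dur_scale: float = 77.5     # mean 310 ms, SD 155 ms
    min_fix_ms: float = 60.0
    noise_deg: float = 0.05         # per-sample positional jitter SD
    blink_rate: float = 0.1         # per second
    blink_dur_ms: Tuple[float, float] = (100.0, 250.0)

    def __post_init__(self) -> None:
        w = np.array(list(self.landmark_weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("landmark weights must be non-negative and sum to 1")
        for name in ("spread_deg", "fix_dur_shape", "fix_dur_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Eye-biased strategy: triangular eyes-and-mouth sampling.
WC_PROFILE = ObserverProfile(
    landmark_weights={"left_eye": 0.35, "right_eye": 0.35, "mouth": 0.20, "nose": 0.10}
)

#: Centre-of-face strategy: fixations gravitate to the nose region.
NOSE_PROFILE = ObserverProfile(
    landmark_weights={"left_eye": 0.10, "right_eye": 0.10, "mouth": 0.20, "nose": 0.60}
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure and behavioural profile of the experiment.

    Each block presents ``n_learn`` identities for ``learn_exposure_ms``
    each, followed by ``n_recog = 2 * n_learn`` recognition trials (the
    learned faces plus as many new ones).  There are ``blocks_per_race``
    blocks for each face race.  ``accuracy_by_aperture`` gives the
    probability of a correct old/new judgement per aperture diameter;
    the 2 deg default of 0.5 operationalises chance performance for the
    two-alternative familiarity decision, rising with aperture size.
    """

    n_learn: int = 14
    n_recog: int = 28
    blocks_per_race: int = 2
    races: Tuple[str, ...] = ("WC", "EA")
    learn_exposure_ms: float = 10000.0
    accuracy_by_aperture: Mapping[float, float] = field(
        default_factory=lambda: {2.0: 0.50, 5.0: 0.75, 8.0: 0.90}
    )
    rt_base_by_aperture: Mapping[float, float] = field(
        default_factory=lambda: {2.0: 2600.0, 5.0: 2100.0, 8.0: 1700.0}
    )

    def __post_init__(self) -> None:
        if self.n_recog != 2 * self.n_learn:
            raise ValueError("n_recog must equal 2 * n_learn (old + new faces)")
        for p in self.accuracy_by_aperture.values():
            if not 0 <= p <= 1:
                raise ValueError("accuracies must lie in [0, 1]")


# --------------------------------------------------------------------------
# face stimuli

FACE_SHAPE = (390, 382)


def _patch(shape, cx, cy, sigma):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2)) / (2.0 * sigma * sigma))


def make_face_image(
    layout: Mapping[str, Landmark] = DEFAULT_LAYOUT,
    seed: int | np.random.Generator | None = 0,
    shape: Tuple[int, int] = FACE_SHAPE,
    variation_sd: float = 10.0,
    variation_sigma_px: float = 18.0,
    landmark_amp_jitter: float = 0.02,
    landmark_pos_jitter: float = 0.2,
) -> np.ndarray:
    """One synthetic face exemplar (gray levels in [1, 256]).

    A gray background carries a face oval with darker Gaussian patches
    at the landmarks.  Identity is a seeded perturbation: a spatially
    smooth random field (SD ``variation_sd`` gray levels, correlation
    scale ``variation_sigma_px``) over the whole image plus mild
    per-landmark amplitude/position jitter.  The broad field dominates,
    standing in for the global identity differences (skin tone, head
    shape, lighting) that in aligned, luminance-normalised photographs
    spread exemplar variance across the whole image rather than piling
    it onto single features.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, 200.0)

    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, 222.0
    oval = (((xx - cx) / 110.0) ** 2 + ((yy - cy) / 150.0) ** 2) <= 1.0
    img[oval] = 172.0

    for lm in layout.values():
        amp = 70.0 * (1.0 + landmark_amp_jitter * rng.standard_normal())
        jx, jy = rng.normal(0.0, landmark_pos_jitter, size=2)
        img -= amp * _patch(shape, lm.x + jx, lm.y + jy, lm.radius * 0.8)

    # periodic smoothing keeps the identity field stationary out to the
    # image border (mirror padding would double edge variance)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, variation_sigma_px, mode="wrap")
    smooth *= variation_sd / smooth.std()
    img += smooth
    return np.clip(img, 1.0, 256.0)


def make_face_set(
    n: int,
    layout: Mapping[str, Landmark] = DEFAULT_LAYOUT,
    seed: int | np.random.Generator | None = 0,
    **kwargs,
) -> List[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [make_face_image(layout, rng, **kwargs) for _ in range(n)]


# --------------------------------------------------------------------------
# scanpath plans


@dataclass
class ScanStep:
    kind: str          # "fixation" | "saccade" | "blink"
    duration_ms: float
    x0: float
    y0: float
    x1: float
    y1: float


@dataclass
class ScanPlan:
    steps: List[ScanStep]
    px_per_deg: float = 25.0

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.steps)


def _saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence duration, shortened for small saccades so the
    minimum-jerk peak velocity (1.875 A / d) stays >= 100 deg/s."""
    d = 2.2 * amplitude_deg + 21.0
    if amplitude_deg > 0:
        d = min(d, 1000.0 * 1.875 * amplitude_deg / 100.0)
    return max(d, 4.0)


def sample_scanpath(
    profile: ObserverProfile,
    layout: Mapping[str, Landmark] = DEFAULT_LAYOUT,
    duration_ms: float = 10000.0,
    seed: int | np.random.Generator | None = 0,
    px_per_deg: float = 25.0,
) -> ScanPlan:
    """Draw an alternating fixation/saccade (occasionally blink) plan.

    Each fixation targets a landmark drawn from the profile mixture
    with isotropic Gaussian scatter; durations come from the profile's
    Gamma distribution.  The plan spans ``duration_ms`` (the final step
    is truncated to fit).
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    names = list(profile.landmark_weights.keys())
    weights = np.array([profile.landmark_weights[k] for k in names])
    spread_px = profile.spread_deg * px_per_deg

    def draw_target():
        lm = layout[names[rng.choice(len(names), p=weights)]]
        return lm.x + rng.normal(0, spread_px), lm.y + rng.normal(0, spread_px)

    steps: List[ScanStep] = []
    t = 0.0
    x, y = draw_target()
    while t < duration_ms:
        dur = max(profile.min_fix_ms, rng.gamma(profile.fix_dur_shape, profile.fix_dur_scale))
        steps.append(ScanStep("fixation", dur, x, y, x, y))
        t += dur
        if t >= duration_ms:
            break
        if rng.random() < profile.blink_rate * dur / 1000.0:
            # blinks interrupt fixation; gaze resumes at the same spot
            bd = rng.uniform(*profile.blink_dur_ms)
            steps.append(ScanStep("blink", bd, x, y, x, y))
            t += bd
            continue
        nx, ny = draw_target()
        amp = np.hypot(nx - x, ny - y) / px_per_deg
        sd = _saccade_duration_ms(amp)
        steps.append(ScanStep("saccade", sd, x, y, nx, ny))
        t += sd
        x, y = nx, ny
    # truncate to the requested span; a trial never ends mid-saccade
    overshoot = t - duration_ms
    if overshoot > 0:
        steps[-1].duration_ms -= overshoot
        if steps[-1].duration_ms <= 0:
            steps.pop()
    if steps and steps[-1].kind == "saccade":
        cut = steps.pop()
        if steps:
            steps[-1].duration_ms += cut.duration_ms
    return ScanPlan(steps, px_per_deg)


def plan_to_events(plan: ScanPlan, trial_id: str = "", rate: float = 1000.0) -> EventSequence:
    """Ground-truth event sequence of a plan (no sample synthesis)."""
    events: List[Event] = []
    t = 0.0
    for s in plan.steps:
        if s.kind == "fixation":
            events.append(Event("fixation", t, t + s.duration_ms, x=s.x0, y=s.y0))
        elif s.kind == "saccade":
            events.append(
                Event("saccade", t, t + s.duration_ms,
                      x_start=s.x0, y_start=s.y0, x_end=s.x1, y_end=s.y1)
            )
        else:
            events.append(Event("blink", t, t + s.duration_ms))
        t += s.duration_ms
    return EventSequence(events, trial_id, plan.px_per_deg, rate)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def synthesize_trial_samples(
    plan: ScanPlan,
    rate: float = 1000.0,
    noise_deg: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    trial_id: str = "trial",
) -> GazeRecording:
    """Render a plan into a uniformly sampled gaze recording.

    Saccades follow a minimum-jerk trajectory (smooth bell-shaped
    velocity whose peak comfortably exceeds the 30 deg/s detector
    threshold for amplitudes >= 1 deg); fixations hold position with
    slow oculomotor drift of marginal SD ``noise_deg`` (white noise
    low-passed at ~20 ms, matching the autocorrelated character of
    fixational drift and tracker filtering rather than per-sample
    white jitter, whose finite-difference velocity would swamp the
    detector); blinks hold position and mark the pupil missing.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / rate
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    pupils: List[np.ndarray] = []
    t_accum = 0.0
    carried = 0.0  # fractional sample carry so the total count matches the span
    for s in plan.steps:
        exact = (s.duration_ms + carried) / dt
        n = int(round(exact))
        carried = (exact - n) * dt
        if n <= 0:
            continue
        if s.kind == "saccade":
            tau = (np.arange(n) + 0.5) / n
            frac = _minimum_jerk(tau)
            xs.append(s.x0 + (s.x1 - s.x0) * frac)
            ys.append(s.y0 + (s.y1 - s.y0) * frac)
            pupils.append(np.full(n, 1000.0))
        elif s.kind == "fixation":
            xs.append(np.full(n, float(s.x0)))
            ys.append(np.full(n, float(s.y0)))
            pupils.append(np.full(n, 1000.0))
        else:  # blink
            xs.append(np.full(n, float(s.x0)))
            ys.append(np.full(n, float(s.y0)))
            pupils.append(np.full(n, np.nan))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    pupil = np.concatenate(pupils)
    noise_px = noise_deg * plan.px_per_deg
    if noise_px > 0:
        from scipy.ndimage import gaussian_filter1d

        tau = max(2.0, 0.020 * rate)  # ~20 ms drift correlation time, in samples
        for arr in (x, y):
            drift = gaussian_filter1d(rng.standard_normal(len(arr)), tau, mode="reflect")
            sd = drift.std()
            if sd > 0:
                arr += drift * (noise_px / sd)
    t = np.arange(len(x)) * dt
    return GazeRecording(trial_id, t, x, y, pupil, rate=rate, px_per_deg=plan.px_per_deg)


# --------------------------------------------------------------------------
# whole experiments


@dataclass
class SimulatedExperiment:
    trials: pd.DataFrame                 # one row per trial with outcomes
    events: Dict[str, EventSequence]     # trial_id -> ground-truth events
    recordings: Dict[str, GazeRecording] # trial_id -> samples (optional)
    seed: int | None = None


def simulate_experiment(
    design: ExperimentDesign,
    cohorts: Mapping[str, Tuple[int, ObserverProfile]],
    aperture_deg: float = 8.0,
    seed: int | None = 0,
    layout: Mapping[str, Landmark] = DEFAULT_LAYOUT,
    synthesize_samples: bool = False,
    px_per_deg: float = 25.0,
) -> SimulatedExperiment:
    """Simulate a full two-group experiment.

    ``cohorts`` maps group label -> (n observers, profile).  Learning
    trials last ``learn_exposure_ms``; recognition trials last a
    seeded lognormal response time whose scale decreases with aperture
    size; correctness is Bernoulli with the design's accuracy for the
    aperture.  Ground-truth events are always produced; sample-level
    recordings only when ``synthesize_samples`` (they are three orders
    of magnitude larger).
    """
    rng = np.random.default_rng(seed)
    acc = design.accuracy_by_aperture.get(float(aperture_deg))
    if acc is None:
        raise ValueError(f"no accuracy defined for aperture {aperture_deg}")
    rt_base = design.rt_base_by_aperture.get(float(aperture_deg), 2000.0)

    rows = []
    events: Dict[str, EventSequence] = {}
    recordings: Dict[str, GazeRecording] = {}
    for group, (n_obs, profile) in cohorts.items():
        for io in range(n_obs):
            obs = f"{group}{io:02d}"
            for race in design.races:
                for block in range(design.blocks_per_race):
                    for phase, n_trials in (("learning", design.n_learn),
                                            ("recognition", design.n_recog)):
                        for it in range(n_trials):
                            trial_id = f"{obs}_{race}_b{block}_{phase[:5]}{it:02d}"
                            if phase == "learning":
                                dur = design.learn_exposure_ms
                                is_old = True
                                correct = True
                                rt = dur
                            else:
                                rt = float(np.clip(
                                    rng.lognormal(np.log(rt_base), 0.35), 400, 10000))
                                dur = rt
                                is_old = it < design.n_learn
                                correct = bool(rng.random() < acc)
                            plan = sample_scanpath(
                                profile, layout, dur, rng, px_per_deg)
                            events[trial_id] = plan_to_events(plan, trial_id)
                            if synthesize_samples:
                                recordings[trial_id] = synthesize_trial_samples(
                                    plan, noise_deg=profile.noise_deg,
                                    seed=rng, trial_id=trial_id)
                            rows.append((trial_id, obs, group, race, block,
                                         phase, it, is_old, correct, rt))
    trials = pd.DataFrame(
        rows,
        columns=["trial_id", "observer", "group", "race", "block",
                 "phase", "trial", "is_old", "correct", "rt_ms"],
    )
    return SimulatedExperiment(trials, events, recordings, seed)
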