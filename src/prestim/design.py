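"""Synthetic session generator.

Builds complete experimental sessions — trial design, latent per-trial
processes, pre-stimulus sensor epochs, behavioral reports and a pupil
trace — with the statistical structure the downstream decoding analyses
assume.  Two latent processes drive everything:

* a *general* arousal-like scalar ``g`` (standard normal per trial) that
  raises the probability of reporting recognition for any stimulus, is
  expressed in the sensor array along a fixed pattern ``w_g`` and is
  coupled to pre-stimulus pupil diameter; and
* a *specific* categorical preference (``preferred_category``, uniform over
  the stimulus categories and independent of the presented category) that is
  expressed along per-category sensor patterns ``W_c`` and, when it matches
  the category of the forthcoming stimulus, acts as a discriminability
  boost: it raises recognition of real images and lowers spurious
  recognition of scrambled images.

Stimulus order is a seeded permutation, so the upcoming category is
unpredictable and independent of the latent states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .containers import EpochSet, PupilTrace

__all__ = [
    "CATEGORIES",
    "DesignSpec",
    "GeneratorParams",
    "LatentStates",
    "Session",
    "generate_design",
    "make_patterns",
    "simulate_latents",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_pupil",
    "simulate_session",
    "simulate_experiment",
]

#: Canonical stimulus categories of the recognition paradigm.
CATEGORIES: tuple[str, ...] = ("face", "house", "object", "animal")


@dataclass(frozen=True)
class DesignSpec:
    """Structural parameters of one experimental session.

    Defaults reproduce the recognition-threshold paradigm: 4 categories x
    (5 real + 1 scrambled) images x 15 repetitions = 360 trials (300 real,
    60 scrambled) in 10 blocks, with a 2-s pre-stimulus window.  Sensor
    count and sampling rate default to desk scale (64 sensors, 100 Hz); the
    recording-faithful values (272 sensors, 1200 Hz) are reachable through
    the same fields.
    """

    n_categories: int = 4
    images_per_category: int = 5
    scrambled_per_category: int = 1
    repeats: int = 15
    n_blocks: int = 10
    prestim_duration: float = 2.0
    sampling_rate: float = 100.0
    n_sensors: int = 64
    stimulus_duration: float = 1.0 / 15.0
    pupil_sampling_rate: float = 100.0
    iti_range: tuple[float, float] = (3.0, 6.0)
    post_range: tuple[float, float] = (2.0, 4.0)
    response_duration: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_categories",
            "images_per_category",
            "scrambled_per_category",
            "repeats",
            "n_blocks",
            "n_sensors",
        ):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"DesignSpec.{name} must be a positive count")
        if self.prestim_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("pre-stimulus window and sampling rate must be positive")
        if self.n_categories > len(CATEGORIES):
            raise ValueError(f"at most {len(CATEGORIES)} categories are supported")

    @property
    def categories(self) -> tuple[str, ...]:
        return CATEGORIES[: self.n_categories]

    @property
    def n_trials(self) -> int:
        return (
            self.n_categories
            * (self.images_per_category + self.scrambled_per_category)
            * self.repeats
        )

    @property
    def n_real_trials(self) -> int:
        return self.n_categories * self.images_per_category * self.repeats

    @property
    def n_scrambled_trials(self) -> int:
        return self.n_categories * self.scrambled_per_category * self.repeats


@dataclass(frozen=True)
class GeneratorParams:
    """Effect sizes and noise levels of the synthetic session generator.

    Recognition reports are Bernoulli draws from a probit model,

    ``P(yes) = Phi(b0 + b_real*is_real + b_g*g
                   + (b_match if real else b_match_scr)*match)``

    where ``Phi`` is the standard normal CDF and ``match`` indicates that
    the trial's latent preferred category equals the (source) category of
    the presented image.  The probit link puts the coefficients on the
    signal-detection evidence axis: the general latent ``g`` shifts the
    effective decision criterion (equal displacement of hit and
    false-alarm rates in Z units, leaving d' untouched), and the match
    effect is a discriminability boost: a valid category prediction helps
    the observer both recognize a real image (``b_match > 0``) and reject
    a scrambled one (``b_match_scr < 0``), moving sensitivity (d') while
    holding the criterion (c) fixed.  ``b_match_scr`` is smaller in
    magnitude than ``b_match`` because the false-alarm side of the
    criterion computation saturates at the design's small per-group
    scrambled-trial counts; the default pair is calibrated so the planted
    specific effect is criterion-neutral at the default design size
    (``None`` falls back to ``-b_match``).

    Categorization accuracies default to the observed operating point of
    the paradigm (86.5% / 40.1% for recognized / unrecognized real images;
    51.9% / 31.6% for scrambled).  ``report_bias_strength`` is the
    probability that the category report is captured by the trial's latent
    preference instead; marginal accuracies are kept at their targets by
    compensating the correct-report probability.

    Sensor expression: each time sample of trial *t* is
    ``w_g*g_t + W_c[pref_t] + drift_slope*(t - block_start) + N(0, noise_sd)``
    with ``w_g``/``W_c`` unit-norm patterns scaled by ``signal_gain_g`` /
    ``signal_gain_cat``.  Pupil: pre-stimulus diameter level is
    ``pupil_gain*g_t`` plus white noise, with square blink drops inserted at
    ``blink_rate`` per minute.
    """

    b0: float = -0.8
    b_real: float = 0.4
    b_g: float = 0.7
    b_match: float = 1.2
    b_match_scr: float | None = -0.9
    b_prev_yes: float = 0.0
    latent_ar1: float = 0.0
    p_correct_recognized: float = 0.865
    p_correct_unrecognized_real: float = 0.401
    p_correct_scrambled_recognized: float = 0.519
    p_correct_scrambled_unrecognized: float = 0.316
    report_bias_strength: float = 0.15
    signal_gain_g: float = 0.16
    signal_gain_cat: float = 1.0
    pattern_overlap: float = 0.0
    drift_slope: float = 0.005
    noise_sd: float = 1.0
    pupil_gain: float = 1.0
    pupil_noise_sd: float = 0.1
    blink_rate: float = 4.0
    blink_depth: float = 5.0
    blink_duration: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "p_correct_recognized",
            "p_correct_unrecognized_real",
            "p_correct_scrambled_recognized",
            "p_correct_scrambled_unrecognized",
            "report_bias_strength",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"GeneratorParams.{name}={value} outside [0, 1]")
        if self.noise_sd < 0 or self.pupil_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not -1.0 < self.latent_ar1 < 1.0:
            raise ValueError("latent_ar1 must lie in (-1, 1)")

    @property
    def match_coefficient_scrambled(self) -> float:
        return -self.b_match if self.b_match_scr is None else self.b_match_scr


@dataclass
class LatentStates:
    """Per-trial latent processes planted by the generator."""

    g: np.ndarray
    preferred_category: np.ndarray
    match: np.ndarray
    report_bias_category: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.g.size


@dataclass
class Session:
    """One complete synthetic session plus its ground truth."""

    trials: pd.DataFrame
    latents: LatentStates
    epochs: EpochSet
    pupil: PupilTrace | None
    w_g: np.ndarray
    W_c: np.ndarray
    spec: DesignSpec
    params: GeneratorParams
    seed: int


def _truncated_exponential(rng: np.random.Generator, lo: float, hi: float,
                           scale: float, size: int) -> np.ndarray:
    """Exponential(scale) truncated to [lo, hi] by inverse-CDF sampling."""
    u = rng.random(size)
    z = 1.0 - math.exp(-(hi - lo) / scale)
    return lo - scale * np.log1p(-u * z)


def generate_design(spec: DesignSpec, seed: int | None = None) -> pd.DataFrame:
    """Build the trial table of one session, behavioral fields unset.

    Each unique image (real or scrambled) appears exactly ``spec.repeats``
    times; trial order is a seeded permutation.  Trials are split into
    ``spec.n_blocks`` consecutive blocks; when the trial count does not
    divide evenly, earlier blocks receive one extra trial.

    Returns a DataFrame with columns ``trial_index, block, image_id,
    objective_category, is_real, prestim_onset, recognition_report,
    category_report`` (the last two filled with NA).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    image_ids: list[str] = []
    categories: list[str] = []
    real_flags: list[bool] = []
    for cat in spec.categories:
        for i in range(spec.images_per_category):
            image_ids.append(f"{cat}_real{i}")
            categories.append(cat)
            real_flags.append(True)
        for i in range(spec.scrambled_per_category):
            image_ids.append(f"{cat}_scr{i}")
            categories.append(cat)
            real_flags.append(False)

    order = rng.permutation(np.repeat(np.arange(len(image_ids)), spec.repeats))
    n = order.size

    base, extra = divmod(n, spec.n_blocks)
    block_sizes = [base + (1 if b < extra else 0) for b in range(spec.n_blocks)]
    block = np.repeat(np.arange(spec.n_blocks), block_sizes)

    iti = _truncated_exponential(rng, *spec.iti_range, scale=1.5, size=n)
    post = _truncated_exponential(rng, *spec.post_range, scale=1.0, size=n)
    onsets = np.empty(n)
    cursor = spec.prestim_duration  # leave room for the first epoch
    for t in range(n):
        if t > 0 and block[t] != block[t - 1]:
            cursor += 5.0  # self-paced break between blocks
        onsets[t] = cursor + iti[t]
        cursor = onsets[t] + spec.stimulus_duration + post[t] + spec.response_duration

    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "block": block,
            "image_id": [image_ids[i] for i in order],
            "objective_category": pd.Categorical(
                [categories[i] for i in order], categories=list(spec.categories)
            ),
            "is_real": np.array([real_flags[i] for i in order]),
            "prestim_onset": onsets,
            "recognition_report": pd.array([pd.NA] * n, dtype="string"),
            "category_report": pd.array([pd.NA] * n, dtype="string"),
        }
    )


def simulate_latents(design: pd.DataFrame, params: GeneratorParams,
                     seed: int = 0) -> LatentStates:
    """Draw the per-trial latent processes.

    ``g`` is standard normal (optionally AR(1) across trials with
    coefficient ``params.latent_ar1`` and unit marginal variance); the
    preferred category is uniform over the categories present in the
    design, independently of the objective category.
    """
    rng = np.random.default_rng(seed)
    n = len(design)
    eps = rng.standard_normal(n)
    rho = params.latent_ar1
    if rho == 0.0:
        g = eps
    else:
        g = np.empty(n)
        g[0] = eps[0]
        scale = math.sqrt(1.0 - rho**2)
        for t in range(1, n):
            g[t] = rho * g[t - 1] + scale * eps[t]
    cats = np.asarray(design["objective_category"].cat.categories)
    preferred = rng.choice(cats, size=n)
    objective = design["objective_category"].to_numpy(dtype=object)
    match = preferred == objective
    return LatentStates(
        g=g,
        preferred_category=preferred,
        match=match,
        report_bias_category=preferred.copy(),
    )


def make_patterns(n_sensors: int, n_categories: int,
                  rng: np.random.Generator, overlap: float = 0.0):
    """Unit-norm sensor patterns for the latents.

    Returns ``(w_g, W_c)`` with ``w_g`` of shape ``(n_sensors,)`` and
    ``W_c`` of shape ``(n_categories, n_sensors)``.  With ``overlap = 0``
    (default) all patterns are mutually orthonormal; a positive ``overlap``
    mixes in a shared component so every pair has cosine similarity
    ``overlap``, making the general and specific signals less separable.
    """
    if n_categories + 2 > n_sensors:
        raise ValueError("need n_sensors > n_categories + 1 for independent patterns")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    raw = rng.standard_normal((n_sensors, n_categories + 2))
    q, _ = np.linalg.qr(raw)
    shared, vecs = q[:, 0], q[:, 1:].T
    mixed = math.sqrt(overlap) * shared + math.sqrt(1.0 - overlap) * vecs
    mixed /= np.linalg.norm(mixed, axis=1, keepdims=True)
    return mixed[0], mixed[1:]


def simulate_epochs(design: pd.DataFrame, latents: LatentStates,
                    params: GeneratorParams, spec: DesignSpec,
                    seed: int = 0, w_g: np.ndarray | None = None,
                    W_c: np.ndarray | None = None) -> EpochSet:
    """Render pre-stimulus sensor epochs expressing the latent states.

    Each sample of trial *t* equals ``w_g*g_t + W_c[pref_t]`` plus a linear
    block drift (``drift_slope`` per second, clock restarting at each block
    start) and i.i.d. Gaussian sensor noise.
    """
    rng = np.random.default_rng(seed)
    if latents.n_trials != len(design):
        raise ValueError("latents are not aligned to the design")
    if w_g is None or W_c is None:
        gen_w, gen_W = make_patterns(
            spec.n_sensors, spec.n_categories, rng, params.pattern_overlap
        )
        w_g = gen_w if w_g is None else w_g
        W_c = gen_W if W_c is None else W_c
    w_g = np.asarray(w_g, dtype=float)
    W_c = np.asarray(W_c, dtype=float)
    if w_g.shape != (spec.n_sensors,) or W_c.shape != (spec.n_categories, spec.n_sensors):
        raise ValueError(
            f"pattern dimensions {w_g.shape}/{W_c.shape} do not match "
            f"{spec.n_sensors} sensors and {spec.n_categories} categories"
        )

    n = len(design)
    n_samples = int(round(spec.prestim_duration * spec.sampling_rate))
    cat_index = design["objective_category"].cat.categories.get_indexer(
        latents.preferred_category
    )
    signal = (
        params.signal_gain_g * np.outer(latents.g, w_g)
        + params.signal_gain_cat * W_c[cat_index]
    )  # (n, sensors)
    values = np.repeat(signal[:, :, None], n_samples, axis=2)

    onsets = design["prestim_onset"].to_numpy()
    block = design["block"].to_numpy()
    if params.drift_slope != 0.0:
        rel = np.arange(n_samples) / spec.sampling_rate
        for b in np.unique(block):
            sel = block == b
            start = onsets[sel].min() - spec.prestim_duration
            t_abs = (onsets[sel, None] - spec.prestim_duration + rel[None, :]) - start
            values[sel] += params.drift_slope * t_abs[:, None, :]
    if params.noise_sd > 0:
        values += params.noise_sd * rng.standard_normal(values.shape)

    return EpochSet(
        values=values,
        sampling_rate=spec.sampling_rate,
        window=spec.prestim_duration,
        block=block,
        onsets=onsets,
    )


def _report_categories(rng: np.random.Generator, objective: np.ndarray,
                       bias_cat: np.ndarray, p_target: np.ndarray,
                       beta: float, categories: np.ndarray) -> np.ndarray:
    """Category reports: preference capture with prob. beta, else correct
    with a compensated probability, else uniform over the other categories.

    The compensation keeps the marginal accuracy at ``p_target`` given that
    the bias category matches the objective one with probability 1/K.
    """
    k = categories.size
    p_adj = (p_target - beta / k) / (1.0 - beta)
    if np.any(p_adj < 0) or np.any(p_adj > 1):
        raise ValueError(
            "report_bias_strength incompatible with target accuracy: "
            "compensated correct-report probability falls outside [0, 1]"
        )
    n = objective.size
    u = rng.random(n)
    captured = u < beta
    correct = ~captured & (u < beta + (1.0 - beta) * p_adj)
    reports = np.empty(n, dtype=object)
    reports[captured] = bias_cat[captured]
    reports[correct] = objective[correct]
    rest = ~captured & ~correct
    if np.any(rest):
        # uniform guess among the k-1 non-objective categories
        offsets = rng.integers(1, k, size=int(rest.sum()))
        order = {c: i for i, c in enumerate(categories)}
        obj_idx = np.array([order[c] for c in objective[rest]])
        reports[rest] = categories[(obj_idx + offsets) % k]
    return reports


def simulate_behavior(design: pd.DataFrame, latents: LatentStates,
                      params: GeneratorParams, seed: int = 0) -> pd.DataFrame:
    """Fill recognition and category reports of the trial table.

    Recognition is Bernoulli under the probit model described in
    :class:`GeneratorParams` (plus an optional previous-report history term
    ``b_prev_yes`` on the evidence axis).  Category reports follow the stratum-specific accuracy
    targets, with residual reports biased toward the trial's latent
    preference.
    """
    rng = np.random.default_rng(seed)
    if latents.n_trials != len(design):
        raise ValueError("latents are not aligned to the design")
    trials = design.copy()
    is_real = trials["is_real"].to_numpy(dtype=bool)
    match = latents.match.astype(float)
    evidence = (
        params.b0
        + params.b_real * is_real
        + params.b_g * latents.g
        + np.where(is_real, params.b_match, params.match_coefficient_scrambled) * match
    )
    u = rng.random(len(trials))
    if params.b_prev_yes == 0.0:
        yes = u < ndtr(evidence)
    else:
        yes = np.zeros(len(trials), dtype=bool)
        prev = 0.0
        for t in range(len(trials)):
            yes[t] = u[t] < ndtr(evidence[t] + params.b_prev_yes * prev)
            prev = 1.0 if yes[t] else 0.0

    objective = trials["objective_category"].to_numpy(dtype=object)
    categories = np.asarray(trials["objective_category"].cat.categories)
    p_target = np.where(
        is_real,
        np.where(yes, params.p_correct_recognized, params.p_correct_unrecognized_real),
        np.where(
            yes,
            params.p_correct_scrambled_recognized,
            params.p_correct_scrambled_unrecognized,
        ),
    )
    reports = _report_categories(
        rng,
        objective,
        latents.report_bias_category,
        p_target,
        params.report_bias_strength,
        categories,
    )
    trials["recognition_report"] = pd.array(
        np.where(yes, "yes", "no"), dtype="string"
    )
    trials["category_report"] = pd.array(reports.astype(str), dtype="string")
    return trials


def simulate_pupil(design: pd.DataFrame, latents: LatentStates,
                   params: GeneratorParams, spec: DesignSpec,
                   seed: int = 0) -> PupilTrace:
    """Render a continuous pupil trace coupled to the general latent.

    The diameter holds the level ``pupil_gain * g_t`` throughout the
    pre-stimulus window of trial *t* (so the window mean is exact in the
    noiseless limit) and interpolates linearly between trials.  White
    measurement noise and square blink drops (depth ``blink_depth``,
    duration ``blink_duration``, ``blink_rate`` events per minute) are
    added on top.
    """
    rng = np.random.default_rng(seed)
    fs = spec.pupil_sampling_rate
    onsets = design["prestim_onset"].to_numpy()
    t_end = onsets[-1] + spec.stimulus_duration + 2.0
    n_samples = int(round(t_end * fs)) + 1
    t = np.arange(n_samples) / fs

    levels = params.pupil_gain * latents.g
    anchor_t = np.empty(2 * onsets.size)
    anchor_v = np.empty(2 * onsets.size)
    anchor_t[0::2] = onsets - spec.prestim_duration
    anchor_t[1::2] = onsets + spec.stimulus_duration
    anchor_v[0::2] = levels
    anchor_v[1::2] = levels
    diameter = np.interp(t, anchor_t, anchor_v)

    if params.pupil_noise_sd > 0:
        diameter = diameter + params.pupil_noise_sd * rng.standard_normal(n_samples)

    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * t_end / 60.0)
        starts = rng.uniform(0.0, t_end - params.blink_duration, size=n_blinks)
        width = max(int(round(params.blink_duration * fs)), 1)
        for s in starts:
            i0 = int(round(s * fs))
            diameter[i0 : i0 + width] -= params.blink_depth
    return PupilTrace(
        diameter=diameter,
        sampling_rate=fs,
        onsets=onsets,
        stimulus_duration=spec.stimulus_duration,
    )


def simulate_session(spec: DesignSpec | None = None,
                     params: GeneratorParams | None = None,
                     seed: int = 0, with_pupil: bool = True) -> Session:
    """Generate one full session (design, latents, epochs, behavior, pupil).

    All randomness derives from ``seed`` through independent child streams,
    so the same seed reproduces the session bit for bit.  ``with_pupil=False``
    skips rendering the pupil trace (the other streams are unaffected); the
    ``pupil`` field is then ``None``.
    """
    spec = spec or DesignSpec()
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    s_design, s_latent, s_epochs, s_behav, s_pupil = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    design = generate_design(spec, seed=s_design)
    latents = simulate_latents(design, params, seed=s_latent)
    pattern_rng = np.random.default_rng(s_epochs)
    w_g, W_c = make_patterns(
        spec.n_sensors, spec.n_categories, pattern_rng, params.pattern_overlap
    )
    epochs = simulate_epochs(
        design, latents, params, spec, seed=s_epochs + 1, w_g=w_g, W_c=W_c
    )
    trials = simulate_behavior(design, latents, params, seed=s_behav)
    pupil = (simulate_pupil(design, latents, params, spec, seed=s_pupil)
             if with_pupil else None)
    return Session(
        trials=trials,
        latents=latents,
        epochs=epochs,
        pupil=pupil,
        w_g=w_g,
        W_c=W_c,
        spec=spec,
        params=params,
        seed=seed,
    )


def simulate_experiment(n_subjects: int, spec: DesignSpec | None = None,
                        params: GeneratorParams | None = None,
                        seed: int = 0,
                        between_subject_b0_sd: float = 0.25,
                        with_pupil: bool = True) -> list[Session]:
    """Generate a cohort of subjects.

    Each subject gets an independent session seed and their own sensor
    patterns; the recognition intercept ``b0`` is jittered across subjects
    (s.d. ``between_subject_b0_sd``) to emulate individual criterion
    differences.
    """
    spec = spec or DesignSpec()
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    sessions = []
    for child in children:
        subj_params = replace(
            params, b0=params.b0 + between_subject_b0_sd * rng.standard_normal()
        )
        sessions.append(
            simulate_session(
                spec, subj_params, seed=int(child.generate_state(1)[0] % (2**31)),
                with_pupil=with_pupil,
            )
        )
    return sessions
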