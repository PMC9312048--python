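"""Synthetic sinus outlines and simulated observer measurements.

The generator emulates the morphology an eligible frontal sinus shows in a
posterior-anterior radiograph: a bilobed, scalloped ("arcaded") arc rising
above the supraorbital baseline, spanning the midline with the two lobes
touching. Each lobe is a smooth Gaussian envelope; arcades are raised-cosine
bumps added on top; a window pins the arc to the baseline termini and keeps
it strictly above the baseline in between, which guarantees eligibility and
that every ray of the fan crosses the arc.

Observer noise is Gaussian and independent per line: angle-placement noise
(degrees), line-length noise (as a fraction of the baseline length), and an
origin-placement jitter along the baseline (mm, one draw per measurement
event). Per-mode defaults encode the expectation that a freehand protocol is
noisier than an overlay-guided one, which in turn is noisier than a
semi-automated one; the magnitudes are package defaults, not measured
quantities (see docs/methods.md).

A single integer seed fans out to independent per-component streams via
``numpy.random.SeedSequence`` so that outline generation and each simulated
measurement event are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError
from .error_stats import ErrorRecord, StudyDataset
from .geometry import (BaselineSpec, OriginSpec, Point2D, SinusOutline, SinusProfile,
                       cast_ray, check_eligibility, measure_profile, ray_angles)
from .identification import rank_candidates, standardize_profile

DEFAULT_N_VERTICES = 241


@dataclass(frozen=True)
class OutlineParams:
    """Population-level shape parameters of the synthetic sinus.

    baseline_width : total supraorbital baseline length B, mm
    lobe_heights : (left, right) mean lobe apex heights above the baseline, mm
    n_arcades : scallop count per lobe
    arcade_amplitude : scallop bump height, mm
    asymmetry : fractional left/right height imbalance
    jitter : relative sd of the per-individual variation applied to the above
    """

    baseline_width: float = 60.0
    lobe_heights: tuple = (24.0, 27.0)
    n_arcades: int = 3
    arcade_amplitude: float = 3.0
    asymmetry: float = 0.1
    jitter: float = 0.15

    def __post_init__(self) -> None:
        if self.baseline_width <= 0 or min(self.lobe_heights) <= 0:
            raise ConfigurationError("baseline width and lobe heights must be positive")
        if self.n_arcades < 1:
            raise ConfigurationError("need at least one arcade per lobe")
        if self.arcade_amplitude < 0:
            raise ConfigurationError("arcade amplitude must be nonnegative")


@dataclass(frozen=True)
class NoiseModel:
    """Observer-noise magnitudes for one collection mode."""

    sigma_angle: float = 0.0       # degrees, per line
    sigma_length: float = 0.0      # fraction of baseline length, per line
    sigma_origin: float = 0.0      # mm along the baseline, per event
    mode_label: str = "custom"

    def __post_init__(self) -> None:
        if min(self.sigma_angle, self.sigma_length, self.sigma_origin) < 0:
            raise ConfigurationError("noise sds must be nonnegative")

    @classmethod
    def for_mode(cls, mode: str) -> "NoiseModel":
        try:
            return _MODE_NOISE[mode]
        except KeyError:
            raise ConfigurationError(f"unknown mode {mode!r}; expected one of {list(_MODE_NOISE)}")

    @classmethod
    def zero(cls, mode_label: str = "noiseless") -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, mode_label)


# package defaults; freehand > overlay > semi_auto in every component
_MODE_NOISE = {
    "freehand": NoiseModel(0.8, 0.015, 0.8, "freehand"),
    "overlay": NoiseModel(0.3, 0.008, 0.5, "overlay"),
    "semi_auto": NoiseModel(0.2, 0.005, 0.3, "semi_auto"),
}

# study design: (observer, round) per measurement event
DEFAULT_EVENTS = ((1, 1), (1, 2), (2, 1))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_outline(params: OutlineParams | None = None, seed=0,
                     n_vertices: int = DEFAULT_N_VERTICES,
                     outline_id: str | None = None
                     ) -> tuple[SinusOutline, BaselineSpec, OriginSpec]:
    """Draw one eligible synthetic sinus outline.

    Individual variation (lobe heights, centres, widths, arcade phase and
    count, midline-ratio placement) is sampled around ``params`` from the
    seeded stream, so the same seed reproduces the same vertices bit for bit.
    """
    if params is None:
        params = OutlineParams()
    rng = _as_rng(seed)
    j = params.jitter

    W = params.baseline_width * (1.0 + 0.10 * j / 0.15 * rng.normal())
    W = float(np.clip(W, 0.5 * params.baseline_width, 1.5 * params.baseline_width))
    hL = params.lobe_heights[0] * float(np.exp(j * rng.normal()))
    hR = params.lobe_heights[1] * float(np.exp(j * rng.normal()))
    hR *= 1.0 + params.asymmetry * rng.normal()
    hR = abs(hR) + 1e-3
    cL = W * (0.27 + 0.04 * rng.normal())
    cR = W * (0.73 + 0.04 * rng.normal())
    wL = W * (0.30 + 0.04 * rng.normal())
    wR = W * (0.30 + 0.04 * rng.normal())
    wL, wR = abs(wL) + 1e-3, abs(wR) + 1e-3
    n_arc = max(1, params.n_arcades + int(rng.integers(-1, 2)))
    amp = params.arcade_amplitude * float(np.exp(j * rng.normal()))
    phase = float(rng.uniform(0.0, np.pi))
    # midline placement: slightly image-right of centre on average
    r = float(np.clip(rng.normal(0.52, 0.02), 0.40, 0.60))

    x = np.linspace(0.0, W, n_vertices)
    envelope = (hL * np.exp(-(((x - cL) / wL) ** 2))
                + hR * np.exp(-(((x - cR) / wR) ** 2)))
    arcades = amp * np.sin(np.pi * (2 * n_arc) * x / W + phase) ** 2
    window = np.clip(np.sin(np.pi * x / W), 0.0, None) ** 0.3
    y = (envelope + arcades) * window
    y[0] = 0.0
    y[-1] = 0.0

    if outline_id is None:
        outline_id = f"synthetic-{seed}" if isinstance(seed, int) else "synthetic"
    outline = SinusOutline.from_coords(np.column_stack([x, y]), id=outline_id)
    baseline = BaselineSpec(Point2D(0.0, 0.0), Point2D(W, 0.0))
    origin = OriginSpec.from_origin(Point2D(W * (1.0 - r), 0.0), baseline)
    report = check_eligibility(outline, baseline, origin)
    if not report:
        raise GeometryError("generated outline is ineligible: " + "; ".join(report.messages))
    return outline, baseline, origin


def simulate_observer(outline: SinusOutline, baseline: BaselineSpec, origin: OriginSpec,
                      noise: NoiseModel, seed, *,
                      image_id: str | None = None, observer: int = 1, round: int = 1,
                      angles: Sequence[float] | None = None
                      ) -> tuple[SinusProfile, list[ErrorRecord]]:
    """Simulate one measurement event of an outline by a noisy observer.

    The expected (ground-truth) values are the noiseless profile from the
    true origin at the nominal angles. The observer jitters the origin along
    the baseline once per event, places each ray at nominal + N(0,
    sigma_angle^2) degrees, and reads a length equal to the true ray length
    at the placed angle plus N(0, (sigma_length * B)^2) mm.
    """
    rng = _as_rng(seed)
    if angles is None:
        angles = ray_angles()
    if image_id is None:
        image_id = outline.id
    B = baseline.length_B
    truth = measure_profile(outline, baseline, origin, angles=angles)

    shift = rng.normal(0.0, noise.sigma_origin) if noise.sigma_origin > 0 else 0.0
    d = baseline.direction
    ox = origin.origin.as_array() + shift * d
    # keep the jittered origin strictly between the termini
    rb = float(np.linalg.norm(baseline.right_terminus.as_array() - ox))
    rb = float(np.clip(rb, 1e-3 * B, (1.0 - 1e-3) * B))
    obs_origin_pt = Point2D(*(baseline.right_terminus.as_array() - rb * d))
    obs_origin = OriginSpec.from_origin(obs_origin_pt, baseline)
    datum = (baseline.right_terminus.as_array() - obs_origin_pt.as_array())
    datum = datum / np.linalg.norm(datum)

    records: list[ErrorRecord] = []
    measurements = []
    for m in truth.measurements:
        theta = m.angle_theta
        obs_theta = theta + (rng.normal(0.0, noise.sigma_angle) if noise.sigma_angle > 0 else 0.0)
        obs_theta = float(np.clip(obs_theta, 1e-3, 180.0 - 1e-3))
        ray = cast_ray(obs_origin_pt, obs_theta, outline, datum=datum)
        obs_len = ray.line_length_L
        if noise.sigma_length > 0:
            obs_len += rng.normal(0.0, noise.sigma_length * B)
        obs_len = max(obs_len, 0.0)
        records.append(ErrorRecord(
            image_id=image_id, mode=noise.mode_label, observer=observer, round=round,
            angle_theta=theta,
            observed_angle=obs_theta, expected_angle=theta,
            observed_length=obs_len, expected_length=m.line_length_L))
        measurements.append(replace(ray, angle_theta=theta, line_length_L=obs_len))

    profile = SinusProfile(outline_id=image_id, baseline=baseline, origin=obs_origin,
                           measurements=tuple(measurements), area=truth.area)
    return profile, records


def simulate_study(n_images: int = 10, modes: Sequence[str] = ("freehand", "overlay", "semi_auto"),
                   events: Sequence[tuple] = DEFAULT_EVENTS,
                   noise_models: dict | None = None, seed=0,
                   params: OutlineParams | None = None) -> StudyDataset:
    """Simulate the full study design: n_images x modes x events, 59 lines each.

    The default design (10 images, 3 modes, 3 events: observer 1 round 1,
    observer 1 round 2, observer 2 round 1) yields 5310 per-line records.
    Midline-ratio observations (one per image x mode x event) are collected
    alongside as summary points.
    """
    if n_images < 0:
        raise ConfigurationError("n_images must be nonnegative")
    if noise_models is None:
        noise_models = {m: NoiseModel.for_mode(m) for m in modes}
    ss = np.random.SeedSequence(_seed_entropy(seed))
    image_seeds = ss.spawn(n_images)
    records: list[ErrorRecord] = []
    summary_rows = []
    for i, img_ss in enumerate(image_seeds):
        outline_rng = np.random.default_rng(img_ss.spawn(1)[0])
        outline, baseline, origin = generate_outline(params, seed=outline_rng,
                                                     outline_id=f"img{i:03d}")
        for mode in modes:
            for (observer, rnd) in events:
                event_rng = np.random.default_rng(img_ss.spawn(1)[0])
                _profile, recs = simulate_observer(
                    outline, baseline, origin, noise_models[mode], event_rng,
                    image_id=f"img{i:03d}", observer=observer, round=rnd)
                records.extend(recs)
                summary_rows.append({
                    "image_id": f"img{i:03d}", "mode": mode,
                    "observer": observer, "round": rnd,
                    "midline_ratio_observed": _profile.origin.midline_ratio_r,
                    "midline_ratio_expected": origin.midline_ratio_r,
                })
    summaries = pd.DataFrame(summary_rows, columns=[
        "image_id", "mode", "observer", "round",
        "midline_ratio_observed", "midline_ratio_expected"])
    return StudyDataset(records=tuple(records), summaries=summaries)


def simulate_identification(n_individuals: int = 20,
                            noise: NoiseModel | None = None, seed=0,
                            params: OutlineParams | None = None) -> float:
    """Desk-scale antemortem/postmortem matching experiment; returns the hit rate in %.

    Generates ``n_individuals`` distinct outlines as the antemortem array,
    re-measures each with observer noise as the postmortem record, ranks every
    postmortem profile against all antemortem candidates by Total Difference,
    and reports the percentage whose true source ranks first.
    """
    if n_individuals < 2:
        raise ConfigurationError("need at least 2 individuals for an identification test")
    if noise is None:
        noise = NoiseModel(sigma_angle=0.2, sigma_length=0.01, sigma_origin=0.0,
                           mode_label="identification")
    ss = np.random.SeedSequence(_seed_entropy(seed))
    am_profiles = []
    truths = []
    for i, child in enumerate(ss.spawn(n_individuals)):
        rng = np.random.default_rng(child.spawn(1)[0])
        outline, baseline, origin = generate_outline(params, seed=rng,
                                                     outline_id=f"indiv{i:03d}")
        truths.append((outline, baseline, origin, child))
        am_profiles.append(standardize_profile(measure_profile(outline, baseline, origin)))

    hits = 0
    for i, (outline, baseline, origin, child) in enumerate(truths):
        pm_rng = np.random.default_rng(child.spawn(1)[0])
        pm_profile, _ = simulate_observer(outline, baseline, origin, noise, pm_rng,
                                          image_id=f"pm{i:03d}")
        ranking = rank_candidates(standardize_profile(pm_profile), am_profiles)
        if ranking[0].id_B == f"indiv{i:03d}":
            hits += 1
    return 100.0 * hits / n_individuals


def _seed_entropy(seed):
    if isinstance(seed, np.random.SeedSequence):
        return seed.entropy
    return int(seed)
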