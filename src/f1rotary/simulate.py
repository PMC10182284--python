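"""Synthetic rotary traces and Michaelis-Menten rate datasets.

The generator emulates the statistical structure that the change-point
analysis assumes: a motor that steps through an ordered set of pauses per
120-degree repeat (three repeats per turn), waits at each pause for an
exponentially distributed dwell, and jumps instantaneously to the next
pause.  The camera observes the current pause angle plus white Gaussian
angular noise at a fixed frame rate.  Dwells shorter than one frame period
are allowed and may leave zero samples, so a downstream detector must
tolerate skipped pauses — this mimics why very short dwells are not
observable at some recording conditions.

Presets encode the pause geometry of the three genuine motors studied in
hybrid-F1 experiments:

* ``tf1_saturating`` — six-stepper: catalytic (main) dwells at 80 degrees
  per repeat, a brief temperature-sensitive dwell at 0, i.e. pauses at
  0, 80, 120, 200, 240 and 320 degrees per turn.
* ``bmf1_saturating`` — nine-stepper observed as six pauses at substrate
  saturation: main catalytic dwells with a short dwell midway between
  successive catalytic angles.
* ``pdf1_saturating`` — three-stepper: binding and catalytic waits share
  one angle, so a single pause per repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import RotaryTrace

__all__ = [
    "Pause",
    "MotorScheme",
    "MMGround",
    "simulate_trace",
    "simulate_mm_dataset",
    "xy_from_angle",
    "tf1_saturating",
    "bmf1_saturating",
    "pdf1_saturating",
]

DWELL_CLASSES = ("binding", "catalytic", "short", "TS")


@dataclass(frozen=True)
class Pause:
    """One pause of the stepping scheme within a 120-degree repeat."""

    offset: float  # degrees in [0, 120)
    mean_dwell: float  # seconds
    dwell_class: str = "catalytic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.offset < 120.0:
            raise ValueError("pause offset must lie in [0, 120)")
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be positive")
        if self.dwell_class not in DWELL_CLASSES:
            raise ValueError(f"dwell_class must be one of {DWELL_CLASSES}")


@dataclass(frozen=True)
class MotorScheme:
    """Generative stepping scheme: ordered pauses per 120-degree repeat.

    ``noise_sd`` is the per-frame Gaussian angular noise in degrees,
    modelling the localization error of the rotary probe.
    """

    pauses: tuple[Pause, ...]
    noise_sd: float = 8.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 1 <= len(self.pauses) <= 3:
            raise ValueError("a scheme has 1 to 3 pauses per 120-degree repeat")
        offs = [p.offset for p in self.pauses]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("pause offsets must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def mean_turn_time(self) -> float:
        """Expected time per 360-degree turn (renewal-process mean)."""
        return 3.0 * sum(p.mean_dwell for p in self.pauses)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "noise_sd": self.noise_sd,
            "pauses": [
                {"offset": p.offset, "mean_dwell": p.mean_dwell, "dwell_class": p.dwell_class}
                for p in self.pauses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotorScheme":
        return cls(
            pauses=tuple(Pause(**p) for p in d["pauses"]),
            noise_sd=d.get("noise_sd", 8.0),
            name=d.get("name", "custom"),
        )


def tf1_saturating(noise_sd: float = 8.0) -> MotorScheme:
    """TF1 at substrate saturation: catalytic dwell ~10 ms at 80 degrees,
    temperature-sensitive dwell ~0.6 ms at the binding angle (0 degrees)."""
    return MotorScheme(
        pauses=(Pause(0.0, 0.6e-3, "TS"), Pause(80.0, 10e-3, "catalytic")),
        noise_sd=noise_sd,
        name="TF1-saturating",
    )


def bmf1_saturating(noise_sd: float = 8.0) -> MotorScheme:
    """bMF1 at saturating ATPgammaS: catalytic dwell ~10 ms with the short
    dwell (~1.0 ms) midway between successive catalytic angles."""
    return MotorScheme(
        pauses=(Pause(0.0, 10e-3, "catalytic"), Pause(60.0, 1.0e-3, "short")),
        noise_sd=noise_sd,
        name="bMF1-saturating",
    )


def pdf1_saturating(noise_sd: float = 8.0) -> MotorScheme:
    """PdF1: binding and catalytic waits at the same angle — one pause per
    repeat, i.e. a three-stepper."""
    return MotorScheme(
        pauses=(Pause(0.0, 10e-3, "binding"),),
        noise_sd=noise_sd,
        name="PdF1-saturating",
    )


def simulate_trace(
    scheme: MotorScheme,
    duration: float,
    fps: float = 10_000.0,
    seed: int = 0,
    return_truth: bool = False,
):
    """Simulate a stepping rotary trace.

    The latent process visits the scheme's pauses in cyclic order; repeat
    ``k`` contributes absolute angles ``offset + 120 k``, continuing across
    turns.  Dwell durations are independent Exponential(mean_dwell) draws,
    transitions are instantaneous, and each frame observes the current
    pause angle plus Gaussian(0, noise_sd) noise.  Identical seeds give
    bit-identical traces.

    Parameters
    ----------
    scheme : MotorScheme
    duration : float
        Trace length in seconds.
    fps : float
        Frames per second (camera rate).
    seed : int
        Seed for the dwell and noise random streams.
    return_truth : bool
        If True, also return a DataFrame of the latent dwells
        (columns start_s, end_s, angle_deg, dwell_class); first and last
        dwells are censored by the observation window.

    Returns
    -------
    RotaryTrace, or (RotaryTrace, DataFrame) when ``return_truth``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration * fps))
    if n_frames < 10:
        raise ValueError("duration * fps must be at least 10 frames")
    rng = np.random.default_rng(seed)

    means = np.array([p.mean_dwell for p in scheme.pauses])
    offsets = np.array([p.offset for p in scheme.pauses])
    classes = [p.dwell_class for p in scheme.pauses]
    k = len(means)

    # draw dwells in blocks until the latent timeline covers the trace
    starts: list[np.ndarray] = []
    durs: list[np.ndarray] = []
    t_cursor = 0.0
    block_repeats = max(16, int(np.ceil(duration / scheme.mean_turn_time * 0.5)) * 3)
    while t_cursor < duration:
        d = rng.exponential(means, size=(block_repeats, k)).ravel()
        s = t_cursor + np.concatenate(([0.0], np.cumsum(d)[:-1]))
        starts.append(s)
        durs.append(d)
        t_cursor = s[-1] + d[-1]
    start_t = np.concatenate(starts)
    dur_t = np.concatenate(durs)
    n_dwell = start_t.size
    repeat_idx = np.arange(n_dwell) // k
    within = np.arange(n_dwell) % k
    latent_angle = offsets[within] + 120.0 * repeat_idx

    frame_t = np.arange(n_frames) / fps
    # frame i sits in the dwell whose start is the last one <= t
    idx = np.searchsorted(start_t, frame_t, side="right") - 1
    angle = latent_angle[idx]
    if scheme.noise_sd > 0:
        angle = angle + rng.normal(0.0, scheme.noise_sd, size=n_frames)

    trace = RotaryTrace(
        time=frame_t,
        angle=angle,
        fps=fps,
        meta={"scheme": scheme.to_dict(), "seed": seed, "duration_s": duration},
    )
    if not return_truth:
        return trace
    last = int(idx[-1])
    truth = pd.DataFrame(
        {
            "start_s": start_t[: last + 1],
            "end_s": start_t[: last + 1] + dur_t[: last + 1],
            "angle_deg": latent_angle[: last + 1],
            "dwell_class": [classes[i % k] for i in range(last + 1)],
        }
    )
    return trace, truth


@dataclass(frozen=True)
class MMGround:
    """Ground truth for a synthetic Michaelis-Menten rate dataset."""

    vmax: float  # rps
    km: float  # molar
    concentrations: tuple[float, ...]  # molar
    rate_noise_sd: float = 0.0  # rps
    n_per_conc: int = 1

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.rate_noise_sd < 0 or self.n_per_conc < 1:
            raise ValueError("invalid noise sd or replicate count")


def simulate_mm_dataset(ground: MMGround, seed: int = 0) -> pd.DataFrame:
    """Rates ``Vmax*S/(Km+S) + N(0, sd)`` truncated at 0, as a
    (conc_M, rate_rps) table with ``n_per_conc`` replicates per level."""
    rng = np.random.default_rng(seed)
    conc = np.repeat(np.asarray(ground.concentrations, dtype=float), ground.n_per_conc)
    rate = ground.vmax * conc / (ground.km + conc)
    if ground.rate_noise_sd > 0:
        rate = rate + rng.normal(0.0, ground.rate_noise_sd, size=conc.size)
    rate = np.maximum(rate, 0.0)
    return pd.DataFrame({"conc_M": conc, "rate_rps": rate})


def xy_from_angle(
    trace: RotaryTrace,
    radius: float = 1.0,
    localization_sd: float = 0.0,
    seed: int = 0,
) -> RotaryTrace:
    """Fill in probe centroids ``(r cos a + e, r sin a + e)`` with Gaussian
    localization noise ``e``; the inverse of angle extraction when sd = 0."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    rad = np.radians(trace.angle)
    x = radius * np.cos(rad)
    y = radius * np.sin(rad)
    if localization_sd > 0:
        x = x + rng.normal(0.0, localization_sd, size=x.size)
        y = y + rng.normal(0.0, localization_sd, size=y.size)
    return RotaryTrace(
        time=trace.time, angle=trace.angle, x=x, y=y, fps=trace.fps, meta=dict(trace.meta)
    )
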