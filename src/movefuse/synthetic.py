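"""Synthetic multi-axial strike simulator.

Real segmented strike ensembles show smooth multi-peaked per-channel
waveforms whose trial-to-trial differences are *non-linear variations*:
latency shifts of the peaks plus expansions/compressions of signal
segments, on top of amplitude noise and unequal segment durations.  The
generator emulates exactly that phenomenology:

- each class has one smooth template per channel (a sum of Gaussian
  bumps), with an inter-class separation control;
- each trial composes the template with a random strictly-increasing
  piecewise-linear time map (monotone segment expansion/compression),
  applies an integer latency shift with edge padding, adds Gaussian
  amplitude noise, and draws a jittered output duration;
- the time map (and shift, and duration) can be shared per channel, per
  sensor, or globally per trial — the three synchronization assumptions
  that distinguish the vector, local-matrix, and global-matrix/cuboid
  input models.

All randomness flows from a single master seed through numpy's
``SeedSequence`` spawning, so a configuration is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .signal_model import MovementRecording, UniaxialSignal

__all__ = ["SyntheticConfig", "make_class_templates", "apply_nonlinear_warp",
           "generate_dataset"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic ensemble.

    Defaults mirror a two-IMU strike setup: 2 sensors x 3 axes at 100 Hz,
    strikes of ~0.64 s (64 samples), templates of 3 Gaussian bumps per
    channel, and moderate non-linear variation (local warp slopes within
    +/-25%, latency shifts up to +/-10 samples, 10% duration jitter).
    ``noise_sigma`` is the additive amplitude noise relative to bump
    amplitudes of order 1.
    """

    n_classes: int = 8
    n_sensors: int = 2
    axes_per_sensor: int = 3
    base_duration: int = 64
    duration_jitter: float = 0.10
    n_bumps: int = 3
    amp_range: tuple[float, float] = (0.5, 2.0)
    width_range: tuple[float, float] = (0.04, 0.12)   # fraction of duration
    class_separation: float = 1.0
    warp_intensity: float = 0.25       # max local slope deviation of the warp
    shift_max: int = 10                # latency shift range, +/- samples
    noise_sigma: float = 0.8
    trials_per_class: int = 20
    warp_sharing: str = "sensor"       # "channel" | "sensor" | "global"
    n_warp_knots: int = 8
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("need >= 1 class")
        if not (0.0 <= self.warp_intensity < 1.0):
            raise ValueError("warp_intensity must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.warp_sharing not in ("channel", "sensor", "global"):
            raise ValueError("warp_sharing must be channel|sensor|global")

    @property
    def n_channels(self) -> int:
        return self.n_sensors * self.axes_per_sensor

    def to_dict(self) -> dict:
        return asdict(self)


def _bumps(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """A smooth waveform: sum of Gaussian bumps over [0, N0)."""
    n = cfg.base_duration
    t = np.arange(n)
    wave = np.zeros(n)
    for _ in range(cfg.n_bumps):
        amp = rng.uniform(*cfg.amp_range) * rng.choice([-1.0, 1.0])
        center = rng.uniform(0.15, 0.85) * n
        width = rng.uniform(*cfg.width_range) * n
        wave += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return wave


def make_class_templates(cfg: SyntheticConfig, seed: int | None = None) -> np.ndarray:
    """Per-class, per-channel smooth template waveforms, shape
    ``(H, M_G, N0)``.

    ``class_separation`` mixes a channel-common waveform with a fully
    class-specific one: at 0 all classes share identical templates, at 1
    they are independent draws (maximally separated in expectation).
    """
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence([seed, 0x7E4])
    rng = np.random.Generator(np.random.PCG64(ss))
    common = np.stack([_bumps(rng, cfg) for _ in range(cfg.n_channels)])
    s = cfg.class_separation
    out = np.empty((cfg.n_classes, cfg.n_channels, cfg.base_duration))
    for h in range(cfg.n_classes):
        specific = np.stack([_bumps(rng, cfg) for _ in range(cfg.n_channels)])
        out[h] = (1.0 - s) * common + s * specific
    return out


def _monotone_time_map(rng: np.random.Generator, n_knots: int,
                       warp_intensity: float) -> tuple[np.ndarray, np.ndarray]:
    """Random strictly-increasing piecewise-linear map of [0,1] onto [0,1]
    with fixed endpoints; local slopes drawn from [1-w, 1+w] and then
    renormalized, so slope deviations stay of order ``warp_intensity``."""
    x = np.linspace(0.0, 1.0, n_knots + 1)
    if warp_intensity == 0.0:
        return x, x   # identity map, detected downstream for exact sampling
    incr = rng.uniform(1.0 - warp_intensity, 1.0 + warp_intensity, size=n_knots)
    y = np.concatenate(([0.0], np.cumsum(incr)))
    y /= y[-1]
    assert np.all(np.diff(y) > 0), "warp map must be strictly increasing"
    return x, y


def apply_nonlinear_warp(
    waveform: np.ndarray,
    warp_intensity: float,
    shift_max: int,
    noise_sigma: float,
    rng: np.random.Generator | int,
    out_len: int | None = None,
    n_knots: int = 8,
    time_map: tuple[np.ndarray, np.ndarray] | None = None,
    shift: int | None = None,
) -> np.ndarray:
    """Corrupt a template the way trials differ from their class mean.

    Composes the waveform with a random monotone piecewise-linear time
    map (endpoints fixed), applies an integer latency shift with edge
    padding (no circular wrap), and adds Gaussian amplitude noise; the
    output duration ``out_len`` may differ from the input's.  A
    pre-drawn ``time_map``/``shift`` can be passed in so several channels
    share one realization (synchronized non-linear variations).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(rng))))
    waveform = np.asarray(waveform, dtype=float)
    n = waveform.size
    out_len = n if out_len is None else int(out_len)
    if time_map is None:
        time_map = _monotone_time_map(rng, n_knots, warp_intensity)
    if shift is None:
        shift = int(rng.integers(-shift_max, shift_max + 1)) if shift_max else 0
    kx, ky = time_map
    if ky is kx:  # identity map: sample on an exact uniform grid
        src = np.linspace(0.0, n - 1.0, out_len)
    else:
        u = np.linspace(0.0, 1.0, out_len)
        src = np.interp(u, kx, ky) * (n - 1)
    y = np.interp(src, np.arange(n), waveform)
    if shift:
        pad = np.empty(out_len)
        if shift > 0:
            pad[shift:] = y[:-shift]
            pad[:shift] = y[0]
        else:
            pad[:shift] = y[-shift:]
            pad[shift:] = y[-1]
        y = pad
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=out_len)
    return y


def generate_dataset(
    cfg: SyntheticConfig, templates: np.ndarray | None = None
) -> list[MovementRecording]:
    """Generate ``H * trials_per_class`` labelled recordings.

    Per trial, a warp realization (time map + latency shift + duration)
    is drawn per channel, per sensor, or once globally according to
    ``cfg.warp_sharing``; amplitude noise is always independent per
    channel.  Class labels are 1-based.
    """
    if templates is None:
        templates = make_class_templates(cfg)
    master = np.random.SeedSequence([cfg.seed, 0xDA7A])
    rng = np.random.Generator(np.random.PCG64(master))
    recs: list[MovementRecording] = []
    for h in range(cfg.n_classes):
        for trial in range(cfg.trials_per_class):
            groups: dict[int, tuple] = {}

            def draw_realization():
                tm = _monotone_time_map(rng, cfg.n_warp_knots, cfg.warp_intensity)
                shift = (int(rng.integers(-cfg.shift_max, cfg.shift_max + 1))
                         if cfg.shift_max else 0)
                if cfg.duration_jitter > 0:
                    factor = rng.uniform(1.0 - cfg.duration_jitter,
                                         1.0 + cfg.duration_jitter)
                    out_len = max(2, int(round(cfg.base_duration * factor)))
                else:
                    out_len = cfg.base_duration
                return tm, shift, out_len

            if cfg.warp_sharing == "global":
                shared = draw_realization()
            signals = []
            for g in range(cfg.n_sensors):
                if cfg.warp_sharing == "sensor":
                    groups[g] = draw_realization()
                for m in range(cfg.axes_per_sensor):
                    if cfg.warp_sharing == "global":
                        tm, shift, out_len = shared
                    elif cfg.warp_sharing == "sensor":
                        tm, shift, out_len = groups[g]
                    else:
                        tm, shift, out_len = draw_realization()
                    ch = g * cfg.axes_per_sensor + m
                    y = apply_nonlinear_warp(
                        templates[h, ch], cfg.warp_intensity, cfg.shift_max,
                        cfg.noise_sigma, rng, out_len=out_len,
                        n_knots=cfg.n_warp_knots, time_map=tm, shift=shift,
                    )
                    signals.append(UniaxialSignal(g, m, y, cfg.sample_rate))
            recs.append(MovementRecording(
                signals, label=h + 1,
                metadata={"class_name": f"class_{h + 1}", "trial": trial},
            ))
    return recs
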