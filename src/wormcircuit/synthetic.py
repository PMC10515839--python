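"""Synthetic-data generators with known ground truth.

Every downstream analysis in this package assumes a particular statistical
structure in its input; this module generates inputs with exactly that
structure so that parameter recovery can be tested against known truth:

* two-channel volumetric fluorescence movies in which a calcium-sensitive
  green channel and a calcium-insensitive red channel share one
  multiplicative artifact process and each decays by double-exponential
  photobleaching, plus an additive noise floor;
* reversal event trains (Poisson-like with a refractory gap);
* crawling worm tracks built from a piecewise-constant heading, sinusoidal
  body undulation, programmed dorsal turning bias and programmed reversals;
* per-division extrachromosomal-array loss over a lineage tree.

All randomness flows from one seed through named substreams (one substream
per generator operation), so partial pipelines are reproducible: the same
(config, seed) always yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DomainError, InvalidConfigError
from .events import EventTrain

__all__ = [
    "BleachParams",
    "ArtifactParams",
    "CalciumKernel",
    "TrackParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_event_train",
    "simulate_calcium_movie",
    "simulate_worm_track",
    "simulate_mosaic_population",
    "calcium_response",
    "double_exponential",
    "substream",
]

# Fixed substream codes: op name -> integer mixed with the user seed.
_STREAMS = {"events": 101, "movie": 202, "track": 303, "mosaic": 404}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named simulation operation."""
    if name not in _STREAMS:
        raise InvalidConfigError(f"unknown substream {name!r}")
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[name]])


def double_exponential(t: np.ndarray, a1: float, lam1: float, a2: float,
                       lam2: float) -> np.ndarray:
    """a1*exp(-lam1*t) + a2*exp(-lam2*t)."""
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t)


@dataclass(frozen=True)
class BleachParams:
    """Double-exponential photobleaching: B(t) = a1 e^{-l1 t} + a2 e^{-l2 t}.

    Amplitudes are relative (a1 + a2 = 1 leaves initial brightness to the
    channel brightness setting); rates are 1/s.
    """

    a1: float = 0.35
    lam1: float = 0.03
    a2: float = 0.65
    lam2: float = 0.004

    def curve(self, t: np.ndarray) -> np.ndarray:
        return double_exponential(t, self.a1, self.lam1, self.a2, self.lam2)


@dataclass(frozen=True)
class ArtifactParams:
    """Shared multiplicative disturbance (focus drift, micro-motion).

    Modeled as an Ornstein–Uhlenbeck-style AR(1) process in the log domain,
    exponentiated and renormalized to mean 1: smooth, positive, and common
    to both channels, as the three-term signal model requires.
    """

    amplitude: float = 0.015      # stationary SD of log-amplitude
    correlation_time_s: float = 1.0

    def series(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = t.size
        if self.amplitude == 0 or n == 0:
            return np.ones(n)
        dt = float(t[1] - t[0]) if n > 1 else 1.0
        rho = np.exp(-dt / self.correlation_time_s)
        innov_sd = self.amplitude * np.sqrt(1.0 - rho**2)
        x = np.empty(n)
        x[0] = rng.normal(0.0, self.amplitude)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i - 1]
        a = np.exp(x)
        return a / a.mean()


@dataclass(frozen=True)
class CalciumKernel:
    """Event-locked fluorescence transient in dF/F units.

    Linear rise over ``rise_s`` then exponential decay with time constant
    ``decay_s``; the slow decay mimics GCaMP6s kinetics.
    """

    rise_s: float = 0.6
    decay_s: float = 2.5
    amplitude: float = 1.5

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        rising = (tau >= 0) & (tau < self.rise_s)
        out[rising] = self.amplitude * tau[rising] / self.rise_s
        decaying = tau >= self.rise_s
        out[decaying] = self.amplitude * np.exp(
            -(tau[decaying] - self.rise_s) / self.decay_s)
        return out


@dataclass(frozen=True)
class TrackParams:
    """Crawling-path generator settings (micrometers, seconds, degrees)."""

    speed_um_s: float = 100.0
    undulation_period_s: float = 2.0
    undulation_amplitude_um: float = 40.0
    dorsal_turn_bias_deg: float = 0.0     # heading turn toward dorsal per step
    reversal_schedule: tuple = ()         # ((onset_s, duration_s), ...)
    frame_rate_hz: float = 20.0
    duration_s: float = 120.0
    noise_um: float = 1.0                 # centroid localization jitter (SD)
    dorsal_side: int = 1                  # +1: dorsal to the left (CCW turns)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic recordings.

    Imaging defaults follow the acquisition geometry the analyses assume:
    volumetric two-channel imaging at 4 Hz, 25 z-planes, 0.4 um lateral and
    1.2 um axial voxels.  The lateral extent is a small crop around the
    simulated neurons rather than a full camera frame.
    """

    random_seed: int = 0
    frame_rate: float = 4.0               # volumes per second
    duration: float = 240.0               # seconds
    voxel_counts: tuple[int, int, int] = (24, 24, 9)    # (x, y, z) crop
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 1.2)  # um
    neuron_positions: tuple[tuple[int, int, int], ...] = ((8, 12, 4),
                                                          (16, 12, 4))
    psf_width: float = 1.6                # Gaussian sigma, voxels
    bleach_red: BleachParams = field(default_factory=BleachParams)
    bleach_green: BleachParams = field(
        default_factory=lambda: BleachParams(a1=0.30, lam1=0.04,
                                             a2=0.70, lam2=0.005))
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    noise_floor_red: float = 100.0        # additive offset, intensity units
    noise_floor_green: float = 100.0
    noise_sd_red: float = 4.0             # additive Gaussian SD
    noise_sd_green: float = 4.0
    brightness_red: float = 800.0         # peak-voxel brightness at t=0, B=A=1
    brightness_green: float = 600.0       # green baseline (dF/F = 0)
    event_rate_per_min: float = 2.0
    event_duration_mean_s: float = 3.0
    event_duration_sd_s: float = 1.0
    refractory_s: float = 5.0
    calcium_kernel: CalciumKernel = field(default_factory=CalciumKernel)
    track: TrackParams = field(default_factory=TrackParams)

    def validate(self) -> None:
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.frame_rate <= 0:
            raise InvalidConfigError("frame_rate must be positive")
        if self.event_rate_per_min < 0:
            raise InvalidConfigError("event rate must be >= 0")
        if self.refractory_s < 0:
            raise InvalidConfigError("refractory must be >= 0")
        if self.event_duration_mean_s <= 0:
            raise InvalidConfigError("event duration mean must be positive")
        if min(self.voxel_counts) < 1:
            raise InvalidConfigError("voxel_counts must be positive")
        if self.psf_width <= 0:
            raise InvalidConfigError("psf_width must be positive")
        nx, ny, nz = self.voxel_counts
        for (x, y, z) in self.neuron_positions:
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
                raise InvalidConfigError(
                    f"neuron position {(x, y, z)} outside volume "
                    f"{self.voxel_counts}")
        tp = self.track
        if tp.speed_um_s <= 0 or tp.undulation_period_s <= 0:
            raise InvalidConfigError("track speed and undulation period must "
                                     "be positive")
        if tp.duration_s <= 0 or tp.frame_rate_hz <= 0:
            raise InvalidConfigError("track duration and frame rate must be "
                                     "positive")

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) / self.frame_rate


@dataclass
class GroundTruth:
    """Known-truth record accompanying each synthetic dataset."""

    true_calcium: dict | None = None        # neuron id -> dF/F series
    true_bleach: dict | None = None         # channel -> multiplicative series
    true_artifact: np.ndarray | None = None  # shared series, mean 1
    true_events: EventTrain | None = None
    true_turn_angles: np.ndarray | None = None   # degrees per step junction
    true_step_boundaries: np.ndarray | None = None  # sample indices
    true_array_states: np.ndarray | None = None  # (n_animals, n_terminals)
    noise_floor: dict | None = None
    dorsal_side: int | None = None


def simulate_event_train(config: SimulationConfig,
                         seed: int | None = None) -> EventTrain:
    """Draw a reversal train: exponential gaps plus a hard refractory period.

    Onsets lie in [0, duration); durations are truncated-normal and clipped
    to end within the recording.
    """
    config.validate()
    rng = substream(config.random_seed if seed is None else seed, "events")
    duration = config.duration
    if config.event_rate_per_min == 0:
        return EventTrain(np.empty(0), np.empty(0), duration)
    mean_gap = 60.0 / config.event_rate_per_min
    onsets = []
    t = config.refractory_s + rng.exponential(mean_gap)
    while t < duration:
        onsets.append(t)
        t += config.refractory_s + rng.exponential(mean_gap)
    onsets = np.asarray(onsets)
    durations = rng.normal(config.event_duration_mean_s,
                           config.event_duration_sd_s, size=onsets.size)
    durations = np.clip(durations, 0.3, None)
    keep = onsets + 0.3 <= duration
    onsets, durations = onsets[keep], durations[keep]
    durations = np.minimum(durations, duration - onsets)
    return EventTrain(onsets, durations, duration)


def calcium_response(times: np.ndarray, events: EventTrain,
                     kernel: CalciumKernel) -> np.ndarray:
    """Summed dF/F transient series for a train of events."""
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for onset in events.onsets:
        out += kernel.evaluate(times - onset)
    return out


def _psf_patch(config: SimulationConfig, position: tuple[int, int, int]):
    """Gaussian PSF weights on the voxel grid around one neuron (truncated)."""
    x0, y0, z0 = position
    nx, ny, nz = config.voxel_counts
    s_lat = config.psf_width
    s_ax = config.psf_width  # in voxel units; axial voxels are coarser in um
    half_lat = int(np.ceil(3 * s_lat))
    half_ax = int(np.ceil(3 * s_ax))
    xs = np.arange(max(0, x0 - half_lat), min(nx, x0 + half_lat + 1))
    ys = np.arange(max(0, y0 - half_lat), min(ny, y0 + half_lat + 1))
    zs = np.arange(max(0, z0 - half_ax), min(nz, z0 + half_ax + 1))
    dz = (zs - z0)[:, None, None]
    dy = (ys - y0)[None, :, None]
    dx = (xs - x0)[None, None, :]
    w = np.exp(-(dx**2 + dy**2) / (2 * s_lat**2) - dz**2 / (2 * s_ax**2))
    return (slice(zs[0], zs[-1] + 1), slice(ys[0], ys[-1] + 1),
            slice(xs[0], xs[-1] + 1)), w


def simulate_calcium_movie(config: SimulationConfig, events: EventTrain,
                           seed: int | None = None):
    """Render a two-channel movie under the three-term multiplicative model.

    Each voxel near a neuron carries PSF(position) * F(t) * B(t) * A(t) on
    top of a constant noise floor plus Gaussian read noise, where F is the
    fluorophore signal (calcium-dependent in green, constant in red), B the
    per-channel photobleaching curve and A the shared artifact series.
    Returns the movie and the ground truth used to build it.
    """
    from .traces import TwoChannelMovie

    config.validate()
    rng = substream(config.random_seed if seed is None else seed, "movie")
    t = config.times()
    nx, ny, nz = config.voxel_counts
    shape = (t.size, nz, ny, nx)

    artifact = config.artifact.series(t, rng)
    bleach = {"red": config.bleach_red.curve(t),
              "green": config.bleach_green.curve(t)}
    dff = calcium_response(t, events, config.calcium_kernel)

    red = np.full(shape, config.noise_floor_red, dtype=np.float64)
    green = np.full(shape, config.noise_floor_green, dtype=np.float64)
    if config.noise_sd_red > 0:
        red += rng.normal(0.0, config.noise_sd_red, size=shape)
    if config.noise_sd_green > 0:
        green += rng.normal(0.0, config.noise_sd_green, size=shape)

    true_calcium = {}
    for i, pos in enumerate(config.neuron_positions):
        sl, w = _psf_patch(config, pos)
        f_red = config.brightness_red * bleach["red"] * artifact
        f_green = (config.brightness_green * (1.0 + dff)
                   * bleach["green"] * artifact)
        red[(slice(None),) + sl] += w[None] * f_red[:, None, None, None]
        green[(slice(None),) + sl] += w[None] * f_green[:, None, None, None]
        true_calcium[f"neuron{i}"] = dff.copy()

    np.clip(red, 0.0, None, out=red)
    np.clip(green, 0.0, None, out=green)
    movie = TwoChannelMovie(red_volumes=red, green_volumes=green,
                            frame_rate=config.frame_rate,
                            voxel_size=config.voxel_size)
    truth = GroundTruth(true_calcium=true_calcium, true_bleach=bleach,
                        true_artifact=artifact, true_events=events,
                        noise_floor={"red": config.noise_floor_red,
                                     "green": config.noise_floor_green})
    return movie, truth


def simulate_worm_track(config: SimulationConfig, seed: int | None = None):
    """Generate a crawling centroid track with programmed turns and reversals.

    The centroid is a smooth heading path plus sinusoidal lateral
    undulation.  The heading is constant within a movement step (five
    undulation periods) and rotates toward the dorsal side by the programmed
    bias at each step boundary; programmed reversals invert motion along the
    body axis for their duration.
    """
    from .behavior import WormTrack

    config.validate()
    tp = config.track
    rng = substream(config.random_seed if seed is None else seed, "track")
    dt = 1.0 / tp.frame_rate_hz
    n = int(round(tp.duration_s * tp.frame_rate_hz))
    t = np.arange(n) * dt

    step_len_s = 5.0 * tp.undulation_period_s
    step_index = np.floor(t / step_len_s).astype(int)
    # +bias rotates toward the dorsal side; dorsal_side=+1 puts dorsal on
    # the left of the heading, i.e. counterclockwise.
    heading = np.deg2rad(tp.dorsal_turn_bias_deg) * tp.dorsal_side * step_index

    direction = np.ones(n)
    sched = tuple(tp.reversal_schedule)
    for onset, dur in sched:
        direction[(t >= onset) & (t < onset + dur)] = -1.0

    ux, uy = np.cos(heading), np.sin(heading)
    vx = tp.speed_um_s * direction * ux
    vy = tp.speed_um_s * direction * uy
    base = np.column_stack([np.cumsum(vx) * dt, np.cumsum(vy) * dt])

    phase = 2.0 * np.pi * t / tp.undulation_period_s
    lateral = tp.undulation_amplitude_um * np.sin(phase)
    normal = np.column_stack([-uy, ux])
    positions = base + lateral[:, None] * normal
    if tp.noise_um > 0:
        positions = positions + rng.normal(0.0, tp.noise_um, size=(n, 2))

    boundaries = np.nonzero(np.diff(step_index))[0] + 1
    n_steps = step_index[-1] + 1
    true_angles = np.full(max(n_steps - 1, 0), 180.0 - tp.dorsal_turn_bias_deg)
    ev = (EventTrain(np.array([o for o, _ in sched]),
                     np.array([d for _, d in sched]), tp.duration_s)
          if sched else EventTrain(np.empty(0), np.empty(0), tp.duration_s))
    track = WormTrack(timestamps=t, positions=positions,
                      dorsal_side=tp.dorsal_side,
                      frame_rate=tp.frame_rate_hz)
    truth = GroundTruth(true_events=ev, true_turn_angles=true_angles,
                        true_step_boundaries=boundaries,
                        dorsal_side=tp.dorsal_side)
    return track, truth


def simulate_mosaic_population(tree, p: float, n_animals: int,
                               seed: int = 0):
    """Simulate per-division array loss for a population of animals.

    The root cell always carries the array; each division transmits it
    independently with probability ``p``.  Returns a boolean matrix of shape
    (n_animals, n_terminal_cells) of terminal retention states, plus the
    terminal labels in column order.
    """
    if not 0 <= p <= 1:
        raise DomainError(f"transmission probability must be in [0, 1], got {p}")
    if n_animals < 1:
        raise DomainError("n_animals must be >= 1")
    rng = substream(seed, "mosaic")
    edges = tree.edges()
    n_edges = len(edges)
    transmitted = rng.random((n_animals, n_edges)) < p
    leaf_labels = tree.leaf_labels
    out = np.empty((n_animals, len(leaf_labels)), dtype=bool)
    for j, label in enumerate(leaf_labels):
        path = tree.root_path_edges(label)
        out[:, j] = transmitted[:, path].all(axis=1)
    return out, leaf_labels
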