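"""Synthetic data generators for the full pipeline.

Real recordings behind this kind of experiment — a female medaka filmed from
two cameras, and head-tip traces of test subjects in front of a display — are
not generally available, so every pipeline stage is exercised with synthetic
stand-ins that have the same structure:

* :func:`simulate_swimmer` — a smooth planar correlated random walk (the
  fish's locomotion) carrying a travelling undulation wave along the trunk
  (its body motion), sampled as 6 equally spaced midline points at 60 fps.
* :func:`simulate_assay` — a two-state (near-display / away) Markov
  occupancy process per subject at 30 fps, with group- and minute-dependent
  transition hazards, emulating a social-approach assay cohort.
* :func:`make_rgb_fixture` — deterministic random RGB images for the
  grey-scale operator.

All generators take explicit integer seeds and are bit-reproducible; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import MidlineTrack

__all__ = [
    "SwimmerParams",
    "AssaySimParams",
    "OccupancyTrace",
    "simulate_swimmer",
    "simulate_assay",
    "make_rgb_fixture",
]

# Nominal body length "about 3 cm" for an adult female medaka.
DEFAULT_BODY_LENGTH_MM = 30.0
# Tail-beat kinematics are not published for the source recordings; these
# defaults are assumptions chosen to look like relaxed cruising: ~1 body
# length/s forward speed, ~2.5 Hz tail beat, one undulation wavelength per
# body length, lateral amplitude growing head→tail to ~0.15 body lengths.
DEFAULT_UNDULATION_FREQ_HZ = 2.5
DEFAULT_SPEED_MM_S = 30.0


@dataclass
class SwimmerParams:
    """Parameters of the synthetic swimming fish.

    Attributes
    ----------
    body_length : float
        Trunk length head→tail in mm.
    n_points : int
        Number of tracked midline points (6 in the source protocol).
    fps, duration : float
        Frame rate (frames/s) and track duration (s).
    undulation_freq : float
        Tail-beat frequency in Hz.
    undulation_wavelength : float
        Wavelength of the travelling wave as a fraction of body length.
    amplitude_envelope : array
        Per-point lateral half-amplitude in mm, non-decreasing head→tail.
    speed_mean : float
        Forward swimming speed in mm/s (held constant).
    heading_persistence : float
        Correlation time (s) of the Ornstein–Uhlenbeck heading process.
    tank : tuple
        Axis-aligned (x, y, z) tank interior dimensions in mm.
    seed : int
        RNG seed.
    """

    body_length: float = DEFAULT_BODY_LENGTH_MM
    n_points: int = 6
    fps: float = 60.0
    duration: float = 60.0
    undulation_freq: float = DEFAULT_UNDULATION_FREQ_HZ
    undulation_wavelength: float = 1.0
    amplitude_envelope: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.8, 1.5, 2.5, 3.5, 4.5])
    )
    speed_mean: float = DEFAULT_SPEED_MM_S
    heading_persistence: float = 2.0
    tank: tuple[float, float, float] = (150.0, 150.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitude_envelope = np.asarray(self.amplitude_envelope, dtype=float)
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if len(self.amplitude_envelope) != self.n_points:
            raise ValueError("amplitude_envelope needs one value per point")
        if np.any(self.amplitude_envelope < 0) or np.any(
            np.diff(self.amplitude_envelope) < 0
        ):
            raise ValueError("amplitude_envelope must be non-negative, non-decreasing")
        margin = self.body_length + self.amplitude_envelope.max() + 5.0
        if min(self.tank[0], self.tank[1]) <= 2 * margin or self.tank[2] <= 10.0:
            raise ValueError(
                f"tank {self.tank} too small for a {self.body_length} mm fish "
                f"(needs > {2 * margin:.0f} mm in each horizontal dimension)"
            )


def _analytic_midline(
    params: SwimmerParams, t: float, n_dense: int = 600
) -> np.ndarray:
    """Dense body-frame midline at time ``t``: head at origin, body along -x.

    Lateral undulation is a travelling wave moving head→tail; the backbone
    parameter extends 25% beyond the nominal body length so that chord-walk
    resampling (which consumes arc length faster than straight-line length)
    never runs off the end of the curve.
    """
    L = params.body_length
    s = np.linspace(0.0, 1.25 * L, n_dense)
    # interpolate the per-point envelope over the backbone (clamped past L)
    s_nodes = np.linspace(0.0, L, params.n_points)
    amp = np.interp(s, s_nodes, params.amplitude_envelope)
    phase = 2.0 * np.pi * (
        s / (params.undulation_wavelength * L) - params.undulation_freq * t
    )
    y = amp * np.sin(phase)
    return np.stack([-s, y, np.zeros_like(s)], axis=1)


def _chord_resample(dense: np.ndarray, n_points: int, chord: float) -> np.ndarray:
    """Pick ``n_points`` points on a polyline with exactly equal chord spacing.

    Starting from the first vertex, each next point is found where the
    polyline first leaves a sphere of radius ``chord`` centred on the
    previous point (quadratic interpolation within the crossing segment), so
    consecutive Euclidean distances equal ``chord`` to machine precision.
    """
    pts = [dense[0]]
    j = 0
    for _ in range(n_points - 1):
        prev = pts[-1]
        while j + 1 < len(dense) and np.linalg.norm(dense[j + 1] - prev) < chord:
            j += 1
        if j + 1 >= len(dense):
            raise RuntimeError("dense midline too short for chord resampling")
        a, b = dense[j], dense[j + 1]
        d = b - a
        f = a - prev
        # solve |f + t d| = chord for t in [0, 1]
        aa = d @ d
        bb = 2.0 * (f @ d)
        cc = f @ f - chord * chord
        t = (-bb + np.sqrt(bb * bb - 4 * aa * cc)) / (2 * aa)
        pts.append(a + t * d)
    return np.asarray(pts)


def simulate_swimmer(params: SwimmerParams | None = None) -> MidlineTrack:
    """Generate a synthetic 6-point midline track of a swimming fish.

    The head follows a constant-speed correlated random walk in the
    horizontal plane (heading is an Ornstein–Uhlenbeck process, steered away
    from the tank walls), depth follows slow, small-amplitude smoothed noise,
    and the trunk behind the head carries the travelling undulation wave.
    Points are resampled each frame to exactly equal chord spacing
    ``body_length / (n_points - 1)`` along the analytic midline.

    Returns a :class:`~fishstim.tracking.MidlineTrack` with
    ``duration * fps`` frames; deterministic for a fixed seed.
    """
    if params is None:
        params = SwimmerParams()
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration * params.fps))
    dt = 1.0 / params.fps
    chord = params.body_length / (params.n_points - 1)
    margin = params.body_length + params.amplitude_envelope.max() + 5.0
    lo = np.array([margin, margin])
    hi = np.array([params.tank[0] - margin, params.tank[1] - margin])
    centre = (lo + hi) / 2.0

    # OU heading: dψ = -ψ_wall/τ dt + σ dW, plus wall-avoidance steering
    tau = params.heading_persistence
    sigma = np.sqrt(2.0 / tau) * 0.8  # rad / sqrt(s); moderate turning
    psi = rng.uniform(0, 2 * np.pi)
    pos = centre + rng.uniform(-10.0, 10.0, size=2)

    # slow depth noise: OU around mid-depth, clamped
    z_mid = params.tank[2] / 2.0
    z = z_mid
    z_tau, z_sigma = 8.0, 1.5

    # small smooth pitch of the whole body (depth motion is gentle)
    pitch = 0.0
    pitch_tau, pitch_sigma = 4.0, 0.03

    # speed_mean == 0 switches locomotion off entirely: no translation, no
    # heading drift, no depth wander (a fish that is not swimming holds
    # position); trunk undulation is governed solely by the amplitude envelope
    locomoting = params.speed_mean > 0

    frames = np.empty((n_frames, params.n_points, 3))
    for i in range(n_frames):
        t = i * dt
        body = _analytic_midline(params, t)
        pts = _chord_resample(body, params.n_points, chord)
        # rotate body frame into world heading, apply small pitch about the
        # body's lateral axis, then translate so the head sits at `pos`
        cp, sp = np.cos(pitch), np.sin(pitch)
        pitched = pts @ np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]]).T
        c, s_ = np.cos(psi), np.sin(psi)
        world = pitched @ np.array([[c, -s_, 0], [s_, c, 0], [0, 0, 1]]).T
        world[:, 0] += pos[0]
        world[:, 1] += pos[1]
        world[:, 2] += z
        frames[i] = world

        # advance the state
        if locomoting:
            pos = pos + params.speed_mean * dt * np.array([np.cos(psi), np.sin(psi)])
            # wall-avoidance: steer toward tank centre outside the margin box
            overshoot = np.maximum(lo - pos, 0.0) - np.maximum(pos - hi, 0.0)
            if np.any(overshoot != 0.0):
                target = np.arctan2(centre[1] - pos[1], centre[0] - pos[0])
                dpsi = np.angle(np.exp(1j * (target - psi)))
                psi += np.clip(dpsi, -1.0, 1.0) * 4.0 * dt
            pos = np.clip(pos, lo, hi)
            psi += sigma * np.sqrt(dt) * rng.standard_normal()
            z += (z_mid - z) / z_tau * dt + z_sigma * np.sqrt(dt) * rng.standard_normal()
            z = float(np.clip(z, 10.0, params.tank[2] - 10.0))
            pitch += (
                -pitch / pitch_tau * dt
                + pitch_sigma * np.sqrt(dt) * rng.standard_normal()
            )
            pitch = float(np.clip(pitch, -0.15, 0.15))

    return MidlineTrack(points=frames, fps=params.fps)


# --------------------------------------------------------------------------
# social-approach assay simulator
# --------------------------------------------------------------------------

@dataclass
class AssaySimParams:
    """Parameters of the synthetic social-approach assay cohort.

    Each subject is a two-state Markov chain: *in zone* (head within the
    scoring zone at the display-side wall) vs *out of zone*.  Transition
    hazards (per second) may differ by group and by minute bin, so fixtures
    can encode patterns like "the Normal group's attraction rises after
    stimulus onset while other groups rise less".

    ``entry_rate[group]`` and ``exit_rate[group]`` are arrays with one value
    per minute bin over baseline + stimulus (6 bins by default).
    """

    n_subjects_per_group: int = 18
    groups: tuple[str, ...] = ("Normal",)
    baseline_s: float = 60.0
    stimulus_s: float = 300.0
    fps: float = 30.0
    entry_rate: dict[str, np.ndarray] = field(default_factory=dict)
    exit_rate: dict[str, np.ndarray] = field(default_factory=dict)
    start_in_zone: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.baseline_s + self.stimulus_s
        if total % 60.0 != 0.0:
            raise ValueError("baseline + stimulus must divide into 1-min bins")
        if self.baseline_s % 60.0 != 0.0:
            raise ValueError("baseline must be whole minutes")
        n_bins = int(total // 60.0)
        for g in self.groups:
            self.entry_rate.setdefault(g, np.full(n_bins, 0.05))
            self.exit_rate.setdefault(g, np.full(n_bins, 0.25))
        for name, table in (("entry_rate", self.entry_rate), ("exit_rate", self.exit_rate)):
            for g in self.groups:
                table[g] = np.asarray(table[g], dtype=float)
                if len(table[g]) != n_bins:
                    raise ValueError(f"{name}[{g!r}] needs {n_bins} minute-bin values")
                if np.any(table[g] < 0):
                    raise ValueError(f"{name}[{g!r}] must be non-negative")

    @property
    def n_bins(self) -> int:
        return int((self.baseline_s + self.stimulus_s) // 60.0)


@dataclass
class OccupancyTrace:
    """Per-frame head-tip distance from the display-side inner wall (mm).

    ``distance_mm`` is sampled at ``fps``; the baseline period occupies
    ``[0, baseline_s)`` and the stimulus period ``[baseline_s,
    baseline_s + stimulus_s)``.
    """

    subject: str
    group: str
    distance_mm: np.ndarray
    fps: float = 30.0
    baseline_s: float = 60.0
    stimulus_s: float = 300.0
    sex: str = "unknown"
    model_variant: int = 1

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.distance_mm < 0):
                raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.distance_mm)

    def to_csv(self, path: str | Path) -> None:
        frames = np.arange(self.n_frames)
        period = np.where(frames < self.baseline_s * self.fps, "baseline", "stimulus")
        pd.DataFrame(
            {"frame": frames, "x_mm": self.distance_mm, "period": period}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, subject: str = "", group: str = "", fps: float = 30.0
    ) -> "OccupancyTrace":
        df = pd.read_csv(path)
        return cls(
            subject=subject or Path(path).stem,
            group=group,
            distance_mm=df["x_mm"].to_numpy(),
            fps=fps,
        )


def simulate_assay(params: AssaySimParams) -> list[OccupancyTrace]:
    """Simulate every subject's occupancy trace as a two-state Markov chain.

    Per-frame transition probabilities are ``1 - exp(-rate / fps)`` with the
    rates of the current minute bin.  When in the zone the reported head
    distance is uniform on [0, 10) mm; when out it is uniform on (10, 140]
    mm.  Subjects start out of the zone unless ``params.start_in_zone`` is
    set.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round((params.baseline_s + params.stimulus_s) * params.fps))
    frames_per_bin = int(round(60.0 * params.fps))
    bins = np.minimum(np.arange(n_frames) // frames_per_bin, params.n_bins - 1)
    traces: list[OccupancyTrace] = []
    for group in params.groups:
        n = params.n_subjects_per_group
        p_in = (1.0 - np.exp(-params.entry_rate[group] / params.fps))[bins]
        p_out = (1.0 - np.exp(-params.exit_rate[group] / params.fps))[bins]
        u = rng.random((n, n_frames))
        state = np.empty((n, n_frames), dtype=bool)
        cur = np.full(n, params.start_in_zone)
        for i in range(n_frames):
            cur = np.where(cur, u[:, i] >= p_out[i], u[:, i] < p_in[i])
            state[:, i] = cur
        dist = np.where(
            state,
            rng.uniform(0.0, 10.0, (n, n_frames)),
            rng.uniform(10.0 + 1e-9, 140.0, (n, n_frames)),
        )
        for s in range(n):
            traces.append(
                OccupancyTrace(
                    subject=f"{group}-{s:02d}",
                    group=group,
                    distance_mm=dist[s],
                    fps=params.fps,
                    baseline_s=params.baseline_s,
                    stimulus_s=params.stimulus_s,
                )
            )
    return traces


def make_rgb_fixture(width: int, height: int, seed: int = 0) -> np.ndarray:
    """Deterministic pseudo-random 8-bit RGB array of shape (height, width, 3)."""
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
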