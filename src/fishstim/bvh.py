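"""Skeletal conversion of midline tracks and BVH (BioVision Hierarchy) I/O.

The tracked fish is reduced to a 5-segment kinematic chain: the head point is
the root (6 channels: translation + rotation) and each of the four interior
points is a joint (3 rotation channels); the tail point is the chain's end
site.  Per frame, the five unit vectors formed by adjacent midline points are
converted to Euler angles and the chain is written to standard BVH text.

Angle convention
----------------
Coordinates are x/y horizontal, z vertical (mm).  Each segment's global
orientation is described by two angles only:

* ``yaw``   — heading of the segment's horizontal projection, degrees,
  anticlockwise from +x;
* ``pitch`` — elevation above the horizontal plane, degrees.

``roll`` is locked to zero: the fish's dorsoventral axis is assumed to stay
aligned with the global vertical, so the body never twists about its own
long axis.  Joint channels store *increments* — the child segment's yaw and
pitch minus the parent's — and forward kinematics accumulates these sums down
the chain.  With roll locked, this heading/elevation composition coincides
with ordinary hierarchical Euler composition whenever motion is planar
(pitch = 0) and reconstructs the global segment directions exactly in all
cases, which is the invariant the pipeline preserves.

In BVH files the rotation channel order is ``Zrotation Yrotation Xrotation``;
``Zrotation`` carries yaw, ``Yrotation`` carries ``-pitch`` (a positive
rotation about +y drops the nose, per the right-hand rule), and ``Xrotation``
carries the (zero) roll.  Angles are degrees in files, as BVH convention
dictates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tracking import MidlineTrack

__all__ = [
    "SkeletonDef",
    "SkeletalAnimation",
    "segment_vectors",
    "vector_to_euler",
    "track_to_animation",
    "forward_kinematics",
    "write_bvh",
    "read_bvh",
]

_VERTICAL_EPS = 1e-6


@dataclass
class SkeletonDef:
    """A linear chain of 5 segments joining 6 midline points.

    ``offsets`` holds each segment's length (mm) along its local forward
    axis; ``joint_names`` names the root and the four interior joints (the
    tail point is the unnamed end site).
    """

    offsets: np.ndarray
    joint_names: tuple[str, ...] = ("head", "spine1", "spine2", "spine3", "spine4")

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.offsets) != len(self.joint_names):
            raise ValueError("need one offset per segment")
        if np.any(self.offsets <= 0):
            raise ValueError("segment lengths must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.offsets)


@dataclass
class SkeletalAnimation:
    """Per-frame root translation plus Euler angles for the root and joints.

    ``root_pos`` has shape ``(n_frames, 3)`` (mm); ``angles_deg`` has shape
    ``(n_frames, n_segments, 3)`` with the last axis ordered
    (yaw, pitch, roll).  Row 0 of the segment axis is the root's rotation,
    rows 1..4 are joint increments relative to the parent segment.
    """

    skeleton: SkeletonDef
    frame_time: float
    root_pos: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.root_pos = np.asarray(self.root_pos, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.root_pos.ndim != 2 or self.root_pos.shape[1] != 3:
            raise ValueError("root_pos must have shape (n_frames, 3)")
        expected = (self.root_pos.shape[0], self.skeleton.n_segments, 3)
        if self.angles_deg.shape != expected:
            raise ValueError(f"angles_deg must have shape {expected}")
        if not (
            np.all(np.isfinite(self.root_pos)) and np.all(np.isfinite(self.angles_deg))
        ):
            raise ValueError("animation contains non-finite values")
        pitch = self.angles_deg[:, 0, 1]
        if np.any(np.abs(pitch) >= 90.0):
            raise ValueError("root pitch must stay within (-90, 90) degrees")

    @property
    def n_frames(self) -> int:
        return self.root_pos.shape[0]

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_time

    def copy(self) -> "SkeletalAnimation":
        return SkeletalAnimation(
            skeleton=SkeletonDef(
                offsets=self.skeleton.offsets.copy(),
                joint_names=self.skeleton.joint_names,
            ),
            frame_time=self.frame_time,
            root_pos=self.root_pos.copy(),
            angles_deg=self.angles_deg.copy(),
        )


def segment_vectors(track: MidlineTrack) -> np.ndarray:
    """Unit vectors along each body segment, shape (n_frames, n_points-1, 3).

    Vector ``i`` points from midline point ``i`` to point ``i+1`` (head to
    tail).  Raises if any two consecutive points coincide, naming the frame
    and segment.
    """
    diffs = np.diff(track.points, axis=1)
    norms = np.linalg.norm(diffs, axis=2)
    if np.any(norms < 1e-12):
        f, s = np.argwhere(norms < 1e-12)[0]
        raise ValueError(f"coincident consecutive points at frame {f}, segment {s}")
    return diffs / norms[..., None]


def vector_to_euler(v: np.ndarray, fallback_yaw_deg: float = 0.0) -> tuple[float, float, float]:
    """Euler angles (yaw, pitch, roll) in degrees of one unit vector.

    yaw is the heading of the horizontal projection, pitch the elevation
    from horizontal, and roll is identically 0 (vertical-axis lock).  For a
    vector within ~1e-6 of vertical the heading is undefined; the caller's
    ``fallback_yaw_deg`` (by convention, the previous frame's yaw) is used.
    """
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError("vector must be unit length")
    horiz = np.hypot(v[0], v[1])
    yaw = fallback_yaw_deg if horiz < _VERTICAL_EPS else np.degrees(np.arctan2(v[1], v[0]))
    pitch = np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    return float(yaw), float(pitch), 0.0


def euler_to_vector(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """Unit vector with the given heading and elevation (inverse of above)."""
    psi, theta = np.radians(yaw_deg), np.radians(pitch_deg)
    return np.array(
        [np.cos(psi) * np.cos(theta), np.sin(psi) * np.cos(theta), np.sin(theta)]
    )


def _global_angles(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame global (yaw, pitch) of every segment, yaw unwrapped in time.

    Near-vertical segments carry the previous frame's yaw forward so the
    heading channel has no spurious jumps.
    """
    n_frames, n_seg, _ = vectors.shape
    pitch = np.degrees(np.arcsin(np.clip(vectors[..., 2], -1.0, 1.0)))
    yaw = np.degrees(np.arctan2(vectors[..., 1], vectors[..., 0]))
    horiz = np.hypot(vectors[..., 0], vectors[..., 1])
    degenerate = horiz < _VERTICAL_EPS
    for s in range(n_seg):
        prev = 0.0
        col = yaw[:, s]
        bad = degenerate[:, s]
        for f in range(n_frames):
            if bad[f]:
                col[f] = prev
            else:
                prev = col[f]
    yaw = np.degrees(np.unwrap(np.radians(yaw), axis=0))
    return yaw, pitch


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def track_to_animation(track: MidlineTrack) -> SkeletalAnimation:
    """Convert a (smoothed) midline track into a skeletal animation.

    The root carries the head point's path and the first segment's global
    yaw/pitch; each joint carries its segment's yaw/pitch increment over the
    parent segment.  Segment offsets are the median chord lengths over all
    frames, which makes forward kinematics exact on tracks whose chord
    lengths are constant and accurate to the chord-length jitter otherwise.
    """
    vectors = segment_vectors(track)
    yaw, pitch = _global_angles(vectors)
    offsets = np.median(track.chord_lengths(), axis=0)
    n_frames, n_seg = yaw.shape
    angles = np.zeros((n_frames, n_seg, 3))
    angles[:, 0, 0] = yaw[:, 0]
    angles[:, 0, 1] = pitch[:, 0]
    angles[:, 1:, 0] = _wrap_deg(np.diff(yaw, axis=1))
    angles[:, 1:, 1] = np.diff(pitch, axis=1)
    return SkeletalAnimation(
        skeleton=SkeletonDef(offsets=offsets),
        frame_time=1.0 / track.fps,
        root_pos=track.points[:, 0, :].copy(),
        angles_deg=angles,
    )


def forward_kinematics(anim: SkeletalAnimation) -> MidlineTrack:
    """Reconstruct the global midline points from an animation.

    The chain is walked head→tail accumulating yaw and pitch increments;
    each next point lies one segment offset along the accumulated heading /
    elevation direction.  This is the verification oracle for
    :func:`track_to_animation` and for the stimulus manipulations.
    """
    yaw_acc = np.cumsum(anim.angles_deg[:, :, 0], axis=1)
    pitch_acc = np.cumsum(anim.angles_deg[:, :, 1], axis=1)
    psi, theta = np.radians(yaw_acc), np.radians(pitch_acc)
    dirs = np.stack(
        [np.cos(psi) * np.cos(theta), np.sin(psi) * np.cos(theta), np.sin(theta)],
        axis=2,
    )
    steps = dirs * anim.skeleton.offsets[None, :, None]
    pts = np.concatenate(
        [anim.root_pos[:, None, :], anim.root_pos[:, None, :] + np.cumsum(steps, axis=1)],
        axis=1,
    )
    return MidlineTrack(points=pts, fps=anim.fps)


# --------------------------------------------------------------------------
# BVH text I/O
# --------------------------------------------------------------------------

def write_bvh(anim: SkeletalAnimation, path: str | Path) -> None:
    """Write standard BVH text (HIERARCHY + MOTION sections).

    Channel layout: root ``Xposition Yposition Zposition Zrotation Yrotation
    Xrotation``, joints ``Zrotation Yrotation Xrotation``; Zrotation = yaw,
    Yrotation = -pitch, Xrotation = roll (always 0 here).  Values are printed
    with 6 decimals, so a write/read round trip preserves channels to 5e-7.
    """
    if anim.n_frames == 0:
        raise ValueError("cannot write an animation with zero frames")
    sk = anim.skeleton
    lines: list[str] = ["HIERARCHY", f"ROOT {sk.joint_names[0]}", "{"]
    indent = "  "
    lines.append(f"{indent}OFFSET 0.000000 0.000000 0.000000")
    lines.append(
        f"{indent}CHANNELS 6 Xposition Yposition Zposition "
        "Zrotation Yrotation Xrotation"
    )
    depth = 1
    for j in range(1, sk.n_segments):
        indent = "  " * depth
        lines.append(f"{indent}JOINT {sk.joint_names[j]}")
        lines.append(f"{indent}{{")
        inner = "  " * (depth + 1)
        lines.append(f"{inner}OFFSET {sk.offsets[j - 1]:.6f} 0.000000 0.000000")
        lines.append(f"{inner}CHANNELS 3 Zrotation Yrotation Xrotation")
        depth += 1
    indent = "  " * depth
    lines.append(f"{indent}End Site")
    lines.append(f"{indent}{{")
    lines.append(f"{indent}  OFFSET {sk.offsets[-1]:.6f} 0.000000 0.000000")
    lines.append(f"{indent}}}")
    for d in range(depth - 1, -1, -1):
        lines.append("  " * d + "}")
    lines.append("MOTION")
    lines.append(f"Frames: {anim.n_frames}")
    lines.append(f"Frame Time: {anim.frame_time:.7f}")

    yaw = anim.angles_deg[:, :, 0]
    pitch = anim.angles_deg[:, :, 1]
    roll = anim.angles_deg[:, :, 2]
    rot = np.stack([yaw, -pitch, roll], axis=2).reshape(anim.n_frames, -1)
    motion = np.concatenate([anim.root_pos, rot[:, :3], rot[:, 3:]], axis=1)
    body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in motion)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


class BvhParseError(ValueError):
    """Malformed BVH file; the message names the offending line."""


def read_bvh(path: str | Path) -> SkeletalAnimation:
    """Parse a BVH file written by :func:`write_bvh` (linear chains only)."""
    text = Path(path).read_text().splitlines()
    it = iter(enumerate(text, start=1))

    def next_tokens() -> tuple[int, list[str]]:
        for lineno, line in it:
            toks = line.split()
            if toks:
                return lineno, toks
        raise BvhParseError("unexpected end of file")

    lineno, toks = next_tokens()
    if toks != ["HIERARCHY"]:
        raise BvhParseError(f"line {lineno}: expected HIERARCHY")
    names: list[str] = []
    offsets: list[float] = []
    n_channels = 0
    depth = 0
    while True:
        lineno, toks = next_tokens()
        key = toks[0]
        if key in ("ROOT", "JOINT"):
            if len(toks) != 2:
                raise BvhParseError(f"line {lineno}: joint needs a name")
            names.append(toks[1])
        elif key == "End" and toks[1] == "Site":
            names.append("__end__")
        elif key == "{":
            depth += 1
        elif key == "}":
            depth -= 1
            if depth == 0:
                break
        elif key == "OFFSET":
            if len(toks) != 4:
                raise BvhParseError(f"line {lineno}: OFFSET needs 3 values")
            offsets.append(float(toks[1]))
        elif key == "CHANNELS":
            n_channels += int(toks[1])
        else:
            raise BvhParseError(f"line {lineno}: unexpected token {key!r}")
    if names[-1] != "__end__":
        raise BvhParseError("chain must terminate in an End Site")
    joint_names = tuple(names[:-1])
    # OFFSET list: root's zero offset, then one per segment
    seg_offsets = np.asarray(offsets[1:], dtype=float)

    lineno, toks = next_tokens()
    if toks != ["MOTION"]:
        raise BvhParseError(f"line {lineno}: expected MOTION")
    lineno, toks = next_tokens()
    if toks[0] != "Frames:":
        raise BvhParseError(f"line {lineno}: expected 'Frames:'")
    n_frames = int(toks[1])
    lineno, toks = next_tokens()
    if toks[:2] != ["Frame", "Time:"]:
        raise BvhParseError(f"line {lineno}: expected 'Frame Time:'")
    frame_time = float(toks[2])

    rows = []
    for _ in range(n_frames):
        lineno, toks = next_tokens()
        if len(toks) != n_channels:
            raise BvhParseError(
                f"line {lineno}: expected {n_channels} channels, got {len(toks)}"
            )
        rows.append([float(v) for v in toks])
    motion = np.asarray(rows)
    root_pos = motion[:, :3]
    rot = motion[:, 3:].reshape(n_frames, -1, 3)
    angles = np.stack([rot[:, :, 0], -rot[:, :, 1], rot[:, :, 2]], axis=2)
    return SkeletalAnimation(
        skeleton=SkeletonDef(offsets=seg_offsets, joint_names=joint_names),
        frame_time=frame_time,
        root_pos=root_pos,
        angles_deg=angles,
    )
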