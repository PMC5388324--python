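"""Factorial stimulus manipulations: colour, shape, locomotion, body motion.

The stimulus set is built by switching four visual features of the normal
virtual fish on or off:

* **colour** — natural texture vs grey scale (:func:`to_greyscale`);
* **shape** — normal vs "pressed", width tripled and height reduced to a
  third (:func:`press_shape`);
* **locomotion** — whole-body translation and heading through the tank; when
  off, the fish is pinned at its starting pose while the tail keeps beating
  (:func:`remove_locomotion`);
* **body motion** — trunk/tail articulation; when off, the body is held
  rigid and straight while the swimming trajectory is kept intact
  (:func:`remove_body_motion`).

Static stimuli hold the animation's first frame (:func:`make_static`), and
presentation-length stimuli are built by looping a one-minute block five
times (:func:`loop_concatenate`).  All operators are pure: they return new
objects and commute wherever the composition is meaningful, so the order in
which a factorial cell is assembled cannot silently matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bvh import SkeletalAnimation

__all__ = [
    "StimulusSpec",
    "ShapeScale",
    "remove_locomotion",
    "remove_body_motion",
    "press_shape",
    "to_greyscale",
    "make_static",
    "loop_concatenate",
    "apply_spec",
]

# ITU-R BT.709 luminance weights; the conversion mode of the original image
# editor is unknown, so the standard luma weighting is used and configurable.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class StimulusSpec:
    """One cell of the factorial stimulus design.

    Flags mirror the experiment-design table: a ✓ keeps the natural feature,
    an × applies the corresponding manipulation.  ``static`` freezes the
    animation at its first frame (implying no locomotion and no body
    motion); ``blank`` is the no-stimulus negative control.
    """

    name: str = "Normal"
    colour: str = "natural"  # "natural" | "grey"
    shape: str = "normal"  # "normal" | "pressed"
    locomotion: bool = True
    body_motion: bool = True
    static: bool = False
    blank: bool = False

    def __post_init__(self) -> None:
        if self.colour not in ("natural", "grey"):
            raise ValueError("colour must be 'natural' or 'grey'")
        if self.shape not in ("normal", "pressed"):
            raise ValueError("shape must be 'normal' or 'pressed'")
        if self.static and (self.locomotion or self.body_motion):
            raise ValueError("a static stimulus cannot have locomotion or body motion")


@dataclass(frozen=True)
class ShapeScale:
    """Anisotropic body scaling in body-local axes (length, width, height)."""

    width_factor: float = 3.0
    height_factor: float = 1.0 / 3.0
    length_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.width_factor, self.height_factor, self.length_factor) <= 0:
            raise ValueError("scale factors must be positive")


def remove_locomotion(
    anim: SkeletalAnimation, freeze_heading: bool = True
) -> SkeletalAnimation:
    """Stop the fish's locomotion while keeping its body-axis motion.

    The root translation — and, by default, the root heading (yaw), since a
    drifting heading is itself locomotion — is frozen at the frame-0 value;
    root pitch and every joint channel are untouched, so the tail keeps
    beating in place.  Idempotent.
    """
    out = anim.copy()
    out.root_pos[:] = anim.root_pos[0]
    if freeze_heading:
        out.angles_deg[:, 0, 0] = anim.angles_deg[0, 0, 0]
    return out


def remove_body_motion(anim: SkeletalAnimation) -> SkeletalAnimation:
    """Hold the body rigid and straight; keep the moving trajectory intact.

    All joint rotation channels are zeroed (the trunk stays straight behind
    the head) while root translation and rotation are bit-identical to the
    input.  Idempotent.
    """
    out = anim.copy()
    out.angles_deg[:, 1:, :] = 0.0
    return out


def press_shape(
    geometry: np.ndarray, scale: ShapeScale = ShapeScale()
) -> np.ndarray:
    """Scale body-local geometry anisotropically (the "pressed" shape).

    ``geometry`` is an ``(..., 3)`` array of points in body axes ordered
    (length, width, height).  The default triples the width and reduces the
    height to one third, which preserves bounding-box volume
    (3 x 1/3 x 1 = 1).
    """
    geometry = np.asarray(geometry, dtype=float)
    if geometry.shape[-1] != 3:
        raise ValueError("geometry must be (..., 3) in (length, width, height) axes")
    return geometry * np.array(
        [scale.length_factor, scale.width_factor, scale.height_factor]
    )


def to_greyscale(
    image: np.ndarray, weights: tuple[float, float, float] = LUMA_WEIGHTS
) -> np.ndarray:
    """Convert an 8-bit RGB image to grey scale (equal channels).

    The grey value is the luminance-weighted sum of the input channels,
    rounded to the nearest integer and replicated across R, G and B, so the
    output is still a 3-channel image.  Idempotent on grey images.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.dtype != np.uint8:
        raise ValueError("expected 8-bit channels")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    grey = np.rint(image.astype(float) @ w).clip(0, 255).astype(np.uint8)
    return np.repeat(grey[:, :, None], 3, axis=2)


def make_static(anim: SkeletalAnimation, n_frames: int = 1) -> SkeletalAnimation:
    """Freeze the animation at its first frame.

    Returns frame 0 repeated ``n_frames`` times (default a single frame), so
    forward kinematics of the result is the same point set in every frame.
    """
    if anim.n_frames < 1:
        raise ValueError("animation has no frames")
    out = anim.copy()
    out.root_pos = np.repeat(anim.root_pos[:1], n_frames, axis=0)
    out.angles_deg = np.repeat(anim.angles_deg[:1], n_frames, axis=0)
    return out


def loop_concatenate(anim: SkeletalAnimation, repeats: int = 5) -> SkeletalAnimation:
    """Tile the motion block ``repeats`` times (e.g. 1 min x 5 -> 5 min).

    Frame time is unchanged; the join between repeats is a hard cut, so any
    pose discontinuity equals the input's last-to-first frame difference.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    out = anim.copy()
    out.root_pos = np.tile(anim.root_pos, (repeats, 1))
    out.angles_deg = np.tile(anim.angles_deg, (repeats, 1, 1))
    return out


def apply_spec(
    anim: SkeletalAnimation,
    geometry: np.ndarray,
    texture: np.ndarray,
    spec: StimulusSpec,
    repeats: int = 5,
) -> dict:
    """Assemble one factorial stimulus bundle from the normal inputs.

    Composition order (the operators commute, so the order is a convention,
    not a semantic choice): shape -> colour -> motion edits -> static/loop.
    Returns a dict with keys ``animation``, ``geometry``, ``texture`` and
    ``spec``; a blank spec returns ``None`` for all content entries.
    """
    if spec.blank:
        return {"animation": None, "geometry": None, "texture": None, "spec": spec}
    geom = press_shape(geometry) if spec.shape == "pressed" else np.asarray(geometry, float).copy()
    tex = to_greyscale(texture) if spec.colour == "grey" else np.asarray(texture).copy()
    out = anim.copy()
    if not spec.locomotion:
        out = remove_locomotion(out)
    if not spec.body_motion:
        out = remove_body_motion(out)
    if spec.static:
        out = make_static(out, n_frames=anim.n_frames)
    out = loop_concatenate(out, repeats=repeats)
    return {"animation": out, "geometry": geom, "texture": tex, "spec": spec}
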