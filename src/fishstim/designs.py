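"""Experiment designs: factorial group tables and presentation geometry.

Three experiments probe which visual features of a virtual conspecific drive
social approach.  Experiment 1 contrasts the fully animated normal fish with
static images (and a blank control); experiment 2 changes two features at a
time; experiment 3 changes exactly one feature at a time.
"""

from __future__ import annotations

from .manipulations import StimulusSpec

__all__ = [
    "EXPERIMENT_1",
    "EXPERIMENT_2",
    "EXPERIMENT_3",
    "EXPERIMENTS",
    "GROUP_SIZES",
    "DisplayGeometry",
    "DISPLAY",
]

# flags: (colour natural?, shape normal?, locomotion?, body motion?, static?, blank?)
EXPERIMENT_1: tuple[StimulusSpec, ...] = (
    StimulusSpec("Normal"),
    StimulusSpec("Static", locomotion=False, body_motion=False, static=True),
    StimulusSpec("Grey scale/Static", colour="grey", locomotion=False, body_motion=False, static=True),
    StimulusSpec("Pressed/Static", shape="pressed", locomotion=False, body_motion=False, static=True),
    StimulusSpec("Pressed/Grey scale/Static", colour="grey", shape="pressed", locomotion=False, body_motion=False, static=True),
    StimulusSpec("Blank", locomotion=False, body_motion=False, static=True, blank=True),
)

EXPERIMENT_2: tuple[StimulusSpec, ...] = (
    StimulusSpec("Normal"),
    StimulusSpec("Grey scale/No locomotion", colour="grey", locomotion=False),
    StimulusSpec("Grey scale/No body motion", colour="grey", body_motion=False),
    StimulusSpec("Pressed/Grey scale", colour="grey", shape="pressed"),
    StimulusSpec("Pressed/No locomotion", shape="pressed", locomotion=False),
    StimulusSpec("Pressed/No body motion", shape="pressed", body_motion=False),
)

EXPERIMENT_3: tuple[StimulusSpec, ...] = (
    StimulusSpec("Normal"),
    StimulusSpec("Pressed", shape="pressed"),
    StimulusSpec("Grey scale", colour="grey"),
    StimulusSpec("No locomotion", locomotion=False),
    StimulusSpec("No body motion", body_motion=False),
)

EXPERIMENTS: dict[int, tuple[StimulusSpec, ...]] = {
    1: EXPERIMENT_1,
    2: EXPERIMENT_2,
    3: EXPERIMENT_3,
}

# analysed subjects per group in each experiment
GROUP_SIZES: dict[int, int] = {1: 18, 2: 24, 3: 24}


class DisplayGeometry:
    """Presentation geometry of the stimulus display.

    Stimuli occupy a ``width_px x height_px`` area at the display's physical
    inter-pixel pitch, sized so the on-screen fish matches a real one.
    """

    def __init__(
        self,
        width_px: int = 960,
        height_px: int = 540,
        inter_pixel_mm: float = 0.16,
    ) -> None:
        if width_px <= 0 or height_px <= 0 or inter_pixel_mm <= 0:
            raise ValueError("display dimensions must be positive")
        self.width_px = width_px
        self.height_px = height_px
        self.inter_pixel_mm = inter_pixel_mm

    @property
    def width_mm(self) -> float:
        return self.width_px * self.inter_pixel_mm

    @property
    def height_mm(self) -> float:
        return self.height_px * self.inter_pixel_mm


DISPLAY = DisplayGeometry()
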