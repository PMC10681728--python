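"""Imaging configuration shared by the simulator and the analysis pipelines.

Two acquisition modes are used on the DNA-curtain microscope:

* **two-color** (shuttered): 0.2 s camera integration plus a 0.2 s shutter
  delay while the other laser fires, giving an effective 0.4 s frame interval.
* **unshuttered** (photobleaching): continuous 0.2 s frames, no delay.

Positions are expressed in pixels along the DNA axis; 1 pixel corresponds to
``bp_per_pixel`` base pairs (1000 bp by default, the conversion used in the
velocity formula).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when an imaging configuration is physically meaningless."""


@dataclass(frozen=True)
class ImagingConfig:
    """Geometry and timing of a simulated or real acquisition.

    Parameters
    ----------
    frame_integration : float
        Camera integration time per frame, seconds.
    inter_frame_delay : float
        Dead time between frames (laser shuttering), seconds.  0 for
        unshuttered photobleaching movies.
    bp_per_pixel : float
        Base pairs of DNA per image pixel along the tether axis.
    frames : int
        Number of frames in a movie / rows in a kymograph.
    shape : tuple of int
        (height, width) of a single camera frame in pixels.  The width is
        the DNA-axis extent; the default matches a 512-px EMCCD chip.
    """

    frame_integration: float = 0.2
    inter_frame_delay: float = 0.2
    bp_per_pixel: float = 1000.0
    frames: int = 400
    shape: tuple[int, int] = field(default=(16, 512))

    def __post_init__(self) -> None:
        if self.frame_integration <= 0:
            raise ConfigurationError("frame_integration must be positive")
        if self.inter_frame_delay < 0:
            raise ConfigurationError("inter_frame_delay must be >= 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame interval must be positive")
        if self.bp_per_pixel <= 0:
            raise ConfigurationError("bp_per_pixel must be positive")
        if self.frames < 1:
            raise ConfigurationError("frames must be >= 1")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ConfigurationError("shape must be two positive integers")

    @property
    def frame_interval(self) -> float:
        """Effective time between consecutive frames, seconds."""
        return self.frame_integration + self.inter_frame_delay

    @classmethod
    def two_color(cls, **kw) -> "ImagingConfig":
        """Shuttered alternating-illumination mode (0.4 s frame interval)."""
        kw.setdefault("frame_integration", 0.2)
        kw.setdefault("inter_frame_delay", 0.2)
        return cls(**kw)

    @classmethod
    def unshuttered(cls, **kw) -> "ImagingConfig":
        """Continuous single-laser mode used for photobleaching (0.2 s/frame)."""
        kw.setdefault("frame_integration", 0.2)
        kw.setdefault("inter_frame_delay", 0.0)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)
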