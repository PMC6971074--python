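"""Domain types shared across the pipeline.

Conventions used everywhere:

* images are ``(channel, y, x)`` arrays, 0-based pixel indices, y-down;
* physical coordinates in micrometres are ``index * pixel_size_um``;
* label masks use 0 for background and consecutive positive integers for
  cells, each label a single 8-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "SchemaError",
    "ValidationError",
    "DegenerateImageError",
    "PlacementError",
    "MarkerPanel",
    "MultiplexImage",
    "LabelMask",
    "MASK_KINDS",
]


class FormatError(ValueError):
    """A file's structure does not match the declared contract."""


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class ValidationError(ValueError):
    """A domain object violates its invariants."""


class DegenerateImageError(ValueError):
    """An image channel carries no usable signal (e.g. constant DAPI)."""


class PlacementError(ValueError):
    """A synthetic cell does not fit inside the rendered field."""


MASK_KINDS = ("nuclear", "targeted")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker manifest for a (possibly multi-round) staining design.

    Parameters
    ----------
    markers
        Channel names, in channel order. Unique.
    pixel_size_um
        Physical pixel size of the scans, micrometres per pixel.
    rounds
        Number of staining rounds the panel spans. An aligned,
        concatenated stack is a one-round panel.
    dapi_channel_per_round
        Map ``round -> channel index`` of that round's DAPI
        counterstain; every round has exactly one.
    """

    markers: tuple[str, ...]
    pixel_size_um: float
    rounds: int = 1
    dapi_channel_per_round: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(
            self, "dapi_channel_per_round", dict(self.dapi_channel_per_round)
        )
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError(f"duplicate marker names in panel: {self.markers}")
        if not self.markers:
            raise ValidationError("panel has no markers")
        if self.pixel_size_um <= 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.rounds < 1:
            raise ValidationError("rounds must be >= 1")
        dapi = self.dapi_channel_per_round
        if not dapi:
            # default: a single round whose DAPI channel is named "DAPI"
            if "DAPI" in self.markers and self.rounds == 1:
                object.__setattr__(
                    self,
                    "dapi_channel_per_round",
                    {1: self.markers.index("DAPI")},
                )
            else:
                raise ValidationError("dapi_channel_per_round not given and no 'DAPI' marker")
        else:
            if sorted(dapi) != list(range(1, self.rounds + 1)):
                raise ValidationError(
                    f"need exactly one DAPI channel per round 1..{self.rounds}, got {sorted(dapi)}"
                )
            for r, c in dapi.items():
                if not 0 <= c < len(self.markers):
                    raise ValidationError(f"DAPI channel {c} of round {r} out of range")

    @property
    def n_channels(self) -> int:
        return len(self.markers)

    @property
    def dapi_indices(self) -> tuple[int, ...]:
        return tuple(self.dapi_channel_per_round[r] for r in sorted(self.dapi_channel_per_round))

    @property
    def non_dapi_markers(self) -> tuple[str, ...]:
        skip = set(self.dapi_indices)
        return tuple(m for i, m in enumerate(self.markers) if i not in skip)

    def index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel {self.markers}") from None

    def dapi_marker(self, round_: int = 1) -> str:
        return self.markers[self.dapi_channel_per_round[round_]]


@dataclass
class MultiplexImage:
    """An intensity stack with its marker manifest.

    ``channels`` is ``(n_markers, height, width)``, non-negative float.
    """

    channels: np.ndarray
    panel: MarkerPanel

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValidationError(f"channels must be 3-D (c, y, x), got shape {self.channels.shape}")
        if self.channels.shape[0] != self.panel.n_channels:
            raise ValidationError(
                f"{self.channels.shape[0]} channels for {self.panel.n_channels} panel markers"
            )
        if np.any(self.channels < 0):
            raise ValidationError("negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def pixel_size_um(self) -> float:
        return self.panel.pixel_size_um

    def channel(self, marker: str) -> np.ndarray:
        return self.channels[self.panel.index(marker)]

    def dapi(self, round_: int = 1) -> np.ndarray:
        return self.channels[self.panel.dapi_channel_per_round[round_]]


@dataclass
class LabelMask:
    """Integer-labeled segmentation image; 0 is background.

    Labels are consecutive ``1..K``; each is one 8-connected component.
    """

    labels: np.ndarray
    kind: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integer-typed")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("negative labels")
        if self.kind not in MASK_KINDS:
            raise ValidationError(f"kind must be one of {MASK_KINDS}, got {self.kind!r}")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def validate(self) -> None:
        """Check the consecutive-labels and one-component-per-label invariants."""
        from scipy import ndimage

        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValidationError("labels are not consecutive 1..K")
        structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
        for lab in present:
            _, n = ndimage.label(self.labels == lab, structure=structure)
            if n != 1:
                raise ValidationError(f"label {lab} has {n} connected components")


def check_same_geometry(a: LabelMask | MultiplexImage, b: LabelMask | MultiplexImage) -> None:
    sa = a.shape if isinstance(a, MultiplexImage) else a.labels.shape
    sb = b.shape if isinstance(b, MultiplexImage) else b.labels.shape
    if sa != sb:
        raise ValueError(f"spatial shape mismatch: {sa} vs {sb}")
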