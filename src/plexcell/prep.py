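"""Round-to-round registration on DAPI and autofluorescence subtraction.

Staining rounds of the same physical section differ by a rigid stage
offset; each round's DAPI counterstain is matched against the first
round's by phase cross-correlation at integer-pixel resolution and the
inverse shift is applied to all of that round's channels. The aligned
stack keeps the first round's DAPI plus every non-DAPI channel.
Autofluorescence is modelled as a single blank channel subtracted from
all non-DAPI channels with a global scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .model import DegenerateImageError, MarkerPanel, MultiplexImage
from .synth import _translate

__all__ = ["RegistrationResult", "register_rounds", "subtract_autofluorescence"]


@dataclass
class RegistrationResult:
    """Per-round estimated (dy, dx) offsets relative to round 1 and the
    Pearson correlation of the aligned DAPI against the reference."""

    shifts: list[tuple[int, int]]
    peak_correlations: list[float]

    def __post_init__(self) -> None:
        if self.shifts and tuple(self.shifts[0]) != (0, 0):
            raise ValueError("round 1 is the reference; its shift must be (0, 0)")


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def register_rounds(rounds: list[MultiplexImage]) -> tuple[MultiplexImage, RegistrationResult]:
    """Align staining rounds on DAPI and concatenate into one stack.

    Returns the aligned image (round-1 DAPI first, then every round's
    non-DAPI channels in order) and the estimated per-round offsets.
    """
    if not rounds:
        raise ValueError("register_rounds needs at least one round")
    ref = rounds[0].dapi(1)
    if ref.std() == 0:
        raise DegenerateImageError("round 1 DAPI has zero variance")
    for r in rounds[1:]:
        if r.shape != rounds[0].shape:
            raise ValueError("rounds differ in spatial shape")

    px = rounds[0].pixel_size_um
    dapi_name = rounds[0].panel.dapi_marker(1)
    markers: list[str] = [dapi_name]
    channels: list[np.ndarray] = [ref]
    shifts: list[tuple[int, int]] = []
    corrs: list[float] = []

    for i, rnd in enumerate(rounds):
        moving = rnd.dapi(1)
        if moving.std() == 0:
            raise DegenerateImageError(f"round {i + 1} DAPI has zero variance")
        if i == 0:
            dy, dx = 0, 0
        else:
            # offset of this round relative to round 1: moving = ref translated by (dy, dx)
            est, _, _ = phase_cross_correlation(ref, moving, upsample_factor=1)
            dy, dx = -int(round(est[0])), -int(round(est[1]))
        shifts.append((dy, dx))
        aligned = _translate(rnd.channels, -dy, -dx)
        corrs.append(_correlation(ref, aligned[rnd.panel.dapi_channel_per_round[1]]))
        dapi_idx = rnd.panel.dapi_channel_per_round[1]
        for c, name in enumerate(rnd.panel.markers):
            if c == dapi_idx:
                continue
            if name in markers:
                raise ValueError(f"duplicate marker {name!r} across rounds")
            markers.append(name)
            channels.append(aligned[c])

    panel = MarkerPanel(markers=tuple(markers), pixel_size_um=px, rounds=1,
                        dapi_channel_per_round={1: 0})
    image = MultiplexImage(channels=np.stack(channels), panel=panel)
    return image, RegistrationResult(shifts=shifts, peak_correlations=corrs)


def subtract_autofluorescence(image: MultiplexImage, af_channel: str,
                              scale: float = 1.0) -> MultiplexImage:
    """Subtract ``scale * AF`` from every non-DAPI channel, clipped at zero.

    The autofluorescence channel itself is removed from the output panel;
    DAPI is left untouched.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    af_idx = image.panel.index(af_channel)  # KeyError if absent
    af = image.channels[af_idx]
    dapi_idx = set(image.panel.dapi_indices)
    markers, channels = [], []
    for c, name in enumerate(image.panel.markers):
        if c == af_idx:
            continue
        if c in dapi_idx:
            channels.append(image.channels[c])
        else:
            channels.append(np.maximum(0.0, image.channels[c] - scale * af))
        markers.append(name)
    dapi_map = {r: markers.index(image.panel.markers[i])
                for r, i in image.panel.dapi_channel_per_round.items()}
    panel = MarkerPanel(markers=tuple(markers), pixel_size_um=image.pixel_size_um,
                        rounds=image.panel.rounds, dapi_channel_per_round=dapi_map)
    return MultiplexImage(channels=np.stack(channels), panel=panel)
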