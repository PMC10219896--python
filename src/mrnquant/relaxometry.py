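"""Two-point T2 relaxometry and morphometry on nerve regions of interest.

Given co-registered short-echo (TE1) and long-echo (TE2) magnitude images and
a binary nerve mask, each axial slice yields four markers:

* ``t2_app`` — apparent T2 relaxation time,
  ``(TE2 - TE1) / ln(SI(TE1) / SI(TE2))`` in ms;
* ``rho`` — proton spin density, the signal extrapolated to TE = 0,
  ``SI(TE1) / exp(-TE1 / T2_app)`` in arbitrary units;
* ``t2w_signal`` — semiquantitative signal of the T2-weighted (long-echo)
  image in arbitrary units;
* ``csa`` — nerve cross-sectional area, foreground pixel count times the
  squared pixel spacing, in mm².

Signal intensities are averaged over the ROI *before* the formulas are
applied (ROI-first estimation): at the high in-plane resolution needed for
nerve imaging, single-pixel noise makes pixel-wise T2/ρ maps unreliable, and
averaging first suppresses it.  A pixel-wise mode exists for testing the
equivalence of the two estimators on homogeneous tissue.

Slices whose ROI means do not decay (``mean_si1 <= mean_si2``, possible
under noise) have no physical T2 solution; they are flagged invalid and
carried through rather than dropped, so downstream aggregation can account
for them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyROIError,
    IncompleteCoverageError,
    InvalidParameterError,
)
from .protocol import RIGHT_THIGH_SLAB


@dataclass
class DualEchoVolume:
    """Paired short/long-echo magnitude images for one imaging slab.

    Arrays are shaped ``(nx, ny, n_slices)`` (NIfTI axis order); both echoes
    share one grid.  ``slice_offset`` is the global index of the slab's first
    slice in the proximal→distal ordering.
    """

    image_te1: np.ndarray
    image_te2: np.ndarray
    te1: float
    te2: float
    pixel_spacing: float
    slab_id: int
    slice_offset: int = 0
    participant_id: str = ""

    def __post_init__(self):
        self.image_te1 = np.asarray(self.image_te1)
        self.image_te2 = np.asarray(self.image_te2)
        if self.image_te1.shape != self.image_te2.shape:
            raise InvalidParameterError("echo images must share one shape")
        if self.image_te1.ndim != 3:
            raise InvalidParameterError("echo images must be 3-D (x, y, slice)")
        if not 0 < self.te1 < self.te2:
            raise InvalidParameterError("require te2 > te1 > 0")
        if self.pixel_spacing <= 0:
            raise InvalidParameterError("pixel_spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.image_te1.shape[2]

    @property
    def side(self) -> str:
        return "right" if self.slab_id == RIGHT_THIGH_SLAB else "left"


@dataclass
class NerveMask:
    """Binary nerve ROI aligned to a :class:`DualEchoVolume`."""

    mask: np.ndarray
    slab_id: int
    provenance: str = "synthetic"  # or "manual"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise InvalidParameterError("mask must be 3-D (x, y, slice)")


@dataclass
class SliceMeasurement:
    """Per-slice markers for one participant and one axial slice."""

    participant_id: str
    slice_index: int
    slab_id: int
    side: str
    mean_si1: float
    mean_si2: float
    t2_app: float  # ms; NaN when flagged undefined
    rho: float  # a.u.; NaN when flagged undefined
    t2w_signal: float
    csa: float
    valid: bool


@dataclass
class ParticipantProfile:
    """Ordered slice measurements for one participant.

    Left-leg measurements (slabs 1..4) are ordered proximal→distal by global
    slice index; contralateral slab-5 measurements (side ``right``) mirror
    the left mid-to-distal thigh slab.
    """

    participant_id: str
    group: str
    measurements: list = field(default_factory=list)

    def side(self, which: str) -> list:
        return [m for m in self.measurements if m.side == which]

    @property
    def n_valid(self) -> int:
        return sum(m.valid for m in self.measurements)

    @property
    def n_flagged(self) -> int:
        return sum(not m.valid for m in self.measurements)


def roi_mean_signals(volume: DualEchoVolume, mask: NerveMask,
                     slice_index: int) -> tuple[float, float]:
    """Arithmetic mean of masked pixels in each echo image of one slice.

    The ROI mean is taken *before* any relaxometry formula is applied.
    ``slice_index`` is local to the slab (0-based).
    """
    m = mask.mask[:, :, slice_index]
    if not m.any():
        raise EmptyROIError(
            f"slab {volume.slab_id}, local slice {slice_index}: empty nerve ROI"
        )
    si1 = float(volume.image_te1[:, :, slice_index][m].mean())
    si2 = float(volume.image_te2[:, :, slice_index][m].mean())
    return si1, si2


def t2app_from_signals(mean_si1: float, mean_si2: float,
                       te1: float, te2: float) -> float:
    """Apparent T2 in ms from two ROI-mean signals.

    Returns NaN (flagged undefined) when ``mean_si1 <= mean_si2``: the
    measured signal does not decay between the echoes, so no positive T2
    satisfies the mono-exponential model.  Non-positive signals are a
    contract violation and raise.
    """
    if mean_si1 <= 0 or mean_si2 <= 0:
        raise InvalidParameterError("signal intensities must be positive")
    if not te2 > te1:
        raise InvalidParameterError("require te2 > te1")
    if mean_si1 <= mean_si2:
        return math.nan
    return (te2 - te1) / math.log(mean_si1 / mean_si2)


def rho_from_signals(mean_si1: float, t2_app: float, te1: float) -> float:
    """Proton spin density (a.u.): short-echo signal corrected for T2 decay.

    ``rho = mean_si1 / exp(-te1 / t2_app) = mean_si1 * exp(te1 / t2_app)``,
    hence always >= ``mean_si1``.  An undefined (NaN) ``t2_app`` propagates.
    """
    if mean_si1 <= 0:
        raise InvalidParameterError("signal intensity must be positive")
    if math.isnan(t2_app):
        return math.nan
    if t2_app <= 0:
        raise InvalidParameterError("t2_app must be positive when defined")
    return mean_si1 * math.exp(te1 / t2_app)


def t2w_signal(volume: DualEchoVolume, mask: NerveMask,
               slice_index: int) -> float:
    """Semiquantitative T2-weighted nerve signal: ROI mean of the TE2 image."""
    _, si2 = roi_mean_signals(volume, mask, slice_index)
    return si2


def csa(mask: NerveMask, slice_index: int, pixel_spacing: float) -> float:
    """Nerve cross-sectional area in mm²: pixel count × spacing²."""
    m = mask.mask[:, :, slice_index]
    n = int(m.sum())
    if n == 0:
        raise EmptyROIError(f"slab {mask.slab_id}, local slice {slice_index}: "
                            "empty nerve ROI")
    return n * pixel_spacing ** 2


def measure_slice(volume: DualEchoVolume, mask: NerveMask, slice_index: int,
                  pixelwise: bool = False) -> SliceMeasurement:
    """All four markers for one slab-local slice.

    With ``pixelwise=True``, T2 and ρ are computed per pixel and then
    averaged over the ROI (testing mode; noisier on real data).  Pixels or
    slices without physical decay are flagged, never silently dropped.
    """
    si1, si2 = roi_mean_signals(volume, mask, slice_index)
    if pixelwise:
        m = mask.mask[:, :, slice_index]
        p1 = volume.image_te1[:, :, slice_index][m]
        p2 = volume.image_te2[:, :, slice_index][m]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((p1 > 0) & (p2 > 0) & (p1 > p2), p1 / p2, np.nan)
            t2_px = (volume.te2 - volume.te1) / np.log(ratio)
            rho_px = p1 * np.exp(volume.te1 / t2_px)
        t2 = float(np.nanmean(t2_px)) if np.isfinite(t2_px).any() else math.nan
        rho = float(np.nanmean(rho_px)) if np.isfinite(rho_px).any() else math.nan
    else:
        t2 = t2app_from_signals(si1, si2, volume.te1, volume.te2)
        rho = rho_from_signals(si1, t2, volume.te1)
    return SliceMeasurement(
        participant_id=volume.participant_id,
        slice_index=volume.slice_offset + slice_index,
        slab_id=volume.slab_id,
        side=volume.side,
        mean_si1=si1,
        mean_si2=si2,
        t2_app=t2,
        rho=rho,
        t2w_signal=si2,
        csa=csa(mask, slice_index, volume.pixel_spacing),
        valid=not math.isnan(t2),
    )


def compute_profile(volumes: Sequence[DualEchoVolume],
                    masks: Sequence[NerveMask],
                    participant_id: str,
                    group: str = "",
                    expected_left_slabs: Iterable[int] | None = None,
                    pixelwise: bool = False) -> ParticipantProfile:
    """Measure every slice of every supplied slab for one participant.

    ``expected_left_slabs`` (default: the slab ids present) lets callers
    enforce complete anatomical coverage; a missing slab raises
    :class:`~mrnquant.errors.IncompleteCoverageError`.
    """
    if len(volumes) != len(masks):
        raise InvalidParameterError("need one mask per volume")
    present = {v.slab_id for v in volumes}
    if expected_left_slabs is not None:
        missing = set(expected_left_slabs) - present
        if missing:
            raise IncompleteCoverageError(
                f"participant {participant_id}: missing slab(s) {sorted(missing)}"
            )
    measurements = []
    for vol, msk in sorted(zip(volumes, masks), key=lambda vm: vm[0].slab_id):
        if msk.slab_id != vol.slab_id:
            raise InvalidParameterError("mask/volume slab_id mismatch")
        vol.participant_id = vol.participant_id or participant_id
        for s in range(vol.n_slices):
            measurements.append(measure_slice(vol, msk, s, pixelwise=pixelwise))
    measurements.sort(key=lambda m: (m.side, m.slice_index))
    return ParticipantProfile(participant_id=participant_id, group=group,
                              measurements=measurements)


SLICE_COLUMNS = [
    "participant_id", "group", "slice_index", "slab_id", "side",
    "mean_si1", "mean_si2", "t2_app_ms", "rho_au", "t2w_signal_au",
    "csa_mm2", "valid",
]


def profiles_to_frame(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per participant × slice.

    Column dictionary: ``mean_si1``/``mean_si2`` — ROI-mean magnitude signal
    at TE1/TE2 (a.u.); ``t2_app_ms`` — apparent T2 (ms, NaN when flagged);
    ``rho_au`` — proton spin density (a.u., NaN when flagged);
    ``t2w_signal_au`` — long-echo ROI mean (a.u.); ``csa_mm2`` — nerve
    cross-sectional area (mm²); ``valid`` — physical-decay flag.
    """
    rows = []
    for p in profiles:
        for m in p.measurements:
            rows.append((p.participant_id, p.group, m.slice_index, m.slab_id,
                         m.side, m.mean_si1, m.mean_si2, m.t2_app, m.rho,
                         m.t2w_signal, m.csa, m.valid))
    return pd.DataFrame(rows, columns=SLICE_COLUMNS)


def profiles_from_frame(frame: pd.DataFrame) -> list[ParticipantProfile]:
    """Inverse of :func:`profiles_to_frame` (round-trips the slice CSV)."""
    profiles = []
    for (pid, group), sub in frame.groupby(["participant_id", "group"],
                                           sort=True):
        measurements = [
            SliceMeasurement(
                participant_id=pid, slice_index=int(r.slice_index),
                slab_id=int(r.slab_id), side=r.side, mean_si1=r.mean_si1,
                mean_si2=r.mean_si2, t2_app=r.t2_app_ms, rho=r.rho_au,
                t2w_signal=r.t2w_signal_au, csa=r.csa_mm2, valid=bool(r.valid),
            )
            for r in sub.itertuples()
        ]
        measurements.sort(key=lambda m: (m.side, m.slice_index))
        profiles.append(ParticipantProfile(participant_id=pid, group=group,
                                           measurements=measurements))
    return profiles
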