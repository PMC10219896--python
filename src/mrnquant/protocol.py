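"""Acquisition geometry of the dual-echo turbo-spin-echo relaxometry protocol.

The default instance reproduces the study protocol this package emulates:
axial 2D dual-echo TSE with spectral fat saturation, TE1 = 14 ms,
TE2 = 86 ms, four contiguous left-leg slabs of 35 slices each (proximal
thigh down to the tibiotalar joint), one contralateral right mid-to-distal
thigh slab, 3.5 mm slices with a 0.35 mm gap, 170 mm field of view on a
512 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: slab_id of the contralateral (right mid-to-distal thigh) slab
RIGHT_THIGH_SLAB = 5

DEFAULT_SLAB_LABELS = (
    "proximal_thigh",
    "distal_thigh",
    "proximal_lower_leg",
    "distal_lower_leg",
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence timing and slab geometry for one dual-echo acquisition.

    Parameters
    ----------
    te1, te2 : float
        Short and long echo times in ms; ``te2 > te1 > 0``.
    n_slabs_left : int
        Number of contiguous left-leg slabs, ordered proximal to distal.
    slices_per_slab : int
        Axial slices per slab.
    slice_thickness, interslice_gap : float
        Through-plane geometry in mm.
    fov : float
        In-plane field of view in mm (square).
    matrix : int
        Acquisition matrix per side; in-plane pixel spacing is ``fov/matrix``.
    slab_labels : tuple of str
        Anatomical labels of the left-leg slabs, proximal to distal.
    """

    te1: float = 14.0
    te2: float = 86.0
    n_slabs_left: int = 4
    slices_per_slab: int = 35
    slice_thickness: float = 3.5
    interslice_gap: float = 0.35
    fov: float = 170.0
    matrix: int = 512
    slab_labels: tuple = field(default=DEFAULT_SLAB_LABELS)

    def __post_init__(self):
        if not 0 < self.te1 < self.te2:
            raise InvalidParameterError(
                f"require te2 > te1 > 0, got te1={self.te1}, te2={self.te2}"
            )
        if self.slices_per_slab < 1:
            raise InvalidParameterError("slices_per_slab must be >= 1")
        if self.n_slabs_left < 1:
            raise InvalidParameterError("n_slabs_left must be >= 1")
        if self.fov <= 0 or self.matrix < 1:
            raise InvalidParameterError("fov and matrix must be positive")
        if len(self.slab_labels) != self.n_slabs_left:
            object.__setattr__(
                self, "slab_labels",
                tuple(f"slab_{k}" for k in range(1, self.n_slabs_left + 1)),
            )

    @property
    def pixel_spacing(self) -> float:
        """In-plane pixel spacing in mm (``fov / matrix``)."""
        return self.fov / self.matrix

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm²."""
        return self.pixel_spacing ** 2

    @property
    def n_slices_left(self) -> int:
        """Total left-leg slices across all slabs (140 under the default)."""
        return self.n_slabs_left * self.slices_per_slab

    @property
    def slice_spacing(self) -> float:
        """Center-to-center slice distance in mm (thickness + gap)."""
        return self.slice_thickness + self.interslice_gap

    def slab_slice_range(self, slab_id: int) -> range:
        """Global 0-based slice indices owned by a slab (proximal→distal).

        Left-leg slab ``k`` (1-based) owns the half-open range
        ``[(k-1)*slices_per_slab, k*slices_per_slab)``.  The contralateral
        slab mirrors the left mid-to-distal thigh slab (slab 2) and reuses
        its indices.
        """
        if slab_id == RIGHT_THIGH_SLAB:
            slab_id = min(2, self.n_slabs_left)
        if not 1 <= slab_id <= self.n_slabs_left:
            raise InvalidParameterError(f"unknown slab_id {slab_id}")
        start = (slab_id - 1) * self.slices_per_slab
        return range(start, start + self.slices_per_slab)
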