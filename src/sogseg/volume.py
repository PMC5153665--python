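"""Core containers for volume-EM image stacks.

The working representation throughout the package is a 3D scalar array in
(z, y, x) axis order with anisotropic physical voxel sizes in nanometres.
Labelled (DAB/osmiophilic) structures are HIGH intensity by convention; raw
stain-dark data can be inverted at the I/O layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "IntensityRange"]


@dataclass
class VolumeGrid:
    """A 3D scalar intensity volume with physical voxel metadata.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Intensities, kept within ``[0, 2**bit_depth - 1]``. Stored as
        float32 internally so filtering does not quantise prematurely.
    voxel_size : tuple of float, (z, y, x)
        Physical voxel extents in nanometres. May be ``None`` for purely
        voxel-unit work; physical-unit operations will then raise.
    bit_depth : int
        Working intensity domain, default 8 (values 0-255).
    provenance : list of dict
        Append-only record of the operations applied, with parameters.
    name : str
        Free-text dataset reference (e.g. an acquisition id).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    bit_depth: int = 8
    provenance: list[dict] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D (z, y, x); got ndim={self.values.ndim}")
        if self.voxel_size is not None:
            vs = tuple(float(v) for v in self.voxel_size)
            if len(vs) != 3 or any(v <= 0 for v in vs):
                raise ValueError(f"voxel_size must be 3 positive extents (nm); got {self.voxel_size}")
            self.voxel_size = vs
        if not (isinstance(self.bit_depth, (int, np.integer)) and self.bit_depth in (8, 16)):
            raise ValueError(f"bit_depth must be 8 or 16; got {self.bit_depth}")
        lo, hi = float(self.values.min(initial=0)), float(self.values.max(initial=0))
        if lo < 0 or hi > self.domain_max:
            raise ValueError(
                f"values [{lo}, {hi}] outside the {self.bit_depth}-bit domain [0, {self.domain_max}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def domain_max(self) -> float:
        return float(2**self.bit_depth - 1)

    def require_voxel_size(self) -> tuple[float, float, float]:
        if self.voxel_size is None:
            raise ValueError("this operation needs physical voxel sizes, but voxel_size is unset")
        return self.voxel_size

    @property
    def voxel_volume_nm3(self) -> float:
        z, y, x = self.require_voxel_size()
        return z * y * x

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³ (1 µm³ = 1e9 nm³)."""
        return self.voxel_volume_nm3 / 1e9

    def evolve(self, values: np.ndarray, op: str, voxel_size=None, **params) -> "VolumeGrid":
        """Return a copy with new values and one provenance entry appended."""
        entry = {"op": op, **params}
        return dataclasses.replace(
            self,
            values=values,
            voxel_size=self.voxel_size if voxel_size is None else voxel_size,
            provenance=[*self.provenance, entry],
        )


@dataclass(frozen=True)
class IntensityRange:
    """Closed intensity interval [lo, hi] used for range thresholding."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValueError(f"need lo <= hi; got [{self.lo}, {self.hi}]")

    def validate_domain(self, domain_max: float) -> None:
        if self.lo < 0 or self.hi > domain_max:
            raise ValueError(f"range [{self.lo}, {self.hi}] outside intensity domain [0, {domain_max}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values inside the closed interval (both bounds inclusive)."""
        return (values >= self.lo) & (values <= self.hi)
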