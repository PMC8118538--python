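"""In-memory containers for dynamic MR image series and temperature maps.

Images are indexed ``[dynamic, slice, row, col]`` (0-based).  Temperatures
are increases above baseline (ΔT, °C), never absolute temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ComplexImageSeries:
    """A dynamic stack of complex-valued slices with acquisition metadata.

    Parameters
    ----------
    data : complex ndarray, shape (n_dynamics, n_slices, n_rows, n_cols)
        Complex image values (magnitude * exp(i*phase)).
    times : ndarray, shape (n_dynamics,)
        Acquisition time of each dynamic in seconds.  Spacing must be
        uniform and equal to the repetition time.
    pixel_spacing : (float, float)
        In-plane pixel spacing (row, col) in millimetres.
    te : float
        Echo time in seconds.
    b0 : float
        Static field strength in tesla.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    times: np.ndarray
    pixel_spacing: tuple[float, float]
    te: float
    b0: float
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4-D [dynamic, slice, row, col], got {self.data.ndim}-D"
            )
        if not np.iscomplexobj(self.data):
            raise ValueError("data must be complex-valued")
        if self.times.shape != (self.data.shape[0],):
            raise ValueError("times must have one entry per dynamic")
        if self.te <= 0:
            raise ValueError(f"te must be positive, got {self.te}")
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def phase(self) -> np.ndarray:
        """Phase images in radians, wrapped to (−π, π]."""
        return np.angle(self.data)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class TemperatureSeries:
    """Per-pixel temperature-change maps over dynamics with provenance."""

    dT: np.ndarray  # °C, [dynamic, slice, row, col]
    times: np.ndarray  # s, one per dynamic
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    drift_corrected: bool = False
    filtered: bool = False
    lag_samples: int = 0
    _extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dT = np.asarray(self.dT, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.dT.ndim != 4:
            raise ValueError("dT must be 4-D [dynamic, slice, row, col]")
        if self.times.shape != (self.dT.shape[0],):
            raise ValueError("times must have one entry per dynamic")
        if not np.all(np.isfinite(self.dT)):
            raise ValueError("dT must contain only finite values")

    @property
    def n_dynamics(self) -> int:
        return self.dT.shape[0]

    def pixel_curve(self, index: tuple[int, int, int]) -> np.ndarray:
        """Temperature trajectory of a single pixel over all dynamics."""
        s, r, c = index
        return self.dT[:, s, r, c]

    def replace(self, **kw) -> "TemperatureSeries":
        d = dict(
            dT=self.dT,
            times=self.times,
            pixel_spacing=self.pixel_spacing,
            drift_corrected=self.drift_corrected,
            filtered=self.filtered,
            lag_samples=self.lag_samples,
        )
        d.update(kw)
        return TemperatureSeries(**d)
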