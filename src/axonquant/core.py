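"""Shared in-memory containers for calibrated image data and section metadata.

All physical quantities are carried in micrometres (µm) or µm²; pixel units
appear only inside detector internals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

REGIONS = ("BLA", "NAC", "PFC", "VTA", "other")
SEXES = ("male", "female")
ESTROUS_STAGES = ("proestrus", "estrus", "metestrus", "diestrus", "NA")


@dataclass
class ImageStack:
    """A single-channel 3-D intensity volume with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (z, rows, cols)
        Nonnegative fluorescence intensities.
    pixel_size_um : float
        In-plane calibration, µm per pixel (isotropic).
    z_step_um : float
        Spacing between consecutive planes, µm.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected a (z, rows, cols) volume, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class GroundTruth:
    """Simulator-side truth used as the oracle for every detector.

    ``axon_paths`` are polylines in µm coordinates ((x, y) columns);
    ``soma_centers_um`` rows are (x, y, area_um2).
    """

    axon_paths: list = field(default_factory=list)
    total_axon_length_um: float = 0.0
    bouton_centers_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    soma_centers_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    region_label: str = "other"

    def __post_init__(self) -> None:
        self.bouton_centers_um = np.asarray(self.bouton_centers_um, dtype=float).reshape(-1, 2)
        self.soma_centers_um = np.asarray(self.soma_centers_um, dtype=float).reshape(-1, 3)
        if self.region_label not in REGIONS:
            raise ValueError(f"unknown region {self.region_label!r}")
        if self.total_axon_length_um < 0:
            raise ValueError("total_axon_length_um must be nonnegative")

    @property
    def n_boutons(self) -> int:
        return len(self.bouton_centers_um)

    @property
    def n_somata(self) -> int:
        return len(self.soma_centers_um)


@dataclass
class SectionRecord:
    """One anatomical section of one mouse: both channels plus metadata.

    ``roi_px`` is a polygon in pixel coordinates (x, y columns); the centre of
    pixel (row j, col i) is at (i + 0.5, j + 0.5).
    """

    mouse_id: str
    sex: str
    estrous_stage: str
    bregma_um: float
    region: str
    red: ImageStack
    green: ImageStack
    roi_px: np.ndarray
    section_index: int = 0
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.estrous_stage not in ESTROUS_STAGES:
            raise ValueError(f"unknown estrous stage {self.estrous_stage!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        self.roi_px = np.asarray(self.roi_px, dtype=float).reshape(-1, 2)
        # Anterior-posterior sanity: BLA sections live in [-3.0, -1.0] mm,
        # VTA sections in [-3.6, -3.1] mm.
        if self.region == "BLA" and not (-3000.0 <= self.bregma_um <= -1000.0):
            raise ValueError(f"BLA section bregma {self.bregma_um} µm outside [-3000, -1000]")
        if self.region == "VTA" and not (-3600.0 <= self.bregma_um <= -3100.0):
            raise ValueError(f"VTA section bregma {self.bregma_um} µm outside [-3600, -3100]")
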