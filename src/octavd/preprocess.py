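"""De-striping and quality-control gates applied before vessel detection.

En-face angiograms carry two acquisition nuisances this module handles:

* slow illumination gradients and pixel-level noise, removed by a Gaussian
  bandpass in the frequency domain, with an optional directional notch that
  suppresses full-width horizontal white lines caused by eye movement;
* scan-quality gates: a segment image is discarded when it shows more than
  two white lines (high motion) or its device signal-strength index is
  below 40. Segments are gated individually; other segments of the same
  scan stay usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MACULA_SEGMENTS",
    "DISC_SEGMENTS",
    "EnFaceImage",
    "QcReport",
    "gaussian_bandpass",
    "count_white_lines",
    "qc_evaluate",
]

#: Device depth-segment labels, in canonical reporting order.
MACULA_SEGMENTS: Sequence[str] = (
    "superficial_retina", "deep_retina", "outer_retina", "choriocapillaris")
DISC_SEGMENTS: Sequence[str] = (
    "vitreoretinal_interface", "superficial_nerve_head", "rpc", "disc_choroid")

_SEGMENTS_BY_SCAN = {"macula": MACULA_SEGMENTS, "disc": DISC_SEGMENTS}


@dataclass
class EnFaceImage:
    """One grayscale en-face segment image plus its scan metadata."""

    pixels: np.ndarray
    scan_type: str  # macula | disc
    segment_label: str
    laterality: str  # OD | OS
    subject_id: str
    scan_index: int  # 1 | 2
    signal_strength_index: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.scan_type not in _SEGMENTS_BY_SCAN:
            raise ValueError(f"unknown scan_type {self.scan_type!r}")
        if self.segment_label not in _SEGMENTS_BY_SCAN[self.scan_type]:
            raise ValueError(
                f"segment {self.segment_label!r} is not a {self.scan_type} segment")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if self.scan_index not in (1, 2):
            raise ValueError("scan_index must be 1 or 2")


@dataclass(frozen=True)
class QcReport:
    """Per-segment quality-control outcome."""

    white_line_count: int
    high_motion: bool
    ssi_pass: bool
    discarded: bool


def gaussian_bandpass(image: np.ndarray, sigma_low: float = 40.0,
                      sigma_high: float = 1.5, stripe_notch: bool = True,
                      boundary: str = "periodic",
                      notch_width_cycles: float = 1.0) -> np.ndarray:
    """Difference-of-Gaussian bandpass with an optional horizontal-stripe notch.

    The transfer function is ``H = G(sigma_high) - G(sigma_low)`` where
    ``G(s)`` is the Fourier transform of a spatial Gaussian of scale ``s``
    pixels: scales coarser than ``sigma_low`` (including the DC component)
    and finer than ``sigma_high`` are removed. Horizontal white lines
    concentrate spectral energy at near-zero horizontal frequency, which an
    isotropic bandpass leaves untouched; with ``stripe_notch`` a Gaussian
    notch of width ``notch_width_cycles`` cycles/image additionally
    attenuates that band.

    Parameters
    ----------
    sigma_low, sigma_high
        Spatial scales in pixels with ``0 < sigma_high < sigma_low``.
    boundary
        ``periodic`` filters the raw FFT (stripes span the full width, so
        wraparound is harmless for them); ``symmetric`` mirror-pads first.

    Returns
    -------
    Filtered image, same shape, mean approximately zero.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if not (0 < sigma_high < sigma_low):
        raise ValueError("require 0 < sigma_high < sigma_low")
    if boundary not in ("periodic", "symmetric"):
        raise ValueError("boundary must be 'periodic' or 'symmetric'")

    if boundary == "symmetric":
        h, w = image.shape
        padded = np.pad(image, ((h, h), (w, w)), mode="symmetric")
        return gaussian_bandpass(padded, sigma_low, sigma_high, stripe_notch,
                                 "periodic", notch_width_cycles)[h:2 * h, w:2 * w]

    h, w = image.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho2 = fx**2 + fy**2
    two_pi2 = 2.0 * np.pi**2
    transfer = np.exp(-two_pi2 * sigma_high**2 * rho2) \
        - np.exp(-two_pi2 * sigma_low**2 * rho2)
    if stripe_notch:
        width = notch_width_cycles / w  # cycles/pixel
        transfer = transfer * (1.0 - np.exp(-fx**2 / (2.0 * width**2)))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * transfer))


def count_white_lines(image: np.ndarray, z_thresh: float = 3.0,
                      max_row_cv: float = 0.2) -> int:
    """Count full-width horizontal white lines in an image.

    A row is flagged when it is *bright* (row mean exceeds the global mean
    by ``z_thresh`` global standard deviations) and *uniform* across the
    full width (within-row coefficient of variation at most
    ``max_row_cv``). Maximal runs of consecutive flagged rows count as a
    single line, so a multi-row saturated band is one artifact.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D grid")
    if z_thresh <= 0:
        raise ValueError("z_thresh must be > 0")
    mu = image.mean()
    sd = image.std()
    row_mean = image.mean(axis=1)
    row_sd = image.std(axis=1)
    bright = row_mean > mu + z_thresh * sd
    uniform = row_sd <= max_row_cv * np.abs(row_mean)
    flagged = bright & uniform
    # count maximal runs of flagged rows
    padded = np.concatenate([[False], flagged])
    return int(np.sum(~padded[:-1] & flagged))


def qc_evaluate(image: EnFaceImage, white_line_count: int,
                ssi_min: float = 40.0) -> QcReport:
    """Apply the motion and signal-strength gates to one segment image.

    High motion means strictly more than two white lines. Images without a
    recorded signal-strength index pass the SSI gate (the index is device
    metadata that synthetic inputs lack). A discarded segment does not
    implicate the other segments of the same scan.
    """
    if white_line_count < 0:
        raise ValueError("white_line_count must be >= 0")
    high_motion = white_line_count > 2
    ssi = image.signal_strength_index
    ssi_pass = ssi is None or ssi >= ssi_min
    report = QcReport(
        white_line_count=int(white_line_count),
        high_motion=high_motion,
        ssi_pass=ssi_pass,
        discarded=high_motion or not ssi_pass,
    )
    if report.discarded:
        logger.info("QC discard: subject=%s eye=%s segment=%s scan=%d "
                    "white_lines=%d ssi=%s", image.subject_id, image.laterality,
                    image.segment_label, image.scan_index, white_line_count, ssi)
    return report
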