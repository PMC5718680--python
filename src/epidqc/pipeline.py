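"""End-to-end analysis of one portal image into a QAResult."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from . import metrics, phantom as ph, registration as reg
from .simulate import PortalImage

__all__ = ["QAResult", "analyze_image"]


@dataclass(frozen=True)
class QAResult:
    """The five metric groups for one image, comparable against a baseline."""

    imager_label: str
    timestamp: str                      # ISO-8601
    calibration: reg.CalibrationTransform
    polarity: str
    linearity: metrics.LinearityResult
    local_linearity: metrics.LocalLinearityResult
    snr: metrics.SNRResult
    low_contrast: metrics.LowContrastResult
    mtf: metrics.MTFResult

    def summary(self) -> dict[str, float | None]:
        """Flat scalar summary used for baseline comparison and trending."""
        return {
            "rotation_deg": self.calibration.rotation_deg,
            "calibration_residual_px": self.calibration.residual,
            "linearity_max_deviation_pct": self.linearity.max_deviation,
            "local_linearity_worst_pct": self.local_linearity.worst_deviation,
            "mean_snr": (None if self.snr.infinite else self.snr.mean_snr),
            "mtf50_in_plane": self.mtf.in_plane.mtf50,
            "mtf50_cross_plane": self.mtf.cross_plane.mtf50,
        }

    def to_dict(self) -> dict:
        """JSON-serializable full report (non-finite floats become None)."""
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return clean(obj.tolist())
            if isinstance(obj, (np.floating, float)):
                return float(obj) if np.isfinite(obj) else None
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.bool_,)):
                return bool(obj)
            return obj
        return clean({
            "imager_label": self.imager_label,
            "timestamp": self.timestamp,
            "calibration": dataclasses.asdict(self.calibration),
            "polarity": self.polarity,
            "linearity": dataclasses.asdict(self.linearity),
            "local_linearity": dataclasses.asdict(self.local_linearity),
            "snr": dataclasses.asdict(self.snr),
            "low_contrast": dataclasses.asdict(self.low_contrast),
            "mtf": dataclasses.asdict(self.mtf),
            "summary": self.summary(),
        })

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=kwargs.pop("indent", 1), **kwargs)


def analyze_image(image: PortalImage,
                  layout: ph.PhantomLayout | None = None,
                  geometry: ph.BeamGeometry | None = None,
                  corner_seeds=None,
                  snr_convention: str = "variance",
                  mtf_method: str = "profile_fit",
                  timestamp: str | None = None) -> QAResult:
    """Run the full five-metric QA analysis on one portal image.

    Calibrates the phantom position from the corner markers (automatically,
    or from the manual ``corner_seeds`` clicks), localizes every element,
    detects and normalizes the gray-scale polarity, then computes
    linearity, local linearity, SNR, low contrast and MTF.
    """
    layout = layout or ph.build_layout()
    geometry = geometry or ph.BeamGeometry()
    transform = reg.calibrate(image, layout, geometry, corner_seeds=corner_seeds)
    rois = reg.locate_elements(transform, layout, image.imager)
    norm_image, polarity = reg.normalize_polarity(image, rois)
    return QAResult(
        imager_label=image.imager.vendor_label,
        timestamp=timestamp or datetime.now(timezone.utc).isoformat(),
        calibration=transform,
        polarity=polarity,
        linearity=metrics.linearity(norm_image, rois, layout),
        local_linearity=metrics.local_linearity(norm_image, rois, layout),
        snr=metrics.snr(norm_image, rois, layout, convention=snr_convention),
        low_contrast=metrics.low_contrast(norm_image, transform, layout),
        mtf=metrics.mtf(norm_image, transform, layout, method=mtf_method),
    )
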