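"""Flat key/value run configuration.

Every tunable of the pipeline lives under a dotted key (``bandpass.sigma_low``,
``scird.threshold_param``, ...). A config file is a YAML mapping of those flat
keys to scalars or short lists; unknown keys are rejected so typos fail loudly.
The full resolved mapping is snapshot into every run manifest.
"""

from __future__ import annotations

import copy
from typing import Any, Mapping, Optional

import yaml

DEFAULTS: dict[str, Any] = {
    # Gaussian bandpass de-striping (spatial sigmas in pixels)
    "bandpass.sigma_low": 40.0,
    "bandpass.sigma_high": 1.5,
    "bandpass.stripe_notch": True,
    "bandpass.boundary": "periodic",  # periodic | symmetric
    # QC gates
    "qc.z_thresh": 3.0,
    "qc.max_row_cv": 0.2,
    "qc.ssi_min": 40.0,
    # SCIRD filter bank
    "scird.sigma1": [4.0, 6.0, 8.0],
    "scird.sigma2": [1.0, 1.5, 2.0, 3.0],
    "scird.k": [-0.1, -0.05, 0.0, 0.05, 0.1],
    "scird.n_theta": 12,
    "scird.halfsize": 24,
    "scird.scale_norm": "area",  # area | none
    "scird.threshold_method": "percentile",  # percentile | fixed
    "scird.threshold_param": 0.25,
    # Region construction
    "region.disc_interior": "include",  # include | exclude_inside_ellipse | only_inside_ellipse
    "region.od_nasal_side": "right",  # right | left
    # Repeatability statistics
    "repeatability.ci_method": "normal",  # normal | chi2
    # Simulation defaults (study-scale conditions)
    "simulate.grid_size": 304,
    "simulate.n_vessels": 22,
    "simulate.width_min": 1.0,
    "simulate.width_max": 3.0,
    "simulate.curvature_min": 0.0,
    "simulate.curvature_max": 0.02,
    "simulate.vessel_intensity": 180.0,
    "simulate.background_noise_sd": 10.0,
    "simulate.n_artifact_lines": 0,
    "simulate.n_image_subjects": 2,
    "simulate.n_subjects": 47,
    "simulate.true_density_mean": 0.22,
    "simulate.between_subject_sd": 0.05,
    "simulate.within_subject_sd": 0.02,
}


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> dict[str, Any]:
    """Return the default config merged with a YAML file and/or overrides.

    Parameters
    ----------
    path
        Optional path to a YAML file holding a flat ``key: value`` mapping.
    overrides
        Optional in-memory mapping applied after the file.
    """
    cfg = copy.deepcopy(DEFAULTS)
    for source in (_read_yaml(path) if path else {}, overrides or {}):
        for key, value in source.items():
            if key not in DEFAULTS:
                raise KeyError(f"unknown config key: {key!r}")
            cfg[key] = value
    return cfg


def _read_yaml(path: str) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a flat mapping")
    return data
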