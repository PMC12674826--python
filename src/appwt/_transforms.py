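"""Parameter transformations used throughout the package.

Population parameters live on transformed (unbounded) scales: rate and
scale parameters are log-normal, bounded parameters (baseline appetite on
(0, 100) mm, maximal improvement on (0, 100) mm, maximal inhibition on
(0, 1)) use a scaled-logit ("beta-transformed") parameterisation
``x = lo + (hi - lo) * logistic(z)``.
"""

from __future__ import annotations

import numpy as np

# name -> ("log",) or ("logit", lo, hi)
PARAMETER_TRANSFORMS: dict[str, tuple] = {
    "L0": ("logit", 0.0, 100.0),
    "SLP": ("log",),
    "PMAX": ("logit", 0.0, 100.0),
    "Kp": ("log",),
    "WT0": ("log",),
    "Kin": ("log",),
    "Imax": ("logit", 0.0, 1.0),
    "IC50": ("log",),
}

PARAMETER_NAMES = tuple(PARAMETER_TRANSFORMS)

_EPS = 1e-12


def transform(name: str, value):
    """Map a natural-scale parameter value to its unbounded scale."""
    spec = PARAMETER_TRANSFORMS[name]
    value = np.asarray(value, dtype=float)
    if spec[0] == "log":
        return np.log(np.maximum(value, _EPS))
    lo, hi = spec[1], spec[2]
    u = np.clip((value - lo) / (hi - lo), _EPS, 1.0 - _EPS)
    return np.log(u / (1.0 - u))


def untransform(name: str, z):
    """Inverse of :func:`transform`."""
    spec = PARAMETER_TRANSFORMS[name]
    z = np.asarray(z, dtype=float)
    if spec[0] == "log":
        return np.exp(z)
    lo, hi = spec[1], spec[2]
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def transform_dict(values: dict) -> dict:
    return {k: float(transform(k, v)) for k, v in values.items()}


def untransform_dict(zvalues: dict) -> dict:
    return {k: float(untransform(k, z)) for k, z in zvalues.items()}
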