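"""Synthetic fixture generator.

Produces the two kinds of input the coupling pipeline consumes, without
running either solver:

* endocardial wall-pressure fields — a smooth chamber-pressure waveform
  shared by all elements, plus localized deviations (a systolic bump near
  the outlet elements, a filling-jet bump near the apex) and pseudo-random
  noise.  This emulates the observed structure of ventricular wall-pressure
  fields: one dominant mean with the large deviations concentrated near the
  aortic valve during ejection and near the apex during filling.
* periodic wall-motion traces of a contracting chamber — a base-tapered
  radial contraction synchronized with the waveform.

All randomness flows from the explicit ``seed``; equal seeds give equal
fields.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .geometry import ChamberGeometry

__all__ = ["make_synthetic_pressure_field", "make_synthetic_wall_motion",
           "PROFILES"]

PROFILES = ("uniform", "outlet-jet", "apex-jet", "noise")


def _waveform(tau: np.ndarray, p_dia: float, p_sys: float) -> np.ndarray:
    """Smooth one-cycle chamber-pressure trace: diastolic baseline with a
    systolic hump centred at 60% of the cycle."""
    hump = np.exp(-0.5 * ((tau - 0.6) / 0.12) ** 2)
    return p_dia + (p_sys - p_dia) * hump


def make_synthetic_pressure_field(n_elements: int, n_times: int,
                                  profile: str = "outlet-jet",
                                  seed: int = 0,
                                  T_cycle: float = 1.247,
                                  p_dia: float = 1000.0,
                                  p_sys: float = 16000.0,
                                  bump_frac: float = 0.05,
                                  noise_frac: float = 0.01,
                                  outlet_elements: np.ndarray | None = None,
                                  apex_elements: np.ndarray | None = None):
    """Seeded wall-pressure field (times, p) with p of shape (T, E).

    profile:
      "uniform"    — every element carries the bare waveform
      "outlet-jet" — systolic overpressure bump on the outlet elements
      "apex-jet"   — early-filling bump near the apex elements
      "noise"      — waveform plus white noise only

    By default the outlet set is the first 15% of elements and the apex set
    the middle 20% (matching the geometry convention: element 0 at the
    base-right, the apex mid-array).
    """
    if n_elements < 4:
        raise ConfigurationError("need at least 4 elements")
    if profile not in PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; expected one of {PROFILES}")
    rng = np.random.default_rng(seed)
    times = np.arange(n_times) * (T_cycle / n_times)
    tau = times / T_cycle
    base = _waveform(tau, p_dia, p_sys)
    p = np.tile(base[:, None], (1, n_elements))
    if profile == "uniform":
        return times, p

    e = np.arange(n_elements)
    if outlet_elements is None:
        outlet_elements = e[: max(1, n_elements // 7)]
    if apex_elements is None:
        mid = n_elements // 2
        w = max(1, n_elements // 10)
        apex_elements = e[mid - w: mid + w]

    if profile == "outlet-jet":
        gate = np.exp(-0.5 * ((tau - 0.62) / 0.08) ** 2)
        shape = np.zeros(n_elements)
        shape[outlet_elements] = np.hanning(2 * outlet_elements.size)[
            outlet_elements.size:]
        p += bump_frac * p_sys * gate[:, None] * shape[None, :]
    elif profile == "apex-jet":
        gate = np.exp(-0.5 * ((tau - 0.12) / 0.06) ** 2)
        shape = np.zeros(n_elements)
        han = np.hanning(apex_elements.size + 2)[1:-1]
        shape[apex_elements] = han
        p += bump_frac * p_sys * gate[:, None] * shape[None, :]

    p += noise_frac * p_sys * rng.standard_normal(p.shape)
    return times, p


def make_synthetic_wall_motion(geom: ChamberGeometry, n_times: int = 250,
                               T_cycle: float = 1.247,
                               contraction: float = 0.08,
                               taper: float = 1.0,
                               seed: int = 0):
    """Periodic contracting-chamber wall motion (times, node_xy).

    Radial contraction of relative amplitude ``contraction`` follows the
    systolic phase of the pressure waveform and tapers toward the base
    corners with sin(theta)^taper, so the valve plane stays put.
    """
    times = np.arange(n_times) * (T_cycle / n_times)
    tau = times / T_cycle
    hump = np.exp(-0.5 * ((tau - 0.6) / 0.12) ** 2)
    w = np.sin(geom.theta) ** taper if taper > 0 else np.ones_like(geom.theta)
    lam = 1.0 - contraction * hump[:, None] * w[None, :]
    r = lam * geom.r0[None, :]
    xy = np.empty((n_times, geom.n_seg + 1, 2))
    xy[:, :, 0] = r * np.cos(geom.theta)
    xy[:, :, 1] = -r * np.sin(geom.theta)
    return times, xy
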