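"""Population-averaged bi-exponential arterial input function (AIF).

The plasma concentration after a bolus is modeled as

    Cp(t) = a exp(-c1 (t - t0)) + b exp(-c2 (t - t0))   for t >= t0, else 0

with the fast rate c1 (uptake/distribution) strictly larger than the slow
rate c2 (washout/clearance).  Rates are in min^-1 and amplitudes in mM;
time arguments throughout the package are in seconds and converted here.

The default parameter set is the classical gadopentetate population
biexponential scaled to a 0.1 mmol/kg dose; individual AIF measurement is
out of scope, so these values are explicit, documented inputs that users
should confirm for their own cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AIFParams", "evaluate_aif", "aif_integral"]

SECONDS_PER_MINUTE = 60.0


@dataclass
class AIFParams:
    """Bi-exponential plasma curve parameters.

    a, b : amplitudes, mM; c1, c2 : decay rates, min^-1 (c1 > c2 > 0);
    t0 : bolus arrival time, seconds.
    """

    a: float = 0.399
    b: float = 0.478
    c1: float = 0.144
    c2: float = 0.0111
    t0: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.a + self.b <= 0:
            raise ValueError("AIF must have positive total amplitude")
        if not (self.c1 > self.c2 > 0):
            raise ValueError("decay rates must satisfy c1 > c2 > 0")

    def shifted(self, t0: float) -> "AIFParams":
        return AIFParams(self.a, self.b, self.c1, self.c2, t0)


def _minutes_after_arrival(params: AIFParams, time_s) -> np.ndarray:
    return (np.asarray(time_s, dtype=float) - params.t0) / SECONDS_PER_MINUTE


def evaluate_aif(params: AIFParams, time_s) -> np.ndarray:
    """Plasma concentration Cp(t) in mM at times given in seconds."""
    u = _minutes_after_arrival(params, time_s)
    cp = params.a * np.exp(-params.c1 * np.maximum(u, 0.0)) \
        + params.b * np.exp(-params.c2 * np.maximum(u, 0.0))
    return np.where(u >= 0.0, cp, 0.0)


def _kernel_term(amp: float, c: float, kep, u):
    """amp * integral_0^u exp(-c s) exp(-kep (u - s)) ds, elementwise in (kep, u).

    Closed form amp/(kep-c) (exp(-c u) - exp(-kep u)); the removable
    singularity at kep == c is evaluated by its analytic limit
    amp * u * exp(-c u) via a first-order series in (kep - c).
    """
    kep = np.asarray(kep, dtype=float)
    u = np.asarray(u, dtype=float)
    d = kep - c
    near = np.abs(d) < 1e-8
    d_safe = np.where(near, 1.0, d)
    exact = (np.exp(-c * u) - np.exp(-kep * u)) / d_safe
    # limit + first-order correction: u e^{-cu} (1 - d u / 2)
    series = u * np.exp(-c * u) * (1.0 - d * u / 2.0)
    return amp * np.where(near, series, exact)


def aif_integral(params: AIFParams, kep, time_s) -> np.ndarray:
    """Closed-form ``integral_0^t Cp(tau) exp(-kep (t - tau)) dtau`` in mM*min.

    ``kep`` is in min^-1 and may be an array (broadcast against time);
    ``time_s`` in seconds.  Zero before the bolus arrival t0.
    """
    kep = np.asarray(kep, dtype=float)
    if np.any(kep <= 0):
        raise ValueError("kep must be positive")
    u = _minutes_after_arrival(params, time_s)
    upos = np.maximum(u, 0.0)
    out = _kernel_term(params.a, params.c1, kep, upos) \
        + _kernel_term(params.b, params.c2, kep, upos)
    return np.where(u >= 0.0, out, 0.0)


def aif_integral_dkep(params: AIFParams, kep, time_s) -> np.ndarray:
    """Analytic derivative of :func:`aif_integral` with respect to kep (min units)."""
    kep = np.asarray(kep, dtype=float)
    u = _minutes_after_arrival(params, time_s)
    upos = np.maximum(u, 0.0)
    total = np.zeros(np.broadcast_shapes(kep.shape, upos.shape))
    for amp, c in ((params.a, params.c1), (params.b, params.c2)):
        d = kep - c
        near = np.abs(d) < 1e-6
        d_safe = np.where(near, 1.0, d)
        g = (np.exp(-c * upos) - np.exp(-kep * upos)) / d_safe
        exact = (upos * np.exp(-kep * upos) - g) / d_safe
        series = -0.5 * upos ** 2 * np.exp(-c * upos) * (1.0 - d * upos * 2.0 / 3.0)
        total = total + amp * np.where(near, series, exact)
    return np.where(u >= 0.0, total, 0.0)
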