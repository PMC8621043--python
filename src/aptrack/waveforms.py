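"""Charge waveforms Q'(t) for the extended-source forward model.

The waveform is the normalised time course of the travelling charge
distribution.  Two shapes are provided:

* ``gaussian`` — a single positive lobe; analytically convenient because
  the resulting channel potential peaks exactly at the closest-approach
  time, which makes timing tests sharp.
* ``biphasic`` — an asymmetric negative-then-positive pair of lobes, the
  shape extracellular spikes actually take; the dominant first lobe keeps
  peak detection unambiguous.

Amplitudes are normalised on use via the L1 integral so that the total
(absolute) effective charge equals the axon's ``q_prime`` regardless of
shape or duration; in the short-duration limit the extended model then
converges to the point-charge potential.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidWaveformError, ValidationError

_KINDS = ("gaussian", "biphasic")


@dataclass(frozen=True)
class Waveform:
    """Normalized charge time course with compact support.

    Parameters
    ----------
    kind:
        ``"gaussian"`` or ``"biphasic"``.
    duration_s:
        Total support of the waveform in seconds (default 1 ms, a typical
        unmyelinated action-potential duration).  The waveform is zero
        outside ``[-duration_s/2, duration_s/2]``.
    """

    kind: str = "biphasic"
    duration_s: float = 1.0e-3
    _l1: float = field(default=0.0, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown waveform kind {self.kind!r}")
        if not (self.duration_s > 0.0 and np.isfinite(self.duration_s)):
            raise ValidationError("waveform duration must be positive and finite")
        tau = np.linspace(-self.half_support, self.half_support, 4001)
        w = self(tau)
        if not np.all(np.isfinite(w)):
            raise InvalidWaveformError("waveform produced non-finite values")
        l1 = float(np.trapezoid(np.abs(w), tau))
        if l1 <= 0.0:
            raise InvalidWaveformError("waveform has zero L1 mass")
        object.__setattr__(self, "_l1", l1)

    @property
    def half_support(self) -> float:
        return 0.5 * self.duration_s

    @property
    def l1_norm(self) -> float:
        """Integral of |Q'(t)| dt in seconds, used to normalise total charge."""
        return self._l1

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        T = self.duration_s
        out = np.zeros_like(tau)
        inside = np.abs(tau) <= self.half_support
        t = tau[inside]
        if self.kind == "gaussian":
            sigma = T / 6.0
            out[inside] = np.exp(-0.5 * (t / sigma) ** 2)
        else:  # biphasic: dominant early negative lobe, smaller late positive
            s1, s2 = T / 9.0, T / 6.0
            out[inside] = -np.exp(-0.5 * ((t + 0.15 * T) / s1) ** 2) + 0.5 * np.exp(
                -0.5 * ((t - 0.2 * T) / s2) ** 2
            )
        return out if out.shape else float(out)


def gaussian(duration_s: float = 1.0e-3) -> Waveform:
    return Waveform("gaussian", duration_s)


def biphasic(duration_s: float = 1.0e-3) -> Waveform:
    return Waveform("biphasic", duration_s)
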