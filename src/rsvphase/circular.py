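"""Circular arithmetic on 24-hour clock phases.

Acrophases live on a 24-h dial, so clusters that straddle midnight (a peak
at 23:55 one day and 00:22 the next) cannot be averaged or differenced
linearly.  Everything downstream — window means, IQR fences, t-tests,
signed pre/post differences — goes through the three primitives here:
a vector circular mean, an unwrap-about-reference map that turns a dial
sample into ordinary reals, and a signed difference wrapped to half a day.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "UndefinedMeanError",
    "circular_mean_phase",
    "unwrap_phases",
    "phase_difference",
]

_HOURS = 24.0
_RAD_PER_HOUR = 2.0 * np.pi / _HOURS


class UndefinedMeanError(ValueError):
    """Raised when the resultant vector of a phase sample is (numerically) zero."""


def circular_mean_phase(phases) -> float:
    """Circular mean of clock phases, in hours on ``[0, 24)``.

    The mean direction of the unit vectors ``exp(i * 2*pi*phase/24)``:
    the correct average for clock-time data that may span midnight.

    Parameters
    ----------
    phases : array-like of float
        Phases in hours; values are taken modulo 24.

    Raises
    ------
    UndefinedMeanError
        If the mean resultant length is below 1e-9 (perfectly dispersed
        sample, e.g. two antipodal phases), where no mean direction exists.
    """
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("circular_mean_phase requires at least one phase")
    ang = ph * _RAD_PER_HOUR
    c = float(np.cos(ang).mean())
    s = float(np.sin(ang).mean())
    if np.hypot(c, s) < 1e-9:
        raise UndefinedMeanError(
            "mean resultant length < 1e-9: circular mean is undefined"
        )
    mean = float((np.arctan2(s, c) / _RAD_PER_HOUR) % _HOURS)
    return 0.0 if mean >= _HOURS else mean  # modulo can round up to exactly 24.0


def unwrap_phases(phases, reference: float) -> np.ndarray:
    """Map each phase to its unique representative in ``(reference-12, reference+12]``.

    Turns dial-valued phases into plain reals centred on *reference* so
    that interval statistics (quartiles, t-tests, regression) apply.
    Order is preserved and ``unwrapped % 24 == phases % 24``.
    """
    ph = np.asarray(phases, dtype=float)
    d = (ph - reference) % _HOURS
    d = np.where(d > _HOURS / 2, d - _HOURS, d)
    return reference + d


def phase_difference(pre_mean: float, post_mean: float) -> float:
    """Signed circular difference ``post - pre`` in minutes, in ``(-720, 720]``.

    Negative values are phase advances (the post-transition peak occurs
    earlier on the clock), positive values are delays.  The wrap handles
    pairs straddling midnight, e.g. 23:55 pre vs 00:22 post gives +27.
    """
    d = (float(post_mean) - float(pre_mean)) * 60.0
    d = (d + 720.0) % 1440.0 - 720.0
    if d == -720.0:
        d = 720.0
    return float(d)
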