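"""Independent transfer-function oracle for the EMG envelope.

Butterworth coefficients are derived from the analog prototype poles with
a hand-written bilinear transform (no scipy filter design), and the filter
is applied as a direct-form difference equation, forward and backward with
zero initial state.  Away from the series edges this must agree with any
correct zero-phase implementation of the same cascade.
"""

import numpy as np


def _butter_lowpass(order: int, cutoff_hz: float, fs: float):
    """Digital Butterworth low-pass (b, a) via bilinear transform."""
    fs2 = 2.0 * fs
    warped = fs2 * np.tan(np.pi * cutoff_hz / fs)
    k = np.arange(1, order + 1)
    prototype = np.exp(1j * np.pi * (2 * k + order - 1) / (2 * order))  # left half-plane
    poles = warped * prototype
    zd = (fs2 + poles) / (fs2 - poles)
    gain = warped**order / np.prod(fs2 - poles)
    b = np.real(gain * np.poly(-np.ones(order)))
    a = np.real(np.poly(zd))
    return b, a


def _butter_highpass(order: int, cutoff_hz: float, fs: float):
    """Digital Butterworth high-pass (b, a) via bilinear transform."""
    fs2 = 2.0 * fs
    warped = fs2 * np.tan(np.pi * cutoff_hz / fs)
    k = np.arange(1, order + 1)
    prototype = np.exp(1j * np.pi * (2 * k + order - 1) / (2 * order))
    poles = warped / prototype
    zd = (fs2 + poles) / (fs2 - poles)
    gain = fs2**order / np.prod(fs2 - poles)
    b = np.real(gain * np.poly(np.ones(order)))
    a = np.real(np.poly(zd))
    return b, a


def _difference_equation(b, a, x):
    """Direct-form IIR filter, zero initial conditions, extended precision.

    The 20 Hz / 10 Hz cutoffs are tiny fractions of the 2 kHz rate, so the
    direct form is ill-conditioned in float64; accumulating in long double
    keeps the oracle's own rounding well below the comparison tolerance.
    """
    b = np.asarray(b, dtype=np.longdouble) / np.longdouble(a[0])
    a = np.asarray(a, dtype=np.longdouble) / np.longdouble(a[0])
    x = np.asarray(x, dtype=np.longdouble)
    v = np.convolve(x, b)[: x.size]  # moving-average part
    y = np.zeros_like(x)
    for n in range(x.size):
        acc = v[n]
        for j in range(1, len(a)):
            if n - j >= 0:
                acc -= a[j] * y[n - j]
        y[n] = acc
    return y


def _zero_phase(b, a, x):
    y = _difference_equation(b, a, x)
    y = _difference_equation(b, a, y[::-1])
    return y[::-1]


def reference_envelope(raw: np.ndarray, rate: float) -> np.ndarray:
    """Rectify, 20 Hz high-pass, 10 Hz low-pass, each zero phase."""
    b_hp, a_hp = _butter_highpass(4, 20.0, rate)
    b_lp, a_lp = _butter_lowpass(4, 10.0, rate)
    env = _zero_phase(b_hp, a_hp, np.abs(np.asarray(raw, dtype=float)))
    return _zero_phase(b_lp, a_lp, env)
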