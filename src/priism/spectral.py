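"""Discrete Fourier transform utilities for framed expression series.

Convention: forward transform G_n = sum_k g(kT) exp(-i 2 pi n k / N) with no
normalization, inverse g(kT) = (1/N) sum_n G_n exp(i 2 pi n k / N).  This is
numpy.fft's convention, so the FFT is used directly; tests pin it against a
naive summation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import MeanShiftedSeries

__all__ = ["Spectrum", "AmplitudeSpectrum", "dft", "amplitude_spectrum", "idft"]

_SYM_TOL = 1e-9


@dataclass
class Spectrum:
    """Complex Fourier coefficients of one framed series.

    ``frequencies[n] = n / (N * T)`` in cycles per hour; multiply by 24 for
    cycles per day.  For real input the coefficients are conjugate-symmetric:
    G_{N-n} = conj(G_n).
    """

    coefficients: np.ndarray
    sample_interval_h: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)

    @property
    def N(self) -> int:
        return self.coefficients.size

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.N) / (self.N * self.sample_interval_h)

    def is_conjugate_symmetric(self, tol: float = _SYM_TOL) -> bool:
        g = self.coefficients
        return bool(
            np.all(np.abs(g[1:] - np.conj(g[1:][::-1])) <= tol)
            and abs(g[0].imag) <= tol
        )


@dataclass
class AmplitudeSpectrum:
    """Moduli |G_n| over the non-redundant bins n = 0..floor(N/2).

    ``relative_amplitudes`` are normalized by the maximum so the dominant bin
    reads exactly 1; an all-zero spectrum is flagged degenerate and keeps all
    relative amplitudes at zero.
    """

    amplitudes: np.ndarray
    relative_amplitudes: np.ndarray
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return self.amplitudes.size


def dft(s: MeanShiftedSeries | np.ndarray, sample_interval_h: float | None = None) -> Spectrum:
    """Forward DFT of a (mean-shifted) framed series.

    Accepts a :class:`MeanShiftedSeries` or a raw sample array (in which case
    ``sample_interval_h`` is required).
    """
    if isinstance(s, MeanShiftedSeries):
        samples = s.samples
        interval = s.base.T
    else:
        samples = np.asarray(s, dtype=float)
        if sample_interval_h is None:
            raise ValueError("sample_interval_h required for raw arrays")
        interval = float(sample_interval_h)
    if samples.size < 4:
        raise ValueError("series too short for spectral analysis (need >= 4)")
    return Spectrum(np.fft.fft(samples), interval)


def amplitude_spectrum(sp: Spectrum) -> AmplitudeSpectrum:
    """Amplitude spectrum over the non-redundant half of the bins."""
    half = sp.N // 2
    amps = np.abs(sp.coefficients[: half + 1])
    peak = amps.max() if amps.size else 0.0
    if peak == 0.0:
        return AmplitudeSpectrum(amps, np.zeros_like(amps), degenerate=True)
    return AmplitudeSpectrum(amps, amps / peak)


def idft(sp: Spectrum, tol: float = _SYM_TOL) -> np.ndarray:
    """Inverse DFT back to a real series.

    Rejects spectra that are not conjugate-symmetric, since those would invert
    to a complex signal; the (sub-``tol``) imaginary residue of a symmetric
    spectrum is discarded.
    """
    if not sp.is_conjugate_symmetric(max(tol, 1e-6 * np.abs(sp.coefficients).max(initial=0.0))):
        raise ValueError("spectrum is not conjugate-symmetric; inverse would be complex")
    series = np.fft.ifft(sp.coefficients)
    return series.real
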