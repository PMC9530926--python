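"""High-resolution 2f1-f2 DPOAE spectra: synthesis, averaging, unmixing.

A distortion-product otoacoustic emission recorded with swept primaries at
fixed ratio r = f2/f1 is, to a good approximation, the sum of two
components: the nonlinear-distortion ("zero-latency", ZL) component with a
short cochlear delay (~0.5 ms) and a coherent-reflection component with a
much longer delay (~10 ms).  Their interference produces the quasi-periodic
fine structure of the DPOAE spectrum with ripple spacing ~1/delay.  On a
uniform frequency grid the two can be separated in the delay (latency)
domain: an inverse DFT maps the complex spectrum to delay space, energy
beyond a latency cutoff is zeroed, and the forward DFT returns the ZL-only
spectrum.  Band levels are then computed in third-octave bands labelled by
the distortion-product frequency f_DP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DpoaeSpectrum",
    "BandScheme",
    "default_grid",
    "fdp_to_f2",
    "synthesize_spectrum",
    "coherent_average",
    "unmix_zero_latency",
    "band_levels",
]

#: Guard value (dB) reported instead of -inf for a vanishing noise floor.
NOISE_FLOOR_DB = -120.0


def default_grid(f_lo: float = 1000.0, f_hi: float = 4000.0, df: float = 20.0) -> np.ndarray:
    """Uniform f_DP grid, default 1-4 kHz at 20 Hz resolution."""
    n = int(round((f_hi - f_lo) / df)) + 1
    return f_lo + df * np.arange(n)


@dataclass
class DpoaeSpectrum:
    """A complex DPOAE spectrum on a uniform f_DP grid.

    Levels are dB re an arbitrary unit pressure (consistent across the
    pipeline); stimulus bookkeeping (r, L1, L2) rides along as metadata.
    """

    f_dp: np.ndarray
    pressure: np.ndarray
    n_averages: int = 20
    r: float = 1.22
    L1: float = 61.0
    L2: float = 55.0

    def __post_init__(self) -> None:
        self.f_dp = np.asarray(self.f_dp, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=complex)
        if self.f_dp.ndim != 1 or self.pressure.shape != self.f_dp.shape:
            raise ValueError("f_dp and pressure must be matching 1-d arrays")
        if len(self.f_dp) >= 2:
            df = np.diff(self.f_dp)
            if not np.allclose(df, df[0]):
                raise ValueError("frequency grid must be uniform")
        if self.r <= 1:
            raise ValueError("primary ratio r must exceed 1")

    @property
    def df(self) -> float:
        return float(self.f_dp[1] - self.f_dp[0])

    def level_db(self) -> np.ndarray:
        mag = np.abs(self.pressure)
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(mag)


@dataclass
class BandScheme:
    """Third-octave analysis bands labelled by their f_DP center."""

    centers: tuple[float, ...] = (1153.0, 1452.0, 1830.0, 2305.0, 2904.0)
    width: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if not np.all(np.diff(c) > 0):
            raise ValueError("band centers must be strictly increasing")

    def edges(self, center: float) -> tuple[float, float]:
        half = 2.0 ** (self.width / 2.0)
        return center / half, center * half


def fdp_to_f2(f_dp: float | np.ndarray, r: float = 1.22) -> float | np.ndarray:
    """Frequency of the f2 primary probing the cochlear place of 2f1-f2.

    With a fixed primary ratio r = f2/f1, the distortion product
    f_DP = 2 f1 - f2 = f2 (2/r - 1), so f2 = f_DP / (2/r - 1); at the
    standard r = 1.22 this is f2 = 1.564 f_DP.
    """
    if not 1.0 < r < 2.0:
        raise ValueError("r must lie strictly between 1 and 2")
    return f_dp / (2.0 / r - 1.0)


def synthesize_spectrum(
    zl_level: float,
    refl_level: float,
    zl_delay: float = 0.5e-3,
    refl_delay: float = 10e-3,
    noise_level: float = -20.0,
    n_repetitions: int = 20,
    f_dp: np.ndarray | None = None,
    seed: int = 0,
) -> list[DpoaeSpectrum]:
    """Elementary (pre-average) spectra of a two-component DPOAE.

    Each repetition is ZL phasor + reflection phasor + independent complex
    Gaussian noise.  Levels are amplitude levels in dB (20 log10 |p|);
    ``-np.inf`` suppresses a component.  Delays in seconds; the reflection's
    longer delay produces fine-structure ripple with spacing ~ 1/refl_delay.
    """
    if n_repetitions < 0:
        raise ValueError("repetition count must be non-negative")
    for name, d in (("zl_delay", zl_delay), ("refl_delay", refl_delay)):
        if d <= 0:
            raise ValueError(f"{name} must be positive")
    f = default_grid() if f_dp is None else np.asarray(f_dp, dtype=float)
    rng = np.random.default_rng(seed)

    a_zl = 0.0 if np.isneginf(zl_level) else 10.0 ** (zl_level / 20.0)
    a_rf = 0.0 if np.isneginf(refl_level) else 10.0 ** (refl_level / 20.0)
    signal = a_zl * np.exp(-2j * np.pi * f * zl_delay) + a_rf * np.exp(
        -2j * np.pi * f * refl_delay
    )
    # noise_level is the expected per-bin noise power in dB: E|n|^2 = 10^(L/10)
    sigma = 0.0 if np.isneginf(noise_level) else 10.0 ** (noise_level / 20.0)
    out = []
    for _ in range(n_repetitions):
        noise = sigma / np.sqrt(2.0) * (
            rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))
        )
        out.append(DpoaeSpectrum(f_dp=f, pressure=signal + noise, n_averages=1))
    return out


def coherent_average(spectra: list[DpoaeSpectrum]) -> tuple[DpoaeSpectrum, np.ndarray]:
    """Complex mean of elementary spectra plus a per-frequency SNR estimate.

    The noise floor of the average is estimated from half-differences of
    consecutive repetition pairs: for N repetitions of signal + independent
    noise of variance s^2, each half-difference has variance s^2/2, so the
    mean pair power times 2/N estimates the averaged spectrum's noise power
    s^2/N.  SNR (dB) = averaged level - noise-floor level.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to estimate a noise floor")
    f = spectra[0].f_dp
    for s in spectra[1:]:
        if not np.array_equal(s.f_dp, f):
            raise ValueError("spectra must share one frequency grid")
    stack = np.stack([s.pressure for s in spectra])
    n = len(spectra)
    mean = stack.mean(axis=0)

    pairs = stack[: 2 * (n // 2)]
    half_diff = (pairs[0::2] - pairs[1::2]) / 2.0
    noise_power = np.mean(np.abs(half_diff) ** 2, axis=0) * 2.0 / n
    with np.errstate(divide="ignore"):
        noise_db = 10.0 * np.log10(noise_power)
    noise_db = np.maximum(noise_db, NOISE_FLOOR_DB)
    with np.errstate(divide="ignore"):
        sig_db = 20.0 * np.log10(np.abs(mean))
    snr = sig_db - noise_db
    avg = DpoaeSpectrum(
        f_dp=f, pressure=mean, n_averages=n, r=spectra[0].r,
        L1=spectra[0].L1, L2=spectra[0].L2,
    )
    return avg, snr


def unmix_zero_latency(
    spectrum: DpoaeSpectrum, latency_cutoff: float = 4e-3
) -> DpoaeSpectrum:
    """Keep only short-latency (nonlinear-distortion) energy of a spectrum.

    The complex spectrum is mapped to the delay domain by an inverse DFT
    over the uniform grid; bins whose (circular) delay magnitude exceeds
    ``latency_cutoff`` are zeroed; the forward DFT returns the zero-latency
    spectrum on the same grid.  This removes the long-latency coherent
    reflection and with it the fine structure.  The operation is an
    orthogonal projection: idempotent, never power-increasing.
    """
    df = spectrum.df
    max_delay = 1.0 / (2.0 * df)
    if not 0.0 < latency_cutoff < max_delay:
        raise ValueError(
            f"latency_cutoff must lie in (0, {max_delay:.4g}) s for a {df:g} Hz grid"
        )
    q = np.fft.ifft(spectrum.pressure)
    k = len(q)
    delay = np.fft.fftfreq(k, d=df)  # circular delay per bin, seconds
    q[np.abs(delay) > latency_cutoff] = 0.0
    return DpoaeSpectrum(
        f_dp=spectrum.f_dp, pressure=np.fft.fft(q), n_averages=spectrum.n_averages,
        r=spectrum.r, L1=spectrum.L1, L2=spectrum.L2,
    )


def band_levels(
    spectrum: DpoaeSpectrum, scheme: BandScheme | None = None
) -> dict[float, float]:
    """Mean-power level (dB) per third-octave band.

    A bin belongs to the band whose half-open interval
    [center / 2^(w/2), center * 2^(w/2)) contains its f_DP.
    """
    scheme = scheme if scheme is not None else BandScheme()
    power = np.abs(spectrum.pressure) ** 2
    out: dict[float, float] = {}
    for c in scheme.centers:
        lo, hi = scheme.edges(c)
        mask = (spectrum.f_dp >= lo) & (spectrum.f_dp < hi)
        if not mask.any():
            raise ValueError(f"band centered at {c:g} Hz contains no bins")
        mean_pow = float(power[mask].mean())
        out[c] = 10.0 * np.log10(mean_pow) if mean_pow > 0 else -np.inf
    return out
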