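"""Rovibrational spectra from MD trajectories.

A power spectrum is the Fourier transform of the mass-weighted velocity
autocorrelation function of a trajectory; an IR spectrum uses the dipole
autocorrelation instead.  Both use the autocorrelation estimator

    C(tau) = mean over t of x(t) . x(t + tau)

(summed over vector components), a Hann window by default, zero-padding to
the next power of two, and report intensity magnitudes on a wavenumber grid
nu~ = f / c with resolution 1/(n_pad * dt * c).  The zero-frequency bin is
dropped and the grid is truncated at a configurable maximum wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import SPEED_OF_LIGHT_CM_FS
from .dynamics import Trajectory

__all__ = ["Spectrum", "autocorrelation", "power_spectrum", "ir_spectrum"]


@dataclass
class Spectrum:
    """Wavenumber grid (cm^-1, strictly increasing) and intensities (a.u.)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    kind: str = "power"

    def peak(self) -> tuple[float, float]:
        """(wavenumber, intensity) of the global maximum."""
        i = int(np.argmax(self.intensities))
        return float(self.wavenumbers[i]), float(self.intensities[i])

    @property
    def resolution(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def dump(self, path) -> None:
        """Two-column text: wavenumber, intensity."""
        lines = [f"{w:14.6f} {a:18.10e}"
                 for w, a in zip(self.wavenumbers, self.intensities)]
        Path(path).write_text("\n".join(lines) + "\n")

    def plot(self, path=None, ax=None):
        """Render with matplotlib (optional dependency)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.plot(self.wavenumbers, self.intensities, lw=0.8)
        ax.set_xlabel(r"wavenumber / cm$^{-1}$")
        ax.set_ylabel("intensity / a.u.")
        ax.set_title(f"{self.kind} spectrum")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax


def autocorrelation(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased autocorrelation of a (possibly vector-valued) time series.

    ``series`` is (N,) or (N, d); C(tau) is the average of x(t) . x(t+tau)
    over the N - tau available origins t.  Computed via FFT; identical to
    the direct O(N^2) sum to roundoff.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.ndim == 1:
        x = x[:, None]
    N = x.shape[0]
    if max_lag is None:
        max_lag = N - 1
    if max_lag >= N:
        raise ValueError("max_lag must be < series length")
    n_pad = 1 << int(np.ceil(np.log2(2 * N)))
    acf = np.zeros(max_lag + 1)
    for comp in range(x.shape[1]):
        f = np.fft.rfft(x[:, comp], n_pad)
        corr = np.fft.irfft(f * np.conj(f), n_pad)[: max_lag + 1]
        acf += corr
    return acf / (N - np.arange(max_lag + 1))


def _acf_to_spectrum(
    acf: np.ndarray,
    dt: float,
    kind: str,
    window: str = "hann",
    zero_pad: bool = True,
    nu_max: float = 5000.0,
) -> Spectrum:
    n = acf.size
    if window == "hann":
        w = np.hanning(2 * n)[n:]
    elif window in (None, "none", "rect"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    data = acf * w
    n_fft = 1 << int(np.ceil(np.log2(n))) if zero_pad else n
    n_fft = max(n_fft, n)
    spec = np.abs(np.fft.rfft(data, n_fft))
    freq = np.fft.rfftfreq(n_fft, d=dt)          # 1/fs
    wavenumbers = freq / SPEED_OF_LIGHT_CM_FS    # cm^-1
    keep = (wavenumbers > 0) & (wavenumbers <= nu_max)
    return Spectrum(wavenumbers[keep], spec[keep], kind=kind)


def power_spectrum(
    traj: Trajectory,
    masses: np.ndarray | None = None,
    max_lag: int | None = None,
    window: str = "hann",
    nu_max: float = 5000.0,
) -> Spectrum:
    """Power spectrum from the mass-weighted velocity autocorrelation.

    ``masses`` weight the per-atom velocity autocorrelations (unit weights
    when omitted).  The trajectory must carry velocities on a uniform time
    grid.
    """
    v = traj.velocities_array()               # (N, natoms, 3)
    if v.size == 0:
        raise ValueError("trajectory has no velocities")
    N, natoms, _ = v.shape
    if masses is None:
        masses = np.ones(natoms)
    masses = np.asarray(masses, dtype=float)
    acf = None
    for i in range(natoms):
        a = autocorrelation(v[:, i, :], max_lag)
        acf = masses[i] * a if acf is None else acf + masses[i] * a
    return _acf_to_spectrum(acf, traj.dt, "power", window=window, nu_max=nu_max)


def ir_spectrum(
    traj_or_dipoles,
    dt: float | None = None,
    max_lag: int | None = None,
    window: str = "hann",
    nu_max: float = 5000.0,
    quantum_correction=None,
    subtract_mean: bool = True,
) -> Spectrum:
    """IR spectrum from the dipole autocorrelation of a trajectory.

    Accepts a :class:`Trajectory` with dipoles or a raw (N, 3)/(N,) dipole
    series plus its time step in fs.  The time-mean dipole is subtracted by
    default (the permanent dipole only contributes at zero frequency and
    would otherwise leak into the low-frequency bins through the window).
    ``quantum_correction`` is an optional callable
    ``f(wavenumbers) -> prefactor`` applied to the intensities (off by
    default).
    """
    if isinstance(traj_or_dipoles, Trajectory):
        mu = traj_or_dipoles.dipoles_array()
        dt = traj_or_dipoles.dt
    else:
        if dt is None:
            raise ValueError("dt is required with a raw dipole series")
        mu = np.asarray(traj_or_dipoles, dtype=float)
    if subtract_mean:
        mu = mu - mu.mean(axis=0, keepdims=True) if mu.ndim > 1 else mu - mu.mean()
    acf = autocorrelation(mu, max_lag)
    spec = _acf_to_spectrum(acf, dt, "ir", window=window, nu_max=nu_max)
    if quantum_correction is not None:
        spec.intensities = spec.intensities * quantum_correction(spec.wavenumbers)
    return spec
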