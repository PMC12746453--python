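"""Gaussian laser pulses, field tables and spectral diagnostics.

The pulse is a Gaussian-envelope carrier

    E(t) = E0 * exp(-4 ln2 (t - tc)^2 / FWHM^2) * cos(w0 (t - tc) + theta) * e

where FWHM is the full width at half maximum of the *field envelope*.  The
experiment-facing durations (20/100/500 fs) are intensity FWHMs; since the
intensity is the squared envelope, ``FWHM_field = sqrt(2) * FWHM_intensity``.
Fields are real 3-vectors; tables are plain uniform time grids.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .units import AUT_FS, HARTREE_EV, au_to_fs, ev_to_au, fs_to_au

__all__ = [
    "LaserPulse",
    "FieldTable",
    "from_intensity_fwhm",
    "power_spectrum",
    "read_laser_file",
    "write_laser_file",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclasses.dataclass
class LaserPulse:
    """Gaussian pulse in atomic units (time, field, angular frequency)."""

    e0: float
    fwhm_field: float          # FWHM of the field envelope, atomic time units
    omega0: float              # carrier angular frequency, hartree
    t_c: float = 0.0
    theta: float = 0.0
    polarization: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self):
        if self.e0 < 0:
            raise ValueError("field amplitude must be non-negative")
        if self.fwhm_field <= 0:
            raise ValueError("field FWHM must be positive")
        self.polarization = np.asarray(self.polarization, dtype=float)
        self.polarization = self.polarization / np.linalg.norm(self.polarization)

    # -- unit-convenience accessors -------------------------------------
    @property
    def omega0_ev(self) -> float:
        return self.omega0 * HARTREE_EV

    @property
    def fwhm_field_fs(self) -> float:
        return au_to_fs(self.fwhm_field)

    @property
    def fwhm_intensity_fs(self) -> float:
        return au_to_fs(self.fwhm_field) / np.sqrt(2.0)

    @property
    def tau(self) -> float:
        """Gaussian parameter of the exp(-t^2/2 tau^2) envelope convention."""
        return self.fwhm_field / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    # -- evaluation ------------------------------------------------------
    def envelope(self, t):
        t = np.asarray(t, dtype=float)
        return self.e0 * np.exp(-_4LN2 * (t - self.t_c) ** 2 / self.fwhm_field**2)

    def field_at(self, t):
        """Exact 3-vector field at time ``t`` (au); broadcasts over arrays."""
        t = np.asarray(t, dtype=float)
        scalar = self.envelope(t) * np.cos(
            self.omega0 * (t - self.t_c) + self.theta
        )
        return scalar[..., None] * self.polarization

    def sample(self, dt: float, cutoff: float = 1e-8, block: int = 1) -> "FieldTable":
        """Sample the pulse on a uniform grid of spacing ``dt`` (au).

        The table spans the interval where the envelope exceeds
        ``cutoff * E0``; the grid is aligned so that ``t_c`` lies on a grid
        point, and the number of steps before ``t_c`` is a multiple of
        ``block`` (so that stride-decimated storage keeps ``t_c`` on the
        stored grid).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if cutoff <= 0:
            raise ValueError(
                "cutoff must be positive: a Gaussian envelope has unbounded support"
            )
        half = self.fwhm_field * np.sqrt(np.log(1.0 / cutoff) / _4LN2)
        n_half = int(np.ceil(half / dt / block)) * block
        times = self.t_c + dt * np.arange(-n_half, n_half + 1)
        return FieldTable(times=times, field=self.field_at(times))


def from_intensity_fwhm(
    fwhm_intensity_fs: float,
    omega0_ev: float,
    e0: float = 0.001,
    t_c_fs: float = 0.0,
    theta: float = 0.0,
    polarization=(0.0, 0.0, 1.0),
) -> LaserPulse:
    """Build a pulse from study-style parameters (intensity FWHM in fs,
    carrier energy in eV, amplitude in au)."""
    if fwhm_intensity_fs <= 0:
        raise ValueError("intensity FWHM must be positive")
    return LaserPulse(
        e0=e0,
        fwhm_field=fs_to_au(fwhm_intensity_fs) * np.sqrt(2.0),
        omega0=ev_to_au(omega0_ev),
        t_c=fs_to_au(t_c_fs),
        theta=theta,
        polarization=np.asarray(polarization, dtype=float),
    )


@dataclasses.dataclass
class FieldTable:
    """Sampled electric field: uniform times (au) and (n, 3) field (au)."""

    times: np.ndarray
    field: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.field = np.asarray(self.field, dtype=float)
        if self.field.shape != (self.times.size, 3):
            raise ValueError("field must have shape (n_times, 3)")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.field)):
            raise ValueError("field table contains non-finite values")
        dts = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(
            dts, dts[0], rtol=1e-9, atol=1e-12
        ):
            raise ValueError("field table requires a uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def midpoint_field(self) -> np.ndarray:
        """Field at interval midpoints (linear interpolation), (n-1, 3)."""
        return 0.5 * (self.field[:-1] + self.field[1:])


def power_spectrum(table: FieldTable, pad_to: int = 1 << 20, dc_tol: float = 1e-4):
    """Discrete power spectrum of a sampled field.

    Returns ``(omega, intensity, info)`` with angular frequencies in hartree,
    the Fourier magnitude squared of the field (summed over Cartesian
    components), and diagnostics: spectral intensity FWHM in eV (``fwhm_ev``,
    half-maximum crossings by linear interpolation), peak position
    (``peak_ev``) and the zero-frequency fraction ``dc_fraction`` which is
    flagged when above ``dc_tol``.  Warns if the envelope has not decayed at
    the table ends (truncated pulse).
    """
    amp = np.linalg.norm(table.field, axis=1)
    peak = amp.max()
    if peak > 0 and max(amp[0], amp[-1]) > 1e-3 * peak:
        warnings.warn("field table appears truncated; spectrum may be distorted")
    n = max(pad_to, table.times.size)
    ft = np.fft.rfft(table.field, n=n, axis=0) * table.dt
    intensity = np.sum(np.abs(ft) ** 2, axis=1)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=table.dt)

    ipk = int(np.argmax(intensity))
    half = intensity[ipk] / 2.0

    def crossing(i0, step):
        i = i0
        while 0 <= i + step < intensity.size and intensity[i + step] > half:
            i += step
        j = i + step
        if j < 0 or j >= intensity.size:
            return omega[i]
        f = (intensity[i] - half) / (intensity[i] - intensity[j])
        return omega[i] + f * (omega[j] - omega[i])

    lo = crossing(ipk, -1)
    hi = crossing(ipk, +1)
    dc_fraction = float(intensity[0] / intensity[ipk]) if intensity[ipk] > 0 else 0.0
    info = {
        "fwhm_ev": float((hi - lo) * HARTREE_EV),
        "peak_ev": float(omega[ipk] * HARTREE_EV),
        "dc_fraction": dc_fraction,
        "dc_flagged": dc_fraction > dc_tol,
    }
    return omega, intensity, info


def write_laser_file(path, table: FieldTable, time_unit: str = "fs") -> None:
    """Write a plain-text laser file: time, Ex, Ey, Ez columns."""
    scale = AUT_FS if time_unit == "fs" else 1.0
    with open(path, "w") as fh:
        fh.write("# eoexcite laser file v1\n")
        fh.write(f"# time_unit {time_unit}\n")
        fh.write("# columns: t Ex Ey Ez  (field in au)\n")
        np.savetxt(fh, np.column_stack([table.times * scale, table.field]))


def read_laser_file(path) -> FieldTable:
    """Read a laser file written by :func:`write_laser_file` (or any text
    table with a ``# time_unit fs|au`` header line)."""
    time_unit = "au"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "time_unit" in line:
                time_unit = line.split()[-1]
            if not line.startswith("#"):
                break
    data = np.loadtxt(path)
    times = data[:, 0] / (AUT_FS if time_unit == "fs" else 1.0)
    return FieldTable(times=times, field=data[:, 1:4])
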