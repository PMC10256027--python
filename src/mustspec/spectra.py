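"""Spectra data model and preprocessing for NIR must calibration.

A :class:`Spectrum` is one wavelength-indexed intensity vector from the
miniaturized transmission instrument (1100--1350 nm, 5 mm path, samples
measured at 10/14/18 degC against a 20 degC water blank), tagged with the
sample id, grape variety, measurement temperature and a processing-state
tag.  Processing states form a one-way chain::

    raw_transmission -> absorbance -> snv -> snv_sg1

``absorbance`` is -log10(I_sample / I_water); ``snv`` is the standard
normal variate (per-spectrum centering and scaling, removing multiplicative
scatter and offset effects); ``snv_sg1`` is the Savitzky--Golay first
derivative (7 points, polynomial order 2 by default), the representation
the regression models are built on.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectraCollection",
    "OutlierReport",
    "SpectraError",
    "StateError",
    "GridError",
    "DegenerateSpectrumError",
    "snv",
    "savgol_weights",
    "savgol_first_derivative",
    "preprocess",
    "to_absorbance",
    "flag_outliers",
    "STATES",
]

#: Processing states in pipeline order.
STATES = ("raw_transmission", "absorbance", "snv", "snv_sg1")
_NEXT_STATE = {
    "raw_transmission": "absorbance",
    "absorbance": "snv",
    "snv": "snv_sg1",
}

#: Default instrument wavelength bounds (nm).
WAVELENGTH_MIN = 1100.0
WAVELENGTH_MAX = 1350.0
_BOUNDS_TOL = 1e-6


class SpectraError(ValueError):
    """Base class for spectra validation and processing errors."""


class StateError(SpectraError):
    """Operation applied to a spectrum in the wrong processing state."""


class GridError(SpectraError):
    """Wavelength grids are invalid or incompatible."""


class DegenerateSpectrumError(SpectraError):
    """A spectrum is degenerate for the requested operation (e.g. constant)."""


@dataclass(eq=False)
class Spectrum:
    """One spectrum with its acquisition metadata and processing state.

    Parameters
    ----------
    sample_id:
        Identifier of the must sample the spectrum belongs to; the three
        temperature replicates of one sample share this id.
    variety:
        Grape variety name (e.g. ``"Riesling"``).
    temperature_c:
        Sample temperature during acquisition, degC.
    wavelengths_nm:
        Strictly increasing wavelength grid in nm, within the instrument
        bounds [1100, 1350].
    values:
        Intensity/absorbance values, same length as the grid (>= 7 points
        so the Savitzky--Golay window fits).
    state:
        One of :data:`STATES`.
    date:
        Optional ISO acquisition date.
    """

    sample_id: str
    variety: str
    temperature_c: float
    wavelengths_nm: np.ndarray
    values: np.ndarray
    state: str
    date: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in STATES:
            raise StateError(
                f"unknown processing state {self.state!r}; expected one of {STATES}"
            )
        if self.wavelengths_nm.ndim != 1 or self.values.ndim != 1:
            raise SpectraError("wavelengths and values must be 1-D vectors")
        if self.wavelengths_nm.shape != self.values.shape:
            raise SpectraError(
                f"wavelengths ({self.wavelengths_nm.size}) and values "
                f"({self.values.size}) differ in length"
            )
        if self.wavelengths_nm.size < 7:
            raise SpectraError(
                "spectrum needs >= 7 points (Savitzky-Golay window must fit), "
                f"got {self.wavelengths_nm.size}"
            )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise GridError("wavelengths must be strictly increasing")
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if lo < WAVELENGTH_MIN - _BOUNDS_TOL or hi > WAVELENGTH_MAX + _BOUNDS_TOL:
            raise GridError(
                f"wavelengths [{lo:.2f}, {hi:.2f}] outside instrument bounds "
                f"[{WAVELENGTH_MIN:.0f}, {WAVELENGTH_MAX:.0f}] nm"
            )

    # arrays make the generated dataclass __eq__ unusable
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.variety == other.variety
            and self.temperature_c == other.temperature_c
            and self.date == other.date
            and self.state == other.state
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.values, other.values)
        )

    @property
    def n_points(self) -> int:
        return int(self.wavelengths_nm.size)

    def advanced(self, values: np.ndarray, new_state: str,
                 wavelengths_nm: np.ndarray | None = None) -> "Spectrum":
        """Return a copy advanced one step along the processing chain."""
        allowed = _NEXT_STATE.get(self.state)
        if allowed is None or new_state != allowed:
            raise StateError(
                f"cannot move spectrum from state {self.state!r} to {new_state!r}; "
                f"states advance only along {' -> '.join(STATES)}"
            )
        wl = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return replace(self, values=np.asarray(values, float),
                       wavelengths_nm=np.asarray(wl, float), state=new_state)


@dataclass
class SpectraCollection:
    """An ordered list of spectra, optionally sharing one wavelength grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraCollection):
            return NotImplemented
        return self.spectra == other.spectra

    @property
    def uniform_grid(self) -> bool:
        """True when all member spectra share one wavelength grid."""
        if not self.spectra:
            return True
        g0 = self.spectra[0].wavelengths_nm
        return all(np.array_equal(s.wavelengths_nm, g0) for s in self.spectra[1:])

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            raise GridError("empty collection has no grid")
        if not self.uniform_grid:
            raise GridError("collection spectra do not share one wavelength grid")
        return self.spectra[0].wavelengths_nm

    def values_matrix(self) -> np.ndarray:
        """Stack values into an (n_spectra, n_wavelengths) matrix.

        Requires a uniform grid; this is the regression design matrix.
        """
        _ = self.grid  # validates uniformity / non-emptiness
        return np.vstack([s.values for s in self.spectra])


@dataclass
class OutlierReport:
    """Result of robust outlier screening of a spectra collection."""

    kept: np.ndarray           # bool, True = kept
    scores: np.ndarray         # robust distance per spectrum
    threshold: float           # flagging threshold k
    rule: str = "mad-median-absorbance"

    @property
    def n_excluded(self) -> int:
        return int((~self.kept).sum())

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Output is ``(x - mean(x)) / sd(x)`` with the n-1 (sample) standard
    deviation, so the result has mean 0 and sample sd 1 exactly.  SNV makes
    the spectrum invariant to per-spectrum multiplicative gain and additive
    offset, the dominant scatter artifacts in turbid must.

    Raises
    ------
    StateError
        If the spectrum is not in the ``absorbance`` state.
    DegenerateSpectrumError
        If the spectrum is constant (zero standard deviation).
    """
    x = s.values
    if not np.all(np.isfinite(x)):
        raise SpectraError(f"non-finite values in spectrum {s.sample_id!r}")
    sd = float(np.std(x, ddof=1))
    scale = max(1.0, float(np.max(np.abs(x))))
    if sd <= 1e-13 * scale:
        raise DegenerateSpectrumError(
            f"constant spectrum {s.sample_id!r}: SNV undefined (sd = {sd:g})"
        )
    return s.advanced((x - x.mean()) / sd, "snv")


def savgol_weights(window: int, polyorder: int, deriv: int = 1) -> np.ndarray:
    """Savitzky--Golay convolution weights from local least squares.

    The weights are derived from first principles: fit a polynomial of
    degree ``polyorder`` through the ``window`` points centered on the
    target point (in units of the grid step) and read off the ``deriv``-th
    derivative of the fit at the center.  Because the fit is linear in the
    data, the derivative is a fixed linear combination of the window
    values; this returns that weight vector (to be scaled by
    ``deriv! / step**deriv`` for physical units — handled by the caller).
    """
    if window % 2 != 1 or window < 3:
        raise SpectraError(f"window must be odd and >= 3, got {window}")
    if not 0 <= polyorder < window:
        raise SpectraError(
            f"polyorder must satisfy 0 <= polyorder < window, got {polyorder}"
        )
    if not 0 <= deriv <= polyorder:
        raise SpectraError("derivative order must be <= polyorder")
    half = window // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    design = np.vander(offsets, polyorder + 1, increasing=True)
    # row `deriv` of the pseudoinverse gives the deriv-th polynomial
    # coefficient of the local fit; derivative at center = deriv! * coeff
    coeff_rows = np.linalg.pinv(design)
    return coeff_rows[deriv] * math.factorial(deriv)


def savgol_first_derivative(s: Spectrum, window: int = 7, polyorder: int = 2) -> Spectrum:
    """Savitzky--Golay first derivative on a uniform wavelength grid.

    The output is scaled by 1/step so units are absorbance-equivalent per
    nm, and the grid is truncated to interior points (half a window dropped
    at each edge) — extrapolated edge derivatives are artifact-prone and
    never used downstream.
    """
    steps = np.diff(s.wavelengths_nm)
    step = float(steps[0])
    if not np.allclose(steps, step, rtol=1e-8, atol=1e-10):
        raise GridError("Savitzky-Golay derivative requires a uniform wavelength grid")
    if s.n_points < window:
        raise SpectraError(
            f"spectrum length {s.n_points} shorter than window {window}"
        )
    w = savgol_weights(window, polyorder, deriv=1)
    half = window // 2
    # out[j] = sum_k w[k] * x[j + k]  (valid convolution with reversed kernel)
    deriv = np.convolve(s.values, w[::-1], mode="valid") / step
    return s.advanced(deriv, "snv_sg1", wavelengths_nm=s.wavelengths_nm[half:-half])


def preprocess(s: Spectrum, window: int = 7, polyorder: int = 2) -> Spectrum:
    """Full preprocessing chain: SNV, then Savitzky--Golay first derivative.

    Input must be in the ``absorbance`` state; output is ``snv_sg1`` on the
    interior grid.  The composition is invariant to per-spectrum affine
    (gain/offset) transforms of the absorbance, which is the point: scatter
    effects cancel before the derivative sharpens the analyte bands.
    """
    if s.state != "absorbance":
        raise StateError(
            f"preprocess expects an 'absorbance' spectrum, got {s.state!r}"
        )
    return savgol_first_derivative(snv(s), window=window, polyorder=polyorder)


def to_absorbance(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Water-blank referencing: A(lambda) = -log10(I_sample / I_reference).

    Both inputs must be raw transmission spectra on the identical
    wavelength grid; the reference (water at 20 degC) must be strictly
    positive everywhere.
    """
    if sample.state != "raw_transmission" or reference.state != "raw_transmission":
        raise StateError(
            "referencing requires raw_transmission spectra, got "
            f"{sample.state!r} / {reference.state!r}"
        )
    if not np.array_equal(sample.wavelengths_nm, reference.wavelengths_nm):
        raise GridError("sample and reference wavelength grids differ")
    if np.any(reference.values <= 0):
        raise SpectraError("reference (water blank) intensities must be strictly positive")
    if np.any(sample.values <= 0):
        raise SpectraError("sample intensities must be strictly positive for -log10")
    return sample.advanced(-np.log10(sample.values / reference.values), "absorbance")


def flag_outliers(collection: SpectraCollection, k: float = 3.5) -> OutlierReport:
    """Flag spectra whose overall absorbance level is inconsistent with the set.

    Insufficient water-blank referencing shifts the whole spectrum, so the
    score is the robust z-distance of each spectrum's median absorbance
    from the collection median, scaled by 1.4826 x MAD.  Spectra with
    score > ``k`` (default 3.5, the conventional robust cut) are excluded.

    Collections with fewer than 3 spectra are returned unflagged with a
    warning — no meaningful spread can be estimated.
    """
    n = len(collection)
    if n == 0:
        raise SpectraError("cannot screen an empty collection")
    _ = collection.grid  # uniform-grid precondition
    medians = np.array([float(np.median(s.values)) for s in collection])
    if n < 3:
        warnings.warn(
            f"only {n} spectra: outlier screening skipped, all kept", stacklevel=2
        )
        return OutlierReport(kept=np.ones(n, bool), scores=np.zeros(n), threshold=k)
    center = float(np.median(medians))
    mad = float(np.median(np.abs(medians - center)))
    scale = max(1.4826 * mad, 1e-12 * max(1.0, abs(center)))
    scores = np.abs(medians - center) / scale
    kept = ~(scores > k)
    return OutlierReport(kept=kept, scores=scores, threshold=k)
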