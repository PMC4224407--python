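"""Inversion-recovery T1 relaxometry.

Signal model
------------
A magnitude inversion-recovery acquisition with fixed repetition time TR
samples, at each inversion time TI,

    S(TI) = S0 * | 1 - 2 exp(-TI/T1) + exp(-TR/T1) |

with perfect inversion (efficiency fixed at 2) and the constant echo-time
weighting absorbed into the amplitude S0.  Pixel-wise estimates of
(T1, S0) are obtained by Nelder-Mead simplex minimization of the residual
sum of squares over the series of images, seeded by a coarse grid search
over T1 to step over the null-point local minima of the magnitude signal.

Fitted T1 values outside the physiological acceptance window
[400, 1500] ms are flagged invalid and excluded from all downstream
statistics.

Mis-normalized series (scanner auto-scaling left on, one unknown positive
scale per image) are corrected against subcutaneous fat: fat T1 is
constant across the study, so the observed per-image fat means must lie
on the model curve for the configured fat T1; per-image multipliers that
put them there are estimated by least squares and applied to the whole
image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import CorrectionError, InputError, ProtocolError, StateError

__all__ = [
    "AcquisitionProtocol",
    "IRSeries",
    "T1Map",
    "FatReference",
    "DEFAULT_TI_MS",
    "T1_VALID_MIN_MS",
    "T1_VALID_MAX_MS",
    "ir_signal",
    "fit_t1_pixel",
    "fit_t1_map",
    "normalization_factors",
    "apply_normalization",
]

#: Inversion times of the 7-image protocol, ms.
DEFAULT_TI_MS: tuple[float, ...] = (50.0, 150.0, 350.0, 700.0, 1050.0, 1400.0, 2000.0)

#: Validity window applied to fitted T1 before any averaging, ms.
T1_VALID_MIN_MS = 400.0
T1_VALID_MAX_MS = 1500.0

#: Default reference T1 of subcutaneous fat at 3 T, ms.  A configuration
#: knob, not a measured constant; override to match the scanner/field.
DEFAULT_FAT_T1_MS = 380.0

_T1_GRID_MS = np.arange(200.0, 2000.1, 100.0)
_SIMPLEX_RTOL = 1e-6
_SIMPLEX_MAXITER = 2000


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of one inversion-recovery series.

    Parameters
    ----------
    tr_ms : repetition time, ms.
    te_ms : echo time, ms (informational; not part of the signal model).
    ti_ms : strictly increasing inversion times, ms.
    field_strength_T : nominal field strength, tesla (informational).
    matrix : acquisition matrix (rows, cols).
    fov_mm : field of view (x, y), mm.
    slice_thickness_mm : slice thickness, mm.
    """

    tr_ms: float = 1800.0
    te_ms: float = 13.0
    ti_ms: tuple[float, ...] = DEFAULT_TI_MS
    field_strength_T: float = 3.0
    matrix: tuple[int, int] = (512, 512)
    fov_mm: tuple[float, float] = (300.0, 300.0)
    slice_thickness_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ProtocolError(f"tr_ms must be positive, got {self.tr_ms}")
        ti = np.asarray(self.ti_ms, dtype=float)
        if ti.ndim != 1 or ti.size == 0:
            raise ProtocolError("ti_ms must be a non-empty sequence")
        if np.any(ti <= 0):
            raise ProtocolError("all inversion times must be positive")
        if np.any(np.diff(ti) <= 0):
            raise ProtocolError("inversion times must be strictly increasing")
        if np.any(ti >= 2 * self.tr_ms):
            raise ProtocolError("inversion times must be < 2*TR")
        object.__setattr__(self, "ti_ms", tuple(float(t) for t in ti))

    @property
    def n_ti(self) -> int:
        return len(self.ti_ms)

    def to_dict(self) -> dict:
        return {
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "ti_ms": list(self.ti_ms),
            "field_strength_T": self.field_strength_T,
            "matrix": list(self.matrix),
            "fov_mm": list(self.fov_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            tr_ms=float(d["tr_ms"]),
            te_ms=float(d.get("te_ms", 13.0)),
            ti_ms=tuple(float(t) for t in d["ti_ms"]),
            field_strength_T=float(d.get("field_strength_T", 3.0)),
            matrix=tuple(d.get("matrix", (512, 512))),
            fov_mm=tuple(d.get("fov_mm", (300.0, 300.0))),
            slice_thickness_mm=float(d.get("slice_thickness_mm", 3.0)),
        )


@dataclass
class SeriesMeta:
    """Study provenance of one series."""

    subject: str = ""
    disc_level: str = ""
    timepoint: str = ""  # "pre-bedrest" | "post-bedrest"
    contrast_state: str = ""  # "native" | "post-contrast"
    slice_index: int = 0
    autonormalized: bool = False  # scanner auto-scaling was left on

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "disc_level": self.disc_level,
            "timepoint": self.timepoint,
            "contrast_state": self.contrast_state,
            "slice_index": self.slice_index,
            "autonormalized": self.autonormalized,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeriesMeta":
        return cls(
            subject=str(d.get("subject", "")),
            disc_level=str(d.get("disc_level", "")),
            timepoint=str(d.get("timepoint", "")),
            contrast_state=str(d.get("contrast_state", "")),
            slice_index=int(d.get("slice_index", 0)),
            autonormalized=bool(d.get("autonormalized", False)),
        )


@dataclass
class IRSeries:
    """One inversion-recovery series: stacked magnitude images plus protocol.

    ``images`` has shape (n_ti, rows, cols); image i was acquired at
    ``protocol.ti_ms[i]``.
    """

    images: np.ndarray
    protocol: AcquisitionProtocol
    meta: SeriesMeta = field(default_factory=SeriesMeta)
    normalization_applied: bool = False

    def __post_init__(self) -> None:
        img = np.asarray(self.images, dtype=float)
        if img.ndim != 3:
            raise InputError(f"images must be 3-D (n_ti, rows, cols), got shape {img.shape}")
        if img.shape[0] != self.protocol.n_ti:
            raise ProtocolError(
                f"series has {img.shape[0]} images but protocol lists "
                f"{self.protocol.n_ti} inversion times"
            )
        if not np.all(np.isfinite(img)):
            raise InputError("image intensities must be finite")
        if np.any(img < 0):
            raise InputError("magnitude images must be nonnegative")
        self.images = img

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class T1Map:
    """Per-pixel T1 fit results.

    ``valid`` is True only where the simplex converged and the fitted T1
    lies inside [`T1_VALID_MIN_MS`, `T1_VALID_MAX_MS`].
    """

    t1_ms: np.ndarray
    s0: np.ndarray
    rss: np.ndarray
    valid: np.ndarray
    meta: SeriesMeta = field(default_factory=SeriesMeta)
    protocol: AcquisitionProtocol | None = None

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.t1_ms, self.s0, self.rss, self.valid)}
        if len(shapes) != 1:
            raise InputError("t1_ms, s0, rss and valid must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return np.shape(self.t1_ms)


@dataclass
class FatReference:
    """Subcutaneous-fat reference for correcting auto-scaled series.

    ``fat_pixels`` is a boolean mask (or anything convertible to one) of
    fat pixels; ``per_image_means`` and ``factors`` are filled by
    :func:`normalization_factors`.
    """

    fat_t1_ms: float = DEFAULT_FAT_T1_MS
    fat_pixels: np.ndarray | None = None
    per_image_means: np.ndarray | None = None
    factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fat_t1_ms <= 0:
            raise InputError("fat_t1_ms must be positive")


def ir_signal(
    ti_ms: float | np.ndarray,
    t1_ms: float | np.ndarray,
    s0: float | np.ndarray,
    tr_ms: float,
) -> np.ndarray:
    """Magnitude IR signal S0*|1 - 2 exp(-TI/T1) + exp(-TR/T1)|.

    Broadcasts over any mix of scalar/array arguments.  T1 and TR must be
    strictly positive.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise InputError("t1_ms must be strictly positive")
    if tr_ms <= 0:
        raise InputError("tr_ms must be strictly positive")
    ti = np.asarray(ti_ms, dtype=float)
    return np.asarray(s0) * np.abs(1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr_ms / t1))


def _pixel_objective(signals: np.ndarray, ti: np.ndarray, tr_ms: float):
    def rss(t1: float, s0: float) -> float:
        model = s0 * np.abs(1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr_ms / t1))
        d = model - signals
        return float(d @ d)

    return rss


def fit_t1_pixel(
    signals: Sequence[float] | np.ndarray,
    protocol: AcquisitionProtocol,
) -> tuple[float, float, float, bool]:
    """Fit (T1, S0) to one pixel's signal-vs-TI curve.

    Returns ``(t1_ms, s0, rss, converged)``.  The residual sum of squares
    is minimized by Nelder-Mead over (T1, S0), initialized at
    S0 = max(signals) and the best T1 on a 200..2000 ms coarse grid;
    parameters are scaled by their initializers so the simplex tolerance
    (1e-6) acts relatively.  All-zero input returns ``converged=False``.
    """
    y = np.asarray(signals, dtype=float)
    if y.shape != (protocol.n_ti,):
        raise InputError(f"expected {protocol.n_ti} signals, got shape {y.shape}")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise InputError("signals must be finite and nonnegative")
    if np.all(y == 0):
        return np.nan, 0.0, 0.0, False

    ti = np.asarray(protocol.ti_ms)
    tr = protocol.tr_ms
    s0_init = float(y.max())
    # coarse grid over T1 steps across the magnitude null-point minima
    model = s0_init * np.abs(
        1.0 - 2.0 * np.exp(-ti[None, :] / _T1_GRID_MS[:, None])
        + np.exp(-tr / _T1_GRID_MS[:, None])
    )
    grid_rss = ((model - y[None, :]) ** 2).sum(axis=1)
    t1_init = float(_T1_GRID_MS[int(np.argmin(grid_rss))])

    rss = _pixel_objective(y, ti, tr)

    def objective(x: np.ndarray) -> float:
        t1 = x[0] * t1_init
        s0 = x[1] * s0_init
        if t1 <= 0 or s0 < 0:
            return np.inf
        return rss(t1, s0)

    res = minimize(
        objective,
        x0=np.array([1.0, 1.0]),
        method="Nelder-Mead",
        options={
            "xatol": _SIMPLEX_RTOL,
            "fatol": _SIMPLEX_RTOL * max(float(grid_rss.min()), 1e-30),
            "maxiter": _SIMPLEX_MAXITER,
            "maxfev": 2 * _SIMPLEX_MAXITER,
        },
    )
    t1 = float(res.x[0] * t1_init)
    s0 = float(res.x[1] * s0_init)
    return t1, s0, float(res.fun), bool(res.success)


def _validity(
    t1: np.ndarray,
    converged: np.ndarray,
    valid_range: tuple[float, float],
) -> np.ndarray:
    lo, hi = valid_range
    if not lo < hi:
        raise InputError("validity thresholds must satisfy low < high")
    with np.errstate(invalid="ignore"):
        inside = (t1 >= lo) & (t1 <= hi)
    return converged & np.nan_to_num(inside, nan=False)


def fit_t1_map(
    series: IRSeries,
    roi_mask: np.ndarray | None = None,
    valid_range: tuple[float, float] = (T1_VALID_MIN_MS, T1_VALID_MAX_MS),
) -> T1Map:
    """Fit T1 pixel-wise over ``roi_mask`` (or the whole image).

    Pixels outside the mask, non-converged fits and fits outside the
    [400, 1500] ms window (``valid_range``) are marked invalid.
    """
    shape = series.shape
    if roi_mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(roi_mask, dtype=bool)
        if mask.shape != shape:
            raise InputError(
                f"roi_mask shape {mask.shape} does not match images {shape}"
            )

    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        t1[r, c], s0[r, c], rss[r, c], converged[r, c] = fit_t1_pixel(
            series.images[:, r, c], series.protocol
        )

    return T1Map(
        t1_ms=t1,
        s0=s0,
        rss=rss,
        valid=_validity(t1, converged, valid_range),
        meta=series.meta,
        protocol=series.protocol,
    )


def expected_fat_curve(protocol: AcquisitionProtocol, fat_t1_ms: float) -> np.ndarray:
    """Relative IR signal of fat (unit amplitude) at the protocol's TIs."""
    return np.abs(
        1.0
        - 2.0 * np.exp(-np.asarray(protocol.ti_ms) / fat_t1_ms)
        + np.exp(-protocol.tr_ms / fat_t1_ms)
    )


def normalization_factors(series: IRSeries, fat: FatReference) -> FatReference:
    """Estimate per-image correction multipliers from the fat region.

    Fat T1 is constant, so the observed per-image fat means f_i should be
    proportional to the model curve e_i at the reference fat T1.  The fat
    amplitude is the least-squares fit S = (sum f_i e_i) / (sum e_i^2) and
    image i is corrected by factor_i = S e_i / f_i, placing the fat means
    exactly on the expected curve.
    """
    if fat.fat_pixels is None:
        raise CorrectionError("fat pixel set is empty")
    mask = np.asarray(fat.fat_pixels, dtype=bool)
    if mask.shape != series.shape:
        raise InputError(
            f"fat mask shape {mask.shape} does not match images {series.shape}"
        )
    if not mask.any():
        raise CorrectionError("fat pixel set is empty")

    f = series.images[:, mask].mean(axis=1)
    if np.any(f <= 0):
        raise CorrectionError("observed fat mean is zero in at least one image")

    e = expected_fat_curve(series.protocol, fat.fat_t1_ms)
    s_hat = float(f @ e) / float(e @ e)
    factors = s_hat * e / f
    return replace(fat, fat_pixels=mask, per_image_means=f, factors=factors)


def apply_normalization(series: IRSeries, fat: FatReference) -> IRSeries:
    """Return a new series with image i multiplied by ``fat.factors[i]``.

    Warns (and still proceeds) if the series is already flagged as
    corrected — the correction is not idempotent.
    """
    if fat.factors is None:
        raise StateError("normalization factors not filled; run normalization_factors first")
    factors = np.asarray(fat.factors, dtype=float)
    if factors.shape != (series.protocol.n_ti,):
        raise StateError(f"expected {series.protocol.n_ti} factors, got {factors.shape}")
    if np.any(factors <= 0):
        raise CorrectionError("correction factors must be strictly positive")
    if series.normalization_applied:
        warnings.warn(
            "series already normalization-corrected; applying factors again",
            UserWarning,
            stacklevel=2,
        )
    return IRSeries(
        images=series.images * factors[:, None, None],
        protocol=series.protocol,
        meta=replace(series.meta),
        normalization_applied=True,
    )
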