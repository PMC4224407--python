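"""Synthetic disc phantoms with known ground truth.

The generator emulates the study material end to end: an elliptical disc
whose T1 decreases from the nucleus (ring 1) outward, surrounded by a
rectangular subcutaneous-fat reference region; seven magnitude images
simulated from the inversion-recovery model at the protocol's inversion
times; additive Gaussian noise on the magnitude signal (a Rician mode —
magnitude of complex Gaussian — is available but off by default); and,
optionally, the scanner "auto-normalization" defect in which each image
carries an unknown positive intensity scale.

Default ring T1 values are the study-level pre-bedrest means of a healthy
lumbar disc (native ~1131 ms in the nucleus center falling to ~533 ms in
the outer annulus; post-contrast correspondingly shortened); the bedrest
effect is emulated purely by swapping in the post-bedrest ring vectors.

Landmarks are placed at eight fixed parametric angles (0, 45, ..., 315
degrees) on the true boundary, optionally jittered, mirroring the manual
8-point placement the segmentation expects.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .errors import ConfigurationError, InputError, ProtocolError
from .relaxometry import AcquisitionProtocol, IRSeries, SeriesMeta, ir_signal
from .segmentation import EllipseParams, assign_sectors

__all__ = [
    "RING_T1_NATIVE_PRE_MS",
    "RING_T1_POST_CONTRAST_PRE_MS",
    "RING_T1_NATIVE_POSTBR_MS",
    "RING_T1_POST_CONTRAST_POSTBR_MS",
    "PhantomSpec",
    "PhantomTruth",
    "generate_landmarks",
    "simulate_series",
    "simulate_study",
]

#: Study-mean ring T1 vectors (rings 1..5, ms): native and post-contrast,
#: before and after the bedrest intervention.
RING_T1_NATIVE_PRE_MS = (1131.38, 1007.97, 916.16, 680.31, 532.66)
RING_T1_POST_CONTRAST_PRE_MS = (972.32, 864.45, 756.98, 602.19, 495.44)
RING_T1_NATIVE_POSTBR_MS = (972.09, 872.82, 789.31, 591.37, 490.62)
RING_T1_POST_CONTRAST_POSTBR_MS = (992.94, 904.37, 799.49, 603.88, 512.16)

_LANDMARK_PARAM_DEG = np.arange(0.0, 360.0, 45.0)  # 8 points


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one synthetic disc phantom.

    noise_sigma is the Gaussian noise standard deviation as a fraction of
    ``s0_disc``; ``autonorm_factors`` (7 positive scales, or None)
    emulates the per-image auto-scaling defect; ``fat_region`` is
    (row0, row1, col0, col1), half-open, and must not intersect the disc.
    """

    grid_size: int = 128
    ellipse_center: tuple[float, float] = (70.0, 64.0)
    semi_axes: tuple[float, float] = (40.0, 24.0)
    orientation_deg: float = 0.0
    anterior_deg: float = 0.0
    ring_t1_native: tuple[float, ...] = RING_T1_NATIVE_PRE_MS
    ring_t1_post_contrast: tuple[float, ...] = RING_T1_POST_CONTRAST_PRE_MS
    s0_disc: float = 100.0
    fat_t1: float = 380.0
    fat_region: tuple[int, int, int, int] = (4, 16, 8, 120)
    noise_sigma: float = 0.02
    autonorm_factors: tuple[float, ...] | None = None
    landmark_jitter_sigma: float = 0.0
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise InputError("semi-axes must be strictly positive")
        if a < b:
            raise InputError("semi_axes must satisfy a >= b")
        for name, vec in (
            ("ring_t1_native", self.ring_t1_native),
            ("ring_t1_post_contrast", self.ring_t1_post_contrast),
        ):
            if len(vec) != 5:
                raise InputError(f"{name} must have 5 ring values")
            if not all(0 < t < 5000 for t in vec):
                raise InputError(f"{name} values must lie in (0, 5000) ms")
        if self.s0_disc <= 0:
            raise InputError("s0_disc must be positive")
        if self.noise_sigma < 0 or self.landmark_jitter_sigma < 0:
            raise InputError("noise and jitter sigmas must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise InputError("noise_model must be 'gaussian' or 'rician'")
        if self.autonorm_factors is not None:
            if len(self.autonorm_factors) != 7:
                raise InputError("autonorm_factors must have 7 entries")
            if any(f <= 0 for f in self.autonorm_factors):
                raise InputError("autonorm_factors must be strictly positive")
        if self._fat_intersects_ellipse():
            raise InputError("fat_region must not intersect the ellipse interior")

    def _fat_intersects_ellipse(self) -> bool:
        r0, r1, c0, c1 = self.fat_region
        rr, cc = np.mgrid[r0:r1, c0:c1]
        a, b = self.semi_axes
        phi = np.deg2rad(self.orientation_deg)
        dx = cc - self.ellipse_center[1]
        dy = rr - self.ellipse_center[0]
        u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
        v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
        return bool(np.any(u**2 + v**2 < 1.0))

    @property
    def ellipse(self) -> EllipseParams:
        return EllipseParams(
            center=self.ellipse_center,
            semi_axes=self.semi_axes,
            orientation_deg=self.orientation_deg,
            anterior_deg=self.anterior_deg,
        )

    def fat_mask(self) -> np.ndarray:
        mask = np.zeros((self.grid_size, self.grid_size), dtype=bool)
        r0, r1, c0, c1 = self.fat_region
        mask[r0:r1, c0:c1] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "grid_size": self.grid_size,
            "ellipse_center": list(self.ellipse_center),
            "semi_axes": list(self.semi_axes),
            "orientation_deg": self.orientation_deg,
            "anterior_deg": self.anterior_deg,
            "ring_t1_native": list(self.ring_t1_native),
            "ring_t1_post_contrast": list(self.ring_t1_post_contrast),
            "s0_disc": self.s0_disc,
            "fat_t1": self.fat_t1,
            "fat_region": list(self.fat_region),
            "noise_sigma": self.noise_sigma,
            "autonorm_factors": (
                None if self.autonorm_factors is None else list(self.autonorm_factors)
            ),
            "landmark_jitter_sigma": self.landmark_jitter_sigma,
            "noise_model": self.noise_model,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("ellipse_center", "semi_axes", "ring_t1_native",
                    "ring_t1_post_contrast", "fat_region"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("autonorm_factors") is not None:
            d["autonorm_factors"] = tuple(d["autonorm_factors"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth accompanying one simulated series pair."""

    spec: PhantomSpec
    ellipse: EllipseParams
    landmarks: np.ndarray  # (8, 2) (row, col)
    t1_native: np.ndarray  # per-pixel, NaN outside the disc
    t1_post_contrast: np.ndarray
    ring_mean_delta_t1: np.ndarray  # (5,), ms
    autonorm_factors: np.ndarray | None

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "ellipse": self.ellipse.to_dict(),
            "landmarks": self.landmarks.tolist(),
            "ring_mean_delta_t1": self.ring_mean_delta_t1.tolist(),
            "autonorm_factors": (
                None if self.autonorm_factors is None else self.autonorm_factors.tolist()
            ),
        }


def generate_landmarks(spec: PhantomSpec) -> np.ndarray:
    """Eight (row, col) boundary points at parametric angles 0,45,...,315.

    Each point is perturbed by isotropic Gaussian noise of sd
    ``landmark_jitter_sigma``; deterministic given ``spec.seed``.  The
    point at parametric angle 0 (index 0) lies on the anterior midline
    when ``anterior_deg == orientation_deg``.
    """
    ell = spec.ellipse
    pts = np.array([ell.boundary_point(t) for t in _LANDMARK_PARAM_DEG])
    if spec.landmark_jitter_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x1A]))
        pts = pts + rng.normal(0.0, spec.landmark_jitter_sigma, pts.shape)
    return pts


def _true_t1_field(spec: PhantomSpec, ring_t1: tuple[float, ...]) -> np.ndarray:
    labels = assign_sectors(spec.ellipse, (spec.grid_size, spec.grid_size))
    t1 = np.full((spec.grid_size, spec.grid_size), np.nan)
    for ring in range(1, 6):
        t1[labels.ring == ring] = ring_t1[ring - 1]
    return t1


def simulate_series(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol | None = None,
    contrast_state: str = "native",
    meta: SeriesMeta | None = None,
) -> tuple[IRSeries, PhantomTruth]:
    """Simulate one 7-image IR series of a disc phantom, with truth.

    Disc pixels carry the IR signal of their ring's true T1, fat pixels
    that of ``fat_t1``, background is zero; zero-mean Gaussian noise of sd
    ``noise_sigma * s0_disc`` is added and the magnitude taken (or Rician
    magnitude noise if configured); if ``autonorm_factors`` is set, image
    i is scaled by factor i afterwards.
    """
    protocol = protocol if protocol is not None else AcquisitionProtocol()
    if protocol.n_ti != 7:
        raise ProtocolError(f"protocol must list 7 inversion times, got {protocol.n_ti}")
    if contrast_state not in ("native", "post-contrast"):
        raise InputError("contrast_state must be 'native' or 'post-contrast'")

    ring_t1 = (
        spec.ring_t1_native if contrast_state == "native" else spec.ring_t1_post_contrast
    )
    t1_native = _true_t1_field(spec, spec.ring_t1_native)
    t1_post = _true_t1_field(spec, spec.ring_t1_post_contrast)
    t1_field = t1_native if contrast_state == "native" else t1_post

    shape = (spec.grid_size, spec.grid_size)
    disc = np.isfinite(t1_field)
    fat = spec.fat_mask()
    ti = np.asarray(protocol.ti_ms)

    clean = np.zeros((protocol.n_ti, *shape))
    clean[:, disc] = ir_signal(ti[:, None], t1_field[disc][None, :], spec.s0_disc,
                               protocol.tr_ms)
    clean[:, fat] = ir_signal(ti[:, None], spec.fat_t1, spec.s0_disc, protocol.tr_ms)

    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0x2B, 0 if contrast_state == "native" else 1])
    )
    sigma = spec.noise_sigma * spec.s0_disc
    if sigma > 0:
        if spec.noise_model == "rician":
            images = np.hypot(clean + rng.normal(0.0, sigma, clean.shape),
                              rng.normal(0.0, sigma, clean.shape))
        else:
            images = np.abs(clean + rng.normal(0.0, sigma, clean.shape))
    else:
        images = clean

    factors = None
    if spec.autonorm_factors is not None:
        factors = np.asarray(spec.autonorm_factors, dtype=float)
        images = images * factors[:, None, None]

    meta = meta if meta is not None else SeriesMeta()
    meta = replace(meta, contrast_state=contrast_state,
                   autonormalized=factors is not None)
    series = IRSeries(images=images, protocol=protocol, meta=meta)
    truth = PhantomTruth(
        spec=spec,
        ellipse=spec.ellipse,
        landmarks=generate_landmarks(spec),
        t1_native=t1_native,
        t1_post_contrast=t1_post,
        ring_mean_delta_t1=(
            np.asarray(spec.ring_t1_native) - np.asarray(spec.ring_t1_post_contrast)
        ),
        autonorm_factors=factors,
    )
    return series, truth


@dataclass(frozen=True)
class StudyCell:
    """One cell of the study design: subject x disc level x timepoint."""

    subject: str
    disc_level: str
    timepoint: str

    @property
    def key(self) -> str:
        tp = self.timepoint.replace("-", "")
        return f"{self.subject}_{self.disc_level.replace('/', '')}_{tp}"


def _derive_seed(base: int, *parts: str) -> int:
    crc = [zlib.crc32(p.encode()) for p in parts]  # stable across processes
    h = np.random.SeedSequence([int(base)] + crc).generate_state(1)[0]
    return int(h) % (2**31 - 1)


def simulate_study(
    study_spec: Mapping[tuple[str, str, str], PhantomSpec],
    out_dir: str | Path,
    protocol: AcquisitionProtocol | None = None,
    seed: int = 0,
    slices_per_disc: int = 2,
) -> Path:
    """Write a complete synthetic study bundle to disk.

    ``study_spec`` maps (subject, disc_level, timepoint) to the phantom
    spec of that cell.  For each cell and slice, a native and a
    post-contrast series are written (NIfTI + JSON sidecar) together with
    landmarks, fat mask and truth; a TSV manifest lists every series.
    Returns the manifest path.  Deterministic given ``seed``.
    """
    from . import io as pio  # deferred: io imports relaxometry types

    keys = list(study_spec.keys())
    if len(set(keys)) != len(keys):
        raise ConfigurationError("duplicate study cells")
    protocol = protocol if protocol is not None else AcquisitionProtocol()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject, disc_level, timepoint), spec in sorted(study_spec.items()):
        cell = StudyCell(subject, disc_level, timepoint)
        for slice_index in range(slices_per_disc):
            cell_seed = _derive_seed(seed, cell.key, str(slice_index))
            sspec = replace(spec, seed=cell_seed)
            cell_dir = out_dir / cell.key / f"slice{slice_index}"
            cell_dir.mkdir(parents=True, exist_ok=True)
            truth = None
            for contrast_state in ("native", "post-contrast"):
                meta = SeriesMeta(subject=subject, disc_level=disc_level,
                                  timepoint=timepoint, slice_index=slice_index)
                series, truth = simulate_series(sspec, protocol, contrast_state, meta)
                stem = "native" if contrast_state == "native" else "post"
                pio.write_series(cell_dir / f"{stem}.nii", series)
                rows.append({
                    "subject": subject,
                    "disc_level": disc_level,
                    "timepoint": timepoint,
                    "contrast_state": contrast_state,
                    "slice_index": slice_index,
                    "series_path": str((cell_dir / f"{stem}.nii").relative_to(out_dir)),
                })
            pio.write_landmarks(cell_dir / "landmarks.json", truth.landmarks,
                                anterior_index=0)
            pio.write_mask(cell_dir / "fat_mask.nii", sspec.fat_mask())
            (cell_dir / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1, sort_keys=True)
            )

    import pandas as pd

    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def default_study_design(
    n_subjects: int = 5,
    disc_levels: tuple[str, ...] = ("L1/2", "L2/3", "L3/4", "L4/5"),
    base_spec: PhantomSpec | None = None,
) -> dict[tuple[str, str, str], PhantomSpec]:
    """The study's factorial design: subjects x lumbar levels x timepoints.

    Pre-bedrest cells use the pre-bedrest ring T1 vectors, post-bedrest
    cells the post-bedrest vectors; everything else is shared.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    subjects = [chr(ord("A") + i) for i in range(n_subjects)]
    design: dict[tuple[str, str, str], PhantomSpec] = {}
    for subject in subjects:
        for level in disc_levels:
            design[(subject, level, "pre-bedrest")] = replace(
                base,
                ring_t1_native=RING_T1_NATIVE_PRE_MS,
                ring_t1_post_contrast=RING_T1_POST_CONTRAST_PRE_MS,
            )
            design[(subject, level, "post-bedrest")] = replace(
                base,
                ring_t1_native=RING_T1_NATIVE_POSTBR_MS,
                ring_t1_post_contrast=RING_T1_POST_CONTRAST_POSTBR_MS,
            )
    return design
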