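"""Regional statistics of T1 and dT1 maps, and GAG estimation.

dT1 = native T1 - post-contrast T1, computed pixel-wise on the
intersection of the two validity masks: the contrast agent distributes
inversely to glycosaminoglycan content, so a small dT1 indicates a
GAG-rich disc.  Regional roll-ups (sector, ring, nucleus/annulus,
anterior/posterior zone, whole disc) are valid-pixel-weighted means, so a
disc mean is always the mean over the pooled valid pixels of its slices.

GAG content is estimated from dT1 by the published linear calibration
against biochemically assayed glycosaminoglycan,

    GAG [ug/mg] = -1.38 * dT1 [ms] + 238.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, IntegrityError, PairingError
from .relaxometry import SeriesMeta, T1Map
from .segmentation import RegionDefinition, SectorLabelMap

__all__ = [
    "GAG_SLOPE",
    "GAG_INTERCEPT",
    "DeltaT1Map",
    "delta_t1",
    "region_summary",
    "gag_from_delta",
    "build_study_table",
    "STUDY_TABLE_COLUMNS",
]

#: Linear dT1 -> GAG calibration (ug GAG per mg dry weight).
GAG_SLOPE = -1.38
GAG_INTERCEPT = 238.0

STUDY_TABLE_COLUMNS = [
    "subject", "disc_level", "timepoint", "measure",
    "region_type", "region", "mean", "sd", "n",
]


@dataclass
class DeltaT1Map:
    """Per-pixel dT1 (ms), valid where both input maps were valid."""

    delta_ms: np.ndarray
    valid: np.ndarray
    meta: SeriesMeta = field(default_factory=SeriesMeta)

    @property
    def shape(self) -> tuple[int, int]:
        return np.shape(self.delta_ms)


def delta_t1(native: T1Map, post: T1Map) -> DeltaT1Map:
    """Pixel-wise native minus post-contrast T1 on the joint valid mask.

    The two maps must describe the same subject, disc and timepoint.
    """
    if native.shape != post.shape:
        raise InputError(f"map shapes differ: {native.shape} vs {post.shape}")
    for attr in ("subject", "disc_level", "timepoint", "slice_index"):
        a, b = getattr(native.meta, attr), getattr(post.meta, attr)
        if a != b:
            raise PairingError(f"maps disagree on {attr}: {a!r} vs {b!r}")
    valid = native.valid & post.valid
    delta = np.where(valid, native.t1_ms - post.t1_ms, np.nan)
    return DeltaT1Map(delta_ms=delta, valid=valid,
                      meta=SeriesMeta(
                          subject=native.meta.subject,
                          disc_level=native.meta.disc_level,
                          timepoint=native.meta.timepoint,
                          contrast_state="delta",
                          slice_index=native.meta.slice_index,
                      ))


def _values_and_valid(m: T1Map | DeltaT1Map) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, DeltaT1Map):
        return m.delta_ms, m.valid
    return m.t1_ms, m.valid


def _stats(values: np.ndarray) -> dict:
    n = int(values.size)
    return {
        "mean": float(values.mean()) if n >= 1 else np.nan,
        "sd": float(values.std(ddof=1)) if n >= 2 else np.nan,
        "n": n,
    }


def region_summary(
    maps: T1Map | DeltaT1Map | list,
    labels: SectorLabelMap | list,
    regions: RegionDefinition | None = None,
) -> pd.DataFrame:
    """Sector statistics and regional roll-ups of one disc.

    ``maps``/``labels`` may be single objects or parallel lists (one per
    slice); slices are pooled at the pixel level, so every roll-up is a
    valid-pixel-weighted mean.  Returns a tidy frame with columns
    [region_type, region, mean, sd, n]; region types are ``sector``
    (r{ring}w{wedge}), ``ring`` (1..5), ``zone`` (nucleus, annulus,
    anterior, posterior) and ``disc``.  Regions with no valid pixel are
    reported with n = 0 and NaN mean (missing, not zero).
    """
    regions = regions if regions is not None else RegionDefinition()
    map_list = maps if isinstance(maps, list) else [maps]
    label_list = labels if isinstance(labels, list) else [labels]
    if len(map_list) != len(label_list):
        raise InputError("need one label map per value map")

    vals, ring, wedge = [], [], []
    for m, lab in zip(map_list, label_list):
        v, valid = _values_and_valid(m)
        if np.shape(v) != lab.ring.shape:
            raise InputError("map and label shapes disagree")
        keep = valid & lab.inside
        vals.append(np.asarray(v)[keep])
        ring.append(lab.ring[keep])
        wedge.append(lab.wedge[keep])
    vals = np.concatenate(vals) if vals else np.array([])
    ring = np.concatenate(ring) if ring else np.array([], dtype=int)
    wedge = np.concatenate(wedge) if wedge else np.array([], dtype=int)

    rows = []
    for r in range(1, 6):
        for w in range(12):
            sel = vals[(ring == r) & (wedge == w)]
            rows.append({"region_type": "sector", "region": f"r{r}w{w}", **_stats(sel)})
    for r in range(1, 6):
        rows.append({"region_type": "ring", "region": str(r), **_stats(vals[ring == r])})

    nucleus = np.isin(ring, list(regions.nucleus_rings))
    annulus = np.isin(ring, list(regions.annulus_rings))
    anterior = annulus & np.isin(wedge, list(regions.anterior_wedges))
    posterior = annulus & np.isin(wedge, list(regions.posterior_wedges))
    for name, sel in (("nucleus", nucleus), ("annulus", annulus),
                      ("anterior", anterior), ("posterior", posterior)):
        rows.append({"region_type": "zone", "region": name, **_stats(vals[sel])})
    rows.append({"region_type": "disc", "region": "disc", **_stats(vals)})

    return pd.DataFrame(rows, columns=["region_type", "region", "mean", "sd", "n"])


def gag_from_delta(delta_t1_ms):
    """GAG estimate (ug/mg dry weight) from dT1 via the linear calibration."""
    x = np.asarray(delta_t1_ms, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("delta_t1_ms must be finite")
    out = GAG_SLOPE * x + GAG_INTERCEPT
    return float(out) if np.isscalar(delta_t1_ms) else out


def build_study_table(records: list[dict]) -> pd.DataFrame:
    """Assemble long-format study records into a validated StudyTable.

    Each record must carry subject, disc_level, timepoint, measure
    (native_t1 | post_t1 | delta_t1), region_type, region, mean, sd, n.
    Duplicate (subject, disc_level, timepoint, measure, region_type,
    region) keys raise :class:`IntegrityError`.
    """
    table = pd.DataFrame(records, columns=STUDY_TABLE_COLUMNS)
    if len(table):
        key_cols = ["subject", "disc_level", "timepoint", "measure",
                    "region_type", "region"]
        dup = table.duplicated(subset=key_cols)
        if dup.any():
            first = table.loc[dup.idxmax(), key_cols].to_dict()
            raise IntegrityError(f"duplicate study record: {first}")
    return table


def summary_records(
    summary: pd.DataFrame, meta: SeriesMeta, measure: str
) -> list[dict]:
    """Flatten a :func:`region_summary` frame into StudyTable records."""
    recs = []
    for _, row in summary.iterrows():
        recs.append({
            "subject": meta.subject,
            "disc_level": meta.disc_level,
            "timepoint": meta.timepoint,
            "measure": measure,
            "region_type": row["region_type"],
            "region": row["region"],
            "mean": row["mean"],
            "sd": row["sd"],
            "n": row["n"],
        })
    return recs
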