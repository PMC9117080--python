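"""Time-domain power-spectrum descriptors (TD-PSD) of wavelet subbands.

Each subband matrix is flattened row-major, exact (or near-) zeros are
stripped, and the surviving coefficients are treated as a 1-D pseudo-time
series x[0..N-1].  Root-squared spectral moments are then computed entirely
in the time domain — by Parseval's theorem the sum of squared k-th finite
differences equals the k-th frequency-weighted power-spectrum sum:

    m0_raw = sqrt(sum x^2)        (total power)
    m2_raw = sqrt(sum (dx)^2)     (second spectral moment; N-1 terms)
    m4_raw = sqrt(sum (d2x)^2)    (fourth spectral moment; N-2 terms)

A power transform m = m_raw**lam / lam (lam > 0, default 0.1) compresses
the moment range before the seven descriptors are formed:

    f1 = log m0
    f2 = log(m0 - m2)
    f3 = log(m0 - m4)
    f4 = log( m0 / ((m0 - m2)(m0 - m4)) )        (sparseness)
    f5 = m2 / sqrt(m0 * m4)                      (irregularity factor)
    f6 = log( population std / |mean| )          (coefficient of variation)
    f7 = log( sum_j x[j]^2 - x[j-1] x[j+1] )     (Teager energy)

Every log and division is guarded (see GUARD_EPS); a guard fires a named
flag so downstream stages can distinguish genuine values from substituted
ones.  Degenerate bands (all-zero, or fewer than 3 surviving coefficients)
yield an all-zero sentinel row, flagged per band, never an aborted image.

Seven subbands x seven descriptors give the 49-element feature vector per
image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSeriesError, ShortSeriesError
from .wavelet import BAND_KEYS, DEFAULT_MODE, DEFAULT_WAVELET, ImageSample, decompose_two_level

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7")

#: Column order of the 49-feature layout: band-major, feature-minor.
FEATURE_COLUMNS = tuple(f"{band}_{feat}" for band in BAND_KEYS for feat in FEATURE_NAMES)

GUARD_EPS = 1e-12

#: Feature row substituted for a band whose pseudo-time series is degenerate.
SENTINEL_ROW = np.zeros(len(FEATURE_NAMES))


@dataclass
class PseudoTimeSeries:
    """Zero-stripped row-major flattening of one subband."""

    values: np.ndarray
    source_band: str = ""
    original_count: int = 0
    removed_count: int = 0


@dataclass
class MomentSet:
    """Root-squared spectral moments, raw and power-transformed."""

    m0_raw: float
    m2_raw: float
    m4_raw: float
    m0: Optional[float] = None
    m2: Optional[float] = None
    m4: Optional[float] = None
    lam: Optional[float] = None


@dataclass
class FeatureConfig:
    """All tunable parameters of the descriptor stage."""

    wavelet_name: str = DEFAULT_WAVELET
    boundary_mode: str = DEFAULT_MODE
    lam: float = 0.1
    zero_tolerance: float = 0.0
    normalize_m0: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigurationError(f"lambda must be > 0, got {self.lam}")
        if self.zero_tolerance < 0:
            raise ConfigurationError(
                f"zero_tolerance must be >= 0, got {self.zero_tolerance}"
            )


@dataclass
class FeatureVector:
    """The 49 descriptor values for one image (band-major order).

    ``flags`` maps band key -> guard-flag names that fired; ``sentinel_bands``
    lists bands whose whole row is the sentinel substitute.
    """

    values: np.ndarray
    image_id: str = ""
    label: Optional[str] = None
    flags: dict[str, list[str]] = field(default_factory=dict)
    sentinel_bands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (49,):
            raise ValueError(f"feature vector must have 49 entries, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for image {self.image_id!r}")


def subband_to_series(
    band_matrix: np.ndarray, zero_tolerance: float = 0.0, source_band: str = ""
) -> PseudoTimeSeries:
    """Flatten a subband row-major and delete entries of magnitude <= tolerance.

    Survivor order is preserved.  Raises :class:`DegenerateSeriesError` when
    nothing survives (an all-zero band).
    """
    if zero_tolerance < 0:
        raise ConfigurationError(f"zero_tolerance must be >= 0, got {zero_tolerance}")
    flat = np.asarray(band_matrix, dtype=np.float64).ravel(order="C")
    if flat.size == 0:
        raise DegenerateSeriesError(f"band {source_band!r}: empty matrix")
    keep = np.abs(flat) > zero_tolerance
    values = flat[keep]
    if values.size == 0:
        raise DegenerateSeriesError(
            f"band {source_band!r}: all {flat.size} coefficients are zero"
        )
    return PseudoTimeSeries(
        values=values,
        source_band=source_band,
        original_count=int(flat.size),
        removed_count=int(flat.size - values.size),
    )


def raw_moments(series: PseudoTimeSeries) -> MomentSet:
    """Root-squared moments of orders 0, 2, 4 from plain forward differences.

    Requires at least 3 samples (the second difference needs them).
    """
    x = series.values
    if x.size < 3:
        raise ShortSeriesError(
            f"band {series.source_band!r}: series length {x.size} < 3"
        )
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    return MomentSet(
        m0_raw=float(np.sqrt(np.sum(x * x))),
        m2_raw=float(np.sqrt(np.sum(d1 * d1))),
        m4_raw=float(np.sqrt(np.sum(d2 * d2))),
    )


def power_transform(moments: MomentSet, lam: float) -> MomentSet:
    """Apply m = m_raw**lam / lam to the three raw moments.

    ``lam`` must be strictly positive; the published "lambda = 0" setting
    makes the expression undefined and is rejected.
    """
    if lam <= 0:
        raise ConfigurationError(f"lambda must be > 0, got {lam}")
    return MomentSet(
        m0_raw=moments.m0_raw,
        m2_raw=moments.m2_raw,
        m4_raw=moments.m4_raw,
        m0=moments.m0_raw**lam / lam,
        m2=moments.m2_raw**lam / lam,
        m4=moments.m4_raw**lam / lam,
        lam=lam,
    )


def _guarded_log(arg: float, flag: str, flags: list[str]) -> float:
    if arg <= 0:
        flags.append(flag)
        return math.log(abs(arg) + GUARD_EPS)
    return math.log(arg)


def tdpsd_features(
    series: PseudoTimeSeries, lam: float = 0.1, m0_scale: float = 1.0
) -> tuple[np.ndarray, list[str]]:
    """Compute the seven descriptors of one pseudo-time series.

    ``m0_scale`` multiplies the raw zero-order moment before the power
    transform (used for optional cross-band normalization).  Returns the
    7-vector together with the list of guard flags that fired.
    """
    flags: list[str] = []
    raw = raw_moments(series)
    raw = MomentSet(raw.m0_raw * m0_scale, raw.m2_raw, raw.m4_raw)
    m = power_transform(raw, lam)
    m0, m2, m4 = m.m0, m.m2, m.m4

    f1 = _guarded_log(m0, "f1_nonpositive", flags)
    f2 = _guarded_log(m0 - m2, "f2_nonpositive", flags)
    f3 = _guarded_log(m0 - m4, "f3_nonpositive", flags)

    denom = (m0 - m2) * (m0 - m4)
    if denom == 0.0:
        flags.append("f4_zero_denominator")
        denom = GUARD_EPS
    f4 = _guarded_log(m0 / denom, "f4_nonpositive", flags)

    if_denom = math.sqrt(m0 * m4) if m0 * m4 > 0 else 0.0
    if if_denom == 0.0:
        flags.append("f5_degenerate")
        f5 = 0.0
    else:
        f5 = m2 / if_denom

    x = series.values
    mean = float(np.mean(x))
    std = float(np.sqrt(np.mean((x - mean) ** 2)))
    if abs(mean) < GUARD_EPS:
        flags.append("f6_zero_mean")
    f6 = _guarded_log(std / max(abs(mean), GUARD_EPS), "f6_nonpositive", flags)

    teo = float(np.sum(x[1:-1] ** 2 - x[:-2] * x[2:]))
    f7 = _guarded_log(teo, "f7_nonpositive", flags)

    return np.array([f1, f2, f3, f4, f5, f6, f7]), flags


def extract_features(
    image: ImageSample, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full descriptor extraction for one image: 7 subbands x 7 features.

    Degenerate bands (all-zero or < 3 surviving coefficients) contribute the
    sentinel row and are recorded in ``sentinel_bands``; the remaining bands
    are unaffected.  Output order is band-major
    (LH1, HL1, HH1, LL2, LH2, HL2, HH2) x (f1..f7).
    """
    if config is None:
        config = FeatureConfig()
    subbands = decompose_two_level(image, config.wavelet_name, config.boundary_mode)

    series: dict[str, Optional[PseudoTimeSeries]] = {}
    sentinel: list[str] = []
    for band in BAND_KEYS:
        try:
            s = subband_to_series(subbands[band], config.zero_tolerance, band)
            if s.values.size < 3:
                raise ShortSeriesError(
                    f"band {band!r}: series length {s.values.size} < 3"
                )
            series[band] = s
        except (DegenerateSeriesError, ShortSeriesError):
            series[band] = None
            sentinel.append(band)

    m0_scale = 1.0
    if config.normalize_m0:
        total = sum(
            raw_moments(s).m0_raw for s in series.values() if s is not None
        )
        if total > 0:
            m0_scale = 1.0 / total

    rows = []
    flags: dict[str, list[str]] = {}
    for band in BAND_KEYS:
        s = series[band]
        if s is None:
            rows.append(SENTINEL_ROW)
            flags[band] = ["sentinel"]
        else:
            feats, band_flags = tdpsd_features(s, config.lam, m0_scale)
            rows.append(feats)
            if band_flags:
                flags[band] = band_flags
    return FeatureVector(
        values=np.concatenate(rows),
        image_id=image.id,
        label=image.label,
        flags=flags,
        sentinel_bands=sentinel,
    )


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical CSV layout."""
    return pd.DataFrame(
        [
            {"image_id": v.image_id, "label": v.label}
            | dict(zip(FEATURE_COLUMNS, v.values))
            for v in vectors
        ]
    )


def flag_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Companion table of guard-flag events (one row per image/band/flag)."""
    records = [
        {"image_id": v.image_id, "band": band, "flag": flag}
        for v in vectors
        for band, band_flags in v.flags.items()
        for flag in band_flags
    ]
    return pd.DataFrame(records, columns=["image_id", "band", "flag"])
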