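"""Two-level 2-D discrete wavelet decomposition into the seven analysis subbands.

A grayscale image is decomposed once into an approximation band (LL1) and
three detail bands (LH1, HL1, HH1); LL1 is decomposed again into LL2, LH2,
HL2, HH2 and then discarded.  The seven retained bands feed the descriptor
stage.  The inverse transform is provided as well so that round-trip and
energy oracles can be checked.

Orientation convention (separable filter bank): LH = low-pass rows /
high-pass columns = horizontal detail, HL = vertical detail, HH = diagonal
detail, matching PyWavelets' ``(cA, (cH, cV, cD))`` ordering.

Defaults are the Haar wavelet with periodization boundary handling, under
which subband sizes are exactly half the (even-padded) input per level and
the transform is orthonormal, so coefficient energy equals pixel energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pywt

from .errors import ConfigurationError, DimensionError, ShapeError

#: Band keys in the canonical (band-major feature layout) order.
BAND_KEYS = ("LH1", "HL1", "HH1", "LL2", "LH2", "HL2", "HH2")

DEFAULT_WAVELET = "haar"
DEFAULT_MODE = "periodization"


@dataclass
class ImageSample:
    """One grayscale image with an optional class label.

    ``pixels`` holds intensities as floats on the 0-255 scale as read from
    an 8-bit file; no rescaling is applied.
    """

    pixels: np.ndarray
    label: Optional[str] = None
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DimensionError(
                f"image {self.id!r}: expected a non-empty 2-D pixel grid, "
                f"got shape {self.pixels.shape}"
            )


@dataclass
class SubbandSet:
    """The seven coefficient matrices of a two-level decomposition.

    ``padded_shape`` is the level-1 input shape after any even-padding;
    ``ll1_shape`` the shape of the (discarded) level-1 approximation band
    before its own padding.  Both are needed to invert exactly.
    """

    bands: dict[str, np.ndarray]
    wavelet_name: str
    boundary_mode: str
    padded_shape: tuple[int, int]
    ll1_shape: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_KEYS):
            raise ShapeError(
                f"subband keys must be exactly {BAND_KEYS}, got {sorted(self.bands)}"
            )

    def __getitem__(self, key: str) -> np.ndarray:
        return self.bands[key]

    def energy(self) -> float:
        """Total squared-coefficient energy over the seven retained bands."""
        return float(sum(np.sum(b * b) for b in self.bands.values()))

    def to_npz(self, path) -> None:
        """Debug dump: one compressed archive entry per band key."""
        np.savez_compressed(path, **self.bands)


def _validate_wavelet(wavelet_name: str) -> pywt.Wavelet:
    try:
        return pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet_name!r}") from exc


def _pad_even(arr: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetric-pad each odd dimension by one so both are even."""
    pad_r = arr.shape[0] % 2
    pad_c = arr.shape[1] % 2
    if pad_r or pad_c:
        arr = np.pad(arr, ((0, pad_r), (0, pad_c)), mode="symmetric")
    return arr, (pad_r, pad_c)


def decompose_two_level(
    image: ImageSample | np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    boundary_mode: str = DEFAULT_MODE,
) -> SubbandSet:
    """Decompose an image into the seven retained subbands.

    Level 1 yields LH1, HL1, HH1 (details) plus LL1; level 2 decomposes LL1
    into LL2, LH2, HL2, HH2.  LL1 itself is not kept.  Odd dimensions are
    symmetric-padded to even before each level and the padding is recorded
    in ``metadata``.

    Raises
    ------
    ConfigurationError
        If ``wavelet_name`` is not a known discrete wavelet.
    DimensionError
        If the image is empty or any dimension is < 2 (a 1xN strip cannot
        be decomposed twice along both axes).
    """
    if isinstance(image, ImageSample):
        arr = image.pixels
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError(f"expected non-empty 2-D array, got shape {arr.shape}")
    if min(arr.shape) < 2:
        raise DimensionError(
            f"both image dimensions must be >= 2 for a 2-D decomposition, "
            f"got shape {arr.shape}"
        )
    wav = _validate_wavelet(wavelet_name)

    arr1, pad1 = _pad_even(arr)
    ll1, (lh1, hl1, hh1) = pywt.dwt2(arr1, wav, mode=boundary_mode)
    ll1_shape = ll1.shape
    ll1p, pad2 = _pad_even(ll1)
    ll2, (lh2, hl2, hh2) = pywt.dwt2(ll1p, wav, mode=boundary_mode)

    return SubbandSet(
        bands={
            "LH1": lh1,
            "HL1": hl1,
            "HH1": hh1,
            "LL2": ll2,
            "LH2": lh2,
            "HL2": hl2,
            "HH2": hh2,
        },
        wavelet_name=wavelet_name,
        boundary_mode=boundary_mode,
        padded_shape=arr1.shape,
        ll1_shape=ll1_shape,
        metadata={"pad_level1": pad1, "pad_level2": pad2},
    )


def reconstruct_two_level(
    subbands: SubbandSet, original_shape: tuple[int, int]
) -> np.ndarray:
    """Invert :func:`decompose_two_level`, cropping any even-padding.

    Composing with the forward transform is the identity up to floating
    round-off for any supported wavelet.
    """
    b = subbands.bands
    for lvl2 in ("LH2", "HL2", "HH2"):
        if b[lvl2].shape != b["LL2"].shape:
            raise ShapeError(
                f"level-2 band {lvl2} shape {b[lvl2].shape} != LL2 shape "
                f"{b['LL2'].shape}"
            )
    for lvl1 in ("HL1", "HH1"):
        if b[lvl1].shape != b["LH1"].shape:
            raise ShapeError(
                f"level-1 band {lvl1} shape {b[lvl1].shape} != LH1 shape "
                f"{b['LH1'].shape}"
            )
    wav = _validate_wavelet(subbands.wavelet_name)
    mode = subbands.boundary_mode

    ll1 = pywt.idwt2((b["LL2"], (b["LH2"], b["HL2"], b["HH2"])), wav, mode=mode)
    ll1 = ll1[: subbands.ll1_shape[0], : subbands.ll1_shape[1]]
    if ll1.shape != b["LH1"].shape:
        raise ShapeError(
            f"reconstructed LL1 shape {ll1.shape} inconsistent with level-1 "
            f"details {b['LH1'].shape}"
        )
    img = pywt.idwt2((ll1, (b["LH1"], b["HL1"], b["HH1"])), wav, mode=mode)
    img = img[: subbands.padded_shape[0], : subbands.padded_shape[1]]
    return img[: original_shape[0], : original_shape[1]]
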