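"""Per-slice embeddings behind a pluggable extractor contract.

Two extractors satisfy the contract (slice in, fixed-length finite vector
out, deterministic):

* ``reference`` — a dependency-free, frozen 64-dimensional descriptor used
  for all offline testing; its exact layout is documented below and must not
  change, because the cluster-to-relevance "foreground-mass" rule reads
  specific coordinate blocks.
* ``cnn-adapter`` — a thin shim around any registered frozen CNN embedding
  function (penultimate-layer features of a pre-trained network). No CNN is
  bundled; adapters are registered at runtime.

Reference layout (after resampling the slice to ``input_size``):

====================  ====  =====================================================
block                 dims  contents
====================  ====  =====================================================
``HIST``   [0, 16)     16   intensity histogram over [0, 1], fraction per bin
``GRID``   [16, 32)    16   4 x 4 grid of cell mean intensities (row-major)
``EDGE``   [32, 48)    16   4 orientations x 2 scales of zero-sum edge kernels,
                            mean-absolute and root-mean-square response each
``VAR``    [48, 64)    16   variances of a 4 x 4 lattice of overlapping
                            half-size windows
====================  ====  =====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import convolve

from .errors import (
    AdapterUnavailableError,
    DimensionMismatchError,
    DuplicateSliceError,
    InvalidInputError,
)
from .imgio import SliceImage

logger = logging.getLogger(__name__)

REFERENCE_DIM = 64
HIST_SLICE = slice(0, 16)
GRID_SLICE = slice(16, 32)
EDGE_SLICE = slice(32, 48)
VAR_SLICE = slice(48, 64)

SliceKey = Tuple[str, str, int]


@dataclass(frozen=True)
class ExtractorConfig:
    name: str = "reference"
    input_size: Tuple[int, int] = (64, 64)
    adapter_options: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.input_size) < 8:
            raise InvalidInputError("input_size dimensions must be >= 8")


@dataclass
class FeatureMatrix:
    """n x d embedding matrix with a row-to-slice mapping."""

    values: np.ndarray
    row_keys: List[SliceKey]
    extractor_name: str
    normalized: bool

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def d(self) -> int:
        return int(self.values.shape[1])

    def to_frame(self):
        """Flat table: key columns followed by d value columns."""
        import pandas as pd

        frame = pd.DataFrame(
            self.row_keys, columns=["patient_id", "series_id", "slice_index"]
        )
        for j in range(self.d):
            frame[f"f{j:03d}"] = self.values[:, j]
        return frame


def _resample(pixels: np.ndarray, size: Tuple[int, int]) -> np.ndarray:
    if pixels.shape == tuple(size):
        return np.asarray(pixels, dtype=np.float64)
    im = Image.fromarray(np.asarray(pixels, dtype=np.float32), mode="F")
    im = im.resize((size[1], size[0]), resample=Image.BILINEAR)
    return np.asarray(im, dtype=np.float64)


def _edge_kernels() -> List[np.ndarray]:
    """8 fixed zero-sum kernels: 4 orientations at 3x3 and 5x5 scale."""
    sob_h = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
    sob_d = np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=np.float64)
    k3 = [sob_h, sob_d, sob_h.T, sob_d[::-1].copy()]
    kernels = [k / 8.0 for k in k3]
    smooth = np.array([1.0, 2.0, 1.0]) / 4.0
    for k in k3:
        big = np.zeros((5, 5))
        big[1:4, 1:4] = k
        big = convolve(convolve(big, smooth[None, :], mode="constant"),
                       smooth[:, None], mode="constant")
        kernels.append(big / 8.0)
    return kernels


_KERNELS = _edge_kernels()


def _grid_cells(img: np.ndarray, n: int = 4):
    h, w = img.shape
    rs = np.linspace(0, h, n + 1).round().astype(int)
    cs = np.linspace(0, w, n + 1).round().astype(int)
    for i in range(n):
        for j in range(n):
            yield img[rs[i]:rs[i + 1], cs[j]:cs[j + 1]]


def _half_windows(img: np.ndarray, n: int = 4):
    h, w = img.shape
    wh, ww = max(h // 2, 1), max(w // 2, 1)
    rs = np.linspace(0, h - wh, n).round().astype(int)
    cs = np.linspace(0, w - ww, n).round().astype(int)
    for r in rs:
        for c in cs:
            yield img[r:r + wh, c:c + ww]


def extract_reference(slice_image: SliceImage, cfg: ExtractorConfig | None = None) -> np.ndarray:
    """Frozen 64-d descriptor of one windowed slice (layout in module docs)."""
    cfg = cfg or ExtractorConfig()
    pixels = np.asarray(slice_image.pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise InvalidInputError(f"invalid input: non-finite pixels in {slice_image.key}")
    img = _resample(pixels, cfg.input_size)

    counts, _ = np.histogram(img, bins=16, range=(0.0, 1.0))
    hist = counts.astype(np.float64) / img.size

    grid = np.array([cell.mean() for cell in _grid_cells(img)])

    edge = np.empty(16)
    for i, kernel in enumerate(_KERNELS):
        resp = convolve(img, kernel, mode="nearest")
        edge[2 * i] = np.abs(resp).mean()
        edge[2 * i + 1] = np.sqrt(np.mean(resp ** 2))

    var = np.array([win.var() for win in _half_windows(img)])

    return np.concatenate([hist, grid, edge, var])


_ADAPTERS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_adapter(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a frozen embedding function.

    ``fn`` receives an (H, W, C) float array in [0, 1] and must return a
    fixed-length finite 1-D vector, deterministically.
    """
    _ADAPTERS[name] = fn


def unregister_adapter(name: str) -> None:
    _ADAPTERS.pop(name, None)


def extract_cnn(slice_image: SliceImage, cfg: ExtractorConfig) -> np.ndarray:
    """Run a registered CNN adapter on one slice; grayscale is replicated to
    the channel count the adapter expects (default 3)."""
    adapter_name = str(cfg.adapter_options.get("adapter", ""))
    fn = _ADAPTERS.get(adapter_name)
    if fn is None:
        raise AdapterUnavailableError(
            f"adapter unavailable: no adapter registered under {adapter_name!r}"
        )
    pixels = np.asarray(slice_image.pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise InvalidInputError(f"invalid input: non-finite pixels in {slice_image.key}")
    img = _resample(pixels, cfg.input_size)
    n_channels = int(cfg.adapter_options.get("n_channels", 3))
    stacked = np.repeat(img[:, :, None], n_channels, axis=2)
    row = np.asarray(fn(stacked), dtype=np.float64).ravel()
    if row.size == 0 or not np.all(np.isfinite(row)):
        raise AdapterUnavailableError(
            f"adapter unavailable: non-finite embedding for slice {slice_image.key}"
        )
    return row


def extract_slice(slice_image: SliceImage, cfg: ExtractorConfig) -> np.ndarray:
    """Dispatch on ``cfg.name``; a missing CNN adapter falls back to the
    reference extractor with a logged warning."""
    if cfg.name == "reference":
        return extract_reference(slice_image, cfg)
    if cfg.name == "cnn-adapter":
        try:
            return extract_cnn(slice_image, cfg)
        except AdapterUnavailableError as exc:
            logger.warning("%s; falling back to reference extractor", exc)
            return extract_reference(slice_image, ExtractorConfig(input_size=cfg.input_size))
    raise InvalidInputError(f"invalid input: unknown extractor {cfg.name!r}")


def assemble_and_normalize(rows: Sequence[np.ndarray], row_keys: Sequence[SliceKey],
                           do_normalize: bool = True,
                           extractor_name: str = "reference") -> FeatureMatrix:
    """Stack feature rows and optionally z-score each column.

    Constant columns are set to 0 instead of dividing by a ~zero standard
    deviation. Normalizing an already-normalized matrix is a no-op up to
    floating-point round-off.
    """
    if len(rows) != len(row_keys):
        raise DimensionMismatchError("dimension mismatch: rows and keys differ in length")
    if len(set(row_keys)) != len(row_keys):
        raise DuplicateSliceError("duplicate slice: repeated row keys")
    lengths = {len(np.ravel(r)) for r in rows}
    if len(lengths) > 1:
        raise DimensionMismatchError(f"dimension mismatch: ragged row lengths {sorted(lengths)}")
    values = np.asarray([np.ravel(r) for r in rows], dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("invalid input: non-finite feature values")
    if do_normalize:
        values = zscore_columns(values)
    return FeatureMatrix(
        values=values,
        row_keys=list(row_keys),
        extractor_name=extractor_name,
        normalized=bool(do_normalize),
    )


def zscore_columns(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    out = values - mean
    constant = sd < 1e-12
    sd_safe = np.where(constant, 1.0, sd)
    out = out / sd_safe
    out[:, constant] = 0.0
    return out


def extract_matrix(slices: Sequence[SliceImage], cfg: ExtractorConfig | None = None,
                   do_normalize: bool = True) -> FeatureMatrix:
    """Convenience: extract every slice and assemble the normalized matrix."""
    cfg = cfg or ExtractorConfig()
    name = cfg.name
    if name == "cnn-adapter" and str(cfg.adapter_options.get("adapter", "")) not in _ADAPTERS:
        name = "reference"  # extract_slice will fall back slice-by-slice too
    rows = [extract_slice(s, cfg) for s in slices]
    keys = [s.key for s in slices]
    return assemble_and_normalize(rows, keys, do_normalize, extractor_name=name)
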