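"""Gramian angular field (GASF/GADF) encodings of one-minute ECG segments.

A series is min-max rescaled to [-1, 1],

    x~_i = ((x_i - max x) + (x_i - min x)) / (max x - min x),

mapped to polar angles ``phi_i = arccos(x~_i)`` (the radius ``r_i = t_i / N``
carries the timestamp but does not enter the matrices), and encoded as

    GASF_ij = cos(phi_i + phi_j)        GADF_ij = sin(phi_i - phi_j).

A 6000-sample minute would produce a 6000^2 Gram matrix; the series is first
reduced to 224 points by piecewise aggregate approximation (PAA), which gives
the 224x224 output geometry directly with ~700x less memory than building the
full matrix and resizing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import EncodedImage
from .errors import ValidationError
from .rendering import DEFAULT_COLORMAP, IMAGE_SIZE, apply_colormap, resize_bilinear


@dataclass
class RescaledSeries:
    """A series rescaled to [-1, 1] with its polar-coordinate view."""

    x_tilde: np.ndarray   # values in [-1, 1]
    phi: np.ndarray       # arccos(x_tilde), in [0, pi]
    r: np.ndarray         # timestamps t_i / N (kept for fidelity; unused below)
    n: int


@dataclass
class GafMatrix:
    values: np.ndarray
    kind: str             # "GASF" | "GADF"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("GAF matrix must be square")
        if self.kind not in ("GASF", "GADF"):
            raise ValidationError(f"unknown GAF kind {self.kind!r}")


def rescale_unit(x: np.ndarray) -> RescaledSeries:
    """Min-max rescale to [-1, 1] and transform to polar coordinates."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("series must be 1-D with at least 2 points")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValidationError("constant series has zero range; cannot rescale")
    x_tilde = ((x - hi) + (x - lo)) / (hi - lo)
    x_tilde = np.clip(x_tilde, -1.0, 1.0)   # guard rounding at the endpoints
    n = len(x)
    return RescaledSeries(
        x_tilde=x_tilde,
        phi=np.arccos(x_tilde),
        r=np.arange(1, n + 1, dtype=np.float64) / n,
        n=n,
    )


def gasf_matrix(rs: RescaledSeries) -> GafMatrix:
    """Summation field: ``cos(phi_i + phi_j)`` (symmetric, diagonal 2x~^2-1)."""
    return GafMatrix(np.cos(rs.phi[:, None] + rs.phi[None, :]), "GASF")


def gadf_matrix(rs: RescaledSeries) -> GafMatrix:
    """Difference field: ``sin(phi_i - phi_j)`` (antisymmetric, zero diagonal)."""
    return GafMatrix(np.sin(rs.phi[:, None] - rs.phi[None, :]), "GADF")


def paa(x: np.ndarray, m: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``m`` points.

    Element ``k`` is the mean of ``x`` over the (possibly fractional) bin
    ``[k*n/m, (k+1)*n/m)``; boundary samples contribute proportionally to the
    overlap.  Computed exactly via the cumulative integral of the
    piecewise-constant interpolant, so ``m == n`` is the identity.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if not 1 <= m <= n:
        raise ValidationError(f"PAA target length must be in [1, {n}], got {m}")
    if m == n:
        return x.copy()
    cum = np.concatenate(([0.0], np.cumsum(x)))

    def integral(t: np.ndarray) -> np.ndarray:
        idx = np.minimum(np.floor(t).astype(int), n - 1)
        return cum[idx] + x[idx] * (t - idx)

    edges = np.arange(m + 1) * (n / m)
    area = integral(edges[1:]) - integral(edges[:-1])
    return area / (n / m)


def render_gaf(matrix: GafMatrix, colormap: str = DEFAULT_COLORMAP,
               source: tuple[str, int] = ("", 0),
               label: str = "N") -> EncodedImage:
    """Map matrix values affinely from [-1, 1] to [0, 1], colormap, resize."""
    u = (np.clip(matrix.values, -1.0, 1.0) + 1.0) / 2.0
    rgb = apply_colormap(u, colormap)
    return EncodedImage(pixels=resize_bilinear(rgb).astype(np.float32),
                        modality=matrix.kind, source=source, label=label)


def encode_segment(samples: np.ndarray, kind: str,
                   paa_length: int = IMAGE_SIZE,
                   colormap: str = DEFAULT_COLORMAP,
                   source: tuple[str, int] = ("", 0),
                   label: str = "N") -> EncodedImage:
    """One-call GASF/GADF encoding of a preprocessed segment."""
    if kind not in ("GASF", "GADF"):
        raise ValidationError(f"unknown GAF kind {kind!r}")
    reduced = paa(np.asarray(samples, dtype=np.float64), paa_length)
    rs = rescale_unit(reduced)
    matrix = gasf_matrix(rs) if kind == "GASF" else gadf_matrix(rs)
    return render_gaf(matrix, colormap=colormap, source=source, label=label)
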