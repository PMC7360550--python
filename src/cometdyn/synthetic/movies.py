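"""Comet-movie renderer and controlled noise injection.

Each comet is rendered as an isotropic 2-D Gaussian at its per-frame
position on a constant background; zero-mean Gaussian noise of a stated SD
(on the pixel-value scale) can then be injected to probe detection
robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cometdyn.io import TrackTable


@dataclass
class MovieSimSpec:
    """Rendering parameters: PSF sigma and intensities in pixel units."""

    psf_sigma_px: float = 1.5
    peak_intensity: float = 2000.0
    background: float = 400.0
    noise_sd: float = 0.0
    pixel_size: float = 0.25
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def render_comet_movie(
    tracks: TrackTable,
    spec: MovieSimSpec,
    shape: tuple[int, int] | None = None,
    n_frames: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a (frames, y, x) stack plus the ground-truth point list.

    Ground truth holds each comet's sub-pixel position per frame in pixel
    coordinates.  An empty track table yields a pure background movie.
    """
    ps = spec.pixel_size
    df = tracks.data
    if len(df) > 0:
        max_col = int(np.ceil(df["x"].max() / ps)) + 8
        max_row = int(np.ceil(df["y"].max() / ps)) + 8
        last = int(df["frame"].max()) + 1
    else:
        max_col = max_row = 32
        last = 1
    if shape is None:
        shape = (max_row, max_col)
    if n_frames is None:
        n_frames = last

    stack = np.full((n_frames, *shape), spec.background, dtype=np.float64)
    half = int(np.ceil(4 * spec.psf_sigma_px))
    truth = []
    for _, row in df.iterrows():
        f = int(row["frame"])
        if f >= n_frames:
            continue
        cx, cy = row["x"] / ps, row["y"] / ps
        truth.append((int(row["track_id"]), f, cx, cy))
        c0, r0 = int(round(cx)), int(round(cy))
        rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, shape[0]))
        cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, shape[1]))
        if len(rr) == 0 or len(cc) == 0:
            continue
        gy = np.exp(-((rr - cy) ** 2) / (2 * spec.psf_sigma_px**2))
        gx = np.exp(-((cc - cx) ** 2) / (2 * spec.psf_sigma_px**2))
        stack[f, rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1] += (
            spec.peak_intensity * np.outer(gy, gx)
        )

    if spec.noise_sd > 0:
        stack = inject_gaussian_noise(stack, spec.noise_sd, seed=spec.seed)

    dtype = np.dtype(spec.dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        if stack.max() > info.max:
            warnings.warn("rendered intensities saturate the target dtype",
                          stacklevel=2)
        stack = np.clip(np.round(stack), info.min, info.max)
    gt = pd.DataFrame(truth, columns=["track_id", "frame", "x_px", "y_px"])
    return stack.astype(dtype), gt


def inject_gaussian_noise(
    movie: np.ndarray, sd: float, seed: int = 0
) -> np.ndarray:
    """Add independent zero-mean Gaussian noise of the given SD.

    Integer stacks are clipped to their dtype range; float stacks are
    returned unclipped.  ``sd = 0`` returns the input unchanged.
    """
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return movie
    rng = np.random.default_rng(seed)
    noisy = movie.astype(np.float64) + rng.normal(0.0, sd, movie.shape)
    if np.issubdtype(movie.dtype, np.integer):
        info = np.iinfo(movie.dtype)
        noisy = np.clip(np.round(noisy), info.min, info.max)
    return noisy.astype(movie.dtype)
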