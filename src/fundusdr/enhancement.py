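"""Type-2 fuzzy-set contrast enhancement for fundus images.

Pipeline (per intensity channel):

1. fuzzify      mu = (g - g_min) / (g_max - g_min)          in [0, 1]
2. upper/lower  mu_U = mu**alpha,  mu_L = mu**(1/alpha)      (0 < alpha <= 1)
3. combine      Hamacher T co-norm
                S_lambda(a, b) = (a + b + (lambda - 2) a b) / (1 - (1 - lambda) a b)
                with lambda = mean of the fuzzified map
4. defuzzify    g_enh = round(g_min + mu_enh * (g_max - g_min))

The upper/lower pair represents the type-2 footprint of uncertainty of the
membership; the Hamacher union pushes memberships toward 1 wherever either
bound is high, which raises contrast between bright lesions (exudates) and
the darker retinal background.  alpha = 0.9 is the operating default;
alpha = 1 collapses upper = lower = mu and the pipeline becomes (nearly)
the identity.

For colour fundus photographs enhancement is applied to a single channel
(default: green, the highest-contrast channel for retinal vasculature), to
the luminance, or independently per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GrayImage",
    "EnhancementParams",
    "fuzzify",
    "upper_membership",
    "lower_membership",
    "hamacher_conorm",
    "enhance_image",
    "enhance_array",
    "Type2FuzzyEnhancer",
    "read_image",
    "write_image",
]


class DegenerateImageError(ValueError):
    """Raised for constant images, where fuzzification is undefined."""


@dataclass(frozen=True)
class GrayImage:
    """Integer-intensity raster with its colour-level bounds.

    ``pixels`` holds intensities in ``0..levels-1``; ``g_min``/``g_max``
    are the observed extremes (both attained in ``pixels``).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError("pixels must be an integer array")
        if px.min() < 0 or px.max() > self.levels - 1:
            raise ValueError(
                f"intensities must lie in 0..{self.levels - 1}; "
                f"observed [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def g_min(self) -> int:
        return int(self.pixels.min())

    @property
    def g_max(self) -> int:
        return int(self.pixels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class EnhancementParams:
    """Exponent ``alpha`` in (0, 1] and Hamacher parameter ``lam`` in [0, 1].

    ``lam`` is conventionally the mean of the fuzzified map; pass ``None``
    to have :func:`enhance_image` compute it from the image.
    """

    alpha: float = 0.9
    lam: float | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1]; got {self.alpha!r}")
        if self.lam is not None and not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must lie in [0, 1]; got {self.lam!r}")


def _as_membership(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.size and (m.min() < 0.0 or m.max() > 1.0):
        raise ValueError(
            f"membership values must lie in [0, 1]; "
            f"observed [{m.min()}, {m.max()}]"
        )
    return m


def fuzzify(img: GrayImage) -> np.ndarray:
    """Map intensities to memberships ``(g - g_min)/(g_max - g_min)``.

    Raises :class:`DegenerateImageError` for a constant image.
    """
    g = img.pixels.astype(float)
    g_min, g_max = img.g_min, img.g_max
    if g_max == g_min:
        raise DegenerateImageError(
            "constant image: g_max == g_min, fuzzification (g - g_min)/"
            "(g_max - g_min) is undefined"
        )
    return (g - g_min) / (g_max - g_min)


def upper_membership(mu, params: EnhancementParams) -> np.ndarray:
    """Upper type-2 bound ``mu ** alpha`` (>= mu for alpha <= 1)."""
    return _as_membership(mu) ** params.alpha


def lower_membership(mu, params: EnhancementParams) -> np.ndarray:
    """Lower type-2 bound ``mu ** (1/alpha)`` (<= mu for alpha <= 1)."""
    return _as_membership(mu) ** (1.0 / params.alpha)


def hamacher_conorm(upper, lower, params: EnhancementParams) -> np.ndarray:
    """Hamacher T co-norm ``S(a,b) = (a + b + (lam-2)ab) / (1 - (1-lam)ab)``.

    Satisfies S(a, 0) = a, S(0, b) = b, S(a, b) = S(b, a) and maps
    [0,1]^2 into [0,1] for lam in [0, 1].
    """
    a = _as_membership(upper)
    b = _as_membership(lower)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    lam = params.lam
    if lam is None:
        raise ValueError("params.lam must be set for hamacher_conorm")
    ab = a * b
    denom = 1.0 - (1.0 - lam) * ab
    # For a,b in [0,1] and lam in [0,1]: (1-lam)*ab <= 1, equality only at
    # lam=0, a=b=1 where the numerator is 0 too; guard defensively.
    if np.any(denom <= 0.0):
        if lam == 0.0:
            # S_0(1,1) is the 0/0 limit of the Hamacher family; equals 1.
            out = np.where(denom > 0.0, 0.0, 1.0)
            safe = np.where(denom > 0.0, denom, 1.0)
            np.divide(a + b + (lam - 2.0) * ab, safe, out=out, where=denom > 0.0)
            return out
        raise FloatingPointError(
            "Hamacher denominator 1-(1-lam)ab <= 0; inputs outside [0,1]?"
        )
    return (a + b + (lam - 2.0) * ab) / denom


def enhance_array(
    pixels: np.ndarray,
    alpha: float = 0.9,
    lam: float | None = None,
    levels: int = 256,
) -> np.ndarray:
    """Enhance a 2-D integer array; see :func:`enhance_image`."""
    img = GrayImage(np.asarray(pixels), levels=levels)
    return enhance_image(img, EnhancementParams(alpha=alpha, lam=lam)).pixels


def enhance_image(
    img: GrayImage, params: EnhancementParams | None = None
) -> GrayImage:
    """Full enhancement: fuzzify -> upper/lower -> Hamacher -> defuzzify.

    If ``params`` is omitted, alpha = 0.9 and lam = mean of the fuzzified
    map.  Defuzzification rescales memberships linearly back onto
    ``[g_min, g_max]`` and rounds half up, so the extremes are fixed
    points.  Deterministic.
    """
    if params is None:
        params = EnhancementParams()
    mu = fuzzify(img)
    lam = params.lam if params.lam is not None else float(mu.mean())
    p = EnhancementParams(alpha=params.alpha, lam=lam)
    mu_enh = hamacher_conorm(
        upper_membership(mu, p), lower_membership(mu, p), p
    )
    g_min, g_max = img.g_min, img.g_max
    # round-half-up defuzzification
    g_enh = np.floor(g_min + mu_enh * (g_max - g_min) + 0.5)
    g_enh = np.clip(g_enh, g_min, g_max).astype(img.pixels.dtype)
    return GrayImage(g_enh, levels=img.levels)


class Type2FuzzyEnhancer:
    """sklearn-style stateless transformer around :func:`enhance_image`.

    Parameters
    ----------
    alpha : float, default 0.9
        Membership exponent in (0, 1]; larger alpha -> stronger contrast.
    channel : {"green", "luminance", "per-channel"}, default "green"
        How colour images are reduced/processed.  Grayscale inputs are
        enhanced directly.
    levels : int, default 256
        Number of colour levels (256 for 8-bit, 65536 for 16-bit).

    ``transform`` accepts a single 2-D/3-D array or a list of arrays and
    returns enhanced arrays of the same dtype.  ``lam`` is recomputed per
    image from its fuzzified map; the per-image values are exposed on
    ``lambdas_`` after a transform.
    """

    def __init__(self, alpha: float = 0.9, channel: str = "green",
                 levels: int = 256):
        self.alpha = alpha
        self.channel = channel
        self.levels = levels

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "channel": self.channel,
                "levels": self.levels}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("alpha", "channel", "levels"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        """No-op; the enhancer is stateless. Returns self."""
        EnhancementParams(alpha=self.alpha)  # validate
        if self.channel not in ("green", "luminance", "per-channel"):
            raise ValueError(
                "channel must be 'green', 'luminance' or 'per-channel'; "
                f"got {self.channel!r}"
            )
        return self

    def _enhance_one(self, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr)
        if arr.ndim == 2:
            return enhance_array(arr, alpha=self.alpha, levels=self.levels)
        if arr.ndim == 3 and arr.shape[2] in (3, 4):
            rgb = arr[..., :3]
            if self.channel == "per-channel":
                out = arr.copy()
                for c in range(3):
                    out[..., c] = enhance_array(
                        rgb[..., c], alpha=self.alpha, levels=self.levels
                    )
                return out
            if self.channel == "green":
                plane = rgb[..., 1]
            else:  # luminance (ITU-R BT.601)
                plane = np.round(
                    0.299 * rgb[..., 0] + 0.587 * rgb[..., 1]
                    + 0.114 * rgb[..., 2]
                ).astype(arr.dtype)
            return enhance_array(plane, alpha=self.alpha, levels=self.levels)
        raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")

    def transform(self, X):
        self.fit()
        single = isinstance(X, np.ndarray) and X.ndim in (2, 3) and (
            X.ndim == 2 or X.shape[2] in (3, 4)
        )
        imgs = [X] if single else list(X)
        out, lambdas = [], []
        for arr in imgs:
            arr = np.asarray(arr)
            plane = arr if arr.ndim == 2 else arr[..., 1]
            lambdas.append(float(fuzzify(GrayImage(
                np.asarray(plane), levels=self.levels)).mean()))
            out.append(self._enhance_one(arr))
        self.lambdas_ = lambdas
        return out[0] if single else out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# I/O helpers (PNG/JPEG/TIFF, 8- or 16-bit)
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a raster image as an integer numpy array (HxW or HxWxC)."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{path}: expected integer pixel type, got {arr.dtype}")
    return arr


def write_image(path: str | Path, arr: np.ndarray) -> None:
    """Write an integer array as PNG/JPEG/TIFF inferred from the suffix."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(arr))
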