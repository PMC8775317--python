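"""Histogram-based information-entropy and statistical-complexity measures.

Everything in this module operates on the digital-number (DN) histogram of a
pixel set — the multiset of integer values a raster band takes over an image,
a region of interest, or a moving window. Six quantities are computed:

* ``N`` — the *system extension*: the number of distinct DN values present
  (the number of occupied states).
* ``Hmax`` — the maximum entropy, attained when the N occupied states are
  equiprobable. By default ``Hmax = log2(N)`` bits; an alternative "literal"
  mode exposes ``Hmax = N`` for comparison with legacy scripts that used the
  extension itself as the normalizer.
* ``He`` — the Shannon (Boltzmann–Gibbs–Shannon) entropy, in bits, of the DN
  relative-frequency distribution.
* ``He/Hmax`` — the *variability*: normalized disorder in [0, 1]; 0 for a
  single-DN (fully ordered) set, 1 for an equiprobable (fully disordered) set.
* ``D`` — the *disequilibrium*: the squared Euclidean distance between the DN
  probability vector and the uniform distribution over the N occupied states.
* ``SDL`` and ``LMC`` — convex statistical-complexity measures,
  ``SDL = v(1 - v)`` and ``LMC = v·D`` with ``v = He/Hmax``. Both vanish at
  the two extremes of perfect order (one DN) and perfect disorder
  (equiprobability) and peak at intermediate heterogeneity, which is what
  makes them useful for locating transition zones in a landscape.

Probabilities are plug-in relative frequencies ``count/total`` with no
smoothing. Only DNs actually present enter any sum: absent values lie outside
the system extension and contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "DNHistogram",
    "ComplexityMetrics",
    "NoValidPixelsError",
    "build_histogram",
    "system_extension",
    "max_entropy",
    "shannon_entropy",
    "entropy_of_distribution",
    "disequilibrium_of_distribution",
    "variability",
    "disequilibrium",
    "sdl",
    "lmc",
    "compute_all",
    "METRIC_NAMES",
]

#: Names of the metrics that ROI tables and complexity maps can report.
METRIC_NAMES = ("He", "He_Hmax", "SDL", "LMC")

_ATOL = 1e-9  # absolute tolerance for internal consistency checks


class NoValidPixelsError(ValueError):
    """Raised when a pixel set is empty after nodata removal."""


@dataclass(frozen=True)
class DNHistogram:
    """Multiset of DN values as a value -> count mapping.

    Invariants: counts are positive (absent DNs are not stored), ``total``
    equals the sum of counts, and the mapping is non-empty.
    """

    counts: Mapping[int, int]
    total: int

    def __post_init__(self) -> None:
        if not self.counts:
            raise NoValidPixelsError("histogram has no values")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("histogram counts must be >= 1")
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not match the sum of counts")

    def probabilities(self) -> np.ndarray:
        """Relative frequencies of the present DNs, in key order."""
        c = np.fromiter(self.counts.values(), dtype=np.float64, count=len(self.counts))
        return c / self.total


@dataclass(frozen=True)
class ComplexityMetrics:
    """All six quantities for one pixel set.

    ``h_max`` and ``h_e`` are in bits under the default base-2 logarithm;
    ``variability`` lies in [0, 1], ``sdl`` in [0, 0.25], ``disequilibrium``
    and ``lmc`` are non-negative and vanish together with ``sdl`` at both the
    single-state and equiprobable extremes.
    """

    n_states: int
    h_max: float
    h_e: float
    variability: float
    disequilibrium: float
    sdl: float
    lmc: float


def build_histogram(
    values: Iterable[int] | np.ndarray, nodata: Optional[int] = None
) -> DNHistogram:
    """Build a DN histogram from a sequence of integers, dropping nodata.

    Raises :class:`NoValidPixelsError` if no values remain.
    """
    arr = np.asarray(values).ravel()
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("DN values must be integer-valued")
        arr = arr.astype(np.int64)
    if nodata is not None:
        arr = arr[arr != nodata]
    if arr.size == 0:
        raise NoValidPixelsError("no valid pixels (empty or all-nodata input)")
    uniq, counts = np.unique(arr, return_counts=True)
    return DNHistogram(
        counts={int(v): int(c) for v, c in zip(uniq, counts)}, total=int(arr.size)
    )


def system_extension(hist: DNHistogram) -> int:
    """Number of distinct DN values present (occupied states), N >= 1."""
    return len(hist.counts)


def max_entropy(n_states: int, hmax_mode: str = "log2") -> float:
    """Entropy of the equiprobable distribution over ``n_states`` states.

    ``hmax_mode="log2"`` (default) returns ``log2(N)`` bits; ``"literal"``
    returns ``N`` itself, matching scripts that normalize by the extension.
    """
    if n_states < 1:
        raise ValueError(f"system extension must be >= 1, got {n_states}")
    if hmax_mode == "log2":
        return float(np.log2(n_states))
    if hmax_mode == "literal":
        return float(n_states)
    raise ValueError(f"unknown hmax_mode: {hmax_mode!r}")


def entropy_of_distribution(probs: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Shannon entropy, in bits, of probability vector(s).

    Zero-probability entries contribute nothing. Vectorized over leading axes
    so families of distributions can be scanned in one call.
    """
    p = np.asarray(probs, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = terms.sum(axis=axis)
    return float(h) if np.isscalar(h) or h.ndim == 0 else h


def disequilibrium_of_distribution(probs: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Squared distance of probability vector(s) from the uniform distribution.

    The uniform reference has probability ``1/N`` on each of the N entries of
    the vector; callers pass only the occupied states.
    """
    p = np.asarray(probs, dtype=np.float64)
    n = p.shape[axis]
    d = ((p - 1.0 / n) ** 2).sum(axis=axis)
    return float(d) if np.isscalar(d) or d.ndim == 0 else d


def shannon_entropy(hist: DNHistogram) -> float:
    """Shannon entropy He of the histogram's DN distribution, in bits."""
    return float(entropy_of_distribution(hist.probabilities()))


def variability(h_e, h_max):
    """Normalized disorder ``He/Hmax`` in [0, 1].

    By convention a single-state set (``Hmax = 0``) has variability 0: a
    constant patch is the paradigm of order. Accepts scalars or arrays.
    """
    h_e = np.asarray(h_e, dtype=np.float64)
    h_max = np.asarray(h_max, dtype=np.float64)
    if np.any(h_e < -_ATOL) or np.any(h_e > h_max + _ATOL):
        raise ValueError("He must satisfy 0 <= He <= Hmax")
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(h_max > 0, h_e / np.where(h_max > 0, h_max, 1.0), 0.0)
    v = np.clip(v, 0.0, 1.0)
    return float(v) if v.ndim == 0 else v


def disequilibrium(hist: DNHistogram) -> float:
    """Disequilibrium D = sum over present DNs of (p - 1/N)^2."""
    return float(disequilibrium_of_distribution(hist.probabilities()))


def sdl(v):
    """SDL complexity ``v(1 - v)``; in [0, 0.25], maximal at v = 0.5."""
    v = np.asarray(v, dtype=np.float64)
    if np.any(v < -_ATOL) or np.any(v > 1 + _ATOL):
        raise ValueError("variability must lie in [0, 1]")
    out = v * (1.0 - v)
    return float(out) if out.ndim == 0 else out


def lmc(v, d):
    """LMC complexity ``v * d``; zero at both the ordered and disordered extremes."""
    v = np.asarray(v, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if np.any(v < -_ATOL) or np.any(v > 1 + _ATOL):
        raise ValueError("variability must lie in [0, 1]")
    if np.any(d < -_ATOL):
        raise ValueError("disequilibrium must be >= 0")
    out = v * d
    return float(out) if out.ndim == 0 else out


def compute_all(hist: DNHistogram, hmax_mode: str = "log2") -> ComplexityMetrics:
    """Compute N, Hmax, He, He/Hmax, D, SDL and LMC for one histogram."""
    n = system_extension(hist)
    h_max = max_entropy(n, hmax_mode)
    h_e = shannon_entropy(hist)
    # guard against summation round-off pushing He a hair above Hmax
    h_e = min(h_e, h_max)
    v = variability(h_e, h_max)
    d = disequilibrium(hist)
    return ComplexityMetrics(
        n_states=n,
        h_max=h_max,
        h_e=h_e,
        variability=v,
        disequilibrium=d,
        sdl=sdl(v),
        lmc=lmc(v, d),
    )
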