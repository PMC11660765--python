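"""Maximum mean discrepancy (MMD) distances between unit-mass spectra.

Each unit-mass spectrum is treated as a probability distribution P over
frequency.  Its kernel mean embedding mu_P = E_{x~P}[k(x, .)] is never
materialised; only inner products appear, so the squared MMD

    MMD^2(P, Q) = ||mu_P - mu_Q||^2
                = E[k(x, x')] + E[k(z, z')] - 2 E[k(x, z)]

reduces to count- or weight-weighted sums of inner-kernel evaluations over
bin centers.  Two equivalent computation modes are provided:

* ``weighted`` (default): plugs the bin weights in directly — the exact
  n -> infinity limit of deterministic sampling, with no rounding error;
* ``samples``: deterministically expands each spectrum into n samples
  (a bin of height 0.2 with n=1000 contributes 200 samples at its center
  frequency) and evaluates the empirical estimator on the counts.

The default estimator is the biased V-statistic (self-pair diagonal terms
included); the unbiased U-statistic is available behind a flag.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .spectra import ChannelSpectrum, Cohort

__all__ = [
    "InnerKernelSpec",
    "WeightedSample",
    "DistanceMatrix",
    "DistanceCache",
    "inner_kernel_eval",
    "deterministic_sample",
    "mmd_squared_samples",
    "mmd_squared_weighted",
    "distance_matrix",
]


@dataclass(frozen=True)
class InnerKernelSpec:
    """The kernel k(x, z) on frequency values (Hz) used inside the MMD.

    Families: ``rbf`` exp(-gamma (x-z)^2) — characteristic, hence MMD is a
    proper metric on distributions; ``linear`` x*z; ``polynomial``
    (x*z + coef0)^degree.  ``gamma`` defaults to 1.0 and frequencies enter
    in raw Hz.
    """

    family: str = "rbf"
    gamma: float = 1.0
    degree: int = 2
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown inner kernel family {self.family!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def gram(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Kernel matrix k(x_i, z_j) for frequency vectors x, z."""
        x = np.asarray(x, float)[:, None]
        z = np.asarray(z, float)[None, :]
        if self.family == "rbf":
            return np.exp(-self.gamma * (x - z) ** 2)
        if self.family == "linear":
            return x * z
        return (x * z + self.coef0) ** self.degree

    def key(self) -> tuple:
        return (self.family, self.gamma, self.degree, self.coef0)


def inner_kernel_eval(x: float, z: float, spec: InnerKernelSpec) -> float:
    """Evaluate the inner kernel at a single pair of frequencies."""
    return float(spec.gram(np.array([x]), np.array([z]))[0, 0])


@dataclass(frozen=True)
class WeightedSample:
    """A multiset of frequency samples stored as (support, counts)."""

    support: np.ndarray
    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        s = np.asarray(self.support, float)
        c = np.asarray(self.counts, int)
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "counts", c)
        if s.shape != c.shape:
            raise ValueError("support and counts must be aligned")
        if np.any(np.diff(s) <= 0):
            raise ValueError("support must be strictly ascending")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if int(c.sum()) != self.n_total:
            raise ValueError("counts must sum to n_total")

    def expand(self) -> np.ndarray:
        """Explicit sample vector (for small n; testing/debugging only)."""
        return np.repeat(self.support, self.counts)


def _apportion_counts(weights: np.ndarray, n: int) -> np.ndarray:
    # Largest-remainder (Hamilton) apportionment; ties broken by lower
    # frequency first so the result is deterministic.
    quota = n * weights
    counts = np.floor(quota).astype(int)
    deficit = n - int(counts.sum())
    if deficit > 0:
        remainders = quota - counts
        order = np.lexsort((np.arange(weights.size), -remainders))
        counts[order[:deficit]] += 1
    return counts


def deterministic_sample(spectrum: ChannelSpectrum, n: int) -> WeightedSample:
    """Deterministically expand a unit-mass spectrum into ``n`` samples.

    A bin with weight w_i at center f_i contributes round(n * w_i) samples
    at f_i, corrected by largest-remainder apportionment so the counts sum
    to exactly ``n``.  Zero-weight bins get zero samples.
    """
    if n < 1:
        raise ValueError("sample budget n must be >= 1")
    if not spectrum.is_unit_mass(tol=1e-6):
        raise ValueError("spectrum must be rescaled to unit mass before sampling")
    counts = _apportion_counts(spectrum.weights, int(n))
    return WeightedSample(spectrum.grid.bin_centers, counts, int(n))


def mmd_squared_samples(
    P: WeightedSample,
    Q: WeightedSample,
    k: InnerKernelSpec,
    unbiased: bool = False,
) -> float:
    """Empirical squared MMD between two weighted samples.

    Computed via count-weighted sums (never materialising n*m pairs).  The
    default is the V-statistic including self-pair diagonal terms; with
    ``unbiased=True`` the within-sample terms exclude them (U-statistic).
    """
    n, m = P.n_total, Q.n_total
    if n == 0 or m == 0:
        raise ValueError("samples must be non-empty")
    cp = P.counts.astype(float)
    cq = Q.counts.astype(float)
    Gxx = k.gram(P.support, P.support)
    Gzz = k.gram(Q.support, Q.support)
    Gxz = k.gram(P.support, Q.support)
    cross = 2.0 / (n * m) * (cp @ Gxz @ cq)
    if unbiased:
        if n < 2 or m < 2:
            raise ValueError("unbiased estimator needs at least 2 samples per side")
        xx = (cp @ Gxx @ cp - cp @ np.diag(Gxx)) / (n * (n - 1))
        zz = (cq @ Gzz @ cq - cq @ np.diag(Gzz)) / (m * (m - 1))
    else:
        xx = (cp @ Gxx @ cp) / n**2
        zz = (cq @ Gzz @ cq) / m**2
    return float(xx + zz - cross)


def mmd_squared_weighted(
    P: ChannelSpectrum, Q: ChannelSpectrum, k: InnerKernelSpec
) -> float:
    """Exact squared MMD using bin weights as probabilities (no sampling).

    Equals :func:`mmd_squared_samples` exactly whenever n*w_i and m*v_j are
    all integers, and is its n -> infinity limit otherwise.
    """
    if P.grid.n_bins != Q.grid.n_bins or np.any(
        np.abs(P.grid.bin_centers - Q.grid.bin_centers) > 1e-9
    ):
        raise ValueError("spectra must share one frequency grid")
    d = P.weights - Q.weights
    G = k.gram(P.grid.bin_centers, P.grid.bin_centers)
    return float(d @ G @ d)


@dataclass
class DistanceMatrix:
    """Subject-by-subject MMD distances for one channel (symmetric, zero diag)."""

    values: np.ndarray
    subject_ids: list[str]
    channel: str
    kernel: InnerKernelSpec = field(default_factory=InnerKernelSpec)
    mode: str = "weighted"

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        if V.shape != (len(self.subject_ids),) * 2:
            raise ValueError("distance matrix shape must match subject list")
        if np.max(np.abs(V - V.T)) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if np.any(V < -1e-9):
            raise ValueError("distances must be non-negative")
        self.values = np.clip((V + V.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.subject_ids)
        df.to_csv(path, index_label="subject_id")
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "channel": self.channel,
                    "mode": self.mode,
                    "kernel": {
                        "family": self.kernel.family,
                        "gamma": self.kernel.gamma,
                        "degree": self.kernel.degree,
                        "coef0": self.kernel.coef0,
                    },
                },
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        sidecar = Path(path).with_suffix(".json")
        meta = {"channel": "", "mode": "weighted", "kernel": {}}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
        return cls(
            values=df.to_numpy(float),
            subject_ids=[str(s) for s in df.index],
            channel=meta.get("channel", ""),
            kernel=InnerKernelSpec(**meta.get("kernel", {})),
            mode=meta.get("mode", "weighted"),
        )


class DistanceCache:
    """In-memory cache of distance matrices keyed by content hash of the spectra."""

    def __init__(self) -> None:
        self._store: dict[tuple, DistanceMatrix] = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _content_key(W: np.ndarray, f: np.ndarray) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(W).tobytes())
        h.update(np.ascontiguousarray(f).tobytes())
        return h.hexdigest()

    def get_or_compute(self, key: tuple, compute) -> DistanceMatrix:
        if key in self._store:
            self.hits += 1
            return self._store[key]
        self.misses += 1
        result = compute()
        self._store[key] = result
        return result


def _squared_mmd_matrix(
    W: np.ndarray, f: np.ndarray, k: InnerKernelSpec, mode: str, n: int, unbiased: bool
) -> np.ndarray:
    G = k.gram(f, f)
    if mode == "weighted":
        P = W
        M = P @ G @ P.T
        diag = np.diag(M)
        sq = diag[:, None] + diag[None, :] - 2.0 * M
    elif mode == "samples":
        C = np.vstack(
            [_apportion_counts(W[i], n) for i in range(W.shape[0])]
        ).astype(float)
        A = C @ G @ C.T
        if unbiased:
            if n < 2:
                raise ValueError("unbiased estimator needs n >= 2")
            s = C @ np.diag(G)
            xx = (np.diag(A) - s) / (n * (n - 1))
        else:
            xx = np.diag(A) / n**2
        sq = xx[:, None] + xx[None, :] - 2.0 * A / n**2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sq


def distance_matrix(
    cohort: Cohort,
    channel: str,
    k: InnerKernelSpec | None = None,
    mode: str = "weighted",
    n: int = 1000,
    unbiased: bool = False,
    cache: DistanceCache | None = None,
) -> DistanceMatrix:
    """Pairwise MMD distance matrix D for one channel of a cohort.

    Entry (i, j) is sqrt(max(0, MMD^2(P_i, P_j))).  All spectra must be
    unit-mass on the shared grid.  With a ``cache``, recomputation across
    cross-validation folds is skipped when the spectra content, kernel spec
    and mode match.
    """
    if channel not in cohort.channels:
        raise KeyError(f"unknown channel {channel!r}")
    k = k or InnerKernelSpec()
    W = cohort.spectra[channel]
    masses = W.sum(axis=1)
    if np.any(np.abs(masses - 1.0) > 1e-6):
        raise ValueError(
            f"channel {channel!r}: spectra must be rescaled to unit mass first"
        )
    f = cohort.grid.bin_centers

    def compute() -> DistanceMatrix:
        sq = _squared_mmd_matrix(W, f, k, mode, n, unbiased)
        D = np.sqrt(np.clip(sq, 0.0, None))
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        return DistanceMatrix(D, cohort.subject_ids, channel, k, mode)

    if cache is None:
        return compute()
    key = (channel, k.key(), mode, n, unbiased, DistanceCache._content_key(W, f))
    return cache.get_or_compute(key, compute)
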