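"""Cohort containers and spectral preprocessing.

A *cohort* bundles per-subject metadata (age in years, sex, acquisition
site) with per-channel power spectral densities sampled on a shared
frequency grid.  Downstream stages treat each unit-mass spectrum as a
probability distribution over frequency, so the preprocessing here is
mostly about getting spectra onto a common grid with total mass 1:

* rescaling each spectrum so its bin weights sum to 1;
* truncating all sites to the lowest common maximum cutoff frequency;
* dropping subjects without a recorded age or outside an age range;
* excluding channels (typically the reference electrode, e.g. Cz).

The on-disk interchange format is plain text: a metadata CSV
(``subject_id,age,sex,site``), one spectra CSV per channel
(``subject_id,f_<center>,...``) and a JSON grid descriptor
(``{"bin_centers_hz": [...], "resolution_hz": ..., "channels": [...]}``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "FrequencyGrid",
    "ChannelSpectrum",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "filter_subjects",
    "exclude_channels",
    "rescale_unit_mass",
    "rescale_cohort",
    "truncate_common_grid",
    "normalize_bins_across_subjects",
    "bin_variance_scales",
]

#: tolerance used when matching bin centers between grids (absorbs decimal
#: printing of 0.39-Hz grids)
GRID_ALIGN_TOL = 1e-6

SEX_LEVELS = ("F", "M", "U")


class FormatError(ValueError):
    """A file does not conform to the cohort bundle format."""


class ValidationError(ValueError):
    """File contents are well-formed but scientifically invalid."""


@dataclass(frozen=True)
class FrequencyGrid:
    """An equally spaced grid of positive frequencies (bin centers, Hz)."""

    bin_centers: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        if centers.ndim != 1 or centers.size == 0:
            raise ValidationError("grid needs at least one bin center")
        if np.any(centers <= 0):
            raise ValidationError("bin centers must be positive frequencies")
        if centers.size > 1:
            steps = np.diff(centers)
            if np.any(steps <= 0):
                raise ValidationError("bin centers must be strictly ascending")
            if np.any(np.abs(steps - self.resolution) > 1e-9):
                raise ValidationError(
                    "bin centers must be equally spaced at the stated resolution"
                )

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    @property
    def fmax(self) -> float:
        return float(self.bin_centers[-1])

    def aligned_with(self, other: "FrequencyGrid", tol: float = GRID_ALIGN_TOL) -> bool:
        """True if the grids share resolution and bin-center phase within ``tol``."""
        if abs(self.resolution - other.resolution) > tol:
            return False
        offset = (self.bin_centers[0] - other.bin_centers[0]) / self.resolution
        return abs(offset - round(offset)) * self.resolution <= tol

    def truncated(self, fmax: float, tol: float = GRID_ALIGN_TOL) -> "FrequencyGrid":
        keep = self.bin_centers <= fmax + tol
        if not np.any(keep):
            raise ValidationError(f"no bins at or below {fmax} Hz")
        return FrequencyGrid(self.bin_centers[keep], self.resolution)


@dataclass(frozen=True)
class ChannelSpectrum:
    """Non-negative spectral weights on a frequency grid.

    After :func:`rescale_unit_mass` the weights sum to one and the spectrum
    can be read as a probability distribution with point masses at the bin
    centers.
    """

    grid: FrequencyGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (self.grid.n_bins,):
            raise ValidationError("weights must have one entry per grid bin")
        if np.any(w < 0):
            raise ValidationError("spectral weights must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    def is_unit_mass(self, tol: float = 1e-9) -> bool:
        return abs(self.total_mass - 1.0) <= tol

    def mean_frequency(self) -> float:
        """First moment sum(w_i * f_i); for unit-mass spectra, the mean of P."""
        return float(self.weights @ self.grid.bin_centers)


@dataclass
class Cohort:
    """Subjects x channels x frequency bins, with one shared grid.

    ``meta`` has columns ``subject_id`` (unique strings), ``age`` (years,
    NaN when missing), ``sex`` (one of F/M/U) and ``site``.  ``spectra``
    maps each channel name to an (n_subjects, n_bins) array whose rows are
    aligned with ``meta``.
    """

    meta: pd.DataFrame
    channels: list[str]
    grid: FrequencyGrid
    spectra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        ids = self.meta["subject_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise FormatError(f"duplicate subject_id(s): {dupes}")
        bad_sex = set(self.meta["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise ValidationError(f"sex labels must be in {SEX_LEVELS}, got {bad_sex}")
        for ch in self.channels:
            if ch not in self.spectra:
                raise FormatError(f"channel {ch!r} listed but has no spectra")
            arr = np.asarray(self.spectra[ch], dtype=float)
            if arr.shape != (len(self.meta), self.grid.n_bins):
                raise FormatError(
                    f"channel {ch!r}: spectra shape {arr.shape} does not match "
                    f"({len(self.meta)} subjects, {self.grid.n_bins} bins)"
                )
            if np.any(arr < 0):
                raise ValidationError(f"channel {ch!r} contains negative spectral values")
            self.spectra[ch] = arr

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def subject_ids(self) -> list[str]:
        return self.meta["subject_id"].tolist()

    @property
    def sites(self) -> list[str]:
        """Site labels in order of first appearance."""
        return self.meta["site"].drop_duplicates().tolist()

    def ages(self) -> np.ndarray:
        return self.meta["age"].to_numpy(dtype=float)

    def spectrum(self, subject_id: str, channel: str) -> ChannelSpectrum:
        idx = self.meta.index[self.meta["subject_id"] == subject_id]
        if len(idx) == 0:
            raise KeyError(f"unknown subject {subject_id!r}")
        return ChannelSpectrum(self.grid, self.spectra[channel][idx[0]])

    def take(self, row_idx: np.ndarray | Sequence[int]) -> "Cohort":
        """Row-subset the cohort (preserves order of ``row_idx``)."""
        idx = np.asarray(row_idx, dtype=int)
        return Cohort(
            meta=self.meta.iloc[idx].reset_index(drop=True),
            channels=list(self.channels),
            grid=self.grid,
            spectra={ch: arr[idx] for ch, arr in self.spectra.items()},
        )


# ---------------------------------------------------------------------------
# bundle I/O


def _bin_column(center: float) -> str:
    return f"f_{center:.10g}"


def read_cohort(
    metadata_path: str | Path,
    spectra_paths: Mapping[str, str | Path] | str | Path,
    grid_descriptor_path: str | Path,
) -> Cohort:
    """Read a cohort bundle (metadata CSV + per-channel spectra CSVs + grid JSON).

    ``spectra_paths`` is either a mapping channel -> CSV path, or a directory
    containing ``<channel>.csv`` for every channel in the grid descriptor.
    Subjects present in the metadata but absent from any spectra file are
    dropped (with a warning), as are spectra rows without metadata.
    """
    with open(grid_descriptor_path) as fh:
        desc = json.load(fh)
    grid = FrequencyGrid(np.asarray(desc["bin_centers_hz"], float), float(desc["resolution_hz"]))
    channels = list(desc["channels"])

    if not isinstance(spectra_paths, Mapping):
        root = Path(spectra_paths)
        spectra_paths = {ch: root / f"{ch}.csv" for ch in channels}
    missing = [ch for ch in channels if ch not in spectra_paths]
    if missing:
        raise FormatError(f"no spectra file for channel(s) {missing}")

    meta = pd.read_csv(
        metadata_path, dtype={"subject_id": str}, float_precision="round_trip"
    )
    required = {"subject_id", "age", "sex", "site"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    if meta["subject_id"].duplicated().any():
        raise FormatError("duplicate subject_id in metadata")
    meta = meta[["subject_id", "age", "sex", "site"]].copy()
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    meta["sex"] = meta["sex"].fillna("U").astype(str)
    meta["site"] = meta["site"].astype(str)

    frames: dict[str, pd.DataFrame] = {}
    keep_ids: set[str] | None = None
    for ch in channels:
        df = pd.read_csv(
            spectra_paths[ch], dtype={"subject_id": str},
            float_precision="round_trip",
        )
        if df.columns[0] != "subject_id":
            raise FormatError(f"{spectra_paths[ch]}: first column must be subject_id")
        value_cols = list(df.columns[1:])
        if len(value_cols) != grid.n_bins:
            raise FormatError(
                f"{spectra_paths[ch]}: {len(value_cols)} spectral columns but the "
                f"grid has {grid.n_bins} bins"
            )
        for col, center in zip(value_cols, grid.bin_centers):
            try:
                header_hz = float(col.removeprefix("f_"))
            except ValueError as exc:
                raise FormatError(f"bad spectral column name {col!r}") from exc
            if abs(header_hz - center) > GRID_ALIGN_TOL:
                raise FormatError(
                    f"column {col!r} does not match grid bin center {center} Hz"
                )
        if df["subject_id"].duplicated().any():
            raise FormatError(f"{spectra_paths[ch]}: duplicate subject_id")
        values = df[value_cols].to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValidationError(f"{spectra_paths[ch]}: negative spectral value")
        df = df.set_index("subject_id")
        frames[ch] = df
        ids = set(df.index)
        keep_ids = ids if keep_ids is None else keep_ids & ids

    assert keep_ids is not None
    present = meta["subject_id"].isin(keep_ids)
    if not present.all():
        dropped = meta.loc[~present, "subject_id"].tolist()
        warnings.warn(
            f"{len(dropped)} subject(s) in metadata have no spectra and were dropped",
            stacklevel=2,
        )
    meta = meta[present].reset_index(drop=True)
    order = meta["subject_id"].tolist()
    spectra = {ch: frames[ch].loc[order].to_numpy(dtype=float) for ch in channels}
    return Cohort(meta=meta, channels=channels, grid=grid, spectra=spectra)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the canonical bundle; returns the bundle directory.

    Layout: ``metadata.csv``, ``grid.json`` and ``spectra/<channel>.csv``.
    Floats are written with full repr so a write -> read -> write round trip
    is byte-identical.
    """
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    cohort.meta.to_csv(out / "metadata.csv", index=False)
    desc = {
        "bin_centers_hz": [float(c) for c in cohort.grid.bin_centers],
        "resolution_hz": float(cohort.grid.resolution),
        "channels": list(cohort.channels),
    }
    with open(out / "grid.json", "w") as fh:
        json.dump(desc, fh, indent=1)
        fh.write("\n")
    cols = [_bin_column(c) for c in cohort.grid.bin_centers]
    for ch in cohort.channels:
        df = pd.DataFrame(cohort.spectra[ch], columns=cols)
        df.insert(0, "subject_id", cohort.meta["subject_id"])
        df.to_csv(out / "spectra" / f"{ch}.csv", index=False)
    return out


def read_bundle(bundle_dir: str | Path) -> Cohort:
    """Read a bundle written by :func:`write_cohort`."""
    root = Path(bundle_dir)
    return read_cohort(root / "metadata.csv", root / "spectra", root / "grid.json")


# ---------------------------------------------------------------------------
# preprocessing operations


def filter_subjects(
    cohort: Cohort,
    min_age: float,
    max_age: float,
    drop_missing_age: bool = True,
) -> Cohort:
    """Keep subjects whose recorded age lies in [min_age, max_age] (inclusive).

    Subjects with missing age are dropped unless ``drop_missing_age`` is
    False, in which case they are retained regardless of the bounds.
    """
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    age = cohort.meta["age"]
    in_range = (age >= min_age) & (age <= max_age)
    keep = in_range.where(age.notna(), other=not drop_missing_age)
    if not keep.any():
        warnings.warn("age filter removed every subject", stacklevel=2)
    return cohort.take(np.flatnonzero(keep.to_numpy()))


def exclude_channels(cohort: Cohort, names: Iterable[str]) -> Cohort:
    """Drop the named channels (e.g. the reference electrode) from the cohort."""
    names = list(names)
    unknown = [n for n in names if n not in cohort.channels]
    if unknown:
        raise KeyError(f"unknown channel(s): {unknown}")
    remaining = [ch for ch in cohort.channels if ch not in names]
    return Cohort(
        meta=cohort.meta.copy(),
        channels=remaining,
        grid=cohort.grid,
        spectra={ch: cohort.spectra[ch] for ch in remaining},
    )


def rescale_unit_mass(spectrum: ChannelSpectrum) -> ChannelSpectrum:
    """Rescale so the weights sum to 1 (probability-distribution view)."""
    total = spectrum.total_mass
    if total <= 0:
        raise ValidationError("cannot rescale an all-zero spectrum to unit mass")
    return ChannelSpectrum(spectrum.grid, spectrum.weights / total)


def rescale_cohort(cohort: Cohort) -> Cohort:
    """Rescale every spectrum of every channel to unit mass."""
    spectra = {}
    for ch, arr in cohort.spectra.items():
        totals = arr.sum(axis=1)
        if np.any(totals <= 0):
            bad = cohort.meta["subject_id"][totals <= 0].tolist()
            raise ValidationError(f"channel {ch!r}: all-zero spectrum for {bad}")
        spectra[ch] = arr / totals[:, None]
    return Cohort(cohort.meta.copy(), list(cohort.channels), cohort.grid, spectra)


def truncate_common_grid(cohorts: Sequence[Cohort] | Cohort) -> Cohort:
    """Merge per-site cohorts onto the lowest common maximum cutoff frequency.

    All inputs must share bin resolution and aligned bin centers up to the
    minimum cutoff.  Spectra are truncated at the minimum of the per-site
    maximum cutoffs and then re-rescaled to unit mass.  A single cohort is
    the identity up to re-rescaling.
    """
    if isinstance(cohorts, Cohort):
        cohorts = [cohorts]
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("need at least one cohort")
    ref = cohorts[0].grid
    for c in cohorts[1:]:
        if not ref.aligned_with(c.grid):
            raise ValidationError(
                "cohort grids are misaligned (different resolution or offset)"
            )
    cutoff = min(c.grid.fmax for c in cohorts)
    channels = [ch for ch in cohorts[0].channels if all(ch in c.channels for c in cohorts)]
    if not channels:
        raise ValidationError("cohorts share no channels")

    grid = ref.truncated(cutoff)
    metas, blocks = [], {ch: [] for ch in channels}
    for c in cohorts:
        keep = c.grid.bin_centers <= cutoff + GRID_ALIGN_TOL
        metas.append(c.meta)
        for ch in channels:
            blocks[ch].append(c.spectra[ch][:, keep])
    meta = pd.concat(metas, ignore_index=True)
    spectra = {ch: np.vstack(blocks[ch]) for ch in channels}
    merged = Cohort(meta=meta, channels=channels, grid=grid, spectra=spectra)
    return rescale_cohort(merged)


def bin_variance_scales(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Per-bin 1/std scale factors; degenerate (constant) bins get scale 1.

    Exposed separately so cross-validation can derive scales from training
    rows only and apply them to held-out rows.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects to normalize bins")
    sd = X.std(axis=0, ddof=ddof)
    constant = sd <= 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} bin(s) are constant across subjects; "
            "passed through unscaled",
            stacklevel=2,
        )
    scales = np.where(constant, 1.0, 1.0 / np.where(constant, 1.0, sd))
    return scales


def normalize_bins_across_subjects(cohort: Cohort, channel: str) -> np.ndarray:
    """Feature view with each frequency bin scaled to unit variance across subjects.

    This is the per-bin normalisation variant used by the linear/kernel ridge
    baselines; it does NOT alter the distribution view used by the embedding
    distance (which always sees unit-mass spectra).
    """
    if channel not in cohort.channels:
        raise KeyError(f"unknown channel {channel!r}")
    X = cohort.spectra[channel]
    return X * bin_variance_scales(X)[None, :]
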