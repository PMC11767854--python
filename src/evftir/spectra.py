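"""Containers and CSV input/output for collections of ATR-FTIR absorbance spectra.

The central object is :class:`SpectraSet`: a matrix of absorbance spectra on a
shared, uniform wavenumber grid together with per-spectrum sample metadata and a
plain-text provenance log.  By FTIR convention the axis is stored in descending
wavenumber order (4000 -> 600 cm^-1); ascending input is normalized on load and
the reordering is recorded in the provenance.

On disk a spectra collection is a pair of CSV files:

* spectra CSV: header ``wavenumber,<sample_id>,...``, one row per grid point,
  one column per spectrum;
* metadata CSV: columns ``sample_id,sample_type,condition,bio_rep,tech_rep``.

A uniform grid is required because the Savitzky-Golay derivative filters used
downstream assume equally spaced points; non-uniform data must be resampled
before entering this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("cells", "EVs")
CONDITIONS = ("control", "abeta")

#: Relative tolerance within which all consecutive grid differences must agree
#: with the median spacing for the grid to count as uniform.
GRID_RTOL = 1e-6


class SpectraValidationError(ValueError):
    """A spectra table or its metadata violates the data contract."""


@dataclass(eq=False)
class WavenumberAxis:
    """A strictly monotonic, uniformly spaced wavenumber grid in cm^-1.

    Parameters
    ----------
    values
        Grid points in cm^-1.  Stored exactly as given; callers that require
        the canonical descending order should construct through
        :meth:`canonical`.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectraValidationError(
                "wavenumber axis must be one-dimensional with at least 2 points"
            )
        if not np.all(np.isfinite(v)):
            raise SpectraValidationError("wavenumber axis contains non-finite values")
        d = np.diff(v)
        if np.any(d == 0):
            raise SpectraValidationError("wavenumber axis contains duplicate values")
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraValidationError("wavenumber axis is not strictly monotonic")
        med = float(np.median(np.abs(d)))
        if not np.allclose(np.abs(d), med, rtol=GRID_RTOL, atol=0.0):
            worst = int(np.argmax(np.abs(np.abs(d) - med)))
            raise SpectraValidationError(
                f"non-uniform wavenumber grid: spacing between points {worst} and "
                f"{worst + 1} ({abs(d[worst]):g} cm^-1) deviates from the median "
                f"spacing ({med:g} cm^-1)"
            )
        self.values = v

    @classmethod
    def canonical(cls, values: np.ndarray) -> tuple["WavenumberAxis", bool]:
        """Build an axis in descending order; return ``(axis, was_reversed)``."""
        axis = cls(np.asarray(values, dtype=float))
        if not axis.descending:
            return cls(axis.values[::-1].copy()), True
        return axis, False

    @property
    def spacing(self) -> float:
        """Grid spacing in cm^-1 (median absolute consecutive difference)."""
        return float(np.median(np.abs(np.diff(self.values))))

    @property
    def descending(self) -> bool:
        return bool(self.values[0] > self.values[-1])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one acquired spectrum.

    ``bio_rep`` indexes the independent biological experiment and ``tech_rep``
    the repeated acquisition of the same sample; the four-tuple
    ``(sample_type, condition, bio_rep, tech_rep)`` must be unique within a
    :class:`SpectraSet`.
    """

    sample_id: str
    sample_type: str
    condition: str
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise SpectraValidationError(
                f"sample {self.sample_id!r}: sample_type {self.sample_type!r} "
                f"not in {SAMPLE_TYPES}"
            )
        if self.condition not in CONDITIONS:
            raise SpectraValidationError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"not in {CONDITIONS}"
            )
        for name in ("bio_rep", "tech_rep"):
            val = getattr(self, name)
            if int(val) != val or int(val) < 1:
                raise SpectraValidationError(
                    f"sample {self.sample_id!r}: {name} must be an integer >= 1, "
                    f"got {val!r}"
                )

    @property
    def design_key(self) -> tuple[str, str, int, int]:
        return (self.sample_type, self.condition, self.bio_rep, self.tech_rep)


@dataclass(eq=False)
class SpectraSet:
    """Absorbance spectra on a shared wavenumber axis plus per-row metadata."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    meta: tuple[SampleMeta, ...]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            a = a.reshape(-1, len(self.axis))
        self.meta = tuple(self.meta)
        if a.shape[0] != len(self.meta):
            raise SpectraValidationError(
                f"{a.shape[0]} spectra rows but {len(self.meta)} metadata entries"
            )
        if a.shape[1] != len(self.axis):
            raise SpectraValidationError(
                f"spectra have {a.shape[1]} points but the axis has {len(self.axis)}"
            )
        if a.size and not np.all(np.isfinite(a)):
            bad = np.argwhere(~np.isfinite(a))[0]
            raise SpectraValidationError(
                f"non-finite absorbance in spectrum {self.meta[bad[0]].sample_id!r} "
                f"at {self.axis.values[bad[1]]:g} cm^-1"
            )
        self.absorbance = a
        self.provenance = tuple(self.provenance)

        keys = [m.design_key for m in self.meta]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise SpectraValidationError(
                f"duplicate (sample_type, condition, bio_rep, tech_rep) = {dup}"
            )
        ids = [m.sample_id for m in self.meta]
        if len(set(ids)) != len(ids):
            dup_id = next(i for i in ids if ids.count(i) > 1)
            raise SpectraValidationError(f"duplicate sample_id {dup_id!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.meta)

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a tidy DataFrame, one row per spectrum."""
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "sample_type": [m.sample_type for m in self.meta],
                "condition": [m.condition for m in self.meta],
                "bio_rep": [m.bio_rep for m in self.meta],
                "tech_rep": [m.tech_rep for m in self.meta],
            }
        )

    def with_data(
        self,
        absorbance: np.ndarray,
        axis: WavenumberAxis | None = None,
        log: str | None = None,
        meta: tuple[SampleMeta, ...] | None = None,
    ) -> "SpectraSet":
        """Return a new set sharing this one's metadata, with ``log`` appended."""
        prov = self.provenance + ((log,) if log else ())
        return SpectraSet(
            axis=axis if axis is not None else self.axis,
            absorbance=absorbance,
            meta=meta if meta is not None else self.meta,
            provenance=prov,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def crop_region(s: SpectraSet, high: float, low: float) -> SpectraSet:
    """Restrict ``s`` to axis points in the closed interval ``[low, high]``.

    ``high``/``low`` are in cm^-1 with ``high > low``; grid points equal to the
    bounds are included.  The input set is never mutated.
    """
    if not high > low:
        raise ValueError(f"crop bounds must satisfy high > low, got {high} <= {low}")
    mask = (s.axis.values >= low) & (s.axis.values <= high)
    if not mask.any():
        raise ValueError(
            f"crop region [{low}, {high}] cm^-1 does not intersect the axis "
            f"({s.axis.values.min():g}-{s.axis.values.max():g} cm^-1)"
        )
    axis = WavenumberAxis(s.axis.values[mask].copy())
    return s.with_data(
        s.absorbance[:, mask].copy(),
        axis=axis,
        log=f"crop_region: {high:g}-{low:g} cm^-1 ({int(mask.sum())} points)",
    )


def subset(s: SpectraSet, predicate: Callable[[SampleMeta], bool]) -> SpectraSet:
    """Rows of ``s`` whose metadata satisfy ``predicate``, order preserved."""
    idx = [i for i, m in enumerate(s.meta) if predicate(m)]
    return SpectraSet(
        axis=s.axis,
        absorbance=s.absorbance[idx].copy(),
        meta=tuple(s.meta[i] for i in idx),
        provenance=s.provenance + (f"subset: kept {len(idx)}/{s.n_spectra} spectra",),
    )


META_COLUMNS = ("sample_id", "sample_type", "condition", "bio_rep", "tech_rep")


def _read_meta_csv(meta_path: str | Path) -> dict[str, SampleMeta]:
    try:
        mdf = pd.read_csv(meta_path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise SpectraValidationError(f"cannot parse metadata file {meta_path}: {exc}")
    missing = [c for c in META_COLUMNS if c not in mdf.columns]
    if missing:
        raise SpectraValidationError(
            f"metadata file {meta_path} is missing columns {missing}"
        )
    out: dict[str, SampleMeta] = {}
    for _, row in mdf.iterrows():
        try:
            m = SampleMeta(
                sample_id=str(row["sample_id"]),
                sample_type=str(row["sample_type"]),
                condition=str(row["condition"]),
                bio_rep=int(row["bio_rep"]),
                tech_rep=int(row["tech_rep"]),
            )
        except (TypeError, ValueError) as exc:
            raise SpectraValidationError(
                f"metadata row for sample_id {row['sample_id']!r}: {exc}"
            )
        out[m.sample_id] = m
    return out


def read_spectra_csv(path: str | Path, meta_path: str | Path) -> SpectraSet:
    """Load a spectra CSV plus its metadata CSV into a validated SpectraSet.

    The spectra file's first column is the wavenumber grid; every remaining
    column is one spectrum whose header is its ``sample_id``.  An ascending
    grid is silently re-sorted to the canonical descending order and the
    reordering is recorded in the provenance.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SpectraValidationError(f"cannot parse spectra file {path}: {exc}")
    if df.shape[1] < 1:
        raise SpectraValidationError(f"spectra file {path} has no columns")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (TypeError, ValueError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise SpectraValidationError(
                f"non-numeric value {bad.iloc[0]!r} in column {col!r} "
                f"(row {int(bad.index[0])}) of {path}"
            )
    wn_col = df.columns[0]
    axis, reversed_ = WavenumberAxis.canonical(df[wn_col].to_numpy())
    sample_cols = list(df.columns[1:])

    meta_by_id = _read_meta_csv(meta_path)
    missing_meta = [c for c in sample_cols if c not in meta_by_id]
    if missing_meta:
        raise SpectraValidationError(
            f"spectra columns with no metadata entry: {missing_meta}"
        )

    data = df[sample_cols].to_numpy(dtype=float).T
    if reversed_:
        data = data[:, ::-1]
    prov = [f"read_spectra_csv: {len(sample_cols)} spectra x {len(axis)} points"]
    if reversed_:
        prov.append("read_spectra_csv: ascending axis re-sorted to descending")
    return SpectraSet(
        axis=axis,
        absorbance=data,
        meta=tuple(meta_by_id[c] for c in sample_cols),
        provenance=tuple(prov),
    )


def write_spectra_csv(
    s: SpectraSet, path: str | Path, meta_path: str | Path | None = None
) -> Path:
    """Write ``s`` as a wide spectra CSV (and optionally its metadata CSV).

    Floats are written with Python's shortest round-tripping representation,
    so ``read_spectra_csv(write_spectra_csv(s))`` reproduces the absorbance
    matrix exactly.
    """
    path = Path(path)
    df = pd.DataFrame({"wavenumber": s.axis.values})
    for i, m in enumerate(s.meta):
        df[m.sample_id] = s.absorbance[i]
    df.to_csv(path, index=False)
    if meta_path is not None:
        s.meta_frame().to_csv(meta_path, index=False)
    return path
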