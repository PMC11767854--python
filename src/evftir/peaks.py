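"""Peak detection, target matching and shift screening on inverted derivatives.

After inversion, absorption bands of the original spectrum appear as local
maxima of the second-derivative trace.  Detection is deliberately simple and
grid-faithful: a peak is a strict sign change of the first difference (plateau
runs take their highest-wavenumber point), filtered by topographic prominence.
Positions are grid points; intensities are the inverted-second-derivative
value at the apex (arbitrary units).  A 3-point parabolic refinement of the
position is available but off by default, matching the practice of reading
values off a discrete derivative trace.

Each sample type has a fixed list of target wavenumbers whose intensities are
quantified (6 for cells, 9 for EVs).  Detected peaks are matched to targets
within a tolerance (default 6 cm^-1, the scale of the doublet splittings in
the assignment table and of the grid step).  A target whose matched apex
position varies by more than ``max_spread`` within one condition group is
flagged shift-excluded: its intensity is reported but withheld from group
statistics, mirroring how a wandering band cannot be read as one peak.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .spectra import SpectraSet

#: Target wavenumbers (cm^-1) whose intensities are quantified, per sample type.
TARGETS = {
    "cells": (1240.0, 1170.0, 1121.0, 1085.0, 969.0, 903.0),
    "EVs": (1240.0, 1172.0, 1121.0, 1102.0, 1085.0, 1056.0, 991.0, 969.0, 915.0),
}

DEFAULT_TOLERANCE = 6.0  # cm^-1


def target_peak_set(sample_type: str) -> tuple[float, ...]:
    """The fixed target wavenumbers for ``sample_type`` ('cells' or 'EVs')."""
    try:
        return TARGETS[sample_type]
    except KeyError:
        raise ValueError(
            f"unknown sample type {sample_type!r}; expected one of {tuple(TARGETS)}"
        )


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus yield their leftmost index."""
    idx: list[int] = []
    n = y.size
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and y[j + 1] == y[j]:
            j += 1
        if j < n - 1 and y[i] > y[i - 1] and y[j] > y[j + 1]:
            idx.append(i)
        i = j + 1
    return idx


def topographic_prominences(y: np.ndarray, idx: list[int]) -> np.ndarray:
    """Classic topographic prominence of the peaks at ``idx``.

    For each peak, every side is walked until strictly higher terrain is met;
    the key saddle is the higher of the per-side minima over sides that *do*
    reach higher terrain.  A side that runs off the signal end without meeting
    higher terrain defines no saddle, so a band truncated by the region edge
    keeps its full prominence (unlike window-bounded conventions, which would
    erase real peaks sitting one grid point inside the edge).  The global
    maximum has no higher terrain at all; its prominence is height above the
    signal minimum.
    """
    proms = np.empty(len(idx))
    for k, i in enumerate(idx):
        saddles = []
        mins = []
        for step in (-1, 1):
            low = y[i]
            j = i + step
            found_higher = False
            while 0 <= j < y.size:
                low = min(low, y[j])
                if y[j] > y[i]:
                    found_higher = True
                    break
                j += step
            mins.append(low)
            if found_higher:
                saddles.append(low)
        base = max(saddles) if saddles else min(mins)
        proms[k] = y[i] - base
    return proms


def default_prominence(y: np.ndarray) -> float:
    """3x the median absolute deviation of the trace's negative part.

    The negative part of an inverted second derivative is noise plus the side
    lobes of bands, so its MAD tracks the noise floor without being inflated
    by the peaks themselves.  Falls back to the MAD of the whole trace when
    nothing is negative.
    """
    neg = y[y < 0]
    ref = neg if neg.size else y
    mad = float(np.median(np.abs(ref - np.median(ref))))
    return 3.0 * mad


def detect_peaks(
    inverted: SpectraSet,
    min_prominence: float | None = None,
    refine: bool = False,
) -> pd.DataFrame:
    """Detect per-spectrum peaks on inverted second-derivative spectra.

    Parameters
    ----------
    inverted
        Inverted second-derivative spectra.
    min_prominence
        Topographic prominence cutoff in A.U.; ``None`` applies the
        per-spectrum :func:`default_prominence`.
    refine
        If true, positions (not intensities) are refined by a 3-point
        parabolic fit around the apex.

    Returns
    -------
    DataFrame with columns ``sample_id, position_cm1, intensity_au,
    prominence`` (one row per detected peak, possibly none).
    """
    v = inverted.axis.values
    rows = []
    for i, meta in enumerate(inverted.meta):
        y = inverted.absorbance[i]
        cand = _local_maxima(y)
        # absorption bands have positive inverted curvature at the apex;
        # maxima at negative values are side-lobe artifacts, and maxima below
        # numerical noise relative to the trace scale are dust
        floor = 1e-9 * np.max(np.abs(y)) if y.size else 0.0
        cand = [j for j in cand if y[j] > floor]
        if not cand:
            continue
        prom = topographic_prominences(y, cand)
        cutoff = default_prominence(y) if min_prominence is None else min_prominence
        for j, p in zip(cand, prom):
            if p < cutoff:
                continue
            pos = float(v[j])
            if refine and 0 < j < y.size - 1:
                denom = y[j - 1] - 2 * y[j] + y[j + 1]
                if denom < 0:
                    pos += 0.5 * (y[j - 1] - y[j + 1]) / denom * (v[j + 1] - v[j])
            rows.append(
                {
                    "sample_id": meta.sample_id,
                    "position_cm1": pos,
                    "intensity_au": float(y[j]),
                    "prominence": float(p),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "position_cm1", "intensity_au", "prominence"]
    )


def match_targets(
    inverted: SpectraSet,
    peaks: pd.DataFrame,
    targets: tuple[float, ...],
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Match detected peaks to target wavenumbers, one row per (spectrum, target).

    For every spectrum and target, the detected peak nearest the target within
    ``tolerance`` cm^-1 is taken (distance ties break toward the higher
    intensity); targets with no peak in reach get ``matched = False``.  The
    returned PeakTable carries the sample metadata and a ``shift_flag`` column
    initialized to False (see :func:`check_peak_shift`).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_id = dict(tuple(peaks.groupby("sample_id"))) if len(peaks) else {}
    rows = []
    for meta in inverted.meta:
        sub = by_id.get(meta.sample_id)
        for target in targets:
            found, intensity, matched = np.nan, np.nan, False
            if sub is not None and len(sub):
                d = np.abs(sub["position_cm1"].to_numpy() - target)
                within = d <= tolerance
                if within.any():
                    dmin = d[within].min()
                    ties = sub[within & (d <= dmin + 1e-12)]
                    best = ties.loc[ties["intensity_au"].idxmax()]
                    found = float(best["position_cm1"])
                    intensity = float(best["intensity_au"])
                    matched = True
            rows.append(
                {
                    "sample_id": meta.sample_id,
                    "sample_type": meta.sample_type,
                    "condition": meta.condition,
                    "bio_rep": meta.bio_rep,
                    "tech_rep": meta.tech_rep,
                    "target_cm1": float(target),
                    "found_cm1": found,
                    "intensity_au": intensity,
                    "matched": matched,
                    "shift_flag": False,
                }
            )
    return pd.DataFrame(rows)


def check_peak_shift(table: pd.DataFrame, max_spread: float | None = None,
                     grid_step: float | None = None) -> pd.DataFrame:
    """Flag targets whose matched position wanders within a condition group.

    For each (target, condition), if ``max(found) - min(found)`` among matched
    rows exceeds ``max_spread`` (default: one grid step, estimated from the
    matched positions when ``grid_step`` is not given), the whole target is
    marked ``shift_flag = True``.  Flagged targets stay in the table -- they
    are excluded from statistics downstream, never silently dropped.
    """
    out = table.copy()
    if max_spread is None:
        if grid_step is None:
            pos = np.unique(out.loc[out["matched"], "found_cm1"].dropna())
            grid_step = float(np.min(np.diff(pos))) if pos.size > 1 else 0.0
        max_spread = grid_step
    flagged: set[float] = set()
    matched = out[out["matched"]]
    for (target, _cond), grp in matched.groupby(["target_cm1", "condition"]):
        spread = grp["found_cm1"].max() - grp["found_cm1"].min()
        if spread > max_spread:
            flagged.add(target)
    out["shift_flag"] = out["target_cm1"].isin(flagged)
    return out


def load_assignments() -> pd.DataFrame:
    """The bundled peak-assignment table for the 1280-900 cm^-1 region.

    Columns: ``wavenumber`` (cm^-1), ``observed_in`` (semicolon-separated
    sample types), ``assignment`` (vibrational-mode text), ``note``.
    """
    ref = resources.files("evftir").joinpath("data/peak_assignments.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if df.empty or "assignment" not in df.columns:
        raise RuntimeError("bundled peak assignment table is missing or corrupt")
    df["note"] = df.get("note", pd.Series(dtype=str)).fillna("")
    return df


def lookup_assignment(wavenumber: float, assignments: pd.DataFrame | None = None) -> str | None:
    """Assignment text for an exactly listed wavenumber, or ``None``."""
    table = load_assignments() if assignments is None else assignments
    hit = table[table["wavenumber"] == wavenumber]
    if hit.empty:
        return None
    return str(hit.iloc[0]["assignment"])
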