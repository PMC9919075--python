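"""Chromatographic fingerprint processing.

Turns per-sample peak tables (retention time, area) into the normalized
characteristic-peak matrix that the gray relational and PLS stages use as
their X block.  Matching assigns each reference peak the nearest sample
peak inside a retention-time window (default 0.2 min); undetected peaks
are floored at a small positive area (default 0.01) before row
normalization so that every extract contributes a full-length, unit-sum
composition vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PeakList",
    "PeakMatrix",
    "MatchReport",
    "match_peaks",
    "build_reference_rts",
    "apply_area_floor",
    "normalize_rows",
    "compute_rsd",
    "FingerprintMatcher",
    "read_peak_tables",
    "write_peak_tables",
]

DEFAULT_WINDOW_MIN = 0.2
DEFAULT_AREA_FLOOR = 0.01


@dataclass(frozen=True)
class PeakList:
    """One sample's detected peaks."""

    sample_id: str
    rts: np.ndarray
    areas: np.ndarray

    def __post_init__(self):
        rts = np.asarray(self.rts, float)
        areas = np.asarray(self.areas, float)
        if rts.shape != areas.shape:
            raise ValueError("rts and areas must have the same length")
        if not np.all(np.isfinite(rts)):
            raise ValueError("retention times must be finite")
        if np.any(areas < 0):
            raise ValueError("areas must be nonnegative")
        object.__setattr__(self, "rts", rts)
        object.__setattr__(self, "areas", areas)


@dataclass
class PeakMatrix:
    """Samples x characteristic peaks area matrix.

    ``areas`` may contain NaN for unmatched peaks until the floor is
    applied.  ``normalized`` records whether rows sum to one.
    """

    sample_ids: list[str]
    reference_rts: np.ndarray
    areas: np.ndarray
    normalized: bool = False
    floor_value: float | None = None

    def __post_init__(self):
        self.reference_rts = np.asarray(self.reference_rts, float)
        self.areas = np.asarray(self.areas, float)
        if self.areas.shape != (len(self.sample_ids), self.reference_rts.size):
            raise ValueError("areas shape must be (n_samples, n_reference_peaks)")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"P{j + 1}" for j in range(self.reference_rts.size)]
        return pd.DataFrame(self.areas, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            list(self.sample_ids),
            self.reference_rts.copy(),
            self.areas.copy(),
            self.normalized,
            self.floor_value,
        )


@dataclass
class MatchReport:
    """Bookkeeping from peak matching: per sample, matched/missing counts
    and per-peak rt deviations; close reference pairs are warned about."""

    rows: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _check_reference(reference_rts: np.ndarray, window: float, report: MatchReport | None):
    ref = np.asarray(reference_rts, float)
    if ref.ndim != 1 or ref.size == 0:
        raise ValueError("reference_rts must be a nonempty 1-d array")
    if not np.all(np.diff(ref) > 0):
        raise ValueError("reference rts must be strictly increasing")
    if window <= 0:
        raise ValueError("window must be positive")
    gaps = np.diff(ref)
    close = np.nonzero(gaps < 2 * window)[0]
    if close.size and report is not None:
        for j in close:
            report.warnings.append(
                f"reference peaks {j + 1} and {j + 2} are {gaps[j]:.3f} min apart "
                f"(< 2*window = {2 * window:.3f}); ambiguous assignment possible"
            )
    return ref


def match_peaks(
    reference_rts: Sequence[float],
    sample: PeakList,
    window: float = DEFAULT_WINDOW_MIN,
    report: MatchReport | None = None,
) -> np.ndarray:
    """Assign sample peaks to reference peaks by nearest retention time.

    Greedy over candidate (reference, sample-peak) pairs in ascending
    |Δrt|, ties broken toward the earlier retention time; each sample
    peak is used at most once.  Unmatched reference peaks come back NaN.
    """
    report = report if report is not None else MatchReport()
    ref = _check_reference(reference_rts, window, report)
    out = np.full(ref.size, np.nan)
    dev = np.full(ref.size, np.nan)

    cand = []
    for i, r in enumerate(ref):
        d = np.abs(sample.rts - r)
        for j in np.nonzero(d <= window)[0]:
            cand.append((float(d[j]), float(sample.rts[j]), i, int(j)))
    cand.sort()

    used_sample: set[int] = set()
    assigned: set[int] = set()
    for d, _, i, j in cand:
        if i in assigned or j in used_sample:
            continue
        out[i] = sample.areas[j]
        dev[i] = sample.rts[j] - ref[i]
        assigned.add(i)
        used_sample.add(j)

    report.rows.append(
        {
            "sample_id": sample.sample_id,
            "matched": int(len(assigned)),
            "missing": int(ref.size - len(assigned)),
            "max_abs_rt_dev": float(np.nanmax(np.abs(dev))) if assigned else np.nan,
        }
    )
    return out


def build_reference_rts(
    samples: Sequence[PeakList],
    window: float = DEFAULT_WINDOW_MIN,
    anchor: int = 0,
) -> np.ndarray:
    """Robust reference retention times from replicate/sample peak lists.

    The anchor sample's rts seed an initial match of every sample; the
    reference is then the per-peak median of matched rts, followed by one
    re-matching pass against that median grid.
    """
    if not samples:
        raise ValueError("need at least one sample")
    anchor_rts = np.sort(samples[anchor].rts)
    matched = _collect_matched_rts(anchor_rts, samples, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(matched, axis=0)
    med = np.where(np.isfinite(med), med, anchor_rts)
    med = np.maximum.accumulate(med)  # keep monotone if medians cross
    # strictly increasing guard for degenerate inputs
    eps = 1e-9
    for j in range(1, med.size):
        if med[j] <= med[j - 1]:
            med[j] = med[j - 1] + eps
    return med


def _collect_matched_rts(ref, samples, window):
    rows = []
    for s in samples:
        rep = MatchReport()
        out = np.full(len(ref), np.nan)
        cand = []
        for i, r in enumerate(ref):
            d = np.abs(s.rts - r)
            for j in np.nonzero(d <= window)[0]:
                cand.append((float(d[j]), float(s.rts[j]), i, int(j)))
        cand.sort()
        used, assigned = set(), set()
        for d, rt, i, j in cand:
            if i in assigned or j in used:
                continue
            out[i] = rt
            assigned.add(i)
            used.add(j)
        rows.append(out)
    return np.asarray(rows)


def match_samples(
    reference_rts: Sequence[float],
    samples: Sequence[PeakList],
    window: float = DEFAULT_WINDOW_MIN,
) -> tuple[PeakMatrix, MatchReport]:
    """Match every sample against the reference grid."""
    report = MatchReport()
    ref = _check_reference(reference_rts, window, report)
    rows = [match_peaks(ref, s, window=window, report=report) for s in samples]
    pm = PeakMatrix([s.sample_id for s in samples], ref, np.asarray(rows))
    return pm, report


def apply_area_floor(matrix: PeakMatrix, floor: float = DEFAULT_AREA_FLOOR) -> PeakMatrix:
    """Replace missing or zero areas by a small positive floor.

    Mirrors the convention of setting undetected peak areas to 0.01 so
    every characteristic peak enters the composition with a tiny,
    non-informative value instead of a hard zero.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = matrix.copy()
    mask = ~np.isfinite(out.areas) | (out.areas == 0)
    out.areas[mask] = floor
    out.floor_value = floor
    out.floored_count = int(mask.sum())
    return out


def normalize_rows(
    matrix: PeakMatrix,
    denominator: Literal["characteristic_total", "supplied_total"] = "characteristic_total",
    supplied_totals: Sequence[float] | None = None,
) -> PeakMatrix:
    """Divide each sample row by its total peak area.

    ``characteristic_total`` uses the row sum over the characteristic
    peaks (rows then sum to exactly 1); ``supplied_total`` divides by a
    caller-provided total (e.g. the full-chromatogram area, of which the
    characteristic peaks are typically >90%).
    """
    out = matrix.copy()
    if denominator == "characteristic_total":
        denom = out.areas.sum(axis=1)
    elif denominator == "supplied_total":
        if supplied_totals is None:
            raise ValueError("supplied_totals required for denominator='supplied_total'")
        denom = np.asarray(supplied_totals, float)
        if denom.size != len(out.sample_ids):
            raise ValueError("supplied_totals length must equal number of samples")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    bad = np.nonzero(~(denom > 0))[0]
    if bad.size:
        names = ", ".join(out.sample_ids[i] for i in bad)
        raise ValueError(f"nonpositive normalization denominator for sample(s): {names}")
    out.areas = out.areas / denom[:, None]
    out.normalized = True
    return out


def compute_rsd(
    replicate_matrices: Sequence[PeakMatrix],
    threshold_pct: float = 5.0,
) -> pd.DataFrame:
    """Per-peak relative standard deviation (%) across replicate runs.

    RSD_j = 100 * sd_j / mean_j with the n-1 sample standard deviation.
    The pass flag applies the precision rule RSD < threshold (default
    5%); a zero-mean peak has undefined RSD and fails with NaN.
    """
    if len(replicate_matrices) < 2:
        raise ValueError("need at least 2 replicates")
    shapes = {m.areas.shape for m in replicate_matrices}
    if len(shapes) != 1:
        raise ValueError("replicate matrices must share a shape")
    stack = np.stack([m.areas for m in replicate_matrices])  # (rep, sample, peak)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_rsd = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    # worst case over samples: precision must hold for every extract
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rsd = np.nanmax(cell_rsd, axis=0)
    return pd.DataFrame(
        {
            "peak": [f"P{j + 1}" for j in range(rsd.size)],
            "rsd_pct": rsd,
            "passes": np.where(np.isfinite(rsd), rsd < threshold_pct, False),
        }
    )


class FingerprintMatcher(TransformerMixin, BaseEstimator):
    """Peak-table -> normalized characteristic-peak matrix transformer.

    Parameters
    ----------
    window : retention-time matching window in minutes.
    floor : area assigned to undetected peaks before normalization.
    normalize : whether to row-normalize to the characteristic total.
    reference_rts : fix the reference grid; if None, ``fit`` derives it
        from the training peak lists (anchor pass + per-peak median).

    Attributes
    ----------
    reference_rts_ : the reference retention-time grid used.
    match_report_ : :class:`MatchReport` from the last ``transform``.
    """

    def __init__(self, window: float = DEFAULT_WINDOW_MIN, floor: float = DEFAULT_AREA_FLOOR,
                 normalize: bool = True, reference_rts=None):
        self.window = window
        self.floor = floor
        self.normalize = normalize
        self.reference_rts = reference_rts

    def fit(self, X: Sequence[PeakList], y=None):
        if self.reference_rts is not None:
            self.reference_rts_ = np.asarray(self.reference_rts, float)
        else:
            self.reference_rts_ = build_reference_rts(list(X), window=self.window)
        return self

    def transform(self, X: Sequence[PeakList]) -> PeakMatrix:
        pm, report = match_samples(self.reference_rts_, list(X), window=self.window)
        pm = apply_area_floor(pm, self.floor)
        if self.normalize:
            pm = normalize_rows(pm)
        self.match_report_ = report
        return pm


# ---------------------------------------------------------------------------
# delimited-text IO: long format sample_id, rt_min, area

def read_peak_tables(path: str | Path, sep: str = "\t") -> list[PeakList]:
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "rt_min", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak table must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        out.append(PeakList(str(sid), grp["rt_min"].to_numpy(float), grp["area"].to_numpy(float)))
    return out


def write_peak_tables(tables: Iterable[pd.DataFrame | PeakList], path: str | Path, sep: str = "\t") -> None:
    frames = []
    for t in tables:
        if isinstance(t, PeakList):
            frames.append(pd.DataFrame({"sample_id": t.sample_id, "rt_min": t.rts, "area": t.areas}))
        else:
            frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def write_peak_matrix(matrix: PeakMatrix, path: str | Path, sep: str = "\t") -> None:
    df = matrix.to_frame()
    df.columns = [f"{c}_rt{rt:.2f}" for c, rt in zip(df.columns, matrix.reference_rts)]
    df.to_csv(path, sep=sep)
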