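"""Reduction of raw assay measurements to activity endpoints.

Covers the three assay families feeding the screening stage:

* enzyme inhibition (α-glucosidase / α-amylase): absorbance quadruples
  -> inhibition rate (%), dose-response -> IC50 via a four-parameter
  logistic fit;
* broth microdilution: growth indicators over a two-fold dilution
  series -> minimum inhibitory concentration (MIC), with censoring for
  off-scale plates;
* Kirby-Bauer disk diffusion: triplicate zone diameters -> mean ± sd.

Endpoints are assembled into an :class:`ActivityTable` carrying per-
endpoint direction metadata (zone diameters: larger = more active; IC50:
smaller = more active) used downstream for characteristic-sequence
construction and PLS sign handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import four_pl_curve

__all__ = [
    "DILUTION_SERIES_MG_ML",
    "AbsorbanceQuadruple",
    "inhibition_rate",
    "FourPLFit",
    "fit_four_pl",
    "summarize_ic50",
    "MICPlate",
    "MICResult",
    "read_mic",
    "zone_summary",
    "ActivityTable",
    "build_activity_table",
    "format_mean_sd",
]

#: Two-fold dilution series used for the microdilution assay (mg/mL).
#: Shipped as printed, not recomputed: it is a rounded two-fold series.
DILUTION_SERIES_MG_ML: tuple[float, ...] = (3.12, 1.56, 0.78, 0.39, 0.20, 0.10, 0.05, 0.025, 0.0125)


@dataclass(frozen=True)
class AbsorbanceQuadruple:
    """Absorbances of the four enzyme-assay groups.

    asa: enzyme + sample + substrate; asc: sample + buffer;
    aea: buffer + enzyme + substrate; aec: substrate + buffer.
    """

    asa: float
    asc: float
    aea: float
    aec: float


def inhibition_rate(q: AbsorbanceQuadruple) -> float:
    """Percent inhibition: [1 - (Asa - Asc) / (Aea - Aec)] * 100.

    Sample-colour interference can push the rate negative (seen with
    sugar-rich aqueous extracts); negative rates are returned unclamped.
    """
    denom = q.aea - q.aec
    if not denom > 0:
        raise ValueError("enzyme activity control Aea - Aec must be positive (dead enzyme control)")
    return (1.0 - (q.asa - q.asc) / denom) * 100.0


@dataclass
class FourPLFit:
    """Four-parameter logistic fit result (IC50 = curve midpoint)."""

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def _fit_once(c, y, x0, bounds):
    def resid(theta):
        bottom, top, log_ic50, log_hill = theta
        return four_pl_curve(c, bottom, top, math.exp(log_ic50), math.exp(log_hill)) - y

    return least_squares(resid, x0, bounds=bounds, method="trf", max_nfev=2000)


def fit_four_pl(
    concentrations: Sequence[float],
    rates: Sequence[float],
    min_active_rate: float = 10.0,
    min_active_points: int = 3,
) -> FourPLFit:
    """Least-squares 4PL fit of inhibition rate against concentration.

    rate = bottom + (top - bottom) / (1 + (ic50/c)^hill)

    Multi-start: hill initialized over {0.5, 1, 2, 4} and IC50 over the
    observed concentration quantiles, each refined locally (IC50 and hill
    fitted on the log scale to keep them positive).  A fit is flagged
    degenerate when fewer than ``min_active_points`` rates exceed
    ``min_active_rate`` percent — a flat or interference-dominated curve
    has no meaningful midpoint.
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(rates, float)
    if c.shape != y.shape:
        raise ValueError("concentrations and rates must align")
    if np.unique(c[c > 0]).size < 4 or np.any(c <= 0):
        raise ValueError("need at least 4 distinct positive concentrations")
    if not np.all(np.isfinite(y)):
        raise ValueError("rates must be finite")

    degenerate = int(np.sum(y > min_active_rate)) < min_active_points
    if np.allclose(y, y[0]):
        return FourPLFit(float(y[0]), float(y[0]), math.nan, math.nan, 0.0, False, True,
                         "flat response: no IC50")

    span = y.max() - y.min()
    lo = [y.min() - 0.5 * span - 1e-6, y.min() - 0.5 * span - 1e-6,
          math.log(c.min() / 100.0), math.log(1e-2)]
    hi = [y.max() + 0.5 * span + 1e-6, y.max() + 0.5 * span + 1e-6,
          math.log(c.max() * 100.0), math.log(1e2)]
    best = None
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        for q in (0.25, 0.5, 0.75):
            ic0 = float(np.quantile(c, q))
            x0 = [y.min(), y.max(), math.log(ic0), math.log(hill0)]
            try:
                res = _fit_once(c, y, x0, (lo, hi))
            except Exception:
                continue
            if not np.all(np.isfinite(res.fun)):
                continue
            rss = float(res.cost * 2)
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, degenerate,
                         "all starts failed")
    rss, res = best
    bottom, top, log_ic50, log_hill = res.x
    hill = math.exp(log_hill)
    if top < bottom:
        # equivalent parametrization with top > bottom (hill sign flips):
        # B + (T-B)/(1+(ic50/c)^h) == T + (B-T)/(1+(ic50/c)^-h)
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(float(bottom), float(top), math.exp(log_ic50), float(hill),
                     rss, bool(res.success and not degenerate), degenerate, res.message)


def summarize_ic50(fits: Sequence[FourPLFit]) -> dict:
    """Mean ± n-1 sd of converged replicate IC50s.

    Returns a dict with keys mean, sd, n, missing, reason; a panel with
    no converged replicate is reported missing (the table prints "-").
    """
    ok = [f.ic50 for f in fits if f.converged and math.isfinite(f.ic50)]
    if not ok:
        return {"mean": math.nan, "sd": math.nan, "n": 0, "missing": True,
                "reason": "no converged replicate fit"}
    mean = float(np.mean(ok))
    sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else math.nan
    return {"mean": mean, "sd": sd, "n": len(ok), "missing": False, "reason": ""}


@dataclass
class MICPlate:
    """One dilution row of a microdilution plate.

    ``growth[i]`` is True when well i (concentration ``series[i]``) shows
    visible growth after the indicator is added.  Control outcomes:
    positive control must grow, negative control must not.
    """

    series: tuple[float, ...] = DILUTION_SERIES_MG_ML
    growth: Sequence[bool] = ()
    positive_control_growth: bool = True
    negative_control_growth: bool = False

    def __post_init__(self):
        s = np.asarray(self.series, float)
        if not np.all(np.diff(s) < 0):
            raise ValueError("series must be strictly decreasing")
        if len(self.growth) != s.size:
            raise ValueError("growth length must equal series length")


@dataclass(frozen=True)
class MICResult:
    """MIC readout; ``censored`` is '' (observed), '>' (all-growth plate,
    MIC above the series) or '<' (all-clear plate, MIC below)."""

    value: float
    censored: Literal["", ">", "<"] = ""

    def __str__(self) -> str:
        return f"{self.censored}{self.value:g}"


def read_mic(plate: MICPlate) -> MICResult:
    """MIC = lowest concentration at which growth is fully suppressed.

    Requires the canonical monotone pattern (no growth at and above the
    MIC, growth below); a well growing above a clear well indicates
    contamination or a pipetting fault and is rejected.
    """
    if not plate.positive_control_growth:
        raise ValueError("positive control shows no growth: assay invalid")
    if plate.negative_control_growth:
        raise ValueError("negative control shows growth: contamination")
    growth = np.asarray(plate.growth, bool)
    series = np.asarray(plate.series, float)
    if growth.all():
        return MICResult(float(series[0]), ">")
    if not growth.any():
        return MICResult(float(series[-1]), "<")
    # series is decreasing: expect a block of False (clear) then True (growth)
    first_growth = int(np.argmax(growth))
    if growth[first_growth:].all():
        return MICResult(float(series[first_growth - 1]), "")
    bad = [i for i in range(first_growth, growth.size) if not growth[i]]
    raise ValueError(f"non-monotone growth pattern: clear wells {bad} below a growing well")


def zone_summary(diameters_mm: Sequence[float]) -> tuple[float, float]:
    """Mean and n-1 sd of replicate inhibition-zone diameters (mm)."""
    d = np.asarray(diameters_mm, float)
    if d.size < 2:
        raise ValueError("need at least 2 replicate diameters")
    return float(d.mean()), float(d.std(ddof=1))


def format_mean_sd(mean: float, sd: float, digits: int = 2) -> str:
    """Table-style '9.78 ± 0.72' formatting; missing values print '-'."""
    if not math.isfinite(mean):
        return "-"
    if not math.isfinite(sd):
        return f"{mean:.{digits}f}"
    return f"{mean:.{digits}f} ± {sd:.{digits}f}"


@dataclass
class ActivityTable:
    """Per-sample activity endpoints with direction metadata.

    ``values`` is a samples x endpoints frame (NaN = missing endpoint for
    that sample); ``direction`` maps each endpoint to
    'higher_is_active' (zone diameters) or 'lower_is_active' (IC50).
    """

    values: pd.DataFrame
    direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for ep in self.values.columns:
            if ep not in self.direction:
                raise ValueError(f"no direction recorded for endpoint {ep!r}")
            if self.direction[ep] not in ("higher_is_active", "lower_is_active"):
                raise ValueError(f"bad direction for {ep!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def write(self, path, sep: str = "\t") -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.loc["#direction"] = [self.direction[c] for c in out.columns]
        out.to_csv(path, sep=sep)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "ActivityTable":
        df = pd.read_csv(path, sep=sep, index_col="sample_id")
        direction = {c: str(df.loc["#direction", c]) for c in df.columns}
        df = df.drop(index="#direction").astype(float)
        return cls(df, direction)


def build_activity_table(
    endpoints: Mapping[str, Mapping[str, float]],
    direction: Mapping[str, str],
) -> ActivityTable:
    """Assemble endpoint summaries into an :class:`ActivityTable`.

    ``endpoints`` maps endpoint name -> {sample_id: value}; missing
    samples for an endpoint become NaN (masked downstream).  Conflicting
    duplicate entries for a (sample, endpoint) cell raise.
    """
    if not endpoints:
        return ActivityTable(pd.DataFrame(), dict(direction))
    sample_ids: list[str] = []
    for vals in endpoints.values():
        for sid in vals:
            if sid not in sample_ids:
                sample_ids.append(sid)
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"),
                      columns=list(endpoints), dtype=float)
    for ep, vals in endpoints.items():
        for sid, v in vals.items():
            if not pd.isna(df.loc[sid, ep]) and not np.isclose(df.loc[sid, ep], v):
                raise ValueError(f"conflicting duplicate entry for ({sid}, {ep})")
            df.loc[sid, ep] = v
    return ActivityTable(df, {ep: direction[ep] for ep in endpoints})
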