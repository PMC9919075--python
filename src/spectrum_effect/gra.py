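"""Gray relational analysis (Deng's relational degree).

Ranks each chromatographic peak by the similarity of its area profile
across extracts to a bioactivity "characteristic sequence" (zone
diameters, or reciprocal IC50 so that larger always means more active).

For a reference sequence y0 and comparison sequences x_i over samples k,
after normalization the relational coefficient is

    xi_i(k) = (Dmin + rho * Dmax) / (D_i(k) + rho * Dmax),
    D_i(k) = |y0(k) - x_i(k)|,

with Dmin/Dmax the global extremes over all i and k, and the relational
degree r_i is the mean of xi_i(k) over k.  rho is the resolution
coefficient (conventionally 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bioassay import ActivityTable

__all__ = [
    "CharacteristicSequence",
    "GRAResult",
    "build_characteristic_sequences",
    "gra_degree",
    "rank_table",
    "GrayRelationalAnalysis",
]

Normalization = Literal["mean", "initial", "none"]


@dataclass(frozen=True)
class CharacteristicSequence:
    """Bioactivity reference sequence; larger value = more active."""

    endpoint: str
    values: np.ndarray
    sample_ids: tuple[str, ...]
    dropped_samples: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.size < 3:
            raise ValueError("characteristic sequence needs >= 3 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("characteristic sequence must be finite")
        object.__setattr__(self, "values", v)


@dataclass
class GRAResult:
    """Relational degrees and ranks for one endpoint (rank 1 = highest)."""

    endpoint: str
    peak_names: list[str]
    degrees: np.ndarray
    ranks: np.ndarray
    rho: float
    normalization: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peak": self.peak_names, "degree": self.degrees, "rank": self.ranks}
        ).set_index("peak")


def build_characteristic_sequences(activity: ActivityTable) -> list[CharacteristicSequence]:
    """Activity endpoints -> GRA reference sequences.

    Zone-diameter endpoints pass through unchanged; IC50 endpoints are
    transformed to their reciprocal so that every sequence reads "larger
    = more active".  Samples missing an endpoint are dropped from that
    endpoint's sequence (row deletion, recorded in ``dropped_samples``).
    """
    out = []
    for ep in activity.values.columns:
        col = activity.values[ep]
        kept = col.dropna()
        dropped = tuple(col.index[col.isna()])
        vals = kept.to_numpy(float)
        if activity.direction[ep] == "lower_is_active":
            if np.any(vals == 0):
                raise ValueError(f"IC50 of 0 in endpoint {ep!r}: reciprocal undefined")
            vals = 1.0 / vals
        out.append(CharacteristicSequence(ep, vals, tuple(kept.index), dropped))
    return out


def _normalize_sequences(y0: np.ndarray, X: np.ndarray, normalization: Normalization):
    if normalization == "mean":
        my = y0.mean()
        mx = X.mean(axis=0)
        if my == 0 or np.any(mx == 0):
            raise ValueError("mean normalization undefined for zero-mean sequence")
        return y0 / my, X / mx
    if normalization == "initial":
        if y0[0] == 0 or np.any(X[0] == 0):
            raise ValueError("initial-value normalization undefined for zero first element")
        return y0 / y0[0], X / X[0]
    if normalization == "none":
        return y0, X
    raise ValueError(f"unknown normalization {normalization!r}")


def gra_degree(
    y0: CharacteristicSequence | np.ndarray,
    X: np.ndarray | pd.DataFrame,
    rho: float = 0.5,
    normalization: Normalization = "mean",
    peak_names: Sequence[str] | None = None,
    endpoint: str = "",
) -> GRAResult:
    """Deng's relational degree of every peak against one endpoint.

    Steps: (1) normalize the reference and each comparison sequence;
    (2) absolute differences D_i(k); (3) global Dmin/Dmax over all i, k;
    (4) relational coefficients xi_i(k); (5) degree r_i = mean_k xi_i(k).
    Ranks descend by degree, ties broken by ascending peak index.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    if isinstance(y0, CharacteristicSequence):
        endpoint = endpoint or y0.endpoint
        y = np.asarray(y0.values, float)
    else:
        y = np.asarray(y0, float)
    if isinstance(X, pd.DataFrame):
        peak_names = peak_names or list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
    if Xa.shape[0] != y.size:
        raise ValueError("X rows must match the characteristic-sequence samples")
    if peak_names is None:
        peak_names = [f"P{j + 1}" for j in range(Xa.shape[1])]

    yn, Xn = _normalize_sequences(y, Xa, normalization)
    delta = np.abs(Xn - yn[:, None])  # (k, i)
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0:
        warnings.warn("all sequences identical after normalization: degrees all 1")
        degrees = np.ones(Xa.shape[1])
    else:
        xi = (dmin + rho * dmax) / (delta + rho * dmax)
        degrees = xi.mean(axis=0)
    order = np.lexsort((np.arange(degrees.size), -degrees))
    ranks = np.empty(degrees.size, int)
    ranks[order] = np.arange(1, degrees.size + 1)
    return GRAResult(endpoint, list(peak_names), degrees, ranks, rho, normalization)


def rank_table(results: Sequence[GRAResult]) -> pd.DataFrame:
    """Wide table: one row per peak, degree + rank per endpoint."""
    if not results:
        raise ValueError("no GRA results supplied")
    peaks = results[0].peak_names
    for r in results[1:]:
        if r.peak_names != peaks:
            raise ValueError("mismatched peak sets across GRA results")
    data = {}
    for r in results:
        data[f"{r.endpoint}_degree"] = r.degrees
        data[f"{r.endpoint}_rank"] = r.ranks
    return pd.DataFrame(data, index=pd.Index(peaks, name="peak"))


class GrayRelationalAnalysis(BaseEstimator):
    """Estimator wrapper: fit(X, y) computes degrees and ranks.

    Parameters
    ----------
    rho : resolution coefficient in (0, 1], default 0.5.
    normalization : 'mean' (default), 'initial' or 'none'.

    Attributes
    ----------
    degrees_ : relational degree per column of X.
    ranks_ : dense ranks, 1 = most related.
    """

    def __init__(self, rho: float = 0.5, normalization: Normalization = "mean"):
        self.rho = rho
        self.normalization = normalization

    def fit(self, X, y):
        res = gra_degree(np.asarray(y, float), X, rho=self.rho, normalization=self.normalization)
        self.result_ = res
        self.degrees_ = res.degrees
        self.ranks_ = res.ranks
        return self

    def fit_predict(self, X, y):
        return self.fit(X, y).degrees_
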