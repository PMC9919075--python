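"""Consensus screening of putative active components.

Combines, per peak and endpoint, three lines of evidence:

* gray relational evidence — degree above a cut (default 0.8) OR rank
  within the top k (default 6);
* PLS importance — VIP above the conventional cut of 1;
* PLS direction — positive regression coefficient toward activity
  (responses tagged lower-is-active are negated before fitting, so
  "positive" always means "more of the peak, more activity").

A peak's consensus score counts the endpoints on which all three hold;
the peak is called active when the score reaches ``min_endpoints``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioassay import ActivityTable
from .gra import GRAResult, build_characteristic_sequences, gra_degree
from .pls import NIPALSPLS

__all__ = [
    "ScreeningThresholds",
    "ScreeningReport",
    "screen_active",
    "rank_consensus",
    "screen_peak_matrix",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """gra_cut: minimum relational degree; gra_top_k: alternative rank
    cut (OR-combined with gra_cut); vip_cut: VIP importance threshold;
    min_endpoints: endpoints on which all evidence must agree (None =
    every endpoint screened)."""

    gra_cut: float = 0.8
    gra_top_k: int = 6
    vip_cut: float = 1.0
    min_endpoints: int | None = None

    def __post_init__(self):
        if not 0 < self.gra_cut <= 1:
            raise ValueError("gra_cut must be in (0, 1]")
        if self.gra_top_k < 1:
            raise ValueError("gra_top_k must be >= 1")


@dataclass
class ScreeningReport:
    """Per-peak evidence table plus the active calls."""

    table: pd.DataFrame
    endpoints: list[str]
    thresholds: ScreeningThresholds

    @property
    def active_peaks(self) -> list[str]:
        return list(self.table.index[self.table["active"]])

    def summary(self) -> str:
        act = self.active_peaks
        lines = [
            f"Screened {len(self.table)} peaks over {len(self.endpoints)} endpoints "
            f"(GRA degree > {self.thresholds.gra_cut} or rank <= {self.thresholds.gra_top_k}; "
            f"VIP > {self.thresholds.vip_cut}; positive coefficient).",
            f"Active components ({len(act)}): {', '.join(act) if act else 'none'}",
        ]
        return "\n".join(lines)

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep)


def screen_active(
    gra_results: Sequence[GRAResult],
    pls_models: Mapping[str, NIPALSPLS],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> ScreeningReport:
    """Apply the consensus rule to matched GRA and PLS evidence.

    ``gra_results`` and ``pls_models`` must cover the same endpoints and
    the same peak set; models are expected to be fitted on responses
    oriented so that positive coefficients mean activity.
    """
    if not gra_results:
        raise ValueError("no GRA results supplied")
    endpoints = [g.endpoint for g in gra_results]
    missing = [e for e in endpoints if e not in pls_models]
    if missing:
        raise ValueError(f"no PLS model for endpoint(s): {missing}")
    peaks = gra_results[0].peak_names
    p = len(peaks)
    for g in gra_results[1:]:
        if g.peak_names != peaks:
            raise ValueError("mismatched peak sets across GRA results")

    th = thresholds
    min_ep = th.min_endpoints if th.min_endpoints is not None else len(endpoints)
    cols: dict[str, np.ndarray] = {}
    score = np.zeros(p, int)
    for g in gra_results:
        m = pls_models[g.endpoint]
        if m.vip_.size != p:
            raise ValueError(f"PLS model for {g.endpoint!r} has wrong peak count")
        gra_high = (g.degrees > th.gra_cut) | (g.ranks <= th.gra_top_k)
        vip_high = m.vip_ > th.vip_cut
        pos_coef = m.coef_ > 0
        all_three = gra_high & vip_high & pos_coef
        score += all_three.astype(int)
        cols[f"{g.endpoint}_degree"] = g.degrees
        cols[f"{g.endpoint}_rank"] = g.ranks
        cols[f"{g.endpoint}_vip"] = m.vip_
        cols[f"{g.endpoint}_coef"] = m.coef_
        cols[f"{g.endpoint}_gra_high"] = gra_high
        cols[f"{g.endpoint}_vip_high"] = vip_high
        cols[f"{g.endpoint}_positive_coef"] = pos_coef
        cols[f"{g.endpoint}_evidence"] = all_three
    table = pd.DataFrame(cols, index=pd.Index(peaks, name="peak"))
    table["consensus_score"] = score
    table["mean_degree"] = np.mean([g.degrees for g in gra_results], axis=0)
    table["active"] = score >= min_ep
    return ScreeningReport(table, endpoints, th)


def screen_peak_matrix(
    X: pd.DataFrame,
    activity: ActivityTable,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    rho: float = 0.5,
    normalization: str = "mean",
    n_components: int = 2,
    scale: str = "unit_variance",
) -> ScreeningReport:
    """End-to-end screen: normalized peak matrix + activity table -> report.

    Per endpoint: the GRA characteristic sequence (reciprocal IC50 where
    needed) is scored against every peak, and a single-response PLS model
    is fitted with the response oriented so that larger means more active
    (lower-is-active endpoints are negated).  Samples missing an endpoint
    are dropped from that endpoint only.
    """
    seqs = build_characteristic_sequences(activity)
    gra_results = []
    pls_models: dict[str, NIPALSPLS] = {}
    for seq in seqs:
        sub = X.loc[list(seq.sample_ids)]
        gra_results.append(
            gra_degree(seq, sub, rho=rho, normalization=normalization)
        )
        y = activity.values.loc[list(seq.sample_ids), seq.endpoint].to_numpy(float)
        if activity.direction[seq.endpoint] == "lower_is_active":
            y = -y
        a = min(n_components, sub.shape[1], sub.shape[0] - 1)
        pls_models[seq.endpoint] = NIPALSPLS(n_components=a, scale=scale).fit(
            sub.to_numpy(float), y
        )
    return screen_active(gra_results, pls_models, thresholds)


def rank_consensus(report: ScreeningReport) -> list[str]:
    """Peaks ordered by consensus score, then mean GRA degree, then index."""
    t = report.table
    order = sorted(
        range(len(t)),
        key=lambda i: (-t["consensus_score"].iloc[i], -t["mean_degree"].iloc[i], i),
    )
    return [t.index[i] for i in order]
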