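"""Synthetic fixture generators for the screening pipeline.

Every generator is a pure function of its parameters and an integer seed.
A single global seed drives all generators through named substreams
(:func:`stream_rng`), so individual fixtures are reproducible piecewise:
regenerating only the activity column of a dataset yields exactly the
values it had inside the full dataset.

The default study geometry mirrors a typical polarity-fractionation
screen: 10 extracts profiled over 20 characteristic chromatographic
peaks, with a small subset of peaks carrying the bioactivity signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintTruth",
    "make_fingerprint_truth",
    "gen_peak_tables",
    "gen_activity",
    "gen_dose_response",
    "gen_mic_plate",
    "gen_target_data",
    "stream_rng",
    "demo_dataset",
]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for the named substream of a global seed."""
    tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass(frozen=True)
class FingerprintTruth:
    """Ground truth for one synthetic fingerprint study.

    Attributes
    ----------
    reference_rts : retention times (minutes) of the characteristic peaks,
        strictly increasing.
    true_area_matrix : (n_samples, n_peaks) strictly positive peak areas.
    active_index_set : 0-based indices of the peaks that drive activity.
    effect_weights : positive weight per active peak (same order as
        ``active_index_set``).
    """

    n_samples: int
    n_peaks: int
    reference_rts: np.ndarray
    true_area_matrix: np.ndarray
    active_index_set: tuple[int, ...]
    effect_weights: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        rts = np.asarray(self.reference_rts, float)
        if not np.all(np.diff(rts) > 0):
            raise ValueError("reference_rts must be strictly increasing")
        if np.any(np.asarray(self.true_area_matrix) <= 0):
            raise ValueError("true_area_matrix must be strictly positive")
        if any(j < 0 or j >= self.n_peaks for j in self.active_index_set):
            raise ValueError("active_index_set out of range")

    @property
    def normalized_areas(self) -> np.ndarray:
        a = np.asarray(self.true_area_matrix, float)
        return a / a.sum(axis=1, keepdims=True)

    @property
    def latent_potency(self) -> np.ndarray:
        """Noiseless potency: weighted sum of normalized active-peak areas."""
        idx = list(self.active_index_set)
        return self.normalized_areas[:, idx] @ np.asarray(self.effect_weights, float)


def make_fingerprint_truth(
    n_samples: int = 10,
    n_peaks: int = 20,
    n_active: int = 3,
    seed: int = 0,
    rt_range: tuple[float, float] = (2.0, 50.0),
    area_sigma: float = 0.8,
    active_wiggle: float = 0.3,
) -> FingerprintTruth:
    """Draw a ground-truth fingerprint study.

    Peak areas are log-normal (median 1, log-sd ``area_sigma``), the usual
    heavy-tailed shape of chromatographic peak areas across fractions of
    differing polarity.  The active peaks are chemically related
    constituents of one class, so their abundances co-vary: each active
    peak's area is a shared class-abundance profile (log-sd
    ``area_sigma``) times an independent log-normal wiggle (log-sd
    ``active_wiggle``).  This co-variation of actives with the latent
    potency is the statistical structure spectrum-effect screening
    assumes.  Effect weights are 1 per active peak.
    """
    rng = stream_rng(seed, "truth")
    lo, hi = rt_range
    rts = np.sort(rng.uniform(lo, hi, size=n_peaks))
    # enforce a minimum gap so a 0.2 min window is unambiguous
    min_gap = 0.6
    for j in range(1, n_peaks):
        if rts[j] - rts[j - 1] < min_gap:
            rts[j] = rts[j - 1] + min_gap
    areas = rng.lognormal(mean=0.0, sigma=area_sigma, size=(n_samples, n_peaks))
    active = tuple(sorted(rng.choice(n_peaks, size=n_active, replace=False).tolist()))
    class_profile = rng.lognormal(mean=0.0, sigma=area_sigma, size=n_samples)
    for j in active:
        areas[:, j] = class_profile * rng.lognormal(0.0, active_wiggle, size=n_samples)
    weights = np.ones(n_active)
    return FingerprintTruth(
        n_samples=n_samples,
        n_peaks=n_peaks,
        reference_rts=rts,
        true_area_matrix=areas,
        active_index_set=active,
        effect_weights=weights,
        seed=seed,
    )


def gen_peak_tables(
    truth: FingerprintTruth,
    rt_jitter_sd: float = 0.05,
    dropout_prob: float = 0.0,
) -> list[pd.DataFrame]:
    """Per-sample peak tables (columns sample_id, rt_min, area).

    Each true peak appears at its reference rt plus Gaussian jitter; each
    peak is independently dropped with ``dropout_prob`` (emulating peaks
    below the detection limit in some extracts).
    """
    if rt_jitter_sd < 0:
        raise ValueError("rt_jitter_sd must be >= 0")
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must be in [0, 1)")
    rng = stream_rng(truth.seed, "peak_tables")
    tables = []
    for s in range(truth.n_samples):
        jitter = rng.normal(0.0, rt_jitter_sd, size=truth.n_peaks) if rt_jitter_sd > 0 else np.zeros(truth.n_peaks)
        keep = rng.uniform(size=truth.n_peaks) >= dropout_prob
        rts = truth.reference_rts + jitter
        df = pd.DataFrame(
            {
                "sample_id": f"S{s + 1}",
                "rt_min": rts[keep],
                "area": truth.true_area_matrix[s, keep],
            }
        )
        tables.append(df.reset_index(drop=True))
    return tables


def gen_activity(
    truth: FingerprintTruth,
    noise_sd: float = 0.0,
    endpoint_kind: Literal["zone", "ic50"] = "zone",
    base: float = 6.0,
    scale: float = 40.0,
    ic50_scale: float = 50.0,
    ic50_offset: float = 0.05,
    stream: str = "activity",
) -> tuple[np.ndarray, np.ndarray]:
    """One activity endpoint driven by the planted active peaks.

    Latent potency ``u_s`` is the weighted sum of normalized active-peak
    areas plus Gaussian noise.  The zone link is affine increasing
    (``base + scale * u``, larger = more active, mm; the default base of
    6 mm is the paper-disk diameter, the floor of a disk-diffusion
    readout); the IC50 link is ``ic50_scale / (u + ic50_offset)``
    (smaller = more active, μg/mL); its reciprocal — the form entering
    gray relational analysis — is linear in the latent potency.

    Returns ``(endpoint values, realized latent potency)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = stream_rng(truth.seed, stream)
    u = truth.latent_potency.copy()
    if noise_sd > 0:
        u = u + rng.normal(0.0, noise_sd, size=truth.n_samples)
    if endpoint_kind == "zone":
        return base + scale * u, u
    if endpoint_kind == "ic50":
        shifted = u + ic50_offset
        if np.any(shifted <= 0):
            raise ValueError("nonpositive potency under the ic50 link (u + offset <= 0)")
        return ic50_scale / shifted, u
    raise ValueError(f"unknown endpoint_kind {endpoint_kind!r}")


def four_pl_curve(c, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic: inhibition rises from bottom to top with dose."""
    c = np.asarray(c, float)
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 100.0,
    concentrations: Sequence[float] = tuple(3.125 * 2**i for i in range(10)),
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-structured 4PL dose-response records (% inhibition).

    The default design is a ten-step two-fold dilution series (3.125 to
    1600, spanning both response plateaus around a mid-range IC50) run in
    triplicate — the usual 96-well enzyme-inhibition layout.
    """
    conc = np.asarray(concentrations, float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not top > bottom:
        raise ValueError("top must exceed bottom")
    rng = stream_rng(seed, "dose_response")
    rows = []
    for r in range(replicates):
        y = four_pl_curve(conc, bottom, top, ic50, hill)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=conc.size)
        rows.append(pd.DataFrame({"concentration": conc, "replicate": r + 1, "inhibition_pct": y}))
    return pd.concat(rows, ignore_index=True)


def gen_mic_plate(true_mic: float, series: Sequence[float]) -> list[bool]:
    """Growth indicators for a two-fold dilution row.

    ``True`` means visible growth.  Wells at concentration >= true MIC are
    clear; a true MIC above the series maximum gives an all-growth plate,
    below the minimum an all-clear plate (both legal; the reader censors).
    """
    series = np.asarray(series, float)
    if not np.all(np.diff(series) < 0):
        raise ValueError("series must be strictly decreasing")
    return [bool(c < true_mic) for c in series]


def gen_target_data(
    seed: int,
    universe_size: int = 200,
    n_terms: int = 25,
    planted_term_size: int = 15,
    study_size: int = 20,
    planted_overlap: int = 12,
    term_size_range: tuple[int, int] = (8, 25),
) -> tuple[set[str], dict[str, set[str]], set[str]]:
    """Annotation universe with one planted enriched term.

    Returns ``(universe, term -> member set, study set)``.  The planted
    term (``T000``) shares exactly ``planted_overlap`` members with the
    study set; the remaining terms are uniform random draws from the
    universe, so under the null they overlap the study set only by chance.
    """
    if planted_overlap > min(planted_term_size, study_size):
        raise ValueError("planted_overlap exceeds term or study size")
    if max(planted_term_size, study_size, *term_size_range) > universe_size:
        raise ValueError("counts exceed universe_size")
    rng = stream_rng(seed, "target_data")
    universe = [f"G{i:04d}" for i in range(universe_size)]
    study = set(rng.choice(universe, size=study_size, replace=False).tolist())
    non_study = sorted(set(universe) - study)
    planted = set(rng.choice(sorted(study), size=planted_overlap, replace=False).tolist())
    planted |= set(
        rng.choice(non_study, size=planted_term_size - planted_overlap, replace=False).tolist()
    )
    terms: dict[str, set[str]] = {"T000": planted}
    lo, hi = term_size_range
    for t in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"T{t:03d}"] = set(rng.choice(universe, size=size, replace=False).tolist())
    return set(universe), terms, study


def make_screening_study(
    seed: int,
    n_samples: int = 10,
    n_peaks: int = 20,
    n_active: int = 3,
    noise_frac: float = 0.1,
):
    """Complete synthetic screening study for one seed.

    Returns ``(truth, X, activity)``: the ground truth, the row-normalized
    peak matrix as a samples x peaks DataFrame, and an ActivityTable with
    one disk-diffusion endpoint (zone_mm) and two enzyme-inhibition IC50
    endpoints.  ``noise_frac`` sets the activity noise as a fraction of
    the latent-potency standard deviation (independent per endpoint).
    """
    from .bioassay import ActivityTable  # lazy: bioassay imports this module

    truth = make_fingerprint_truth(n_samples=n_samples, n_peaks=n_peaks,
                                   n_active=n_active, seed=seed)
    noise_sd = noise_frac * float(truth.latent_potency.std(ddof=1))
    ids = [f"S{i + 1}" for i in range(n_samples)]
    zone, _ = gen_activity(truth, noise_sd=noise_sd, endpoint_kind="zone",
                           stream="endpoint-zone")
    am, _ = gen_activity(truth, noise_sd=noise_sd, endpoint_kind="ic50",
                         stream="endpoint-amylase")
    gl, _ = gen_activity(truth, noise_sd=noise_sd, endpoint_kind="ic50",
                         stream="endpoint-glucosidase")
    values = pd.DataFrame(
        {"zone_mm": zone, "amylase_ic50": am, "glucosidase_ic50": gl},
        index=pd.Index(ids, name="sample_id"),
    )
    direction = {"zone_mm": "higher_is_active", "amylase_ic50": "lower_is_active",
                 "glucosidase_ic50": "lower_is_active"}
    X = pd.DataFrame(truth.normalized_areas, index=ids,
                     columns=[f"P{j + 1}" for j in range(n_peaks)])
    return truth, X, ActivityTable(values, direction)


def demo_dataset(seed: int, outdir: str | Path, noise_sd: float = 0.01) -> dict[str, Path]:
    """Write a complete delimited-text demo dataset and return its paths."""
    from .fingerprint import write_peak_tables

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_fingerprint_truth(seed=seed)
    tables = gen_peak_tables(truth, rt_jitter_sd=0.05, dropout_prob=0.05)
    paths = {"peaks": out / "peak_tables.tsv"}
    write_peak_tables(tables, paths["peaks"])

    sample_ids = [f"S{i + 1}" for i in range(truth.n_samples)]
    zone, _ = gen_activity(truth, noise_sd=noise_sd, endpoint_kind="zone", stream="zone-demo")
    ic50, _ = gen_activity(truth, noise_sd=noise_sd, endpoint_kind="ic50", stream="ic50-demo")
    act = pd.DataFrame({"sample_id": sample_ids, "zone_mm": zone, "ic50_ug_ml": ic50})
    paths["activity"] = out / "activity.tsv"
    act.to_csv(paths["activity"], sep="\t", index=False)

    ref = pd.DataFrame({"peak": [f"P{j + 1}" for j in range(truth.n_peaks)], "rt_min": truth.reference_rts})
    paths["reference"] = out / "reference_rts.tsv"
    ref.to_csv(paths["reference"], sep="\t", index=False)
    truth_df = pd.DataFrame(
        {"active_peak": [f"P{j + 1}" for j in truth.active_index_set], "weight": truth.effect_weights}
    )
    paths["truth"] = out / "planted_actives.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
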