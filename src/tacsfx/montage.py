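"""Group-level electric-field montage evaluation for tES planning.

Given per-subject values of the normal electric-field component averaged
over the hand-knob ROI (precentral gyrus), this module computes per-montage
group statistics — mean, SD, relative standard deviation (RSD = 100·SD/mean)
— and ranks the candidate montages. The planning criterion is twofold: the
field on target should be high (efficacy) and its between-subject
variability low (a one-for-all montage that works without individual head
models). Because no single montage need win both, the selection rule is an
explicit composite: among montages whose group mean reaches at least a
configurable fraction (default 90%) of the best mean, pick the one with the
smallest RSD; ties break lexicographically by label. The full ranked table
is always returned so the rule is auditable.

Stimulation dose helpers (electrode area, current density) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import InputError

__all__ = [
    "MontageGroupStats",
    "roi_mean",
    "group_stats",
    "rank_montages",
    "montage_table",
    "electrode_area_cm2",
    "current_density_ma_per_cm2",
]


@dataclass
class MontageGroupStats:
    montage: str
    group_mean: float  # mV/m
    group_sd: float  # mV/m, sample (n−1) SD
    rsd: float  # percent
    min: float
    max: float
    n_subjects: int


def roi_mean(values, weights=None) -> float:
    """Weighted arithmetic mean of per-element field values over an ROI.

    ``weights`` are element areas or volumes; uniform when omitted.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("empty ROI")
    if weights is None:
        return float(v.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != v.shape:
        raise InputError("values and weights must have equal length")
    if np.any(w <= 0):
        raise InputError("weights must be positive")
    return float(np.sum(w * v) / np.sum(w))


def group_stats(subject_means, montage: str = "") -> MontageGroupStats:
    """Group mean, sample SD, RSD and range of per-subject ROI means."""
    x = np.asarray(subject_means, dtype=float)
    if x.size < 2:
        raise InputError("group statistics need n >= 2 subjects")
    mean = float(x.mean())
    if mean <= 0:
        raise InputError(f"group mean {mean} <= 0: RSD undefined")
    sd = float(x.std(ddof=1))
    return MontageGroupStats(
        montage=montage,
        group_mean=mean,
        group_sd=sd,
        rsd=100.0 * sd / mean,
        min=float(x.min()),
        max=float(x.max()),
        n_subjects=x.size,
    )


def rank_montages(
    stats: list[MontageGroupStats], mean_filter: float = 0.9
) -> tuple[list[MontageGroupStats], MontageGroupStats]:
    """Rank montages by group mean and select the planning montage.

    Returns ``(ranked, selected)``: montages sorted by group mean
    (descending, label as tie-break), and the selected montage — minimal RSD
    among those whose mean is at least ``mean_filter`` × the best mean.
    """
    if not stats:
        raise InputError("no montages to rank")
    ranked = sorted(stats, key=lambda s: (-s.group_mean, s.montage))
    threshold = mean_filter * ranked[0].group_mean
    eligible = [s for s in ranked if s.group_mean >= threshold]
    selected = min(eligible, key=lambda s: (s.rsd, s.montage))
    return ranked, selected


def montage_table(
    frame: pd.DataFrame, mean_filter: float = 0.9, unit: str = "mvpm"
) -> tuple[pd.DataFrame, str]:
    """Group-level montage table from a long subject × montage field table.

    ``frame`` needs columns ``subject, montage, efield_mvpm`` (precomputed
    ROI means) or ``subject, montage, value_mvpm, weight`` (per-element
    values, averaged here). ``unit="vpm"`` converts V/m input to mV/m.
    Returns the ranked summary table and the selected montage label.
    """
    frame = frame.copy()
    if "efield_mvpm" not in frame.columns:
        if not {"value_mvpm", "weight"}.issubset(frame.columns):
            raise InputError(
                "need either an efield_mvpm column or value_mvpm + weight"
            )
        frame = (
            frame.groupby(["subject", "montage"], observed=True)
            .apply(
                lambda g: roi_mean(g["value_mvpm"], g["weight"]),
                include_groups=False,
            )
            .rename("efield_mvpm")
            .reset_index()
        )
    if unit == "vpm":
        frame["efield_mvpm"] = frame["efield_mvpm"] * 1000.0
    elif unit != "mvpm":
        raise InputError(f"unknown unit {unit!r}")
    stats = [
        group_stats(g["efield_mvpm"].to_numpy(), montage=str(m))
        for m, g in frame.groupby("montage", observed=True)
    ]
    ranked, selected = rank_montages(stats, mean_filter=mean_filter)
    table = pd.DataFrame(
        {
            "montage": [s.montage for s in ranked],
            "group_mean_mvpm": [s.group_mean for s in ranked],
            "group_sd_mvpm": [s.group_sd for s in ranked],
            "rsd_pct": [s.rsd for s in ranked],
            "min": [s.min for s in ranked],
            "max": [s.max for s in ranked],
            "n": [s.n_subjects for s in ranked],
        }
    )
    return table, selected.montage


# ---------------------------------------------------------------------------
# stimulation dose arithmetic
# ---------------------------------------------------------------------------


def electrode_area_cm2(side_cm: float = 1.8) -> float:
    """Area of a square rubber electrode (default 1.8 × 1.8 cm → 3.24 cm²)."""
    if side_cm <= 0:
        raise InputError("side must be positive")
    return side_cm * side_cm


def current_density_ma_per_cm2(
    amplitude_pp_ma: float = 0.6, side_cm: float = 1.8
) -> float:
    """Single-phase current density under one electrode, mA/cm².

    The stimulator amplitude is peak-to-peak, so the single-phase amplitude
    is half of it; dividing by the electrode area gives the density
    (0.6 mA pp over 3.24 cm² → 0.093 mA/cm²).
    """
    if amplitude_pp_ma < 0:
        raise InputError("amplitude must be nonnegative")
    return (amplitude_pp_ma / 2.0) / electrode_area_cm2(side_cm)
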