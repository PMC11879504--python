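"""Visual acuity / contrast sensitivity thresholds and age-normed comparison.

Acuity (VA) is the Landolt-C gap threshold in arc minutes, contrast
sensitivity (CS) the percent-contrast threshold, each measured separately
for positive (white-on-gray) and negative (black-on-gray) optotype
polarity.  Measured VA is compared against an age-normed median table;
the package ships only a synthetic uniform stub of that table (cohort-mean
median/UNL values applied to every age band) — real norms are supplied as
CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staircase import ThresholdEstimate

# Instrument range of best-corrected VA for this optotype, in arcmin.
BCVA_RANGE_ARCMIN = (0.5, 1.25)


def weber_contrast(target_luminance: float, background_luminance: float) -> float:
    """Weber contrast in percent: 100 * (L_target - L_bg) / L_bg.

    Negative-polarity (dark) optotypes are bounded below at -100% because
    luminance cannot go below zero; positive polarity is unbounded above.
    """
    if background_luminance <= 0:
        raise ValueError("background luminance must be positive")
    if target_luminance < 0:
        raise ValueError("target luminance cannot be negative")
    return 100.0 * (target_luminance - background_luminance) / background_luminance


@dataclass(frozen=True)
class NormTable:
    """Age-banded normed VA medians and upper normed limits (UNL), arcmin."""

    bands: tuple  # ((age_min, age_max, polarity, median, unl), ...)

    def __post_init__(self) -> None:
        for pol in ("pos", "neg"):
            rows = sorted(b for b in self.bands if b[2] == pol)
            for (a0, a1, _, med, unl) in rows:
                if a1 <= a0:
                    raise ValueError(f"empty age band ({a0}, {a1})")
                if unl < med:
                    raise ValueError("UNL must be >= median in every band")
            for prev, cur in zip(rows, rows[1:]):
                if cur[0] < prev[1]:
                    raise ValueError("age bands overlap")

    def lookup(self, age_years: float, polarity: str) -> tuple[float, float]:
        for a0, a1, pol, med, unl in self.bands:
            if pol == polarity and a0 <= age_years < a1:
                return med, unl
        raise ValueError(
            f"age {age_years} outside the norm table range for polarity {polarity!r}"
        )

    @classmethod
    def from_csv(cls, path) -> "NormTable":
        df = pd.read_csv(path)
        cols = ["age_min", "age_max", "polarity", "median_arcmin", "unl_arcmin"]
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"norm table CSV missing columns: {sorted(missing)}")
        return cls(tuple(df[cols].itertuples(index=False, name=None)))

    @classmethod
    def default_stub(cls) -> "NormTable":
        """Synthetic stand-in: cohort-mean normed median/UNL applied uniformly
        across ages 18-80.  Not normative; supply real norms via CSV."""
        return cls(
            (
                (18.0, 80.0, "pos", 0.91, 1.52),
                (18.0, 80.0, "neg", 0.84, 1.43),
            )
        )


def normed_median_diff(
    va_arcmin: float, age_years: float, polarity: str, norm_table: NormTable
) -> tuple[float, bool]:
    """Signed difference measured VA - age-normed median (positive = worse),
    plus a flag for exceeding the upper normed limit (strict >; a value
    exactly at the UNL is within limit)."""
    med, unl = norm_table.lookup(age_years, polarity)
    return float(va_arcmin - med), bool(va_arcmin > unl)


@dataclass(frozen=True)
class VisionThresholds:
    va_pos_arcmin: float | None = None
    va_neg_arcmin: float | None = None
    cs_pos_pct: float | None = None
    cs_neg_pct: float | None = None
    va_pos_median_diff: float | None = None
    va_neg_median_diff: float | None = None
    va_pos_above_unl: bool = False
    va_neg_above_unl: bool = False
    out_of_instrument_range: tuple = ()


def estimate_vision_thresholds(
    staircase_results: dict,
    age_years: float | None = None,
    norm_table: NormTable | None = None,
    plausibility_margin: float = 3.0,
) -> VisionThresholds:
    """Assemble per-participant vision thresholds from completed staircases.

    ``staircase_results`` maps ("va"|"cs", "pos"|"neg") to a
    :class:`ThresholdEstimate`; missing runs yield missing fields, not
    errors.  VA values outside ``plausibility_margin`` times the instrument
    BCVA range are kept but flagged.
    """
    def get(task, pol):
        est = staircase_results.get((task, pol))
        if est is None:
            return None
        if isinstance(est, ThresholdEstimate):
            return float(est.threshold)
        return float(est)

    va_pos, va_neg = get("va", "pos"), get("va", "neg")
    cs_pos, cs_neg = get("cs", "pos"), get("cs", "neg")

    flagged = []
    hi = BCVA_RANGE_ARCMIN[1] * plausibility_margin
    lo = BCVA_RANGE_ARCMIN[0] / plausibility_margin
    for name, va in (("va_pos", va_pos), ("va_neg", va_neg)):
        if va is not None and not lo <= va <= hi:
            flagged.append(name)

    diffs = {"pos": (None, False), "neg": (None, False)}
    if age_years is not None:
        table = norm_table or NormTable.default_stub()
        if va_pos is not None:
            diffs["pos"] = normed_median_diff(va_pos, age_years, "pos", table)
        if va_neg is not None:
            diffs["neg"] = normed_median_diff(va_neg, age_years, "neg", table)

    return VisionThresholds(
        va_pos_arcmin=va_pos,
        va_neg_arcmin=va_neg,
        cs_pos_pct=cs_pos,
        cs_neg_pct=cs_neg,
        va_pos_median_diff=diffs["pos"][0],
        va_neg_median_diff=diffs["neg"][0],
        va_pos_above_unl=diffs["pos"][1],
        va_neg_above_unl=diffs["neg"][1],
        out_of_instrument_range=tuple(flagged),
    )
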