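"""Closed-form biochemical assay metrics.

TR-FRET proximity curves (520/490 nm emission ratio, with hook-peak
localization for ternary-complex titrations) and covalent labeling
efficiency from deconvoluted intact-mass peak heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ValidationError

__all__ = [
    "fret_ratio",
    "HookPeak",
    "hook_peak",
    "DeconvolutedPeaks",
    "labeling_efficiency",
]

DEFAULT_ADDUCT_TOLERANCE_DA = 2.0


def fret_ratio(em520: float, em490: float) -> float:
    """TR-FRET signal: 520 nm acceptor emission over 490 nm donor emission."""
    if em490 <= 0:
        raise ValidationError("490 nm (donor) emission must be positive")
    if em520 < 0:
        raise ValidationError("520 nm emission must be nonnegative")
    return em520 / em490


@dataclass
class HookPeak:
    """Location of the maximum of a dose-dependent ternary-complex curve.

    ``no_hook`` is set when the maximum sits at the highest dose, i.e. the
    curve never turns over within the tested range.
    """

    concentration: float
    ratio: float
    no_hook: bool


def hook_peak(concentrations, ratios, smooth: bool = True,
              span: float = 0.75) -> HookPeak:
    """Locate the hook peak of a TR-FRET titration.

    With ``smooth`` (and at least 5 points) the curve is LOESS-smoothed on
    log10 concentration before taking the argmax over the input doses;
    otherwise the raw argmax is used.  Concentrations must be strictly
    increasing and positive.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("concentrations and ratios differ in length")
    if x.size < 3:
        raise ValidationError("need at least 3 points to locate a hook peak")
    if (np.diff(x) <= 0).any():
        raise ValidationError("concentrations must be strictly increasing")
    if (x <= 0).any():
        raise ValidationError("concentrations must be positive")
    values = y
    if smooth and x.size >= 5:
        lx = np.log10(x)
        fit = lowess(y, lx, frac=span, it=0, return_sorted=True)
        values = np.interp(lx, fit[:, 0], fit[:, 1])
    idx = int(np.argmax(values))
    return HookPeak(float(x[idx]), float(values[idx]), idx == x.size - 1)


@dataclass
class DeconvolutedPeaks:
    """Zero-charge mass peaks: ``(mass_da, height, label)`` triples.

    ``label`` is ``"unlabeled"``, ``"labeled"`` or ``"other"``; the labeled
    species may instead be identified by ``expected_adduct_mass``.
    """

    species: list[tuple[float, float, str]]
    expected_adduct_mass: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.species,
                            columns=["mass_da", "height", "label"])


def labeling_efficiency(peaks, expected_adduct_mass: float | None = None,
                        tolerance: float = DEFAULT_ADDUCT_TOLERANCE_DA) -> float:
    """Covalent labeling efficiency in percent from deconvoluted peak heights.

    ``100 * labeled / (labeled + unlabeled)``.  Exactly one ``unlabeled``
    peak is required.  The labeled peak is taken from an explicit
    ``labeled`` row (checked against the expected adduct mass when one is
    given) or, failing that, identified among the remaining peaks as the
    unique one with ``|mass - unlabeled_mass - expected_adduct_mass| <=
    tolerance``; zero or several candidates are an error.
    """
    if isinstance(peaks, DeconvolutedPeaks):
        if expected_adduct_mass is None:
            expected_adduct_mass = peaks.expected_adduct_mass
        df = peaks.to_frame()
    elif isinstance(peaks, pd.DataFrame):
        df = peaks.copy()
    else:
        df = pd.DataFrame(list(peaks), columns=["mass_da", "height", "label"])
    for col in ("mass_da", "height"):
        if col not in df.columns:
            raise ValidationError(f"peak table missing column {col!r}")
    if "label" not in df.columns:
        df["label"] = "other"
    df["label"] = df["label"].fillna("other")
    if (df["height"] < 0).any():
        raise ValidationError("peak heights must be nonnegative")

    unlab = df[df["label"] == "unlabeled"]
    if len(unlab) != 1:
        raise ValidationError(
            f"exactly one 'unlabeled' peak required, found {len(unlab)}"
        )
    mass_u = float(unlab["mass_da"].iloc[0])
    height_u = float(unlab["height"].iloc[0])

    lab = df[df["label"] == "labeled"]
    if len(lab) > 1:
        raise ValidationError(f"multiple 'labeled' peaks: "
                              f"{lab['mass_da'].tolist()}")
    if len(lab) == 1:
        mass_l = float(lab["mass_da"].iloc[0])
        height_l = float(lab["height"].iloc[0])
        if expected_adduct_mass is not None:
            delta = mass_l - mass_u - expected_adduct_mass
            if abs(delta) > tolerance:
                raise ValidationError(
                    f"labeled peak mass {mass_l} Da is {delta:+.2f} Da off the "
                    f"expected adduct (+{expected_adduct_mass} Da, "
                    f"tolerance {tolerance} Da)"
                )
    else:
        if expected_adduct_mass is None:
            raise ValidationError(
                "no 'labeled' peak and no expected adduct mass to identify one"
            )
        rest = df[df["label"] != "unlabeled"]
        dev = (rest["mass_da"] - mass_u - expected_adduct_mass).abs()
        cand = rest[dev <= tolerance]
        if len(cand) == 0:
            raise ValidationError(
                f"no peak within {tolerance} Da of the expected labeled mass "
                f"{mass_u + expected_adduct_mass:.1f} Da"
            )
        if len(cand) > 1:
            raise ValidationError(
                f"ambiguous labeled peak, candidates at "
                f"{cand['mass_da'].tolist()} Da"
            )
        mass_l = float(cand["mass_da"].iloc[0])
        height_l = float(cand["height"].iloc[0])
    if height_l + height_u == 0:
        raise ValidationError("labeled and unlabeled peak heights are both zero")
    return (100.0 * height_l) / (height_l + height_u)
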