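"""Seeded generators for sorted-gate screens with known ground truth.

The generators emulate the two screen designs the statistics serve:

* a ubiquitin-proteasome-system-targeted knockout screen (713 genes, 4
  sgRNAs each, 2,852 guides) read out by sorting the top and bottom 5%
  eGFP/mCherry gates in 3 replicates, and
* an alanine-scanning reporter screen (one variant per residue, contiguous
  sub-libraries sequenced separately and concatenated before analysis).

The effect model is deliberately simple and symmetric: a target with
log-scale gate-shift effect ``beta`` multiplies its features' sampling
weight by ``exp(+beta)`` in the stable (numerator) gate and ``exp(-beta)``
in the unstable (denominator) gate, so the expected normalized count ratio
is ``exp(2*beta)`` (up to renormalization, negligible when few targets carry
effects).  In a resistance screen only the drug arm is shifted, by
``exp(beta)``.  Counts are multinomial at fixed depth per sample, optionally
overdispersed through a Dirichlet-multinomial with concentration
``weights / dispersion`` (``dispersion == 0`` recovers the pure
multinomial).  Library abundances default to a normalized lognormal to
mimic the skew of real cloned libraries.

Every sample draws from its own deterministic substream,
``default_rng([seed, stream_index])``, so adding samples never perturbs
earlier ones and identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import alascan as _alascan
from .doseresp import four_pl
from .io import (
    CountMatrix,
    GuideLibrary,
    LibraryEntry,
    Sample,
    ScreenDesign,
    ValidationError,
)

__all__ = [
    "SimTruth",
    "make_bison_library",
    "make_alascan_library",
    "simulate_reporter_screen",
    "simulate_resistance_screen",
    "simulate_alascan",
    "simulate_dose_response",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimTruth:
    """Planted effects and generator parameters for one simulated screen."""

    effects: dict[str, float]
    abundance: dict[str, float]
    depth: int = 1_000_000
    dispersion: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        total = float(sum(self.abundance.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"abundance must sum to 1 (got {total!r})")
        if any(v < 0 for v in self.abundance.values()):
            raise ValidationError("abundance proportions must be nonnegative")

    @classmethod
    def for_library(cls, library: GuideLibrary, seed: int = 0,
                    effects: Mapping[str, float] | None = None,
                    abundance_sigma: float = 0.5, depth: int = 1_000_000,
                    dispersion: float = 0.0, n_replicates: int = 3) -> "SimTruth":
        """Lognormal library abundance, zero effects except those given."""
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(library))
        raw /= raw.sum()
        abundance = dict(zip(library.feature_ids, raw))
        eff = {t: 0.0 for t in library.target_ids}
        if effects:
            unknown = [t for t in effects if t not in eff]
            if unknown:
                raise ValidationError(f"effects reference unknown targets: {unknown[:5]}")
            eff.update({t: float(b) for t, b in effects.items()})
        return cls(effects=eff, abundance=abundance, depth=depth,
                   dispersion=dispersion, n_replicates=n_replicates, seed=seed)


def make_bison_library(n_genes: int = 713, guides_per_gene: int = 4,
                       n_control_genes: int = 50) -> GuideLibrary:
    """A UPS-targeted-style knockout library: ``n_genes`` genes (the last
    ``n_control_genes`` of them non-targeting-style controls), a fixed
    number of guides each.  Defaults give 713 genes x 4 = 2,852 guides."""
    if not (0 <= n_control_genes <= n_genes):
        raise ValidationError("n_control_genes must be in [0, n_genes]")
    entries = []
    width = len(str(n_genes))
    for i in range(n_genes):
        is_ctrl = i >= n_genes - n_control_genes
        gene = (f"CTRL{i - (n_genes - n_control_genes) + 1:0{width}d}" if is_ctrl
                else f"GENE{i + 1:0{width}d}")
        for g in range(guides_per_gene):
            entries.append(LibraryEntry(f"{gene}_sg{g + 1}", gene, None, is_ctrl))
    return GuideLibrary(entries)


def _feature_betas(library: GuideLibrary, effects: Mapping[str, float]) -> np.ndarray:
    for t in library.target_ids:
        if t not in effects:
            raise ValidationError(f"truth.effects has no entry for target {t!r}")
    nonzero_controls = [t for t in library.control_targets if effects.get(t, 0.0) != 0.0]
    if nonzero_controls:
        raise ValidationError(
            f"control targets must have beta = 0: {nonzero_controls[:5]}"
        )
    target_of = library.target_of
    return np.array([effects[target_of[f]] for f in library.feature_ids])


def _draw_counts(rng: np.random.Generator, weights: np.ndarray, depth: int,
                 dispersion: float) -> np.ndarray:
    p = weights / weights.sum()
    if dispersion > 0:
        p = rng.dirichlet(p / dispersion)
    return rng.multinomial(depth, p)


def _simulate_two_arm(truth: SimTruth, library: GuideLibrary, roles: tuple[str, str],
                      mode: str, num_scale: np.ndarray, den_scale: np.ndarray,
                      stream_salt: Sequence[int] = ()) -> tuple[CountMatrix, ScreenDesign]:
    missing = [f for f in library.feature_ids if f not in truth.abundance]
    if missing:
        raise ValidationError(f"truth.abundance missing features: {missing[:5]}")
    abundance = np.array([truth.abundance[f] for f in library.feature_ids])
    samples, columns, pairs = [], [], []
    stream = 0
    for rep in range(1, truth.n_replicates + 1):
        ids = []
        for role, scale_vec in zip(roles, (num_scale, den_scale)):
            sid = f"rep{rep}_{role}"
            rng = np.random.default_rng([truth.seed, *stream_salt, stream])
            columns.append(_draw_counts(rng, abundance * scale_vec, truth.depth,
                                        truth.dispersion))
            samples.append(Sample(sid, rep, role))
            ids.append(sid)
            stream += 1
        pairs.append((rep, ids[0], ids[1]))
    counts = CountMatrix(library.feature_ids, samples, np.column_stack(columns))
    design = ScreenDesign(mode=mode, pairs=pairs, seed=truth.seed)
    return counts, design


def simulate_reporter_screen(truth: SimTruth, library: GuideLibrary
                             ) -> tuple[CountMatrix, ScreenDesign]:
    """Sorted-gate reporter screen: stable and unstable 5% gates per replicate.

    The stable-gate sampling weight of feature g is
    ``abundance_g * exp(+beta_g)`` and the unstable-gate weight
    ``abundance_g * exp(-beta_g)``, renormalized per sample.
    """
    beta = _feature_betas(library, truth.effects)
    return _simulate_two_arm(truth, library, ("stable", "unstable"), "reporter_sort",
                             np.exp(beta), np.exp(-beta))


def simulate_resistance_screen(truth: SimTruth, library: GuideLibrary
                               ) -> tuple[CountMatrix, ScreenDesign]:
    """Resistance screen: beta shifts the drug-treated arm only; the DMSO
    arm samples the unperturbed library abundance."""
    beta = _feature_betas(library, truth.effects)
    return _simulate_two_arm(truth, library, ("drug", "dmso"), "resistance",
                             np.exp(beta), np.ones_like(beta))


# ---------------------------------------------------------------------------
# alanine scan
# ---------------------------------------------------------------------------

def make_alascan_library(positions: Sequence[int] = range(349, 462),
                         n_sublibraries: int = 2, seed: int = 0) -> GuideLibrary:
    """One variant per residue position over a seeded random wild-type
    sequence; alanines are mutated to arginine, everything else to alanine.
    Positions are split into contiguous sub-libraries, earlier blocks larger
    when the split is uneven."""
    positions = list(positions)
    if not positions:
        raise ValidationError("positions must be nonempty")
    if not (1 <= n_sublibraries <= len(positions)):
        raise ValidationError("n_sublibraries must be in [1, n_positions]")
    rng = np.random.default_rng([seed, 104729])  # sequence substream
    wt = rng.choice(list(AMINO_ACIDS), size=len(positions))
    blocks = np.array_split(np.arange(len(positions)), n_sublibraries)
    entries = []
    for b, idx in enumerate(blocks):
        for i in idx:
            sub = "A" if wt[i] != "A" else "R"
            vid = f"{wt[i]}{positions[i]}{sub}"
            entries.append(LibraryEntry(vid, vid, f"sub{b + 1}", False))
    return GuideLibrary(entries)


def simulate_alascan(positions: Sequence[int] = range(349, 462),
                     n_sublibraries: int = 2,
                     effects: Mapping[int | str, float] | None = None,
                     depth: int = 1_000_000, dispersion: float = 0.0,
                     n_replicates: int = 3, seed: int = 0,
                     abundance_sigma: float = 0.5
                     ) -> tuple[CountMatrix, GuideLibrary, ScreenDesign]:
    """Alanine-scanning reporter screen over contiguous sub-libraries.

    Each sub-library is an independently cloned and sequenced pool: its
    abundances are lognormal and renormalized within the sub-library, and
    its counts are drawn at ``depth`` reads per sample from its own
    substream.  The returned matrix is the row-stacked concatenation (use
    :func:`sortscreen.alascan.split_sublibraries` to recover the parts).
    ``effects`` may be keyed by residue position (int) or variant id.
    """
    library = make_alascan_library(positions, n_sublibraries, seed)
    eff = np.zeros(len(library))
    if effects:
        by_pos = {}
        for e in library.entries:
            by_pos[int(e.feature_id[1:-1])] = e.feature_id
        index = {f: i for i, f in enumerate(library.feature_ids)}
        for key, b in effects.items():
            vid = by_pos.get(key) if isinstance(key, int) else key
            if vid not in index:
                raise ValidationError(f"effect key {key!r} matches no variant")
            eff[index[vid]] = float(b)
    sub_order = library.sublibraries
    matrices = []
    feat_index = {f: i for i, f in enumerate(library.feature_ids)}
    for b, sub in enumerate(sub_order):
        feats = [e.feature_id for e in library.entries if e.sublibrary == sub]
        beta = eff[[feat_index[f] for f in feats]]
        rng_ab = np.random.default_rng([seed, 7, b])
        raw = rng_ab.lognormal(0.0, abundance_sigma, size=len(feats))
        truth = SimTruth(effects={f: float(x) for f, x in zip(feats, beta)},
                         abundance=dict(zip(feats, raw / raw.sum())),
                         depth=depth, dispersion=dispersion,
                         n_replicates=n_replicates, seed=seed)
        sub_lib = GuideLibrary([e for e in library.entries if e.sublibrary == sub])
        counts, design = _simulate_two_arm(
            truth, sub_lib, ("stable", "unstable"), "reporter_sort",
            np.exp(beta), np.exp(-beta), stream_salt=(b + 1,))
        matrices.append(counts)
    counts = _alascan.concat_sublibraries(matrices)
    return counts, library, design


# ---------------------------------------------------------------------------
# dose-response curves
# ---------------------------------------------------------------------------

def simulate_dose_response(params: Sequence[float], concentrations: Sequence[float],
                           cv: float = 0.0, seed: int = 0,
                           n_replicates: int = 1):
    """Noisy observations on a four-parameter log-logistic curve.

    ``response = 4PL(conc; a, b, c, d) * (1 + eps)`` with Gaussian ``eps`` of
    mean 0 and standard deviation ``cv`` (a multiplicative coefficient of
    variation).  Returns a DataFrame with columns ``concentration_M``,
    ``response`` and ``replicate``.
    """
    import pandas as pd

    a, b, c, d = (float(v) for v in params)
    if cv < 0:
        raise ValidationError("cv must be nonnegative")
    conc = np.asarray(list(concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        clean = four_pl(conc, a, b, c, d)
        noise = rng.normal(0.0, cv, size=conc.size) if cv > 0 else np.zeros(conc.size)
        rows.append(pd.DataFrame({"concentration_M": conc,
                                  "response": clean * (1.0 + noise),
                                  "replicate": rep}))
    return pd.concat(rows, ignore_index=True)
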