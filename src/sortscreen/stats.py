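"""Five-stage rank-sum enrichment statistics for sorted-gate screens.

The analysis of a pooled FACS-sorted reporter screen (or a growth-based
resistance screen) runs in five stages:

1. **Normalization** — reads per feature are scaled to the total reads of
   each sample (reads per million by default), removing depth differences
   between the sorted gates / treatment arms.
2. **Enrichment ratios** — for every feature and replicate, the ratio of
   normalized reads in the numerator gate (stable, or drug-treated) over
   the denominator gate (unstable, or DMSO).  A symmetric pseudocount keeps
   ratios finite when a feature drops out of one gate.
3. **Ranking** — features are ranked within each replicate by their ratio
   (rank 1 = most enriched by default); ties get average ranks, so each
   replicate's ranks always sum to N(N+1)/2.
4. **Aggregation** — per feature, the median ratio across replicates and
   the sum of ranks across replicates; per target, the median of its
   features' median ratios (the fold change) and the median of its
   features' rank sums (the rank statistic).  Medians of an even number of
   values use the midpoint of the two central order statistics.
5. **Empirical p-values** — the observed target rank statistic is compared
   to a null distribution built by randomly assigning ranks to features
   (independently per replicate), recomputing rank sums, grouping features
   into pseudo-targets of the same size, and taking their medians.  The
   two-sided p-value doubles the smaller of the two +1-corrected tails and
   is therefore bounded below by 2/(M+1) for M null draws.

All stages are deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (
    CountMatrix,
    GuideLibrary,
    ScreenDesign,
    ValidationError,
    validate_screen,
)

__all__ = [
    "normalize_counts",
    "enrichment_ratios",
    "rank_features",
    "compute_feature_stats",
    "aggregate_targets",
    "NullDistribution",
    "build_null",
    "empirical_pvalues",
    "analyze_normalized",
    "analyze_screen",
]

DEFAULT_SCALE = 1e6  # reads per million


def normalize_counts(counts: CountMatrix, scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Scale each sample to a common total (reads per ``scale``).

    Entries are ``raw * scale / sample_total``, so every column sums to
    ``scale`` exactly (up to rounding).  Computed as an exact integer product
    divided by an exact integer total, which makes the result invariant to
    rescaling a sample's raw counts by a constant factor, bit for bit.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    totals = counts.counts.sum(axis=0)
    zero = [s.sample_id for s, t in zip(counts.samples, totals) if t == 0]
    if zero:
        raise ValidationError(f"samples with zero total counts: {zero}")
    norm = (counts.counts.astype(np.float64) * float(scale)) / totals.astype(np.float64)
    return pd.DataFrame(norm, index=pd.Index(counts.features, name="feature_id"),
                        columns=counts.sample_ids)


def enrichment_ratios(normalized: pd.DataFrame, design: ScreenDesign) -> pd.DataFrame:
    """Per-feature, per-replicate (numerator + pc) / (denominator + pc) ratios.

    Returns a DataFrame indexed by feature with one column per replicate.
    """
    pc = design.pseudocount
    out = {}
    for rep, num, den in design.pairs:
        for sid in (num, den):
            if sid not in normalized.columns:
                raise ValidationError(f"design references sample {sid!r} absent "
                                      f"from the normalized matrix")
        den_v = normalized[den].to_numpy() + pc
        if pc == 0 and (den_v == 0).any():
            bad = normalized.index[den_v == 0].tolist()[:10]
            raise ValidationError(
                f"zero denominator counts with pseudocount 0 in replicate {rep} "
                f"for features {bad}; use a positive pseudocount"
            )
        out[rep] = (normalized[num].to_numpy() + pc) / den_v
    return pd.DataFrame(out, index=normalized.index)


def rank_features(ratios: pd.DataFrame, direction: str = "enriched_first") -> pd.DataFrame:
    """Rank features within each replicate; ties receive average ranks.

    ``enriched_first``: rank 1 is the largest ratio.  ``depleted_first``:
    rank 1 is the smallest.
    """
    if direction not in ("enriched_first", "depleted_first"):
        raise ValidationError(f"unknown rank direction {direction!r}")
    arr = ratios.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("NaN enrichment ratios cannot be ranked")
    signed = -arr if direction == "enriched_first" else arr
    ranks = rankdata(signed, method="average", axis=0)
    return pd.DataFrame(ranks, index=ratios.index, columns=ratios.columns)


def compute_feature_stats(ratios: pd.DataFrame, ranks: pd.DataFrame) -> pd.DataFrame:
    """Median ratio across replicates and summed rank per feature."""
    if not ratios.index.equals(ranks.index):
        raise ValidationError("ratio and rank tables index different features")
    return pd.DataFrame(
        {
            "median_ratio": np.median(ratios.to_numpy(), axis=1),
            "rank_sum": ranks.to_numpy().sum(axis=1),
        },
        index=ratios.index,
    )


def aggregate_targets(feature_stats: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Collapse feature statistics to targets by the median.

    fold_change = median over the target's features of their median ratios;
    rank_stat = median over the target's features of their rank sums.
    """
    target_of = library.target_of
    unmapped = [f for f in feature_stats.index if f not in target_of]
    if unmapped:
        raise ValidationError(f"features without a library target: {unmapped[:10]}")
    groups = feature_stats.groupby(
        feature_stats.index.map(target_of.__getitem__), sort=False
    )
    agg = groups.agg(
        fold_change=("median_ratio", "median"),
        rank_stat=("rank_sum", "median"),
        n_features=("rank_sum", "size"),
    )
    present = set(feature_stats.index)
    empty = [t for t in library.target_ids
             if not any(f in present for f in library.features_of(t))]
    if empty:
        raise ValidationError(f"targets with zero features in the data: {empty[:10]}")
    agg.index.name = "target_id"
    return agg.reset_index()


# ---------------------------------------------------------------------------
# empirical null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Simulated target-level rank statistics under random rank assignment."""

    stats: np.ndarray
    n_iterations: int
    features_per_target: int
    seed: int | tuple

    @property
    def size(self) -> int:
        return int(self.stats.size)

    @property
    def p_floor(self) -> float:
        return 2.0 / (self.size + 1)


def build_null(n_features_total: int, replicate_count: int, features_per_target: int,
               n_iterations: int, seed) -> NullDistribution:
    """Simulate the null distribution of the target rank statistic.

    Per iteration: each replicate's ranks ``1..N`` are independently randomly
    permuted over the features, per-feature rank sums are recomputed, the
    features are partitioned into ``floor(N/k)`` disjoint pseudo-targets of
    size ``k``, and each pseudo-target's median rank sum is recorded.  All
    pseudo-targets within an iteration are pooled, enlarging the draw count
    beyond the iteration count at no extra cost.
    """
    n = int(n_features_total)
    r = int(replicate_count)
    k = int(features_per_target)
    iters = int(n_iterations)
    if iters < 1:
        raise ValidationError("n_iterations must be >= 1")
    if not (1 <= k <= n):
        raise ValidationError(f"features_per_target {k} must be in [1, {n}]")
    if r < 1:
        raise ValidationError("replicate_count must be >= 1")
    rng = np.random.default_rng(seed)
    n_t = n // k
    out = np.empty(iters * n_t, dtype=np.float64)
    # chunk iterations to bound the (chunk, r, n) working array at ~50M doubles
    chunk = max(1, int(50_000_000 // max(1, r * n)))
    pos = 0
    done = 0
    while done < iters:
        m = min(chunk, iters - done)
        u = rng.random((m, r, n))
        order = np.argsort(u, axis=-1)
        ranks = np.argsort(order, axis=-1) + 1
        sums = ranks.sum(axis=1, dtype=np.float64)  # (m, n)
        med = np.median(sums[:, : n_t * k].reshape(m, n_t, k), axis=-1)
        out[pos:pos + m * n_t] = med.ravel()
        pos += m * n_t
        done += m
    return NullDistribution(out, iters, k, seed)


def empirical_pvalues(observed, null: NullDistribution) -> np.ndarray:
    """Two-sided empirical p-values with the +1 tail correction.

    ``lower = (#{null <= obs} + 1)/(M + 1)``, ``upper`` symmetric;
    ``p = min(1, 2 * min(lower, upper))``, so ``p`` lies in
    ``[2/(M+1), 1]`` and can never be zero.
    """
    if null.size == 0:
        raise ValidationError("null distribution is empty")
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    s = np.sort(null.stats)
    m = s.size
    lower = (np.searchsorted(s, obs, side="right") + 1) / (m + 1)
    upper = (m - np.searchsorted(s, obs, side="left") + 1) / (m + 1)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def analyze_normalized(normalized: pd.DataFrame, library: GuideLibrary,
                       design: ScreenDesign, exclude_controls: bool = False
                       ) -> pd.DataFrame:
    """Run stages 2-5 on an already normalized matrix.

    Returns one row per target with columns ``target_id``, ``fold_change``,
    ``rank_stat``, ``p_two_sided`` and ``n_features``, ordered by increasing
    rank statistic (ties broken by target id).  Targets with different
    feature counts are compared against separate nulls of matching
    pseudo-target size.
    """
    if exclude_controls:
        drop = library.control_features
        normalized = normalized.loc[[f for f in normalized.index if f not in drop]]
        library = library.subset(normalized.index)
    ratios = enrichment_ratios(normalized, design)
    ranks = rank_features(ratios, design.rank_direction)
    fstats = compute_feature_stats(ratios, ranks)
    agg = aggregate_targets(fstats, library)
    n_total = len(fstats)
    n_reps = len(design.pairs)
    pvals = np.empty(len(agg))
    for k in sorted(agg["n_features"].unique()):
        null = build_null(n_total, n_reps, int(k), design.n_null_iterations,
                          seed=[design.seed, int(k)])
        sel = agg["n_features"].to_numpy() == k
        pvals[sel] = empirical_pvalues(agg.loc[sel, "rank_stat"].to_numpy(), null)
    agg["p_two_sided"] = pvals
    agg = agg[["target_id", "fold_change", "rank_stat", "p_two_sided", "n_features"]]
    return agg.sort_values(["rank_stat", "target_id"], kind="mergesort",
                           ignore_index=True)


def analyze_screen(counts: CountMatrix, library: GuideLibrary, design: ScreenDesign,
                   exclude_controls: bool = False,
                   scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Full pipeline: normalize, ratio, rank, aggregate, empirical p-values.

    Reporter-sort and resistance screens run identically; the design decides
    which sample is the numerator of the enrichment ratio.
    """
    validate_screen(counts, library, design)
    normalized = normalize_counts(counts, scale=scale)
    return analyze_normalized(normalized, library, design,
                              exclude_controls=exclude_controls)
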