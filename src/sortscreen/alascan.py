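"""Alanine-scanning variant of the screen pipeline.

An alanine scan measures one feature per target: every residue in the
scanned window is individually mutated to alanine (alanines to arginine)
and each variant's reads report directly on its residue.  The statistics
are the sgRNA pipeline with target size one — the fold change of a variant
is its own median enrichment ratio across sorting replicates, its rank
statistic its own summed rank — plus two scan-specific steps: sub-libraries
sequenced separately are concatenated before ratios and ranks are computed,
and variant ids are parsed into residue position and substitution for
residue-level reporting.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GuideLibrary, ScreenDesign, ValidationError
from .stats import DEFAULT_SCALE, analyze_normalized, normalize_counts

__all__ = [
    "concat_sublibraries",
    "split_sublibraries",
    "parse_variant_id",
    "analyze_alascan",
    "VARIANT_COLUMNS",
]

VARIANT_COLUMNS = ["variant_id", "position", "substitution",
                   "fold_change", "rank_stat", "p_two_sided"]

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_SUBSTITUTION_NAMES = {"A": "Ala", "R": "Arg"}


def concat_sublibraries(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Row-stack per-sub-library count matrices of the same sorting replicates.

    All inputs must share the identical sample structure (ids, replicates,
    roles); feature sets must be disjoint.  Per-sample totals are recomputed
    on the concatenated matrix when it is later normalized, so sub-library
    sequencing depth differences are absorbed jointly.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("no count matrices to concatenate")
    ref = matrices[0]
    ref_struct = {(s.sample_id, s.replicate, s.role) for s in ref.samples}
    seen: dict[str, int] = {}
    blocks = []
    features: list[str] = []
    for i, cm in enumerate(matrices):
        struct = {(s.sample_id, s.replicate, s.role) for s in cm.samples}
        if struct != ref_struct:
            raise ValidationError(
                f"sub-library {i} sample structure {sorted(struct)} does not "
                f"match the first sub-library {sorted(ref_struct)}"
            )
        overlap = [f for f in cm.features if f in seen]
        if overlap:
            raise ValidationError(
                f"overlapping feature ids across sub-libraries: {overlap[:10]}"
            )
        for f in cm.features:
            seen[f] = i
        # align columns to the first matrix's sample order
        order = [cm.sample_ids.index(sid) for sid in ref.sample_ids]
        blocks.append(cm.counts[:, order])
        features.extend(cm.features)
    return CountMatrix(features, ref.samples, np.vstack(blocks))


def split_sublibraries(counts: CountMatrix, library: GuideLibrary
                       ) -> list[CountMatrix]:
    """Inverse of :func:`concat_sublibraries` using the library's labels."""
    out = []
    index = {f: i for i, f in enumerate(counts.features)}
    for sub in library.sublibraries:
        feats = [e.feature_id for e in library.entries if e.sublibrary == sub]
        missing = [f for f in feats if f not in index]
        if missing:
            raise ValidationError(f"sub-library {sub!r} features absent from "
                                  f"counts: {missing[:5]}")
        rows = [index[f] for f in feats]
        out.append(CountMatrix(feats, counts.samples, counts.counts[rows, :]))
    return out


def parse_variant_id(variant_id: str) -> tuple[int, str]:
    """``"H437A" -> (437, "Ala")``; alanine-to-arginine ids map to ``"Arg"``."""
    m = _VARIANT_RE.match(variant_id)
    if not m:
        raise ValidationError(
            f"variant id {variant_id!r} is not of the form <wt><position><sub>"
        )
    sub = m.group(3)
    return int(m.group(2)), _SUBSTITUTION_NAMES.get(sub, sub)


def analyze_alascan(counts: CountMatrix | Sequence[CountMatrix],
                    library: GuideLibrary, design: ScreenDesign,
                    per_sublibrary_normalization: bool = False,
                    scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Residue-level screen analysis with one feature per variant.

    ``counts`` may be the already concatenated matrix or the per-sub-library
    matrices.  By default the matrices are concatenated first and normalized
    on the merged totals; with ``per_sublibrary_normalization=True`` each
    sub-library is normalized to ``scale`` on its own totals before the rows
    are merged (the two readings of "concatenated before calculating the
    ratios and ranks").

    Returns one row per variant: ``variant_id``, ``position``,
    ``substitution``, ``fold_change``, ``rank_stat``, ``p_two_sided``.
    """
    fpt = library.features_per_target()
    not_single = fpt[fpt != 1]
    if len(not_single):
        raise ValidationError(
            f"alanine-scan targets must have exactly one feature; offending "
            f"targets: {not_single.index.tolist()[:5]}"
        )
    if isinstance(counts, CountMatrix):
        normalized = normalize_counts(counts, scale=scale)
    elif per_sublibrary_normalization:
        normalized = pd.concat([normalize_counts(cm, scale=scale)
                                for cm in counts])
    else:
        normalized = normalize_counts(concat_sublibraries(counts), scale=scale)
    extra = [f for f in normalized.index if f not in set(library.feature_ids)]
    if extra:
        raise ValidationError(f"counts contain features not in library: {extra[:5]}")
    res = analyze_normalized(normalized, library, design)
    parsed = [parse_variant_id(v) for v in res["target_id"]]
    res = res.rename(columns={"target_id": "variant_id"})
    res["position"] = [p for p, _ in parsed]
    res["substitution"] = [s for _, s in parsed]
    return res[VARIANT_COLUMNS]


def write_variant_results(results: pd.DataFrame, path) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"variant results missing columns: {missing}")
    results[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)
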