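"""Data model and plain-text I/O for pooled sorted-gate screens.

The pipeline exchanges four small text artifacts:

* a **library map** (TSV): one row per measured feature (sgRNA or alanine
  variant) with its target (gene or residue variant), optional sub-library
  label and a control flag;
* a **count table** (TSV): nonnegative integer read counts, one row per
  feature, one column per sequenced sample;
* a **sample sheet / design** (YAML): which samples exist, their replicate
  index and gate/arm role, and the analysis parameters (pseudocount, null
  iterations, seed, ranking direction);
* a **results table** (TSV): one row per target with fold change, rank
  statistic, empirical two-sided p-value and feature count.

All validation errors raise :class:`ValidationError` with a message naming
the offending records; nothing is silently coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sortscreen")
if not logger.handlers:  # default: structured lines to stderr
    _handler = logging.StreamHandler()
    _handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_handler)
    logger.setLevel(logging.INFO)

#: token for a missing sub-library label in library TSVs
MISSING_SUBLIBRARY = "."

#: (numerator role, denominator role) per screen mode
ROLE_PAIRS = {
    "reporter_sort": ("stable", "unstable"),
    "resistance": ("drug", "dmso"),
}
VALID_ROLES = ("stable", "unstable", "drug", "dmso")
RANK_DIRECTIONS = ("enriched_first", "depleted_first")


class ScreenError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ScreenError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# library map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryEntry:
    """One measured feature and the target it reports on."""

    feature_id: str
    target_id: str
    sublibrary: str | None = None
    is_control: bool = False


class GuideLibrary:
    """Maps features (sgRNAs or variants) to targets (genes or residues).

    Feature ids must be unique across the whole library, including across
    sub-libraries; every target has at least one feature by construction.
    """

    def __init__(self, entries: Iterable[LibraryEntry | tuple]):
        parsed = []
        for e in entries:
            parsed.append(e if isinstance(e, LibraryEntry) else LibraryEntry(*e))
        if not parsed:
            raise ValidationError("library is empty")
        ids = [e.feature_id for e in parsed]
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate feature_id in library: {dup}")
        self.entries: list[LibraryEntry] = parsed
        self._target_of = {e.feature_id: e.target_id for e in parsed}

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, GuideLibrary) and self.entries == other.entries

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    @property
    def target_ids(self) -> list[str]:
        """Targets in order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.target_id, None)
        return list(seen)

    @property
    def target_of(self) -> dict[str, str]:
        return dict(self._target_of)

    @property
    def control_targets(self) -> set[str]:
        return {e.target_id for e in self.entries if e.is_control}

    @property
    def control_features(self) -> set[str]:
        return {e.feature_id for e in self.entries if e.is_control}

    @property
    def sublibraries(self) -> list[str]:
        """Non-missing sub-library labels in order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.sublibrary is not None:
                seen.setdefault(e.sublibrary, None)
        return list(seen)

    def features_per_target(self) -> pd.Series:
        return pd.Series(self._target_of).groupby(pd.Series(self._target_of)).size()

    def features_of(self, target_id: str) -> list[str]:
        return [e.feature_id for e in self.entries if e.target_id == target_id]

    def subset(self, feature_ids: Iterable[str]) -> "GuideLibrary":
        keep = set(feature_ids)
        return GuideLibrary([e for e in self.entries if e.feature_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [e.feature_id for e in self.entries],
                "target_id": [e.target_id for e in self.entries],
                "sublibrary": [
                    MISSING_SUBLIBRARY if e.sublibrary is None else e.sublibrary
                    for e in self.entries
                ],
                "is_control": [e.is_control for e in self.entries],
            }
        )


def read_library(path: str | Path) -> GuideLibrary:
    """Read a library map TSV (columns feature_id, target_id, sublibrary, is_control)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["feature_id", "target_id", "sublibrary", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"library file {path} missing columns: {missing}")
    truthy = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
    entries = []
    for row in df.itertuples(index=False):
        flag = truthy.get(str(row.is_control).strip().lower())
        if flag is None:
            raise ValidationError(
                f"library file {path}: is_control value {row.is_control!r} "
                f"for feature {row.feature_id!r} is not boolean"
            )
        sub = None if row.sublibrary == MISSING_SUBLIBRARY else row.sublibrary
        entries.append(LibraryEntry(row.feature_id, row.target_id, sub, flag))
    return GuideLibrary(entries)


def write_library(library: GuideLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """One sequenced sample: id, sorting/treatment replicate, gate/arm role."""

    sample_id: str
    replicate: int
    role: str

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: role {self.role!r} not one of {VALID_ROLES}"
            )


class CountMatrix:
    """Nonnegative integer feature x sample read counts."""

    def __init__(self, features: Sequence[str], samples: Sequence[Sample], counts):
        features = list(features)
        samples = list(samples)
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape != (len(features), len(samples)):
            raise ValidationError(
                f"count matrix shape {arr.shape} does not match "
                f"{len(features)} features x {len(samples)} samples"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac = np.mod(arr, 1) != 0
            if frac.any():
                bad = [features[i] for i in np.unique(np.nonzero(frac)[0])[:5]]
                raise ValidationError(f"non-integer counts for features {bad}")
            arr = arr.astype(np.int64)
        arr = arr.astype(np.int64, copy=False)
        if arr.size and arr.min() < 0:
            bad = [features[i] for i in np.unique(np.nonzero(arr < 0)[0])[:5]]
            raise ValidationError(f"negative counts for features {bad}")
        dup_f = pd.Index(features)[pd.Index(features).duplicated()].unique().tolist()
        if dup_f:
            raise ValidationError(f"duplicate feature_id in count matrix: {dup_f}")
        ids = [s.sample_id for s in samples]
        dup_s = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample_id: {dup_s}")
        self.features = features
        self.samples = samples
        self.counts = arr

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.features, name="feature_id"),
                            columns=self.sample_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.features == other.features
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# screen design / sample sheet
# ---------------------------------------------------------------------------

@dataclass
class ScreenDesign:
    """Which sample pairs form replicates and how the statistics are run.

    ``pairs`` lists ``(replicate, numerator_sample_id, denominator_sample_id)``;
    for a reporter sort the numerator is the stable gate, for a resistance
    screen the drug-treated arm.
    """

    mode: str
    pairs: list[tuple[int, str, str]]
    pseudocount: float = 0.5
    n_null_iterations: int = 100
    seed: int = 0
    rank_direction: str = "enriched_first"

    def __post_init__(self):
        if self.mode not in ROLE_PAIRS:
            raise ValidationError(f"mode {self.mode!r} not one of {sorted(ROLE_PAIRS)}")
        if self.rank_direction not in RANK_DIRECTIONS:
            raise ValidationError(
                f"rank_direction {self.rank_direction!r} not one of {RANK_DIRECTIONS}"
            )
        if self.n_null_iterations < 1:
            raise ValidationError("n_null_iterations must be >= 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be nonnegative")
        if not self.pairs:
            raise ValidationError("design has no replicate pairs")
        self.pairs = [(int(r), str(n), str(d)) for r, n, d in self.pairs]
        reps = [r for r, _, _ in self.pairs]
        if len(set(reps)) != len(reps):
            raise ValidationError(f"duplicate replicate indices in design: {sorted(reps)}")

    @property
    def replicates(self) -> list[int]:
        return [r for r, _, _ in self.pairs]


def _derive_pairs(samples: Sequence[Sample], mode: str) -> list[tuple[int, str, str]]:
    num_role, den_role = ROLE_PAIRS[mode]
    pairs = []
    for rep in sorted({s.replicate for s in samples}):
        nums = [s.sample_id for s in samples if s.replicate == rep and s.role == num_role]
        dens = [s.sample_id for s in samples if s.replicate == rep and s.role == den_role]
        if len(nums) != 1 or len(dens) != 1:
            raise ValidationError(
                f"replicate {rep} must have exactly one {num_role!r} and one "
                f"{den_role!r} sample, found {len(nums)} and {len(dens)}"
            )
        pairs.append((rep, nums[0], dens[0]))
    return pairs


def read_sample_sheet(source: str | Path | Mapping) -> tuple[list[Sample], ScreenDesign]:
    """Parse a YAML sample sheet into samples plus a :class:`ScreenDesign`.

    Expected keys: ``mode``, ``samples`` (list of ``{sample_id, replicate,
    role}``), and optionally ``pairs``, ``pseudocount``, ``n_null_iterations``,
    ``seed``, ``rank_direction``.  When ``pairs`` is omitted it is derived
    from the roles: one numerator and one denominator sample per replicate.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError("sample sheet must be a YAML mapping")
    if "mode" not in doc or "samples" not in doc:
        raise ValidationError("sample sheet requires 'mode' and 'samples' keys")
    samples = []
    for rec in doc["samples"]:
        try:
            samples.append(Sample(str(rec["sample_id"]), int(rec["replicate"]), str(rec["role"])))
        except KeyError as exc:
            raise ValidationError(f"sample record {rec!r} missing key {exc}") from None
    mode = str(doc["mode"])
    if mode not in ROLE_PAIRS:
        raise ValidationError(f"mode {mode!r} not one of {sorted(ROLE_PAIRS)}")
    pairs = doc.get("pairs")
    if pairs is None:
        pairs = _derive_pairs(samples, mode)
    else:
        pairs = [tuple(p) for p in pairs]
    design = ScreenDesign(
        mode=mode,
        pairs=pairs,
        pseudocount=float(doc.get("pseudocount", 0.5)),
        n_null_iterations=int(doc.get("n_null_iterations", 100)),
        seed=int(doc.get("seed", 0)),
        rank_direction=str(doc.get("rank_direction", "enriched_first")),
    )
    known = {s.sample_id for s in samples}
    for rep, num, den in design.pairs:
        if num not in known or den not in known:
            raise ValidationError(
                f"design pair for replicate {rep} references unknown sample "
                f"({num!r}, {den!r})"
            )
    return samples, design


def write_sample_sheet(samples: Sequence[Sample], design: ScreenDesign,
                       path: str | Path) -> None:
    doc = {
        "mode": design.mode,
        "samples": [
            {"sample_id": s.sample_id, "replicate": s.replicate, "role": s.role}
            for s in samples
        ],
        "pairs": [list(p) for p in design.pairs],
        "pseudocount": design.pseudocount,
        "n_null_iterations": design.n_null_iterations,
        "seed": design.seed,
        "rank_direction": design.rank_direction,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count table I/O
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path,
                     sample_sheet: str | Path | Mapping | Sequence[Sample],
                     library: GuideLibrary | None = None) -> CountMatrix:
    """Read a TSV count table validated against a sample sheet.

    The first column must be ``feature_id``; remaining columns are samples.
    Column order follows the sample sheet, not the file.  When ``library``
    is given, features present in the library but absent from the table are
    zero-filled (with a logged warning) and the matrix is reordered to the
    library's feature order; features absent from the library are an error.
    """
    if isinstance(sample_sheet, (str, Path, Mapping)):
        samples, _ = read_sample_sheet(sample_sheet)
    else:
        samples = list(sample_sheet)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature_id":
        raise ValidationError(
            f"count table {path}: first column must be 'feature_id', got {df.columns[0]!r}"
        )
    df = df.set_index("feature_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"count table {path}: duplicate feature_id {dup}")
    absent = [s.sample_id for s in samples if s.sample_id not in df.columns]
    if absent:
        raise ValidationError(f"count table {path}: samples missing from table: {absent}")
    df = df[[s.sample_id for s in samples]]
    if library is not None:
        unknown = [f for f in df.index if f not in library._target_of]
        if unknown:
            raise ValidationError(
                f"count table {path}: features not in library: {unknown[:10]}"
            )
        missing = [f for f in library.feature_ids if f not in df.index]
        if missing:
            logger.warning(
                "count table %s: %d library features absent, zero-filled (e.g. %s)",
                path, len(missing), missing[:5],
            )
            fill = pd.DataFrame(0, index=pd.Index(missing, name="feature_id"),
                                columns=df.columns)
            df = pd.concat([df, fill])
        df = df.loc[library.feature_ids]
    return CountMatrix(list(df.index), samples, df.to_numpy())


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetResult:
    """Per-target screen outcome (row schema of the results table)."""

    target_id: str
    fold_change: float
    rank_stat: float
    p_two_sided: float
    n_features: int


RESULT_COLUMNS = ["target_id", "fold_change", "rank_stat", "p_two_sided", "n_features"]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results table missing columns: {missing}")
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"results file {path} missing columns: {missing}")
    return df[RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]]


def write_truth(effects: Mapping[str, float], path: str | Path) -> None:
    """Write planted per-target effects (TSV: target_id, beta)."""
    pd.DataFrame({"target_id": list(effects), "beta": list(effects.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"target_id", "beta"} <= set(df.columns):
        raise ValidationError(f"truth file {path} requires columns target_id, beta")
    return dict(zip(df["target_id"].astype(str), df["beta"].astype(float)))


# ---------------------------------------------------------------------------
# cross-artifact validation
# ---------------------------------------------------------------------------

def validate_screen(counts: CountMatrix, library: GuideLibrary,
                    design: ScreenDesign) -> None:
    """Check that counts, library and design are mutually consistent."""
    if set(counts.features) != set(library.feature_ids):
        extra = sorted(set(counts.features) - set(library.feature_ids))[:5]
        lack = sorted(set(library.feature_ids) - set(counts.features))[:5]
        raise ValidationError(
            f"count matrix and library feature sets differ "
            f"(extra in counts: {extra}, missing: {lack})"
        )
    by_id = {s.sample_id: s for s in counts.samples}
    num_role, den_role = ROLE_PAIRS[design.mode]
    for rep, num, den in design.pairs:
        for sid, role in ((num, num_role), (den, den_role)):
            if sid not in by_id:
                raise ValidationError(f"design references unknown sample {sid!r}")
            s = by_id[sid]
            if s.role != role:
                raise ValidationError(
                    f"sample {sid!r} has role {s.role!r} but the design uses it "
                    f"as {role!r} in replicate {rep}"
                )
            if s.replicate != rep:
                raise ValidationError(
                    f"sample {sid!r} is replicate {s.replicate} but paired under "
                    f"replicate {rep}"
                )
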