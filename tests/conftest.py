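import numpy as np
import pytest

from sortscreen import (
    CountMatrix,
    GuideLibrary,
    LibraryEntry,
    Sample,
    ScreenDesign,
)


@pytest.fixture
def small_library():
    """Two genes x 4 guides."""
    entries = []
    for gene in ("geneA", "geneB"):
        for i in range(1, 5):
            entries.append(LibraryEntry(f"{gene}_sg{i}", gene))
    return GuideLibrary(entries)


@pytest.fixture
def small_samples():
    return [
        Sample("rep1_stable", 1, "stable"),
        Sample("rep1_unstable", 1, "unstable"),
        Sample("rep2_stable", 2, "stable"),
        Sample("rep2_unstable", 2, "unstable"),
    ]


@pytest.fixture
def small_design():
    return ScreenDesign(
        mode="reporter_sort",
        pairs=[(1, "rep1_stable", "rep1_unstable"), (2, "rep2_stable", "rep2_unstable")],
        pseudocount=0.5,
        n_null_iterations=200,
        seed=7,
    )


@pytest.fixture
def small_counts(small_library, small_samples):
    rng = np.random.default_rng(11)
    counts = rng.integers(50, 500, size=(len(small_library), len(small_samples)))
    return CountMatrix(small_library.feature_ids, small_samples, counts)


def random_count_matrix(n_features=50, n_replicates=3, seed=0, low=0, high=1000):
    """A random reporter-sort CountMatrix plus its paired design."""
    rng = np.random.default_rng(seed)
    samples = []
    pairs = []
    for r in range(1, n_replicates + 1):
        samples += [Sample(f"rep{r}_stable", r, "stable"),
                    Sample(f"rep{r}_unstable", r, "unstable")]
        pairs.append((r, f"rep{r}_stable", f"rep{r}_unstable"))
    features = [f"f{i:03d}" for i in range(n_features)]
    counts = rng.integers(low, high, size=(n_features, 2 * n_replicates))
    # ensure no all-zero sample
    counts[0, :] += 1
    design = ScreenDesign(mode="reporter_sort", pairs=pairs, seed=seed)
    return CountMatrix(features, samples, counts), design
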