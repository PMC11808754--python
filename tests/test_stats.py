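"""Feature detection, PCA phenotyping, volcano differential analysis."""

import numpy as np
import pytest

from fastpass.errors import StatsError
from fastpass.io import LineScanRun, MassSpectrum, default_layout
from fastpass.quant import FeatureTable
from fastpass.stats import (
    detect_features,
    pca_phenotypes,
    significant_counts,
    volcano,
)


def _planted_run(layout, species_mz, species_intensity, pixel_size=50.0):
    """Deterministic run whose sample pixels carry the given species peaks."""
    n = int(np.ceil(layout.scan_length / pixel_size))
    d = np.arange(n) * pixel_size
    sample_mask = np.zeros(n, dtype=bool)
    for spot in layout.by_role("sample"):
        sample_mask |= spot.contains(d)
    mz = np.asarray(species_mz)
    order = np.argsort(mz)
    mz, inten = mz[order], np.asarray(species_intensity)[order]
    pixels = []
    for i in range(n):
        if sample_mask[i]:
            pixels.append((d[i], MassSpectrum(mz, inten)))
        else:
            pixels.append((d[i], MassSpectrum(np.array([]), np.array([]))))
    return LineScanRun(pixels=pixels, raster_rate=125.0, pixel_size=pixel_size)


@pytest.fixture
def grid_layout():
    return default_layout(4, 2000.0, 14_000.0, margin=500.0)


def test_top_n_filter_retains_exactly_n(grid_layout):
    n_species = 600
    mz = np.linspace(100, 1100, n_species)
    inten = np.arange(1, n_species + 1, dtype=float)
    run = _planted_run(grid_layout, mz, inten)
    table = detect_features(run, grid_layout, top_n=500)
    assert table.n_features == 500


def test_under_threshold_features_pass_through(grid_layout):
    mz = np.linspace(100, 500, 10)
    run = _planted_run(grid_layout, mz, np.full(10, 5.0))
    table = detect_features(run, grid_layout, top_n=500)
    assert table.n_features == 10


def test_retained_minimum_exceeds_discarded_maximum(grid_layout):
    """Sort-order oracle for the abundance prioritization."""
    rng = np.random.default_rng(11)
    n_species = 120
    mz = np.sort(rng.uniform(100, 1100, n_species))
    inten = rng.uniform(1, 1000, n_species)
    run = _planted_run(grid_layout, mz, inten)
    top_n = 40
    table = detect_features(run, grid_layout, top_n=top_n)
    totals = {m: t for m, t in zip(mz, inten)}
    # map detected features back to planted species by nearest m/z
    retained = set()
    for f in table.feature_mzs:
        retained.add(min(totals, key=lambda m: abs(m - f)))
    discarded = set(totals) - retained
    assert len(retained) == top_n
    assert min(totals[m] for m in retained) >= max(totals[m] for m in discarded)


def test_detection_separates_distant_mz_and_merges_close(grid_layout):
    mz = np.array([200.0, 200.0005, 300.0])  # 2.5 ppm apart -> one feature
    run = _planted_run(grid_layout, mz, np.array([10.0, 10.0, 5.0]))
    table = detect_features(run, grid_layout, cluster_ppm=10.0)
    assert table.n_features == 2


def test_pca_identical_groups_show_no_separation():
    values = np.tile(np.array([[1.0, 5.0, 2.0]]), (4, 1))
    values += np.array([[0.0], [0.1], [0.0], [0.1]])  # replicate pairs
    table = FeatureTable(["a1", "a2", "b1", "b2"], [1.0, 2.0, 3.0], values)
    result = pca_phenotypes(table, n_components=2)
    a = result.scores.loc[["a1", "a2"]].mean(axis=0)
    b = result.scores.loc[["b1", "b2"]].mean(axis=0)
    assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


def test_pca_explained_variance_bounded_by_total():
    rng = np.random.default_rng(2)
    values = rng.normal(size=(6, 10))
    table = FeatureTable(
        [f"s{i}" for i in range(6)], list(np.arange(10.0) + 100), values
    )
    result = pca_phenotypes(table, n_components=3)
    total = np.var(values - values.mean(0), axis=0, ddof=1).sum()
    assert result.explained_variance.sum() <= total + 1e-9
    assert np.all(np.diff(result.explained_variance) <= 1e-12)


def test_pca_rejects_constant_table():
    table = FeatureTable(["a", "b"], [1.0, 2.0], np.ones((2, 2)))
    with pytest.raises(StatsError):
        pca_phenotypes(table)


def test_pca_recovers_planted_strain_clusters():
    """Three planted profiles separate with positive silhouette on PC1/PC2."""
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(7)
    profiles = {
        "A": np.array([100.0, 5.0, 5.0, 40.0, 10.0]),
        "B": np.array([5.0, 80.0, 10.0, 5.0, 10.0]),
        "C": np.array([5.0, 5.0, 5.0, 5.0, 10.0]),
    }
    labels, rows, groups = [], [], []
    for g, prof in profiles.items():
        for r in range(3):
            labels.append(f"{g}{r}")
            rows.append(prof * rng.lognormal(0, 0.05, prof.size))
            groups.append(g)
    table = FeatureTable(labels, [1.0, 2.0, 3.0, 4.0, 5.0], np.stack(rows))
    result = pca_phenotypes(table, n_components=2)
    score = silhouette_score(result.scores.to_numpy(), groups)
    assert score > 0


def _volcano_table(rng, n_features=200, n_planted=10, fold=4.0, noise=0.05):
    base = rng.uniform(50, 500, n_features)
    rows, labels = [], []
    for g, mult in (("a", fold), ("b", 1.0)):
        for r in range(3):
            profile = base.copy()
            profile[:n_planted] *= mult if g == "a" else 1.0
            rows.append(profile * rng.lognormal(0, noise, n_features))
            labels.append(f"{g}{r}")
    return FeatureTable(labels, list(np.arange(n_features) + 100.0), np.stack(rows))


def test_volcano_identical_groups_yield_nothing():
    rng = np.random.default_rng(3)
    base = rng.uniform(10, 100, 50)
    rows = [base for _ in range(4)]
    table = FeatureTable(
        ["a1", "a2", "b1", "b2"], list(np.arange(50) + 100.0), np.stack(rows)
    )
    res = volcano(table, ["a1", "a2"], ["b1", "b2"])
    assert significant_counts(res)["significant"] == 0


def test_volcano_recovers_planted_fold_changes():
    rng = np.random.default_rng(5)
    table = _volcano_table(rng)
    res = volcano(table, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    planted = {r.feature_mz for r in res[:10]}
    flagged_up = {r.feature_mz for r in res if r.significant and r.direction == "up"}
    assert planted <= flagged_up
    false_pos = flagged_up - planted
    # null false positives consistent with the 0.05 level (binomial 3-sigma)
    n_null = 190
    assert len(false_pos) <= 0.05 * n_null + 3 * np.sqrt(n_null * 0.05 * 0.95)


def test_volcano_direction_flips_when_groups_swap():
    rng = np.random.default_rng(6)
    table = _volcano_table(rng)
    fwd = volcano(table, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    rev = volcano(table, ["b0", "b1", "b2"], ["a0", "a1", "a2"])
    for f, r in zip(fwd, rev):
        assert f.log2_fold_change == pytest.approx(-r.log2_fold_change, abs=1e-9)
        if f.significant:
            assert r.significant
            assert {f.direction, r.direction} == {"up", "down"}


def test_volcano_invariant_to_global_rescaling():
    rng = np.random.default_rng(8)
    table = _volcano_table(rng)
    scaled = FeatureTable(
        table.spot_labels, table.feature_mzs, table.values * 1000.0
    )
    a = volcano(table, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    b = volcano(scaled, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
    assert [r.significant for r in a] == [r.significant for r in b]


def test_volcano_rejects_single_replicate():
    rng = np.random.default_rng(9)
    table = _volcano_table(rng)
    with pytest.raises(StatsError):
        volcano(table, ["a0"], ["b0", "b1"])


def test_more_planted_changes_yield_more_significant_features():
    """A heavily edited profile produces more volcano hits than a light one."""
    rng = np.random.default_rng(10)
    n = 100
    base = rng.uniform(50, 500, n)
    def group_rows(mult_mask):
        rows = []
        for _ in range(3):
            profile = base.copy()
            profile[mult_mask] *= 4.0
            rows.append(profile * rng.lognormal(0, 0.05, n))
        return rows
    heavy_mask = np.zeros(n, bool); heavy_mask[:20] = True
    light_mask = np.zeros(n, bool); light_mask[50:55] = True
    labels = [f"{g}{r}" for g in ("h", "l", "c") for r in range(3)]
    rows = group_rows(heavy_mask) + group_rows(light_mask) + group_rows(
        np.zeros(n, bool)
    )
    table = FeatureTable(labels, list(np.arange(n) + 100.0), np.stack(rows))
    heavy = volcano(table, ["h0", "h1", "h2"], ["c0", "c1", "c2"])
    light = volcano(table, ["l0", "l1", "l2"], ["c0", "c1", "c2"])
    assert (
        significant_counts(heavy)["significant"]
        > significant_counts(light)["significant"]
    )
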