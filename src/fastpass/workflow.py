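"""End-to-end Fast-Pass runs: configuration, staging, artifacts, provenance.

A run goes read/simulate -> lock-mass correction -> spatial normalization ->
feature detection -> media-blank subtraction -> analyte normalization ->
annotation -> statistics, writing every intermediate artifact and a JSON
provenance log (versions, seed, thresholds, file list).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import annotate as _ann
from . import panels as _panels
from .errors import ConfigError, FastPassError
from .io import (
    SpotLayout,
    default_layout,
    read_imzml,
    read_layout,
    write_imzml,
    write_layout,
)
from .quant import FeatureTable, analyte_normalize, blank_subtract, replicate_cv_report
from .sim import AnalytePanelEntry, NoiseModel, RateResponseModel, simulate_run
from .stats import (
    detect_features,
    pca_phenotypes,
    significant_counts,
    volcano,
    volcano_frame,
)
from .trace import extract_xic, lockmass_correct, spatial_normalize

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one Fast-Pass processing run."""

    layout_path: str | None = None
    sim_panel_path: str | None = None
    compound_panel: str = "ffa"  # bundled panel name or a CSV/TSV path
    polarity: str = "negative"
    raster_rate: float = 125.0  # µm/s, the optimized acquisition rate
    pixel_size: float = 50.0  # µm
    lockmass_formula: str = _panels.LOCKMASS_FORMULA
    lockmass_adduct: str | None = None  # default: [M-H]- / [M+H]+ by polarity
    max_ppm: float = 5.0
    min_similarity: float = 0.8
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    top_n: int = 500
    cluster_ppm: float = 10.0
    control_group: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_ppm", "min_similarity", "p_threshold", "fc_threshold",
                     "top_n", "cluster_ppm", "raster_rate", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")
        if self.lockmass_adduct is None:
            self.lockmass_adduct = "[M-H]-" if self.polarity == "negative" else "[M+H]+"

    @property
    def lockmass_mz(self) -> float:
        return _ann.adduct_mz(
            _ann.monoisotopic_mass(self.lockmass_formula), self.lockmass_adduct
        )


# ---------------------------------------------------------------------------
# bundled strain-screen fixture: 3 producer groups x 3 replicates + media blank

INTERNAL_STANDARD = ("internal standard (C17 ceramide)", "C35H69NO3")


def strain_screen_layout() -> SpotLayout:
    """One 10-spot row: 9 strain replicates plus a media blank at position 3."""
    labels, roles = [], []
    groups = ["strainA", "strainB", "control"]
    position = 0
    rep = {g: 0 for g in groups}
    order = [
        "strainA", "strainB", None, "control", "strainA",
        "strainB", "control", "strainA", "strainB", "control",
    ]  # pseudorandomized deposition; None = media blank
    for entry in order:
        position += 1
        if entry is None:
            labels.append("media-blank")
            roles.append("media_blank")
        else:
            rep[entry] += 1
            labels.append(f"{entry}-{rep[entry]}")
            roles.append("sample")
    return default_layout(
        10, spot_width=3000.0, span=50_000.0, margin=2500.0,
        roles=roles, labels=labels,
    )


def strain_screen_panel(
    layout: SpotLayout, replicate_noise: float = 0.05, seed: int = 0
) -> list[AnalytePanelEntry]:
    """Fatty-acid production profiles for the bundled 3-group screen.

    strainA preferentially accumulates C12:0 (with C12:1 and C14:1 side
    products), strainB accumulates C8:0, and the control produces only trace
    levels. Every spot, including the media blank, carries the exogenous
    internal standard. ``replicate_noise`` applies multiplicative lognormal
    jitter to per-spot abundances to emulate biological replicates.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {"strainA": [], "strainB": [], "control": []}
    blank_label = None
    for spot in layout.spots:
        if spot.role == "media_blank":
            blank_label = spot.label
        else:
            groups[spot.label.rsplit("-", 1)[0]].append(spot.label)
    all_samples = [s.label for s in layout.by_role("sample")]
    all_spots = [s.label for s in layout.spots]

    # per-analyte relative abundance by group (relative to base_intensity)
    profile = {
        "C12:0": {"strainA": 1.0, "strainB": 0.05, "control": 0.03, "base": 2000.0},
        "C12:1": {"strainA": 0.30, "strainB": 0.03, "control": 0.02, "base": 1000.0},
        "C14:1": {"strainA": 0.50, "strainB": 0.10, "control": 0.03, "base": 1000.0},
        "C8:0": {"strainA": 0.08, "strainB": 1.0, "control": 0.03, "base": 1500.0},
        "C10:0": {"strainA": 0.10, "strainB": 0.25, "control": 0.04, "base": 800.0},
        "C14:0": {"strainA": 0.25, "strainB": 0.15, "control": 0.10, "base": 800.0},
    }
    media_background = 0.02

    entries = []
    for name, prof in profile.items():
        scale: dict[str, float] = {}
        for group, labels in groups.items():
            for lb in labels:
                jitter = rng.lognormal(0.0, replicate_noise) if replicate_noise else 1.0
                scale[lb] = prof[group] * jitter
        spot_labels = list(all_samples)
        if blank_label is not None:
            scale[blank_label] = media_background
            spot_labels.append(blank_label)
        entries.append(
            AnalytePanelEntry(
                name=name,
                formula=_panels.FFA_FORMULAS[name],
                adduct="[M-H]-",
                base_intensity=prof["base"],
                spatial_profile="uniform",
                spot_labels=spot_labels,
                spot_scale=scale,
            )
        )
    is_name, is_formula = INTERNAL_STANDARD
    entries.append(
        AnalytePanelEntry(
            name=is_name,
            formula=is_formula,
            adduct="[M-H]-",
            base_intensity=1200.0,
            spatial_profile="uniform",
            spot_labels=all_spots,
        )
    )
    return entries


def lockmass_entry(config: RunConfig) -> AnalytePanelEntry:
    return AnalytePanelEntry(
        name="lock mass",
        formula=config.lockmass_formula,
        adduct=config.lockmass_adduct,
        base_intensity=800.0,
        spatial_profile="uniform",
        spot_labels=[],
    )


def _load_compound_panel(spec: str):
    bundled = {
        "ffa": _panels.ffa_panel,
        "peptides": _panels.peptide_panel,
        "maltose": _panels.maltose_panel,
        "exogenous": _panels.exogenous_panel,
        "standards": _panels.standards_panel,
    }
    if spec in bundled:
        return bundled[spec]()
    path = Path(spec)
    if not path.exists():
        raise ConfigError(
            f"compound panel {spec!r} is neither a bundled panel "
            f"({sorted(bundled)}) nor an existing file"
        )
    return _panels.read_panel_csv(path)


def observed_envelope_from_table(
    table: FeatureTable, feature_mz: float, charge: int = 1, match_ppm: float = 10.0
) -> list[tuple[float, float]]:
    """Observed isotopic envelope of a feature, read off the feature table.

    Looks for companion features at +k * 1.003355 / |charge| Th (k = 0, 1, 2)
    and uses their total intensities across spots as relative abundances.
    """
    spacing = 1.003355 / abs(charge)
    totals = table.values.sum(axis=0)
    envelope = []
    for k in range(3):
        target = feature_mz + k * spacing
        best = None
        for j, mz in enumerate(table.feature_mzs):
            if abs(mz - target) <= target * match_ppm * 1e-6:
                if best is None or totals[j] > totals[best]:
                    best = j
        if best is not None:
            envelope.append((float(table.feature_mzs[best]), float(totals[best])))
    if envelope:
        peak = max(ab for _, ab in envelope)
        if peak > 0:
            envelope = [(mz, ab / peak) for mz, ab in envelope]
    return envelope


def group_map_from_labels(labels: list[str]) -> dict[str, str]:
    """Spot label -> group name, stripping a trailing ``-<replicate>`` part."""
    out = {}
    for lb in labels:
        head, sep, tail = lb.rpartition("-")
        out[lb] = head if sep and tail.isdigit() else lb
    return out


def run_fastpass(
    config: RunConfig,
    input_source: str | Path,
    outdir: str | Path,
    layout: SpotLayout | None = None,
    sim_panel: list[AnalytePanelEntry] | None = None,
) -> dict:
    """Execute the full pipeline; returns the report dict written to JSON.

    ``input_source`` is either an imzML path or the literal ``"simulate"``,
    in which case the bundled strain-screen fixture (or the given layout and
    simulator panel) is acquired in silico first. Any stage failure raises
    with the stage named; artifacts produced before the failure remain on
    disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    report: dict = {"config": {k: str(v) for k, v in vars(config).items()}}

    def _emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts.append(name)
        return path

    stage = "input"
    try:
        if str(input_source) == "simulate":
            if layout is None:
                layout = strain_screen_layout()
            if sim_panel is None:
                sim_panel = strain_screen_panel(layout, seed=config.seed)
            run = simulate_run(
                layout,
                sim_panel,
                rate=config.raster_rate,
                pixel_size=config.pixel_size,
                rate_model=RateResponseModel(),
                noise=NoiseModel(seed=config.seed),
                lockmass=lockmass_entry(config),
                polarity=config.polarity,
            )
            _emit("run.imzML", lambda p: write_imzml(run, p))
            artifacts.append("run.ibd")
        else:
            if config.layout_path is None and layout is None:
                raise ConfigError("processing a file requires a layout")
            if layout is None:
                layout = read_layout(config.layout_path)
            run = read_imzml(
                input_source, config.raster_rate, config.pixel_size,
                polarity=config.polarity,
            )
        _emit("layout.yaml", lambda p: write_layout(layout, p))

        stage = "lockmass_correct"
        lock_mz = config.lockmass_mz
        run = lockmass_correct(run, lock_mz)

        stage = "spatial_normalize"
        lock_xic = extract_xic(run, lock_mz)
        run = spatial_normalize(run, lock_xic)
        _emit("lock_trace.tsv", lock_xic.to_tsv)

        stage = "detect_features"
        table = detect_features(
            run, layout, top_n=config.top_n, cluster_ppm=config.cluster_ppm
        )
        raw_table = table
        _emit("features_raw.tsv", table.to_tsv)

        stage = "blank_subtract"
        blanks = layout.by_role("media_blank")
        if blanks:
            table = blank_subtract(table, blanks[0].label)
            _emit("features_blank_subtracted.tsv", table.to_tsv)

        stage = "analyte_normalize"
        normalized = analyte_normalize(table)
        _emit("features_normalized.tsv", normalized.to_tsv)

        stage = "annotate"
        panel = _load_compound_panel(config.compound_panel)
        annotations = {}
        for mz in table.feature_mzs:
            env = observed_envelope_from_table(table, mz)
            hits = _ann.annotate_feature(
                mz, env if len(env) >= 2 else None, panel,
                config.max_ppm, config.min_similarity,
            )
            if hits:
                annotations[mz] = hits
        _emit(
            "annotations.tsv",
            lambda p: _write_annotations(annotations, p),
        )
        report["n_annotated_features"] = len(annotations)

        stage = "stats"
        sample_labels = [s.label for s in layout.by_role("sample")]
        group_map = group_map_from_labels(sample_labels)
        groups = sorted(set(group_map.values()))
        sample_table = FeatureTable(
            spot_labels=sample_labels,
            feature_mzs=table.feature_mzs,
            values=np.stack([table.row(lb) for lb in sample_labels]),
            stage=table.stage,
        )
        replicated = [
            g for g in groups if sum(1 for v in group_map.values() if v == g) >= 2
        ]
        if len(sample_labels) >= 2 and sample_table.n_features >= 2:
            pca = pca_phenotypes(sample_table)
            _emit("pca_scores.tsv", lambda p: pca.scores.to_csv(p, sep="\t"))
            _emit("pca_loadings.tsv", lambda p: pca.loadings.to_csv(p, sep="\t"))
            report["pca_explained_variance_ratio"] = [
                float(v) for v in pca.explained_variance_ratio
            ]
        if len(replicated) >= 2:
            # reproducibility is assessed on raw integrals; blank subtraction
            # leaves near-zero channels whose %CV is unbounded
            raw_samples = FeatureTable(
                spot_labels=sample_labels,
                feature_mzs=raw_table.feature_mzs,
                values=np.stack([raw_table.row(lb) for lb in sample_labels]),
                stage=raw_table.stage,
            )
            cv = replicate_cv_report(raw_samples, group_map)
            _emit("reproducibility.json", cv.to_json)
            report["overall_mean_cv_percent"] = cv.overall_mean_cv
            control = config.control_group
            if control is None and "control" in replicated:
                control = "control"
            if control in replicated:
                report["volcano"] = {}
                for g in replicated:
                    if g == control:
                        continue
                    res = volcano(
                        sample_table,
                        [lb for lb, grp in group_map.items() if grp == g],
                        [lb for lb, grp in group_map.items() if grp == control],
                        config.p_threshold,
                        config.fc_threshold,
                    )
                    name = f"volcano_{g}_vs_{control}.tsv"
                    _emit(name, lambda p, r=res: volcano_frame(r).to_csv(
                        p, sep="\t", index=False))
                    report["volcano"][f"{g}_vs_{control}"] = significant_counts(res)
    except FastPassError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    report["artifacts"] = artifacts
    report["provenance"] = {
        "fastpass_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "thresholds": {
            "max_ppm": config.max_ppm,
            "min_similarity": config.min_similarity,
            "p_threshold": config.p_threshold,
            "fc_threshold": config.fc_threshold,
            "top_n": config.top_n,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _write_annotations(annotations: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_mz\tcompound\tadduct\tppm_error\tenvelope_similarity\n")
        for mz, hits in sorted(annotations.items()):
            for h in hits:
                fh.write(
                    f"{mz:.5f}\t{h.compound}\t{h.adduct}\t"
                    f"{h.ppm_error:.3f}\t{h.envelope_similarity:.4f}\n"
                )
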