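"""End-to-end orchestration: epochs -> connectivity -> features -> biotypes.

A :class:`PipelineConfig` fixes every analysis choice (bands, windows,
wavelet, surrogate normalisation, clustering settings, seeds), serialises
losslessly to YAML, and drives :func:`run_pipeline`, which writes a
deterministic result bundle: per-subject feature tables, the cluster
solution, discriminant coefficients and scores, projections of the
replication and control sets, group-comparison tables, and a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epochs import (
    EpochedRecording,
    WindowSpec,
    baseline_correct,
    reject_artifacts,
)
from .connectivity import band_window_matrices
from .network import NetworkFeatures, SurrogateEnsemble
from .entropy import se_modulation
from .biotype import (
    BiotypeClustering,
    BiotypeDiscriminant,
    jackknife_accuracy,
    project,
)
from .stats import adjust_results, anova_bonferroni, report_tables
from .simulate import SimConfig, C1_LIKE, C2_LIKE, simulate_subject
from .validity import DEFAULT_INDICES


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with an explicit seed per stage."""

    bands: dict = field(
        default_factory=lambda: {"theta": [4.0, 8.0], "broadband": [1.0, 70.0]}
    )
    feature_band: str = "broadband"
    prestim_window_ms: tuple[float, float] = (-300.0, 0.0)
    response_window_ms: tuple[float, float] = (150.0, 450.0)
    omega0: float = 6.0
    voices_per_octave: int = 4
    artifact_limit_uv: float = 100.0
    normalize_metrics: bool = True
    n_surrogates: int = 50
    surrogate_seed: int = 0
    k: int | None = None
    k_range: tuple[int, int] = (2, 8)
    n_init: int = 50
    n_subsets: int = 50
    indices: tuple[str, ...] = DEFAULT_INDICES
    seed: int = 0

    def windows(self) -> tuple[WindowSpec, WindowSpec]:
        return (
            WindowSpec("prestimulus", *self.prestim_window_ms),
            WindowSpec("response", *self.response_window_ms),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        d["indices"] = list(d["indices"])
        d["prestim_window_ms"] = list(d["prestim_window_ms"])
        d["response_window_ms"] = list(d["response_window_ms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("k_range", "prestim_window_ms", "response_window_ms"):
            if key in d:
                d[key] = tuple(d[key])
        if "indices" in d:
            d["indices"] = tuple(d["indices"])
        return cls(**d)


def features_from_recording(
    recording: EpochedRecording, config: PipelineConfig
) -> tuple[dict, dict]:
    """One subject's feature row (and all band/window matrices).

    Applies artifact rejection and baseline correction, computes the
    band/window PLV matrices, graph metrics with surrogate normalisation,
    the six clustering features from the configured band, and spectral
    entropy modulation averaged over sensors.
    """
    rec, _ = reject_artifacts(recording, config.artifact_limit_uv)
    pre_w, resp_w = config.windows()
    rec = baseline_correct(rec, pre_w)
    bands = {k: tuple(v) for k, v in config.bands.items()}
    matrices = band_window_matrices(
        rec,
        bands=bands,
        windows=(pre_w, resp_w),
        voices_per_octave=config.voices_per_octave,
        omega0=config.omega0,
    )
    ensemble = SurrogateEnsemble(
        n_surrogates=config.n_surrogates, seed=config.surrogate_seed
    )
    band = config.feature_band
    nf = NetworkFeatures.from_matrices(
        matrices[band]["prestimulus"],
        matrices[band]["response"],
        band=band,
        subject_id=rec.subject_id,
        normalize=config.normalize_metrics,
        ensemble=ensemble,
    )
    se = se_modulation(
        rec,
        band=bands.get("broadband", (1.0, 70.0)),
        windows=(pre_w, resp_w),
        voices_per_octave=config.voices_per_octave,
        omega0=config.omega0,
    )
    row = {"subject_id": rec.subject_id, **nf.feature_row()}
    row["clc_prestim"] = nf.prestimulus.clc
    row["clc_modulation"] = nf.modulation.clc
    row["se_modulation_mean"] = float(se.se_modulation.mean())
    return row, matrices


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(
    config: PipelineConfig,
    main_features: pd.DataFrame,
    replication_features: pd.DataFrame | None = None,
    control_features: pd.DataFrame | None = None,
    out_dir: str | Path = "results",
    feature_columns: tuple[str, ...] = (
        "pl_prestim",
        "cs_prestim",
        "sw_prestim",
        "pl_modulation",
        "cs_modulation",
        "sw_modulation",
    ),
) -> dict:
    """Cluster the main feature table, validate, project, compare, write.

    The bundle under ``out_dir`` contains ``features_main.tsv``, the
    cluster solution and discriminant JSONs, projection tables for
    replication/control sets when given, group-comparison tables, and
    ``manifest.json`` (config + package version + seeds).  Output is
    byte-deterministic for a fixed config and inputs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = main_features[list(feature_columns)]

    clustering = BiotypeClustering(
        k=config.k,
        k_range=config.k_range,
        n_init=config.n_init,
        n_subsets=config.n_subsets,
        indices=config.indices,
        random_state=config.seed,
    ).fit(feats)
    z = clustering.scaler_.transform(feats)
    zdf = pd.DataFrame(z, columns=list(feature_columns))
    discriminant = BiotypeDiscriminant().fit(zdf, clustering.labels_)
    jackknife = jackknife_accuracy(zdf, clustering.labels_)

    bundle: dict = {
        "cluster_solution": {
            "k": clustering.k_,
            "labels": clustering.labels_.tolist(),
            "index_votes": dict(sorted(clustering.index_votes_.items())),
            "silhouette": clustering.silhouette_,
            "stability_agreement": clustering.stability_agreement_,
        },
        "discriminant": {
            "coefficients": discriminant.coefficients_.to_dict(),
            "coefficients_scaled": discriminant.coefficients_scaled_.to_dict(),
            "scores": discriminant.scores_.tolist(),
            "jackknife_accuracy": jackknife,
        },
    }

    _write_tsv(main_features, out / "features_main.tsv")
    (out / "cluster_solution.json").write_text(
        json.dumps(bundle["cluster_solution"], sort_keys=True, indent=1,
                   default=_json_default)
    )
    (out / "discriminant.json").write_text(
        json.dumps(bundle["discriminant"], sort_keys=True, indent=1,
                   default=_json_default)
    )

    for tag, table in (
        ("replication", replication_features),
        ("controls", control_features),
    ):
        if table is None:
            continue
        proj = project(
            discriminant, table[list(feature_columns)], clustering.scaler_
        )
        proj_df = pd.DataFrame(
            {
                "subject_id": table.get(
                    "subject_id", pd.RangeIndex(len(table)).astype(str)
                ),
                "score": proj["scores"],
                "label": proj["labels"],
            }
        )
        _write_tsv(proj_df, out / f"projection_{tag}.tsv")
        bundle[f"projection_{tag}"] = {
            "mean_score": float(np.mean(proj["scores"])),
            "labels": np.asarray(proj["labels"]).tolist(),
        }

    # Three-group comparisons (clusters vs controls) on each feature.
    if control_features is not None:
        values, groups = [], []
        stacked = []
        for col in feature_columns:
            vals = np.concatenate(
                [feats[col].to_numpy(), control_features[col].to_numpy()]
            )
            grp = np.concatenate(
                [
                    np.array([f"C{l + 1}" for l in clustering.labels_]),
                    np.repeat("HC", len(control_features)),
                ]
            )
            overall, contrasts = anova_bonferroni(
                vals, grp, name=col, family="EEG graph theory parameters"
            )
            stacked.append(overall)
            values.append((col, vals, grp))
        adjust_results(stacked)
        all_feats = pd.concat(
            [feats, control_features[list(feature_columns)]],
            ignore_index=True,
        )
        all_groups = np.concatenate(
            [
                np.array([f"C{l + 1}" for l in clustering.labels_]),
                np.repeat("HC", len(control_features)),
            ]
        )
        table = report_tables(stacked, all_feats, all_groups)
        _write_tsv(table, out / "group_comparisons.tsv", index=True)
        bundle["group_comparisons"] = {
            r.name: {"F": r.statistic, "p_raw": r.p_raw,
                     "p_adjusted": r.p_adjusted}
            for r in stacked
        }

    manifest = {
        "package_version": __version__,
        "config": json.loads(
            json.dumps(dataclasses.asdict(config), default=_json_default)
        ),
        "n_main": int(len(feats)),
        "n_replication": (
            int(len(replication_features))
            if replication_features is not None
            else 0
        ),
        "n_controls": (
            int(len(control_features)) if control_features is not None else 0
        ),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=_json_default)
    )
    bundle["manifest"] = manifest
    return bundle


def simulate_eeg_feature_table(
    n_per_group: int,
    sim_config: SimConfig,
    pipeline_config: PipelineConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate an EEG cohort (two latent subgroups) and reduce each
    subject's recording to the feature row; returns (table, true labels)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for gi, params in enumerate((C1_LIKE, C2_LIKE)):
        for _ in range(n_per_group):
            rec, _truth = simulate_subject(
                sim_config, params, seed=int(rng.integers(2**31))
            )
            row, _ = features_from_recording(rec, pipeline_config)
            rows.append(row)
            labels.append(gi)
    return pd.DataFrame(rows), np.asarray(labels)
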