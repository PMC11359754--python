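"""End-to-end orchestration: simulate/load -> preprocess -> features ->
statistics -> classify -> report.

A :class:`PipelineConfig` mirrors each stage's parameters; unknown keys
are rejected up front and the fully resolved configuration is echoed
into the output directory, so a run is reproducible from its artifacts
alone.  All randomness flows through three named seeds (simulate, ica,
split).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_features, classifier, entropy_features, preprocess, \
    signal_io, stats_analysis, synthetic_eeg, tlx as tlx_mod
from .errors import ConfigError

logger = logging.getLogger("neuroload.pipeline")


def _from_dict(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {where!r}")
    return cls(**data)


@dataclass
class InputSection:
    recording: str | None = None
    events: str | None = None


@dataclass
class FilterSection:
    enabled: bool = True
    low_hz: float = 0.1
    high_hz: float = 40.0
    transition_hz: float = 0.5


@dataclass
class ICASection:
    enabled: bool = True
    seed: int = 0


@dataclass
class EpochSection:
    window_s: float = 2.0
    overlap_frac: float = 0.5


@dataclass
class FeatureSection:
    bins: int = 100
    m: int = 2
    r_frac: float = 0.2
    wavelet: str = "db4"
    target_bandwidth_hz: float = 2.0
    entropy_channels: list[str] | None = None   # None = all channels


@dataclass
class ClassifierSection:
    features: list[str] = field(
        default_factory=lambda: ["beta_ratio", "shannon", "sampen"]
    )
    channels: list[str] = field(default_factory=lambda: ["T7", "T8"])
    n_train: int | None = None          # default: 90% of the pool
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0
    pool_turns: bool = True


@dataclass
class TLXSection:
    responses: str | None = None


@dataclass
class PipelineConfig:
    simulate: dict | None = None        # SyntheticConfig overrides, or None
    input: InputSection = field(default_factory=InputSection)
    filter: FilterSection = field(default_factory=FilterSection)
    ica: ICASection = field(default_factory=ICASection)
    epochs: EpochSection = field(default_factory=EpochSection)
    features: FeatureSection = field(default_factory=FeatureSection)
    classifier: ClassifierSection = field(default_factory=ClassifierSection)
    tlx: TLXSection = field(default_factory=TLXSection)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "input": InputSection, "filter": FilterSection, "ica": ICASection,
            "epochs": EpochSection, "features": FeatureSection,
            "classifier": ClassifierSection, "tlx": TLXSection,
        }
        kwargs: dict = {}
        if "simulate" in data:
            sim = data.pop("simulate")
            if sim is not None:
                valid = {f.name for f in dataclasses.fields(synthetic_eeg.SyntheticConfig)}
                unknown = set(sim) - valid
                if unknown:
                    raise ConfigError(
                        f"unknown key(s) {sorted(unknown)} in section 'simulate'"
                    )
            kwargs["simulate"] = sim
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _from_dict(section_cls, data.pop(name) or {}, name)
        if data:
            raise ConfigError(f"unknown top-level section(s): {sorted(data)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def validate(self) -> None:
        has_input = self.input.recording is not None
        if self.simulate is None and not has_input:
            raise ConfigError("either a 'simulate' section or input.recording is required")
        if has_input and self.input.events is None:
            raise ConfigError("input.recording requires input.events")

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(
                dataclasses.replace(synthetic_eeg.SyntheticConfig(), **self.simulate)
            )
            sim["schedule"] = [list(x) for x in sim["schedule"]]
            out["simulate"] = sim
        return out


def _features_frame(
    summary: band_features.BandEnergySummary,
    entropies: entropy_features.EntropyResult,
) -> pd.DataFrame:
    """One row per epoch x channel: energies, ratios, entropies, phase."""
    rows = []
    ent_idx = {c: j for j, c in enumerate(entropies.channels)}
    for i in range(summary.n_epochs):
        for c, ch in enumerate(summary.channels):
            row = {"epoch": i, "channel": ch, "phase": summary.labels[i]}
            for band in summary.bands.names:
                row[f"E_{band}"] = summary.energies[band][i, c]
                row[f"{band}_ratio"] = summary.ratios[band][i, c]
            row["beta_theta_alpha"] = summary.beta_theta_alpha[i, c]
            j = ent_idx.get(ch)
            row["shannon"] = entropies.shannon[i, j] if j is not None else np.nan
            row["sampen"] = entropies.sampen[i, j] if j is not None else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage and write the artifact set into ``out_dir``.

    Artifacts: clean.edf, events.tsv, features.csv, correlations.csv,
    normality.csv, tlx_scores.csv (when responses are given), report.json,
    report.md, config_resolved.yaml and run.log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("neuroload")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "configuration"
    try:
        (out / "config_resolved.yaml").write_text(
            yaml.safe_dump(config.resolved(), sort_keys=True)
        )

        stage = "acquire"
        if config.simulate is not None:
            rec, events = synthetic_eeg.generate(**config.simulate)
            logger.info("simulated %d channels x %d samples", rec.n_channels, rec.n_samples)
        else:
            rec = signal_io.read_recording(config.input.recording)
            events = signal_io.EventTable.from_tsv(config.input.events)
            logger.info("loaded %s (%d channels, fs=%g)", config.input.recording,
                        rec.n_channels, rec.fs)

        stage = "filter"
        if config.filter.enabled:
            spec = preprocess.FilterSpec(
                low_hz=config.filter.low_hz, high_hz=config.filter.high_hz,
                transition_hz=config.filter.transition_hz,
            )
            rec = preprocess.bandpass_fir(rec, spec)
            logger.info("band-passed %g-%g Hz", spec.low_hz, spec.high_hz)

        stage = "ica"
        if config.ica.enabled:
            ica = preprocess.ica_decompose(rec, seed=config.ica.seed)
            ica = preprocess.flag_artifact_components(ica, rec)
            rec = preprocess.remove_components(ica)
            logger.info("ICA removed %d/%d components", len(ica.flags), ica.n_components)

        signal_io.write_recording(rec, out / "clean.edf")
        events.to_tsv(out / "events.tsv")

        stage = "epochs"
        epochs = signal_io.extract_epochs(
            rec, events, config.epochs.window_s, config.epochs.overlap_frac
        )
        logger.info("%d epochs of %gs", epochs.n_epochs, config.epochs.window_s)

        stage = "features"
        summary = band_features.band_energy_table(
            epochs, wavelet=config.features.wavelet,
            target_bandwidth_hz=config.features.target_bandwidth_hz,
        )
        entropies = entropy_features.entropy_table(
            epochs, bins=config.features.bins, m=config.features.m,
            r_frac=config.features.r_frac,
            channels=config.features.entropy_channels,
        )
        feat = _features_frame(summary, entropies)
        feat.to_csv(out / "features.csv", index=False)

        stage = "statistics"
        corr_frames = []
        for phase in ("turn_left", "turn_right"):
            if (epochs.labels == phase).any():
                cm = stats_analysis.channel_correlation(epochs, phase, band="beta")
                s = cm.mean_abs()
                corr_frames.append(pd.DataFrame(
                    {"phase": phase, "channel": s.index, "mean_abs_r": s.values}
                ))
        if corr_frames:
            pd.concat(corr_frames).to_csv(out / "correlations.csv", index=False)
        present = feat.dropna(subset=["shannon"])
        stats_analysis.feature_correlations(present).to_csv(out / "feature_correlations.csv")
        stats_analysis.normality_check(present).to_csv(out / "normality.csv", index=False)

        stage = "tlx"
        tlx_scores = None
        if config.tlx.responses:
            responses = tlx_mod.read_responses(config.tlx.responses)
            tlx_scores = tlx_mod.score_responses(responses)
            with_stats = tlx_scores.copy()
            with_stats.attrs = tlx_scores.attrs
            with_stats.to_csv(out / "tlx_scores.csv", index=False)
            (out / "tlx_group.json").write_text(json.dumps(
                {"alpha": tlx_scores.attrs["alpha"], "kmo": tlx_scores.attrs["kmo"],
                 "phase_means": tlx_scores.attrs["phase_means"]}, indent=2
            ))

        stage = "classify"
        fm = classifier.build_feature_matrix(
            summary, entropies,
            features=tuple(config.classifier.features),
            channels=tuple(config.classifier.channels),
            pool_turns=config.classifier.pool_turns,
        )
        n_train = config.classifier.n_train or max(int(round(fm.n_rows * 0.9)), 1)
        report = classifier.classify_features(
            fm, n_train=n_train, kernel=config.classifier.kernel,
            C=config.classifier.C, gamma=config.classifier.gamma,
            seed=config.classifier.seed,
        )
        report.to_json(out / "report.json")
        logger.info("accuracy: train %.2f%%, test %.2f%%",
                    report.train_accuracy_pct, report.test_accuracy_pct)

        stage = "report"
        (out / "report.md").write_text(make_report(out))
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _phase_table(feat: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("beta_ratio", "beta_theta_alpha", "shannon", "sampen")
            if c in feat.columns]
    return feat.groupby("phase")[cols].mean()


def make_report(out_dir: str | Path) -> str:
    """Human-readable markdown summary of a pipeline run's artifacts.

    Missing artifacts are listed as absent; the report is always produced.
    """
    out = Path(out_dir)
    lines = ["# Workload pipeline report", ""]

    feat_path = out / "features.csv"
    if feat_path.exists():
        feat = pd.read_csv(feat_path)
        lines += ["## Per-phase feature means", "",
                  _phase_table(feat).to_markdown(), ""]
        beta = feat.groupby(["phase", "channel"])["E_beta"].mean().unstack()
        for phase in ("turn_left", "turn_right"):
            if phase in beta.index:
                lines.append(
                    f"- argmax beta-energy electrode during {phase}: "
                    f"**{beta.loc[phase].idxmax()}**"
                )
        lines.append("")
    else:
        lines += ["## Per-phase feature means", "", "*absent (features.csv missing)*", ""]

    fc_path = out / "feature_correlations.csv"
    if fc_path.exists():
        lines += ["## Entropy x energy-ratio correlations", "",
                  pd.read_csv(fc_path).to_markdown(index=False), ""]
    else:
        lines += ["## Entropy x energy-ratio correlations", "", "*absent*", ""]

    tlx_path = out / "tlx_group.json"
    if tlx_path.exists():
        group = json.loads(tlx_path.read_text())
        lines += ["## NASA-TLX", "",
                  f"- Cronbach's alpha: {group['alpha']:.3f}",
                  f"- KMO: {group['kmo']:.3f}"]
        for phase, mean in sorted(group.get("phase_means", {}).items()):
            lines.append(f"- mean workload, {phase}: {mean:.2f}")
        lines.append("")
    else:
        lines += ["## NASA-TLX", "", "*absent (no questionnaire input)*", ""]

    rep_path = out / "report.json"
    if rep_path.exists():
        rep = json.loads(rep_path.read_text())
        lines += ["## Classifier", "",
                  f"- kernel: {rep['kernel']}",
                  f"- train accuracy: {rep['train_accuracy_pct']:.2f}%",
                  f"- test accuracy: {rep['test_accuracy_pct']:.2f}%",
                  f"- split: {rep['split']['n_train']} train / {rep['split']['n_test']} test",
                  ""]
    else:
        lines += ["## Classifier", "", "*absent (report.json missing)*", ""]

    return "\n".join(lines)
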