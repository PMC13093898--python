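"""End-to-end orchestration: simulate/ingest -> extract -> detect -> QC -> compare.

Every table artifact carries a provenance header (``# patchkit ...``) with the
config hash and seed; reruns with the same configuration are bit-identical at
the table level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epsc import DetectionSettings, KineticCriteria, analyze_sweep
from .passive import (
    PLACEHOLDER_INDEX_CONFIG,
    compute_passive_properties,
    physiology_index,
)
from .qc import QCThresholds, assess_cell_qc, finalize_qc, regular_spiking
from .recording import ProtocolTag, Recording, read_recording, write_recording
from .spikes import (
    SpikeDetectionSettings,
    compute_fi_curve,
    detect_spikes,
    first_spike_features,
    rheobase_and_latency,
)
from .stats import STUDY_ARMS, StatsConfig, build_summary_table, compare_fi_curves
from .synthetic import CohortDesign, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "extract_cell_features",
    "run_pipeline",
    "make_fixtures",
    "SCALAR_FEATURES",
]

#: Scalar features entered into the three-group comparison.
SCALAR_FEATURES = [
    "gain",
    "max_frequency",
    "total_spike_output",
    "rheobase",
    "latency",
    "threshold",
    "amplitude",
    "half_width",
    "max_rise_slope",
    "max_decay_slope",
    "rmp_mV",
    "r_in_MOhm",
    "tc_ms",
    "c_in_pF",
    "sag_ratio",
    "sepsc_frequency",
    "sepsc_amplitude",
    "sepsc_decay_tc",
]


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: str | None = None  # fixture directory; None -> simulate
    output_dir: str = "patchkit_out"
    seed: int = 0
    cells_per_group: int = 12
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    kinetics: KineticCriteria = field(default_factory=KineticCriteria)
    spike_detection: SpikeDetectionSettings = field(default_factory=SpikeDetectionSettings)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    features: pd.DataFrame
    qc: pd.DataFrame
    summary: pd.DataFrame
    fi_comparisons: pd.DataFrame
    events: pd.DataFrame
    output_dir: Path


def extract_cell_features(
    recs: dict[str, Recording],
    config: PipelineConfig | None = None,
) -> dict:
    """One feature row from a cell's four protocol recordings.

    ``recs`` maps protocol tag values to recordings; missing protocols yield
    NaN for the features they carry.
    """
    config = config or PipelineConfig()
    row: dict = {}
    spike_times_supra = np.array([])
    fi = None

    fi_rec = recs.get(ProtocolTag.FI_STEPS.value)
    if fi_rec is not None:
        fi = compute_fi_curve(fi_rec, config.spike_detection)
        row.update(
            gain=fi.gain,
            max_frequency=fi.max_frequency,
            current_at_max=fi.current_at_max,
            total_spike_output=fi.total_spike_output,
            block_detected=fi.block_detected,
        )
        # first spike of the lowest suprathreshold 1-s step
        for sweep in sorted(fi_rec.sweeps, key=lambda s: s.command.amplitude):
            spikes = detect_spikes(sweep, config.spike_detection)
            if spikes:
                feats = first_spike_features(sweep, spikes, config.spike_detection)
                if feats is not None:
                    row.update(
                        threshold=feats.threshold,
                        peak=feats.peak,
                        amplitude=feats.amplitude,
                        half_width=feats.half_width,
                        max_rise_slope=feats.max_rise_slope,
                        max_decay_slope=feats.max_decay_slope,
                    )
                break
        # spike train for the firing-pattern gate: first step with >= 3 spikes
        for sweep in sorted(fi_rec.sweeps, key=lambda s: s.command.amplitude):
            spikes = detect_spikes(sweep, config.spike_detection)
            if len(spikes) >= 3:
                spike_times_supra = np.array([s.threshold_time for s in spikes])
                break

    rheo_rec = recs.get(ProtocolTag.RHEOBASE_STEPS.value)
    if rheo_rec is not None:
        rheo = rheobase_and_latency(rheo_rec, config.spike_detection)
        row.update(rheobase=rheo.rheobase, latency=rheo.latency)

    hyp_rec = recs.get(ProtocolTag.HYPERPOLARIZING_STEPS.value)
    if hyp_rec is not None:
        passive = compute_passive_properties(hyp_rec)
        row.update(
            rmp_mV=passive.rmp,
            r_in_MOhm=passive.r_in,
            tc_ms=passive.tc,
            c_in_pF=passive.c_in,
            sag_ratio=passive.sag_ratio,
        )
        row["physiology_index"] = physiology_index(
            {"sag_ratio": passive.sag_ratio}, PLACEHOLDER_INDEX_CONFIG
        )

    sepsc_rec = recs.get(ProtocolTag.SEPSC.value)
    events_rows = []
    if sepsc_rec is not None:
        freqs, amps, taus, rss, rins = [], [], [], [], []
        for sweep in sepsc_rec.sweeps:
            events, summary, tp = analyze_sweep(sweep, config.detection, config.kinetics)
            freqs.append(summary.frequency)
            if summary.mean_amplitude is not None:
                amps.append(summary.mean_amplitude)
            if summary.decay_tc is not None:
                taus.append(summary.decay_tc)
            rss.append(tp.r_s)
            rins.append(tp.r_in)
            for e in events:
                events_rows.append(
                    {
                        "sweep_index": sweep.sweep_index,
                        "onset_time": e.onset_time,
                        "peak_time": e.peak_time,
                        "baseline_current": e.baseline_current,
                        "amplitude": e.amplitude,
                        "decay_tau": e.decay_tau,
                        "accepted": e.accepted,
                        "rejection_reason": e.rejection_reason,
                    }
                )
        row.update(
            sepsc_frequency=float(np.mean(freqs)),
            sepsc_amplitude=float(np.mean(amps)) if amps else math.nan,
            sepsc_decay_tc=float(np.mean(taus)) if taus else math.nan,
            r_s_MOhm=float(np.mean(rss)),
            r_in_vc_MOhm=float(np.mean(rins)),
        )

    row["_spike_times_supra"] = spike_times_supra
    row["_fi"] = fi
    row["_events"] = events_rows
    return row


def _provenance_header(config: PipelineConfig) -> str:
    return (
        f"# patchkit {__version__} | config_hash={config.content_hash()} "
        f"| seed={config.seed}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write(_provenance_header(config))
        df.to_csv(f, index=False)


def _load_fixture_cohort(input_dir: Path) -> dict[str, dict[str, Recording]]:
    recordings: dict[str, dict[str, Recording]] = {}
    manifests = sorted(input_dir.glob("*.json"))
    manifests = [m for m in manifests if m.name != "ground_truth.json"]
    if not manifests:
        raise FileNotFoundError(f"no fixture manifests found in {input_dir}")
    for m in manifests:
        rec = read_recording(m, format="fixture")
        recordings.setdefault(rec.cell_id, {})[rec.protocol_tag.value] = rec
    return recordings


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/ingest -> extract -> detect -> QC -> compare -> report."""
    out_dir = Path(config.output_dir)

    if config.input_dir is not None:
        input_dir = Path(config.input_dir)
        if not input_dir.is_dir():
            raise FileNotFoundError(f"input directory does not exist: {input_dir}")
        recordings = _load_fixture_cohort(input_dir)
    else:
        design = CohortDesign(cells_per_group=config.cells_per_group, seed=config.seed)
        recordings, _ = generate_cohort(design)

    feature_rows = []
    qc_rows = []
    event_rows = []
    fi_by_cell: dict[str, object] = {}
    for cell_id, recs in sorted(recordings.items()):
        any_rec = next(iter(recs.values()))
        try:
            row = extract_cell_features(recs, config)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for cell {cell_id}: {exc}") from exc
        spike_times = row.pop("_spike_times_supra")
        fi = row.pop("_fi")
        for e in row.pop("_events"):
            event_rows.append({"cell_id": cell_id, **e})
        row = {"cell_id": cell_id, "group": any_rec.group_label.value, **row}
        feature_rows.append(row)
        fi_by_cell[cell_id] = fi

        qc_res = assess_cell_qc(
            cell_id,
            rmp=row.get("rmp_mV", math.nan),
            r_s=row.get("r_s_MOhm", 0.0),
            thresholds=config.qc_thresholds,
        )
        is_rs = regular_spiking(
            spike_times,
            config.qc_thresholds,
            block_detected=bool(fi.block_detected) if fi is not None else False,
        )
        qc_res = finalize_qc(
            qc_res, row.get("physiology_index", 0.0), is_rs, config.qc_thresholds
        )
        qc_rows.append(
            {
                "cell_id": cell_id,
                "group": any_rec.group_label.value,
                "rmp": qc_res.rmp,
                "r_s": qc_res.r_s,
                "physiology_index": qc_res.physiology_index,
                "regular_spiking": qc_res.regular_spiking,
                "passed": qc_res.passed,
                "failed_checks": ";".join(qc_res.failed_checks),
            }
        )

    features = pd.DataFrame(feature_rows)
    qc = pd.DataFrame(qc_rows)
    events = pd.DataFrame(event_rows)

    summary, _ = build_summary_table(features, qc, SCALAR_FEATURES, config.stats)

    # f-I curve permutation contrasts on the shared current grid
    fi_rows = []
    passed_ids = set(qc.loc[qc["passed"], "cell_id"])
    curves_by_group: dict[str, list] = {g: [] for g in STUDY_ARMS}
    grids = set()
    for cell_id, fi in fi_by_cell.items():
        if fi is None or cell_id not in passed_ids:
            continue
        group = features.loc[features["cell_id"] == cell_id, "group"].iloc[0]
        grids.add(tuple(fi.currents))
        curves_by_group[group].append(fi.frequencies)
    if len(grids) == 1 and all(len(v) >= 3 for v in curves_by_group.values()):
        import itertools

        for pair in itertools.combinations(STUDY_ARMS, 2):
            comp = compare_fi_curves(curves_by_group, pair, config.stats)
            fi_rows.append(
                {
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "n_a": comp.n_a,
                    "n_b": comp.n_b,
                    "max_abs_difference_Hz": comp.statistic,
                    "test": comp.test_name,
                    "p_value": comp.p_value,
                    "significant": comp.significant,
                }
            )
    fi_comparisons = pd.DataFrame(fi_rows)

    _write_table(features, out_dir / "features.csv", config)
    _write_table(qc, out_dir / "qc.csv", config)
    _write_table(events, out_dir / "events.csv", config)
    _write_table(summary, out_dir / "comparisons.csv", config)
    _write_table(fi_comparisons, out_dir / "fi_comparisons.csv", config)
    _write_report(out_dir / "report.md", config, features, qc, summary, fi_comparisons)

    return PipelineResult(
        features=features,
        qc=qc,
        summary=summary,
        fi_comparisons=fi_comparisons,
        events=events,
        output_dir=out_dir,
    )


def _write_report(
    path: Path,
    config: PipelineConfig,
    features: pd.DataFrame,
    qc: pd.DataFrame,
    summary: pd.DataFrame,
    fi_comparisons: pd.DataFrame,
) -> None:
    lines = [
        _provenance_header(config).rstrip("\n"),
        "",
        "# Cohort comparison report",
        "",
        f"Cells analysed: {len(features)}; QC-passed: {int(qc['passed'].sum())}.",
        "",
        "f-I curves are compared by a cell-level permutation test on the maximum",
        "absolute pointwise difference of group mean frequencies (design choice:",
        "the original workflow does not name its curve-level test).",
        "",
        "## Pairwise f-I curve contrasts",
        "",
        fi_comparisons.to_markdown(index=False) if len(fi_comparisons) else "(not computed)",
        "",
        "## Scalar feature contrasts (QC-passed cells)",
        "",
        summary.to_markdown(index=False) if len(summary) else "(not computed)",
        "",
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines))


def make_fixtures(scale: str = "tiny", out_dir: str | Path = "fixtures", seed: int = 0) -> Path:
    """Write a packaged fixture cohort (recordings + ground truth) to disk.

    ``tiny`` (3 cells/group, 2 sEPSC sweeps) regenerates in seconds and is
    meant for continuous testing; ``default`` (12 cells/group) matches the
    study-scale cohort.
    """
    if scale == "tiny":
        design = CohortDesign(cells_per_group=3, seed=seed, sepsc_sweeps=2, hyperpol_sweeps=10)
    elif scale == "default":
        design = CohortDesign(cells_per_group=12, seed=seed)
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings, truth = generate_cohort(design)
    for cell_id, recs in recordings.items():
        for tag, rec in recs.items():
            write_recording(rec, out / f"{cell_id}__{tag}.json")
    truth_rows = [
        {
            "cell_id": c.cell_id,
            "group": c.group_label.value,
            "seed": c.seed,
            **{f"membrane_{k}": v for k, v in dataclasses.asdict(c.membrane).items()},
            **{f"synapse_{k}": v for k, v in dataclasses.asdict(c.synapse).items()},
        }
        for c in truth.cells
    ]
    (out / "ground_truth.json").write_text(json.dumps(truth_rows, indent=1))
    return out
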