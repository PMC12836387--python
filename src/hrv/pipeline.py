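"""End-to-end orchestration: per-subject index computation and the paired
Pre/Post comparison, driven by a single run configuration.

A run either analyses existing beat/RR records (``mode: analyze``) or
simulates a paired cohort first (``mode: simulate+analyze``).  Each subject
and condition flows through window selection, NN filtering and every index
module; per-index results are aggregated into exact paired comparisons and a
publication-style results table.  A failing subject is dropped with a logged
reason rather than aborting the whole run — mirroring how a cohort study
handles a subject with missing data — but a comparison needs at least two
complete subjects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frequency import DEFAULT_BAND_EDGES, spectral_indices
from .poincare import sd1_sd2
from .preprocess import filter_nn, read_beats, select_window
from .prsa import PRSAConfig, prsa_indices
from .series import BeatSeries, FilterRules, NNSeries
from .stats import PairedComparison, compare_paired, format_table, results_table
from .synthetic import AutonomicConfig, generate_cohort
from .time_domain import time_domain_indices

log = logging.getLogger("hrv")

#: Units for the results table.  Normalised spectral indices
#: and the Poincare ratios are dimensionless by their defining equations.
INDEX_UNITS = {
    "HR": "bpm", "SDNN": "ms", "RMSSD": "ms",
    "TP": "ms^2", "ULF": "ms^2", "VLF": "ms^2", "LF": "ms^2", "HF": "ms^2",
    "nHF": "", "nLF": "", "LF/HF": "",
    "SD1": "ms", "SD2": "ms", "SD1/SD2": "", "SD2/SD1": "",
    "AC": "ms", "DC": "ms",
}

#: Row order of the results table.
INDEX_ORDER = ("HR", "nHF", "LF/HF", "SDNN", "RMSSD",
               "SD1", "SD2", "SD1/SD2", "SD2/SD1", "AC", "DC")


@dataclass(frozen=True)
class WindowSpec:
    start_clock: str = "00:00"
    end_clock: str = "08:00"
    start_day_index: int = 1
    end_day_index: int = 2
    nightly: bool = False


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate+analyze"          # or "analyze"
    seed: int | None = None
    output_dir: str | None = None
    window: WindowSpec | None = None
    filter_rules: FilterRules = FilterRules()
    fs: float = 4.0
    psd_method: str = "periodogram"
    band_edges: tuple = DEFAULT_BAND_EDGES
    prsa: PRSAConfig = PRSAConfig()
    decimals: int = 2
    spread: str = "iqr"
    # simulate+analyze:
    simulation: AutonomicConfig = AutonomicConfig()
    n_subjects: int = 6
    shift: float = 0.8
    # analyze: list of {"id": ..., "pre": path, "post": path}
    subjects: tuple = ()
    record_start_clock: str = "00:00"

    def __post_init__(self) -> None:
        if self.mode not in ("analyze", "simulate+analyze"):
            raise ValueError("mode must be 'analyze' or 'simulate+analyze'")
        if self.mode == "simulate+analyze" and self.seed is None:
            raise ValueError("simulation mode requires a seed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        for key in ("mode", "seed", "output_dir", "fs", "psd_method", "decimals",
                    "spread", "n_subjects", "shift", "record_start_clock"):
            if key in raw:
                kw[key] = raw[key]
        if raw.get("window"):
            kw["window"] = WindowSpec(**raw["window"])
        if raw.get("filter"):
            kw["filter_rules"] = FilterRules(**raw["filter"])
        if raw.get("band_edges"):
            kw["band_edges"] = tuple(raw["band_edges"])
        if raw.get("prsa"):
            kw["prsa"] = PRSAConfig(**raw["prsa"])
        if raw.get("simulation"):
            kw["simulation"] = AutonomicConfig(**raw["simulation"])
        if raw.get("subjects"):
            kw["subjects"] = tuple(raw["subjects"])
        return cls(**kw)


def compute_indices(nn: NNSeries, config: RunConfig = RunConfig(seed=0)) -> dict[str, float]:
    """All HRV indices for one NN series, keyed by their field names."""
    td = time_domain_indices(nn)
    sp = spectral_indices(nn, fs=config.fs, method=config.psd_method,
                          edges=config.band_edges)
    pc = sd1_sd2(nn)
    dc = prsa_indices(nn, dataclasses.replace(config.prsa, anchor_mode="deceleration"))
    ac = prsa_indices(nn, dataclasses.replace(config.prsa, anchor_mode="acceleration"))
    return {
        "HR": td.mean_hr, "SDNN": td.sdnn, "RMSSD": td.rmssd,
        "TP": sp.tp, "ULF": sp.ulf, "VLF": sp.vlf, "LF": sp.lf, "HF": sp.hf,
        "nHF": sp.n_hf, "nLF": sp.n_lf, "LF/HF": sp.lf_hf,
        "SD1": pc.sd1, "SD2": pc.sd2, "SD1/SD2": pc.sd1_sd2, "SD2/SD1": pc.sd2_sd1,
        "AC": ac.capacity, "DC": dc.capacity,
        "n_intervals": float(td.n_intervals), "n_rejected": float(nn.n_rejected),
    }


def analyze_beats(beats: BeatSeries, config: RunConfig = RunConfig(seed=0)) -> dict[str, float]:
    """Window selection, NN filtering and every index for one record."""
    if config.window is not None:
        w = config.window
        beats = select_window(beats, w.start_clock, w.end_clock,
                              w.start_day_index, w.end_day_index, w.nightly)
        window = (w.start_clock, w.end_clock)
    else:
        window = None
    nn = filter_nn(beats, config.filter_rules, window=window)
    return compute_indices(nn, config)


@dataclass
class RunResult:
    per_subject: pd.DataFrame            # long table: subject, condition, index, value
    comparisons: list[PairedComparison]
    table: pd.DataFrame
    manifest: dict
    failed_subjects: list = field(default_factory=list)


def _load_cohort(config: RunConfig) -> list[tuple[str, BeatSeries, BeatSeries]]:
    if config.mode == "simulate+analyze":
        pairs = generate_cohort(config.simulation, config.shift,
                                config.n_subjects, config.seed)
        return [(f"subject{i + 1}", pre, post) for i, (pre, post) in enumerate(pairs)]
    cohort = []
    for entry in config.subjects:
        pre = read_beats(entry["pre"], entry.get("record_start_clock",
                                                 config.record_start_clock))
        post = read_beats(entry["post"], entry.get("record_start_clock",
                                                   config.record_start_clock))
        cohort.append((str(entry["id"]), pre, post))
    return cohort


def run(config: RunConfig) -> RunResult:
    """Execute a full cohort run and (optionally) write the result bundle."""
    cohort = _load_cohort(config)
    rows, failed = [], []
    for subject_id, pre, post in cohort:
        try:
            for condition, beats in (("pre", pre), ("post", post)):
                for name, value in analyze_beats(beats, config).items():
                    rows.append({"subject": subject_id, "condition": condition,
                                 "index": name, "value": value})
        except Exception as exc:  # noqa: BLE001 - subject-level isolation
            log.warning("subject %s dropped: %s", subject_id, exc)
            failed.append({"subject": subject_id, "reason": str(exc)})
            rows = [r for r in rows if r["subject"] != subject_id]
    per_subject = pd.DataFrame(rows, columns=["subject", "condition", "index", "value"])
    complete = sorted(set(per_subject["subject"])) if len(per_subject) else []
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete subjects: paired comparison aborted")

    comparisons = []
    for name in INDEX_ORDER:
        sub = per_subject[per_subject["index"] == name]
        wide = sub.pivot(index="subject", columns="condition", values="value")
        comparisons.append(compare_paired(name, wide["pre"].to_numpy(),
                                          wide["post"].to_numpy()))
    table = results_table(comparisons, units=INDEX_UNITS,
                          decimals=config.decimals, spread=config.spread)

    manifest = {
        "package_version": __version__,
        "config": _config_echo(config),
        "seed": config.seed,
        "library_versions": {"numpy": np.__version__, "scipy": _scipy_version(),
                             "pandas": pd.__version__},
        "subjects_complete": complete,
        "subjects_failed": failed,
        "n_rejected": {
            f"{r['subject']}/{r['condition']}": r["value"]
            for r in rows if r["index"] == "n_rejected"
        },
    }
    result = RunResult(per_subject=per_subject, comparisons=comparisons,
                       table=table, manifest=manifest, failed_subjects=failed)
    if config.output_dir:
        _write_bundle(result, config)
    return result


def _scipy_version() -> str:
    import scipy

    return scipy.__version__


def _config_echo(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return encode(config)


def _write_bundle(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "results_table.csv", index=False)
    (out / "results_table.txt").write_text(format_table(result.table) + "\n")
    result.per_subject.to_csv(out / "indices_long.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n")
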