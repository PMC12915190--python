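"""File formats, run configuration and the pipeline driver.

Dialects are pinned rather than sniffed: UTF-8, LF, '.' decimal separator,
no quoting. Recording CSV has header ``time_s,f470,f410``; bouts are TSV
``onset_s<TAB>offset_s<TAB>label``; abundance tables are TSV with a
``feature_id`` first column plus a two-column sample->group TSV; gene sets
are GMT (name, source, member ids); edge lists are two-column TSV.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataError, FormatError, ParameterError
from .omics import (
    PRESETS,
    AbundanceTable,
    FeatureStat,
    GeneSet,
    InteractionNetwork,
    classify_features,
    compute_feature_stats,
    summarize_screen,
)
from .photometry import (
    BoutAnnotation,
    EventDetectionParams,
    PeriEventMatrix,
    PhotometryRecording,
    TransientEvent,
    compute_dff,
    detect_events,
    extract_peri_event,
    fit_control_channel,
    mean_peri_event_z,
    summarize_events,
    zscore_trace,
)

log = logging.getLogger("photomics")

RECORDING_HEADER = ["time_s", "f470", "f410"]


# ---------------------------------------------------------------------------
# photometry formats
# ---------------------------------------------------------------------------


def write_photometry_csv(rec: PhotometryRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": rec.time, "f470": rec.f_signal, "f410": rec.f_control}
    )
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_photometry_csv(path: str | Path) -> PhotometryRecording:
    """Parse a recording CSV, enforcing schema and uniform sampling."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != RECORDING_HEADER:
        raise FormatError(
            f"{path}: expected header {','.join(RECORDING_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    for col in RECORDING_HEADER:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(
                f"{path}: column {col} is not numeric "
                "(comma decimal separators are not accepted)"
            )
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise FormatError(f"{path}: needs >= 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.nonzero(dt <= 0)[0][0]) + 2  # 1-based incl. header
        raise FormatError(f"{path}: time not increasing at data row {row}")
    step = float(np.median(dt))
    bad = np.nonzero(np.abs(dt - step) > 1e-6 * step)[0]
    if bad.size:
        raise FormatError(
            f"{path}: non-uniform sampling at data row {int(bad[0]) + 2}"
        )
    return PhotometryRecording(
        time=t,
        f_signal=df["f470"].to_numpy(float),
        f_control=df["f410"].to_numpy(float),
        sampling_rate=1.0 / step,
        label=str(path),
    )


def write_bouts_tsv(bouts: BoutAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset_s\toffset_s\tlabel\n")
        for on, off, lab in bouts.intervals:
            fh.write(f"{on:.12g}\t{off:.12g}\t{lab}\n")


def read_bouts_tsv(
    path: str | Path, session_duration: float | None = None
) -> BoutAnnotation:
    intervals = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["onset_s", "offset_s", "label"]:
            raise FormatError(f"{path}: expected header onset_s/offset_s/label")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                on, off = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric bound") from exc
            if on >= off:
                raise FormatError(
                    f"{path}:{lineno}: onset {on} >= offset {off}"
                )
            intervals.append((on, off, parts[2]))
    if session_duration is None:
        session_duration = max((off for _, off, _ in intervals), default=0.0)
    try:
        return BoutAnnotation(intervals=intervals,
                              session_duration=session_duration)
    except DataError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# omics formats
# ---------------------------------------------------------------------------


def write_abundance_tsv(
    table: AbundanceTable, table_path: str | Path, groups_path: str | Path
) -> None:
    df = pd.DataFrame(table.values, index=table.feature_ids,
                      columns=table.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(table_path, sep="\t", float_format="%.12g", lineterminator="\n")
    with open(groups_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for s in table.sample_ids:
            fh.write(f"{s}\t{table.groups[s]}\n")


def read_table_tsv(
    table_path: str | Path, groups_path: str | Path
) -> AbundanceTable:
    try:
        df = pd.read_csv(table_path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse {table_path}: {exc}") from exc
    if df.index.name != "feature_id":
        raise FormatError(f"{table_path}: first column must be feature_id")
    gdf = pd.read_csv(groups_path, sep="\t")
    if list(gdf.columns) != ["sample_id", "group"]:
        raise FormatError(f"{groups_path}: expected header sample_id/group")
    groups = dict(zip(gdf["sample_id"].astype(str), gdf["group"].astype(str)))
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise FormatError(f"{groups_path}: no group for samples {missing}")
    try:
        return AbundanceTable(
            feature_ids=[str(i) for i in df.index],
            values=df.to_numpy(float),
            sample_ids=[str(c) for c in df.columns],
            groups=groups,
        )
    except DataError as exc:
        raise FormatError(f"{table_path}: {exc}") from exc


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line, ``name<TAB>source<TAB>id1<TAB>id2...``.

    Duplicate member ids within a line are deduplicated with a warning.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, source, >=1 id"
                )
            ids = [p for p in parts[2:] if p]
            uniq = set(ids)
            if len(uniq) < len(ids):
                log.warning("%s:%d: %d duplicate ids dropped",
                            path, lineno, len(ids) - len(uniq))
            sets.append(GeneSet(name=parts[0], ids=frozenset(uniq),
                                source=parts[1]))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source, *sorted(gs.ids)]) + "\n")


def read_edges_tsv(path: str | Path) -> InteractionNetwork:
    """Two-column TSV edge list; duplicates deduplicated with a warning,
    self-loops rejected with the offending line number."""
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            u, v = parts[0], parts[1]
            if lineno == 1 and {u, v} <= {"node_a", "node_b", "source",
                                          "target"}:
                continue  # optional header
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop edge on {u!r}")
            key = (u, v) if u <= v else (v, u)
            if key in edges:
                n_dup += 1
            edges.add(key)
            nodes.update(key)
    if n_dup:
        log.warning("%s: %d duplicate edges deduplicated", path, n_dup)
    return InteractionNetwork(nodes=sorted(nodes), edges=sorted(edges))


def write_edges_tsv(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_a\tnode_b\n")
        for u, v in net.edges:
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def write_events_tsv(events: list[TransientEvent], path: str | Path) -> None:
    """Events TSV; dff is reported both as a ratio and in percent."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset_s\tpeak_s\tend_s\tpeak_amp\tpeak_amp_pct\tauc\t"
                 "tau_s\tr2\n")
        for ev in events:
            tau = f"{ev.decay_tau:.12g}" if ev.decay_tau is not None else "NA"
            r2 = f"{ev.fit_r2:.12g}" if ev.fit_r2 is not None else "NA"
            fh.write(
                f"{ev.onset_t:.12g}\t{ev.peak_t:.12g}\t{ev.end_t:.12g}\t"
                f"{ev.peak_amp:.12g}\t{100 * ev.peak_amp:.12g}\t"
                f"{ev.auc:.12g}\t{tau}\t{r2}\n"
            )


def write_peri_event_csv(m: PeriEventMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        m.values,
        index=[f"{t:.12g}" for t in m.align_times],
        columns=[f"{t:.12g}" for t in m.relative_time],
    )
    df.index.name = "align_time_s"
    df.to_csv(path, float_format="%.12g", lineterminator="\n")


def write_feature_stats_tsv(
    stats: list[FeatureStat], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\tmean_ctrl\tmean_trt\tfc\tp\tp_adj\tcls\n")
        for st in stats:
            fh.write(
                f"{st.feature_id}\t{st.mean_ctrl:.12g}\t{st.mean_trt:.12g}\t"
                f"{st.fc:.12g}\t{st.p:.12g}\t{st.p_adj:.12g}\t"
                f"{st.cls or 'NA'}\n"
            )


def write_json(obj: Any, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_STAGE_KEYS = {
    "simulate_photometry": {"stage", "name", "params", "bouts"},
    "photometry": {"stage", "name", "recording", "bouts", "label", "params",
                   "window_pre", "window_post"},
    "screen": {"stage", "name", "table", "groups", "preset", "p_mode"},
}
_TOP_KEYS = {"seed", "out_dir", "stages", "log_level"}


@dataclass
class RunConfig:
    """Validated pipeline configuration. Unknown keys are rejected."""

    seed: int
    out_dir: Path
    stages: list[dict]
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "stages" not in raw or not raw["stages"]:
            raise ParameterError("config needs a non-empty 'stages' list")
        stages = []
        for i, st in enumerate(raw["stages"]):
            kind = st.get("stage")
            if kind not in _STAGE_KEYS:
                raise ParameterError(
                    f"stage {i}: unknown stage {kind!r} "
                    f"(expected one of {sorted(_STAGE_KEYS)})"
                )
            bad = set(st) - _STAGE_KEYS[kind]
            if bad:
                raise ParameterError(
                    f"stage {i} ({kind}): unknown keys {sorted(bad)}"
                )
            stages.append(dict(st))
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "photomics_out")),
            stages=stages,
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text))
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve(path_str: str, out_dir: Path) -> Path:
    p = Path(path_str)
    if p.exists():
        return p
    alt = out_dir / p
    if alt.exists():
        return alt
    raise ParameterError(f"input path not found: {path_str}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    Outputs land in ``out_dir`` (stage name prefixes). The manifest records
    the package version, timestamp, resolved parameters, input checksums
    and seed; numeric outputs are a pure function of (config, seed).
    """
    from .synthgen import PhotometrySimParams, simulate_bouts, simulate_photometry

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    checksums: dict[str, str] = {}
    resolved: list[dict] = []

    for i, st in enumerate(config.stages):
        kind = st["stage"]
        name = st.get("name", f"{i:02d}_{kind}")
        log.info("stage %s (%s)", name, kind)
        if kind == "simulate_photometry":
            p = dict(st.get("params", {}))
            p.setdefault("seed", config.seed)
            params = PhotometrySimParams(**p)
            rec, truth = simulate_photometry(params)
            write_photometry_csv(rec, out / f"{name}_recording.csv")
            with open(out / f"{name}_truth.tsv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write("onset_s\tamplitude\tdecay_tau_s\n")
                for t0, a in zip(truth.onset_times, truth.amplitudes):
                    fh.write(f"{t0:.12g}\t{a:.12g}\t{truth.decay_tau:.12g}\n")
            if "bouts" in st:
                b = dict(st["bouts"])
                b.setdefault("seed", config.seed)
                b.setdefault("duration", params.duration)
                bouts = simulate_bouts(**b)
                write_bouts_tsv(bouts, out / f"{name}_bouts.tsv")
            resolved.append({"stage": kind, "name": name,
                             "params": vars(params)})
        elif kind == "photometry":
            rec_path = _resolve(st["recording"], out)
            checksums[str(rec_path)] = _sha256(rec_path)
            rec = read_photometry_csv(rec_path)
            params = EventDetectionParams(**st.get("params", {}))
            fit = fit_control_channel(rec)
            trace = compute_dff(rec, fit)
            z = zscore_trace(trace)
            events = detect_events(trace, params)
            summary = summarize_events(events, rec.duration)
            write_events_tsv(events, out / f"{name}_events.tsv")
            summary_obj: dict[str, Any] = {
                "control_fit": {"intercept": fit.intercept,
                                "slope": fit.slope,
                                "residual_rms": fit.residual_rms},
                "events": vars(summary),
            }
            if "bouts" in st:
                bouts_path = _resolve(st["bouts"], out)
                checksums[str(bouts_path)] = _sha256(bouts_path)
                bouts = read_bouts_tsv(bouts_path,
                                       session_duration=rec.duration)
                m = extract_peri_event(
                    z, bouts, st.get("label", "struggle"),
                    st.get("window_pre", 2.0), st.get("window_post", 6.0),
                )
                per_trial, grand = mean_peri_event_z(m)
                write_peri_event_csv(m, out / f"{name}_peri_event.csv")
                summary_obj["peri_event"] = {
                    "n_trials": m.n_trials,
                    "n_dropped": m.n_dropped,
                    "per_trial_mean_z": list(map(float, per_trial)),
                    "grand_mean_z": grand,
                }
            write_json(summary_obj, out / f"{name}_summary.json")
            resolved.append({"stage": kind, "name": name,
                             "params": vars(params)})
        elif kind == "screen":
            table_path = _resolve(st["table"], out)
            groups_path = _resolve(st["groups"], out)
            checksums[str(table_path)] = _sha256(table_path)
            checksums[str(groups_path)] = _sha256(groups_path)
            table = read_table_tsv(table_path, groups_path)
            preset = st.get("preset", "proteomic")
            if preset not in PRESETS:
                raise ParameterError(f"unknown preset {preset!r}")
            thr = PRESETS[preset]
            if "p_mode" in st:
                from .omics import ScreenThresholds

                thr = ScreenThresholds(thr.fc_up, thr.fc_down, thr.alpha,
                                       st["p_mode"])
            stats = classify_features(compute_feature_stats(table), thr)
            summary = summarize_screen(stats)
            write_feature_stats_tsv(stats, out / f"{name}_stats.tsv")
            write_json(vars(summary), out / f"{name}_summary.json")
            resolved.append({"stage": kind, "name": name,
                             "preset": preset, "thresholds": vars(thr)})

    manifest = {
        "package": "photomics",
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": config.seed,
        "stages": resolved,
        "input_checksums": checksums,
    }
    write_json(manifest, out / "manifest.json")
    return manifest
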