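"""Plate-scale orchestration.

Discovers field images by a user-defined filename convention (named
placeholders, e.g. ``{plate}_{well}_f{field}_{channel}``), analyzes
every field with the per-channel pipeline configuration, isolates
per-field failures in a log instead of aborting the plate, and exports
everything as tab-delimited tables:

``fields.tsv``
    one row per field x channel with all primary and derived columns;
``conditions.tsv``
    per (channel, condition) mean / sd / sem of every measurement, with
    NaN exclusion counts;
``failures.tsv``
    one row per unreadable/unanalyzable field;
overlays
    one colour-coded tracing PNG per field under ``overlays/``.

Row order is fixed by sorting on (plate, well, field, channel), so two
runs over the same inputs produce byte-identical tables regardless of
traversal or channel processing order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .derived_stats import MEASUREMENT_NAMES, derive, summarize_condition
from .field_pipeline import (
    FieldReadError,
    PipelineConfig,
    measure_field,
    read_field_image,
)

__all__ = [
    "FieldKey",
    "RunConfig",
    "PlateResult",
    "discover",
    "run_plate",
    "load_run",
]

_IMAGE_EXTENSIONS = (".tif", ".tiff", ".png")
_PLACEHOLDER_RE = re.compile(r"\{(plate|well|field|channel)\}")
UNANNOTATED = "unannotated"


@dataclass(frozen=True, order=True)
class FieldKey:
    plate: str
    well: str
    field: int
    channel: str


@dataclass
class RunConfig:
    """Everything one batch run needs.

    ``pattern`` is a filename stem template with ``{plate}``, ``{well}``,
    ``{field}`` and ``{channel}`` placeholders; it must contain at least
    ``{well}`` and ``{channel}``. ``channel_configs`` maps channel names
    to pipeline configurations; the ``"*"`` entry is the fallback for
    channels without their own.
    """

    input_dir: Path
    output_dir: Path
    pattern: str = "{plate}_{well}_f{field}_{channel}"
    annotations: Path | None = None
    channel_configs: dict[str, PipelineConfig] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.annotations is not None:
            self.annotations = Path(self.annotations)
        names = set(_PLACEHOLDER_RE.findall(self.pattern))
        if not {"well", "channel"} <= names:
            raise ValueError(
                f"filename pattern must capture at least well and channel, got {self.pattern!r}")
        if "*" not in self.channel_configs:
            self.channel_configs = {**self.channel_configs, "*": PipelineConfig()}

    def config_for(self, channel: str) -> PipelineConfig:
        return self.channel_configs.get(channel, self.channel_configs["*"])

    def compiled_pattern(self) -> re.Pattern:
        regex = ""
        pos = 0
        for m in _PLACEHOLDER_RE.finditer(self.pattern):
            regex += re.escape(self.pattern[pos:m.start()])
            group = m.group(1)
            regex += f"(?P<{group}>\\d+)" if group == "field" else f"(?P<{group}>[A-Za-z0-9]+)"
            pos = m.end()
        regex += re.escape(self.pattern[pos:])
        return re.compile(f"^{regex}$")


@dataclass
class PlateResult:
    """All outputs of one batch run, plus where they were written."""

    fields: pd.DataFrame      # one row per measured field x channel
    conditions: pd.DataFrame  # per channel x condition summary rows
    failures: pd.DataFrame    # plate, well, field, channel, path, error
    output_dir: Path

    @property
    def n_measured(self) -> int:
        return len(self.fields)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def discover(cfg: RunConfig) -> tuple[list[tuple[FieldKey, Path]], list[Path]]:
    """Scan the input directory for images matching the filename pattern.

    Returns (matched, unmatched); matched is sorted by FieldKey.
    Raises if the directory is missing or nothing matches (the pattern
    is echoed so misconfiguration is obvious); non-matching image files
    are returned, never silently dropped.
    """
    if not cfg.input_dir.is_dir():
        raise FileNotFoundError(f"input directory {cfg.input_dir} does not exist")
    rx = cfg.compiled_pattern()
    matched: list[tuple[FieldKey, Path]] = []
    unmatched: list[Path] = []
    for path in sorted(cfg.input_dir.iterdir()):
        if path.suffix.lower() not in _IMAGE_EXTENSIONS:
            continue
        m = rx.match(path.stem)
        if not m:
            unmatched.append(path)
            continue
        parts = m.groupdict()
        key = FieldKey(plate=parts.get("plate", "plate"),
                       well=parts["well"],
                       field=int(parts.get("field", 0)),
                       channel=parts["channel"])
        matched.append((key, path))
    if not matched:
        raise FileNotFoundError(
            f"no image in {cfg.input_dir} matches pattern {cfg.pattern!r}")
    matched.sort(key=lambda kp: kp[0])
    return matched, unmatched


def _load_annotations(path: Path | None) -> dict[str, tuple[str, float]]:
    if path is None:
        return {}
    table = pd.read_csv(path, sep="\t", dtype={"well": str})
    if "well" not in table.columns or "condition" not in table.columns:
        raise ValueError(f"annotation table {path} needs 'well' and 'condition' columns")
    out = {}
    for _, row in table.iterrows():
        dose = float(row["dose"]) if "dose" in table.columns and pd.notna(row["dose"]) else 0.0
        out[str(row["well"])] = (str(row["condition"]), dose)
    return out


def run_plate(cfg: RunConfig, write_overlays: bool = True) -> PlateResult:
    """Analyze every discovered field and write all tables.

    Each channel uses its own pipeline configuration (e.g. a
    dendrite-only MAP2 channel next to a pan-neurite TuJ1 channel).
    A field that cannot be read or measured lands in the failure log
    with its identity; the rest of the plate still completes, and
    measured + failed always equals discovered.
    """
    matched, unmatched = discover(cfg)
    out = cfg.output_dir
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    annotations = _load_annotations(cfg.annotations)
    overlay_dir = out / "overlays"
    if write_overlays:
        overlay_dir.mkdir(exist_ok=True)

    rows: list[dict] = []
    failures: list[dict] = []
    for key, path in matched:
        pipe_cfg = cfg.config_for(key.channel)
        condition, dose = annotations.get(key.well, (UNANNOTATED, 0.0))
        try:
            img = read_field_image(path)
            seg, fm = measure_field(img, pipe_cfg)
            dm = derive(fm, pipe_cfg)
        except (FieldReadError, ValueError, OSError) as exc:
            failures.append({"plate": key.plate, "well": key.well, "field": key.field,
                             "channel": key.channel, "path": path.name, "error": str(exc)})
            continue
        overlay_name = ""
        if write_overlays:
            from PIL import Image

            overlay_name = f"{key.plate}_{key.well}_f{key.field}_{key.channel}_overlay.png"
            Image.fromarray(seg.overlay).save(overlay_dir / overlay_name)
        row = {"plate": key.plate, "well": key.well, "field": key.field,
               "channel": key.channel, "condition": condition, "dose": dose,
               "image": path.name, "overlay": overlay_name}
        for name in MEASUREMENT_NAMES:
            source = fm if hasattr(fm, name) else dm
            row[name] = getattr(source, name)
        row["low_content"] = dm.low_content
        rows.append(row)

    fields_df = pd.DataFrame(rows)
    failures_df = pd.DataFrame(failures,
                               columns=["plate", "well", "field", "channel", "path", "error"])

    cond_rows: list[dict] = []
    if len(fields_df):
        for (channel, condition), group in sorted(
                fields_df.groupby(["channel", "condition"], sort=True).groups.items()):
            sub = fields_df.loc[group]
            summary = summarize_condition(condition, sub[list(MEASUREMENT_NAMES)].to_dict("records"))
            for name in MEASUREMENT_NAMES:
                st = summary.stats[name]
                cond_rows.append({"channel": channel, "condition": condition,
                                  "measurement": name, "n_fields": summary.n_fields,
                                  "n_used": st.n_used, "n_excluded": st.n_excluded,
                                  "mean": st.mean, "sd": st.sd, "sem": st.sem})
    conditions_df = pd.DataFrame(cond_rows, columns=["channel", "condition", "measurement",
                                                     "n_fields", "n_used", "n_excluded",
                                                     "mean", "sd", "sem"])

    fields_df.to_csv(out / "fields.tsv", sep="\t", index=False, float_format="%.6g")
    conditions_df.to_csv(out / "conditions.tsv", sep="\t", index=False, float_format="%.6g")
    failures_df.to_csv(out / "failures.tsv", sep="\t", index=False)
    if unmatched:
        (out / "unmatched.txt").write_text("\n".join(p.name for p in unmatched) + "\n")

    assert len(fields_df) + len(failures_df) == len(matched)
    return PlateResult(fields=fields_df, conditions=conditions_df,
                       failures=failures_df, output_dir=out)


def load_run(run_dir: str | Path) -> PlateResult:
    """Reload a finished run's tables from disk (for reporting)."""
    run_dir = Path(run_dir)
    fields = pd.read_csv(run_dir / "fields.tsv", sep="\t",
                         dtype={"well": str, "plate": str, "channel": str})
    conditions = pd.read_csv(run_dir / "conditions.tsv", sep="\t")
    fail_path = run_dir / "failures.tsv"
    if fail_path.exists() and fail_path.stat().st_size > 0:
        failures = pd.read_csv(fail_path, sep="\t", dtype={"well": str})
        if failures.empty:
            failures = pd.DataFrame(columns=["plate", "well", "field", "channel", "path", "error"])
    else:
        failures = pd.DataFrame(columns=["plate", "well", "field", "channel", "path", "error"])
    return PlateResult(fields=fields, conditions=conditions, failures=failures,
                       output_dir=run_dir)
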