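"""Review surface: plate heatmaps, scatter plots and a static HTML browser.

Heatmap colour rule: each well's value is normalized against the plate
mean so that 0 maps to black, the plate average to grey 128 and twice
the average (or more) to white 255; three measurements are packed into
the red, green and blue channels of one plate-layout image. A
tab-delimited audit table stores the raw and normalized value behind
every cell, and the rendered pixels are exactly reproducible from it.

The browser is a self-contained static site (openable from disk, no
server): an index with heatmaps and well links, per-well pages showing
downscaled raw images next to the colour-coded tracings, an SVG scatter
page with hover tooltips, and links to the exported tables. No
timestamps are embedded, so rebuilding from identical inputs gives a
byte-identical site.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .batch_io import UNANNOTATED, PlateResult
from .derived_stats import MEASUREMENT_NAMES

__all__ = [
    "HeatmapSpec",
    "BrowserManifest",
    "normalize_channel_value",
    "render_heatmap",
    "build_browser",
]

CELL = 26          # heatmap cell size in pixels
GAP = 2            # separator between cells
MISSING_RGB = (70, 0, 90)   # sentinel for wells without data
_WELL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


@dataclass(frozen=True)
class HeatmapSpec:
    """Three measurements packed into RGB for one stain channel."""

    red: str = "total_neurite_length"
    green: str = "total_soma_area"
    blue: str = "mean_intensity"
    channel: str = "TuJ1"

    @property
    def measurements(self) -> tuple[str, str, str]:
        return (self.red, self.green, self.blue)


@dataclass
class BrowserManifest:
    root: Path
    pages: list[str] = dc_field(default_factory=list)
    links: list[str] = dc_field(default_factory=list)


def normalize_channel_value(v: float, plate_mean: float) -> int:
    """Map a measurement value to a 0-255 grey level.

    0 -> 0 (black), plate mean -> 128 (grey), >= 2x plate mean -> 255
    (white); linear and monotone in between.
    """
    if plate_mean <= 0:
        raise ValueError("plate mean must be positive")
    return int(np.clip(round(128.0 * v / plate_mean), 0, 255))


def _split_well(well: str) -> tuple[str, int]:
    m = _WELL_RE.match(str(well))
    if not m:
        raise ValueError(f"cannot parse well name {well!r} (expected e.g. 'B07')")
    return m.group(1).upper(), int(m.group(2))


def render_heatmap(result: PlateResult, spec: HeatmapSpec
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one plate heatmap plus its audit table.

    Wells are averaged over their fields before normalization; the
    plate mean for each measurement is taken over annotated wells only
    (all wells if nothing is annotated), so sentinel/empty wells do not
    crush the dynamic range. A measurement whose plate mean is not
    positive renders its channel all black and is flagged in the audit
    table.
    """
    for name in spec.measurements:
        if name not in MEASUREMENT_NAMES:
            raise ValueError(
                f"unknown measurement {name!r}; valid names: {', '.join(MEASUREMENT_NAMES)}")
    sub = result.fields[result.fields["channel"] == spec.channel]
    if sub.empty:
        raise ValueError(f"channel {spec.channel!r} not present in this run")

    per_well = sub.groupby("well")[list(spec.measurements)].mean()
    conditions = sub.groupby("well")["condition"].first()
    annotated = conditions[conditions != UNANNOTATED].index
    norm_base = per_well.loc[per_well.index.intersection(annotated)]
    if norm_base.empty:
        norm_base = per_well

    plate_means: dict[str, float] = {}
    flagged: dict[str, bool] = {}
    for name in spec.measurements:
        mean = float(np.nanmean(norm_base[name].to_numpy()))
        ok = np.isfinite(mean) and mean > 0
        plate_means[name] = mean if ok else 0.0
        flagged[name] = not ok

    rows = sorted({_split_well(w)[0] for w in per_well.index})
    cols = sorted({_split_well(w)[1] for w in per_well.index})
    row_pos = {r: i for i, r in enumerate(rows)}
    col_pos = {c: i for i, c in enumerate(cols)}

    h = len(rows) * (CELL + GAP) + GAP
    w = len(cols) * (CELL + GAP) + GAP
    img = np.full((h, w, 3), 30, dtype=np.uint8)

    audit_rows = []
    present = set(per_well.index)
    for r in rows:
        for c in cols:
            well = f"{r}{c:02d}"
            alt = f"{r}{c}"
            key = well if well in present else (alt if alt in present else None)
            y = GAP + row_pos[r] * (CELL + GAP)
            x = GAP + col_pos[c] * (CELL + GAP)
            if key is None:
                rgb = MISSING_RGB
                raw = [np.nan] * 3
                norm = list(MISSING_RGB)
            else:
                raw, norm = [], []
                for name in spec.measurements:
                    v = float(per_well.loc[key, name])
                    raw.append(v)
                    if flagged[name] or not np.isfinite(v):
                        norm.append(0)
                    else:
                        norm.append(normalize_channel_value(v, plate_means[name]))
                rgb = tuple(norm)
            img[y:y + CELL, x:x + CELL] = rgb
            audit_rows.append({
                "well": well, "present": key is not None,
                "raw_red": raw[0], "raw_green": raw[1], "raw_blue": raw[2],
                "norm_red": rgb[0], "norm_green": rgb[1], "norm_blue": rgb[2],
                "plate_mean_red": plate_means[spec.red],
                "plate_mean_green": plate_means[spec.green],
                "plate_mean_blue": plate_means[spec.blue],
                "flagged_red": flagged[spec.red],
                "flagged_green": flagged[spec.green],
                "flagged_blue": flagged[spec.blue],
            })
    return img, pd.DataFrame(audit_rows)


# ---------------------------------------------------------------------------
# static browser


def _thumbnail(src: Path, dest: Path, max_dim: int = 512) -> bool:
    from PIL import Image

    try:
        with Image.open(src) as im:
            arr = np.asarray(im)
    except OSError:
        return False
    if arr.ndim == 2:  # scale 8/16-bit grey to full 8-bit range
        arr = arr.astype(np.float64)
        hi = max(float(arr.max()), 1.0)
        arr = (arr / hi * 255.0).astype(np.uint8)
    im8 = Image.fromarray(arr)
    im8.thumbnail((max_dim, max_dim))
    dest.parent.mkdir(parents=True, exist_ok=True)
    im8.save(dest)
    return True


_PALETTE = ["#1b6ca8", "#c23b22", "#2e8540", "#8a4f9e", "#b8860b",
            "#00838f", "#aa3377", "#556b2f"]


def _svg_scatter(df: pd.DataFrame, x: str, y: str, size: int = 520) -> str:
    """Inline-SVG scatter of two measurements, points coloured by
    condition with hover tooltips (pure markup, no scripts)."""
    pad = 60
    data = df[np.isfinite(df[x]) & np.isfinite(df[y])]
    parts = [f'<svg width="{size + 2 * pad}" height="{size + 2 * pad}" '
             f'xmlns="http://www.w3.org/2000/svg" style="background:#fff">']
    if data.empty:
        parts.append(f'<text x="{pad}" y="{pad}">no finite data</text></svg>')
        return "\n".join(parts)
    x0, x1 = float(data[x].min()), float(data[x].max())
    y0, y1 = float(data[y].min()), float(data[y].max())
    xr = (x1 - x0) or 1.0
    yr = (y1 - y0) or 1.0

    def sx(v: float) -> float:
        return pad + (v - x0) / xr * size

    def sy(v: float) -> float:
        return pad + size - (v - y0) / yr * size

    parts.append(f'<rect x="{pad}" y="{pad}" width="{size}" height="{size}" '
                 'fill="none" stroke="#888"/>')
    for i in range(5):
        vx = x0 + xr * i / 4
        vy = y0 + yr * i / 4
        parts.append(f'<text x="{sx(vx):.1f}" y="{pad + size + 18}" font-size="11" '
                     f'text-anchor="middle">{vx:.4g}</text>')
        parts.append(f'<text x="{pad - 6}" y="{sy(vy):.1f}" font-size="11" '
                     f'text-anchor="end">{vy:.4g}</text>')
    parts.append(f'<text x="{pad + size / 2:.0f}" y="{pad + size + 40}" font-size="13" '
                 f'text-anchor="middle">{_html.escape(x)}</text>')
    parts.append(f'<text x="16" y="{pad + size / 2:.0f}" font-size="13" text-anchor="middle" '
                 f'transform="rotate(-90 16 {pad + size / 2:.0f})">{_html.escape(y)}</text>')

    conditions = sorted(data["condition"].astype(str).unique())
    colour = {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(conditions)}
    for _, row in data.iterrows():
        tip = (f"{row['plate']} {row['well']} f{row['field']} {row['channel']} "
               f"[{row['condition']}]: {x}={row[x]:.4g}, {y}={row[y]:.4g}")
        parts.append(
            f'<circle cx="{sx(float(row[x])):.1f}" cy="{sy(float(row[y])):.1f}" r="4" '
            f'fill="{colour[str(row["condition"])]}" fill-opacity="0.75">'
            f'<title>{_html.escape(tip)}</title></circle>')
    for i, c in enumerate(conditions):
        yy = pad + 14 + 16 * i
        parts.append(f'<circle cx="{pad + size - 120}" cy="{yy}" r="5" fill="{colour[c]}"/>')
        parts.append(f'<text x="{pad + size - 110}" y="{yy + 4}" font-size="12">'
                     f'{_html.escape(c)}</text>')
    parts.append("</svg>")
    return "\n".join(parts)


def _page(title: str, body: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{_html.escape(title)}</title>"
        "<style>body{font-family:sans-serif;margin:2em;background:#fafafa}"
        "table{border-collapse:collapse}td,th{border:1px solid #bbb;padding:3px 8px;"
        "font-size:13px}img{image-rendering:pixelated}"
        ".thumb{image-rendering:auto;border:1px solid #999;margin:4px}"
        "a{color:#1b6ca8}</style></head>\n"
        f"<body><h1>{_html.escape(title)}</h1>\n{body}\n</body></html>\n")


def build_browser(result: PlateResult, specs: list[HeatmapSpec] | None = None, *,
                  input_dir: str | Path | None = None,
                  scatter: tuple[str, str] = ("total_neurite_length", "total_soma_area"),
                  title: str = "plate analysis") -> BrowserManifest:
    """Write the static review site under ``<run dir>/report/``.

    ``input_dir`` locates the raw images for thumbnailing; without it
    (or for any unreadable image) a placeholder note is shown and the
    build continues. Returns a manifest of pages and link targets, all
    relative to the run directory.
    """
    run_dir = result.output_dir
    report = run_dir / "report"
    report.mkdir(parents=True, exist_ok=True)
    (report / "wells").mkdir(exist_ok=True)
    manifest = BrowserManifest(root=run_dir)
    fields = result.fields
    if specs is None:
        channels = sorted(fields["channel"].astype(str).unique()) if len(fields) else []
        specs = [HeatmapSpec(channel=c) for c in channels]

    # heatmaps + audit tables
    heat_html = []
    from PIL import Image

    for i, spec in enumerate(specs):
        img, audit = render_heatmap(result, spec)
        png = f"heatmap_{i}_{spec.channel}.png"
        tsv = f"heatmap_{i}_{spec.channel}.tsv"
        Image.fromarray(img).save(report / png)
        audit.to_csv(report / tsv, sep="\t", index=False, float_format="%.6g")
        manifest.links += [f"report/{png}", f"report/{tsv}"]
        heat_html.append(
            f"<h3>{spec.channel}: R={spec.red}, G={spec.green}, B={spec.blue}</h3>"
            f"<img src='{png}' alt='heatmap {spec.channel}' width='{img.shape[1] * 3}'>"
            f"<p><a href='{tsv}'>audit table</a></p>")

    # per-well pages
    wells = sorted({(str(r.plate), str(r.well)) for r in fields.itertuples()} |
                   {(str(r.plate), str(r.well)) for r in result.failures.itertuples()})
    well_links = []
    for plate, well in wells:
        page_name = f"wells/{plate}_{well}.html"
        body = []
        sub = fields[(fields["plate"].astype(str) == plate) & (fields["well"].astype(str) == well)]
        for row in sub.itertuples():
            body.append(f"<h3>field {row.field} — {row.channel} ({row.condition})</h3>")
            imgs = []
            if input_dir is not None and row.image:
                src = Path(input_dir) / str(row.image)
                thumb = f"thumbs/{Path(str(row.image)).stem}.png"
                if _thumbnail(src, report / thumb):
                    imgs.append(f"<img class='thumb' src='../{thumb}' alt='raw'>")
                    manifest.links.append(f"report/{thumb}")
            if row.overlay:
                ov = run_dir / "overlays" / str(row.overlay)
                thumb = f"thumbs/{Path(str(row.overlay)).stem}.png"
                if ov.exists() and _thumbnail(ov, report / thumb):
                    imgs.append(f"<img class='thumb' src='../{thumb}' alt='tracing'>")
                    manifest.links.append(f"report/{thumb}")
            body.append("".join(imgs) or "<p><em>no images available</em></p>")
            cells = "".join(f"<tr><th>{m}</th><td>{getattr(row, m):.6g}</td></tr>"
                            for m in MEASUREMENT_NAMES)
            body.append(f"<table>{cells}</table>")
        fail_sub = result.failures[(result.failures["well"].astype(str) == well)]
        for frow in fail_sub.itertuples():
            body.append(f"<p><strong>FAILED</strong> field {frow.field} {frow.channel}: "
                        f"{_html.escape(str(frow.error))}</p>")
        if not len(sub) and not len(fail_sub):
            body.append("<p><em>no data for this well</em></p>")
        body.append("<p><a href='../index.html'>back to index</a></p>")
        (report / page_name).write_text(_page(f"{plate} / {well}", "\n".join(body)))
        manifest.pages.append(f"report/{page_name}")
        well_links.append(f"<a href='{page_name}'>{plate} {well}</a>")

    # scatter page
    if len(fields):
        scatter_body = _svg_scatter(fields, scatter[0], scatter[1])
        (report / "scatter.html").write_text(_page(f"{scatter[0]} vs {scatter[1]}",
                                                   scatter_body +
                                                   "<p><a href='index.html'>back</a></p>"))
        manifest.pages.append("report/scatter.html")

    # index
    n_total = len(fields) + len(result.failures)
    index_body = [
        f"<p>{len(fields)} field measurements, {len(result.failures)} failures "
        f"({n_total} fields total).</p>",
        "<p>Tables: <a href='../fields.tsv'>fields.tsv</a> · "
        "<a href='../conditions.tsv'>conditions.tsv</a> · "
        "<a href='../failures.tsv'>failures.tsv</a></p>",
    ]
    if len(fields):
        index_body.append("<p><a href='scatter.html'>scatter plot</a></p>")
    index_body += heat_html
    index_body.append("<h3>Wells</h3><p>" + " · ".join(well_links) + "</p>")
    (report / "index.html").write_text(_page(title, "\n".join(index_body)))
    manifest.pages.insert(0, "report/index.html")
    manifest.links += ["fields.tsv", "conditions.tsv", "failures.tsv"]
    return manifest
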