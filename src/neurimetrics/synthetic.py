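"""Synthetic neuron-culture fields with exact morphological ground truth.

Renders greyscale micrograph look-alikes — anti-aliased disk somata plus
polyline neurites of ~2 px width, additively composed, Gaussian-blurred
and noised — while recording everything the measurement pipeline is
supposed to recover: outside-soma arc length per neurite, tip, root
(attachment) and junction coordinates, and soma footprints.

Geometry choices that make the ground truth meaningful:

* Neurite headings are biased toward the image axes (a compass base
  direction with bounded +/-15 degree jitter), so the skeleton pixel
  count — the pipeline's raw length metric — tracks true arc length to
  within a few percent. Free-direction paths would undercount by up to
  30 % on diagonals, which is a property of the pixel-count metric, not
  of the generator.
* Each neuron owns a disjoint territory (jittered grid placement), so
  ``clean`` fields contain no crossings and counts are exactly
  recoverable. ``overlap`` fields deliberately add unattached neurites
  crossing somata and interrupted (fragmented) neurites — the
  documented failure modes. ``debris`` fields sprinkle sub-threshold
  bright specks that size filtering must ignore.
* Neurites are drawn from the soma *centre* outward (the marker fills
  the cell), so the fibre mask continues into the cell body and the
  neurite root is not a free skeleton end — exactly the situation the
  endpoint/attachment steps of the pipeline assume.

A single integer seed drives every stochastic choice; the same seed
gives a bit-identical image and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .morphology import GreyImage

__all__ = [
    "RenderParams",
    "SyntheticNeuron",
    "FieldGroundTruth",
    "WellSpec",
    "generate_field",
    "generate_plate",
    "two_condition_layout",
    "dose_series_layout",
    "DEFAULT_FILENAME_PATTERN",
]

DEFAULT_FILENAME_PATTERN = "{plate}_{well}_f{field}_{channel}"

_COMPASS = np.array([0.0, 90.0, 180.0, 270.0])  # degrees


@dataclass(frozen=True)
class RenderParams:
    """Photometric rendering conditions (16-bit, ~10x magnification analogue)."""

    shape: tuple[int, int] = (1024, 1024)
    background: float = 200.0
    soma_amplitude: float = 1600.0
    neurite_amplitude: float = 1000.0
    neurite_width: float = 2.2
    soma_edge_width: float = 3.5
    blur_sigma: float = 0.8
    noise_sd: float = 25.0
    bit_depth: int = 16


@dataclass
class SyntheticNeuron:
    soma_center: tuple[float, float]          # (row, col)
    soma_radius: float
    render_paths: list[np.ndarray] = field(default_factory=list)   # polylines actually drawn
    neurite_lengths: list[float] = field(default_factory=list)     # outside-soma arc per drawn path
    junctions: list[tuple[float, float]] = field(default_factory=list)
    tips: list[tuple[float, float]] = field(default_factory=list)  # biological terminal tips
    n_roots: int = 0                          # attached primary neurites
    kind: str = "neuron"                      # neuron | crosser | fragmented

    @property
    def total_length(self) -> float:
        return float(sum(self.neurite_lengths))

    @property
    def soma_area(self) -> float:
        return math.pi * self.soma_radius**2


@dataclass
class FieldGroundTruth:
    neurons: list[SyntheticNeuron]
    total_true_length: float
    total_true_soma_area: float
    true_tip_count: int
    true_attachment_count: int
    true_junction_count: int
    render_params: RenderParams
    seed: int
    difficulty: str


def _unit(heading_deg: float) -> np.ndarray:
    rad = math.radians(heading_deg)
    return np.array([math.sin(rad), math.cos(rad)])  # (drow, dcol)


def _grow_path(rng: np.random.Generator, start: np.ndarray, base_heading: float,
               target_len: float, center: np.ndarray, max_extent: float,
               shape: tuple[int, int], margin: float,
               keepout: float = 0.0) -> tuple[np.ndarray, float]:
    """Grow a jittered near-axis polyline from ``start``; returns (vertices, arc length).

    Stops early if the path would leave its territory or the image
    margin, so the recorded arc length is always the achieved one.
    """
    heading = base_heading + rng.uniform(-12.0, 12.0)
    pts = [start.astype(float)]
    arc = 0.0
    step = 5.0
    while arc < target_len - 1e-9:
        heading += rng.normal(0.0, 5.0)
        heading = base_heading + float(np.clip(heading - base_heading, -15.0, 15.0))
        this_step = min(step, target_len - arc)
        nxt = pts[-1] + this_step * _unit(heading)
        radial = np.linalg.norm(nxt - center)
        if (radial > max_extent or radial < keepout
                or nxt[0] < margin or nxt[1] < margin
                or nxt[0] > shape[0] - margin or nxt[1] > shape[1] - margin):
            break
        pts.append(nxt)
        arc += this_step
    return np.asarray(pts), arc


def _densify(poly: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly uniform sub-pixel spacing."""
    out = [poly[:1]]
    for a, b in zip(poly[:-1], poly[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(math.ceil(seg / spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a[None, :] + t * (b - a)[None, :])
    return np.concatenate(out, axis=0)


def _arc_outside_somata(dense: np.ndarray, somata: list[tuple[np.ndarray, float]]) -> float:
    """Arc length of a densified polyline outside all soma disks."""
    steps = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    mid = 0.5 * (dense[:-1] + dense[1:])
    outside = np.ones(len(mid), dtype=bool)
    for c, r in somata:
        outside &= np.linalg.norm(mid - c[None, :], axis=1) > r
    return float(steps[outside].sum())


def _grid_centers(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  margin: float) -> tuple[np.ndarray, float]:
    """Jittered-grid soma centres with a guaranteed per-neuron territory radius."""
    if n == 0:
        return np.empty((0, 2)), 0.0
    g = max(int(math.ceil(math.sqrt(n))), 1)
    cell_h = (shape[0] - 2 * margin) / g
    cell_w = (shape[1] - 2 * margin) / g
    cells = rng.permutation(g * g)[:n]
    jitter = 0.10
    centers = []
    for idx in cells:
        r, c = divmod(int(idx), g)
        cy = margin + (r + 0.5) * cell_h + rng.uniform(-jitter, jitter) * cell_h
        cx = margin + (c + 0.5) * cell_w + rng.uniform(-jitter, jitter) * cell_w
        centers.append((cy, cx))
    # territories must stay disjoint even for maximally jittered neighbours
    territory = (0.5 - jitter) * min(cell_h, cell_w) * 0.94
    return np.asarray(centers), territory


def _draw_disk(layer: np.ndarray, center: np.ndarray, radius: float, amp: float,
               edge_width: float = 1.0) -> None:
    """Disk with intensity ramping from full to zero over ``edge_width``
    pixels, half-intensity exactly at ``radius`` (so the half-max
    footprint area is the nominal pi r^2)."""
    pad = edge_width / 2 + 2
    r0 = max(int(center[0] - radius - pad), 0)
    r1 = min(int(center[0] + radius + pad + 1), layer.shape[0])
    c0 = max(int(center[1] - radius - pad), 0)
    c1 = min(int(center[1] + radius + pad + 1), layer.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - center[0], cc - center[1])
    cov = np.clip((radius + edge_width / 2 - dist) / edge_width, 0.0, 1.0)
    layer[r0:r1, c0:c1] = np.maximum(layer[r0:r1, c0:c1], amp * cov)


def _draw_path(layer: np.ndarray, dense: np.ndarray, width: float, amp: float) -> None:
    """Max-composite an anti-aliased tube of given width along a dense polyline."""
    pad = width / 2 + 2.5
    r0 = max(int(dense[:, 0].min() - pad), 0)
    r1 = min(int(dense[:, 0].max() + pad) + 1, layer.shape[0])
    c0 = max(int(dense[:, 1].min() - pad), 0)
    c1 = min(int(dense[:, 1].max() + pad) + 1, layer.shape[1])
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, _ = cKDTree(dense).query(pix, k=1, distance_upper_bound=pad)
    dist = dist.reshape(rr.shape)
    cov = np.clip(width / 2 + 0.5 - dist, 0.0, 1.0)
    sub = layer[r0:r1, c0:c1]
    np.maximum(sub, amp * cov, out=sub)


def _build_neuron(rng: np.random.Generator, center: np.ndarray, territory: float,
                  shape: tuple[int, int], margin: float,
                  neurite_length_range: tuple[float, float],
                  neurites_per_neuron: tuple[int, int],
                  branch_prob: float,
                  soma_r: float,
                  targets: list[float] | None = None,
                  reserved_dirs: tuple[int, ...] = ()) -> SyntheticNeuron:
    neuron = SyntheticNeuron(soma_center=(float(center[0]), float(center[1])),
                             soma_radius=soma_r)
    max_extent = territory
    cap = max_extent - soma_r - 4.0
    if cap < 18.0:
        return neuron  # territory too small for neurites; soma only

    if targets is None:
        k_lo, k_hi = neurites_per_neuron
        k = int(rng.integers(k_lo, k_hi + 1))
        targets = [float(np.clip(rng.uniform(*neurite_length_range), 18.0, cap))
                   for _ in range(k)]
    avail = [d for d in range(4) if d not in reserved_dirs]
    rng.shuffle(avail)
    used: list[int] = []
    primary: list[tuple[np.ndarray, float, float]] = []  # (counted path, arc, base heading)

    for d, target in zip(avail, targets[:len(avail)]):
        base = float(_COMPASS[d])
        target = float(np.clip(target, 18.0, cap))
        start = center + soma_r * _unit(base)
        path, arc = _grow_path(rng, start, base, target, center, max_extent, shape, margin)
        if arc < 15.0:
            continue
        used.append(d)
        full = np.vstack([center[None, :], path])  # drawn from the soma centre
        neuron.render_paths.append(full)
        primary.append((path, arc, base))
        neuron.tips.append(tuple(path[-1]))
    neuron.n_roots = len(primary)

    # one optional side branch, grown into a compass direction no sibling uses
    free = [d for d in range(4) if d not in used and d not in reserved_dirs]
    if primary and free and rng.random() < branch_prob:
        idx = int(rng.integers(len(primary)))
        path, arc, base = primary[idx]
        if arc >= 40.0:
            seglen = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))]
            t = rng.uniform(0.40, 0.65) * arc
            vi = int(np.searchsorted(seglen, t))
            vi = min(max(vi, 1), len(path) - 3)
            bp = path[vi]
            parent_dir = int(np.argmin(np.abs(((_COMPASS - base) + 180) % 360 - 180)))
            # only branch sideways, never back toward (and across) the soma
            side = [d for d in free if (d - parent_dir) % 2 == 1]
            if not side:
                return neuron
            child_base = float(_COMPASS[side[int(rng.integers(len(side)))]])
            child_target = float(np.clip(rng.uniform(25.0, 60.0), 18.0, cap))
            child, child_arc = _grow_path(rng, bp, child_base, child_target,
                                          center, max_extent, shape, margin,
                                          keepout=soma_r + 6.0)
            if child_arc >= 15.0 and all(
                    np.linalg.norm(child[-1] - np.asarray(tp)) >= 8.0 for tp in neuron.tips):
                neuron.render_paths.append(child)
                neuron.junctions.append(tuple(bp))
                neuron.tips.append(tuple(child[-1]))
    return neuron


def generate_field(n_neurons: int, difficulty: str = "clean", seed: int = 0, *,
                   render: RenderParams | None = None,
                   neurite_length_range: tuple[float, float] = (45.0, 160.0),
                   neurites_per_neuron: tuple[int, int] = (1, 3),
                   branch_prob: float = 0.6,
                   total_length_target: float | None = None,
                   ) -> tuple[GreyImage, FieldGroundTruth]:
    """Render one synthetic field and its exact ground truth.

    ``difficulty``: ``clean`` (disjoint, fully recoverable), ``overlap``
    (adds soma-crossing unattached neurites and interrupted neurites),
    ``debris`` (clean plus sub-size bright specks).

    ``total_length_target`` switches to budget-driven geometry: neurite
    length targets are allocated round-robin across neurons (up to
    three unbranched primaries each) until the requested total
    outside-soma arc length is spent, so the achieved total lands close
    to the request. The recorded truth is always the achieved geometry,
    never the request.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    if difficulty not in ("clean", "overlap", "debris"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    render = render or RenderParams()
    rng = np.random.default_rng(seed)
    margin = 26.0
    shape = render.shape
    centers, territory = _grid_centers(rng, n_neurons, shape, margin)

    # the full-intensity soma core (radius minus half the edge ramp, minus
    # blur) must exceed the pipeline's default opening radius of 8 px, or
    # the opening guts the soma and its rim floods the top-hat
    soma_radii = [float(rng.uniform(12.0, 15.0)) for _ in range(n_neurons)]

    targets_per_neuron: list[list[float] | None] = [None] * n_neurons
    if total_length_target is not None and n_neurons > 0:
        branch_prob = 0.0  # budget mode: unbranched primaries only
        caps = [max(territory - r - 4.0, 0.0) for r in soma_radii]
        targets_per_neuron = [[] for _ in range(n_neurons)]
        remaining = float(total_length_target)
        for _ in range(3):  # at most three primaries per neuron
            for i in range(n_neurons):
                if remaining < 18.0 or caps[i] < 18.0:
                    continue
                t = min(float(rng.uniform(0.75, 1.0)) * caps[i], remaining)
                if t < 18.0:
                    t = min(18.0, caps[i])
                targets_per_neuron[i].append(t)
                remaining -= t
            if remaining < 18.0:
                break

    n_cross = max(1, n_neurons // 5) if difficulty == "overlap" and n_neurons else 0
    n_frag = max(1, n_neurons // 5) if difficulty == "overlap" and n_neurons else 0

    neurons: list[SyntheticNeuron] = []
    for i in range(n_neurons):
        center = centers[i]
        if i < n_cross:
            neurons.append(_make_crossed_neuron(
                rng, center, territory, shape, margin, neurite_length_range,
                soma_radii[i]))
        elif i < n_cross + n_frag:
            nrn = _build_neuron(rng, center, territory, shape, margin,
                                neurite_length_range, (1, 2), branch_prob=0.0,
                                soma_r=soma_radii[i], targets=targets_per_neuron[i])
            _fragment_first_path(nrn)
            nrn.kind = "fragmented"
            neurons.append(nrn)
        else:
            neurons.append(_build_neuron(rng, center, territory, shape, margin,
                                         neurite_length_range, neurites_per_neuron,
                                         branch_prob, soma_r=soma_radii[i],
                                         targets=targets_per_neuron[i]))

    somata = [(np.asarray(n.soma_center), n.soma_radius) for n in neurons]
    soma_layer = np.zeros(shape, dtype=np.float64)
    fiber_layer = np.zeros(shape, dtype=np.float64)
    for nrn in neurons:
        _draw_disk(soma_layer, np.asarray(nrn.soma_center), nrn.soma_radius,
                   render.soma_amplitude, edge_width=render.soma_edge_width)
        nrn.neurite_lengths = []
        for poly in nrn.render_paths:
            dense = _densify(poly)
            _draw_path(fiber_layer, dense, render.neurite_width,
                       render.neurite_amplitude)
            nrn.neurite_lengths.append(_arc_outside_somata(dense, somata))

    if difficulty == "debris":
        # dedicated stream: a debris field is identical to its clean twin
        # apart from the specks themselves
        _sprinkle_debris(np.random.default_rng((seed, 2)), fiber_layer,
                         soma_layer, render, margin)

    canvas = render.background + soma_layer + fiber_layer
    canvas = ndi.gaussian_filter(canvas, render.blur_sigma)
    noise_rng = np.random.default_rng((seed, 1))
    canvas = canvas + noise_rng.normal(0.0, render.noise_sd, size=shape)
    canvas = np.clip(np.round(canvas), 0, 2**render.bit_depth - 1)
    img = GreyImage(canvas.astype(np.uint16 if render.bit_depth == 16 else np.uint8),
                    bit_depth=render.bit_depth)

    truth = FieldGroundTruth(
        neurons=neurons,
        total_true_length=float(sum(n.total_length for n in neurons)),
        total_true_soma_area=float(sum(n.soma_area for n in neurons)),
        true_tip_count=sum(len(n.tips) for n in neurons),
        true_attachment_count=sum(n.n_roots for n in neurons),
        true_junction_count=sum(len(n.junctions) for n in neurons),
        render_params=render,
        seed=seed,
        difficulty=difficulty,
    )
    return img, truth


def _make_crossed_neuron(rng, center, territory, shape, margin,
                         neurite_length_range, soma_r) -> SyntheticNeuron:
    """A soma traversed by an unattached neurite (the documented
    two-attachment failure mode); truth records zero attachments."""
    nrn = _build_neuron(rng, center, territory, shape, margin,
                        neurite_length_range, (0, 0), branch_prob=0.0,
                        soma_r=soma_r, reserved_dirs=(0, 2))
    nrn.kind = "crosser"
    halves = []
    for base in (0.0, 180.0):
        target = float(np.clip(rng.uniform(*neurite_length_range),
                               25.0, territory - 4.0))
        path, arc = _grow_path(rng, center, base, target, center, territory,
                               shape, margin)
        halves.append(path)
    crosser = np.vstack([halves[0][::-1], halves[1][1:]])
    if len(crosser) >= 3:
        nrn.render_paths.append(crosser)
        nrn.tips.extend([tuple(crosser[0]), tuple(crosser[-1])])
    return nrn


def _fragment_first_path(nrn: SyntheticNeuron) -> None:
    """Split a neuron's first neurite into two pieces separated by a gap,
    emulating an interrupted neurite; biological truth keeps one tip and
    one root, but the detached distal piece inflates measured endpoints."""
    if not nrn.render_paths:
        return
    poly = nrn.render_paths[0]
    dense = _densify(poly, spacing=1.0)
    if len(dense) < 30:
        return
    centre = np.asarray(nrn.soma_center)
    # break beyond the attachment band, keep a ~8 px gap
    dist = np.linalg.norm(dense - centre[None, :], axis=1)
    eligible = np.nonzero(dist > nrn.soma_radius + 12.0)[0]
    if len(eligible) < 20:
        return
    cut = eligible[len(eligible) // 2]
    gap = 8
    piece1, piece2 = dense[:cut], dense[cut + gap:]
    if len(piece2) < 8:
        return
    nrn.render_paths[0] = piece1
    nrn.render_paths.insert(1, piece2)
    # tips/roots unchanged: biologically this is still one attached neurite


def _sprinkle_debris(rng, fiber_layer, soma_layer, render: RenderParams,
                     margin: float, n_specks: int = 40) -> None:
    """Bright specks well below the neurite size floor, kept clear of
    real structures so they test the size filter and nothing else."""
    occupied = ndi.binary_dilation((fiber_layer > 0) | (soma_layer > 0),
                                   iterations=8)
    h, w = fiber_layer.shape
    placed = 0
    for _ in range(n_specks * 20):
        if placed >= n_specks:
            break
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if occupied[int(r), int(c)]:
            continue
        _draw_disk(fiber_layer, np.array([r, c]), rng.uniform(0.8, 1.5),
                   render.neurite_amplitude)
        occupied[max(int(r) - 8, 0):int(r) + 9, max(int(c) - 8, 0):int(c) + 9] = True
        placed += 1


# ---------------------------------------------------------------------------
# plate-scale generation


@dataclass(frozen=True)
class WellSpec:
    """Per-well generation parameters of a synthetic plate."""

    well: str
    condition: str
    dose: float = 0.0
    n_neurons: int = 8
    total_length_target: float | None = None
    difficulty: str = "clean"
    n_fields: int = 1


def two_condition_layout(seed: int, n_wells_per_condition: int = 8, *,
                         neg_mean: float = 800.0, pos_mean: float = 2400.0,
                         sd: float = 400.0 / 3.0,
                         neg_neurons: int = 8, pos_neurons: int = 20) -> list[WellSpec]:
    """Differentiated-vs-undifferentiated mini-screen layout.

    Per-well true total neurite length is drawn N(mean, sd) per
    condition; with the defaults the closed-form Z-factor of the
    generating parameters, 1 - 3(sd+sd)/(pos_mean - neg_mean), is
    exactly 0.5.
    """
    rng = np.random.default_rng(seed)
    wells = []
    for i in range(n_wells_per_condition):
        t = max(float(rng.normal(neg_mean, sd)), 150.0)
        wells.append(WellSpec(well=f"A{i + 1:02d}", condition="undifferentiated",
                              n_neurons=neg_neurons, total_length_target=t))
    for i in range(n_wells_per_condition):
        t = max(float(rng.normal(pos_mean, sd)), 150.0)
        wells.append(WellSpec(well=f"B{i + 1:02d}", condition="differentiated",
                              n_neurons=pos_neurons, total_length_target=t))
    return wells


def dose_series_layout(doses: list[float], *, base_length: float = 700.0,
                       max_gain: float = 2.0, n_neurons: int = 10) -> list[WellSpec]:
    """Monotone dose-response layout: total neurite length rises with dose
    while soma content stays constant (fixed neuron number)."""
    if not doses:
        return []
    top = max(doses) or 1.0
    wells = []
    for i, d in enumerate(doses):
        gain = 1.0 + (max_gain - 1.0) * (d / top)
        wells.append(WellSpec(well=f"A{i + 1:02d}", condition=f"dose_{d:g}", dose=d,
                              n_neurons=n_neurons,
                              total_length_target=base_length * gain))
    return wells


def generate_plate(wells: list[WellSpec], out_dir: str | Path, seed: int, *,
                   plate: str = "P1", channel: str = "TuJ1",
                   render: RenderParams | None = None) -> Path:
    """Write a synthetic plate: one TIFF per field named
    ``{plate}_{well}_f{field}_{channel}.tif``, plus ``manifest.tsv``
    (per-field generation parameters and achieved ground truth) and
    ``annotations.tsv`` (well / condition / dose).

    Returns the manifest path. Field seeds are derived deterministically
    from ``seed`` and the field's position in the (sorted) layout.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    ann_rows = []
    for w_idx, spec in enumerate(sorted(wells, key=lambda s: s.well)):
        ann_rows.append((spec.well, spec.condition, spec.dose))
        for f_idx in range(spec.n_fields):
            field_seed = (seed * 1000003 + w_idx * 7919 + f_idx * 131 + 17) % (2**31 - 1)
            img, truth = generate_field(
                spec.n_neurons, spec.difficulty, field_seed, render=render,
                total_length_target=spec.total_length_target)
            fname = f"{plate}_{spec.well}_f{f_idx + 1}_{channel}.tif"
            tifffile.imwrite(out_dir / fname, np.asarray(img.pixels, dtype=np.uint16))
            rows.append({
                "plate": plate, "well": spec.well, "field": f_idx + 1,
                "channel": channel, "condition": spec.condition, "dose": spec.dose,
                "n_neurons": spec.n_neurons, "difficulty": spec.difficulty,
                "seed": field_seed,
                "length_target": ("" if spec.total_length_target is None
                                  else f"{spec.total_length_target:.3f}"),
                "true_total_length": f"{truth.total_true_length:.3f}",
                "true_soma_area": f"{truth.total_true_soma_area:.3f}",
                "true_tips": truth.true_tip_count,
                "true_attachments": truth.true_attachment_count,
                "true_junctions": truth.true_junction_count,
                "file": fname,
            })

    import pandas as pd

    manifest = out_dir / "manifest.tsv"
    columns = ["plate", "well", "field", "channel", "condition", "dose",
               "n_neurons", "difficulty", "seed", "length_target",
               "true_total_length", "true_soma_area", "true_tips",
               "true_attachments", "true_junctions", "file"]
    pd.DataFrame(rows, columns=columns).to_csv(manifest, sep="\t", index=False)
    pd.DataFrame(ann_rows, columns=["well", "condition", "dose"]).to_csv(
        out_dir / "annotations.tsv", sep="\t", index=False)
    return manifest
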