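"""Synthetic nuclear-spread images with known ground truth.

The simulator emulates the statistical structure of immunostained
meiotic spread nuclei at the level the quantification pipeline sees:
piecewise-linear chromosome axes inside a circular nucleus mask, each
flagged synapsed or unsynapsed; Gaussian puncta planted on or off the
axes in two channels with a controlled coincidence (co-focus) fraction
and amplitude distribution; rare large (>1 µm) foci; a smooth background
gradient; and additive (optionally shot) noise. Every planted object is
recorded in a ground-truth table so detection, co-cluster calling and
density estimation can be scored against what was planted.

Genotype-like presets reproduce the contrasts the pipeline is meant to
resolve: a seeding-deficient regime (fewer but brighter co-foci), a
growth-deficient regime (normal co-focus numbers, dimmer and without
large PAR-like clusters), and a synapsis-asymmetry regime with different
planted focus densities on unsynapsed vs synapsed axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .axis import AxisTrace
from .io import ChannelStack

__all__ = [
    "SimConfig",
    "SimulatedCell",
    "PRESETS",
    "generate_axes",
    "plant_foci",
    "render",
    "generate_cell",
    "generate_cohort",
    "truth_foci",
    "truth_point_foci",
]

TRUTH_COLUMNS = [
    "object_id", "channel", "row", "col", "amplitude", "sigma_px",
    "on_axis", "host_segment_id", "is_cofocus", "is_large",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated nucleus.

    Counts are exact numbers of planted objects; alternatively, when
    ``density_unsyn_per_um``/``density_syn_per_um`` are set, per-trace
    focus counts are drawn from a Poisson law with those per-µm rates
    (the two-channel identity of each focus is then a fair coin,
    emulating DMC1/RPA2 co-staining) and the count fields are ignored.

    Geometry defaults approximate a mouse spermatocyte spread imaged at
    0.1 µm/px: a ~51 µm field, 19 axes of 10-18 µm (~270 µm total axis),
    and a diffraction-scale PSF of 1.6 px (0.16 µm).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1            # µm per px
    n_axes: int = 19  # mouse: 19 autosome pairs + XY, a few merge in spreads
    axis_length_range: tuple[float, float] = (10.0, 18.0)  # µm
    synapsed_fraction: float = 0.5
    synapsed_fraction_range: tuple[float, float] | None = None  # per-cell draw
    n_cofoci: int = 120
    n_single_ch1: int = 30
    n_single_ch2: int = 30
    off_axis_fraction: float = 0.1
    amplitude_mean: float = 100.0      # AU
    amplitude_sd: float = 10.0
    psf_sigma: float = 1.6             # px
    cofocus_jitter_px: float = 0.0     # channel-2 center offset sd
    n_large_foci: int = 2
    large_focus_diameter: float = 1.3  # µm (rendered FWHM)
    large_focus_amplitude: float = 200.0
    background_level: float = 50.0     # AU
    background_gradient_amplitude: float = 10.0
    noise_sd: float = 20.0
    shot_noise: bool = False
    density_unsyn_per_um: float | None = None
    density_syn_per_um: float | None = None
    min_separation_px: float = 7.0
    channels: tuple[str, str] = ("MEI4", "REC114")
    seed: int = 0

    def validate(self):
        if any(n < 0 for n in (self.n_cofoci, self.n_single_ch1,
                               self.n_single_ch2, self.n_large_foci, self.n_axes)):
            raise ValueError("counts must be >= 0")
        for name in ("synapsed_fraction", "off_axis_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be > 0")
        if self.axis_length_range[0] > self.axis_length_range[1]:
            raise ValueError("axis_length_range must be (lo, hi)")
        return self


@dataclass(frozen=True)
class SimulatedCell:
    cell_id: str
    stack: ChannelStack | None
    traces: list[AxisTrace]
    truth: pd.DataFrame
    config: SimConfig


def _nucleus_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    r = 0.45 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= r ** 2


def _split_polyline(verts: np.ndarray, at_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a polyline at arc length ``at_px`` into two vertex arrays."""
    seg = np.hypot(*np.diff(verts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    at_px = min(max(at_px, 0.0), cum[-1])
    i = int(np.searchsorted(cum, at_px, side="right") - 1)
    i = min(i, len(seg) - 1)
    frac = (at_px - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    cut = verts[i] + frac * (verts[i + 1] - verts[i])
    head = np.vstack([verts[: i + 1], cut])
    tail = np.vstack([cut, verts[i + 1:]])
    return head, tail


def generate_axes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[AxisTrace], np.ndarray]:
    """Generate axis polylines inside a circular nucleus mask.

    Each axis is a bounded-turning random walk (step 4 px, max turn
    0.5 rad per step) rejected and re-drawn if it leaves the mask. After
    drawing, whole axes are flagged synapsed greedily and at most one
    axis is split in two so that the synapsed length fraction matches
    ``config.synapsed_fraction`` almost exactly. Raises if the requested
    geometry repeatedly fails to fit inside the mask.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = config.image_shape
    mask = _nucleus_mask(config.image_shape)
    radius = 0.45 * min(h, w)
    center = np.array([h / 2, w / 2])
    step = 4.0
    max_turn = 0.5

    max_len_px = config.axis_length_range[1] / config.pixel_size
    if max_len_px > 2 * radius * 4:  # walk cannot plausibly stay inside
        raise ValueError("requested axis length cannot fit in the nucleus mask")

    polylines = []
    for _ in range(config.n_axes):
        target_um = rng.uniform(*config.axis_length_range)
        target_px = target_um / config.pixel_size
        for attempt in range(500):
            start = center + (rng.uniform(0, 0.8 * radius)
                              * np.array([math.sin(a := rng.uniform(0, 2 * math.pi)),
                                          math.cos(a)]))
            heading = rng.uniform(0, 2 * math.pi)
            pts = [start]
            n_steps = int(math.ceil(target_px / step))
            ok = True
            for k in range(n_steps):
                heading += rng.uniform(-max_turn, max_turn)
                s = step if k < n_steps - 1 else target_px - step * (n_steps - 1)
                nxt = pts[-1] + s * np.array([math.sin(heading), math.cos(heading)])
                # 2 px margin keeps every vertex inside the pixelated mask
                if np.sum((nxt - center) ** 2) > (radius - 2.0) ** 2:
                    ok = False
                    break
                pts.append(nxt)
            if ok:
                polylines.append(np.array(pts))
                break
        else:
            raise ValueError("could not fit an axis inside the nucleus mask")

    lengths = [float(np.sum(np.hypot(*np.diff(v, axis=0).T))) for v in polylines]
    total = sum(lengths)
    target_syn = config.synapsed_fraction * total

    traces: list[AxisTrace] = []
    seg_id = 0
    acc = 0.0
    for verts, L in zip(polylines, lengths):
        if acc >= target_syn:
            traces.append(AxisTrace(seg_id, verts, False))
            seg_id += 1
        elif acc + L <= target_syn:
            traces.append(AxisTrace(seg_id, verts, True))
            seg_id += 1
            acc += L
        else:  # split this axis to hit the target fraction
            head, tail = _split_polyline(verts, target_syn - acc)
            if len(head) >= 2:
                traces.append(AxisTrace(seg_id, head, True))
                seg_id += 1
            if len(tail) >= 2:
                traces.append(AxisTrace(seg_id, tail, False))
                seg_id += 1
            acc = target_syn
    return traces, mask


def _point_on_trace(trace: AxisTrace, at_px: float) -> np.ndarray:
    seg = np.hypot(*np.diff(trace.vertices, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    at_px = min(max(at_px, 0.0), cum[-1])
    i = int(np.searchsorted(cum, at_px, side="right") - 1)
    i = min(i, len(seg) - 1)
    frac = (at_px - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return trace.vertices[i] + frac * (trace.vertices[i + 1] - trace.vertices[i])


class _Placer:
    """Rejection-samples positions with per-object exclusion radii.

    Two objects must be at least r_i + r_j apart; point-like foci get
    radius min_sep / 2 so their pairwise separation is min_sep, while
    large blobs carry a wider radius so dim puncta are not swallowed by
    their skirts.
    """

    def __init__(self, min_sep: float):
        self.default_radius = min_sep / 2
        self.points: list[np.ndarray] = []
        self.radii: list[float] = []

    def try_add(self, p: np.ndarray, radius: float | None = None) -> bool:
        r = self.default_radius if radius is None else radius
        if self.points:
            d = np.sqrt(np.sum((np.array(self.points) - p) ** 2, axis=1))
            if np.any(d < np.array(self.radii) + r):
                return False
        self.points.append(p)
        self.radii.append(r)
        return True


def plant_foci(
    axes: list[AxisTrace],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Plant ground-truth puncta on and off the axes.

    Returns one row per (object, channel): a co-focus contributes a row
    in each channel sharing one ``object_id`` and (up to the configured
    jitter) one center. On-axis objects sit exactly on a polyline; the
    off-axis fraction is scattered uniformly over the nucleus mask. In
    density mode (``density_*_per_um`` set), per-trace counts are
    Poisson with the class rate and each focus lands in one of the two
    channels with probability 1/2.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if mask is None:
        mask = _nucleus_mask(config.image_shape)
    ch1, ch2 = config.channels
    rows: list[dict] = []
    oid = 0

    def amp() -> float:
        # clip far-left tail so planted spots stay well above zero signal
        lo = max(1e-3, config.amplitude_mean - 3 * config.amplitude_sd)
        return float(max(lo, rng.normal(config.amplitude_mean, config.amplitude_sd)))

    if config.density_unsyn_per_um is not None or config.density_syn_per_um is not None:
        if not axes:
            raise ValueError("density mode requires axis traces")
        for t in axes:
            rate = (config.density_syn_per_um if t.synapsed
                    else config.density_unsyn_per_um) or 0.0
            L_um = t.length_px() * config.pixel_size
            n = rng.poisson(rate * L_um)
            for _ in range(n):
                p = _point_on_trace(t, rng.uniform(0, t.length_px()))
                ch = ch1 if rng.random() < 0.5 else ch2
                rows.append(dict(object_id=oid, channel=ch, row=p[0], col=p[1],
                                 amplitude=amp(), sigma_px=config.psf_sigma,
                                 on_axis=True, host_segment_id=t.segment_id,
                                 is_cofocus=False, is_large=False))
                oid += 1
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    if (config.n_cofoci + config.n_single_ch1 + config.n_single_ch2) > 0 \
            and not axes and config.off_axis_fraction < 1:
        raise ValueError("on-axis planting requires nonempty axes")

    placer = _Placer(config.min_separation_px)
    lengths = np.array([t.length_px() for t in axes]) if axes else np.array([])
    weights = lengths / lengths.sum() if lengths.size and lengths.sum() > 0 else None
    h, w = config.image_shape
    inside = np.argwhere(mask)

    def sample_position(on_axis: bool, radius: float | None = None):
        for _ in range(5000):
            if on_axis:
                ti = int(rng.choice(len(axes), p=weights))
                t = axes[ti]
                p = _point_on_trace(t, rng.uniform(0, t.length_px()))
                host = t.segment_id
            else:
                p = inside[rng.integers(len(inside))].astype(float) + rng.random(2)
                host = None
            if placer.try_add(p, radius):
                return p, host
        raise ValueError("could not place foci at the requested separation; "
                         "reduce counts or min_separation_px")

    def plant(n: int, kind: str):
        nonlocal oid
        n_off = int(round(n * config.off_axis_fraction))
        flags = [False] * n_off + [True] * (n - n_off)
        rng.shuffle(flags)
        for on_axis in flags:
            p, host = sample_position(on_axis)
            if kind == "cofocus":
                p2 = p + rng.normal(0, config.cofocus_jitter_px, 2) \
                    if config.cofocus_jitter_px > 0 else p
                # one physical cluster drives both channel signals: the
                # partner amplitude tracks the first up to 5% jitter
                a1 = amp()
                a2 = a1 * math.exp(rng.normal(0.0, 0.05))
                rows.append(dict(object_id=oid, channel=ch1, row=p[0], col=p[1],
                                 amplitude=a1, sigma_px=config.psf_sigma,
                                 on_axis=on_axis, host_segment_id=host,
                                 is_cofocus=True, is_large=False))
                rows.append(dict(object_id=oid, channel=ch2, row=p2[0], col=p2[1],
                                 amplitude=a2, sigma_px=config.psf_sigma,
                                 on_axis=on_axis, host_segment_id=host,
                                 is_cofocus=True, is_large=False))
            else:
                rows.append(dict(object_id=oid, channel=kind, row=p[0], col=p[1],
                                 amplitude=amp(), sigma_px=config.psf_sigma,
                                 on_axis=on_axis, host_segment_id=host,
                                 is_cofocus=False, is_large=False))
            oid += 1

    # rare large (>1 µm) foci first, so their wide exclusion zone holds:
    # bright PAR-like ch1 blobs whose skirts would swallow dim puncta
    sigma_large = config.large_focus_diameter / config.pixel_size / 2.355  # FWHM -> sigma
    for _ in range(config.n_large_foci):
        p, host = sample_position(bool(axes), radius=3.0 * sigma_large)
        rows.append(dict(object_id=oid, channel=ch1, row=p[0], col=p[1],
                         amplitude=config.large_focus_amplitude, sigma_px=sigma_large,
                         on_axis=bool(axes), host_segment_id=host,
                         is_cofocus=False, is_large=True))
        oid += 1

    plant(config.n_cofoci, "cofocus")
    plant(config.n_single_ch1, ch1)
    plant(config.n_single_ch2, ch2)
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def render(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ChannelStack:
    """Render planted objects into a noisy two-channel image.

    Each object contributes an isotropic Gaussian ``A * exp(-r^2 / 2s^2)``
    evaluated on the pixel grid (on a local window of +/- 5 sigma), on
    top of a constant background plus a smooth linear gradient of random
    orientation. Gaussian read noise (and optional Poisson shot noise)
    is added last and the image clipped at zero.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = config.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * math.pi)
    ramp = (np.sin(theta) * (yy - h / 2) + np.cos(theta) * (xx - w / 2)) / max(h, w)
    base = config.background_level + config.background_gradient_amplitude * ramp

    channels = {}
    for name in config.channels:
        img = base.copy()
        sub = truth[truth["channel"] == name] if len(truth) else truth
        for row in sub.itertuples():
            s = row.sigma_px
            r0, c0 = row.row, row.col
            win = int(math.ceil(5 * s))
            rlo, rhi = max(0, int(r0) - win), min(h, int(r0) + win + 1)
            clo, chi = max(0, int(c0) - win), min(w, int(c0) + win + 1)
            if rlo >= rhi or clo >= chi:
                continue
            gy = np.arange(rlo, rhi)[:, None] - r0
            gx = np.arange(clo, chi)[None, :] - c0
            img[rlo:rhi, clo:chi] += row.amplitude * np.exp(
                -(gy ** 2 + gx ** 2) / (2 * s ** 2))
        if config.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.noise_sd > 0:
            img = img + rng.normal(0, config.noise_sd, img.shape)
        channels[name] = np.clip(img, 0, None)
    return ChannelStack(channels, config.pixel_size)


def generate_cell(
    config: SimConfig,
    cell_id: str = "cell0",
    rng: np.random.Generator | None = None,
    render_images: bool = True,
) -> SimulatedCell:
    """Simulate one nucleus end to end: axes, planted truth, optional image."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    traces, mask = generate_axes(config, rng)
    truth = plant_foci(traces, config, rng, mask)
    stack = render(truth, config, rng) if render_images else None
    return SimulatedCell(cell_id, stack, traces, truth, config)


# ------------------------------------------------------------------- presets

def _preset_configs() -> dict[str, SimConfig]:
    wt = SimConfig()
    return {
        # moderate-intensity, abundant co-foci
        "wildtype_like": wt,
        # fewer (2.5x reduction) but brighter (1.5x) co-foci
        "seeding_deficient_like": replace(
            wt, n_cofoci=48, amplitude_mean=150.0, amplitude_sd=15.0),
        # normal seed numbers, dim foci, no large PAR-like clusters
        "growth_deficient_like": replace(
            wt, amplitude_mean=60.0, amplitude_sd=6.0, n_large_foci=0),
        # DMC1/RPA2 density asymmetry: planted unsyn:syn ratio 2.0
        "asynapsis_density_like": replace(
            wt, channels=("DMC1", "RPA2"),
            density_unsyn_per_um=0.4, density_syn_per_um=0.2,
            synapsed_fraction_range=(0.35, 0.85),
            n_cofoci=0, n_single_ch1=0, n_single_ch2=0, n_large_foci=0),
    }


PRESETS = tuple(_preset_configs())


def generate_cohort(
    preset: str,
    n_cells: int,
    seed: int = 0,
    render_images: bool = True,
    overrides: dict | None = None,
) -> list[SimulatedCell]:
    """Simulate a cohort of nuclei under a genotype-like preset.

    Per-cell randomness derives deterministically from (seed, cell
    index), so cohorts are reproducible and individual cells can be
    regenerated in isolation.
    """
    configs = _preset_configs()
    if preset not in configs:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(configs)}")
    base = configs[preset]
    if overrides:
        base = replace(base, **overrides)
    cells = []
    for i in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        cfg = base
        if base.synapsed_fraction_range is not None:
            cfg = replace(base, synapsed_fraction=float(
                rng.uniform(*base.synapsed_fraction_range)))
        cells.append(generate_cell(cfg, cell_id=f"{preset}_{i:03d}",
                                   rng=rng, render_images=render_images))
    return cells


def truth_foci(truth: pd.DataFrame, channel: str):
    """Ground-truth (row, col) centers for one channel, as an (n, 2) array."""
    sub = truth[truth["channel"] == channel]
    return np.column_stack([sub["row"].to_numpy(float), sub["col"].to_numpy(float)])


def truth_point_foci(truth: pd.DataFrame, channel: str, pixel_size: float):
    """Planted centers of one channel as single-pixel Focus objects.

    Lets position-based stages (focus merging, axis assignment, density
    estimation) run directly on ground truth, bypassing rendering and
    detection.
    """
    from .detect import Focus

    sub = truth[truth["channel"] == channel]
    return [
        Focus(focus_id=int(row.object_id), channel=channel,
              pixels=np.array([[int(round(row.row)), int(round(row.col))]]),
              pixel_size=pixel_size, peak_intensity=float(row.amplitude))
        for row in sub.itertuples()
    ]
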