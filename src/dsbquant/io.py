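"""File formats, pipeline configuration, and the stage-composition driver.

Interchange is deliberately plain: multichannel grayscale TIFF for
images and fixed-schema CSV for every table (traces, foci, co-clusters,
per-cell summaries, densities), so each stage can be run, inspected and
re-fed independently — mirroring how macro-based quantification
workflows pass tabular object data between tools.

CSV schemas
-----------
traces:     cell_id, segment_id, vertex_index, x_px, y_px, synapsed_flag
foci:       cell_id, channel, focus_id, area_px, centroid_row,
            centroid_col, equiv_diameter_um, peak, pixels
            (pixels = "r:c;r:c;..." run of member pixel coordinates)
coclusters: cell_id, mei4_focus_id, rec114_partner_id, overlap_fraction,
            integrated_intensity
per_cell:   cell_id, n_coclusters, median_intensity, n_large_foci
density:    cell_id, n_syn, n_unsyn, n_unassigned, length_syn_um,
            length_unsyn_um, density_syn_per_um, density_unsyn_per_um,
            ratio_unsyn_to_syn, percent_synapsed, synapsis_class
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import DetectionParams, Focus, Image2D, classify_large_foci, detect_foci
from .cocluster import call_coclusters, integrated_intensity, per_cell_stats
from .axis import AxisTrace, compute_density, merge_two_channel_foci

__all__ = [
    "ChannelStack",
    "PipelineConfig",
    "read_channel_stack",
    "write_channel_stack",
    "write_traces_csv",
    "read_traces_csv",
    "foci_to_frame",
    "frame_to_foci",
    "run_pipeline",
]


@dataclass(frozen=True)
class ChannelStack:
    """Co-registered single-plane channels keyed by name, with pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self):
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    def image(self, name: str) -> Image2D:
        return Image2D(self.channels[name], self.pixel_size)


_ALLOWED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def read_channel_stack(
    path: str | Path, channel_names: list[str], pixel_size: float
) -> ChannelStack:
    """Read a multichannel/multipage grayscale TIFF into a ChannelStack.

    Pages (or leading-axis planes) are assigned to ``channel_names`` in
    order. Integer and float pixel types are converted to float64
    without rescaling.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D pages, got array of shape {arr.shape}")
    if str(arr.dtype) not in _ALLOWED_DTYPES:
        raise ValueError(f"unsupported pixel type {arr.dtype}")
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{arr.shape[0]} pages in {path} but {len(channel_names)} channels configured"
        )
    channels = {name: arr[i].astype(np.float64) for i, name in enumerate(channel_names)}
    return ChannelStack(channels, pixel_size)


def write_channel_stack(stack: ChannelStack, path: str | Path, channel_order=None):
    """Write channels as a multipage float32 TIFF (order = dict order by default)."""
    names = list(channel_order or stack.channels)
    data = np.stack([np.asarray(stack.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(str(path), data)


# ---------------------------------------------------------------- traces CSV

def write_traces_csv(traces_by_cell: dict[str, list[AxisTrace]], path: str | Path):
    rows = []
    for cell_id, traces in traces_by_cell.items():
        for t in traces:
            for i, (r, c) in enumerate(t.vertices):
                rows.append(
                    dict(cell_id=cell_id, segment_id=t.segment_id, vertex_index=i,
                         x_px=c, y_px=r, synapsed_flag=int(t.synapsed))
                )
    pd.DataFrame(rows, columns=["cell_id", "segment_id", "vertex_index",
                                "x_px", "y_px", "synapsed_flag"]).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> dict[str, list[AxisTrace]]:
    df = pd.read_csv(path)
    out: dict[str, list[AxisTrace]] = {}
    for (cell_id, seg_id), grp in df.groupby(["cell_id", "segment_id"], sort=True):
        grp = grp.sort_values("vertex_index")
        verts = np.column_stack([grp["y_px"].to_numpy(float), grp["x_px"].to_numpy(float)])
        out.setdefault(str(cell_id), []).append(
            AxisTrace(int(seg_id), verts, bool(grp["synapsed_flag"].iloc[0]))
        )
    return out


# ------------------------------------------------------------------ foci CSV

def _encode_pixels(px: np.ndarray) -> str:
    return ";".join(f"{int(r)}:{int(c)}" for r, c in px)


def _decode_pixels(s: str) -> np.ndarray:
    pairs = [p.split(":") for p in s.split(";")]
    return np.array([[int(r), int(c)] for r, c in pairs], dtype=np.intp)


def foci_to_frame(foci: list[Focus], cell_id: str) -> pd.DataFrame:
    rows = []
    for f in foci:
        r, c = f.centroid
        rows.append(dict(
            cell_id=cell_id, channel=f.channel, focus_id=f.focus_id,
            area_px=f.area, centroid_row=r, centroid_col=c,
            equiv_diameter_um=f.equivalent_diameter, peak=f.peak_intensity,
            pixels=_encode_pixels(f.pixels),
        ))
    return pd.DataFrame(rows, columns=["cell_id", "channel", "focus_id", "area_px",
                                       "centroid_row", "centroid_col",
                                       "equiv_diameter_um", "peak", "pixels"])


def frame_to_foci(df: pd.DataFrame, pixel_size: float) -> list[Focus]:
    return [
        Focus(
            focus_id=int(row.focus_id), channel=str(row.channel),
            pixels=_decode_pixels(row.pixels), pixel_size=pixel_size,
            peak_intensity=float(row.peak),
        )
        for row in df.itertuples()
    ]


# ------------------------------------------------------------------ pipeline

@dataclass
class PipelineConfig:
    """End-to-end configuration of the quantification pipeline."""

    pixel_size: float = 0.1
    mei4_channel: str = "MEI4"
    rec114_channel: str = "REC114"
    dmc1_channel: str = "DMC1"
    rpa2_channel: str = "RPA2"
    detection: DetectionParams = field(default_factory=DetectionParams)
    min_fraction: float = 0.5
    diameter_threshold: float = 1.0
    max_distance: float = 0.3
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "detection"},
             "detection": asdict(self.detection)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    cells: list[tuple[str, ChannelStack, list[AxisTrace] | None]],
) -> dict[str, pd.DataFrame]:
    """Run detection -> co-clustering -> per-cell stats (-> densities) over cells.

    Each input cell is (cell_id, ChannelStack, axis traces or None).
    Co-clustering runs when both MEI4 and REC114 channels are present;
    density analysis when DMC1/RPA2 channels and traces are present.
    Returns the tables {"foci", "coclusters", "per_cell", "density"} and
    writes them (plus a run log) under ``config.output_dir`` when set.
    Deterministic given (inputs, config).
    """
    foci_frames, cc_rows, cell_rows, dens_rows = [], [], [], []
    for cell_id, stack, traces in cells:
        try:
            _process_cell(config, cell_id, stack, traces,
                          foci_frames, cc_rows, cell_rows, dens_rows)
        except Exception as exc:  # annotate with the failing cell
            raise RuntimeError(f"pipeline failed on cell {cell_id!r}: {exc}") from exc
    out = {
        "foci": (pd.concat(foci_frames, ignore_index=True) if foci_frames
                 else foci_to_frame([], "")),
        "coclusters": pd.DataFrame(cc_rows, columns=[
            "cell_id", "mei4_focus_id", "rec114_partner_id",
            "overlap_fraction", "integrated_intensity"]),
        "per_cell": pd.DataFrame(cell_rows, columns=[
            "cell_id", "n_coclusters", "median_intensity", "n_large_foci"]),
        "density": pd.DataFrame(dens_rows, columns=[
            "cell_id", "n_syn", "n_unsyn", "n_unassigned", "length_syn_um",
            "length_unsyn_um", "density_syn_per_um", "density_unsyn_per_um",
            "ratio_unsyn_to_syn", "percent_synapsed", "synapsis_class"]),
    }
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        log = dict(
            config_hash=config.config_hash(),
            config={**{k: v for k, v in asdict(config).items() if k != "detection"},
                    "detection": asdict(config.detection)},
            n_cells=len(cells),
            versions=dict(numpy=np.__version__, pandas=pd.__version__),
        )
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out


def _process_cell(config, cell_id, stack, traces,
                  foci_frames, cc_rows, cell_rows, dens_rows):
    det = config.detection
    foci_by_channel: dict[str, list[Focus]] = {}
    for name in stack.channels:
        foci_by_channel[name] = detect_foci(stack.image(name), det, channel=name)
        foci_frames.append(foci_to_frame(foci_by_channel[name], cell_id))

    m, r = config.mei4_channel, config.rec114_channel
    if m in foci_by_channel and r in foci_by_channel:
        small, large = classify_large_foci(foci_by_channel[m], config.diameter_threshold)
        ccs = call_coclusters(small, foci_by_channel[r], config.min_fraction)
        raw = stack.image(m)
        by_id = {f.focus_id: f for f in small}
        measured = [
            cc.__class__(cc.mei4_focus_id, cc.rec114_partner_id, cc.overlap_fraction,
                         integrated_intensity(raw, by_id[cc.mei4_focus_id]))
            for cc in ccs
        ]
        for cc in measured:
            cc_rows.append(dict(cell_id=cell_id, mei4_focus_id=cc.mei4_focus_id,
                                rec114_partner_id=cc.rec114_partner_id,
                                overlap_fraction=cc.overlap_fraction,
                                integrated_intensity=cc.integrated_intensity))
        st = per_cell_stats(measured, large, cell_id)
        cell_rows.append(dict(cell_id=cell_id, n_coclusters=st.n_coclusters,
                              median_intensity=st.median_intensity,
                              n_large_foci=st.n_large_foci))

    d, p = config.dmc1_channel, config.rpa2_channel
    if traces and d in foci_by_channel and p in foci_by_channel:
        rec = merge_two_channel_foci(foci_by_channel[d], foci_by_channel[p])
        res = compute_density(rec, traces, config.pixel_size,
                              config.max_distance, cell_id)
        dens_rows.append(dict(
            cell_id=cell_id, n_syn=res.n_syn, n_unsyn=res.n_unsyn,
            n_unassigned=res.n_unassigned, length_syn_um=res.length_syn,
            length_unsyn_um=res.length_unsyn, density_syn_per_um=res.density_syn,
            density_unsyn_per_um=res.density_unsyn,
            ratio_unsyn_to_syn=res.ratio_unsyn_to_syn,
            percent_synapsed=res.percent_synapsed,
            synapsis_class=res.synapsis_class))
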