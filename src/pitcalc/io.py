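"""Delimited-text and sidecar I/O for recordings, traces and tables.

A recording round-trips as a cells × frames TSV (header row of frame times
in seconds) plus a YAML sidecar holding the protocol, frame interval, seed
and generator spec, and an optional ground-truth TSV. An optional export
renders the recording as a single-channel multi-frame TIFF stack (cells as
disks) so ROI mean-intensity extraction can be exercised.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import StimulusProtocol
from .synth import CellGroundTruth, RecordingMatrix

FLOAT_FMT = "%.9g"


def write_recording(rec: RecordingMatrix, path: str | Path) -> dict[str, Path]:
    """Write `<stem>.tsv`, `<stem>.sidecar.yaml` and, when ground truth is
    attached, `<stem>.ground_truth.tsv`. Returns the paths written."""
    path = Path(path)
    stem = path.with_suffix("")
    table = pd.DataFrame(
        rec.fluorescence,
        index=pd.RangeIndex(rec.n_cells, name="cell_id"),
        columns=[f"{t:.9g}" for t in rec.frame_times],
    )
    tsv = stem.with_suffix(".tsv")
    # full precision so an ingest-and-reprocess run is bit-identical
    table.to_csv(tsv, sep="\t", float_format="%.17g")
    sidecar = stem.with_suffix(".sidecar.yaml")
    meta = {
        "frame_interval_s": rec.frame_interval_s,
        "protocol": rec.protocol.to_dict(),
        "seed": rec.meta.get("seed"),
        "spec": rec.meta.get("spec"),
        "truncations": rec.meta.get("truncations", []),
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    out = {"recording": tsv, "sidecar": sidecar}
    if rec.ground_truth is not None:
        gt = ground_truth_table(rec.ground_truth)
        gt_path = stem.with_suffix(".ground_truth.tsv")
        gt.to_csv(gt_path, sep="\t", float_format=FLOAT_FMT)
        out["ground_truth"] = gt_path
    return out


def read_recording(path: str | Path) -> RecordingMatrix:
    """Read a recording written by :func:`write_recording` (ground truth is
    reattached when its table is present)."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".tsv" else path
    table = pd.read_csv(
        stem.with_suffix(".tsv"), sep="\t", index_col="cell_id", float_precision="round_trip"
    )
    meta = yaml.safe_load(stem.with_suffix(".sidecar.yaml").read_text())
    protocol = StimulusProtocol.from_dict(meta["protocol"])
    gt_path = stem.with_suffix(".ground_truth.tsv")
    ground_truth = read_ground_truth(gt_path) if gt_path.exists() else None
    return RecordingMatrix(
        fluorescence=table.to_numpy(dtype=float),
        frame_interval_s=float(meta["frame_interval_s"]),
        protocol=protocol,
        ground_truth=ground_truth,
        meta={k: meta.get(k) for k in ("seed", "spec", "truncations")},
    )


def ground_truth_table(cells: list[CellGroundTruth]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(cells):
        rows.append(
            {
                "cell_id": i,
                "viable": c.viable,
                "spontaneous": c.spontaneous,
                "n_spontaneous_events": c.n_spontaneous_events,
                "responds_to": "|".join(sorted(c.responds_to)),
                "amplitude_scale": c.amplitude_scale,
                "shape_class": c.shape_class,
                "baseline_event_onsets_s": "|".join(f"{t:.9g}" for t in c.baseline_event_onsets_s),
                "response_onsets_s": "|".join(
                    f"{k}:{v:.9g}" for k, v in sorted(c.response_onsets_s.items())
                ),
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def read_ground_truth(path: str | Path) -> list[CellGroundTruth]:
    df = pd.read_csv(path, sep="\t", index_col="cell_id", keep_default_na=False)
    cells = []
    for _, row in df.iterrows():
        onsets = tuple(float(x) for x in str(row["baseline_event_onsets_s"]).split("|") if x)
        resp_onsets = {}
        for item in str(row["response_onsets_s"]).split("|"):
            if item:
                k, v = item.split(":")
                resp_onsets[k] = float(v)
        cells.append(
            CellGroundTruth(
                viable=_to_bool(row["viable"]),
                spontaneous=_to_bool(row["spontaneous"]),
                n_spontaneous_events=int(row["n_spontaneous_events"]),
                responds_to=frozenset(x for x in str(row["responds_to"]).split("|") if x),
                amplitude_scale=float(row["amplitude_scale"]),
                shape_class=str(row["shape_class"]),
                baseline_event_onsets_s=onsets,
                response_onsets_s=resp_onsets,
            )
        )
    return cells


def _to_bool(v) -> bool:
    return str(v).strip().lower() in ("true", "1", "yes")


# ---------------------------------------------------------------------------
# Optional TIFF round-trip (cells rendered as disks; fixed-ROI extraction)
# ---------------------------------------------------------------------------


def export_tiff_stack(
    rec: RecordingMatrix, path: str | Path, disk_radius_px: int = 3, grid_gap_px: int = 10
) -> pd.DataFrame:
    """Render the recording as a multi-frame TIFF with each cell a uniform
    disk on a grid; returns the ROI table (cell_id, center x/y, radius)
    used by :func:`extract_roi_means`."""
    import tifffile

    n = rec.n_cells
    cols = int(np.ceil(np.sqrt(n)))
    size = cols * grid_gap_px + grid_gap_px
    yy, xx = np.mgrid[0:size, 0:size]
    rois = []
    masks = []
    for i in range(n):
        cy = grid_gap_px + (i // cols) * grid_gap_px
        cx = grid_gap_px + (i % cols) * grid_gap_px
        masks.append((yy - cy) ** 2 + (xx - cx) ** 2 <= disk_radius_px**2)
        rois.append({"cell_id": i, "x": cx, "y": cy, "radius": disk_radius_px})
    stack = np.zeros((rec.n_frames, size, size), dtype=np.float32)
    for i, m in enumerate(masks):
        stack[:, m] = rec.fluorescence[i][:, None]
    tifffile.imwrite(str(path), stack)
    return pd.DataFrame(rois).set_index("cell_id")


def extract_roi_means(path: str | Path, rois: pd.DataFrame) -> np.ndarray:
    """Mean intensity inside each fixed disk ROI, per frame — a convenience
    reader for disk-rendered stacks, not a segmentation algorithm."""
    import tifffile

    stack = tifffile.imread(str(path))
    yy, xx = np.mgrid[0 : stack.shape[1], 0 : stack.shape[2]]
    out = np.empty((len(rois), stack.shape[0]))
    for j, (_, r) in enumerate(rois.iterrows()):
        m = (yy - r["y"]) ** 2 + (xx - r["x"]) ** 2 <= r["radius"] ** 2
        out[j] = stack[:, m].mean(axis=1)
    return out
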