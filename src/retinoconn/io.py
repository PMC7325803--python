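"""File formats: TCK tractograms, NIfTI label volumes, per-vertex BOLD
tables, generator configs, and connectivity CSV outputs.

TCK is the canonical tractogram format (mm world coordinates); label volumes
are NIfTI-1 int16 with a voxel-center affine; BOLD runs are per-vertex TSV
plus a JSON sidecar holding the stimulus metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile

from .connectivity import ConnectivityMatrix, ProximityMatrix
from .datatypes import BoldRun, GeneratorConfig, SegmentLabelVolume, StreamlineSet

_V1_NAMES = [f"V1_{k}" for k in range(1, 7)]
_V2_NAMES = [f"V2_{k}" for k in range(1, 7)]

SCHEMA_VERSION = "1"


class TckParseError(ValueError):
    """Raised when a TCK file is malformed or inconsistent."""


def write_tck(path: str | Path, tractogram: StreamlineSet) -> None:
    """Write streamlines as TCK in mm world coordinates (float32)."""
    tg = Tractogram(
        [s.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    TckFile(tg).save(str(path))


def read_tck(path: str | Path) -> StreamlineSet:
    """Read a TCK tractogram; validates the header streamline count."""
    try:
        tck = TckFile.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises several header/stream errors
        raise TckParseError(f"cannot parse TCK file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tck.tractogram.streamlines]
    declared = tck.header.get("count")
    if declared is not None and str(declared).strip() != "":
        if int(declared) != len(streamlines):
            raise TckParseError(
                f"TCK count field ({declared}) does not match the number of "
                f"streamlines read ({len(streamlines)}) in {path}"
            )
    if len(streamlines) == 0:
        return StreamlineSet(streamlines=[], true_cell=None, csf_tag=None)
    return StreamlineSet(streamlines=streamlines)


def write_label_volume(path: str | Path, labels: SegmentLabelVolume) -> None:
    img = nib.Nifti1Image(labels.grid.astype(np.int16), labels.affine)
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> SegmentLabelVolume:
    img = nib.load(str(path))
    return SegmentLabelVolume(
        grid=np.asarray(img.dataobj).astype(np.int16), affine=img.affine
    )


def write_bold_run(path_tsv: str | Path, run: BoldRun) -> None:
    """Per-vertex TSV (rows = vertices, columns = samples) + JSON sidecar."""
    path_tsv = Path(path_tsv)
    frame = pd.DataFrame(
        run.series, columns=[f"t{k}" for k in range(run.n_samples)]
    )
    frame.insert(0, "vertex", np.arange(run.series.shape[0]))
    frame.to_csv(path_tsv, sep="\t", index=False)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "tr_s": run.tr_s,
        "cycle_period_s": run.cycle_period_s,
        "n_cycles": run.n_cycles,
        "direction": run.direction,
        "dimension": run.dimension,
        "t0_s": run.t0_s,
    }
    path_tsv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bold_run(path_tsv: str | Path) -> BoldRun:
    path_tsv = Path(path_tsv)
    frame = pd.read_csv(path_tsv, sep="\t")
    meta = json.loads(path_tsv.with_suffix(".json").read_text())
    series = frame.drop(columns=["vertex"]).to_numpy(dtype=float)
    return BoldRun(
        series=series,
        tr_s=meta["tr_s"],
        cycle_period_s=meta["cycle_period_s"],
        n_cycles=meta["n_cycles"],
        direction=meta["direction"],
        dimension=meta["dimension"],
        t0_s=meta.get("t0_s", 0.0),
    )


def write_config(path: str | Path, cfg: GeneratorConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def read_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _matrix_frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, index=_V1_NAMES, columns=_V2_NAMES)


def write_connectivity(
    out_dir: str | Path,
    matrix: ConnectivityMatrix,
    proximity: ProximityMatrix | None = None,
    stem: str = "connectivity",
) -> None:
    """Write counts/percent (and optionally proximity) CSVs + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _matrix_frame(matrix.counts).to_csv(out_dir / f"{stem}_counts.csv")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "hemisphere_id": matrix.hemisphere_id,
        "acquisition_id": matrix.acquisition_id,
        "n_input": matrix.n_input,
        "n_retained": matrix.total,
        "n_discarded_csf": matrix.n_discarded_csf,
        "n_discarded_termination": matrix.n_discarded_termination,
    }
    if matrix.total > 0:
        _matrix_frame(matrix.percent).to_csv(out_dir / f"{stem}_percent.csv")
    else:
        meta["percent_defined"] = False
    if proximity is not None:
        _matrix_frame(proximity.mean_recip_len).to_csv(
            out_dir / f"{stem}_proximity.csv"
        )
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def read_connectivity_counts(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != _V1_NAMES or list(frame.columns) != _V2_NAMES:
        raise ValueError(f"unexpected row/column headers in {path}")
    return frame.to_numpy()
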