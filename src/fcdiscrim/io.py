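"""Plain-text and NIfTI serialisation for cohort artifacts.

Formats: subject metadata as CSV (subject_id,group,age,gender); ROI time
series and nuisance regressors as TSV, one file per subject, with
``ROI_0001``-style column headers; network matrices as TSV with node labels
as header; parcellations as integer NIfTI label volumes.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohortsim import ParcelVolume, SubjectRecord
from .netbuild import FCNetwork
from .tsprep import TimeSeriesMatrix

__all__ = [
    "write_metadata",
    "read_metadata",
    "write_timeseries",
    "read_timeseries",
    "write_network",
    "read_network",
    "write_edge_list",
    "write_parcellation",
    "read_parcellation",
]


def roi_labels(n: int) -> list[str]:
    return [f"ROI_{i + 1:04d}" for i in range(n)]


def write_metadata(records: list[SubjectRecord], path) -> None:
    pd.DataFrame(
        [
            {"subject_id": r.subject_id, "group": r.group, "age": r.age, "gender": r.gender}
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_metadata(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SubjectRecord(str(r.subject_id), str(r.group), float(r.age), str(r.gender))
        for r in df.itertuples()
    ]


def write_timeseries(values: np.ndarray, path, tr: float = 2.0, prefix: str = "ROI") -> None:
    values = np.atleast_2d(values)
    cols = [f"{prefix}_{i + 1:04d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols)
    df.attrs["tr"] = tr
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path, tr: float = 2.0) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return TimeSeriesMatrix(df.to_numpy(dtype=float), tr)


def write_network(net: FCNetwork, path) -> None:
    pd.DataFrame(net.weights, columns=net.node_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_network(path, cerebellum_mask=None) -> FCNetwork:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return FCNetwork(df.to_numpy(dtype=float), list(df.columns), cerebellum_mask)


def write_edge_list(net: FCNetwork, path) -> None:
    i, j = np.nonzero(np.triu(net.weights, 1))
    pd.DataFrame(
        {
            "node_i": [net.node_labels[a] for a in i],
            "node_j": [net.node_labels[b] for b in j],
            "weight": net.weights[i, j],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_parcellation(parcels: ParcelVolume, path) -> None:
    img = nib.Nifti1Image(parcels.labels.astype(np.int32), affine=np.eye(4))
    nib.save(img, str(path))


def read_parcellation(path) -> ParcelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    return ParcelVolume(labels, int(labels.max()))
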