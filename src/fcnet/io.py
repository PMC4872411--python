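"""Delimited-text interchange: time series, matrices, networks, manifests.

TSV with '.' decimal is the interchange dialect everywhere; region labels
(not positional indices) are the join key across files. Time-series files
have the region labels as the header row and one time point per subsequent
row; connectivity matrices are written as labelled square tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import BinaryNetwork, ConnectivityMatrix, RoiTimeSeries

FLOAT_FMT = "%.10g"


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_timeseries(
    path: str | Path,
    sampling_interval: float,
    subject_id: str = "",
    condition: str = "",
    group: str = "",
) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        values=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        sampling_interval=sampling_interval,
        subject_id=subject_id,
        condition=condition,
        group=group,
    )


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.z, index=cm.region_labels, columns=cm.region_labels)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_connectivity(
    path: str | Path, subject_id: str = "", condition: str = "", group: str = ""
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        z=df.to_numpy(dtype=float),
        region_labels=[str(c) for c in df.columns],
        subject_id=subject_id,
        condition=condition,
        group=group,
    )


def write_network_edgelist(g: BinaryNetwork, path: str | Path) -> None:
    rows = [
        {"region_a": g.region_labels[i], "region_b": g.region_labels[j]}
        for i, j in g.edge_list()
    ]
    pd.DataFrame(rows, columns=["region_a", "region_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_network_adjacency(g: BinaryNetwork, path: str | Path) -> None:
    df = pd.DataFrame(
        g.adjacency, index=g.region_labels, columns=g.region_labels
    )
    df.to_csv(path, sep="\t")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def write_config_echo(config: dict, path: str | Path) -> None:
    from . import __version__

    payload = {"fcnet_version": __version__, **config}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
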