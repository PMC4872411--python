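"""ROI time series -> Fisher-z connectivity -> density-thresholded binary networks.

The pipeline entry point is an extracted regional time-series table (rows =
time points, columns = labelled regions). Connectivity is the Pearson
correlation between each pair of regional signals, Fisher z-transformed.
Binary networks are obtained by proportional thresholding: the top fraction
``density`` of all node pairs, ranked by connectivity, is kept as edges, so
every network in a study has exactly the same number of links and global
differences in correlation strength cannot drive topological differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries",
    "BandpassSpec",
    "ConnectivityMatrix",
    "BinaryNetwork",
    "bandpass",
    "correlation_matrix",
    "threshold_proportional",
]


@dataclass
class RoiTimeSeries:
    """One subject-session's T x N matrix of regional signals.

    Parameters
    ----------
    values
        Array of shape (n_timepoints, n_regions); no missing values.
    region_labels
        Unique, order-stable region names (one per column).
    sampling_interval
        Time between consecutive samples, in seconds (the fMRI TR).
    subject_id, condition, group
        Free-form session metadata carried through the pipeline.
    """

    values: np.ndarray
    region_labels: list[str]
    sampling_interval: float
    subject_id: str = ""
    condition: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x region) array")
        if self.values.shape[1] != len(self.region_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.region_labels)} region labels"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass specification (zero-phase application)."""

    low_hz: float
    high_hz: float
    filter_order: int = 2

    def __post_init__(self) -> None:
        if self.low_hz <= 0:
            raise ValueError("low_hz must be positive")
        if self.high_hz <= self.low_hz:
            raise ValueError("high_hz must exceed low_hz")
        if self.filter_order < 1:
            raise ValueError("filter_order must be a positive integer")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z connectivity with zero diagonal."""

    z: np.ndarray
    region_labels: list[str]
    subject_id: str = ""
    condition: str = ""
    group: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.region_labels)
        if self.z.shape != (n, n):
            raise ValueError("z must be square and match region_labels")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite entries")
        np.fill_diagonal(self.z, 0.0)

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a stated density."""

    adjacency: np.ndarray
    density: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(iu.tolist(), ju.tolist()))

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.region_labels)))


def bandpass(ts: RoiTimeSeries, spec: BandpassSpec) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass filter applied per region.

    Each column is demeaned and filtered forward-backward (``sosfiltfilt``),
    so no phase shift is introduced and the series length is preserved.
    Raises if the band is not representable at the series' sampling rate.
    """
    nyquist = 1.0 / (2.0 * ts.sampling_interval)
    if spec.high_hz >= nyquist:
        raise ValueError(
            f"high_hz={spec.high_hz} is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz implied by sampling_interval="
            f"{ts.sampling_interval}"
        )
    sos = signal.butter(
        spec.filter_order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=1.0 / ts.sampling_interval,
        output="sos",
    )
    demeaned = ts.values - ts.values.mean(axis=0, keepdims=True)
    filtered = signal.sosfiltfilt(sos, demeaned, axis=0)
    return RoiTimeSeries(
        values=filtered,
        region_labels=list(ts.region_labels),
        sampling_interval=ts.sampling_interval,
        subject_id=ts.subject_id,
        condition=ts.condition,
        group=ts.group,
    )


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation, Fisher z-transformed.

    z = atanh(r) for every region pair; the diagonal is forced to zero.
    Zero-variance regions and perfectly correlated off-diagonal pairs are
    degenerate inputs and raise with the offending region names.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points to correlate")
    sd = ts.values.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead)
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(r, 0.0)
    hit = np.abs(r) >= 1.0 - 1e-12
    if hit.any():
        i, j = np.argwhere(hit)[0]
        raise ValueError(
            "degenerate input: |r|=1 between regions "
            f"{ts.region_labels[i]!r} and {ts.region_labels[j]!r}"
        )
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float round-off
    return ConnectivityMatrix(
        z=z,
        region_labels=list(ts.region_labels),
        subject_id=ts.subject_id,
        condition=ts.condition,
        group=ts.group,
        provenance={"n_timepoints": ts.n_timepoints},
    )


def edge_count_for_density(n_nodes: int, density: float) -> int:
    """Number of retained links: round-half-even of density * N(N-1)/2."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.rint(density * n_pairs))


def threshold_proportional(
    cm: ConnectivityMatrix, density: float, ranking: str = "signed"
) -> BinaryNetwork:
    """Binarize by keeping the strongest fraction ``density`` of pairs.

    Ranking is by signed z by default (the strongest positive couplings
    survive; at 5-20 % density this is the usual binary-network convention);
    ``ranking="absolute"`` ranks by |z| instead. Ties at the cutoff are
    broken deterministically by lexicographic (row, column) order and a
    warning is logged, since the retained edge set then depends on node
    order rather than data.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie strictly between 0 and 1")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"unknown ranking {ranking!r}")
    n = cm.n_regions
    n_pairs = n * (n - 1) // 2
    k = edge_count_for_density(n, density)
    if k == 0:
        raise ValueError(
            f"density {density} keeps zero edges on {n} nodes; raise the density"
        )
    if k > n_pairs:
        raise ValueError("requested more edges than node pairs exist")

    iu, ju = np.triu_indices(n, 1)
    vals = cm.z[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    # descending value, then ascending (row, col) for deterministic ties
    order = np.lexsort((ju, iu, -vals))
    kept = order[:k]
    if k < n_pairs and vals[order[k - 1]] == vals[order[k]]:
        logger.warning(
            '{"event": "threshold_tie", "density": %s, "cutoff_value": %s}',
            density,
            float(vals[order[k - 1]]),
        )
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[kept], ju[kept]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj, density=density, region_labels=list(cm.region_labels)
    )
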