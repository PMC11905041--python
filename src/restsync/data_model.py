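"""Shared domain types and file I/O for sensor-space EEG analysis.

The package works on epoched multichannel voltage data (microvolts) together
with an electrode montage on the unit sphere.  The montage drives the spatial
adjacency graph used by cluster-based permutation statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Chord-distance threshold (unit-sphere coordinates) below which two
#: electrodes are considered spatial neighbours.  Calibrated on the packaged
#: 64-channel montage to give a connected graph with median node degree 7,
#: a typical EEG neighbourhood size.
DEFAULT_ADJACENCY_THRESHOLD = 0.58

#: Analysis frequency range in Hz; everything outside is discarded upstream.
ANALYSIS_RANGE = (2.0, 46.0)


@dataclass
class Montage:
    """Ordered electrode labels with unit-sphere 3D positions."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit length
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class EpochedRecording:
    """EEG voltages as channel x epoch x sample, in microvolts.

    A continuous recording is represented with a single epoch spanning the
    whole record; :func:`restsync.preprocess.segment_epochs` reshapes it.
    """

    data: np.ndarray  # (n_channels, n_epochs, n_samples)
    fs: float
    labels: list[str]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_epochs, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"channel count {self.data.shape[0]} != label count {len(self.labels)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_len(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.fs

    def continuous(self) -> np.ndarray:
        """Channel x sample view with epochs concatenated in order."""
        return self.data.reshape(self.n_channels, -1)


@dataclass
class BandScheme:
    """Ordered, non-overlapping half-open frequency intervals [lo, hi) in Hz."""

    bands: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_hi = None
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: need lo < hi")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError(f"band {name} overlaps the previous band")
            if lo < ANALYSIS_RANGE[0] - 1e-9 or hi > ANALYSIS_RANGE[1] + 1e-9:
                raise ValueError(f"band {name} outside analysis range {ANALYSIS_RANGE}")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def interval(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise KeyError(name)

    @classmethod
    def default(cls) -> "BandScheme":
        """Contiguous partition of 2-46 Hz into the five canonical bands.

        The conventional integer band edges (delta 2-3, theta 4-8, alpha 9-13,
        beta 14-30, gamma 31-45 Hz) leave 1-Hz gaps between bands; closing
        them into the half-open partition below makes relative powers sum to
        one per channel.  Use :meth:`printed` for the literal integer edges.
        """
        return cls(
            [
                ("delta", 2.0, 4.0),
                ("theta", 4.0, 9.0),
                ("alpha", 9.0, 14.0),
                ("beta", 14.0, 31.0),
                ("gamma", 31.0, 46.0),
            ]
        )

    @classmethod
    def printed(cls) -> "BandScheme":
        """The literal integer band edges (non-contiguous)."""
        return cls(
            [
                ("delta", 2.0, 3.0),
                ("theta", 4.0, 8.0),
                ("alpha", 9.0, 13.0),
                ("beta", 14.0, 30.0),
                ("gamma", 31.0, 45.0),
            ]
        )


@dataclass
class AdjacencyGraph:
    """Undirected electrode neighbourhood graph for cluster formation."""

    n_nodes: int
    edges: set = field(default_factory=set)  # frozenset-free: sorted tuples

    def __post_init__(self) -> None:
        clean = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError("edge index out of range")
            clean.add((min(i, j), max(i, j)))
        self.edges = clean

    def to_sparse(self) -> sp.csr_matrix:
        if not self.edges:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        idx = np.array(sorted(self.edges))
        rows = np.concatenate([idx[:, 0], idx[:, 1]])
        cols = np.concatenate([idx[:, 1], idx[:, 0]])
        return sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        n_comp, _ = connected_components(self.to_sparse(), directed=False)
        return n_comp == 1

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


# ---------------------------------------------------------------------------
# Montage I/O and adjacency construction
# ---------------------------------------------------------------------------

def load_montage(path: str | Path) -> Montage:
    """Read a whitespace/comma separated table of ``label x y z`` rows.

    Positions are normalised to unit length; row order is preserved.
    Duplicate labels or non-numeric coordinates raise ``ValueError``.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {line!r}")
        label = parts[0]
        if label in labels:
            raise ValueError(f"{path}:{lineno}: duplicate electrode label {label!r}")
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
        labels.append(label)
        rows.append(xyz)
    if not labels:
        raise ValueError(f"{path}: empty montage file")
    pos = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError("electrode at the origin cannot be normalised")
    return Montage(labels=labels, positions=pos / norms[:, None])


def default_montage() -> Montage:
    """The packaged 64-channel Biosemi 10-10 montage."""
    with resources.as_file(
        resources.files("restsync.data").joinpath("biosemi64.tsv")
    ) as p:
        return load_montage(p)


def build_adjacency(
    montage: Montage, threshold: float = DEFAULT_ADJACENCY_THRESHOLD
) -> AdjacencyGraph:
    """Neighbour electrodes are those closer than ``threshold`` chord units.

    A threshold small enough to disconnect the graph is permitted (clusters
    simply cannot span components) but logged as a warning.
    """
    if montage.n_channels < 2:
        raise ValueError("adjacency needs at least two electrodes")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dist = squareform(pdist(montage.positions))
    ii, jj = np.nonzero((dist < threshold) & ~np.eye(montage.n_channels, dtype=bool))
    edges = {(int(i), int(j)) for i, j in zip(ii, jj) if i < j}
    graph = AdjacencyGraph(n_nodes=montage.n_channels, edges=edges)
    if not graph.is_connected():
        logger.warning(
            "adjacency graph disconnected at threshold %.3g; clusters cannot "
            "span components",
            threshold,
        )
    return graph


# ---------------------------------------------------------------------------
# Recording I/O: EDF (read-only, via MNE) and .npy + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: EpochedRecording, path: str | Path) -> None:
    """Write the packaged format: ``.npy`` voltage matrix + JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, rec.data)
    meta = {
        "labels": rec.labels,
        "fs": rec.fs,
        "epoch_len": rec.epoch_len,
        "n_epochs": rec.n_epochs,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> EpochedRecording:
    """Read an EDF file or the packaged ``.npy`` + JSON sidecar format.

    EDF records come back as one continuous epoch with physical units
    converted to microvolts.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    try:
        data = np.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read recording {path}: {exc}") from exc
    meta = json.loads(_sidecar_path(path).read_text())
    if data.shape[0] != len(meta["labels"]):
        raise ValueError(
            f"{path}: data has {data.shape[0]} channels but sidecar lists "
            f"{len(meta['labels'])} labels"
        )
    if data.ndim == 2:
        data = data[:, None, :]
    if data.shape[1] != meta.get("n_epochs", data.shape[1]):
        raise ValueError(f"{path}: epoch count mismatch with sidecar")
    return EpochedRecording(
        data=data,
        fs=float(meta["fs"]),
        labels=list(meta["labels"]),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", "unknown"),
    )


def _read_edf(path: Path) -> EpochedRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return EpochedRecording(
        data=data[:, None, :],
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        subject_id=path.stem,
    )
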