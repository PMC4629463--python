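"""Structural connectome containers and I/O.

A structural connectome bundles, per subject, a symmetric non-negative
``weights`` matrix (fractional anisotropy × streamline count per pathway,
dimensionless) and a ``lengths`` matrix (tract lengths in mm), together
with region labels and group membership.  Binary adjacency graphs derived
from the weights feed the graph-metric layer; the full weighted bundle
feeds the simulator.

Supported on-disk dialects:

``csv_pair``
    ``<stem>_weights.txt`` / ``<stem>_tract_lengths.txt`` /
    ``<stem>_region_labels.txt`` next to each other, whitespace- or
    comma-delimited, plus an optional ``<stem>_meta.json`` sidecar.
``zip_bundle``
    One zip archive containing members ``weights.txt``,
    ``tract_lengths.txt``, ``region_labels.txt`` and optional
    ``meta.json``.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StructuralConnectome",
    "AdjacencyGraph",
    "ConnectomeFormatError",
    "ConnectomeValidationError",
    "read_connectome",
    "write_connectome",
    "binarize",
]

#: largest tolerated absolute asymmetry in an input matrix before it is
#: rejected instead of silently symmetrized
ASYMMETRY_TOLERANCE = 1e-9


class ConnectomeFormatError(ValueError):
    """Raised when an on-disk bundle cannot be parsed."""


class ConnectomeValidationError(ValueError):
    """Raised when parsed matrices violate a connectome invariant."""


@dataclass
class StructuralConnectome:
    """Per-subject structural connectivity bundle.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    region_labels : list of str
        One non-empty label per region.
    weights : (n, n) ndarray
        Symmetric, non-negative, zero-diagonal connection weights
        (FA × streamline count).
    lengths : (n, n) ndarray
        Symmetric, non-negative, zero-diagonal tract lengths in mm.
        Every positive weight must have a positive length.
    group_label : {"control", "stroke"}
    lesion_meta : dict or None
        Optional record ``{"regions": [...], "damage": [...]}`` describing
        an applied lesion.
    """

    subject_id: str
    region_labels: list[str]
    weights: np.ndarray
    lengths: np.ndarray
    group_label: str = "control"
    lesion_meta: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.validate()

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def validate(self) -> None:
        """Check all invariants, raising :class:`ConnectomeValidationError`."""
        n = self.n_regions
        if self.group_label not in ("control", "stroke"):
            raise ConnectomeValidationError(
                f"group_label must be 'control' or 'stroke', got {self.group_label!r}"
            )
        if n < 1:
            raise ConnectomeValidationError("connectome needs at least one region")
        if any((not isinstance(l, str)) or l == "" for l in self.region_labels):
            raise ConnectomeValidationError("region labels must be non-empty strings")
        for name, m in (("weights", self.weights), ("lengths", self.lengths)):
            if m.shape != (n, n):
                raise ConnectomeValidationError(
                    f"{name} has shape {m.shape}, expected ({n}, {n})"
                )
            if not np.all(np.isfinite(m)):
                raise ConnectomeValidationError(f"{name} contains non-finite entries")
            if np.any(m < 0):
                raise ConnectomeValidationError(f"{name} contains negative entries")
            _check_symmetry(m, name)
            if np.any(np.diag(m) != 0):
                raise ConnectomeValidationError(f"{name} has a non-zero diagonal")
        if np.any((self.weights > 0) & (self.lengths <= 0)):
            i, j = np.argwhere((self.weights > 0) & (self.lengths <= 0))[0]
            raise ConnectomeValidationError(
                f"positive weight with non-positive length at ({i}, {j})"
            )

    def copy(self, **changes) -> "StructuralConnectome":
        out = replace(
            self,
            weights=self.weights.copy(),
            lengths=self.lengths.copy(),
            region_labels=list(self.region_labels),
        )
        for k, v in changes.items():
            setattr(out, k, v)
        out.validate()
        return out


@dataclass
class AdjacencyGraph:
    """Symmetric binary graph with zero diagonal (0/1 entries)."""

    a: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        n = len(self.node_labels)
        if self.a.shape != (n, n):
            raise ConnectomeValidationError(
                f"adjacency shape {self.a.shape} does not match {n} labels"
            )
        if not np.array_equal(self.a, self.a.T):
            raise ConnectomeValidationError("adjacency matrix must be symmetric")
        if np.any(np.diag(self.a) != 0):
            raise ConnectomeValidationError("adjacency diagonal must be zero")
        if not np.isin(self.a, (0, 1)).all():
            raise ConnectomeValidationError("adjacency entries must be 0 or 1")
        self.a = self.a.astype(np.int8)

    @property
    def n(self) -> int:
        return len(self.node_labels)


def _check_symmetry(m: np.ndarray, name: str) -> None:
    d = np.abs(m - m.T)
    worst = d.max(initial=0.0)
    if worst > ASYMMETRY_TOLERANCE:
        i, j = np.unravel_index(np.argmax(d), d.shape)
        raise ConnectomeValidationError(
            f"{name} asymmetric beyond tolerance at cell ({i}, {j})/({j}, {i}): "
            f"{m[i, j]!r} vs {m[j, i]!r}"
        )


def _parse_matrix(text: str, name: str) -> np.ndarray:
    delimiter = "," if "," in text else None  # auto-detect: comma else whitespace
    try:
        m = np.loadtxt(io.StringIO(text), delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeFormatError(f"cannot parse {name}: {exc}") from exc
    if m.shape[0] != m.shape[1]:
        raise ConnectomeFormatError(f"{name} is not square: shape {m.shape}")
    return m


def _assemble(
    weights: np.ndarray,
    lengths: np.ndarray,
    labels: list[str],
    meta: dict,
) -> StructuralConnectome:
    if weights.shape != lengths.shape:
        raise ConnectomeFormatError(
            f"weights {weights.shape} and lengths {lengths.shape} differ in shape"
        )
    if len(labels) != weights.shape[0]:
        raise ConnectomeFormatError(
            f"{len(labels)} labels for {weights.shape[0]}x{weights.shape[0]} matrices"
        )
    for name, m in (("weights", weights), ("lengths", lengths)):
        if np.any(m < 0):
            i, j = np.argwhere(m < 0)[0]
            raise ConnectomeValidationError(f"negative entry in {name} at ({i}, {j})")
        _check_symmetry(m, name)
    # exact symmetrization of float-export jitter below tolerance
    weights = (weights + weights.T) / 2.0
    lengths = (lengths + lengths.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    np.fill_diagonal(lengths, 0.0)
    return StructuralConnectome(
        subject_id=meta.get("subject_id", "unknown"),
        region_labels=labels,
        weights=weights,
        lengths=lengths,
        group_label=meta.get("group_label", "control"),
        lesion_meta=meta.get("lesion_meta"),
    )


def _csv_pair_paths(path: Path) -> dict[str, Path]:
    stem = str(path)
    for suffix in ("_weights.txt", ""):
        if stem.endswith(suffix) and suffix:
            stem = stem[: -len(suffix)]
            break
    return {
        "weights": Path(stem + "_weights.txt"),
        "lengths": Path(stem + "_tract_lengths.txt"),
        "labels": Path(stem + "_region_labels.txt"),
        "meta": Path(stem + "_meta.json"),
    }


def read_connectome(path, dialect: str = "zip_bundle") -> StructuralConnectome:
    """Read a structural connectome bundle from disk.

    Parameters
    ----------
    path : path-like
        Zip archive (``zip_bundle``) or the ``<stem>_weights.txt`` /
        ``<stem>`` prefix of a text triplet (``csv_pair``).
    dialect : {"zip_bundle", "csv_pair"}
    """
    path = Path(path)
    if dialect == "zip_bundle":
        if not path.exists():
            raise FileNotFoundError(path)
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            for member in ("weights.txt", "tract_lengths.txt", "region_labels.txt"):
                if member not in names:
                    raise ConnectomeFormatError(f"bundle {path} lacks member {member}")
            weights = _parse_matrix(zf.read("weights.txt").decode(), "weights")
            lengths = _parse_matrix(zf.read("tract_lengths.txt").decode(), "lengths")
            labels = zf.read("region_labels.txt").decode().splitlines()
            labels = [l.strip() for l in labels if l.strip()]
            meta = json.loads(zf.read("meta.json")) if "meta.json" in names else {}
    elif dialect == "csv_pair":
        paths = _csv_pair_paths(path)
        for key in ("weights", "lengths", "labels"):
            if not paths[key].exists():
                raise FileNotFoundError(paths[key])
        weights = _parse_matrix(paths["weights"].read_text(), "weights")
        lengths = _parse_matrix(paths["lengths"].read_text(), "lengths")
        labels = [l.strip() for l in paths["labels"].read_text().splitlines() if l.strip()]
        meta = json.loads(paths["meta"].read_text()) if paths["meta"].exists() else {}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _assemble(weights, lengths, labels, meta)


def _matrix_text(m: np.ndarray) -> str:
    buf = io.StringIO()
    np.savetxt(buf, m, fmt="%.17g")
    return buf.getvalue()


def write_connectome(c: StructuralConnectome, path, dialect: str = "zip_bundle"):
    """Write ``c`` to ``path``; round-trips losslessly through
    :func:`read_connectome` and has a deterministic byte layout."""
    c.validate()
    path = Path(path)
    meta = {
        "subject_id": c.subject_id,
        "group_label": c.group_label,
        "lesion_meta": c.lesion_meta,
    }
    labels_text = "\n".join(c.region_labels) + "\n"
    meta_text = json.dumps(meta, sort_keys=True, indent=1)
    if dialect == "zip_bundle":
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            # fixed timestamps keep the byte layout reproducible
            for name, text in (
                ("weights.txt", _matrix_text(c.weights)),
                ("tract_lengths.txt", _matrix_text(c.lengths)),
                ("region_labels.txt", labels_text),
                ("meta.json", meta_text),
            ):
                zf.writestr(zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0)), text)
    elif dialect == "csv_pair":
        paths = _csv_pair_paths(path)
        paths["weights"].write_text(_matrix_text(c.weights))
        paths["lengths"].write_text(_matrix_text(c.lengths))
        paths["labels"].write_text(labels_text)
        paths["meta"].write_text(meta_text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def binarize(c: StructuralConnectome, threshold: float = 0.0) -> AdjacencyGraph:
    """Binary adjacency: an edge wherever ``weights[i, j] > threshold``.

    The default threshold 0 keeps every traced pathway as an edge;
    deterministic tractography already prunes weak pathways upstream via
    its FA and turning-angle stopping rules.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    a = (c.weights > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return AdjacencyGraph(a=a, node_labels=list(c.region_labels))
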