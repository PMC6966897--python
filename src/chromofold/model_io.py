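"""Locus model plus readers/writers for the pipeline's on-disk formats.

Coordinate conventions are 0-based half-open at base-pair level throughout;
bin ``i`` of a locus spans ``[start + i*bin_size, start + (i+1)*bin_size)``.

Formats handled here: dense whitespace text for Hi-C matrices (the canonical,
download-free fixture format), BED3+label for functional annotations,
whitespace-separated bin-index lines for proximity-cluster data, TSV for
per-bin feature tracks, and XYZ / PDB multi-model / NPZ containers for
conformation ensembles.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polymer import Ensemble, PolymerParams

logger = logging.getLogger(__name__)

ANNOTATION_LABELS = ("SE", "E", "P")


@dataclass(frozen=True)
class LocusSpec:
    """A genomic locus binned at fixed resolution (default 5 kb)."""

    chrom: str
    start: int
    end: int
    bin_size: int = 5000

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def n_bins(self) -> int:
        return math.ceil(self.length_bp / self.bin_size)

    def bin_of(self, pos: int) -> int:
        """Bin index of a bp position (0-based half-open)."""
        if not (self.start <= pos < self.end):
            raise ValueError(f"position {pos} outside locus")
        return (pos - self.start) // self.bin_size

    def bin_span(self, i: int) -> tuple[int, int]:
        if not (0 <= i < self.n_bins):
            raise ValueError("bin index out of range")
        return (self.start + i * self.bin_size,
                min(self.start + (i + 1) * self.bin_size, self.end))


@dataclass
class HiCMatrix:
    """Symmetric non-negative contact matrix over the bins of a locus."""

    locus: LocusSpec
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.locus.n_bins
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match locus ({n} bins)")
        if (v < 0).any():
            raise ValueError("negative Hi-C entries")
        if not np.isfinite(np.diag(v)).all():
            raise ValueError("non-finite diagonal")
        if not np.allclose(v, v.T, rtol=0, atol=1e-9 * max(1.0, np.abs(v).max())):
            raise ValueError("matrix is not symmetric")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.locus.n_bins


def load_hic(path, locus: LocusSpec, fmt: str = "dense",
             symmetrize: bool = False) -> HiCMatrix:
    """Load a Hi-C matrix from dense whitespace text (or NPZ container).

    An upper-triangular input (strict lower triangle all zero) is completed
    by mirroring.  Otherwise an asymmetric matrix is rejected unless
    ``symmetrize=True``, in which case it is averaged with its transpose.
    """
    if fmt == "dense":
        v = np.loadtxt(path, dtype=float)
    elif fmt == "npz":
        with np.load(path) as z:
            v = z["values"]
    else:
        raise ValueError(f"unknown Hi-C format {fmt!r}")
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n = locus.n_bins
    if v.shape != (n, n):
        raise ValueError(f"matrix shape {v.shape} does not match locus ({n} bins)")
    if (v < 0).any():
        raise ValueError("negative Hi-C entries")
    lower = np.tril(v, -1)
    upper = np.triu(v, 1)
    if np.any(upper) and not np.any(lower):
        v = v + upper.T
    elif not np.allclose(v, v.T, rtol=0, atol=1e-9 * max(1.0, np.abs(v).max())):
        if symmetrize:
            v = 0.5 * (v + v.T)
            logger.warning("asymmetric Hi-C input averaged with its transpose")
        else:
            raise ValueError("asymmetric Hi-C input (pass symmetrize=True to average)")
    return HiCMatrix(locus, v)


def save_hic(hic: HiCMatrix, path, fmt: str = "dense"):
    if fmt == "dense":
        np.savetxt(path, hic.values)
    elif fmt == "npz":
        np.savez(path, values=hic.values)
    else:
        raise ValueError(f"unknown Hi-C format {fmt!r}")


@dataclass
class AnnotationTrack:
    """Functional intervals (super-enhancer / enhancer / promoter) on a locus."""

    intervals: list
    locus: LocusSpec

    def __post_init__(self):
        for s, e, lab in self.intervals:
            if lab not in ANNOTATION_LABELS:
                raise ValueError(f"unknown annotation label {lab!r}")
            if not (self.locus.start <= s < e <= self.locus.end):
                raise ValueError("interval outside locus bounds")

    def bin_labels(self) -> list:
        """Per-bin sets of labels (a bin may carry multiple labels)."""
        out = [set() for _ in range(self.locus.n_bins)]
        b = self.locus.bin_size
        for s, e, lab in self.intervals:
            first = (s - self.locus.start) // b
            last = (e - 1 - self.locus.start) // b
            for i in range(first, last + 1):
                out[i].add(lab)
        return out


def load_bed(path, locus: LocusSpec) -> AnnotationTrack:
    """Read BED3+label annotations, clipping intervals to the locus.

    Unknown labels are skipped with a warning; malformed lines are a hard
    error naming the line number.  Intervals entirely outside the locus are
    dropped (count logged).
    """
    intervals = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            chrom, s, e, lab = parts[0], parts[1], parts[2], parts[3]
            try:
                s, e = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}") from exc
            if lab not in ANNOTATION_LABELS:
                warnings.warn(f"skipping unknown annotation label {lab!r} "
                              f"(line {lineno})")
                continue
            if chrom != locus.chrom or e <= locus.start or s >= locus.end:
                dropped += 1
                continue
            intervals.append((max(s, locus.start), min(e, locus.end), lab))
    if dropped:
        logger.info("load_bed: dropped %d interval(s) outside locus", dropped)
    return AnnotationTrack(intervals, locus)


@dataclass
class ClusterData:
    """Sets of co-captured bin indices (proximity-ligation cluster data)."""

    clusters: list
    n_bins: int | None = None

    def __post_init__(self):
        cl = [frozenset(int(i) for i in c) for c in self.clusters]
        for c in cl:
            if len(c) < 1:
                raise ValueError("empty cluster")
            if any(i < 0 for i in c):
                raise ValueError("negative bin index in cluster")
            if self.n_bins is not None and any(i >= self.n_bins for i in c):
                raise ValueError("cluster bin index out of range")
        self.clusters = cl


def load_clusters(path, n_bins: int | None = None) -> ClusterData:
    clusters = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            clusters.append([int(x) for x in line.split()])
    return ClusterData(clusters, n_bins=n_bins)


def save_clusters(clusters: ClusterData, path):
    with open(path, "w") as fh:
        for c in clusters.clusters:
            fh.write(" ".join(str(i) for i in sorted(c)) + "\n")


def load_features(path) -> pd.DataFrame:
    """Per-bin feature tracks as a bins x tracks table (TSV)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def save_features(features: pd.DataFrame, path):
    features.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Ensemble containers
# ---------------------------------------------------------------------------

_PDB_MAX = 999.999  # widest coordinate safely fitting the field (Angstrom,
                    # sign included)


def write_ensemble(ensemble: Ensemble, path, fmt: str = "xyz"):
    """Write an ensemble as XYZ multi-model, PDB multi-model, or NPZ.

    Coordinates are stored in nm (XYZ/NPZ) or Angstrom (PDB, the format's
    convention).  PDB coordinates exceeding the fixed field width are scaled
    down with a warning; XYZ and NPZ round-trip within float precision.
    """
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    if fmt == "xyz":
        with open(path, "w") as fh:
            for k in range(len(ensemble)):
                fh.write(f"{ensemble.n_bins}\n")
                fh.write(f"model={k} log_weight={ensemble.log_weights[k]:.17g}\n")
                for x, y, z in ensemble.coords[k]:
                    fh.write(f"C {x:.17g} {y:.17g} {z:.17g}\n")
    elif fmt == "npz":
        np.savez(path, coords=ensemble.coords, log_weights=ensemble.log_weights,
                 kind=ensemble.kind,
                 constraint_set=np.asarray(ensemble.constraint_set,
                                           dtype=np.int64).reshape(-1, 2))
    elif fmt == "pdb":
        from biotite.structure import Atom, array, stack
        from biotite.structure.io.pdb import PDBFile
        coords_ang = ensemble.coords * 10.0  # nm -> Angstrom
        peak = np.abs(coords_ang).max()
        if peak > _PDB_MAX:
            scale = _PDB_MAX / peak
            warnings.warn("coordinates exceed PDB field width; "
                          f"scaled by {scale:.3g}")
            coords_ang = coords_ang * scale
        models = []
        for k in range(len(ensemble)):
            atoms = [Atom(coords_ang[k, i], chain_id="A", res_id=i + 1,
                          res_name="BIN", atom_name="CA", element="C")
                     for i in range(ensemble.n_bins)]
            models.append(array(atoms))
        pdb = PDBFile()
        pdb.set_structure(stack(models))
        pdb.write(path)
    else:
        raise ValueError(f"unknown ensemble format {fmt!r}")


def read_ensemble(path, params: PolymerParams, fmt: str = "xyz") -> Ensemble:
    if fmt == "xyz":
        coords, logw = [], []
        with open(path) as fh:
            lines = fh.read().splitlines()
        pos = 0
        while pos < len(lines):
            n = int(lines[pos])
            header = lines[pos + 1]
            lw = 0.0
            for tok in header.split():
                if tok.startswith("log_weight="):
                    lw = float(tok.split("=", 1)[1])
            block = np.array([[float(v) for v in ln.split()[1:4]]
                              for ln in lines[pos + 2:pos + 2 + n]])
            coords.append(block)
            logw.append(lw)
            pos += 2 + n
        return Ensemble(np.asarray(coords), np.asarray(logw), params)
    if fmt == "npz":
        with np.load(path) as z:
            cs = tuple(map(tuple, z["constraint_set"]))
            return Ensemble(z["coords"], z["log_weights"], params,
                            kind=str(z["kind"]), constraint_set=cs)
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile
        pdb = PDBFile.read(path)
        arr = pdb.get_structure()
        coords = np.asarray(arr.coord) / 10.0  # Angstrom -> nm
        if coords.ndim == 2:
            coords = coords[None]
        return Ensemble(coords, np.zeros(len(coords)), params)
    raise ValueError(f"unknown ensemble format {fmt!r}")


def save_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
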