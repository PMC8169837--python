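"""Readers and writers for the formats the pipeline touches, plus run configuration.

Count matrices are read either from a MatrixMarket triplet directory
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, the 10x genes-by-cells
convention) or from a dense TSV with gene rows and unit columns.  Gene-set
libraries use the tab-separated GMT format.  Every table written by the
pipeline carries a comment header recording the package version, the seed and
the parameters of the run, so results are traceable to their configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from . import __version__

log = logging.getLogger("gliotraj")


def setup_logging(level: int = logging.INFO) -> None:
    """Log to stderr with a machine-parseable prefix; results go to files/stdout only."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[gliotraj] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Run configuration with the analysis parameters and their defaults.

    Parameters mirror the analysis conventions: library-size normalisation to a
    scale of 10,000 with a log transform; cell QC at a minimum of 500 detected
    genes and a maximum mitochondrial fraction of 25%; ssGSEA rank-weight
    exponent tau = 0.25 with an empirical null of 100,000 random gene sets;
    stage-specific gene calling at a 1.2-fold margin over the other stages; a
    k = 200 nearest-neighbour graph (capped at n_cells - 1 on small data) for
    the diffusion map; and 1,000 root-ward random walks per trajectory tip.
    """

    seed: int = 0
    normalization_scale: float = 10_000.0
    qc_min_genes: int = 500
    qc_max_mito_frac: float = 0.25
    ssgsea_tau: float = 0.25
    null_draws: int = 100_000
    stage_fold: float = 1.2
    knn: int = 200
    n_walks_per_tip: int = 1_000
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normalization_scale <= 0:
            raise ValueError("normalization_scale must be positive")
        if self.qc_min_genes < 0:
            raise ValueError("qc_min_genes must be non-negative")
        if not 0.0 <= self.qc_max_mito_frac <= 1.0:
            raise ValueError("qc_max_mito_frac must lie in [0, 1]")
        if self.ssgsea_tau < 0:
            raise ValueError("ssgsea_tau must be non-negative")
        if self.null_draws < 1:
            raise ValueError("null_draws must be a positive integer")
        if self.stage_fold <= 1:
            raise ValueError("stage_fold must exceed 1")
        if self.knn < 1:
            raise ValueError("knn must be a positive integer")
        if self.n_walks_per_tip < 1:
            raise ValueError("n_walks_per_tip must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class CountMatrix:
    """Integer gene x unit count table with identifiers.

    ``units`` are cells for single-cell input or samples for bulk/pseudo-bulk
    input.  Identifiers must be unique and consistent with the matrix shape.
    """

    values: np.ndarray  # genes x units, non-negative integers
    gene_ids: list[str]
    unit_ids: list[str]
    unit_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.floor(self.values)):
                raise ValueError("count matrix must contain integer entries")
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} matrix rows"
            )
        if len(self.unit_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.unit_ids)} unit ids but {self.values.shape[1]} matrix columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit identifiers")
        if self.unit_meta is not None and len(self.unit_meta) != len(self.unit_ids):
            raise ValueError("unit_meta length does not match number of units")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)


@dataclass
class ModuleLibrary:
    """Ordered collection of named gene sets (signatures, lineage modules, cell-cycle sets)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            # de-duplicate preserving order
            self.sets[name] = list(dict.fromkeys(str(g) for g in genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class DepthProfile:
    """Per-base read depth over an edited locus with two gRNA cut-site coordinates.

    Coordinates are 0-based, half-open (BED convention); ``depth[i]`` is the
    depth at base ``i`` of the locus.
    """

    locus_id: str
    depth: np.ndarray
    site1: int
    site2: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D per-base vector")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")
        if not (0 <= self.site1 < self.site2 <= len(self.depth)):
            raise ValueError("cut sites must satisfy 0 <= site1 < site2 <= locus length")

    @property
    def length(self) -> int:
        return len(self.depth)


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from an MTX triplet directory or a dense TSV.

    A directory is treated as a MatrixMarket triplet (``matrix.mtx`` with
    1-based indices per the standard, ``features.tsv``, ``barcodes.tsv``);
    a file is treated as a dense TSV with gene rows and unit columns.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = frame.to_numpy()
    if not np.all(values == np.floor(values)):
        raise ValueError(f"{path}: non-integer entries in count matrix")
    return CountMatrix(
        values=values.astype(np.int64),
        gene_ids=list(frame.index.astype(str)),
        unit_ids=list(frame.columns.astype(str)),
    )


def _read_mtx_dir(path: Path) -> CountMatrix:
    mtx_path = _first_existing(path, ["matrix.mtx"])
    feat_path = _first_existing(path, ["features.tsv", "genes.tsv"])
    bc_path = _first_existing(path, ["barcodes.tsv"])
    _check_mtx_indices(mtx_path)
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if not np.all(mat == np.floor(mat)):
        raise ValueError(f"{mtx_path}: non-integer entries in count matrix")
    genes = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape == (len(barcodes), len(genes)) and len(genes) != len(barcodes):
        raise ValueError(
            f"{mtx_path}: matrix is {mat.shape} but features/barcodes imply "
            f"{(len(genes), len(barcodes))}; input looks transposed (units x genes) — "
            "rewrite it genes x units rather than relying on silent transposition"
        )
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{mtx_path}: matrix is {mat.shape}, expected ({len(genes)}, {len(barcodes)})"
        )
    return CountMatrix(values=mat.astype(np.int64), gene_ids=genes, unit_ids=barcodes)


def _first_existing(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {list(names)} found in {directory}")


def _check_mtx_indices(mtx_path: Path) -> None:
    """Reject 0-based coordinate entries: the MatrixMarket standard is 1-based."""
    with open(mtx_path) as fh:
        header = fh.readline()
        if "array" in header:
            return  # dense array body has no indices
        for line in fh:
            if line.startswith("%"):
                continue
            break  # size line
        for line in fh:
            parts = line.split()
            if len(parts) >= 2 and (int(parts[0]) < 1 or int(parts[1]) < 1):
                raise ValueError(f"{mtx_path}: 0 index found; MTX indices are 1-based")


def write_counts_mtx(counts: CountMatrix, directory: str | Path) -> Path:
    """Write a count matrix as a MatrixMarket triplet directory (genes x units)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.unit_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return directory


def read_gmt(path: str | Path) -> ModuleLibrary:
    """Read a tab-separated GMT gene-set library (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = genes
    return ModuleLibrary(sets=sets)


def write_gmt(library: ModuleLibrary, path: str | Path, description: str = "gliotraj") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in library.names():
            fh.write("\t".join([name, description] + library[name]) + "\n")
    return path


def read_depth_profile(path: str | Path) -> DepthProfile:
    """Read a per-base depth profile from a BED-like TSV.

    Columns: chrom/locus, start, end, depth — one row per base
    (0-based, half-open, so end = start + 1).  Cut sites are recorded in
    ``#site1=``/``#site2=`` header comments.
    """
    path = Path(path)
    site1 = site2 = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#site1="):
                site1 = int(line.strip().split("=", 1)[1])
            elif line.startswith("#site2="):
                site2 = int(line.strip().split("=", 1)[1])
            elif not line.startswith("#"):
                break
    frame = pd.read_csv(
        path, sep="\t", comment="#",
        names=["locus", "start", "end", "depth"], header=None,
    )
    if site1 is None or site2 is None:
        raise ValueError(f"{path}: missing #site1=/#site2= header comments")
    frame = frame.sort_values("start")
    if not np.array_equal(frame["start"].to_numpy(), np.arange(len(frame))):
        raise ValueError(f"{path}: depth rows must cover every base exactly once")
    return DepthProfile(
        locus_id=str(frame["locus"].iloc[0]),
        depth=frame["depth"].to_numpy(dtype=float),
        site1=site1,
        site2=site2,
    )


def write_depth_profile(profile: DepthProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#site1={profile.site1}\n#site2={profile.site2}\n")
        for i, d in enumerate(profile.depth):
            fh.write(f"{profile.locus_id}\t{i}\t{i + 1}\t{d:g}\n")
    return path


# ---------------------------------------------------------------------------
# writers


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: dict | None = None,
) -> Path:
    """Write a tabular result as TSV with a provenance comment header.

    The header records the tool version, the seed and the parameters of the
    producing run; a read-back with :func:`read_table` reproduces the values
    to full stored precision.
    """
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory, not a writable file path")
    with open(path, "w") as fh:
        fh.write(f"# gliotraj version={__version__}\n")
        fh.write(f"# seed={seed}\n")
        for key, value in sorted((params or {}).items()):
            fh.write(f"# param {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
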