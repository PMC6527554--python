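"""Core data containers and file IO for count-matrix analysis.

The central object is :class:`CountMatrix`, a gene x sample table of
non-negative read counts.  Counts may be fractional: transcript-level
quantification summarized to genes (e.g. length-scaled TPM counts) yields
non-integer estimates, and every estimator downstream accepts them
unrounded.  :class:`SampleDesign` maps samples to groups and optional
covariates (replicate, batch, ...), and :class:`AnalysisConfig` collects
the analysis-wide cutoffs and the seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sps

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "AnalysisConfig",
    "ValidationReport",
    "read_counts",
    "write_counts",
    "read_design",
    "validate_dataset",
    "write_run_metadata",
]

DEFAULT_SEED = 20190520


class CountDataError(ValueError):
    """Raised for malformed count or design inputs."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise CountDataError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative (possibly fractional) counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise CountDataError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountDataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.counts)):
            bad = np.argwhere(~np.isfinite(self.counts))[0]
            raise CountDataError(
                f"non-finite count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise CountDataError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Subset genes by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        genes = [self.gene_ids[i] for i in keep]
        return CountMatrix(genes, list(self.sample_ids), self.counts[keep, :])


@dataclass
class SampleDesign:
    """Assignment of samples to groups, with optional covariates."""

    sample_ids: list[str]
    group: dict[str, str]
    covariates: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        missing = [s for s in self.sample_ids if s not in self.group]
        if missing:
            raise CountDataError(f"samples without a group label: {missing}")
        empty = [s for s in self.sample_ids if str(self.group[s]).strip() == ""]
        if empty:
            raise CountDataError(f"empty group label for samples: {empty}")

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        out: list[str] = []
        for s in self.sample_ids:
            g = self.group[s]
            if g not in out:
                out.append(g)
        return out

    def samples_in(self, group_label: str) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == group_label]

    def comparison_samples(self, comparison: tuple[str, str]) -> list[str]:
        """Samples belonging to either group of a two-group comparison."""
        a, b = self.resolve_comparison(comparison)
        return [s for s in self.sample_ids if self.group[s] in (a, b)]

    def resolve_comparison(self, comparison: tuple[str, str]) -> tuple[str, str]:
        comparison = tuple(comparison)
        if len(comparison) != 2:
            raise CountDataError(
                f"a comparison names exactly two groups, got {len(comparison)}; "
                "use glm_ql_test with covariates for richer designs"
            )
        a, b = comparison
        if a == b:
            raise CountDataError("comparison must name two distinct groups")
        for g in (a, b):
            if not self.samples_in(g):
                raise CountDataError(f"comparison group {g!r} has no samples")
        return a, b

    def covariate_frame(self, samples: Sequence[str]) -> pd.DataFrame:
        data = {
            name: [values.get(s, "") for s in samples]
            for name, values in self.covariates.items()
        }
        return pd.DataFrame(data, index=list(samples))


@dataclass
class AnalysisConfig:
    """Analysis-wide parameters and cutoffs.

    Defaults follow common practice for this kind of power-aware workflow:
    single-gene power at alpha = 0.01 for a two-fold change, gene-wise
    power at FDR level 0.1 with 10% expected true positives, a gene called
    detectable at power >= 0.8, DE at BH-FDR < 0.05, and signature
    membership at power >= 0.7 / FDR < 0.01.
    """

    comparison: tuple[str, str] | None = None
    alpha: float = 0.01
    fold_change: float = 2.0
    fdr_level: float = 0.1
    true_positive_fraction: float = 0.1
    power_detectable_cutoff: float = 0.8
    signature_power_cutoff: float = 0.7
    signature_fdr_cutoff: float = 0.01
    de_fdr_cutoff: float = 0.05
    top_k_variable: int = 500
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_level", "true_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise CountDataError(f"{name} must lie in (0, 1), got {v}")
        if self.fold_change <= 0:
            raise CountDataError("fold_change must be positive")
        for name in (
            "power_detectable_cutoff",
            "signature_power_cutoff",
            "signature_fdr_cutoff",
            "de_fdr_cutoff",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CountDataError(f"{name} must lie in [0, 1], got {v}")
        if self.top_k_variable < 1:
            raise CountDataError("top_k_variable must be >= 1")

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SEP_BY_EXT = {".tsv": "\t", ".txt": "\t", ".csv": ","}


def _infer_sep(path: Path, fmt: str | None) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    return _SEP_BY_EXT.get(path.suffix.lower(), "\t")


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV/CSV or MatrixMarket triplet files.

    Tabular files carry a header row of sample ids and gene ids in the
    first column.  ``format="mtx-triplet"`` (or a ``.mtx`` suffix) reads a
    MatrixMarket coordinate file; gene and sample ids come from sidecar
    files ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one id per
    line).  Cells absent from the triplet list are zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx-triplet" or path.suffix.lower() == ".mtx":
        return _read_mtx_triplet(path)
    sep = _infer_sep(path, format)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    if df.columns.size == 0:
        raise CountDataError(f"{path}: no sample columns found")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise CountDataError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, "
                f"row {bad.index[0]!r}"
            )
    try:
        return CountMatrix.from_frame(df)
    except CountDataError as e:
        raise CountDataError(f"{path}: {e}") from e


def _read_mtx_triplet(path: Path) -> CountMatrix:
    stem = path.with_suffix("")
    gene_file = stem.with_suffix(".genes.txt")
    sample_file = stem.with_suffix(".samples.txt")
    for f in (gene_file, sample_file):
        if not f.exists():
            raise FileNotFoundError(
                f"{path}: sidecar id file {f.name} not found next to the .mtx file"
            )
    mat = spio.mmread(str(path))
    dense = np.asarray(mat.todense() if sps.issparse(mat) else mat, dtype=float)
    genes = gene_file.read_text().split()
    samples = sample_file.read_text().split()
    if dense.shape != (len(genes), len(samples)):
        raise CountDataError(
            f"{path}: matrix shape {dense.shape} does not match sidecar ids "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    try:
        return CountMatrix(genes, samples, dense)
    except CountDataError as e:
        raise CountDataError(f"{path}: {e}") from e


def write_counts(cm: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a count matrix; format inferred from the extension.

    Writing then reading reproduces values to full precision and keeps
    gene/sample order.
    """
    path = Path(path)
    if format == "mtx-triplet" or path.suffix.lower() == ".mtx":
        stem = path.with_suffix("")
        spio.mmwrite(str(path), sps.coo_matrix(cm.counts))
        stem.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
        return
    sep = _infer_sep(path, format)
    cm.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design TSV: ``sample_id``, ``group``, extra columns
    become covariates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_sep(path, None), dtype=str).fillna("")
    cols = list(df.columns)
    if "sample_id" not in cols:
        raise CountDataError(f"{path}: required column 'sample_id' missing (found {cols})")
    group_col = "group" if "group" in cols else next(
        (c for c in cols if c != "sample_id"), None
    )
    if group_col is None:
        raise CountDataError(f"{path}: no group column found")
    samples = list(df["sample_id"])
    group = dict(zip(samples, df[group_col]))
    covariates = {
        c: dict(zip(samples, df[c]))
        for c in cols
        if c not in ("sample_id", group_col)
    }
    try:
        return SampleDesign(samples, group, covariates)
    except CountDataError as e:
        raise CountDataError(f"{path}: {e}") from e


@dataclass
class ValidationReport:
    issues: list[str]
    library_sizes: dict[str, float]
    n_all_zero_genes: int

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(cm: CountMatrix, sd: SampleDesign) -> ValidationReport:
    """Cross-check counts against the design.

    Mismatched sample sets are a hard error; soft issues (all-zero genes,
    zero library sizes) are reported.
    """
    counts_set = set(cm.sample_ids)
    design_set = set(sd.sample_ids)
    if counts_set.isdisjoint(design_set):
        raise CountDataError("counts and design share no sample ids")
    missing = sorted(counts_set - design_set)
    extra = sorted(design_set - counts_set)
    if missing or extra:
        raise CountDataError(
            "sample sets differ between counts and design: "
            f"in counts only {missing}, in design only {extra}"
        )
    issues: list[str] = []
    lib = cm.library_sizes()
    zero_lib = [s for s, l in zip(cm.sample_ids, lib) if l == 0]
    if zero_lib:
        issues.append(f"samples with zero library size: {zero_lib}")
    n_zero = int(np.sum(cm.counts.sum(axis=1) == 0))
    if n_zero:
        issues.append(f"{n_zero} gene(s) have zero counts in every sample")
    return ValidationReport(
        issues=issues,
        library_sizes=dict(zip(cm.sample_ids, lib.astype(float))),
        n_all_zero_genes=n_zero,
    )


def write_run_metadata(path: str | Path, config: AnalysisConfig, **extra) -> None:
    """JSON sidecar recording parameters, versions, and the seed."""
    from . import __version__

    meta = {
        "countpower_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        },
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
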