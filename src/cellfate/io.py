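"""Core containers and file I/O shared by every pipeline stage.

The pipeline's substrate is a gene x sample expression table (raw counts or
TPM), annotated genes (biotype, length), ordered disease-stage labels per
sample, and named gene programs (five cell-death modes, the NOS family, and
necroptosis marker genes) read from GMT files.  Everything here is plain
pandas underneath; the thin dataclass wrappers exist to enforce the
invariants the downstream statistics rely on (unique identifiers,
non-negativity, TPM columns summing to one million, proportions on the
simplex).

Tables are tab-separated UTF-8 with a header row (comma-separated input is
accepted on read by sniffing the delimiter).  Lines starting with ``#`` are
treated as comments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "GeneAnnotation",
    "SampleMetadata",
    "GeneSetCatalog",
    "ProportionMatrix",
    "PipelineConfig",
    "read_expression_table",
    "write_expression_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gmt",
    "write_gmt",
    "read_proportions",
    "write_proportions",
    "counts_to_tpm",
    "log10_tpm",
]

TPM_TOTAL = 1e6

#: default ordered Braak-Lewy-body stage labels (under-sampled BLB1-4 dropped)
DEFAULT_STAGE_ORDER: tuple[str, ...] = ("BLB0", "BLB5", "BLB6")


class ValidationError(ValueError):
    """An input violates a container invariant (duplicates, negatives, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries the offending line."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} ID: {x!r}")
        seen.add(x)
    return ids


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Row/column order is meaningful and preserved.
    unit_kind:
        ``"counts"``, ``"TPM"`` or ``"logTPM"`` (log10(TPM + 1)).
    """

    data: pd.DataFrame
    unit_kind: str = "counts"
    #: column sums are only checked for full TPM matrices; a gene subset of
    #: a TPM table keeps the unit but no longer sums to one million
    strict_tpm: bool = True

    def __post_init__(self) -> None:
        if self.unit_kind not in ("counts", "TPM", "logTPM"):
            raise ValidationError(f"unknown unit_kind {self.unit_kind!r}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if self.unit_kind in ("counts", "TPM"):
            neg = np.argwhere(values < 0)
            if neg.size:
                i, j = neg[0]
                raise ValidationError(
                    f"negative value {values[i, j]!r} at "
                    f"(gene={self.data.index[i]!r}, sample={self.data.columns[j]!r})"
                )
        if self.unit_kind == "TPM" and self.strict_tpm and self.data.shape[0] > 0:
            sums = values.sum(axis=0)
            bad = np.where(np.abs(sums - TPM_TOTAL) > 1e-6 * TPM_TOTAL)[0]
            if bad.size:
                j = bad[0]
                raise ValidationError(
                    f"TPM column {self.data.columns[j]!r} sums to {sums[j]:.6g}, "
                    f"expected {TPM_TOTAL:g}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not present: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.unit_kind,
                                strict_tpm=False)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not present: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)], self.unit_kind,
                                strict_tpm=self.strict_tpm)


@dataclass
class GeneAnnotation:
    """Per-gene biotype and length (base pairs), one row per gene."""

    data: pd.DataFrame  # index: gene_id; columns: biotype, length_bp

    def __post_init__(self) -> None:
        for col in ("biotype", "length_bp"):
            if col not in self.data.columns:
                raise ValidationError(f"annotation is missing column {col!r}")
        _check_unique(self.data.index, "gene")
        lengths = self.data["length_bp"].to_numpy()
        if not np.issubdtype(lengths.dtype, np.number) or (lengths < 1).any():
            bad = self.data.index[np.asarray(lengths < 1).nonzero()[0][:1]]
            raise ValidationError(f"length_bp must be >= 1 (gene {list(bad)!r})")

    def lengths_kb(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"gene missing from annotation: {missing[0]!r}")
        return self.data.loc[list(genes), "length_bp"].to_numpy(float) / 1e3

    def biotype(self, genes: Sequence[str]) -> pd.Series:
        return self.data.loc[list(genes), "biotype"]


@dataclass
class SampleMetadata:
    """Per-sample stage (ordered categorical) and optional binary group."""

    data: pd.DataFrame  # index: sample_id; columns: stage [, group]
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        if "stage" not in self.data.columns:
            raise ValidationError("metadata is missing column 'stage'")
        _check_unique(self.data.index, "sample")
        self.stage_order = tuple(self.stage_order)
        unknown = set(self.data["stage"].astype(str)) - set(self.stage_order)
        if unknown:
            raise ValidationError(
                f"stage labels {sorted(unknown)} not in declared order {self.stage_order}"
            )
        self.data = self.data.copy()
        self.data["stage"] = pd.Categorical(
            self.data["stage"].astype(str), categories=self.stage_order, ordered=True
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_in_stage(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise ValidationError(f"unknown stage {stage!r}")
        return list(self.data.index[self.data["stage"] == stage])

    def stages_present(self) -> list[str]:
        present = set(self.data["stage"].astype(str))
        return [s for s in self.stage_order if s in present]


@dataclass
class GeneSetCatalog:
    """Named gene programs with a role tag per set.

    Roles: ``death_mode`` (the five cell-death programs), ``nos`` (NOS1-3),
    ``marker`` (necroptosis marker genes used for the biomarker stage).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene (set {name!r})")
        for name in self.roles:
            if name not in self.sets:
                raise ValidationError(f"role given for unknown set {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def names_with_role(self, role: str) -> list[str]:
        return [n for n in self.sets if self.roles.get(n) == role]

    def add(self, name: str, genes: Sequence[str], role: str = "death_mode",
            description: str = "") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        self.sets[name] = _check_unique(genes, f"gene (set {name!r})")
        if not genes:
            raise ValidationError(f"gene set {name!r} is empty")
        self.roles[name] = role
        self.descriptions[name] = description


@dataclass
class ProportionMatrix:
    """Sample x cell-type composition estimates on the probability simplex."""

    data: pd.DataFrame  # index: sample_id; columns: cell types

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "cell type")
        values = self.data.to_numpy(float)
        if (values < -1e-12).any():
            raise ValidationError("proportions must be non-negative")
        sums = values.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"proportion row {self.data.index[bad[0]]!r} sums to {sums[bad[0]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


@dataclass
class PipelineConfig:
    """Thresholds and run parameters shared across stages.

    ``log2fc_min`` / ``p_max`` are the differential-expression significance
    criteria (|log2FC| >= 1 and P <= 0.05 by default); ``mantel_r_min`` is the
    strong-correlation cutoff on the Mantel statistic (R > 0.5);
    ``n_permutations`` drives both the Mantel and ordination permutation
    tests (1,000 by default).
    """

    log2fc_min: float = 1.0
    p_max: float = 0.05
    mantel_r_min: float = 0.5
    n_permutations: int = 1000
    rng_seed: int = 0
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    fdr_method: str = "fdr_bh"

    def __post_init__(self) -> None:
        if not self.log2fc_min > 0:
            raise ValidationError("log2fc_min must be > 0")
        if not 0 < self.p_max < 1:
            raise ValidationError("p_max must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        self.stage_order = tuple(self.stage_order)

    def to_dict(self) -> dict:
        return {
            "log2fc_min": self.log2fc_min,
            "p_max": self.p_max,
            "mantel_r_min": self.mantel_r_min,
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
            "stage_order": list(self.stage_order),
            "fdr_method": self.fdr_method,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**payload)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise ParseError(f"{path}: file contains no data lines")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0, comment="#",
                       float_precision="round_trip")


def read_expression_table(path: str | Path, unit_kind: str = "counts") -> ExpressionMatrix:
    """Read a delimited gene x sample table (first column = gene IDs)."""
    path = Path(path)
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        i = int(np.argwhere(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric value for gene {df.index[i]!r} "
            f"(data line {i + 1})"
        )
    return ExpressionMatrix(numeric, unit_kind)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           header_comment: str | None = None) -> None:
    """Write a matrix as TSV; full float precision so a read round-trips."""
    if matrix.data.shape[0] == 0:
        raise ValidationError("refusing to write an expression table with no genes")
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_table(path)
    df.index = df.index.astype(str)
    return GeneAnnotation(df)


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_metadata(path: str | Path,
                         stage_order: Sequence[str] = DEFAULT_STAGE_ORDER) -> SampleMetadata:
    df = _read_table(path)
    df.index = df.index.astype(str)
    return SampleMetadata(df, tuple(stage_order))


def write_sample_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path, roles: Mapping[str, str] | None = None) -> GeneSetCatalog:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    ``roles`` maps set names to role tags; unmapped sets default to
    ``nos``/``marker`` when the name says so, else ``death_mode``.
    """
    catalog = GeneSetCatalog()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in catalog.sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            if roles and name in roles:
                role = roles[name]
            elif "nos" == name.lower():
                role = "nos"
            elif "marker" in name.lower():
                role = "marker"
            else:
                role = "death_mode"
            catalog.add(name, genes, role=role, description=description)
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.sets.items():
            desc = catalog.descriptions.get(name, catalog.roles.get(name, ""))
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_proportions(path: str | Path) -> ProportionMatrix:
    df = _read_table(path)
    df.index = df.index.astype(str)
    values = df.to_numpy(float)
    df = pd.DataFrame(values / values.sum(axis=1, keepdims=True),
                      index=df.index, columns=df.columns)
    return ProportionMatrix(df)


def write_proportions(proportions: ProportionMatrix, path: str | Path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        proportions.data.to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def counts_to_tpm(counts: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    TPM_gs = (count_gs / length_kb_g) / sum_g(count_gs / length_kb_g) * 1e6,
    so every sample column sums to one million.  Library-size invariant:
    scaling a sample's counts by a positive constant leaves its TPM unchanged.
    """
    if counts.unit_kind != "counts":
        raise ValidationError(f"expected counts, got unit_kind={counts.unit_kind!r}")
    lengths_kb = annotation.lengths_kb(counts.gene_ids)
    rate = counts.values / lengths_kb[:, None]
    totals = rate.sum(axis=0)
    zero = np.where(totals <= 0)[0]
    if zero.size:
        raise ValidationError(
            f"sample {counts.sample_ids[zero[0]]!r} has an all-zero count column"
        )
    tpm = rate / totals * TPM_TOTAL
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns),
        unit_kind="TPM",
    )


def log10_tpm(tpm: ExpressionMatrix) -> pd.DataFrame:
    """log10(TPM + 1) table (the pipeline's logTPM convention)."""
    if tpm.unit_kind == "logTPM":
        return tpm.data.copy()
    if tpm.unit_kind != "TPM":
        raise ValidationError(f"expected TPM, got unit_kind={tpm.unit_kind!r}")
    return np.log10(tpm.data + 1.0)
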