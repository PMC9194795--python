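"""Readers and writers for the pipeline's on-disk formats.

Dense TSV (gene x unit, first column gene ids, header row unit ids) is the
canonical interchange format; Matrix Market triplets are accepted for
cell-level matrices, with gene/cell ids in sibling ``<stem>.rows.txt`` and
``<stem>.cols.txt`` files. Annotation is BED-like TSV. All outputs are
deterministic and byte-stable; floating-point ratios are serialised with
six decimal places.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .config import KNOWN_CHROMOSOMES, PipelineConfig
from .containers import AllelicCountMatrix, GeneAnnotation
from .exceptions import FormatError, ValidationError

FLOAT_FORMAT = "%.6f"


# --------------------------------------------------------------------- #
# count matrices
# --------------------------------------------------------------------- #
def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read one gene x unit count table from TSV or Matrix Market."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"count file not found: {path}")
    if path.suffix == ".mtx":
        rows_path, cols_path = _mtx_sidecars(path)
        for side in (rows_path, cols_path):
            if not side.exists():
                raise FormatError(f"missing MTX index file: {side}")
        matrix = scipy.io.mmread(path)
        genes = rows_path.read_text().split()
        units = cols_path.read_text().split()
        dense = np.asarray(matrix.todense() if scipy.sparse.issparse(matrix) else matrix)
        if dense.shape != (len(genes), len(units)):
            raise FormatError(
                f"MTX shape {dense.shape} does not match index files "
                f"({len(genes)} genes x {len(units)} units) in {path}"
            )
        return pd.DataFrame(dense, index=pd.Index(genes, name="gene_id"), columns=units)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_count_table(df: pd.DataFrame, path: str | Path, sparse: bool = False) -> None:
    """Write a count table as dense TSV or (``sparse=True``) Matrix Market."""
    path = Path(path)
    if sparse or path.suffix == ".mtx":
        rows_path, cols_path = _mtx_sidecars(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(df.to_numpy()))
        rows_path.write_text("\n".join(map(str, df.index)) + "\n")
        cols_path.write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        df.to_csv(path, sep="\t")


def read_unit_meta(path: str | Path) -> pd.DataFrame:
    """Read per-unit metadata (first column unit id, e.g. a stage/cluster column)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if not meta.index.is_unique:
        raise FormatError(f"duplicate unit ids in {path}")
    return meta


def read_allelic_counts(
    path_a1: str | Path,
    path_a2: str | Path,
    path_total: Optional[str | Path] = None,
    path_meta: Optional[str | Path] = None,
) -> AllelicCountMatrix:
    """Read the two allele layers (+ optional totals and metadata).

    Gene and unit order is taken from the allele-1 file; the allele-2 layer
    is reindexed to match and must carry exactly the same ids.
    """
    a1 = read_count_table(path_a1)
    a2 = read_count_table(path_a2)
    for axis_name, ref, other in (
        ("gene", a1.index, a2.index),
        ("unit", a1.columns, a2.columns),
    ):
        missing = ref.difference(other)
        extra = other.difference(ref)
        if len(missing) or len(extra):
            raise FormatError(
                f"allele layers disagree on the {axis_name} axis: "
                f"{len(missing)} missing / {len(extra)} extra ids "
                f"(e.g. {list(missing[:3]) + list(extra[:3])})"
            )
    a2 = a2.loc[a1.index, a1.columns]
    total = None
    if path_total is not None:
        total = read_count_table(path_total)
        extra_units = total.columns.difference(a1.columns)
        missing_units = a1.columns.difference(total.columns)
        if len(extra_units) or len(missing_units):
            raise FormatError("totals layer disagrees on the unit axis")
        total = total.loc[:, a1.columns]
    meta = read_unit_meta(path_meta) if path_meta is not None else None
    return AllelicCountMatrix(counts_a1=a1, counts_a2=a2, counts_total=total, unit_meta=meta)


# --------------------------------------------------------------------- #
# annotation
# --------------------------------------------------------------------- #
def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read BED-like annotation: chrom, start, end, gene_id, [patch_flag].

    Coordinates are 0-based half-open. Duplicate gene ids are rejected;
    chromosome labels outside the standard mouse set are kept with a warning.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 4:
        raise FormatError(f"annotation needs >= 4 columns, got {raw.shape[1]} in {path}")
    raw = raw.iloc[:, :5] if raw.shape[1] >= 5 else raw
    raw.columns = ["chromosome", "start", "end", "gene_id", "is_patch"][: raw.shape[1]]
    if "is_patch" not in raw.columns:
        raw["is_patch"] = False
    raw["is_patch"] = raw["is_patch"].map(
        lambda v: str(v).strip().lower() in {"1", "true", "yes", "patch"}
    )
    if raw["gene_id"].duplicated().any():
        dupes = raw.loc[raw["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"duplicate gene ids in annotation: {list(dupes[:5])}")
    unknown = set(raw["chromosome"]) - set(KNOWN_CHROMOSOMES)
    if unknown:
        warnings.warn(
            f"annotation contains unknown chromosome labels: {sorted(unknown)[:5]}",
            stacklevel=2,
        )
    table = raw.set_index("gene_id")[["chromosome", "start", "end", "is_patch"]]
    return GeneAnnotation(table=table)


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.table.reset_index()
    out["is_patch"] = out["is_patch"].astype(int)
    out[["chromosome", "start", "end", "gene_id", "is_patch"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# --------------------------------------------------------------------- #
# result tables
# --------------------------------------------------------------------- #
def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> Path:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)
    return path


def write_tables(
    out_dir: str | Path,
    *,
    gene_classification: Optional[pd.DataFrame] = None,
    annotation: Optional[GeneAnnotation] = None,
    cell_profiles: Optional[pd.DataFrame] = None,
    cluster_summaries: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
    manifest_extra: Optional[Mapping] = None,
) -> list[Path]:
    """Write deterministic TSV outputs plus a YAML run manifest.

    Gene classifications are ordered by genomic position when annotation is
    given (chromosome, then start), otherwise by gene id. Writing the same
    results twice produces identical bytes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    if gene_classification is not None:
        table = gene_classification.copy()
        if annotation is not None:
            pos = annotation.table.reindex(table.index)[["chromosome", "start"]]
            table = table.join(pos)
            table = table.sort_values(
                ["chromosome", "start"], kind="mergesort"
            )
        else:
            table = table.sort_index(kind="mergesort")
        written.append(_write_tsv(table, out_dir / "gene_classification.tsv", "gene_id"))
    if cell_profiles is not None:
        written.append(
            _write_tsv(cell_profiles.sort_index(kind="mergesort"),
                       out_dir / "cell_profiles.tsv", "cell_id")
        )
    if cluster_summaries is not None:
        written.append(
            _write_tsv(cluster_summaries.sort_index(kind="mergesort"),
                       out_dir / "cluster_summaries.tsv", "cluster")
        )
    manifest: dict = {"config": config.to_dict() if config is not None else None}
    if manifest_extra:
        manifest.update({str(k): v for k, v in manifest_extra.items()})
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(manifest_path)
    return written
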