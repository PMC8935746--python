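"""Readers, writers and QC filters for the pipeline's text formats.

Dense matrices are genes-as-rows TSV/CSV with a leading ``gene`` column;
sparse matrices are Matrix-Market coordinate triplets with ``genes.tsv``
and ``barcodes.tsv`` sidecars. Signatures, stable-REO sets, panels and
score tables are plain TSV. Everything round-trips deterministically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset
from .reo import DirectedGenePair, StableREOSet
from .scoring import StemSCScore
from .training import ReferenceSignature, StemnessGenePanel

logger = logging.getLogger("stemsc")

__all__ = [
    "GeneIdMap",
    "read_expression",
    "write_expression",
    "read_sample_meta",
    "read_stable_reo_set",
    "write_stable_reo_set",
    "read_signature",
    "write_signature",
    "read_gene_panel",
    "write_gene_panel",
    "read_gene_set",
    "read_scores",
    "write_scores",
    "read_gene_id_map",
    "qc_filter_cells",
    "map_gene_ids",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class GeneIdMap:
    """Cleaned source -> target identifier mapping (no ambiguous sources)."""

    mapping: Dict[str, str]

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# expression matrices


def _validate_dense(df: pd.DataFrame, path: PathLike) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene rows: {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: matrix contains non-numeric entries")
    if arr.size and (np.any(~np.isfinite(arr)) or arr.min() < 0):
        bad = np.argwhere(~np.isfinite(arr) | (arr < 0))[0]
        raise ValueError(
            f"{path}: negative or non-finite value at data row {bad[0] + 2}, "
            f"column {bad[1] + 2}"
        )


def read_expression(
    path: PathLike,
    format: str = "dense-tsv",
    dataset_id: Optional[str] = None,
) -> ExpressionDataset:
    """Read an expression matrix (``dense-tsv``, ``dense-csv`` or
    ``mtx-triplet``).

    For ``mtx-triplet``, ``path`` is the ``.mtx`` file and the gene and
    sample sidecars ``genes.tsv`` / ``barcodes.tsv`` must sit next to it.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    if format in ("dense-tsv", "dense-csv"):
        sep = "\t" if format == "dense-tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.name != "gene":
            raise ValueError(
                f"{path}: first header column must be 'gene', got {df.index.name!r}"
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _validate_dense(df, path)
        return ExpressionDataset(dataset_id=dataset_id, values=df.astype(float))
    if format == "mtx-triplet":
        mat = scipy.io.mmread(str(path))
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        genes = [ln.split("\t")[0] for ln in _read_lines(genes_path)]
        samples = [ln.split("\t")[0] for ln in _read_lines(barcodes_path)]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"{path}: matrix is {dense.shape} but sidecars declare "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
        _validate_dense(df, path)
        return ExpressionDataset(dataset_id=dataset_id, values=df)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(
    dataset: ExpressionDataset, path: PathLike, format: str = "dense-tsv"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in ("dense-tsv", "dense-csv"):
        sep = "\t" if format == "dense-tsv" else ","
        out = dataset.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep)
        return
    if format == "mtx-triplet":
        sparse = scipy.sparse.coo_matrix(dataset.values.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        (path.parent / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in dataset.genes), encoding="utf-8"
        )
        (path.parent / "barcodes.tsv").write_text(
            "".join(f"{s}\n" for s in dataset.samples), encoding="utf-8"
        )
        return
    raise ValueError(f"unknown expression format {format!r}")


def _read_lines(path: PathLike) -> List[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_sample_meta(path: PathLike) -> pd.DataFrame:
    """Per-sample metadata TSV with a leading ``sample`` column."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


# ---------------------------------------------------------------------------
# gene-pair sets


def _write_pairs(pairs: Sequence[DirectedGenePair], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = sorted(f"{p.gene_high}\t{p.gene_low}" for p in pairs)
    path.write_text("gene_high\tgene_low\n" + "".join(f"{l}\n" for l in lines), encoding="utf-8")


def _read_pairs(path: PathLike) -> List[DirectedGenePair]:
    lines = _read_lines(path)
    if not lines or lines[0].split("\t")[:2] != ["gene_high", "gene_low"]:
        raise ValueError(f"{path}: expected header 'gene_high\\tgene_low'")
    pairs = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {i}: expected 2 fields, got {len(fields)}")
        pairs.append(DirectedGenePair(fields[0], fields[1]))
    return pairs


def write_stable_reo_set(reo_set: StableREOSet, path: PathLike) -> None:
    _write_pairs(reo_set.pairs(), path)


def read_stable_reo_set(path: PathLike, source_id: Optional[str] = None) -> StableREOSet:
    pairs = _read_pairs(path)
    return StableREOSet.from_pairs(source_id or Path(path).stem, 0, pairs)


def write_signature(signature: ReferenceSignature, path: PathLike) -> None:
    """Signature TSV plus a ``<path>.provenance`` key:value sidecar."""
    _write_pairs(signature.pairs(), path)
    if signature.provenance:
        side = Path(str(path) + ".provenance")
        side.write_text(
            "".join(f"{k}: {v}\n" for k, v in sorted(signature.provenance.items())),
            encoding="utf-8",
        )


def read_signature(path: PathLike) -> ReferenceSignature:
    pairs = _read_pairs(path)
    provenance: Dict[str, int] = {}
    side = Path(str(path) + ".provenance")
    if side.exists():
        for ln in _read_lines(side):
            k, _, v = ln.partition(":")
            provenance[k.strip()] = int(v.strip())
    return ReferenceSignature.from_pairs(pairs, provenance=provenance)


def write_gene_panel(panel: StemnessGenePanel, path: PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in panel.genes), encoding="utf-8")


def read_gene_panel(path: PathLike) -> StemnessGenePanel:
    return StemnessGenePanel(genes=_read_lines(path))


def read_gene_set(path: PathLike) -> List[str]:
    """One gene identifier per line (marker sets etc.)."""
    return _read_lines(path)


# ---------------------------------------------------------------------------
# scores


def write_scores(scores: Sequence[StemSCScore], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tn_evaluable\tk_concordant\tstemsc\n")
        for s in scores:
            val = "NA" if s.undefined_flag else f"{s.score:.10g}"
            fh.write(f"{s.sample}\t{s.n_evaluable}\t{s.k_concordant}\t{val}\n")


def read_scores(path: PathLike) -> List[StemSCScore]:
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != ["sample", "n_evaluable", "k_concordant", "stemsc"]:
        raise ValueError(f"{path}: malformed score header")
    out = []
    for ln in lines[1:]:
        sample, n, k, val = ln.split("\t")
        if val == "NA":
            out.append(StemSCScore(sample, int(n), int(k), math.nan, True))
        else:
            out.append(StemSCScore(sample, int(n), int(k), float(val), False))
    return out


# ---------------------------------------------------------------------------
# QC and identifier mapping


def qc_filter_cells(dataset: ExpressionDataset, min_detected: int = 2000) -> ExpressionDataset:
    """Drop cells with fewer than ``min_detected`` detected (value > 0) genes."""
    X = dataset.values.to_numpy(dtype=float)
    detected = (X > 0).sum(axis=0)
    keep = detected >= min_detected
    removed = [s for s, k in zip(dataset.samples, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: all {dataset.n_samples} cells fall "
            f"below {min_detected} detected genes"
        )
    if removed:
        logger.info(
            "qc_filter_cells: removed %d/%d cells below %d detected genes in %r",
            len(removed), dataset.n_samples, min_detected, dataset.dataset_id,
        )
    return dataset.subset_samples([s for s, k in zip(dataset.samples, keep) if k])


def read_gene_id_map(path: PathLike) -> GeneIdMap:
    """Two-column TSV (source, target); conflicting duplicate sources are
    rejected, exact duplicate rows are collapsed."""
    mapping: Dict[str, str] = {}
    for i, ln in enumerate(_read_lines(path), start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {i}: expected 2 fields")
        src, dst = fields
        if src in mapping and mapping[src] != dst:
            raise ValueError(
                f"{path}: source {src!r} maps to both {mapping[src]!r} and {dst!r}"
            )
        mapping[src] = dst
    return GeneIdMap(mapping=mapping)


def map_gene_ids(dataset: ExpressionDataset, id_map: GeneIdMap) -> ExpressionDataset:
    """Rename genes through the map; unmapped genes are dropped and
    many-to-one collisions keep the source row with the highest mean."""
    values = dataset.values
    mapped = {g: id_map.mapping[g] for g in dataset.genes if g in id_map.mapping}
    n_unmapped = dataset.n_genes - len(mapped)
    if not mapped:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: no gene maps to a target identifier"
        )
    if n_unmapped:
        logger.info(
            "map_gene_ids: dropped %d unmapped genes in %r", n_unmapped, dataset.dataset_id
        )
    means = values.mean(axis=1)
    best_source: Dict[str, str] = {}
    for src, dst in mapped.items():
        cur = best_source.get(dst)
        if cur is None or means[src] > means[cur]:
            best_source[dst] = src
    targets = sorted(best_source)
    out = values.loc[[best_source[t] for t in targets]]
    out.index = pd.Index(targets)
    return ExpressionDataset(
        dataset_id=dataset.dataset_id, values=out, sample_meta=dataset.sample_meta
    )
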