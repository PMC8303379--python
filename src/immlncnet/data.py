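"""Domain types, readers/writers, and small shared arithmetic.

The pipeline's canonical containers are thin wrappers around pandas:
an :class:`ExpressionMatrix` holds an integer gene x sample count table
together with per-sample metadata, a gene annotation table maps gene ids
to biotype (protein_coding / lncRNA) and genomic position, and a
:class:`SignatureSet` holds named gene sets read from GMT.

Counts are exchanged as TSV (genes x samples, first column gene ids) or
as Matrix Market triplets with separate gene/sample index files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
TREATMENTS = ("vehicle", "histamine")
BIOTYPES = ("protein_coding", "lncRNA")

METADATA_COLUMNS = ["sample_id", "genotype", "treatment", "timepoint_days", "replicate"]
ANNOTATION_COLUMNS = ["gene_id", "biotype", "chromosome", "start"]


class ImmLncError(Exception):
    """Base class for pipeline errors."""


class ParseError(ImmLncError):
    """A file's contents violate its format contract."""


class SchemaError(ImmLncError):
    """Two inputs that must agree (e.g. counts vs metadata) do not."""


@dataclass(frozen=True)
class SampleMeta:
    """Experimental annotation of one RNA-seq library."""

    sample_id: str
    genotype: str
    treatment: str
    timepoint_days: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise SchemaError(
                f"sample {self.sample_id!r}: genotype {self.genotype!r} "
                f"not in {GENOTYPES}"
            )
        if self.treatment not in TREATMENTS:
            raise SchemaError(
                f"sample {self.sample_id!r}: treatment {self.treatment!r} "
                f"not in {TREATMENTS}"
            )
        if self.replicate < 1:
            raise SchemaError(f"sample {self.sample_id!r}: replicate must be >= 1")

    @property
    def arm(self) -> str:
        return f"{self.genotype}_{self.treatment}"


class ExpressionMatrix:
    """Integer count matrix (genes x samples) with attached sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows indexed by gene id, columns by
        sample id.
    samples
        One :class:`SampleMeta` per column, in column order.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicated gene id(s): {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicated sample id(s): {dup}")
        if counts.shape[1] != len(samples):
            raise SchemaError(
                f"{counts.shape[1]} count columns but {len(samples)} metadata rows"
            )
        meta_ids = [s.sample_id for s in samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise SchemaError("duplicated sample_id in metadata")
        if list(counts.columns) != meta_ids:
            raise SchemaError(
                "sample ids differ between counts and metadata: "
                f"{list(counts.columns)} vs {meta_ids}"
            )
        keys = [(s.genotype, s.treatment, s.timepoint_days, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise SchemaError("duplicated (genotype, treatment, timepoint, replicate)")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("counts must be numeric")
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            bad = np.argwhere((arr != np.floor(arr)) | (arr < 0))[0]
            raise ParseError(
                f"non-integer or negative count at gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.samples = samples

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "genotype": s.genotype,
                    "treatment": s.treatment,
                    "timepoint_days": s.timepoint_days,
                    "replicate": s.replicate,
                }
                for s in self.samples
            ]
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [i for i in ids if i not in self.counts.columns]
        if missing:
            raise SchemaError(f"unknown sample id(s): {missing}")
        by_id = {s.sample_id: s for s in self.samples}
        return ExpressionMatrix(self.counts[ids], [by_id[i] for i in ids])

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        missing = [i for i in ids if i not in self.counts.index]
        if missing:
            raise SchemaError(f"unknown gene id(s): {missing[:10]}")
        return ExpressionMatrix(self.counts.loc[ids], self.samples)

    def which_samples(self, **levels) -> list[str]:
        """Sample ids matching all given metadata levels.

        Example: ``mat.which_samples(genotype="KO", timepoint_days=1)``.
        """
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in levels.items()):
                out.append(s.sample_id)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.samples == other.samples


@dataclass
class SignatureSet:
    """Named gene sets (immunocyte marker panels or pathway collections)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ParseError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ParseError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "SignatureSet":
        names = list(names)
        return SignatureSet(
            {n: list(self.sets[n]) for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleMeta]:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata {path}: missing column(s) {missing}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            genotype=str(r.genotype),
            treatment=str(r.treatment),
            timepoint_days=int(r.timepoint_days),
            replicate=int(r.replicate),
        )
        for r in meta.itertuples()
    ]


def read_counts(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a counts TSV (header of sample ids, first column gene ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    samples = read_metadata(metadata_path)
    order = [s.sample_id for s in samples]
    extra = set(counts.columns) - set(order)
    absent = set(order) - set(counts.columns)
    if extra or absent:
        raise SchemaError(
            f"sample id mismatch between {path} and metadata: "
            f"only in counts {sorted(extra)}, only in metadata {sorted(absent)}"
        )
    return ExpressionMatrix(counts[order], samples)


def write_counts(
    mat: ExpressionMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    mat.counts.to_csv(path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        mat.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    metadata_path: str | Path,
) -> ExpressionMatrix:
    """Read a Matrix Market triplet file with gene/sample index sidecars."""
    m = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(m):
        m = m.toarray()
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
    if m.shape != (len(genes), len(samples)):
        raise SchemaError(
            f"MTX shape {m.shape} does not match index files "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    counts = pd.DataFrame(m, index=genes, columns=samples)
    meta = read_metadata(metadata_path)
    order = [s.sample_id for s in meta]
    if set(order) != set(samples):
        raise SchemaError("sample id mismatch between MTX index and metadata")
    return ExpressionMatrix(counts[order], meta)


def read_gmt(path: str | Path) -> SignatureSet:
    """Read a GMT gene-set file (name TAB description TAB gene TAB ...)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, description = fields[0], fields[1]
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s:%d: duplicate gene %r in set %r", path, lineno, g, name)
                    continue
                seen.add(g)
                genes.append(g)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            desc[name] = description
    return SignatureSet(sets, desc)


def write_gmt(signatures: SignatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.sets.items():
            desc = signatures.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, biotype, chromosome, start).

    Starts are 0-based; they are only used to order the per-chromosome
    export, so the convention is internal.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"annotation {path}: missing column(s) {missing}")
    return validate_annotation(ann.set_index("gene_id"))


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicated gene id(s) in annotation: {dup[:10]}")
    bad = sorted(set(ann["biotype"]) - set(BIOTYPES))
    if bad:
        raise ParseError(f"unknown biotype(s): {bad}")
    if (ann["start"] < 0).any():
        raise ParseError("annotation starts must be >= 0")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Shared arithmetic
# ---------------------------------------------------------------------------

def split_by_biotype(
    mat: ExpressionMatrix, annotation: pd.DataFrame
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a matrix into (protein_coding, lncRNA) sub-matrices."""
    unannotated = [g for g in mat.gene_ids if g not in annotation.index]
    if unannotated:
        raise SchemaError(f"unannotated gene id(s): {unannotated[:10]}")
    biotype = annotation.loc[mat.gene_ids, "biotype"]
    pc_ids = [g for g, b in biotype.items() if b == "protein_coding"]
    lnc_ids = [g for g, b in biotype.items() if b == "lncRNA"]
    pc = ExpressionMatrix(mat.counts.loc[pc_ids], mat.samples)
    lnc = ExpressionMatrix(mat.counts.loc[lnc_ids], mat.samples)
    return pc, lnc


def cpm(
    mat: ExpressionMatrix | pd.DataFrame,
    log: bool = False,
    prior_count: float = 1.0,
    norm_factors: "pd.Series | None" = None,
) -> pd.DataFrame:
    """Counts per million; optionally log2(CPM + prior_count).

    ``norm_factors`` (e.g. TMM factors) multiply the library sizes, giving
    composition-corrected CPM; without them plain library-size scaling is
    used.
    """
    counts = mat.counts if isinstance(mat, ExpressionMatrix) else mat
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise SchemaError(f"zero library size for sample(s): {zero}")
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(lib.index)
    out = counts / lib * 1e6
    if log:
        out = np.log2(out + prior_count)
    return out


def log2_cpm(
    mat: ExpressionMatrix | pd.DataFrame,
    prior_count: float = 1.0,
    norm_factors: "pd.Series | None" = None,
) -> pd.DataFrame:
    return cpm(mat, log=True, prior_count=prior_count, norm_factors=norm_factors)


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative-threshold-cycle fold change, 2^-ddCt.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    one extra cycle of the target in the case halves its relative level.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
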