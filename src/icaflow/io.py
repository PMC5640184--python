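"""Domain types and tab-separated readers/writers.

The study design is a paired pre/post intervention on human subjects:
each subject contributes at most one pre-race and one post-race blood
sample, expression is a log2 intensity matrix (features x samples), and
downstream analyses consume gene-set databases (GMT) and a
regulator -> target-gene table (ORegAnno-style TSV).

All identifiers are opaque case-sensitive strings; no symbol
normalisation is attempted.  TSV is the canonical carrier and
gzip-compressed inputs are accepted transparently.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "ExpressionMatrix",
    "FeatureAnnotation",
    "GeneSetDB",
    "GeneSet",
    "TrTargetDB",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "read_tr_targets",
    "write_tr_targets",
    "map_features_to_genes",
]

TIMEPOINTS = ("pre", "post")
GENDERS = ("male", "female")


class DataError(ValueError):
    """Fatal error in an input file or an inconsistent in-memory object."""


@dataclass
class SampleInfo:
    """One array sample with its design covariates.

    ``distance_km`` is the subject's completed distance; it is 0 for
    pre-race samples under the default covariate encoding, and the
    completed kilometres for post-race samples.
    """

    sample_id: str
    subject_id: str
    timepoint: str
    gender: str
    distance_km: float
    included: bool = True

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise DataError(
                f"sample {self.sample_id!r}: timepoint must be one of {TIMEPOINTS}, "
                f"got {self.timepoint!r}"
            )
        if self.gender not in GENDERS:
            raise DataError(
                f"sample {self.sample_id!r}: gender must be one of {GENDERS}, "
                f"got {self.gender!r}"
            )
        if self.distance_km < 0:
            raise DataError(f"sample {self.sample_id!r}: distance_km must be >= 0")


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix, features (transcript clusters) x samples."""

    feature_ids: list[str]
    samples: list[SampleInfo]
    values: np.ndarray  # (n_features, m_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.feature_ids):
            raise DataError(
                f"value rows ({n}) do not match feature ids ({len(self.feature_ids)})"
            )
        if m != len(self.samples):
            raise DataError(
                f"value columns ({m}) do not match samples ({len(self.samples)})"
            )
        if len(set(self.feature_ids)) != n:
            dupes = pd.Index(self.feature_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise DataError(f"duplicate feature ids: {dupes[:10]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != m:
            raise DataError("duplicate sample ids in sample list")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at feature {self.feature_ids[i]!r}, "
                f"sample {ids[j]!r}"
            )
        # at most one pre and one post per subject
        seen: set[tuple[str, str]] = set()
        for s in self.samples:
            key = (s.subject_id, s.timepoint)
            if key in seen:
                raise DataError(
                    f"subject {s.subject_id!r} has more than one {s.timepoint!r} sample"
                )
            seen.add(key)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def m_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(list(feature_ids), self.samples, self.values[rows, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s.sample_id: j for j, s in enumerate(self.samples)}
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            self.feature_ids, [self.samples[j] for j in cols], self.values[:, cols]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class FeatureAnnotation:
    """Mapping feature_id -> list of gene ids (possibly empty or >1)."""

    mapping: dict[str, list[str]]

    def __post_init__(self) -> None:
        for feat, genes in self.mapping.items():
            if len(set(genes)) != len(genes):
                raise DataError(f"duplicate genes in annotation of feature {feat!r}")


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]


@dataclass
class GeneSetDB:
    """A flat gene-set database (KEGG/Reactome/GO-style)."""

    terms: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate term ids in gene set database")
        for t in self.terms:
            if not t.genes:
                raise DataError(f"term {t.term_id!r} has an empty gene set")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class TrTargetDB:
    """Transcriptional regulator -> target-gene sets.

    The union of all target sets defines the database universe (the
    hypergeometric background of the global regulator-enrichment stage).
    """

    regulators: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.regulators]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate regulator ids")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, targets in self.regulators:
            out |= targets
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.regulators)

    def as_gene_set_db(self) -> GeneSetDB:
        """View regulators as gene-set terms for the shared enrichment engine."""
        return GeneSetDB(
            [GeneSet(tr, tr, "transcriptional_regulator", targets)
             for tr, targets in self.regulators]
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Read a TSV sample sheet with the required columns.

    Columns: sample_id, subject_id, timepoint (pre|post),
    gender (male|female), distance_km.  An optional ``included`` column
    (true/false) carries QC decisions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "subject_id", "timepoint", "gender", "distance_km"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"sample sheet {path}: missing columns {missing}")
    samples = []
    for _, row in df.iterrows():
        included = True
        if "included" in df.columns and str(row["included"]).strip().lower() in (
            "false", "0", "no",
        ):
            included = False
        samples.append(
            SampleInfo(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                timepoint=row["timepoint"],
                gender=row["gender"],
                distance_km=float(row["distance_km"]),
                included=included,
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise DataError(f"sample sheet {path}: duplicate sample ids")
    return samples


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "subject_id": [s.subject_id for s in samples],
            "timepoint": [s.timepoint for s in samples],
            "gender": [s.gender for s in samples],
            "distance_km": [s.distance_km for s in samples],
            "included": [s.included for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> ExpressionMatrix:
    """Read a TSV expression matrix together with its sample sheet.

    The matrix header row holds sample ids and the first column feature
    ids.  Columns are re-ordered to follow the sample sheet; every matrix
    column must match exactly one sample row.
    """
    samples = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0,
                     float_precision="round_trip")
    sheet_ids = [s.sample_id for s in samples]
    matrix_ids = [str(c) for c in df.columns]
    missing = sorted(set(sheet_ids) - set(matrix_ids))
    extra = sorted(set(matrix_ids) - set(sheet_ids))
    if missing or extra:
        raise DataError(
            f"sample ids do not match: missing from matrix {missing}, "
            f"not in sheet {extra}"
        )
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise DataError(f"duplicate feature ids in {matrix_path}: {dupes[:10]}")
    df = df[sheet_ids]
    values = df.to_numpy(dtype=float, na_value=np.nan)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise DataError(
            f"non-numeric or missing cell at feature {df.index[i]!r}, "
            f"sample {sheet_ids[j]!r} in {matrix_path}"
        )
    return ExpressionMatrix([str(f) for f in df.index], samples, values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_annotation(path: str | Path) -> FeatureAnnotation:
    """Read a feature -> gene TSV (columns feature_id, gene_id; one row per pair).

    A row with an empty gene_id records an unannotated feature.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"feature_id", "gene_id"} <= set(df.columns):
        raise DataError(f"annotation {path}: needs columns feature_id, gene_id")
    mapping: dict[str, list[str]] = {}
    for feat, gene in zip(df["feature_id"], df["gene_id"]):
        genes = mapping.setdefault(feat, [])
        if gene and gene not in genes:
            genes.append(gene)
    return FeatureAnnotation(mapping)


def write_annotation(annotation: FeatureAnnotation, path: str | Path) -> None:
    rows = []
    for feat, genes in annotation.mapping.items():
        if genes:
            rows.extend((feat, g) for g in genes)
        else:
            rows.append((feat, ""))
    pd.DataFrame(rows, columns=["feature_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(gmt_path: str | Path) -> GeneSetDB:
    """Read a GMT file: per line, term_id <TAB> description <TAB> gene ids...

    Duplicate genes within a line are collapsed; lines with fewer than
    three fields are skipped with a warning.  The description field may
    carry a ``category|name`` pair; otherwise category is empty.
    """
    terms: list[GeneSet] = []
    with _open_text(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(
                    f"{gmt_path}:{lineno}: fewer than 3 fields, line skipped"
                )
                continue
            term_id, desc = fields[0], fields[1]
            if "|" in desc:
                category, name = desc.split("|", 1)
            else:
                category, name = "", desc
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                warnings.warn(f"{gmt_path}:{lineno}: term {term_id!r} empty, skipped")
                continue
            terms.append(GeneSet(term_id, name, category, genes))
    if not terms:
        raise DataError(f"{gmt_path}: no valid gene-set terms")
    return GeneSetDB(terms)


def write_gene_sets(db: GeneSetDB, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for t in db.terms:
            desc = f"{t.category}|{t.term_name}" if t.category else t.term_name
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{desc}\t{genes}\n")


def read_tr_targets(
    tsv_path: str | Path, type_filter: str = "transcription factor binding site"
) -> TrTargetDB:
    """Read a regulator->target TSV keeping rows whose ``type`` matches.

    Columns: tr_id, target_gene_id, type.  Duplicate (tr, target) pairs
    collapse to one edge; regulators are returned in first-seen order.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"tr_id", "target_gene_id", "type"}
    if not required <= set(df.columns):
        raise DataError(f"{tsv_path}: needs columns {sorted(required)}")
    kept = df[df["type"] == type_filter]
    if kept.empty:
        raise DataError(
            f"{tsv_path}: no rows with type == {type_filter!r} "
            f"(types present: {sorted(df['type'].unique())[:5]})"
        )
    regs: dict[str, set[str]] = {}
    for tr, tg in zip(kept["tr_id"], kept["target_gene_id"]):
        regs.setdefault(tr, set()).add(tg)
    return TrTargetDB([(tr, frozenset(tg)) for tr, tg in regs.items()])


def write_tr_targets(
    db: TrTargetDB, path: str | Path,
    type_label: str = "transcription factor binding site",
) -> None:
    rows = [
        (tr, tg, type_label)
        for tr, targets in db.regulators
        for tg in sorted(targets)
    ]
    pd.DataFrame(rows, columns=["tr_id", "target_gene_id", "type"]).to_csv(
        path, sep="\t", index=False
    )


def map_features_to_genes(
    features: Sequence[str], annotation: FeatureAnnotation
) -> tuple[dict[str, str], dict[str, list[str]], list[str]]:
    """Partition features into unambiguous / ambiguous / unannotated.

    Returns three disjoint collections covering the input: features
    annotated to exactly one gene (feature -> gene), features with
    multiple annotations (feature -> gene list), and features with no
    annotation.  Several features may map to the same gene, so the
    distinct-gene count of the unambiguous partition can be smaller than
    its feature count.
    """
    unambiguous: dict[str, str] = {}
    ambiguous: dict[str, list[str]] = {}
    unannotated: list[str] = []
    for feat in features:
        genes = annotation.mapping.get(feat, [])
        if len(genes) == 1:
            unambiguous[feat] = genes[0]
        elif len(genes) > 1:
            ambiguous[feat] = list(genes)
        else:
            unannotated.append(feat)
    return unambiguous, ambiguous, unannotated
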