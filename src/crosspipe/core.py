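"""Core domain types and file I/O.

The central containers are deliberately thin wrappers around pandas objects:

* :class:`CountMatrix` — genes x samples non-negative integer counts,
* :class:`SampleSheet` — sample -> experimental group (+ optional covariates),
* :class:`ContrastSpec` — an ordered group comparison (numerator - denominator),
* :class:`PipelineID` — one cell of the filtering x method grid,
* :class:`GeneSetCollection` — weighted gene sets (GMT or 3-column TSV).

Gene identifiers are opaque strings; no species or identifier-type validation
is attempted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "ContrastSpec",
    "PipelineID",
    "GeneSetCollection",
    "FILTERING_LEVELS",
    "METHODS",
    "read_count_matrix",
    "read_sample_sheet",
    "read_contrast_table",
    "aggregate_gene_ids",
    "balance_groups",
    "enumerate_contrasts",
    "read_gene_sets",
    "write_gene_sets",
]

FILTERING_LEVELS = ("filtered", "unfiltered")
METHODS = (
    "tmm-limma",
    "vsn-limma",
    "voom-limma",
    "log2quant-limma",
    "edger",
    "deseq2",
)

#: methods that consume normalized values through the moderated-t engine
LIMMA_METHODS = frozenset(m for m in METHODS if m.endswith("-limma"))
#: methods that model raw counts directly
COUNT_METHODS = frozenset(("edger", "deseq2"))


@dataclass(frozen=True)
class PipelineID:
    """One pipeline of the grid: a filtering choice coupled to a DE method."""

    filtering: str
    method: str

    def __post_init__(self) -> None:
        if self.filtering not in FILTERING_LEVELS:
            raise ValidationError(f"unknown filtering level: {self.filtering!r}")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method: {self.method!r}")

    @property
    def label(self) -> str:
        return f"{self.filtering}-{self.method}"

    @property
    def is_filtered(self) -> bool:
        return self.filtering == "filtered"

    @classmethod
    def from_label(cls, label: str) -> "PipelineID":
        filtering, _, method = label.partition("-")
        return cls(filtering, method)

    @classmethod
    def full_grid(cls) -> list["PipelineID"]:
        """The complete 2 x 6 = 12 pipeline grid, in deterministic order."""
        return [cls(f, m) for f in FILTERING_LEVELS for m in METHODS]


@dataclass(frozen=True)
class ContrastSpec:
    """An ordered comparison; effect sizes follow numerator - denominator."""

    numerator: str
    denominator: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValidationError(
                f"contrast numerator equals denominator: {self.numerator!r}"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.numerator}_vs_{self.denominator}")

    @property
    def is_vs_rest(self) -> bool:
        return self.denominator == "rest"


class CountMatrix:
    """Genes x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with gene ids as index and sample ids as columns. Values
        must be non-negative and integral (integer-valued floats accepted).
    allow_duplicate_genes
        Permit duplicate gene ids; the matrix is then flagged for
        :func:`aggregate_gene_ids` before analysis.
    """

    def __init__(self, counts: pd.DataFrame, *, allow_duplicate_genes: bool = False):
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValidationError("count matrix is empty")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count matrix contains non-numeric values")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("count matrix contains missing values")
        if (values < 0).any():
            raise ValidationError("count matrix contains negative values")
        if not np.allclose(values, np.round(values.astype(float)), atol=1e-8):
            raise ValidationError("count matrix contains non-integral values")
        self.counts = counts.astype(np.int64)
        self.has_duplicate_genes = bool(counts.index.duplicated().any())
        if self.has_duplicate_genes and not allow_duplicate_genes:
            raise ValidationError(
                "duplicate gene ids; aggregate with aggregate_gene_ids() first"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample column sums (library sizes)."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_genes(self, mask) -> "CountMatrix":
        return CountMatrix(self.counts.loc[mask])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"CountMatrix({g} genes x {s} samples)"


class SampleSheet:
    """Sample -> group assignment with optional categorical covariates."""

    def __init__(self, table: pd.DataFrame, group_col: str = "group"):
        if "sample_id" in table.columns:
            table = table.set_index("sample_id")
        if table.index.duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        if group_col not in table.columns:
            raise FormatError(f"sample sheet lacks a {group_col!r} column")
        self.table = table.copy()
        self.table.index = self.table.index.astype(str)
        self.group_col = group_col

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def groups(self) -> pd.Series:
        return self.table[self.group_col].astype(str)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    @property
    def covariate_cols(self) -> list[str]:
        return [c for c in self.table.columns if c != self.group_col]

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def samples_of(self, group: str) -> list[str]:
        return self.table.index[self.groups == group].tolist()

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)], self.group_col)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named collection of weighted gene sets.

    ``sets`` maps set id -> list of (gene id, weight). Weights default to 1;
    negative weights encode repression in TF-regulon style resources.
    """

    name: str
    sets: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            genes = [g for g, _ in members]
            if len(genes) != len(set(genes)):
                raise ValidationError(f"duplicate (set, gene) pairs in {set_id!r}")
            for _, w in members:
                if not np.isfinite(w):
                    raise ValidationError(f"non-finite weight in set {set_id!r}")

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {s: len(m) for s, m in self.sets.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, g, w) for s, members in self.sets.items() for g, w in members
        ]
        return pd.DataFrame(rows, columns=["set", "gene", "weight"])

    def unsigned(self) -> "GeneSetCollection":
        """Binary-membership variant (all weights 1)."""
        return GeneSetCollection(
            self.name,
            {s: [(g, 1.0) for g, _ in m] for s, m in self.sets.items()},
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_count_matrix(path, delimiter: str | None = None) -> CountMatrix:
    """Read a genes-in-rows count table (first column = gene ids).

    Duplicate gene ids load successfully but flag the matrix for
    :func:`aggregate_gene_ids`; duplicate sample ids are a format error.
    """
    sep = _sniff_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate sample ids: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(df, allow_duplicate_genes=True)


def read_sample_sheet(path, delimiter: str | None = None, group_col: str = "group") -> SampleSheet:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SampleSheet(df, group_col=group_col)


def read_contrast_table(path, delimiter: str | None = None) -> list[ContrastSpec]:
    """Read a two-column (numerator, denominator) contrast list."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("contrast table needs two columns (numerator, denominator)")
    num, den = df.columns[:2]
    return [ContrastSpec(r[num], r[den]) for _, r in df.iterrows()]


def aggregate_gene_ids(m: CountMatrix, id_map: dict[str, str] | None = None) -> CountMatrix:
    """Collapse rows that map to the same identifier by element-wise summing.

    With ``id_map=None`` duplicated index entries are summed directly. Total
    counts per sample are conserved exactly.
    """
    counts = m.counts
    if id_map is not None:
        missing = [g for g in counts.index if g not in id_map]
        if missing:
            raise ValidationError(f"id_map does not cover gene ids: {missing[:5]}")
        new_index = counts.index.map(id_map)
    else:
        new_index = counts.index
    summed = counts.groupby(new_index, sort=False).sum()
    summed.index.name = counts.index.name
    return CountMatrix(summed)


def balance_groups(
    s: SampleSheet, min_size: int, target_size: int, seed: int
) -> SampleSheet:
    """Drop groups below ``min_size`` and down-sample survivors to ``target_size``.

    Sampling is without replacement and deterministic given ``seed``; groups
    are processed in sorted order so the result does not depend on input row
    order.
    """
    if target_size > min_size:
        raise ValidationError("target_size must be <= min_size")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for group in sorted(s.groups.unique()):
        members = sorted(s.samples_of(group))
        if len(members) < min_size:
            continue
        chosen = rng.choice(len(members), size=target_size, replace=False)
        keep.extend(members[i] for i in sorted(chosen))
    if not keep:
        raise ValidationError("no group survives the balancing thresholds")
    return s.subset(keep)


def enumerate_contrasts(
    s: SampleSheet,
    user_list: list[ContrastSpec] | None = None,
    mode: str = "all-pairwise",
    reference: str | None = None,
    block: str | None = None,
) -> list[ContrastSpec]:
    """Enumerate contrasts from the sample sheet.

    ``all-pairwise`` yields the n(n-1)/2 non-redundant comparisons with a
    deterministic lexicographic orientation (numerator < denominator);
    ``vs-reference`` compares every other group against ``reference``;
    ``one-vs-rest`` compares each group against the pooled remainder. With a
    ``block`` covariate, vs-reference / one-vs-rest contrasts are emitted per
    block level (contrast ids gain a ``block:`` prefix).
    """
    groups = s.group_names
    if user_list:
        for c in user_list:
            for g in (c.numerator, c.denominator):
                if g != "rest" and g not in groups:
                    raise ValidationError(f"contrast group {g!r} not in sample sheet")
        return list(user_list)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups to form contrasts")

    blocks = [None]
    if block is not None:
        if block not in s.table.columns:
            raise ValidationError(f"unknown block covariate {block!r}")
        blocks = sorted(s.table[block].astype(str).unique())

    def _cid(num: str, den: str, blk) -> str:
        base = f"{num}_vs_{den}"
        return f"{blk}:{base}" if blk is not None else base

    out: list[ContrastSpec] = []
    if mode == "all-pairwise":
        for a, b in itertools.combinations(groups, 2):
            out.append(ContrastSpec(a, b, _cid(a, b, None)))
    elif mode == "vs-reference":
        if reference is None or reference not in groups:
            raise ValidationError("vs-reference mode requires a valid reference group")
        for blk in blocks:
            for g in groups:
                if g != reference:
                    out.append(ContrastSpec(g, reference, _cid(g, reference, blk)))
    elif mode == "one-vs-rest":
        for blk in blocks:
            for g in groups:
                out.append(ContrastSpec(g, "rest", _cid(g, "rest", blk)))
    else:
        raise ValidationError(f"unknown contrast mode {mode!r}")
    return out


def read_gene_sets(path, format: str | None = None, name: str | None = None) -> GeneSetCollection:
    """Read a gene-set collection from GMT or 3-column weighted TSV.

    GMT lines are ``set<TAB>description<TAB>gene...`` (weight 1 per gene).
    Weighted TSV has a header and columns set, gene, weight; negative weights
    are preserved. Duplicate (set, gene) pairs collapse to the first
    occurrence with a warning.
    """
    path = str(path)
    if format is None:
        format = "gmt" if path.endswith(".gmt") else "weighted-tsv"
    if name is None:
        name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    sets: dict[str, list[tuple[str, float]]] = {}
    seen: set[tuple[str, str]] = set()
    dup_warned = False

    def _add(set_id: str, gene: str, weight: float) -> None:
        nonlocal dup_warned
        if (set_id, gene) in seen:
            if not dup_warned:
                warnings.warn(
                    f"duplicate (set, gene) pairs in {path}; keeping first occurrence",
                    stacklevel=3,
                )
                dup_warned = True
            return
        seen.add((set_id, gene))
        sets.setdefault(set_id, []).append((gene, weight))

    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
                set_id, _desc, *genes = fields
                for g in genes:
                    if g:
                        _add(set_id, g, 1.0)
    elif format == "weighted-tsv":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            raise FormatError(f"{path}: weighted TSV needs columns set, gene, weight")
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            try:
                w = float(row[2])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric weight") from exc
            _add(str(row[0]), str(row[1]), w)
    else:
        raise ValidationError(f"unknown gene-set format {format!r}")
    return GeneSetCollection(name, sets)


def write_gene_sets(coll: GeneSetCollection, path, format: str = "weighted-tsv") -> None:
    path = str(path)
    if format == "gmt":
        with open(path, "w") as fh:
            for set_id, members in coll.sets.items():
                genes = "\t".join(g for g, _ in members)
                fh.write(f"{set_id}\t{coll.name}\t{genes}\n")
    elif format == "weighted-tsv":
        coll.to_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown gene-set format {format!r}")
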