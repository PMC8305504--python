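"""Annotation flattening and file I/O.

All genomic coordinates are 1-based inclusive, matching both the GTF and
the STAR ``SJ.out.tab`` conventions.  An intron ``[s, e]`` has its donor
at ``s - 1`` and its acceptor at ``e + 1``.  Exonic bins are obtained by
splitting the union of a gene's exons at every exon boundary occurring
in any transcript, so each bin is either wholly included or wholly
skipped by a given isoform.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column layout of the STAR ``SJ.out.tab`` dialect (tab-separated, no header).
SJ_COLUMNS = (
    "chrom",
    "intron_start",  # 1-based first intronic base
    "intron_end",  # 1-based last intronic base
    "strand_code",  # 0 undefined, 1 '+', 2 '-'
    "motif",
    "annotated",
    "unique_reads",
    "multi_reads",
    "max_overhang",
)

#: Minimum unique reads for a junction to be kept (STAR output setting).
MIN_UNIQUE_READS = 5

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


@dataclass(frozen=True)
class ExonBin:
    """A flattened, gene-scoped exonic interval; the unit of PSI quantification."""

    gene_id: str
    bin_index: int  # 1-based ordinal within the gene, genomic order
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bin start {self.start} > end {self.end}")

    @property
    def label(self) -> str:
        return f"E{self.bin_index:03d}"

    @property
    def bin_id(self) -> str:
        return f"{self.gene_id}:{self.label}"


def _parse_gtf_exons(gtf_path: str | Path) -> pd.DataFrame:
    """Extract exon records (gene_id, chrom, start, end, strand) from a GTF.

    Raises ``ValueError`` naming the offending line number on malformed
    input (wrong column count, non-integer coordinates, missing gene_id).
    """
    records = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{gtf_path}, line {lineno}: expected 9 tab-separated "
                    f"fields, found {len(parts)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{gtf_path}, line {lineno}: non-integer coordinates"
                ) from exc
            if start_i > end_i:
                raise ValueError(f"{gtf_path}, line {lineno}: start > end")
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise ValueError(
                    f"{gtf_path}, line {lineno}: exon record without gene_id"
                )
            records.append((m.group(1), chrom, start_i, end_i, strand))
    return pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand"]
    )


def _flatten_gene(exons: pd.DataFrame) -> list[tuple[int, int]]:
    """Split the union of one gene's exons at every exon boundary."""
    starts = exons["start"].to_numpy()
    ends = exons["end"].to_numpy()
    # Cutpoints: every exon start, and the base after every exon end.
    cuts = np.unique(np.concatenate([starts, ends + 1]))
    # Union of exon intervals.
    order = np.argsort(starts)
    union: list[list[int]] = []
    for s, e in zip(starts[order], ends[order]):
        if union and s <= union[-1][1] + 1:
            union[-1][1] = max(union[-1][1], e)
        else:
            union.append([int(s), int(e)])
    bins: list[tuple[int, int]] = []
    for s, e in union:
        inner = cuts[(cuts > s) & (cuts <= e)]
        lo = s
        for c in inner:
            bins.append((lo, int(c) - 1))
            lo = int(c)
        bins.append((lo, e))
    return bins


def flatten_gtf(
    gtf_path: str | Path, return_ambiguous: bool = False
) -> list[ExonBin] | tuple[list[ExonBin], list[ExonBin]]:
    """Flatten a GTF into disjoint exonic bins.

    Per gene, the union of all transcript exons is split at every exon
    boundary occurring in any transcript, producing disjoint bins
    numbered 5'->3' in genomic-coordinate order (``E001``, ``E002``, ...
    regardless of strand).  Bins overlapping more than one gene are
    flagged ambiguous and excluded from quantification; excluded bins do
    not cause renumbering of the retained ones.
    """
    exons = _parse_gtf_exons(gtf_path)
    if exons.empty:
        return ([], []) if return_ambiguous else []
    all_bins: list[ExonBin] = []
    for gene_id, gene_exons in exons.groupby("gene_id", sort=True):
        strand = str(gene_exons["strand"].iloc[0])
        chrom = str(gene_exons["chrom"].iloc[0])
        intervals = _flatten_gene(gene_exons)
        for idx, (s, e) in enumerate(sorted(intervals), start=1):
            all_bins.append(ExonBin(str(gene_id), idx, chrom, s, e, strand))

    # Flag bins overlapping a bin of another gene as ambiguous.
    ambiguous: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(all_bins):
        by_chrom.setdefault(b.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: all_bins[i].start)
        active: list[int] = []
        for i in idxs:
            b = all_bins[i]
            active = [j for j in active if all_bins[j].end >= b.start]
            for j in active:
                if all_bins[j].gene_id != b.gene_id:
                    ambiguous.add(i)
                    ambiguous.add(j)
            active.append(i)

    kept = [b for i, b in enumerate(all_bins) if i not in ambiguous]
    dropped = [b for i, b in enumerate(all_bins) if i in ambiguous]
    if dropped:
        logger.info(
            "flatten_gtf: %d bins kept, %d ambiguous bins excluded",
            len(kept),
            len(dropped),
        )
    if return_ambiguous:
        return kept, dropped
    return kept


def bins_to_gtf(bins: list[ExonBin], path: str | Path) -> None:
    """Write exon bins back out as a one-transcript-per-gene GTF."""
    with open(path, "w") as fh:
        for b in sorted(bins, key=lambda b: (b.gene_id, b.bin_index)):
            attrs = (
                f'gene_id "{b.gene_id}"; transcript_id "{b.gene_id}.1"; '
                f'exon_label "{b.label}";'
            )
            fh.write(
                f"{b.chrom}\tpsipath\texon\t{b.start}\t{b.end}\t.\t"
                f"{b.strand}\t.\t{attrs}\n"
            )


def read_sj_tab(path: str | Path, min_unique: int = MIN_UNIQUE_READS) -> pd.DataFrame:
    """Read a STAR ``SJ.out.tab`` junction file.

    Returns a DataFrame with columns ``chrom, intron_start, intron_end,
    strand_code, unique_reads``.  Only uniquely mapped reads are used
    (the multi-mapping column is ignored) and junctions supported by
    fewer than ``min_unique`` unique reads are dropped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=SJ_COLUMNS, dtype=str, comment=None
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=SJ_COLUMNS)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed junction file ({exc})") from exc
    if df.shape[1] != len(SJ_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(SJ_COLUMNS)} columns, found {df.shape[1]}"
        )
    if len(df):
        for col in ("intron_start", "intron_end", "strand_code", "unique_reads"):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() | (converted != converted.astype("Int64").astype(float))
            if bad.any():
                lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValueError(f"{path}, line {lineno}: non-integer value in {col}")
            df[col] = converted.astype(int)
        if (df["intron_start"] > df["intron_end"]).any():
            raise ValueError(f"{path}: junction with intron_start > intron_end")
        if (df["unique_reads"] < 0).any():
            raise ValueError(f"{path}: negative unique read count")
    else:
        for col in ("intron_start", "intron_end", "strand_code", "unique_reads"):
            df[col] = pd.Series(dtype=int)
    out = df.loc[
        df["unique_reads"] >= min_unique,
        ["chrom", "intron_start", "intron_end", "strand_code", "unique_reads"],
    ].reset_index(drop=True)
    logger.debug("read_sj_tab(%s): %d junctions kept of %d", path, len(out), len(df))
    return out


def write_sj_tab(junctions: pd.DataFrame, path: str | Path) -> None:
    """Write junctions in the 9-column ``SJ.out.tab`` dialect."""
    df = junctions.copy()
    df["motif"] = 1
    df["annotated"] = 1
    df["multi_reads"] = 0
    df["max_overhang"] = 50
    df[list(SJ_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


METADATA_COLUMNS = (
    "sample_id",
    "individual_id",
    "location",
    "ancestry",
    "disease",
    "status",
)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load the samples table; index is sample_id, one row per sample."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    if "group_label" not in meta.columns:
        meta["group_label"] = "differentiated"
    return meta.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV, first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in count matrix")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_psi_matrix(path: str | Path) -> pd.DataFrame:
    """Read a bins x samples PSI matrix; 'NA' cells become missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate bin ids in PSI matrix")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in PSI matrix")
    return df


def write_psi_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a PSI matrix with missing values serialized as 'NA'."""
    matrix.to_csv(path, sep="\t", index_label="bin_id", na_rep="NA")


def validate_samples(matrix: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Check the matrix columns and metadata rows name the same samples."""
    mat, met = set(matrix.columns), set(meta.index)
    if mat != met:
        raise ValueError(
            f"matrix/metadata sample mismatch: {sorted(mat - met)[:5]} only in "
            f"matrix, {sorted(met - mat)[:5]} only in metadata"
        )
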