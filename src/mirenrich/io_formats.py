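"""Readers and writers for every external artifact the pipeline touches.

All tabular artifacts are plain TSV (comma selectable); mature miRNA
sequences come in miRBase ``mature.fa`` dialect FASTA. The two in-memory
containers defined here, :class:`CountMatrix` and :class:`SampleSheet`,
are thin validated wrappers around numpy/pandas and are the root inputs
of every downstream stage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Sorted-population labels used throughout the pipeline.
CELL_TYPES = ("PT", "Mac", "EC", "PDGFRB")
#: Experimental conditions of the reversible-obstruction time course.
CONDITIONS = ("sham", "UUO2", "UUO7", "RUUO")
#: Cell-type labels legal in a sample sheet (bulk cortex samples included).
SAMPLE_CELL_TYPES = CELL_TYPES + ("Bulk",)


class CountMatrix:
    """Non-negative integer miRNA x sample count matrix.

    Invariants enforced at construction: unique miRNA and sample ids,
    integer-valued counts, no negative entries.
    """

    def __init__(self, mirna_ids: Sequence[str], sample_ids: Sequence[str], counts) -> None:
        mirna_ids = [str(m) for m in mirna_ids]
        sample_ids = [str(s) for s in sample_ids]
        counts = np.asarray(counts)
        if counts.shape != (len(mirna_ids), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(mirna_ids)} miRNAs x {len(sample_ids)} samples"
            )
        for label, ids in (("miRNA", mirna_ids), ("sample", sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {label} ids: {dupes}")
        if counts.size:
            if not np.issubdtype(counts.dtype, np.number):
                bad = _first_non_numeric(counts, mirna_ids, sample_ids)
                raise ValueError(f"non-numeric count at {bad}")
            if np.issubdtype(counts.dtype, np.floating):
                frac = counts != np.floor(counts)
                if frac.any():
                    i, j = np.argwhere(frac)[0]
                    raise ValueError(
                        f"non-integer count {counts[i, j]!r} at "
                        f"(miRNA {mirna_ids[i]!r}, sample {sample_ids[j]!r})"
                    )
            if (counts < 0).any():
                i, j = np.argwhere(counts < 0)[0]
                raise ValueError(
                    f"negative count {counts[i, j]} at "
                    f"(miRNA {mirna_ids[i]!r}, sample {sample_ids[j]!r})"
                )
        self.mirna_ids = mirna_ids
        self.sample_ids = sample_ids
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.mirna_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset(self, mirnas: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "CountMatrix":
        df = self.to_frame()
        if mirnas is not None:
            df = df.loc[list(mirnas)]
        if samples is not None:
            df = df[list(samples)]
        return CountMatrix.from_frame(df)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CountMatrix)
                and self.mirna_ids == other.mirna_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} miRNAs x {self.shape[1]} samples)"


def _first_non_numeric(counts, mirna_ids, sample_ids):
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            try:
                float(counts[i, j])
            except (TypeError, ValueError):
                return f"(miRNA {mirna_ids[i]!r}, sample {sample_ids[j]!r})"
    return "(unknown)"


class SampleSheet:
    """Sample annotations: cell type, condition and replicate per sample."""

    REQUIRED = ("sample_id", "cell_type", "condition", "replicate")

    def __init__(self, df: pd.DataFrame,
                 cell_types: Sequence[str] = SAMPLE_CELL_TYPES,
                 conditions: Sequence[str] = CONDITIONS,
                 alias_map: Mapping[str, str] | None = None) -> None:
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        if alias_map:
            df["cell_type"] = df["cell_type"].replace(dict(alias_map))
            df["condition"] = df["condition"].replace(dict(alias_map))
        for col, legal in (("cell_type", cell_types), ("condition", conditions)):
            unknown = sorted(set(df[col]) - set(legal))
            if unknown:
                raise ValueError(
                    f"unknown {col} labels {unknown}; legal: {list(legal)} "
                    "(pass alias_map to remap)"
                )
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive")
        dup_ids = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
        if dup_ids:
            raise ValueError(f"duplicate sample ids: {dup_ids}")
        trip = df[["cell_type", "condition", "replicate"]]
        dup = trip[trip.duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate (cell_type, condition, replicate) triples: "
                f"{dup.to_records(index=False).tolist()}"
            )
        self.df = df.reset_index(drop=True)
        self.cell_types = tuple(cell_types)
        self.conditions = tuple(conditions)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def samples_for(self, condition: str | None = None,
                    cell_type: str | None = None) -> list[str]:
        m = pd.Series(True, index=self.df.index)
        if condition is not None:
            m &= self.df["condition"] == condition
        if cell_type is not None:
            m &= self.df["cell_type"] == cell_type
        return self.df.loc[m, "sample_id"].tolist()

    def cell_type_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["cell_type"]

    def condition_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["condition"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = self.df[self.df["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep, self.cell_types, self.conditions)


@dataclass
class MatureMirnaRecord:
    """One mature miRNA sequence in the miRBase dialect (RNA alphabet)."""
    name: str
    accession: str
    species_code: str
    sequence: str


def read_count_table(path, sep: str = "\t") -> CountMatrix:
    """Read a miRNA x sample count table (first column = miRNA ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    arr = df.to_numpy()
    if arr.dtype == object:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric count {df.loc[row, col]!r} at "
                    f"(miRNA {row!r}, sample {col!r}) in {path}"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        raise ValueError(f"missing values are not allowed in count tables ({path})")
    return CountMatrix.from_frame(df)


def write_count_table(cm: CountMatrix, path, sep: str = "\t") -> None:
    cm.to_frame().to_csv(path, sep=sep, index_label="mirna_id")


def read_sample_sheet(path, sep: str = "\t",
                      alias_map: Mapping[str, str] | None = None,
                      cell_types: Sequence[str] = SAMPLE_CELL_TYPES,
                      conditions: Sequence[str] = CONDITIONS) -> SampleSheet:
    df = pd.read_csv(path, sep=sep, comment="#")
    return SampleSheet(df, cell_types=cell_types, conditions=conditions,
                       alias_map=alias_map)


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    sheet.df.to_csv(path, sep=sep, index=False)


def validate_counts_samples(cm: CountMatrix, sheet: SampleSheet) -> None:
    """Every sample in the count matrix must be annotated in the sheet."""
    missing = sorted(set(cm.sample_ids) - set(sheet.sample_ids))
    if missing:
        raise ValueError(f"samples present in counts but absent from sheet: {missing}")


_RNA = set("ACGU")


def read_mature_fasta(path, species_filter: str | None = None,
                      return_rejected: bool = False):
    """Parse a miRBase ``mature.fa``-style FASTA into mature records.

    Headers follow ``>mmu-miR-16-5p MIMAT0000527 Mus musculus miR-16-5p``;
    the first token is the mature name and its 3-letter prefix the species.
    T is mapped to U; records with empty sequences or non-nucleotide
    characters are rejected with a warning and counted.
    """
    records: list[MatureMirnaRecord] = []
    rejected = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        name = tokens[0]
        accession = tokens[1] if len(tokens) > 1 else ""
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq or set(seq) - _RNA:
            warnings.warn(f"rejecting FASTA record {name!r}: "
                          f"empty or non-nucleotide sequence")
            rejected += 1
            continue
        species = name.split("-", 1)[0] if "-" in name else ""
        if species_filter is not None and species != species_filter:
            continue
        records.append(MatureMirnaRecord(name=name, accession=accession,
                                         species_code=species, sequence=seq))
    if return_rejected:
        return records, rejected
    return records


def write_mature_fasta(records: Iterable[MatureMirnaRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.name}" + (f" {r.accession}" if r.accession else "")
            fh.write(f"{header}\n{r.sequence}\n")


def read_external_de_list(path, name_column: str = "mirna_name",
                          direction_column: str = "direction",
                          logfc_column: str | None = None,
                          source_label: str = "", sep: str = "\t"):
    """Read an external DEmiRNA list and normalize its miRNA names.

    Returns ``(frame, n_dropped)``. Rows with blank/unparseable names or a
    direction inconsistent with the sign of logFC are dropped and counted;
    nothing here is a fatal error.
    """
    from .crossspecies import normalize_mirna_name

    raw = pd.read_csv(path, sep=sep, comment="#")
    if name_column not in raw.columns or direction_column not in raw.columns:
        raise ValueError(f"external DE list must have columns "
                         f"{name_column!r} and {direction_column!r}")
    rows = []
    n_dropped = 0
    for _, r in raw.iterrows():
        name = r[name_column]
        direction = str(r[direction_column]).strip().lower()
        if not isinstance(name, str) or not name.strip() or direction not in ("up", "down"):
            n_dropped += 1
            continue
        logfc = float(r[logfc_column]) if logfc_column and pd.notna(r.get(logfc_column)) else np.nan
        if np.isfinite(logfc) and ((logfc > 0) != (direction == "up")) and logfc != 0:
            n_dropped += 1
            continue
        norm = normalize_mirna_name(name.strip())
        rows.append({
            "mirna_name": name.strip(),
            "direction": direction,
            "logFC": logfc,
            "source_label": source_label,
            "base_name": norm.base_name,
            "arm": norm.arm,
            "species": norm.species,
            "name_parsed": norm.parsed,
        })
    frame = pd.DataFrame(rows, columns=["mirna_name", "direction", "logFC",
                                        "source_label", "base_name", "arm",
                                        "species", "name_parsed"])
    frame = frame.drop_duplicates(subset=["base_name", "arm", "direction"])
    return frame.reset_index(drop=True), n_dropped


def read_ct_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a long-format qPCR Ct table.

    Required columns: subject_id, group_label, assay, ct, is_reference.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ("subject_id", "group_label", "assay", "ct", "is_reference")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    df["ct"] = df["ct"].astype(float)
    df["is_reference"] = df["is_reference"].astype(bool)
    return df


def write_result_table(df: pd.DataFrame, path, comment: str | None = None,
                       sep: str = "\t", index: bool = True,
                       index_label: str | None = None) -> None:
    """Write a result table as TSV with a self-describing '#' header line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep=sep, index=index, index_label=index_label,
                  float_format="%.12g")
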