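"""Data model and TSV readers/writers for the quantification pipeline.

The pipeline consumes protein-level and peptide-level label-free
quantification tables (FragPipe ``combined_protein`` / ``combined_peptide``
style TSV dialects) plus a per-protein annotation table, and emits plain TSV
reports. Three conventions are fixed here:

* an intensity of exactly 0 means "not quantified" and is coerced to MISSING
  on read (prevents log2(0) downstream);
* "identified in a replicate" means the protein has a present intensity in
  that replicate's column;
* file columns are matched to the sample design by exact sample id, with an
  optional user-supplied rename map for tool-specific headers.

MISSING is represented as NaN throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sample",
    "SampleDesign",
    "QuantMatrix",
    "PeptideRecord",
    "AnnotationRecord",
    "read_quant_table",
    "write_quant_table",
    "read_peptide_table",
    "write_peptide_table",
    "read_annotation_table",
    "write_annotation_table",
    "write_report",
]

#: Workflow labels of the seven benchmarked sample-preparation methods.
WORKFLOWS = ("SP3", "SP4", "FASP", "STRAP", "PEPTIDISC", "SPNW30", "SMA2000")
CONDITIONS = ("LFD", "HFD")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    workflow: str
    condition: str
    replicate: int

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer: {self.replicate}")


class SampleDesign:
    """Workflow x condition x replicate layout of the experiment.

    (workflow, condition, replicate) triples and sample ids are unique.
    """

    def __init__(self, samples):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")
        triples = [(s.workflow, s.condition, s.replicate) for s in samples]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (workflow, condition, replicate) triple")
        self.samples: list[Sample] = samples
        self._by_id = {s.sample_id: s for s in samples}

    @classmethod
    def from_layout(
        cls,
        workflows=WORKFLOWS,
        conditions=CONDITIONS,
        n_replicates: int = 3,
        id_format: str = "{workflow}_{condition}_{replicate}",
    ) -> "SampleDesign":
        samples = [
            Sample(
                id_format.format(workflow=w, condition=c, replicate=r),
                w, c, r,
            )
            for w in workflows
            for c in conditions
            for r in range(1, n_replicates + 1)
        ]
        return cls(samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    def subset(self, workflow=None, condition=None) -> list[str]:
        """Sample ids matching the given workflow and/or condition, in
        replicate order."""
        out = [
            s for s in self.samples
            if (workflow is None or s.workflow == workflow)
            and (condition is None or s.condition == condition)
        ]
        return [s.sample_id for s in sorted(out, key=lambda s: (s.workflow, s.condition, s.replicate))]

    @property
    def workflows(self) -> list[str]:
        seen = dict.fromkeys(s.workflow for s in self.samples)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen = dict.fromkeys(s.condition for s in self.samples)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.workflow, s.condition, s.replicate) for s in self.samples],
            columns=["sample_id", "workflow", "condition", "replicate"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(
            Sample(str(r.sample_id), str(r.workflow), str(r.condition), int(r.replicate))
            for r in df.itertuples()
        )


class QuantMatrix:
    """Proteins x samples intensity matrix with explicit missingness.

    ``data`` is a float DataFrame (rows = protein accessions, columns =
    sample ids, NaN = MISSING). ``scale`` is ``"linear"`` (all present values
    > 0) or ``"log2"``; the flag prevents a double log transform.
    """

    def __init__(self, data: pd.DataFrame, scale: str = "linear"):
        if scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {scale!r}")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accession {dup[0]}")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample_id columns")
        data = data.astype(float).rename_axis(index="protein_id")
        if scale == "linear":
            vals = data.to_numpy()
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError("linear-scale intensities must be > 0 (0 means MISSING)")
        self.data = data
        self.scale = scale

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def present(self) -> pd.DataFrame:
        """Boolean mask of quantified cells."""
        return self.data.notna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def select(self, proteins=None, samples=None) -> "QuantMatrix":
        data = self.data
        if proteins is not None:
            data = data.loc[list(proteins)]
        if samples is not None:
            data = data[list(samples)]
        return QuantMatrix(data, self.scale)

    def equals(self, other: "QuantMatrix") -> bool:
        return self.scale == other.scale and self.data.equals(other.data)


@dataclass
class PeptideRecord:
    """One identified peptide with per-sample intensities (NaN = MISSING)."""

    sequence: str
    protein_id: str
    intensity_by_sample: dict[str, float] = field(default_factory=dict)

    def present_samples(self) -> list[str]:
        return [
            s for s, v in self.intensity_by_sample.items()
            if v is not None and np.isfinite(v)
        ]


@dataclass
class AnnotationRecord:
    """Per-protein annotation used for localization classification."""

    protein_id: str
    gene_symbol: str
    go_cc_keywords: str
    tm_count: int
    mol_weight_kda: float

    def __post_init__(self):
        if self.tm_count < 0:
            raise ValueError(f"{self.protein_id}: tm_count must be >= 0")
        if self.mol_weight_kda <= 0:
            raise ValueError(f"{self.protein_id}: mol_weight_kda must be > 0")


# ---------------------------------------------------------------------------
# readers / writers


def read_quant_table(
    path,
    design: SampleDesign,
    protein_col: str = "Protein ID",
    rename: dict[str, str] | None = None,
    scale: str = "linear",
) -> QuantMatrix:
    """Read a protein-level TSV into a QuantMatrix.

    Cells that are empty, non-numeric, or exactly 0 become MISSING (the
    zero coercion applies on the linear scale only). Row order is preserved.
    Raises on duplicate accessions or on a designed sample column that is
    absent from the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if rename:
        df = df.rename(columns=rename)
    if protein_col not in df.columns:
        raise ValueError(f"protein column {protein_col!r} not found in {path}")
    missing_cols = [s for s in design.sample_ids if s not in df.columns]
    if missing_cols:
        raise ValueError(f"designed sample column(s) absent from {path}: {missing_cols}")
    accessions = df[protein_col].astype(str)
    dup = accessions[accessions.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate accession {dup.iloc[0]}")
    values = df[design.sample_ids].apply(pd.to_numeric, errors="coerce")
    if scale == "linear":
        values = values.mask(values == 0)
    values.index = pd.Index(accessions, name="protein_id")
    return QuantMatrix(values, scale=scale)


def write_quant_table(q: QuantMatrix, path, protein_col: str = "Protein ID") -> None:
    """Write a QuantMatrix as TSV (MISSING as empty cell, full float
    precision so that read(write(q)) round-trips exactly)."""
    out = q.data.copy()
    out.index.name = protein_col
    out.to_csv(path, sep="\t", na_rep="")


def read_peptide_table(
    path,
    design: SampleDesign,
    sequence_col: str = "Peptide Sequence",
    protein_col: str = "Protein ID",
    rename: dict[str, str] | None = None,
) -> list[PeptideRecord]:
    """Read a peptide-level TSV. Zero intensities become MISSING.

    Rows whose sequence contains a non-canonical residue are rejected and
    counted, with one logged warning per rejected row and a final total;
    the returned list holds one record per accepted row.
    """
    from .hydropathy import CANONICAL_RESIDUES

    df = pd.read_csv(path, sep="\t", dtype=str)
    if rename:
        df = df.rename(columns=rename)
    for col in (sequence_col, protein_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    missing_cols = [s for s in design.sample_ids if s not in df.columns]
    if missing_cols:
        raise ValueError(f"designed sample column(s) absent from {path}: {missing_cols}")

    values = df[design.sample_ids].apply(pd.to_numeric, errors="coerce")
    values = values.mask(values == 0)
    seqs = df[sequence_col].fillna("").astype(str)
    pattern = "[" + "".join(sorted(CANONICAL_RESIDUES)) + "]+"
    valid = seqs.str.fullmatch(pattern)
    for i in seqs.index[~valid]:
        logger.warning("rejected peptide row %d: non-canonical sequence %r", i, seqs[i])
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("rejected %d peptide row(s) from %s", n_rejected, path)
    cols = design.sample_ids
    records = [
        PeptideRecord(seq, pid, dict(zip(cols, row)))
        for seq, pid, row in zip(
            seqs[valid],
            df.loc[valid, protein_col].astype(str),
            values.loc[valid].to_numpy(dtype=float),
        )
    ]
    return records


def write_peptide_table(
    records: list[PeptideRecord],
    path,
    design: SampleDesign,
    sequence_col: str = "Peptide Sequence",
    protein_col: str = "Protein ID",
) -> None:
    rows = []
    for rec in records:
        row = {sequence_col: rec.sequence, protein_col: rec.protein_id}
        for s in design.sample_ids:
            v = rec.intensity_by_sample.get(s, np.nan)
            row[s] = v
        rows.append(row)
    pd.DataFrame(rows, columns=[sequence_col, protein_col, *design.sample_ids]).to_csv(
        path, sep="\t", index=False, na_rep=""
    )


ANNOTATION_COLUMNS = ["protein_id", "gene_symbol", "go_cc_keywords", "tm_count", "mol_weight_kda"]


def read_annotation_table(path) -> dict[str, AnnotationRecord]:
    """Read the per-protein annotation TSV into a map keyed by accession.

    The GO keyword string is stored verbatim. A missing / non-numeric
    tm_count is a hard error (classification is undefined without it), as is
    a duplicate accession.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation column {col!r} not found in {path}")
    out: dict[str, AnnotationRecord] = {}
    for i, row in df.iterrows():
        pid = str(row["protein_id"])
        if pid in out:
            raise ValueError(f"duplicate protein_id {pid} in annotation table")
        tm = pd.to_numeric(row["tm_count"], errors="coerce")
        if pd.isna(tm):
            raise ValueError(f"{pid}: tm_count missing or non-numeric ({row['tm_count']!r})")
        mw = pd.to_numeric(row["mol_weight_kda"], errors="coerce")
        if pd.isna(mw):
            raise ValueError(f"{pid}: mol_weight_kda missing or non-numeric")
        out[pid] = AnnotationRecord(
            protein_id=pid,
            gene_symbol="" if pd.isna(row["gene_symbol"]) else str(row["gene_symbol"]),
            go_cc_keywords="" if pd.isna(row["go_cc_keywords"]) else str(row["go_cc_keywords"]),
            tm_count=int(tm),
            mol_weight_kda=float(mw),
        )
    return out


def write_annotation_table(annotations: dict[str, AnnotationRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.astuple(rec) for rec in annotations.values()],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_report(
    tables: dict[str, pd.DataFrame],
    out_dir,
    config: dict | None = None,
    seed: int | None = None,
    float_format: str = "%.6g",
    index: bool = True,
) -> list[Path]:
    """Write named result tables as TSV files plus a run-metadata JSON.

    Floats are written at fixed precision so that repeated runs with the
    same seed produce byte-identical files. The metadata file records the
    configuration, seed, and package version (no timestamps, for the same
    reason).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format=float_format, na_rep="", index=index)
        written.append(p)
    from . import __version__

    meta = {"version": __version__, "seed": seed, "config": config}
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(meta_path)
    return written
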