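"""Protein localization classification and identification summaries.

Proteins are partitioned into four localization categories from their GO
cellular-component keyword string and predicted transmembrane (TM) segment
count:

* **SP** — soluble protein: no "membrane" keyword;
* **MAP** — membrane-associated protein: membrane keyword, no TM segment;
* **pIMP** — plasma-membrane integral membrane protein: membrane keyword,
  >= 1 TM segment, "plasma membrane" keyword present;
* **oIMP** — organellar integral membrane protein: every other IMP.

The pIMP/oIMP split within IMPs is binary (pIMP + oIMP = IMP exactly), so a
membrane IMP lacking the plasma keyword is oIMP even when no organellar
keyword matches. Keyword matching is case-insensitive substring matching
against configurable lists.

TM counts normally come from an external topology predictor supplied via the
annotation table; :func:`predict_tm_segments` is a deterministic
hydropathy-sliding-window stand-in for use when no external prediction is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydropathy import KD_SCALE, hydropathy_values
from .io import AnnotationRecord, QuantMatrix, SampleDesign

__all__ = [
    "CATEGORIES",
    "TM_BINS",
    "LocalizationCall",
    "classify_protein",
    "classify_proteins",
    "calls_to_frame",
    "bin_tm_count",
    "flag_slc",
    "predict_tm_segments",
    "summarize_identifications",
]

CATEGORIES = ("SP", "MAP", "pIMP", "oIMP")
TM_BINS = ("1", "2", "3–5", "6–10", "11+")

DEFAULT_PLASMA_KEYWORDS = ("plasma membrane",)
#: Organellar membrane keyword list (superset of the usual named examples);
#: kept configurable because curated GO keyword sets are open-ended.
DEFAULT_ORGANELLAR_KEYWORDS = (
    "endoplasmic reticulum", "golgi", "endosome", "exosome",
    "peroxisome", "lysosome", "vesicle", "mitochond", "nucle",
)


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    category: str  # one of CATEGORIES
    tm_count: int
    tm_bin: str | None  # defined only for IMPs (tm_count >= 1)
    is_slc: bool

    @property
    def is_imp(self) -> bool:
        return self.category in ("pIMP", "oIMP")


def bin_tm_count(tm_count: int) -> str:
    """Bin a TM-segment count: 1, 2, 3–5, 6–10, 11+ (tm_count >= 1)."""
    if tm_count < 1:
        raise ValueError(f"tm_bin undefined for tm_count {tm_count} (< 1: not an IMP)")
    if tm_count == 1:
        return "1"
    if tm_count == 2:
        return "2"
    if tm_count <= 5:
        return "3–5"
    if tm_count <= 10:
        return "6–10"
    return "11+"


def flag_slc(rec: AnnotationRecord, extra_keywords: tuple[str, ...] = ()) -> bool:
    """True iff the gene symbol looks like a solute-carrier (SLC) family
    member: prefix "Slc" (case-insensitive) followed by a digit. Extra
    keywords, if given, are substring-matched against the GO keyword string
    to add members annotated by molecular function instead of name.
    """
    g = rec.gene_symbol.lower()
    if g.startswith("slc") and len(g) > 3 and g[3].isdigit():
        return True
    kw = rec.go_cc_keywords.lower()
    return any(k.lower() in kw for k in extra_keywords)


def classify_protein(
    rec: AnnotationRecord,
    plasma_keywords: tuple[str, ...] = DEFAULT_PLASMA_KEYWORDS,
    organellar_keywords: tuple[str, ...] = DEFAULT_ORGANELLAR_KEYWORDS,
    slc_keywords: tuple[str, ...] = (),
) -> LocalizationCall:
    """Classify one protein into SP / MAP / pIMP / oIMP (total function).

    ``organellar_keywords`` is accepted for interface symmetry and
    diagnostics; the IMP split itself is binary on the plasma keyword, so
    the partition identity pIMP + oIMP = IMP always holds.
    """
    kw = rec.go_cc_keywords.lower()
    if "membrane" not in kw:
        category = "SP"
    elif rec.tm_count == 0:
        category = "MAP"
    elif any(p.lower() in kw for p in plasma_keywords):
        category = "pIMP"
    else:
        category = "oIMP"
    tm_bin = bin_tm_count(rec.tm_count) if category in ("pIMP", "oIMP") else None
    return LocalizationCall(
        protein_id=rec.protein_id,
        category=category,
        tm_count=rec.tm_count,
        tm_bin=tm_bin,
        is_slc=flag_slc(rec, slc_keywords),
    )


def classify_proteins(annotations: dict[str, AnnotationRecord], **kwargs) -> dict[str, LocalizationCall]:
    return {pid: classify_protein(rec, **kwargs) for pid, rec in annotations.items()}


def calls_to_frame(calls: dict[str, LocalizationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.protein_id, c.category, c.tm_count, c.tm_bin or "", c.is_slc) for c in calls.values()],
        columns=["protein_id", "category", "tm_count", "tm_bin", "is_slc"],
    ).set_index("protein_id")


def predict_tm_segments(sequence: str, window: int = 19, threshold: float = 1.6) -> int:
    """Deterministic sliding-window stand-in for a transmembrane predictor.

    Scans all windows of ``window`` residues; a window "hits" when its mean
    Kyte–Doolittle hydropathy is >= ``threshold``. Overlapping hit windows
    are merged into maximal covered runs; a run of length L counts as one
    segment, or ceil(L / window) segments when L exceeds twice the window
    (long unbroken hydrophobic stretches hold multiple helices).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    h = hydropathy_values(sequence)  # validates residues
    n = len(h)
    if n < window:
        return 0
    means = np.convolve(h, np.ones(window) / window, mode="valid")
    hits = np.flatnonzero(means >= threshold)
    if hits.size == 0:
        return 0
    # merge covered intervals [s, s + window)
    segments = 0
    run_start = hits[0]
    prev = hits[0]
    for s in list(hits[1:]) + [None]:
        if s is not None and s <= prev + window:  # windows overlap or touch
            prev = s
            continue
        run_len = prev + window - run_start
        segments += 1 if run_len <= 2 * window else math.ceil(run_len / window)
        if s is not None:
            run_start = prev = s
    return segments


@dataclass
class IdentificationSummary:
    """Per-replicate identification counts and their mean ± SD by
    (workflow, condition), mirroring a benchmark summary table."""

    per_replicate: pd.DataFrame  # one row per sample
    summary: pd.DataFrame  # one row per (workflow, condition), mean/sd columns


_COUNT_COLS = ["TP", "SP", "MAP", "IMP", "pIMP", "oIMP"]


def summarize_identifications(
    q: QuantMatrix,
    calls: dict[str, LocalizationCall],
    design: SampleDesign,
) -> IdentificationSummary:
    """Count identified proteins per category in each replicate and reduce
    to mean ± sample SD per (workflow, condition).

    A protein counts as identified in a replicate iff its intensity is
    present there. Ratios IMP/TP and pIMP/TP (in %) are computed per
    replicate and then averaged. Raises if any protein in the matrix lacks
    a localization call.
    """
    missing = [p for p in q.protein_ids if p not in calls]
    if missing:
        raise ValueError(f"proteins lacking annotation: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    cat = pd.Series({p: calls[p].category for p in q.protein_ids})
    present = q.present()

    rows = []
    for s in design.samples:
        if s.sample_id not in present.columns:
            continue
        mask = present[s.sample_id]
        counts = cat[mask[mask].index].value_counts()
        sp = int(counts.get("SP", 0))
        mp = int(counts.get("MAP", 0))
        pimp = int(counts.get("pIMP", 0))
        oimp = int(counts.get("oIMP", 0))
        imp = pimp + oimp
        tp = sp + mp + imp
        rows.append({
            "sample_id": s.sample_id, "workflow": s.workflow,
            "condition": s.condition, "replicate": s.replicate,
            "TP": tp, "SP": sp, "MAP": mp, "IMP": imp, "pIMP": pimp, "oIMP": oimp,
            "IMP/TP %": 100.0 * imp / tp if tp else 0.0,
            "pIMP/TP %": 100.0 * pimp / tp if tp else 0.0,
        })
    per_rep = pd.DataFrame(rows)

    if per_rep.empty:
        return IdentificationSummary(per_rep, pd.DataFrame())
    agg_cols = _COUNT_COLS + ["IMP/TP %", "pIMP/TP %"]
    grouped = per_rep.groupby(["workflow", "condition"], sort=False)[agg_cols]
    summary = pd.concat(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1)}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
    summary = summary.reindex(columns=agg_cols, level=0)
    return IdentificationSummary(per_rep, summary)
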