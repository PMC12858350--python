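"""Kyte–Doolittle hydropathy: GRAVY scores, intensity-weighted per-workflow
distributions, and pairwise nonparametric comparisons.

The GRAVY (Grand Average of Hydropathy) score of a peptide is the arithmetic
mean of the per-residue Kyte–Doolittle hydropathy values; positive scores
indicate hydrophobic sequences. In a membrane-proteomics benchmark the
peptide-level GRAVY distribution of each sample-preparation workflow,
weighted by measured intensity, shows how strongly the workflow captures
hydrophobic (membrane-embedded) sequence.

The Kyte–Doolittle table defined here is the single source of truth for the
whole package; the sliding-window transmembrane-segment stand-in in
:mod:`membranebench.annotation` uses the same values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KD_SCALE",
    "peptide_gravy",
    "GravyProfile",
    "weighted_gravy_summary",
    "pairwise_gravy_test",
]

#: Kyte & Doolittle (1982) hydropathy values for the 20 canonical residues.
KD_SCALE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CANONICAL_RESIDUES = frozenset(KD_SCALE)


def _check_canonical(sequence: str) -> None:
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {sorted(bad)} in sequence {sequence[:30]!r}"
        )


def peptide_gravy(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy of *sequence* (length >= 1)."""
    if not sequence:
        raise ValueError("empty sequence has no GRAVY score")
    _check_canonical(sequence)
    return sum(KD_SCALE[aa] for aa in sequence) / len(sequence)


def hydropathy_values(sequence: str) -> np.ndarray:
    """Per-residue Kyte–Doolittle values as a float array."""
    _check_canonical(sequence)
    return np.array([KD_SCALE[aa] for aa in sequence], dtype=float)


@dataclass
class GravyProfile:
    """Peptide-level GRAVY distribution for one workflow.

    ``table`` has one row per (deduplicated) peptide sequence with its GRAVY
    score and summed-intensity weight; ``weighted_median`` is the smallest
    score whose cumulative weight reaches half the total. The unweighted
    median over sequences is kept alongside, since published per-method
    medians do not state whether they are intensity weighted.
    """

    workflow: str
    table: pd.DataFrame  # columns: sequence, gravy, weight
    weighted_median: float
    unweighted_median: float
    histogram_edges: np.ndarray = field(repr=False)
    histogram_weighted: np.ndarray = field(repr=False)

    @property
    def scores(self) -> np.ndarray:
        return self.table["gravy"].to_numpy()


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight is >= half the total weight.

    Invariant to uniform rescaling of the weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted median of an empty sample")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(values[order][idx])


def weighted_gravy_summary(
    peptides,
    sample_ids,
    workflow: str = "",
    dedupe: bool = True,
    bins: int | np.ndarray = 60,
) -> GravyProfile:
    """Build the intensity-weighted GRAVY profile of a peptide list.

    Each peptide's weight is the sum of its present (non-missing) intensities
    over the pooled ``sample_ids``; peptides with no present intensity are
    excluded. With ``dedupe`` duplicate sequences are collapsed to a single
    entry whose weight is the summed intensity (scores are averaged per
    peptide sequence, so collapsing leaves the score unchanged).
    """
    rows = []
    for rec in peptides:
        w = 0.0
        seen = False
        for sid in sample_ids:
            v = rec.intensity_by_sample.get(sid)
            if v is not None and np.isfinite(v):
                w += float(v)
                seen = True
        if seen and w > 0:
            rows.append((rec.sequence, w))
    if not rows:
        raise ValueError("no peptide has a present intensity in the pooled samples")
    df = pd.DataFrame(rows, columns=["sequence", "weight"])
    if dedupe:
        df = df.groupby("sequence", as_index=False, sort=False)["weight"].sum()
    df["gravy"] = [peptide_gravy(s) for s in df["sequence"]]
    df = df[["sequence", "gravy", "weight"]]

    if np.isscalar(bins):
        edges = np.linspace(-4.5, 4.5, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    hist, _ = np.histogram(df["gravy"], bins=edges, weights=df["weight"])

    return GravyProfile(
        workflow=workflow,
        table=df,
        weighted_median=weighted_median(df["gravy"].to_numpy(), df["weight"].to_numpy()),
        unweighted_median=float(np.median(df["gravy"])),
        histogram_edges=edges,
        histogram_weighted=hist,
    )


def pairwise_gravy_test(profiles: list[GravyProfile]) -> pd.DataFrame:
    """Bonferroni-adjusted two-sided Wilcoxon rank-sum p-values between all
    workflow pairs.

    The test runs on the per-sequence GRAVY scores (unweighted — rank tests
    are weight-free by construction; intensity weights only shape the
    displayed distribution). The adjusted p is ``min(1, p_raw * n_pairs)``.
    Pairs where either profile has fewer than two scores are left undefined
    (NaN).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    names = [p.workflow for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("profile workflow labels must be unique")
    n_pairs = len(profiles) * (len(profiles) - 1) // 2
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in itertools.combinations(profiles, 2):
        if len(a.scores) < 2 or len(b.scores) < 2:
            continue  # undefined pair, reported as NaN
        p_raw = stats.mannwhitneyu(a.scores, b.scores, alternative="two-sided").pvalue
        p_adj = min(1.0, float(p_raw) * n_pairs)
        out.loc[a.workflow, b.workflow] = p_adj
        out.loc[b.workflow, a.workflow] = p_adj
    return out
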