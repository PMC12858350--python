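"""Replicate-precision metric: the standard deviation of per-protein log2
fold changes between two conditions.

For each protein quantified in every paired replicate of both conditions,
the log2 fold change is computed per replicate pair and its sample SD taken
as the protein's precision; averaging the per-protein SDs within
localization groups (IMPs = pIMP + oIMP; Sols = SP + MAP) ranks workflows
by how reproducibly they measure condition effects on membrane proteins.

Computed on unimputed data — imputed values would fabricate precision — so
proteins with any missing paired value are excluded and counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import LocalizationCall

__all__ = ["FoldChangeSpread", "PrecisionResult", "per_protein_fc_sd", "average_sd_by_category"]


@dataclass
class FoldChangeSpread:
    """Per-protein log2 fold-change vectors and their sample SD."""

    per_protein: pd.DataFrame  # fc_1..fc_k columns plus 'sd'
    n_excluded: int  # proteins dropped for incomplete observation
    pairing: str


@dataclass
class PrecisionResult:
    workflow: str
    per_protein: pd.DataFrame  # sd + category
    avg_sd_imp: float
    avg_sd_sol: float
    n_imp: int
    n_sol: int


def per_protein_fc_sd(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    pairing: str = "matched-index",
) -> FoldChangeSpread:
    """Fold-change vectors (B − A on the log2 scale) and their sample SD.

    ``data_a`` / ``data_b`` are proteins x replicates log2 DataFrames for
    the two conditions, with identical protein indices. Under
    ``matched-index`` pairing (default) replicate i of B is paired with
    replicate i of A, giving n fold changes from n+n replicates; under
    ``all-pairs`` every (i, j) combination contributes, a sensitivity
    variant. Proteins with any missing value among the paired samples are
    excluded and counted; SD uses the n−1 denominator.
    """
    if pairing not in ("matched-index", "all-pairs"):
        raise ValueError(f"unknown pairing {pairing!r}")
    if not data_a.index.equals(data_b.index):
        raise ValueError("condition matrices must share the same protein index")
    if pairing == "matched-index" and data_a.shape[1] != data_b.shape[1]:
        raise ValueError("matched-index pairing requires equal replicate counts")

    A = data_a.to_numpy(dtype=float)
    B = data_b.to_numpy(dtype=float)
    complete = np.isfinite(A).all(axis=1) & np.isfinite(B).all(axis=1)
    n_excluded = int((~complete).sum())

    if pairing == "matched-index":
        fcs = B[complete] - A[complete]
    else:
        pairs = list(itertools.product(range(B.shape[1]), range(A.shape[1])))
        fcs = np.column_stack([B[complete][:, i] - A[complete][:, j] for i, j in pairs])
    if fcs.shape[1] < 2:
        raise ValueError("need at least 2 fold-change values per protein for an SD")
    per = pd.DataFrame(
        fcs,
        index=data_a.index[complete],
        columns=[f"fc_{i + 1}" for i in range(fcs.shape[1])],
    )
    per["sd"] = fcs.std(axis=1, ddof=1)
    return FoldChangeSpread(per_protein=per, n_excluded=n_excluded, pairing=pairing)


def average_sd_by_category(
    spread: FoldChangeSpread,
    calls: dict[str, LocalizationCall],
    workflow: str = "",
) -> PrecisionResult:
    """Mean per-protein fold-change SD within IMPs (pIMP + oIMP) and Sols
    (SP + MAP). An empty group is reported as undefined (NaN) with n = 0."""
    per = spread.per_protein.copy()
    missing = [p for p in per.index if p not in calls]
    if missing:
        raise ValueError(f"proteins lacking localization calls: {missing[:10]}")
    per["category"] = [calls[p].category for p in per.index]
    is_imp = per["category"].isin(["pIMP", "oIMP"])
    imp_sd = per.loc[is_imp, "sd"]
    sol_sd = per.loc[~is_imp, "sd"]
    return PrecisionResult(
        workflow=workflow,
        per_protein=per[["sd", "category"]],
        avg_sd_imp=float(imp_sd.mean()) if len(imp_sd) else float("nan"),
        avg_sd_sol=float(sol_sd.mean()) if len(sol_sd) else float("nan"),
        n_imp=int(is_imp.sum()),
        n_sol=int((~is_imp).sum()),
    )
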