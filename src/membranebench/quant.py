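"""Global structure analyses of the quantification matrix.

Correlation, PCA, abundance-rank compositions, molecular-weight recovery
ratios, exclusive set overlaps and heatmap preparation — the descriptive
layer that sits between raw intensities and the differential stage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .annotation import LocalizationCall
from .io import AnnotationRecord, QuantMatrix, SampleDesign

__all__ = [
    "log2_matrix",
    "pearson_matrix",
    "best_replicate",
    "intermethod_pearson",
    "PCAProfiles",
    "pca_profiles",
    "top_n_composition",
    "quartile_composition",
    "mass_bin_ratio",
    "exclusive_set_overlaps",
    "heatmap_matrix",
]


def log2_matrix(q: QuantMatrix) -> QuantMatrix:
    """log2-transform present intensities; MISSING is preserved. Applying it
    to an already-log2 matrix is an error (the scale flag prevents a double
    transform)."""
    if q.scale == "log2":
        raise ValueError("matrix is already on the log2 scale")
    return QuantMatrix(np.log2(q.data), scale="log2")


def pearson_matrix(
    q: QuantMatrix,
    columns: list[str] | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson r over pairwise-complete observations.

    Cells whose pair shares fewer than ``min_shared`` present proteins are
    left undefined (NaN) rather than silently dropped. Requires log2 scale.
    """
    if q.scale != "log2":
        raise ValueError("Pearson correlations are computed on the log2 scale")
    data = q.data if columns is None else q.data[list(columns)]
    return data.corr(method="pearson", min_periods=min_shared)


def best_replicate(
    q: QuantMatrix,
    design: SampleDesign,
    workflow: str,
    condition: str | None = None,
) -> str:
    """The replicate with the highest number of protein identifications for
    a workflow (ties broken by lowest replicate index)."""
    candidates = [
        s for s in design.samples
        if s.workflow == workflow and (condition is None or s.condition == condition)
        and s.sample_id in q.data.columns
    ]
    if not candidates:
        raise ValueError(f"no samples for workflow {workflow!r} in the matrix")
    present = q.present()
    return max(
        sorted(candidates, key=lambda s: s.replicate),
        key=lambda s: int(present[s.sample_id].sum()),
    ).sample_id


def intermethod_pearson(
    q: QuantMatrix,
    design: SampleDesign,
    condition: str | None = None,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Between-workflow Pearson matrix where each workflow is represented by
    its highest-identification replicate. Returns (r matrix indexed by
    workflow, chosen replicate per workflow)."""
    chosen = {
        w: best_replicate(q, design, w, condition) for w in design.workflows
    }
    r = pearson_matrix(q, columns=list(chosen.values()), min_shared=min_shared)
    r.index = r.columns = list(chosen)
    return r, chosen


@dataclass
class PCAProfiles:
    coordinates: pd.DataFrame  # samples x (PC1, PC2)
    explained_variance_ratio: np.ndarray
    n_proteins: int


def pca_profiles(q: QuantMatrix, samples: list[str] | None = None) -> PCAProfiles:
    """PCA of sample profiles on log2, per-protein centered and unit-scaled
    intensities.

    Restricted to proteins present in all selected samples (complete case,
    no imputation); proteins with zero variance across the samples are
    dropped before scaling. The sign of each component is fixed by forcing
    its first nonzero protein loading to be non-negative, making the output
    deterministic and row-order independent up to that convention.
    """
    if q.scale != "log2":
        raise ValueError("PCA expects log2-scale intensities")
    data = q.data if samples is None else q.data[list(samples)]
    if data.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    complete = data.dropna(axis=0)
    sd = complete.std(axis=1, ddof=1)
    complete = complete[sd > 0]
    if complete.shape[0] < 3:
        raise ValueError(
            f"only {complete.shape[0]} complete-case proteins; need >= 3"
        )
    scaled = complete.sub(complete.mean(axis=1), axis=0).div(
        complete.std(axis=1, ddof=1), axis=0
    )
    X = scaled.to_numpy().T  # samples x proteins
    n_comp = min(2, X.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    for i in range(n_comp):
        loadings = pca.components_[i]
        nz = np.flatnonzero(loadings)
        if nz.size and loadings[nz[0]] < 0:
            coords[:, i] *= -1
            pca.components_[i] *= -1
    return PCAProfiles(
        coordinates=pd.DataFrame(
            coords, index=data.columns, columns=[f"PC{i + 1}" for i in range(n_comp)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_proteins=complete.shape[0],
    )


def _category_counts(categories: pd.Series) -> dict[str, int]:
    c = categories.value_counts()
    return {k: int(c.get(k, 0)) for k in ("pIMP", "oIMP", "MAP", "SP")}


def top_n_composition(
    q: QuantMatrix,
    calls: dict[str, LocalizationCall],
    rank_sample: str,
    n: int = 200,
) -> pd.DataFrame:
    """Localization composition of the top-n most abundant proteins.

    Proteins are ranked by descending intensity in ``rank_sample`` (by
    convention the workflow's highest-identification replicate); ties are
    broken by accession lexicographic order, making the result
    deterministic. If fewer than n proteins are present, composes over all
    present with a warning.
    """
    col = q.data[rank_sample].dropna()
    if len(col) < n:
        warnings.warn(
            f"only {len(col)} present proteins in {rank_sample!r}; "
            f"composing over all of them instead of top {n}"
        )
        n = len(col)
    ranked = col.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    top = ranked.iloc[:n]
    cats = pd.Series({p: calls[p].category for p in top.index})
    counts = _category_counts(cats)
    imp = counts["pIMP"] + counts["oIMP"]
    row = {**counts, "IMP": imp, "n": n, "IMP %": 100.0 * imp / n if n else 0.0}
    return pd.DataFrame([row], index=pd.Index([f"top{n}"], name="group"))


def quartile_composition(
    q: QuantMatrix,
    calls: dict[str, LocalizationCall],
    rank_sample: str,
) -> pd.DataFrame:
    """Localization composition per abundance quartile (Q1 = most abundant).

    Present proteins in ``rank_sample`` are sorted descending (ties by
    accession) and split into four quartiles; when the count is not
    divisible by four the higher quartiles take the extra proteins.
    """
    col = q.data[rank_sample].dropna()
    if len(col) < 4:
        raise ValueError("need at least 4 present proteins for quartiles")
    ranked = col.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    n = len(ranked)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    rows = []
    start = 0
    for i, size in enumerate(sizes, start=1):
        block = ranked.iloc[start:start + size]
        start += size
        cats = pd.Series({p: calls[p].category for p in block.index})
        counts = _category_counts(cats)
        imp = counts["pIMP"] + counts["oIMP"]
        rows.append({
            **counts, "IMP": imp, "n": size,
            "IMP %": 100.0 * imp / size if size else 0.0,
        })
    return pd.DataFrame(rows, index=pd.Index([f"Q{i}" for i in range(1, 5)], name="group"))


def mass_bin_ratio(
    qA: QuantMatrix,
    qB: QuantMatrix,
    calls: dict[str, LocalizationCall],
    annotations: dict[str, AnnotationRecord],
    edges: tuple[float, ...] = (40.0, 70.0, 100.0),
) -> pd.DataFrame:
    """Per molecular-weight bin, IMPs identified by A as % of IMPs
    identified by B (identification = present in >= 1 sample of the
    matrix). Default bins: (0,40], (40,70], (70,100], (100,inf) kDa. Bins
    with an empty denominator are reported as undefined (NaN)."""
    full_edges = [0.0, *edges, np.inf]
    labels = [
        f"{lo:g}–{hi:g} kDa" if np.isfinite(hi) else f">{lo:g} kDa"
        for lo, hi in zip(full_edges[:-1], full_edges[1:])
    ]

    def imp_mw(q: QuantMatrix) -> list[float]:
        idents = q.present().any(axis=1)
        out = []
        for pid in q.protein_ids:
            if not idents[pid]:
                continue
            call = calls.get(pid)
            if call is None or not call.is_imp:
                continue
            out.append(annotations[pid].mol_weight_kda)
        return out

    a_counts = pd.cut(imp_mw(qA), full_edges, labels=labels).value_counts()
    b_counts = pd.cut(imp_mw(qB), full_edges, labels=labels).value_counts()
    rows = []
    for lab in labels:
        na, nb = int(a_counts.get(lab, 0)), int(b_counts.get(lab, 0))
        rows.append({
            "bin": lab, "n_A": na, "n_B": nb,
            "ratio %": 100.0 * na / nb if nb else np.nan,
        })
    return pd.DataFrame(rows).set_index("bin")


def exclusive_set_overlaps(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection sizes of k named sets (UpSet-style).

    Every element is assigned to exactly one membership pattern; the sizes
    of all non-empty patterns are returned sorted descending, with the
    pattern written as "&"-joined set names. The sizes sum to the union
    cardinality.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 named sets")
    names = list(sets)
    patterns: dict[tuple[str, ...], int] = {}
    for el in set().union(*sets.values()):
        pattern = tuple(nm for nm in names if el in sets[nm])
        patterns[pattern] = patterns.get(pattern, 0) + 1
    rows = [
        {"pattern": "&".join(p), "degree": len(p), "size": s}
        for p, s in patterns.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["size", "pattern"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def heatmap_matrix(q: QuantMatrix, constant_fill: float = -4.0) -> pd.DataFrame:
    """Row-standardized log2 matrix for heatmap display.

    MISSING cells are first imputed with a constant (default −4, i.e. far
    below any observed log2 intensity), then each row is centered and scaled
    by its sample SD; zero-variance rows become all-zero.
    """
    if q.scale != "log2":
        raise ValueError("heatmap preparation expects log2-scale intensities")
    filled = q.data.fillna(constant_fill)
    mu = filled.mean(axis=1)
    sd = filled.std(axis=1, ddof=1)
    out = filled.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return out.fillna(0.0)
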