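"""Two-group differential abundance with MNAR imputation, an s0-moderated
t statistic, and permutation-based FDR.

The procedure mirrors the standard label-free-proteomics analysis chain:

1. **Valid-value filter** — keep proteins quantified in at least 3 of the 6
   samples (default), or alternatively in all replicates of at least one
   group.
2. **Downshifted-normal imputation** — missing log2 intensities are drawn
   per sample from Normal(mu − 1.8·sigma, (0.3·sigma)^2), where mu, sigma
   are that sample's observed mean and SD. This models
   missing-not-at-random (MNAR) cells as lying below the detection limit.
3. **Moderated statistic** — t_mod = (mean_B − mean_A) / (SE + s0) with the
   pooled-variance standard error and a small constant s0 (default 0.1)
   that damps the significance of near-zero-variance proteins. Two-sided
   p-values come from the t distribution with n_A + n_B − 2 df evaluated at
   t_mod (deliberately conservative for s0 > 0; exact at s0 = 0).
4. **Permutation FDR** — balanced relabelings of the group assignment give
   a null distribution of |t_mod|; the FDR at each observed |t| threshold
   is (mean permuted count >= threshold) / (observed count >= threshold),
   made monotone and capped at 1. For 3-vs-3 designs all C(6,3)/2 = 10
   distinct relabelings minus the identity are enumerated exactly.
5. **Volcano classification** — up/down calls at |log2FC| >= 1 and
   −log10 p >= 1.3 (both thresholds inclusive and configurable).

The model object is built from a proteins x samples log2 DataFrame (or a
QuantMatrix) and ``fit()`` returns a results object carrying the estimates,
q-values, calls and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import LocalizationCall
from .io import QuantMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationParams",
    "filter_valid",
    "impute_downshifted",
    "moderated_t",
    "permutation_fdr",
    "classify_de",
    "de_counts_by_category",
    "DifferentialAbundance",
    "DifferentialAbundanceResults",
]

VALID_RULES = ("per-comparison-3of6", "all-in-one-condition")


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal imputation parameters (units of per-sample SD)."""

    downshift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if not 0 < self.width <= 1:
            raise ValueError("width must be in (0, 1]")


def filter_valid(
    q: QuantMatrix,
    group_a: list[str],
    group_b: list[str],
    rule: str = "per-comparison-3of6",
    min_valid: int = 3,
) -> QuantMatrix:
    """Valid-value filter ahead of imputation.

    ``per-comparison-3of6`` (default): keep proteins with >= ``min_valid``
    present values among the pooled samples of both groups.
    ``all-in-one-condition``: keep proteins present in every replicate of at
    least one group.
    """
    if rule not in VALID_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {VALID_RULES}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    present = q.present()
    if rule == "per-comparison-3of6":
        keep = present[list(group_a) + list(group_b)].sum(axis=1) >= min_valid
    else:
        keep = present[list(group_a)].all(axis=1) | present[list(group_b)].all(axis=1)
    return q.select(proteins=q.data.index[keep])


def impute_downshifted(
    q: QuantMatrix,
    params: ImputationParams = ImputationParams(),
    rng: np.random.Generator | None = None,
) -> QuantMatrix:
    """Replace MISSING cells by draws from a per-sample downshifted normal.

    For each sample (column) with observed mean mu and SD sigma (ddof=1),
    missing cells get independent draws from
    Normal(mu − downshift·sigma, (width·sigma)^2). Present values are
    untouched; the draw is reproducible given the seed. Requires log2 scale
    and >= 2 present values per column.
    """
    if q.scale != "log2":
        raise ValueError("imputation operates on the log2 scale")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    data = q.data.copy()
    for col in data.columns:
        vals = data[col]
        obs = vals.dropna()
        if len(obs) < 2:
            raise ValueError(
                f"column {col!r} has {len(obs)} present values; need >= 2 to impute"
            )
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
        draws = rng.normal(mu - params.downshift * sigma, params.width * sigma, n_missing)
        data.loc[vals.isna(), col] = draws
    return QuantMatrix(data, scale="log2")


def moderated_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    s0: float = 0.1,
):
    """s0-moderated two-sample statistic.

    ``group_a`` / ``group_b`` are 1-D (one protein) or 2-D
    (proteins x replicates) arrays with no missing values. Returns
    (log2fc, t_mod, p) where log2fc = mean(B) − mean(A),
    t_mod = log2fc / (SE_pooled + s0), and p is the two-sided tail of the
    t distribution with n_A + n_B − 2 df. With s0 = 0 this is exactly the
    classical pooled two-sample t test; zero pooled variance with s0 = 0 is
    an error (undefined statistic).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = na + nb - 2
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if s0 == 0 and np.any(se == 0):
        raise ValueError("zero variance in both groups with s0 = 0: statistic undefined")
    t_mod = log2fc / (se + s0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if np.asarray(group_a).ndim == 1:
        return float(log2fc[0]), float(t_mod[0]), float(p[0])
    return log2fc, t_mod, p


def _balanced_permutations(na: int, nb: int) -> list[np.ndarray]:
    """All distinct group-A index sets of a two-group relabeling, excluding
    the identity; for equal group sizes, complementary relabelings (which
    merely flip the sign of every statistic) are deduplicated."""
    n = na + nb
    identity = tuple(range(na))
    seen = {identity}
    out = []
    for comb in itertools.combinations(range(n), na):
        if comb == identity:
            continue
        if na == nb:
            complement = tuple(sorted(set(range(n)) - set(comb)))
            if complement in seen:
                continue
        seen.add(comb)
        out.append(np.array(comb, dtype=int))
    return out


def permutation_fdr(
    matrix: np.ndarray,
    na: int,
    nb: int,
    s0: float = 0.1,
    n_perm: int = 250,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-based FDR (q-value) per protein.

    ``matrix`` is proteins x (na + nb) with group A in the first ``na``
    columns; no missing values. Group labels are rebalanced over the pooled
    columns; when ``n_perm`` meets or exceeds the number of distinct
    relabelings, all of them are used exactly once (removes Monte-Carlo
    noise at small n), otherwise a seeded subsample without replacement is
    drawn. For each threshold equal to an observed |t_mod| the FDR estimate
    is (mean permuted count >= threshold) / (observed count >= threshold);
    q is the monotone-enforced, capped-at-1 version evaluated at each
    protein's own |t_mod|.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != na + nb:
        raise ValueError("matrix width must equal na + nb")
    _, t_obs, _ = moderated_t(X[:, :na], X[:, na:], s0=s0)
    abs_obs = np.abs(t_obs)

    perms = _balanced_permutations(na, nb)
    if n_perm < len(perms):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(perms), size=n_perm, replace=False)
        perms = [perms[i] for i in idx]
    else:
        if n_perm > len(perms):
            logger.info(
                "n_perm=%d exceeds the %d distinct relabelings; using each once",
                n_perm, len(perms),
            )
    all_cols = np.arange(na + nb)
    perm_stats = []
    for comb in perms:
        rest = np.setdiff1d(all_cols, comb)
        _, t_perm, _ = moderated_t(X[:, comb], X[:, rest], s0=s0)
        perm_stats.append(np.abs(t_perm))
    perm_flat = np.sort(np.concatenate(perm_stats))
    n_perm_used = len(perms)

    # counts >= threshold via sorted arrays
    obs_sorted = np.sort(abs_obs)
    n = len(abs_obs)
    obs_count = n - np.searchsorted(obs_sorted, abs_obs, side="left")
    perm_count = (len(perm_flat) - np.searchsorted(perm_flat, abs_obs, side="left")) / n_perm_used
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_count > 0, perm_count / obs_count, np.nan)
    fdr = np.minimum(fdr, 1.0)

    # monotone: q(|t|) = min over thresholds <= |t| of FDR(threshold)
    order = np.argsort(abs_obs, kind="stable")
    q = np.empty_like(fdr)
    running = np.minimum.accumulate(fdr[order])
    q[order] = running
    return q


def classify_de(
    log2fc: np.ndarray,
    p: np.ndarray,
    fc_threshold: float = 1.0,
    p_threshold_log10: float = 1.3,
) -> np.ndarray:
    """Volcano calls: 'up' if log2fc >= fc_threshold and −log10 p >=
    p_threshold_log10, symmetrically 'down', otherwise 'ns'. Thresholds are
    inclusive."""
    log2fc = np.asarray(log2fc, dtype=float)
    neglog = -np.log10(np.asarray(p, dtype=float))
    sig = neglog >= p_threshold_log10
    calls = np.full(log2fc.shape, "ns", dtype=object)
    calls[sig & (log2fc >= fc_threshold)] = "up"
    calls[sig & (log2fc <= -fc_threshold)] = "down"
    return calls


def de_counts_by_category(
    calls: pd.Series,
    categories: pd.Series,
) -> pd.DataFrame:
    """DE counts and proportions per localization group.

    Groups: pIMP, oIMP, IMP (= pIMP + oIMP) and Sols (= SP + MAP).
    Proportion = DE in group / proteins scored in group.
    """
    if not calls.index.equals(categories.index):
        categories = categories.reindex(calls.index)
    if categories.isna().any():
        missing = list(categories.index[categories.isna()])[:10]
        raise ValueError(f"scored proteins lacking a category: {missing}")
    groups = {
        "pIMP": categories == "pIMP",
        "oIMP": categories == "oIMP",
        "IMP": categories.isin(["pIMP", "oIMP"]),
        "Sols": categories.isin(["SP", "MAP"]),
    }
    rows = []
    for name, mask in groups.items():
        n_scored = int(mask.sum())
        up = int(((calls == "up") & mask).sum())
        down = int(((calls == "down") & mask).sum())
        de = up + down
        rows.append({
            "group": name, "n_scored": n_scored, "up": up, "down": down,
            "de": de, "de %": 100.0 * de / n_scored if n_scored else 0.0,
        })
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# model / results objects


class DifferentialAbundance:
    """Two-group differential-abundance model on log2 intensities.

    Parameters
    ----------
    data
        Proteins x samples log2 DataFrame (NaN = missing) or a log2-scale
        QuantMatrix.
    group_a, group_b
        Sample (column) names of the two groups. ``log2fc`` is reported as
        mean(group_b) − mean(group_a).
    categories
        Optional per-protein localization category (Series indexed by
        accession) used for per-category DE summaries.
    valid_rule, min_valid
        Valid-value filter; see :func:`filter_valid`.
    s0, downshift, width
        Moderation constant and imputation parameters.
    """

    def __init__(
        self,
        data,
        group_a: list[str],
        group_b: list[str],
        categories: pd.Series | None = None,
        valid_rule: str = "per-comparison-3of6",
        min_valid: int = 3,
        s0: float = 0.1,
        downshift: float = 1.8,
        width: float = 0.3,
    ):
        if isinstance(data, QuantMatrix):
            if data.scale != "log2":
                raise ValueError("QuantMatrix must be on the log2 scale")
            data = data.data
        self.data = data.astype(float)
        for col in list(group_a) + list(group_b):
            if col not in self.data.columns:
                raise ValueError(f"sample {col!r} not in data columns")
        self.group_a = list(group_a)
        self.group_b = list(group_b)
        self.categories = categories
        self.valid_rule = valid_rule
        self.min_valid = min_valid
        self.s0 = s0
        self.downshift = downshift
        self.width = width

    @classmethod
    def from_quant_matrix(
        cls,
        q: QuantMatrix,
        design: SampleDesign,
        *,
        workflow: str | None = None,
        condition_a: str | None = None,
        condition_b: str | None = None,
        workflow_a: str | None = None,
        workflow_b: str | None = None,
        condition: str | None = None,
        calls: dict[str, LocalizationCall] | None = None,
        **kwargs,
    ) -> "DifferentialAbundance":
        """Build the model for either of the study's two comparison types:
        condition vs condition within one workflow (pass ``workflow``,
        ``condition_a``, ``condition_b``), or workflow vs workflow within
        one condition (pass ``workflow_a``, ``workflow_b``, ``condition``).
        """
        if workflow is not None:
            ga = design.subset(workflow=workflow, condition=condition_a)
            gb = design.subset(workflow=workflow, condition=condition_b)
        elif workflow_a is not None and workflow_b is not None:
            ga = design.subset(workflow=workflow_a, condition=condition)
            gb = design.subset(workflow=workflow_b, condition=condition)
        else:
            raise ValueError(
                "specify workflow+condition_a/condition_b or workflow_a/workflow_b+condition"
            )
        categories = None
        if calls is not None:
            categories = pd.Series({p: c.category for p, c in calls.items()})
        if q.scale == "linear":
            from .quant import log2_matrix

            q = log2_matrix(q)
        return cls(q, ga, gb, categories=categories, **kwargs)

    def fit(
        self,
        n_perm: int = 250,
        seed: int = 0,
        fc_threshold: float = 1.0,
        p_threshold_log10: float = 1.3,
        impute: bool = True,
    ) -> "DifferentialAbundanceResults":
        """Filter, impute, score and classify; returns the results object."""
        cols = self.group_a + self.group_b
        # deduplicate so a workflow can be compared against itself
        unique_cols = list(dict.fromkeys(cols))
        q = QuantMatrix(self.data[unique_cols], scale="log2")
        n_before = q.shape[0]
        q = filter_valid(q, self.group_a, self.group_b, self.valid_rule, self.min_valid)
        n_after = q.shape[0]
        if n_after == 0:
            raise ValueError("no protein passes the valid-value filter")
        ss = np.random.SeedSequence(seed)
        impute_seed, perm_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
        if impute:
            q = impute_downshifted(
                q,
                ImputationParams(self.downshift, self.width, impute_seed),
            )
        elif q.n_missing:
            raise ValueError("matrix still has missing values and impute=False")
        X = q.data[cols].to_numpy()
        na, nb = len(self.group_a), len(self.group_b)
        log2fc, t_mod, p = moderated_t(X[:, :na], X[:, na:], s0=self.s0)
        qvals = permutation_fdr(X, na, nb, s0=self.s0, n_perm=n_perm, seed=perm_seed)
        calls = classify_de(log2fc, p, fc_threshold, p_threshold_log10)
        frame = pd.DataFrame(
            {
                "log2fc": log2fc,
                "t_mod": t_mod,
                "p": p,
                "neg_log10_p": -np.log10(p),
                "q": qvals,
                "call": calls,
            },
            index=q.data.index,
        )
        if self.categories is not None:
            frame["category"] = self.categories.reindex(frame.index)
        return DifferentialAbundanceResults(
            model=self,
            frame=frame,
            n_input=n_before,
            n_scored=n_after,
            params={
                "s0": self.s0, "downshift": self.downshift, "width": self.width,
                "valid_rule": self.valid_rule, "min_valid": self.min_valid,
                "n_perm": n_perm, "seed": seed,
                "fc_threshold": fc_threshold, "p_threshold_log10": p_threshold_log10,
            },
        )


@dataclass
class DifferentialAbundanceResults:
    """Estimates, uncertainties and calls from a fitted differential model.

    ``frame`` has one row per scored protein with columns log2fc, t_mod, p,
    neg_log10_p, q, call and (when categories were supplied) category.
    """

    model: DifferentialAbundance
    frame: pd.DataFrame
    n_input: int
    n_scored: int
    params: dict = field(default_factory=dict)

    @property
    def n_up(self) -> int:
        return int((self.frame["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["call"] == "down").sum())

    def significant(self, q_threshold: float | None = None) -> pd.DataFrame:
        """Called proteins; optionally additionally gated at a permutation
        FDR threshold (the 'FDR < 0.05' style cut)."""
        out = self.frame[self.frame["call"] != "ns"]
        if q_threshold is not None:
            out = out[out["q"] < q_threshold]
        return out

    def de_counts_by_category(self) -> pd.DataFrame:
        if "category" not in self.frame.columns:
            raise ValueError("model was built without localization categories")
        return de_counts_by_category(self.frame["call"], self.frame["category"])

    def summary(self) -> str:
        p = self.params
        lines = [
            "Differential abundance (moderated t, permutation FDR)",
            "=" * 56,
            f"groups:        {self.model.group_a}  vs  {self.model.group_b}",
            f"proteins:      {self.n_input} input, {self.n_scored} scored "
            f"({self.n_input - self.n_scored} removed by {p.get('valid_rule')})",
            f"s0:            {p.get('s0')}",
            f"imputation:    downshift {p.get('downshift')} SD, width {p.get('width')} SD",
            f"thresholds:    |log2FC| >= {p.get('fc_threshold')}, "
            f"-log10 p >= {p.get('p_threshold_log10')}",
            f"calls:         {self.n_up} up, {self.n_down} down, "
            f"{self.n_scored - self.n_up - self.n_down} ns",
            f"q < 0.05:      {int((self.frame['q'] < 0.05).sum())} proteins",
        ]
        return "\n".join(lines)

    def volcano(self, ax=None, **scatter_kw):
        """Minimal diagnostic volcano plot (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = self.frame["call"].map({"up": "tab:red", "down": "tab:blue", "ns": "0.7"})
        ax.scatter(self.frame["log2fc"], self.frame["neg_log10_p"],
                   c=colors, s=8, **scatter_kw)
        ax.axhline(self.params.get("p_threshold_log10", 1.3), ls="--", lw=0.8, c="k")
        for sign in (1, -1):
            ax.axvline(sign * self.params.get("fc_threshold", 1.0), ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        return ax
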