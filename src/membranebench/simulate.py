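"""Seeded generator of complete multi-workflow, two-condition label-free
quantification datasets with ground truth.

The generator emulates the data structure of a seven-workflow membrane
proteomics benchmark: a proteome with sequences and annotations
(soluble / membrane-associated / plasma-membrane and organellar integral
membrane proteins with planted transmembrane stretches), peptide tables
from in-silico tryptic digestion, and protein quantification matrices with

* log-normal base abundances,
* workflow-specific capture efficiency driven by hydrophobicity (logistic
  in GRAVY), membrane category (affinity-enrichment boost for IMPs,
  depletion for soluble proteins) and optionally molecular weight
  (filter-based loss of small proteins),
* per-replicate multiplicative noise,
* intensity-dependent (MNAR) missingness, and
* planted condition effects (log2 fold changes on a known subset).

Everything is reproducible from a single seed, expanded into per-stage
child seeds via ``numpy.random.SeedSequence.spawn``. The planted truth is
stored for every protein and is never consumed by the analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from pyteomics import mass as pmass
from scipy.special import expit

from .annotation import TM_BINS
from .hydropathy import CANONICAL_RESIDUES, peptide_gravy
from .io import (
    AnnotationRecord,
    PeptideRecord,
    QuantMatrix,
    Sample,
    SampleDesign,
)

__all__ = [
    "WorkflowModel",
    "SimulationConfig",
    "Proteome",
    "SimulatedDataset",
    "DEFAULT_WORKFLOWS",
    "generate_proteome",
    "digest_stricttrypsin",
    "peptide_mass",
    "simulate_workflow_capture",
    "simulate_replicates",
    "apply_missingness",
    "generate_dataset",
]

WATER_MONO = 18.010565
_TM_RESIDUES = "ILVFAM"
# background residue pool: hydrophilic, with K/R frequent enough that tryptic
# digestion yields peptides inside the 7-50 length window
_BG_RESIDUES = np.array(list("DENQSTGHPAKR"))
_BG_WEIGHTS = np.array([9, 9, 9, 9, 9, 9, 9, 5, 6, 6, 10, 10], dtype=float)
_BG_WEIGHTS /= _BG_WEIGHTS.sum()

_ORGANELLE_KEYWORDS = (
    "endoplasmic reticulum membrane",
    "golgi apparatus membrane",
    "mitochondrion inner membrane",
    "lysosome membrane",
    "endosome membrane",
    "peroxisome membrane",
    "nucleus membrane",
    "vesicle membrane",
)
_SP_KEYWORDS = ("cytosol", "cytoplasm", "secreted", "extracellular space")

#: residue -> index of TM_BINS, sampled uniformly within the bin
_TM_BIN_RANGES = {"1": (1, 1), "2": (2, 2), "3–5": (3, 5), "6–10": (6, 10), "11+": (11, 14)}


@dataclass
class WorkflowModel:
    """Generative capture model for one sample-preparation workflow.

    ``capture_midpoint``/``capture_slope`` place a logistic capture curve on
    protein GRAVY (positive slope favours hydrophobic proteins);
    ``imp_enrichment`` (>= 1) multiplies IMP abundances, modelling an
    affinity-enrichment step; ``sp_depletion`` (<= 1) multiplies soluble
    proteins; ``mw_loss_cutoff_kda`` switches on a logistic loss of proteins
    below that molecular weight (filter-based loss); ``replicate_cv`` is the
    multiplicative per-replicate noise; missingness is
    logistic(intercept − slope · log2 intensity).
    """

    name: str = "workflow"
    capture_midpoint: float = 0.0
    capture_slope: float = 0.0
    imp_enrichment: float = 1.0
    sp_depletion: float = 1.0
    mw_loss_cutoff_kda: float | None = None
    mw_loss_width_kda: float = 12.0
    replicate_cv: float = 0.25
    missing_intercept: float = 26.0
    missing_slope: float = 1.5

    def __post_init__(self):
        if self.replicate_cv <= 0:
            raise ValueError("replicate_cv must be > 0")
        if not 0 < self.sp_depletion <= 1:
            raise ValueError("sp_depletion must be in (0, 1]")
        if self.imp_enrichment < 1:
            raise ValueError("imp_enrichment must be >= 1")


def default_workflows() -> dict[str, WorkflowModel]:
    """The seven named presets, qualitatively ordered to mirror the
    benchmark: membrane-mimetic workflows (Peptidisc, spNW30) enrich IMPs
    strongly, favour hydrophobic proteins and have low replicate noise;
    solid-phase workflows (SP3, SP4, S-Trap) favour hydrophilic proteins
    with high noise on membrane proteins; FASP additionally loses
    low-molecular-weight proteins to its filter; SMA2000 is intermediate.
    Illustrative parameterizations, not fits to any measured dataset.
    """
    return {
        "SP3": WorkflowModel("SP3", capture_midpoint=-0.2, capture_slope=-1.2,
                             replicate_cv=0.45),
        "SP4": WorkflowModel("SP4", capture_midpoint=-0.2, capture_slope=-1.4,
                             replicate_cv=0.40),
        "FASP": WorkflowModel("FASP", capture_midpoint=-0.3, capture_slope=-1.6,
                              replicate_cv=0.50, mw_loss_cutoff_kda=40.0),
        "STRAP": WorkflowModel("STRAP", capture_midpoint=-0.1, capture_slope=-0.8,
                               replicate_cv=0.42),
        "PEPTIDISC": WorkflowModel("PEPTIDISC", capture_midpoint=-0.4, capture_slope=1.2,
                                   imp_enrichment=5.0, sp_depletion=0.5,
                                   replicate_cv=0.12),
        "SPNW30": WorkflowModel("SPNW30", capture_midpoint=-0.35, capture_slope=1.2,
                                imp_enrichment=4.0, sp_depletion=0.55,
                                replicate_cv=0.15),
        "SMA2000": WorkflowModel("SMA2000", capture_midpoint=-0.3, capture_slope=0.5,
                                 imp_enrichment=2.5, sp_depletion=0.8,
                                 replicate_cv=0.20),
    }


DEFAULT_WORKFLOWS = default_workflows()


@dataclass
class SimulationConfig:
    """Generative parameters of a full benchmark dataset."""

    n_proteins: int = 800
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {"SP": 0.49, "MAP": 0.34, "pIMP": 0.07, "oIMP": 0.10}
    )
    tm_bin_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            # over TM bins 1, 2, 3-5, 6-10, 11+
            "pIMP": (0.25, 0.20, 0.25, 0.18, 0.12),
            "oIMP": (0.40, 0.25, 0.20, 0.10, 0.05),
        }
    )
    sequence_length: tuple[int, int] = (150, 700)
    abundance_log2_mean: float = 23.0
    abundance_log2_sd: float = 2.0
    workflows: dict[str, WorkflowModel] = field(default_factory=default_workflows)
    effect_fraction: float = 0.10
    effect_log2fc: float = 2.0
    n_replicates: int = 3
    conditions: tuple[str, str] = ("LFD", "HFD")
    slc_fraction_pimp: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        total = sum(self.category_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"category_proportions must sum to 1 (got {total:g})"
            )
        if self.abundance_log2_sd <= 0:
            raise ValueError("abundance_log2_sd must be > 0")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")
        for wm in self.workflows.values():
            wm.__post_init__()


@dataclass
class Proteome:
    """Generated sequences and annotations plus the per-protein truth."""

    sequences: dict[str, str]
    annotations: dict[str, AnnotationRecord]
    truth: pd.DataFrame  # category, tm_count, gravy, mol_weight_kda,
    #                      base_log2_abundance, true_log2fc


@dataclass
class SimulatedDataset:
    design: SampleDesign
    quant: dict[str, QuantMatrix]  # per workflow, linear scale, 6 columns
    peptides: dict[str, list[PeptideRecord]]
    annotations: dict[str, AnnotationRecord]
    truth: pd.DataFrame  # proteome truth + expected capture per workflow
    proteome: Proteome
    config: SimulationConfig

    def combined_quant(self) -> QuantMatrix:
        """All workflows side by side (7 x 2 x 3 = 42 columns by default)."""
        data = pd.concat([q.data for q in self.quant.values()], axis=1)
        return QuantMatrix(data[self.design.sample_ids], scale="linear")


# ---------------------------------------------------------------------------
# proteome generation


def _random_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BG_RESIDUES, size=n, p=_BG_WEIGHTS))


def _build_sequence(rng: np.random.Generator, length: int, tm_count: int) -> str:
    """Hydrophilic background with ``tm_count`` embedded 19-residue
    hydrophobic stretches, separated by spacers of >= 20 residues so the
    sliding-window predictor resolves them as distinct segments."""
    tm_len, min_spacer = 19, 20
    n_spacers = tm_count + 1
    needed = tm_count * tm_len + n_spacers * min_spacer
    if length < needed:
        raise ValueError("sequence too short for the sampled TM stretches")
    extra = length - needed
    # distribute the surplus randomly over the spacers
    if extra > 0:
        split = rng.multinomial(extra, np.full(n_spacers, 1.0 / n_spacers))
    else:
        split = np.zeros(n_spacers, dtype=int)
    parts = []
    for i in range(tm_count):
        parts.append(_random_background(rng, min_spacer + int(split[i])))
        parts.append("".join(rng.choice(list(_TM_RESIDUES), size=tm_len)))
    parts.append(_random_background(rng, min_spacer + int(split[-1])))
    return "".join(parts)


def _sample_tm_count(rng: np.random.Generator, probs: tuple[float, ...]) -> int:
    bin_label = TM_BINS[rng.choice(len(TM_BINS), p=np.asarray(probs) / np.sum(probs))]
    lo, hi = _TM_BIN_RANGES[bin_label]
    return int(rng.integers(lo, hi + 1))


def protein_monoisotopic_kda(sequence: str) -> float:
    return (sum(pmass.std_aa_mass[a] for a in sequence) + WATER_MONO) / 1000.0


def generate_proteome(config: SimulationConfig, rng: np.random.Generator | None = None) -> Proteome:
    """Sample the proteome: categories, TM counts, sequences, GO keyword
    strings satisfying the classification rules, gene symbols (a fraction of
    pIMPs are named as SLC transporters), molecular weights and base
    abundances plus planted condition effects. Deterministic under seed."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cats = list(config.category_proportions)
    props = np.array([config.category_proportions[c] for c in cats], dtype=float)
    categories = rng.choice(cats, size=config.n_proteins, p=props / props.sum())

    sequences: dict[str, str] = {}
    annotations: dict[str, AnnotationRecord] = {}
    rows = []
    lo, hi = config.sequence_length
    n_slc = 0
    for i, cat in enumerate(categories):
        pid = f"P{i:05d}"
        if cat in ("pIMP", "oIMP"):
            tm = _sample_tm_count(rng, config.tm_bin_probs[cat])
        else:
            tm = 0
        # bounded retries when a sampled length cannot hold the TM stretches;
        # after that, sample directly from the feasible length range (multi-TM
        # transporters are long proteins), erroring only when none exists
        needed = tm * 19 + (tm + 1) * 20
        if needed > hi:
            raise ValueError(
                f"cannot fit {tm} TM stretches into max length {hi} for {pid}"
            )
        seq = None
        for _ in range(10):
            length = int(rng.integers(lo, hi + 1))
            if length >= needed:
                seq = _build_sequence(rng, length, tm)
                break
        if seq is None:
            length = int(rng.integers(needed, hi + 1))
            seq = _build_sequence(rng, length, tm)
        if cat == "SP":
            kw = str(rng.choice(_SP_KEYWORDS))
        elif cat == "MAP":
            kw = "membrane; peripheral membrane protein"
        elif cat == "pIMP":
            kw = "plasma membrane; integral component of membrane"
        else:
            kw = "membrane; " + str(rng.choice(_ORGANELLE_KEYWORDS))
        if cat == "pIMP" and rng.random() < config.slc_fraction_pimp:
            n_slc += 1
            gene = f"Slc{n_slc}a{int(rng.integers(1, 10))}"
        else:
            gene = f"Gene{i:05d}"
        mw = protein_monoisotopic_kda(seq)
        sequences[pid] = seq
        annotations[pid] = AnnotationRecord(pid, gene, kw, tm, mw)
        rows.append({
            "protein_id": pid, "category": cat, "tm_count": tm,
            "gravy": peptide_gravy(seq), "mol_weight_kda": mw,
        })

    truth = pd.DataFrame(rows).set_index("protein_id")
    truth["base_log2_abundance"] = rng.normal(
        config.abundance_log2_mean, config.abundance_log2_sd, config.n_proteins
    )
    affected = rng.random(config.n_proteins) < config.effect_fraction
    signs = rng.choice([-1.0, 1.0], size=config.n_proteins)
    truth["true_log2fc"] = np.where(affected, signs * config.effect_log2fc, 0.0)
    return Proteome(sequences=sequences, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# in-silico digestion


def peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass: residue masses plus one water."""
    return sum(pmass.std_aa_mass[a] for a in sequence) + WATER_MONO


def digest_stricttrypsin(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 50,
    min_mass: float = 500.0,
    max_mass: float = 5000.0,
) -> list[str]:
    """Fully tryptic peptides under the "strict trypsin" rule.

    Cleaves after every K and R, *including* before proline (the strict
    rule). All fully tryptic peptides with up to ``max_missed`` internal
    cleavage sites are enumerated, then filtered by length and monoisotopic
    mass. Duplicate sequences within a protein are kept once, in order of
    first occurrence.
    """
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"non-canonical residue(s) {sorted(bad)}")
    cuts = [0] + [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    fragments = [sequence[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    out: list[str] = []
    seen: set[str] = set()
    for i in range(len(fragments)):
        for span in range(1, max_missed + 2):
            if i + span > len(fragments):
                break
            pep = "".join(fragments[i:i + span])
            if pep in seen:
                continue
            if not (min_len <= len(pep) <= max_len):
                continue
            if not (min_mass <= peptide_mass(pep) <= max_mass):
                continue
            seen.add(pep)
            out.append(pep)
    return out


# ---------------------------------------------------------------------------
# capture, replicates, missingness


def simulate_workflow_capture(truth: pd.DataFrame, model: WorkflowModel) -> pd.Series:
    """Expected captured (linear) abundance per protein for one workflow:
    base abundance x logistic GRAVY capture x category factor x optional
    molecular-weight retention."""
    base = np.power(2.0, truth["base_log2_abundance"].to_numpy())
    capture = expit(model.capture_slope * (truth["gravy"].to_numpy() - model.capture_midpoint))
    cat = truth["category"].to_numpy()
    factor = np.ones(len(truth))
    factor[np.isin(cat, ["pIMP", "oIMP"])] = model.imp_enrichment
    factor[cat == "SP"] = model.sp_depletion
    expected = base * capture * factor
    if model.mw_loss_cutoff_kda is not None:
        mw = truth["mol_weight_kda"].to_numpy()
        expected = expected * expit((mw - model.mw_loss_cutoff_kda) / model.mw_loss_width_kda)
    return pd.Series(expected, index=truth.index, name=model.name)


def simulate_replicates(
    expected: pd.Series,
    true_log2fc: pd.Series,
    model: WorkflowModel,
    conditions: tuple[str, str],
    n_replicates: int,
    rng: np.random.Generator,
    sample_ids: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Linear-scale replicate intensities for both conditions.

    The second condition's expected abundance is the first's times
    2^(true log2FC); each replicate value is expected x exp(eps) with
    eps ~ Normal(0, replicate_cv^2), independent and seeded.
    """
    cols = {}
    exp_by_cond = {
        conditions[0]: expected.to_numpy(),
        conditions[1]: expected.to_numpy() * np.power(2.0, true_log2fc.to_numpy()),
    }
    for cond in conditions:
        ids = (
            sample_ids[cond]
            if sample_ids is not None
            else [f"{model.name}_{cond}_{r}" for r in range(1, n_replicates + 1)]
        )
        for sid in ids:
            eps = rng.normal(0.0, model.replicate_cv, len(expected))
            cols[sid] = exp_by_cond[cond] * np.exp(eps)
    return pd.DataFrame(cols, index=expected.index)


def apply_missingness(
    data: pd.DataFrame,
    model: WorkflowModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Intensity-dependent (MNAR) missingness: each cell is independently
    masked with probability logistic(intercept − slope · log2 value), so a
    positive slope preferentially removes low-intensity cells. If a column
    ends up with fewer than 2 present values its mask is regenerated once,
    then an error is raised."""
    out = data.copy()
    log2v = np.log2(data.to_numpy())
    p_missing = expit(model.missing_intercept - model.missing_slope * log2v)
    mask = rng.random(p_missing.shape) < p_missing
    for j, col in enumerate(data.columns):
        if (~mask[:, j]).sum() < 2:  # pathological column: one retry
            mask[:, j] = rng.random(len(data)) < p_missing[:, j]
            if (~mask[:, j]).sum() < 2:
                raise ValueError(
                    f"column {col!r} retains < 2 present values under the missingness model"
                )
    out[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# full dataset


def _allocate_peptides(
    sequences: dict[str, str],
    quant: pd.DataFrame,
    rng: np.random.Generator,
    digest_cache: dict[str, list[str]] | None = None,
    weights_cache: dict[str, np.ndarray] | None = None,
) -> list[PeptideRecord]:
    """Split each protein's intensity over its tryptic peptides with a fixed
    Dirichlet draw per protein (preserves protein totals; missing protein
    values propagate to every peptide)."""
    records: list[PeptideRecord] = []
    for pid in quant.index:
        seq = sequences[pid]
        if digest_cache is not None and pid in digest_cache:
            peps = digest_cache[pid]
        else:
            peps = digest_stricttrypsin(seq)
            if digest_cache is not None:
                digest_cache[pid] = peps
        if not peps:
            continue
        if weights_cache is not None and pid in weights_cache:
            w = weights_cache[pid]
        else:
            w = rng.dirichlet(np.ones(len(peps)))
            if weights_cache is not None:
                weights_cache[pid] = w
        row = quant.loc[pid].to_numpy(dtype=float)
        cols = list(quant.columns)
        for pep, wi in zip(peps, w):
            records.append(PeptideRecord(pep, pid, dict(zip(cols, row * wi))))
    return records


def generate_dataset(config: SimulationConfig, include_peptides: bool = True) -> SimulatedDataset:
    """Generate the full bundle: design, per-workflow quantification
    matrices with missingness, peptide tables, annotations and planted
    truth. One global seed expands to per-stage child seeds
    (SeedSequence.spawn), so each stage is individually reproducible."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + 2 * len(config.workflows))
    proteome = generate_proteome(config, np.random.default_rng(children[0]))
    pep_rng = np.random.default_rng(children[1])

    design = SampleDesign.from_layout(
        workflows=tuple(config.workflows),
        conditions=config.conditions,
        n_replicates=config.n_replicates,
    )

    truth = proteome.truth.copy()
    quant: dict[str, QuantMatrix] = {}
    peptides: dict[str, list[PeptideRecord]] = {}
    digest_cache: dict[str, list[str]] = {}
    weights_cache: dict[str, np.ndarray] = {}
    for k, (name, wm) in enumerate(config.workflows.items()):
        rep_rng = np.random.default_rng(children[2 + 2 * k])
        miss_rng = np.random.default_rng(children[3 + 2 * k])
        expected = simulate_workflow_capture(truth, wm)
        truth[f"expected_capture_{name}"] = expected
        sample_ids = {c: design.subset(workflow=name, condition=c) for c in config.conditions}
        reps = simulate_replicates(
            expected, truth["true_log2fc"], wm, config.conditions,
            config.n_replicates, rep_rng, sample_ids,
        )
        observed = apply_missingness(reps, wm, miss_rng)
        quant[name] = QuantMatrix(observed, scale="linear")
        if include_peptides:
            peptides[name] = _allocate_peptides(
                proteome.sequences, observed, pep_rng, digest_cache, weights_cache
            )

    return SimulatedDataset(
        design=design,
        quant=quant,
        peptides=peptides,
        annotations=proteome.annotations,
        truth=truth,
        proteome=proteome,
        config=config,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable view of a SimulationConfig."""
    d = asdict(config)
    d["workflows"] = {k: asdict(v) for k, v in config.workflows.items()}
    return d
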