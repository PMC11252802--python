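"""Ground-truthed synthetic cohorts and TMA H-score tables.

The cohort generator plants transcription-factor-defined cell states in
negative-binomial counts: each state owns a regulon whose target genes have a
fold-increased mean in that state's cells, patients are assigned per state from
Dirichlet-distributed frequencies (small concentration = patient-specific
state, large = multi-patient state), and cell-surface-antigen genes can be
coupled multiplicatively to chosen states. The H-score generator produces
marker pairs whose population concordance (Lin's CCC) is calibrated in closed
form through a shared-latent construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CellAnnotation,
    ExpressionMatrix,
    HScoreTable,
    KI67_ALIASES,
    Regulon,
    RegulonSet,
    ValidationError,
)

__all__ = [
    "CohortSimSpec",
    "SyntheticTruth",
    "HScoreSimSpec",
    "simulate_cohort",
    "simulate_hscores",
    "simulate_two_cohorts",
]


@dataclass
class CohortSimSpec:
    """Parameters of a planted-state negative-binomial cohort."""

    n_states: int = 5
    cells_per_state: int = 120
    n_patients: int = 8
    #: Dirichlet concentration per state (scalar applied to all states, or one
    #: value per state). 0.05 ~ patient-specific, 50 ~ shared across patients.
    patient_concentration: float | Sequence[float] = 1.0
    genes_per_regulon: int = 18
    n_background_genes: int = 500
    regulon_effect: float = 8.0
    baseline_mean: float = 2.0
    dispersion: float = 10.0  # negative-binomial size; var = m + m^2/size
    #: (antigen_gene, state, fold) multiplicative couplings; antigen genes are
    #: appended to the gene universe with baseline mean elsewhere.
    antigen_coupling: list[tuple[str, str, float]] = field(default_factory=list)
    #: optional category per state; derived from concentration when None
    state_categories: list[str] | None = None
    state_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if min(self.genes_per_regulon, self.n_background_genes, self.cells_per_state,
               self.n_patients) < 1:
            raise ValidationError("counts in the spec must be >= 1")
        if min(self.regulon_effect, self.baseline_mean, self.dispersion) <= 0:
            raise ValidationError("means, folds and dispersion must be > 0")
        alphas = self.alphas
        if len(alphas) != self.n_states or min(alphas) <= 0:
            raise ValidationError("patient_concentration must be > 0, scalar or one per state")
        if self.state_names is not None and len(self.state_names) != self.n_states:
            raise ValidationError("state_names length must equal n_states")

    @property
    def alphas(self) -> list[float]:
        a = self.patient_concentration
        return [float(a)] * self.n_states if np.isscalar(a) else [float(x) for x in a]

    @property
    def states(self) -> list[str]:
        if self.state_names is not None:
            return list(self.state_names)
        return [f"S{i + 1}" for i in range(self.n_states)]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, used as the recovery oracle."""

    state_of_cell: pd.Series  # cell_id -> state
    patient_of_cell: pd.Series
    planted_regulons: RegulonSet
    antigen_map: dict[str, tuple[str, float]]
    gene_means: pd.DataFrame  # genes x states noiseless NB means


def _state_categories(spec: CohortSimSpec) -> list[str]:
    if spec.state_categories is not None:
        if len(spec.state_categories) != spec.n_states:
            raise ValidationError("state_categories length must equal n_states")
        return list(spec.state_categories)
    # small concentration -> patient-private state, as seen in treatment-
    # resistant tumors; large -> shared across patients, as in naive/CSPC
    return ["CRPC_adeno" if a < 1 else "naive_CSPC" for a in spec.alphas]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[ExpressionMatrix, CellAnnotation, RegulonSet, SyntheticTruth]:
    """Simulate a planted-state cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    states = spec.states
    n_cells = spec.n_states * spec.cells_per_state

    # gene universe: one target block per state, then background, then antigens
    target_genes = {
        s: [f"{s}_T{j + 1:03d}" for j in range(spec.genes_per_regulon)] for s in states
    }
    bg_genes = [f"BG{j + 1:04d}" for j in range(spec.n_background_genes)]
    antigen_genes = [a for a, _s, _f in spec.antigen_coupling]
    if len(set(antigen_genes)) != len(antigen_genes):
        raise ValidationError("duplicate antigen gene in antigen_coupling")
    for _a, s, f in spec.antigen_coupling:
        if s not in states:
            raise ValidationError(f"antigen coupled to unknown state {s!r}")
        if f <= 0:
            raise ValidationError("antigen fold must be > 0")
    gene_ids = [g for s in states for g in target_genes[s]] + bg_genes + antigen_genes
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("gene name collision between regulon targets/background/antigens")

    # noiseless mean matrix: genes x states
    means = pd.DataFrame(spec.baseline_mean, index=gene_ids, columns=states, dtype=float)
    for s in states:
        means.loc[target_genes[s], s] *= spec.regulon_effect
    for a, s, f in spec.antigen_coupling:
        means.loc[a, s] *= f

    # cells, states, patients
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    state_of_cell = np.repeat(states, spec.cells_per_state)
    patients = [f"P{j + 1:02d}" for j in range(spec.n_patients)]
    patient_of_cell = np.empty(n_cells, dtype=object)
    for si, s in enumerate(states):
        freqs = rng.dirichlet([spec.alphas[si]] * spec.n_patients)
        idx = np.where(state_of_cell == s)[0]
        patient_of_cell[idx] = rng.choice(patients, size=len(idx), p=freqs)

    counts = np.empty((len(gene_ids), n_cells), dtype=float)
    for si, s in enumerate(states):
        idx = np.where(state_of_cell == s)[0]
        m = means[s].to_numpy()[:, None] * np.ones(len(idx))[None, :]
        counts[:, idx] = _nb_draw(rng, m, spec.dispersion)

    em = ExpressionMatrix(counts, gene_ids, cell_ids, layer="counts")
    cats = dict(zip(states, _state_categories(spec)))
    annot = CellAnnotation(pd.DataFrame({
        "cell_id": cell_ids,
        "patient_id": patient_of_cell,
        "category": [cats[s] for s in state_of_cell],
        "site": "synthetic",
        "true_state": state_of_cell,
    }))
    regulons = RegulonSet([
        Regulon(tf=s, targets=frozenset(target_genes[s])) for s in states
    ])
    truth = SyntheticTruth(
        state_of_cell=pd.Series(state_of_cell, index=cell_ids, name="state"),
        patient_of_cell=pd.Series(patient_of_cell, index=cell_ids, name="patient"),
        planted_regulons=regulons,
        antigen_map={a: (s, f) for a, s, f in spec.antigen_coupling},
        gene_means=means,
    )
    return em, annot, regulons, truth


def simulate_two_cohorts(
    spec_a: CohortSimSpec, spec_b: CohortSimSpec, shared_states: Sequence[str]
) -> tuple[tuple, tuple]:
    """Two cohorts whose ``shared_states`` plant identical regulon gene sets.

    Both cohorts live on the same gene universe (so cross-cohort DE overlap is
    well defined); a state private to one cohort leaves its target genes at
    baseline in the other. Private state names must not collide.
    """
    for s in shared_states:
        if s not in spec_a.states or s not in spec_b.states:
            raise ValidationError(f"shared state {s!r} missing from a spec")
    priv_a = set(spec_a.states) - set(shared_states)
    priv_b = set(spec_b.states) - set(shared_states)
    clash = priv_a & priv_b
    if clash:
        raise ValidationError(f"private state name collision: {sorted(clash)}")

    def build(spec: CohortSimSpec, other: CohortSimSpec) -> tuple:
        # widen the universe with the other cohort's private targets (baseline)
        extra = [
            (f"{s}_T{j + 1:03d}", s)
            for s in other.states if s not in spec.states
            for j in range(other.genes_per_regulon)
        ]
        em, annot, regs, truth = simulate_cohort(spec)
        if extra:
            rng = np.random.default_rng(spec.seed + 10_000)
            extra_names = [g for g, _ in extra]
            m = np.full((len(extra_names), em.n_cells), spec.baseline_mean)
            vals = _nb_draw(rng, m, spec.dispersion)
            em = ExpressionMatrix(
                np.vstack([em.values, vals]), em.gene_ids + extra_names,
                list(em.cell_ids), layer="counts",
            )
        return em, annot, regs, truth

    return build(spec_a, spec_b), build(spec_b, spec_a)


@dataclass
class HScoreSimSpec:
    """Parameters of a synthetic TMA H-score table with calibrated concordance."""

    n_cores: int = 131
    #: (markerA, markerB, target population CCC in (-1, 1], calibrated exactly
    #: before clipping to the score range)
    marker_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    histology_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 20.0
    center: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cores < 10:
            raise ValidationError("n_cores must be >= 10")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for a, b, c in self.marker_pairs:
            if not (-1 <= c <= 1):
                raise ValidationError(f"target_ccc for ({a},{b}) must be in [-1,1]")
            if abs(c) == 1 and self.noise_sd > 0 and c != 1:
                raise ValidationError("target_ccc = -1 requires noise_sd = 0")


def _latent_share_sd(target_ccc: float, noise_sd: float) -> float:
    """Latent sd tau solving CCC = tau^2/(tau^2 + noise_sd^2) (sign via coupling).

    Construction: A = mu + L + eA, B = mu +/- L + eB with L ~ N(0, tau^2) and
    independent N(0, s^2) noises. Means and variances match, so the population
    CCC equals the correlation tau^2/(tau^2+s^2) with the coupling's sign.
    """
    c = abs(target_ccc)
    if c >= 1:
        if noise_sd > 0:
            raise ValidationError(
                f"target_ccc = +/-1 is infeasible with noise_sd = {noise_sd} > 0; "
                "the independent noise bounds |CCC| below 1"
            )
        return 1.0  # any positive latent sd; noiseless copy
    return noise_sd * np.sqrt(c / (1 - c)) if c > 0 else 0.0


def simulate_hscores(spec: HScoreSimSpec) -> tuple[HScoreTable, pd.DataFrame]:
    """Simulate core x marker H-scores; returns the table and a truth summary.

    For a pair of new markers, both are built from a shared latent core-level
    signal whose variance is solved in closed form so the pre-clipping
    population CCC equals the target. A pair may also reuse one marker already
    generated (hub markers such as ASCL1 in an IHC panel): the new marker is
    then regressed on the existing one with matched mean and variance, which
    again fixes the population CCC at the target. Scores are finally clipped
    to [0, 200] (Ki-67 markers are halved onto 0-100), which can shrink the
    realized CCC slightly.
    """
    rng = np.random.default_rng(spec.seed)
    core_ids = [f"core{i + 1:03d}" for i in range(spec.n_cores)]
    hists = np.array(["PRAD", "HGC", "NEPC"])[np.arange(spec.n_cores) % 3]
    patient_ids = [f"TMA_P{1 + i % 16:02d}" for i in range(spec.n_cores)]

    values: dict[str, np.ndarray] = {}  # marker -> pre-clip values, 0-200 scale
    truth_rows = []
    for a, b, c in spec.marker_pairs:
        if a in values and b in values:
            raise ValidationError(
                f"both {a!r} and {b!r} already generated; their CCC is fixed"
            )
        if b in values:  # orient so any existing marker is `a`
            a, b = b, a
        if a in values:
            base = values[a]
            resid_sd = np.sqrt(max((1 - c * c), 0.0)) * base.std()
            vb = spec.center + c * (base - spec.center) + rng.normal(0.0, resid_sd,
                                                                     spec.n_cores)
            values[b] = vb
        else:
            tau = _latent_share_sd(c, spec.noise_sd)
            latent = rng.normal(0.0, tau, spec.n_cores)
            sign = 1.0 if c >= 0 else -1.0
            va = spec.center + latent + rng.normal(0.0, spec.noise_sd, spec.n_cores)
            vb = spec.center + sign * latent + rng.normal(0.0, spec.noise_sd,
                                                          spec.n_cores)
            if c == 1 and spec.noise_sd == 0:
                vb = va.copy()
            values[a], values[b] = va, vb
        truth_rows.append({"marker_a": a, "marker_b": b, "target_ccc": c,
                           "noise_sd": spec.noise_sd})

    rows = []
    for marker, vals in values.items():
        shift = np.array([
            spec.histology_effects.get(h, {}).get(marker, 0.0) for h in hists
        ])
        v = np.clip(vals + shift, 0.0, 200.0)
        if marker in KI67_ALIASES:
            v = v / 2.0  # proliferation index on 0-100
        rows.append(pd.DataFrame({
            "core_id": core_ids, "patient_id": patient_ids, "site": "autopsy",
            "histology": hists, "marker": marker, "score": v,
        }))
    table = pd.concat(rows, ignore_index=True)
    return HScoreTable(table.reset_index(drop=True)), pd.DataFrame(truth_rows)
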