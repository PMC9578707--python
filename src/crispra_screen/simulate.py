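"""Generative model of a pooled CRISPRa bead-selection enrichment screen.

The model follows the wet workflow of a positive-selection screen: a pooled
sgRNA library (10 guides per target plus matched controls) is transduced at
~1000x cell coverage per guide, cells carrying a guide that activates a
receptor for the bait ligand are captured on magnetic beads with elevated
probability, captured cells are expanded back to the original population
size, and each population (naive plus every selection round) is sampled by
deep sequencing.  Ground truth (per-guide activation efficacy, per-gene
binding strength) is retained so that downstream statistics can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenDesign",
    "SimulationParams",
    "Population",
    "CountTable",
    "SimulatedScreen",
    "EmptySelectionError",
    "build_library",
    "simulate_selection_round",
    "simulate_sequencing",
    "simulate_screen",
]

CATEGORY_GENE = "gene"
CATEGORY_SAFE = "safe"
CATEGORY_NONTARGETING = "nontargeting"
CONTROL_CATEGORIES = (CATEGORY_SAFE, CATEGORY_NONTARGETING)
LIBRARY_LABELS = ("TM1", "TM2+", "mini")


class EmptySelectionError(RuntimeError):
    """Raised when a selection round captures zero cells."""


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a pooled CRISPRa library and its ground-truth receptors.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique identifiers of the targeted genes.
    guides_per_gene : int
        Number of sgRNAs per target (10 in the customized cell surface
        libraries).
    n_controls : int
        Number of control sgRNAs targeting genomic locations without
        annotated function ("safe" controls).
    true_receptors : mapping gene_id -> float
        Binding strength in [0, 1] for genes whose product binds the bait;
        genes absent from the mapping have strength 0.
    library_label : str
        One of ``TM1``, ``TM2+`` or ``mini``.
    """

    gene_ids: tuple[str, ...]
    guides_per_gene: int = 10
    n_controls: int = 100
    true_receptors: Mapping[str, float] = field(default_factory=dict)
    library_label: str = "mini"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        for gene, strength in self.true_receptors.items():
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"binding strength for {gene} outside [0, 1]")
            if gene not in self.gene_ids:
                raise ValueError(f"true receptor {gene} not among gene_ids")
        if self.library_label not in LIBRARY_LABELS:
            raise ValueError(f"library_label must be one of {LIBRARY_LABELS}")

    @property
    def n_gene_guides(self) -> int:
        return len(self.gene_ids) * self.guides_per_gene

    @property
    def n_guides(self) -> int:
        return self.n_gene_guides + self.n_controls


@dataclass(frozen=True)
class SimulationParams:
    """Tunable parameters of the screen simulation.

    coverage
        Cells per guide in the naive library (the protocol maintains at
        least 1000x coverage per sgRNA).
    n_rounds
        Consecutive rounds of positive magnetic-bead selection (up to 3).
    capture_base
        Background per-cell bead-capture probability (nonspecific carryover).
    capture_max
        Capture probability of a cell whose guide has efficacy 1 targeting a
        strength-1 receptor; bead-ligand avidity is folded into this number.
    efficacy_dispersion
        Concentration kappa of the Beta(kappa/2, kappa/2) per-guide activation
        efficacy distribution (mean 0.5); 0 selects the degenerate setting in
        which every gene-targeting guide has efficacy exactly 1.
    sequencing_depth
        Reads per sequenced sample.
    abundance_cv
        Coefficient of variation of the initial (log-normal) per-guide cell
        abundance.
    seed
        Seed for all randomness in :func:`simulate_screen`.
    """

    coverage: int = 1000
    n_rounds: int = 3
    capture_base: float = 0.005
    capture_max: float = 0.5
    efficacy_dispersion: float = 4.0
    sequencing_depth: int = 1_000_000
    abundance_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.capture_base <= self.capture_max <= 1.0:
            raise ValueError("need 0 <= capture_base <= capture_max <= 1")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.efficacy_dispersion < 0:
            raise ValueError("efficacy_dispersion must be >= 0")
        if self.abundance_cv < 0:
            raise ValueError("abundance_cv must be >= 0")


@dataclass
class Population:
    """Cell-population state: per-guide cell counts plus ground truth."""

    guide_ids: np.ndarray  # str array, one entry per guide
    gene_ids: np.ndarray  # target gene or control label per guide
    category: np.ndarray  # gene / safe
    cells: np.ndarray  # int64 cell counts
    efficacy: np.ndarray  # activation efficacy in [0, 1], 0 for controls
    strength: np.ndarray  # binding strength of the guide's target gene

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    def frequencies(self) -> np.ndarray:
        total = self.cells.sum()
        if total == 0:
            raise EmptySelectionError("population contains no cells")
        return self.cells / total

    def copy(self) -> "Population":
        return Population(
            self.guide_ids,
            self.gene_ids,
            self.category,
            self.cells.copy(),
            self.efficacy,
            self.strength,
        )


@dataclass
class CountTable:
    """Guide x sample matrix of read counts with per-sample round metadata."""

    counts: pd.DataFrame  # index guide_id, one int column per sample
    guides: pd.DataFrame  # guide_id, gene_id, category
    sample_rounds: dict[str, int]  # sample name -> selection round (naive=0)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.sample_rounds)
        if missing:
            raise ValueError(f"samples missing round metadata: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.guides.set_index("guide_id").loc[self.counts.index].reset_index()
        for sample in self.counts.columns:
            out[sample] = self.counts[sample].to_numpy()
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        meta_cols = ["guide_id", "gene_id", "category"]
        sample_cols = [c for c in frame.columns if c not in meta_cols]
        guides = frame[meta_cols].copy()
        counts = frame.set_index("guide_id")[sample_cols].astype(np.int64)
        rounds = {s: _round_from_name(s) for s in sample_cols}
        return cls(counts=counts, guides=guides, sample_rounds=rounds)

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def _round_from_name(sample: str) -> int:
    if sample == "naive":
        return 0
    if sample.startswith("R") and sample[1:].isdigit():
        return int(sample[1:])
    raise ValueError(f"cannot infer selection round from sample name {sample!r}")


@dataclass
class SimulatedScreen:
    """A simulated screen: design, parameters, counts and ground truth."""

    design: ScreenDesign
    params: SimulationParams
    counts: CountTable
    truth: dict

    def write(self, counts_path, truth_path) -> None:
        self.counts.write_tsv(counts_path)
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _guide_layout(design: ScreenDesign):
    guide_ids, gene_ids, category = [], [], []
    for gene in design.gene_ids:
        for k in range(design.guides_per_gene):
            guide_ids.append(f"{gene}_sg{k + 1}")
            gene_ids.append(gene)
            category.append(CATEGORY_GENE)
    for k in range(design.n_controls):
        guide_ids.append(f"CTRL_sg{k + 1}")
        gene_ids.append("control")
        category.append(CATEGORY_SAFE)
    return (
        np.array(guide_ids, dtype=object),
        np.array(gene_ids, dtype=object),
        np.array(category, dtype=object),
    )


def build_library(
    design: ScreenDesign,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> Population:
    """Assemble the naive library cell population.

    Initial per-guide abundances are log-normal with mean ``coverage`` and
    coefficient of variation ``abundance_cv`` (lentiviral pools are
    right-skewed); each gene-targeting guide receives an activation efficacy
    drawn from Beta(kappa/2, kappa/2); control guides have efficacy 0.
    """
    if design.n_guides == 0:
        raise ValueError("design contains no guides")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    guide_ids, gene_ids, category = _guide_layout(design)
    n = len(guide_ids)

    if params.abundance_cv == 0:
        cells = np.full(n, params.coverage, dtype=np.int64)
    else:
        sigma2 = np.log1p(params.abundance_cv**2)
        mu = np.log(params.coverage) - sigma2 / 2.0
        cells = np.rint(rng.lognormal(mu, np.sqrt(sigma2), size=n)).astype(np.int64)
        cells = np.maximum(cells, 0)

    efficacy = np.zeros(n)
    is_gene = category == CATEGORY_GENE
    if params.efficacy_dispersion == 0:
        efficacy[is_gene] = 1.0
    else:
        a = params.efficacy_dispersion / 2.0
        efficacy[is_gene] = rng.beta(a, a, size=int(is_gene.sum()))

    strength = np.array(
        [design.true_receptors.get(g, 0.0) for g in gene_ids], dtype=float
    )
    strength[~is_gene] = 0.0
    return Population(guide_ids, gene_ids, category, cells, efficacy, strength)


def capture_probabilities(pop: Population, params: SimulationParams) -> np.ndarray:
    """Per-cell bead-capture probability for each guide."""
    return params.capture_base + (
        params.capture_max - params.capture_base
    ) * pop.efficacy * pop.strength


def simulate_selection_round(
    pop: Population,
    design: ScreenDesign,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Population:
    """One round of positive magnetic-bead selection followed by expansion.

    Each cell is captured independently with probability
    ``capture_base + (capture_max - capture_base) * efficacy * strength``;
    captured cells are resampled with replacement back to the pre-selection
    population size, modeling expansion in culture.
    """
    if pop.n_cells == 0:
        raise EmptySelectionError("population contains no cells")
    p = capture_probabilities(pop, params)
    captured = rng.binomial(pop.cells, p)
    total_captured = captured.sum()
    if total_captured == 0:
        raise EmptySelectionError(
            "selection captured zero cells; raise capture_base or coverage"
        )
    expanded = rng.multinomial(pop.n_cells, captured / total_captured)
    out = pop.copy()
    out.cells = expanded.astype(np.int64)
    return out


def simulate_sequencing(
    pop: Population, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample read counts as a multinomial of size ``depth`` over guide
    frequencies; the column sums to ``depth`` exactly."""
    if depth < 1:
        raise ValueError("sequencing depth must be >= 1")
    return rng.multinomial(int(depth), pop.frequencies()).astype(np.int64)


def simulate_screen(
    design: ScreenDesign, params: SimulationParams
) -> SimulatedScreen:
    """Run the full screen: library build, ``n_rounds`` of selection, and
    sequencing of the naive population and every round.

    Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    pop = build_library(design, params, rng)

    columns: dict[str, np.ndarray] = {}
    rounds: dict[str, int] = {}
    columns["naive"] = simulate_sequencing(pop, params.sequencing_depth, rng)
    rounds["naive"] = 0
    for r in range(1, params.n_rounds + 1):
        pop = simulate_selection_round(pop, design, params, rng)
        name = f"R{r}"
        columns[name] = simulate_sequencing(pop, params.sequencing_depth, rng)
        rounds[name] = r

    counts = pd.DataFrame(columns, index=pd.Index(pop.guide_ids, name="guide_id"))
    guides = pd.DataFrame(
        {
            "guide_id": pop.guide_ids,
            "gene_id": pop.gene_ids,
            "category": pop.category,
        }
    )
    table = CountTable(counts=counts, guides=guides, sample_rounds=rounds)
    truth = {
        "seed": params.seed,
        "efficacy": {g: float(e) for g, e in zip(pop.guide_ids, pop.efficacy)},
        "strength": {g: float(s) for g, s in design.true_receptors.items()},
        "params": dataclasses.asdict(params),
    }
    return SimulatedScreen(design=design, params=params, counts=table, truth=truth)


def expected_frequency_after_selection(
    freq: np.ndarray | Sequence[float], capture: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Deterministic one-step frequency map under selection.

    ``f'_i = f_i p_i / sum_j f_j p_j`` for pre-selection frequencies ``f``
    and capture probabilities ``p``.  Exposed for planning scenarios; the
    stochastic simulator has this map as its expectation.
    """
    f = np.asarray(freq, dtype=float)
    p = np.asarray(capture, dtype=float)
    w = f * p
    return w / w.sum()
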