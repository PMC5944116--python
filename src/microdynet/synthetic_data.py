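"""Diet-structured compositional time series with a known interaction matrix.

The generator emulates the layout of the feeding experiment: seven colonies
drawn from one stock (shared day-0 state), six dietary substrates plus a
starved colony, samples on a fixed day schedule with replicate individuals
per time point, and a community of ~56 taxonomic orders in which a handful of
low-abundance "driver" taxa carry most of the interactions.

Dynamics are a multiplicative log-linear update on the simplex,

    x(t+1) = normalise( x(t) * exp(A_taxa' x(t) + A_sub' s + eps) ),

where the rows of the signed matrix ``A`` are input taxa then substrates,
``s`` is the 0/1 substrate presence vector and ``eps`` is i.i.d. Gaussian
noise on the log-abundance scale. The matrix ``A`` is the ground truth
against which sensitivity-derived interaction networks can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .taxon_tables import (
    STARVED_LABEL,
    DietSeries,
    OtuTable,
    TaxonProfile,
    substrate_flags_for,
)

SIMPLEX_ATOL = 1e-9

#: Sampling schedule of the feeding experiment (days after arrival).
DEFAULT_SAMPLING_DAYS = (0, 1, 2, 3, 7, 14, 21, 28, 35, 42, 49)

#: The six dietary substrates; the starved colony has no substrate.
DEFAULT_SUBSTRATES = ("mulch", "spruce", "oak", "maple", "birch", "cardboard")


@dataclass
class SimConfig:
    """Configuration for one simulated feeding experiment.

    ``interaction_matrix`` has shape (n_taxa + n_substrates, n_taxa): row i,
    column j is the per-step effect of input node i on taxon j.
    ``driver_indices`` marks taxa intended as low-abundance drivers (used for
    reporting and for constructing default matrices, not by the update rule).
    ``series_truncation`` optionally maps a diet label to its last sampled
    day, mirroring colonies that ran out of termites early.
    """

    n_taxa: int
    n_substrates: int
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    replicates_per_timepoint: int = 3
    interaction_matrix: np.ndarray | None = None
    baseline_abundances: np.ndarray | None = None
    noise_sd: float = 0.0
    process_noise_sd: float | None = None
    driver_indices: tuple[int, ...] = ()
    substrate_names: tuple[str, ...] | None = None
    taxon_names: tuple[str, ...] | None = None
    series_truncation: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_substrates < 0:
            raise ValueError("need at least one taxon and nonnegative substrates")
        if len(self.sampling_days) < 2:
            raise ValueError("need at least 2 sampling days")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.process_noise_sd is None:
            self.process_noise_sd = self.noise_sd
        if self.process_noise_sd < 0:
            raise ValueError("process_noise_sd must be nonnegative")
        if self.replicates_per_timepoint < 1:
            raise ValueError("replicates_per_timepoint must be >= 1")
        if self.substrate_names is None:
            self.substrate_names = tuple(
                DEFAULT_SUBSTRATES[: self.n_substrates]
                if self.n_substrates <= len(DEFAULT_SUBSTRATES)
                else [f"substrate_{k:02d}" for k in range(self.n_substrates)]
            )
        if len(self.substrate_names) != self.n_substrates:
            raise ValueError("substrate_names length must equal n_substrates")
        if self.taxon_names is None:
            width = len(str(self.n_taxa))
            self.taxon_names = tuple(
                f"order_{i + 1:0{width}d}" for i in range(self.n_taxa)
            )
        if len(self.taxon_names) != self.n_taxa:
            raise ValueError("taxon_names length must equal n_taxa")
        if self.interaction_matrix is None:
            self.interaction_matrix = np.zeros(
                (self.n_taxa + self.n_substrates, self.n_taxa)
            )
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=float)
        if self.interaction_matrix.shape != (
            self.n_taxa + self.n_substrates,
            self.n_taxa,
        ):
            raise ValueError(
                "interaction_matrix must be (n_taxa+n_substrates) x n_taxa"
            )
        if self.baseline_abundances is None:
            self.baseline_abundances = np.full(self.n_taxa, 1.0 / self.n_taxa)
        self.baseline_abundances = np.asarray(self.baseline_abundances, float)
        if (self.baseline_abundances < 0).any() or abs(
            self.baseline_abundances.sum() - 1.0
        ) > SIMPLEX_ATOL:
            raise ValueError("baseline_abundances must lie on the simplex")
        if not set(self.driver_indices) <= set(range(self.n_taxa)):
            raise ValueError("driver_indices must be valid taxon indices")

    @property
    def diet_labels(self) -> tuple[str, ...]:
        return tuple(self.substrate_names) + (STARVED_LABEL,)


@dataclass
class SimulatedDataset:
    """Simulated series per diet plus the ground-truth interaction matrix."""

    diet_series: list[DietSeries]
    replicate_profiles: list[TaxonProfile]
    true_interactions: np.ndarray
    config: SimConfig
    seed: int


def _normalise(x: np.ndarray) -> np.ndarray:
    s = x.sum()
    if s <= 0:
        raise ValueError("cannot normalise a non-positive composition")
    return x / s


def simulate_dynamics(config: SimConfig) -> SimulatedDataset:
    """Run the multiplicative log-linear dynamics for every diet.

    The latent state trajectory per diet starts from the shared baseline and
    advances one step per sampling day (day spacing is recorded but, like the
    downstream network, the dynamics are index-based). Replicate samples are
    the latent state with independent log-normal noise, renormalised. The
    returned ``diet_series`` hold the latent (replicate-aggregated) states;
    ``replicate_profiles`` hold the individual noisy replicates.
    """
    rng = np.random.default_rng(config.seed)
    T, S = config.n_taxa, config.n_substrates
    A_taxa = config.interaction_matrix[:T]
    A_sub = config.interaction_matrix[T:]
    series_list: list[DietSeries] = []
    replicates: list[TaxonProfile] = []
    for diet in config.diet_labels:
        flags = substrate_flags_for(diet, config.substrate_names)
        last_day = config.series_truncation.get(diet)
        days = [
            d for d in config.sampling_days
            if last_day is None or d <= last_day
        ]
        x = config.baseline_abundances.copy()
        latent: list[np.ndarray] = [x]
        for _ in days[1:]:
            drift = A_taxa.T @ x + A_sub.T @ flags
            eps = (rng.normal(0.0, config.process_noise_sd, size=T)
                   if config.process_noise_sd else 0.0)
            x = _normalise(x * np.exp(drift + eps))
            latent.append(x)
        profiles = []
        for day, state in zip(days, latent):
            profiles.append(
                TaxonProfile(f"{diet}_d{day}", diet, day, state,
                             config.taxon_names)
            )
            for r in range(config.replicates_per_timepoint):
                if config.noise_sd:
                    noisy = _normalise(
                        state * np.exp(rng.normal(0, config.noise_sd, size=T))
                    )
                else:
                    noisy = state
                replicates.append(
                    TaxonProfile(f"{diet}_d{day}_r{r + 1}", diet, day, noisy,
                                 config.taxon_names)
                )
        series_list.append(
            DietSeries(diet, config.substrate_names, flags, profiles)
        )
    return SimulatedDataset(
        diet_series=series_list,
        replicate_profiles=replicates,
        true_interactions=config.interaction_matrix.copy(),
        config=config,
        seed=config.seed,
    )


def simulated_to_counts(
    dataset: SimulatedDataset,
    depth: int,
    otus_per_taxon: int = 1,
    seed: int = 0,
) -> OtuTable:
    """Draw multinomial OTU counts at a fixed depth from replicate profiles.

    Each taxon's probability mass is split across ``otus_per_taxon`` OTUs
    (randomly, but reproducibly, within the taxon), and taxonomy strings
    encode the taxon order so order-level collapse inverts the split.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if otus_per_taxon < 1:
        raise ValueError("otus_per_taxon must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = dataset.config
    T = cfg.n_taxa
    # fixed within-taxon split of mass across that taxon's OTUs
    splits = rng.dirichlet(np.ones(otus_per_taxon), size=T)  # (T, K)
    otu_ids = [
        f"OTU_{i + 1:04d}_{k + 1}" for i in range(T) for k in range(otus_per_taxon)
    ]
    taxonomy = {
        f"OTU_{i + 1:04d}_{k + 1}": (
            f"k__Bacteria; p__SimPhylum; c__SimClass; "
            f"o__{cfg.taxon_names[i]}; f__; g__; s__"
        )
        for i in range(T)
        for k in range(otus_per_taxon)
    }
    sample_ids = [p.sample_id for p in dataset.replicate_profiles]
    counts = np.zeros((T * otus_per_taxon, len(sample_ids)), dtype=np.int64)
    for j, prof in enumerate(dataset.replicate_profiles):
        if prof.abundances.sum() <= 0:
            raise ValueError(f"sample {prof.sample_id} has zero total abundance")
        p = (prof.abundances[:, None] * splits).ravel()
        counts[:, j] = rng.multinomial(depth, p / p.sum())
    metadata = {
        p.sample_id: (p.diet, p.day) for p in dataset.replicate_profiles
    }
    return OtuTable(sample_ids, otu_ids, counts, taxonomy, metadata)


# ---------------------------------------------------------------------------
# Study-conditions defaults
# ---------------------------------------------------------------------------


def default_interaction_matrix(
    n_taxa: int,
    n_substrates: int,
    driver_indices: Sequence[int],
    n_edges_per_driver: int = 4,
    edge_scale: float = 1.5,
    substrate_edge_scale: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """A sparse signed matrix dominated by a few driver taxa.

    Each driver row gets ``n_edges_per_driver`` strong signed edges onto
    other taxa; each substrate row gets two moderate edges. Everything else
    is zero.
    """
    rng = np.random.default_rng(seed)
    A = np.zeros((n_taxa + n_substrates, n_taxa))
    for i in driver_indices:
        targets = rng.choice(
            [j for j in range(n_taxa) if j != i],
            size=min(n_edges_per_driver, n_taxa - 1),
            replace=False,
        )
        for j in targets:
            A[i, j] = rng.choice([-1.0, 1.0]) * edge_scale * rng.uniform(0.8, 1.2)
    for k in range(n_substrates):
        targets = rng.choice(n_taxa, size=min(2, n_taxa), replace=False)
        for j in targets:
            A[n_taxa + k, j] = (
                rng.choice([-1.0, 1.0]) * substrate_edge_scale * rng.uniform(0.8, 1.2)
            )
    return A


def study_conditions_config(
    seed: int = 0,
    n_taxa: int = 56,
    n_substrates: int = 6,
    noise_sd: float = 0.15,
    process_noise_sd: float = 0.02,
    replicates_per_timepoint: int = 3,
) -> SimConfig:
    """The default simulated experiment: 56 orders, 6 substrates + starved.

    The baseline community has two dominant orders (>10%), a mid-abundance
    order at a few percent, and a long tail below 1%; five taxa from the tail
    (<1% mean abundance) are designated drivers and carry the strong
    interactions. The starved colony is truncated at day 21 and the oak
    colony at day 28, matching the experimental design being emulated.
    """
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_taxa, 0.5)) * 0.2 + 1e-4
    # two dominant orders and one mid-abundance order on top of the tail
    base[0] += 0.35
    base[1] += 0.25
    base[2] += 0.06
    base = base / base.sum()
    tail = [i for i in range(3, n_taxa) if base[i] < 0.01]
    n_drivers = min(5, len(tail))
    drivers = tuple(
        int(i) for i in rng.choice(tail, size=n_drivers, replace=False)
    )
    A = default_interaction_matrix(
        n_taxa, n_substrates, drivers, seed=seed + 1
    )
    # the first substrate is the colonies' original food: the baseline is its
    # steady state, so staying on it exerts no additional drift (control diet)
    if n_substrates >= 1:
        A[n_taxa, :] = 0.0
    # make the baseline a fixed point of the taxon-taxon block, so only a
    # dietary change (or noise) moves the community off its day-0 state
    offset = A[:n_taxa].T @ base
    A[:n_taxa] -= np.outer(base, offset) / float(base @ base)
    truncation = {}
    if n_substrates >= 3:
        truncation = {STARVED_LABEL: 21, DEFAULT_SUBSTRATES[2]: 28}
    return SimConfig(
        n_taxa=n_taxa,
        n_substrates=n_substrates,
        sampling_days=DEFAULT_SAMPLING_DAYS,
        replicates_per_timepoint=replicates_per_timepoint,
        interaction_matrix=A,
        baseline_abundances=base,
        noise_sd=noise_sd,
        process_noise_sd=process_noise_sd,
        driver_indices=drivers,
        series_truncation=truncation,
        seed=seed,
    )


def sign_recovery_benchmark_config(
    seed: int = 0,
    n_taxa: int = 8,
    n_substrates: int = 6,
    n_days: int = 30,
    edge_magnitude: float = 3.0,
    substrate_magnitude: float = 1.0,
) -> SimConfig:
    """Noise-free benchmark for recovering interaction signs.

    Three strong taxon-taxon edges leave two driver taxa; every substrate
    also acts on the drivers so the diets trace diverging trajectories —
    without that cross-diet variation a driver's abundance is a pure
    function of time and the causal direction of its effects is not
    identifiable from the series. Strong edges must also outweigh the
    compositional closure term (elasticity ~ x_i * (A_ij - 1)), hence the
    magnitude-3 default.
    """
    rng = np.random.default_rng(seed)
    A = np.zeros((n_taxa + n_substrates, n_taxa))
    strong = [(0, 3), (0, 5), (1, 6)]
    for i, j in strong:
        A[i, j] = rng.choice([-1.0, 1.0]) * edge_magnitude
    for k in range(n_substrates):
        A[n_taxa + k, 0] = rng.choice([-1.0, 1.0]) * substrate_magnitude
        A[n_taxa + k, 1] = rng.choice([-1.0, 1.0]) * substrate_magnitude
    base = rng.dirichlet(np.ones(n_taxa) * 6)
    return SimConfig(
        n_taxa=n_taxa,
        n_substrates=n_substrates,
        sampling_days=tuple(range(n_days)),
        replicates_per_timepoint=1,
        interaction_matrix=A,
        baseline_abundances=base,
        noise_sd=0.0,
        driver_indices=(0, 1),
        seed=seed,
    )


def learnability_config(
    seed: int = 0,
    n_taxa: int = 5,
    n_substrates: int = 2,
    n_days: int = 20,
    interaction_scale: float = 0.15,
) -> SimConfig:
    """Small noise-free deterministic system the network should learn well.

    Interactions are mild so abundances stay well away from zero over the
    series; the mean absolute percentage error of a converged network is
    then limited by the training error threshold, not by vanishing
    denominators.
    """
    rng = np.random.default_rng(seed)
    A = default_interaction_matrix(
        n_taxa, n_substrates, driver_indices=(0, 1),
        n_edges_per_driver=2, seed=seed,
    ) * interaction_scale
    base = rng.dirichlet(np.ones(n_taxa) * 8)
    return SimConfig(
        n_taxa=n_taxa,
        n_substrates=n_substrates,
        sampling_days=tuple(range(n_days)),
        replicates_per_timepoint=1,
        interaction_matrix=A,
        baseline_abundances=base,
        noise_sd=0.0,
        driver_indices=(0, 1),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> list[Path]:
    """Write per-diet series CSVs and the true interaction matrix (TSV)."""
    from .taxon_tables import write_diet_series_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for series in dataset.diet_series:
        path = out_dir / f"series_{series.diet}.csv"
        write_diet_series_csv(series, path)
        written.append(path)
    cfg = dataset.config
    rows = list(cfg.taxon_names) + list(cfg.substrate_names)
    path = out_dir / "true_interactions.tsv"
    with open(path, "w") as fh:
        fh.write("source\t" + "\t".join(cfg.taxon_names) + "\n")
        for name, row in zip(rows, dataset.true_interactions):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    written.append(path)
    return written
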