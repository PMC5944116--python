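"""Input-perturbation sensitivity analysis and interaction-network extraction.

Each input node of a trained dynamics network is varied independently
(by default 100 times, uniformly within +/-5% of its reference value) while
all other inputs are held fixed. For every perturbation the relative change
of each output is divided by the relative change of the input,

    relative change = ((new_out - out) / out) / ((new_in - in) / in) * 100%,

and the average over perturbations fills one row of the change matrix:
rows are input nodes (taxa then substrates), columns are output taxa, and
each entry is an elasticity expressed in percent. Substrate inputs are
binary, so they are toggled (0 <-> 1) and the input's relative change is
defined as +/-100%, leaving the output's sign-adjusted relative change.

Entries whose absolute value exceeds mean(|M|) + 3 * sd(|M|) form the signed
interaction network: positive entries are direct correlations, negative ones
inverse; edges are classified as outbound from their source row and inbound
at their target column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .dynamics_ann import (
    AnnModel,
    NetworkTopology,
    TrainingConfig,
    forward,
    forward_batch,
    init_model,
    make_training_pairs,
    train,
)
from .synthetic_data import SimulatedDataset
from .taxon_tables import CorePartition

logger = logging.getLogger(__name__)


@dataclass
class PerturbationConfig:
    """How each input node is varied around the reference state."""

    reference_input: np.ndarray
    relative_range: float = 0.05
    n_perturbations: int = 100
    grid_mode: bool = False
    epsilon_zero: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference_input = np.asarray(self.reference_input, dtype=float)
        if not 0 < self.relative_range < 1:
            raise ValueError("relative_range must be in (0, 1)")
        if self.n_perturbations < 2:
            raise ValueError("n_perturbations must be >= 2")
        if self.epsilon_zero <= 0:
            raise ValueError("epsilon_zero must be positive")


@dataclass
class ChangeMatrix:
    """(taxa + substrates) x taxa matrix of average relative changes (%)."""

    row_names: tuple[str, ...]
    col_names: tuple[str, ...]
    values: np.ndarray
    flagged_rows: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError("values shape must match row/col names")
        if not np.isfinite(self.values).all():
            raise ValueError("change matrix entries must be finite")


@dataclass
class InteractionNetwork:
    threshold: float
    edges: list[tuple[str, str, float, str]]  # (source, target, value, sign)
    outbound_count: dict[str, int]
    inbound_count: dict[str, int]
    core_flags: dict[str, bool]


def relative_change(
    original_output: float,
    new_output: float,
    original_input: float,
    new_input: float,
    epsilon_zero: float = 1e-6,
) -> float:
    """Output relative change divided by input relative change, in percent.

    Zero outputs/inputs are floored at ``epsilon_zero`` so the ratio stays
    finite; an unchanged input leaves the ratio undefined and raises.
    """
    if new_input == original_input:
        raise ValueError("relative change undefined for an unchanged input")
    out0 = max(abs(original_output), epsilon_zero) * (
        -1 if original_output < 0 else 1
    )
    in0 = max(abs(original_input), epsilon_zero) * (
        -1 if original_input < 0 else 1
    )
    out_rel = (new_output - original_output) / out0
    in_rel = (new_input - original_input) / in0
    return float(out_rel / in_rel * 100.0)


def _perturbed_values(
    x: float, config: PerturbationConfig, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = x * (1 - config.relative_range), x * (1 + config.relative_range)
    if config.grid_mode:
        # symmetric grid excluding the reference value itself
        half = config.n_perturbations // 2
        left = np.linspace(lo, x, half + 1)[:-1]
        right = np.linspace(x, hi, config.n_perturbations - half + 1)[1:]
        return np.concatenate([left, right])
    vals = rng.uniform(lo, hi, size=config.n_perturbations)
    while (vals == x).any():  # pragma: no cover - probability zero
        vals[vals == x] = rng.uniform(lo, hi, size=(vals == x).sum())
    return vals


def sensitivity_matrix(
    model: AnnModel, config: PerturbationConfig
) -> ChangeMatrix:
    """Average relative change of every output per perturbed input node.

    Taxon inputs are perturbed within the relative range (a zero reference
    abundance is floored at ``epsilon_zero`` and the row flagged); substrate
    inputs are toggled between presence and absence.
    """
    topo = model.topology
    ref = np.asarray(config.reference_input, dtype=float)
    if ref.shape != (topo.n_input,):
        raise ValueError(
            f"reference_input must have length {topo.n_input}, got {ref.shape}"
        )
    rng = np.random.default_rng(config.seed)
    y0 = forward(model, ref)
    y0_floor = np.maximum(y0, config.epsilon_zero)
    row_names = model.taxon_order_names + model.substrate_names
    values = np.zeros((topo.n_input, topo.n_taxa))
    flagged: set[str] = set()
    for i in range(topo.n_taxa):
        x = ref[i]
        if x == 0.0:
            x = config.epsilon_zero
            flagged.add(row_names[i])
        vals = _perturbed_values(x, config, rng)
        batch = np.tile(ref, (vals.size, 1))
        batch[:, i] = vals
        Y = forward_batch(model, batch)
        in_rel = (vals - ref[i]) / x  # floored input in the denominator
        out_rel = (Y - y0) / y0_floor
        values[i] = (out_rel / in_rel[:, None]).mean(axis=0) * 100.0
    for k in range(topo.n_substrates):
        j = topo.n_taxa + k
        new_val = 1.0 - ref[j]  # toggle presence/absence
        x_new = ref.copy()
        x_new[j] = new_val
        y = forward(model, x_new)
        in_rel = 1.0 if new_val > ref[j] else -1.0  # +/-100% by convention
        values[j] = ((y - y0) / y0_floor) / in_rel * 100.0
    return ChangeMatrix(
        row_names=row_names,
        col_names=model.taxon_order_names,
        values=values,
        flagged_rows=flagged,
    )


def significant_network(
    matrix: ChangeMatrix,
    core: CorePartition | None = None,
    sd_multiplier: float = 3.0,
    abs_mean: bool = True,
) -> InteractionNetwork:
    """Threshold the change matrix at mean(|M|) + k * sd(|M|).

    ``abs_mean=True`` (default) reads the "absolute average" as the mean of
    absolute values; the alternative |mean(M)| is available. Edges require a
    strictly greater absolute value, so a constant matrix yields none.
    Substrate rows can only be sources (the network has no substrate
    outputs).
    """
    absM = np.abs(matrix.values)
    centre = absM.mean() if abs_mean else abs(matrix.values.mean())
    spread = absM.std()
    threshold = float(centre + sd_multiplier * spread)
    logger.info(
        "significance threshold %.4g (centre %.4g, sd %.4g, k=%g, abs_mean=%s)",
        threshold, centre, spread, sd_multiplier, abs_mean,
    )
    if spread == 0:
        logger.warning("constant change matrix: no edge can pass the threshold")
    edges = []
    outbound: dict[str, int] = {}
    inbound: dict[str, int] = {}
    for i, src in enumerate(matrix.row_names):
        for j, tgt in enumerate(matrix.col_names):
            v = matrix.values[i, j]
            if abs(v) > threshold:
                sign = "direct" if v > 0 else "inverse"
                edges.append((src, tgt, float(v), sign))
                outbound[src] = outbound.get(src, 0) + 1
                inbound[tgt] = inbound.get(tgt, 0) + 1
    nodes = set(matrix.row_names) | set(matrix.col_names)
    core_taxa = core.core_taxa if core is not None else set()
    return InteractionNetwork(
        threshold=threshold,
        edges=edges,
        outbound_count={n: outbound.get(n, 0) for n in nodes},
        inbound_count={n: inbound.get(n, 0) for n in nodes},
        core_flags={n: n in core_taxa for n in nodes},
    )


def recover_interactions_benchmark(
    dataset: SimulatedDataset,
    topology: NetworkTopology,
    train_config: TrainingConfig,
    relative_range: float = 0.05,
    n_perturbations: int = 100,
    seed: int = 0,
    strong_quantile: float = 0.9,
) -> float | None:
    """Sign agreement between recovered and true strong interactions.

    Trains the network on the simulated series, computes the change matrix at
    the day-0 state (no substrate), and reports the fraction of true strong
    taxon-taxon edges (|A| above its ``strong_quantile`` over nonzero
    entries) whose recovered sign matches. Returns ``None`` when the truth
    has no strong edges.
    """
    cfg = dataset.config
    A = dataset.true_interactions[: cfg.n_taxa]  # taxon -> taxon block
    nonzero = np.abs(A[A != 0])
    if nonzero.size == 0:
        return None
    cutoff = np.quantile(nonzero, strong_quantile)
    strong = np.argwhere(np.abs(A) >= cutoff)
    if strong.size == 0:
        return None
    pairs = make_training_pairs(dataset.diet_series)
    model = init_model(
        topology, cfg.taxon_names, cfg.substrate_names, train_config
    )
    train(model, pairs, train_config)
    ref = np.concatenate(
        [cfg.baseline_abundances, np.zeros(cfg.n_substrates)]
    )
    pconf = PerturbationConfig(
        reference_input=ref,
        relative_range=relative_range,
        n_perturbations=n_perturbations,
        seed=seed,
    )
    M = sensitivity_matrix(model, pconf).values
    agree = sum(
        1 for i, j in strong if np.sign(M[i, j]) == np.sign(A[i, j])
    )
    return agree / len(strong)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_change_matrix(matrix: ChangeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("input_node\t" + "\t".join(matrix.col_names) + "\n")
        for name, row in zip(matrix.row_names, matrix.values):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_change_matrix(path: str | Path) -> ChangeMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    cols = tuple(lines[0].split("\t")[1:])
    rows, vals = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows.append(parts[0])
        vals.append([float(v) for v in parts[1:]])
    return ChangeMatrix(tuple(rows), cols, np.array(vals))


def to_networkx(network: InteractionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for node, is_core in network.core_flags.items():
        g.add_node(
            node,
            core=bool(is_core),
            outbound=network.outbound_count.get(node, 0),
            inbound=network.inbound_count.get(node, 0),
        )
    for src, tgt, value, sign in network.edges:
        g.add_edge(src, tgt, value=value, sign=sign)
    return g


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tvalue\tsign\tsource_is_core\n")
        for src, tgt, value, sign in network.edges:
            fh.write(
                f"{src}\t{tgt}\t{value:.10g}\t{sign}\t"
                f"{network.core_flags.get(src, False)}\n"
            )


def write_graphml(network: InteractionNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(network), path)


def plot_heatmap(matrix: ChangeMatrix, path: str | Path) -> None:
    """Diverging heatmap of the change matrix (blue direct, red inverse)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.abs(matrix.values).max() or 1.0
    fig, ax = plt.subplots(
        figsize=(max(6, len(matrix.col_names) * 0.25),
                 max(5, len(matrix.row_names) * 0.22))
    )
    im = ax.imshow(
        matrix.values, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto"
    )
    ax.set_xticks(range(len(matrix.col_names)))
    ax.set_xticklabels(matrix.col_names, rotation=90, fontsize=5)
    ax.set_yticks(range(len(matrix.row_names)))
    ax.set_yticklabels(matrix.row_names, fontsize=5)
    ax.set_xlabel("affected taxon (output node)")
    ax.set_ylabel("perturbed taxon / substrate (input node)")
    fig.colorbar(im, ax=ax, label="average relative change (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
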