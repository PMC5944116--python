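"""Community statistics: Shannon H', equitability, Bray-Curtis, PCoA, PERMANOVA.

Shannon diversity is computed in bits (base-2 logs) with equitability
E_H = H' / log2(S_obs), so a perfectly even community scores 1. Bray-Curtis
dissimilarity d(u, v) = sum|u_i - v_i| / sum(u_i + v_i) feeds both the
classical principal-coordinates ordination (Gower double centering +
eigendecomposition) and a permutation-based PERMANOVA with the add-one
p-value convention p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .taxon_tables import OtuTable, TaxonProfile


@dataclass
class DiversityResult:
    sample_id: str
    shannon_H: float
    equitability_EH: float
    observed_richness: int


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal and sample labels."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_labels: list[str]
    sample_size: int
    n_groups: int


def _proportions(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if (vec < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("need at least one positive entry")
    return vec[vec > 0] / total


def shannon(abundance_or_counts: Sequence[float], base: float = 2.0) -> float:
    """Shannon index H' = -sum p_i log(p_i), base-2 by default (bits).

    Scale-invariant: counts and proportions give the same value.
    """
    p = _proportions(np.asarray(abundance_or_counts))
    return float(-(p * (np.log(p) / np.log(base))).sum())


def equitability(abundance_or_counts: Sequence[float], base: float = 2.0) -> float:
    """E_H = H' / log(S_obs); 1 means perfectly even, 0 at richness one."""
    p = _proportions(np.asarray(abundance_or_counts))
    s_obs = p.size
    if s_obs == 1:
        return 0.0
    return float(shannon(p, base=base) / (np.log(s_obs) / np.log(base)))


def alpha_diversity(
    profiles: Sequence[TaxonProfile], base: float = 2.0
) -> list[DiversityResult]:
    results = []
    for prof in profiles:
        s_obs = int((prof.abundances > 0).sum())
        results.append(
            DiversityResult(
                sample_id=prof.sample_id,
                shannon_H=shannon(prof.abundances, base=base),
                equitability_EH=equitability(prof.abundances, base=base),
                observed_richness=s_obs,
            )
        )
    return results


def otu_alpha_diversity(
    table: OtuTable, base: float = 2.0
) -> list[DiversityResult]:
    """Per-sample Shannon/equitability/richness from OTU counts."""
    results = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        results.append(
            DiversityResult(
                sample_id=sid,
                shannon_H=shannon(col, base=base),
                equitability_EH=equitability(col, base=base),
                observed_richness=int((col > 0).sum()),
            )
        )
    return results


def bray_curtis(
    compositions: np.ndarray, sample_ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities for rows of ``compositions``."""
    X = np.asarray(compositions, dtype=float)
    if X.ndim != 2:
        raise ValueError("compositions must be a 2-D samples x taxa matrix")
    if (X < 0).any():
        raise ValueError("compositions must be nonnegative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero samples have undefined Bray-Curtis distance")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(X.shape[0])]
    dm = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(list(sample_ids), dm)


def bray_curtis_pair(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity between two nonnegative vectors."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    denom = (u + v).sum()
    if denom <= 0:
        raise ValueError("both vectors are all zero")
    return float(np.abs(u - v).sum() / denom)


# ---------------------------------------------------------------------------
# Classical PCoA
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix, n_axes: int | None = None):
    """Classical scaling of a distance matrix.

    Double-centres the Gower matrix B = -0.5 J D^2 J, eigendecomposes, orders
    axes by descending eigenvalue and keeps only nonnegative-eigenvalue axes
    (negative eigenvalues are reported but their axes dropped). Returns
    ``(coordinates, eigenvalues)``: a DataFrame of sample coordinates and the
    full eigenvalue vector including any negative values.
    """
    D = dm.values
    n = D.shape[0]
    D2 = D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # drop numerically-zero and negative axes
    keep = eigvals > max(1e-12, 1e-12 * abs(eigvals[0]))
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    df = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return df, eigvals


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return float((ss_among / df_among) / (ss_within / df_within))


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with seeded label permutation.

    The p-value uses the add-one convention and therefore has resolution
    1/(n_permutations + 1) and can never be exactly zero.
    """
    labels = [str(l) for l in labels]
    if len(labels) != len(dm.sample_ids):
        raise ValueError("labels must match the distance matrix samples")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    codes = np.array([uniq.index(l) for l in labels])
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [uniq[g] for g in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = dm.values ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=p,
        n_permutations=n_permutations,
        group_labels=uniq,
        sample_size=len(labels),
        n_groups=len(uniq),
    )


def day0_vs_diet_test(
    profiles: Sequence[TaxonProfile],
    diets: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Compare day-0 samples to the last two sampled days of given diets.

    Day-0 profiles (any diet label) form one group; for each requested diet,
    profiles at its two largest sampling days form the other.
    """
    day0 = [p for p in profiles if p.day == 0]
    if not day0:
        raise ValueError("no day-0 profiles")
    end_profiles: list[TaxonProfile] = []
    for diet in diets:
        diet_days = sorted({p.day for p in profiles if p.diet == diet and p.day > 0})
        if len(diet_days) < 2:
            raise ValueError(f"diet {diet!r} has fewer than 2 sampled days")
        last2 = set(diet_days[-2:])
        end_profiles.extend(
            p for p in profiles if p.diet == diet and p.day in last2
        )
    selected = day0 + end_profiles
    X = np.stack([p.abundances for p in selected])
    ids = [p.sample_id for p in selected]
    labels = ["day0"] * len(day0) + ["diet_end"] * len(end_profiles)
    return permanova(bray_curtis(X, ids), labels, n_permutations, seed)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
        path, sep="\t"
    )


def write_diversity_report(
    results: Sequence[DiversityResult], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "shannon_H": r.shannon_H,
            "equitability_EH": r.equitability_EH,
            "observed_richness": r.observed_richness,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(rows, indent=2) + "\n")
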