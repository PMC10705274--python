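"""Bespoke expertise inference: greedy covariate-subnetwork search,
connectome conversion (transplanting expert structural edges into the
non-expert average connectome), structural similarity accounting, and
cognitive term-map correlation.

The greedy search looks for the functional subnetwork whose mean FC best
correlates with playing time: it starts from the single masked edge with
the highest Pearson correlation and keeps adding the edge that most
increases the correlation of the running mean, stopping at the maximum of
the trace (greedy, so a certified global optimum is not claimed).

Connectome conversion ranks the structural edges most strengthened in the
expert group, transfers the top fraction into the non-expert average SC
(preserving overall mean strength by rescaling), re-simulates, and tracks
the Euclidean distance between the converted and expert functional
connectivity restricted to an edge mask (typically the NBS component).
The smallest fraction whose distance sits within tolerance of the curve
minimum defines the minimal "core" structural subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome_core import (
    FunctionalConnectome,
    GroupDataset,
    StructuralConnectome,
)
from .hopf_model import ModelParameters, compute_fc, simulate_bold
from .model_fitting import group_average_sc
from .stats import bh_fdr, pearson_r
from .synthetic_data import derive_seed

__all__ = [
    "GreedyResult",
    "ConversionResult",
    "TermMap",
    "greedy_subnetwork",
    "ranked_transfer_edges",
    "transfer_connections",
    "conversion_curve",
    "sc_similarity",
    "term_map_correlation",
]


@dataclass
class GreedyResult:
    edges: list[tuple[int, int]]  # in order of addition
    r_trace: list[float]  # correlation after each addition
    r_final: float
    n_edges: int


@dataclass
class ConversionResult:
    fractions: np.ndarray
    distances: np.ndarray  # Euclidean distance from the expert reference FC
    plateau_fraction: float
    core_edges: list[tuple[int, int]]  # edges transferred at the plateau
    similarity_to_expert: tuple[float, float]  # (before, after)
    similarity_to_nonexpert: tuple[float, float]


@dataclass
class TermMap:
    """Per-region association map of one cognitive term."""

    term: str
    values: np.ndarray
    n_studies: int | None = None


def _as_values(fc) -> np.ndarray:
    return fc.values if isinstance(fc, FunctionalConnectome) else np.asarray(fc, float)


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------

def _corr_with(covariate: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Pearson correlation of the covariate with every column; constant
    columns score -inf so they are never selected."""
    x = covariate - covariate.mean()
    sx = np.sqrt((x * x).sum())
    y = columns - columns.mean(axis=0)
    sy = np.sqrt((y * y).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ y) / (sx * sy)
    return np.where(np.isfinite(r), r, -np.inf)


def greedy_subnetwork(
    fcs: list, covariate, mask: list[tuple[int, int]]
) -> GreedyResult:
    """Greedy forward selection of masked edges maximizing corr(mean FC,
    covariate).

    Ties break by (correlation desc, edge lexicographic); the search stops
    as soon as no remaining edge increases the correlation.
    """
    cov = np.asarray(covariate, float)
    if cov.std() == 0.0:
        raise ValueError("zero-variance covariate")
    if not mask:
        raise ValueError("edge mask must be nonempty")
    if len(fcs) != cov.size or cov.size < 4:
        raise ValueError("need one covariate per subject and at least 4 subjects")

    edges = sorted({(min(i, j), max(i, j)) for i, j in mask})
    mats = np.stack([_as_values(f) for f in fcs])
    cols = np.stack([mats[:, i, j] for i, j in edges], axis=1)  # subjects x edges

    n_edges = len(edges)
    chosen: list[int] = []
    r_trace: list[float] = []
    running = np.zeros(cov.size)
    remaining = np.ones(n_edges, dtype=bool)
    best_r = -np.inf
    while remaining.any():
        k = len(chosen)
        cand_means = (running[:, None] + cols[:, remaining]) / (k + 1)
        rs = _corr_with(cov, cand_means)
        rs_round = np.round(rs, 12)  # lexicographic tie-break on equal r
        best_local = int(np.argmax(rs_round))
        r_new = float(rs[best_local])
        if r_new <= best_r + 1e-12:
            break
        idx = np.flatnonzero(remaining)[best_local]
        chosen.append(int(idx))
        running = running + cols[:, idx]
        remaining[idx] = False
        best_r = r_new
        r_trace.append(r_new)

    picked = [edges[i] for i in chosen]
    return GreedyResult(
        edges=picked, r_trace=r_trace, r_final=best_r, n_edges=len(picked)
    )


# ---------------------------------------------------------------------------
# Connectome conversion
# ---------------------------------------------------------------------------

def ranked_transfer_edges(
    expert: np.ndarray, nonexpert: np.ndarray, min_entry: float = 0.01
) -> list[tuple[int, int]]:
    """Eligible edges (expert weight > min_entry) ranked by expert-minus-
    nonexpert difference, descending; ties lexicographic."""
    n = expert.shape[0]
    iu = np.triu_indices(n, 1)
    diff = expert[iu] - nonexpert[iu]
    eligible = expert[iu] > min_entry
    order = np.lexsort((iu[1], iu[0], -diff))
    return [
        (int(iu[0][k]), int(iu[1][k])) for k in order if eligible[k]
    ]


def transfer_connections(
    expert_mean_sc: StructuralConnectome,
    nonexpert_mean_sc: StructuralConnectome,
    fraction: float,
    min_entry: float = 0.01,
) -> StructuralConnectome:
    """Transplant the top ``fraction`` of expert-ranked edges into the
    non-expert average SC, preserving its mean strength.

    The output is rescaled by (mean non-expert weight / mean output weight)
    so the group-average strength is unchanged; symmetry is maintained.
    The transferred edge list itself is available from
    :func:`ranked_transfer_edges`.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    ew = expert_mean_sc.weights
    nw = nonexpert_mean_sc.weights
    if ew.shape != nw.shape:
        raise ValueError("SC dimension mismatch")
    mean_ne = nw.mean()
    if mean_ne == 0.0:
        raise ValueError("all-zero non-expert SC cannot be rescaled")

    ranked = ranked_transfer_edges(ew, nw, min_entry)
    k = int(round(fraction * len(ranked)))
    out = nw.copy()
    for i, j in ranked[:k]:
        out[i, j] = out[j, i] = ew[i, j]
    if k > 0:
        out *= mean_ne / out.mean()
    return StructuralConnectome(weights=out, subject_id="CVGP-mean", group="CVGP")


def _mask_vector(fc_values: np.ndarray, edge_mask: list[tuple[int, int]]) -> np.ndarray:
    return np.array([fc_values[i, j] for i, j in edge_mask])


def _mean_fc_over_seeds(
    sc: StructuralConnectome, G: float, n_seeds: int, master_seed: int, tag: str,
    base_params: ModelParameters | None = None,
) -> np.ndarray:
    acc = None
    for s in range(n_seeds):
        seed = derive_seed(master_seed, "conversion", tag, s)
        if base_params is None:
            params = ModelParameters(sc=sc, G=G, seed=seed)
        else:
            params = ModelParameters(
                sc=sc, G=G, a=base_params.a.copy(), f=base_params.f.copy(),
                beta=base_params.beta, dt=base_params.dt,
                duration=base_params.duration, transient=base_params.transient,
                seed=seed,
            )
        fc = compute_fc(simulate_bold(params)).values
        acc = fc if acc is None else acc + fc
    return acc / n_seeds


def conversion_curve(
    dataset: GroupDataset,
    fractions,
    nbs_mask: list[tuple[int, int]],
    expert_g: float,
    nonexpert_g: float,
    n_seeds: int = 10,
    master_seed: int = 0,
    plateau_tol: float = 0.02,
    expert_group: str = "VGP",
    nonexpert_group: str = "NVGP",
    base_params: ModelParameters | None = None,
    refit_g: bool = False,
) -> ConversionResult:
    """Distance-to-expert curve over transfer fractions.

    For each fraction the converted SC is simulated (multi-seed averaged
    FC, reusing the non-expert fitted G unless ``refit_g``), masked by the
    NBS edge set, and compared with the expert reference FC by Euclidean
    distance of the vectorized masked entries.  The plateau is the smallest
    fraction within ``plateau_tol`` (relative) of the curve minimum.
    """
    if not nbs_mask:
        raise ValueError("nbs_mask must be nonempty")
    fractions = np.asarray(sorted(fractions), float)
    edge_mask = sorted({(min(i, j), max(i, j)) for i, j in nbs_mask})

    expert_sc = group_average_sc(dataset.subjects, expert_group)
    nonexpert_sc = group_average_sc(dataset.subjects, nonexpert_group)

    ref_fc = _mean_fc_over_seeds(
        expert_sc, expert_g, n_seeds, master_seed, "expert-ref", base_params
    )
    ref_vec = _mask_vector(ref_fc, edge_mask)

    ranked = ranked_transfer_edges(expert_sc.weights, nonexpert_sc.weights)
    distances = np.empty(fractions.size)
    converted_scs = []
    for fi, frac in enumerate(fractions):
        converted = transfer_connections(expert_sc, nonexpert_sc, frac)
        g_use = nonexpert_g
        fc = _mean_fc_over_seeds(
            converted, g_use, n_seeds, master_seed, f"frac-{fi}", base_params
        )
        distances[fi] = float(np.linalg.norm(_mask_vector(fc, edge_mask) - ref_vec))
        converted_scs.append(converted)

    dmin = distances.min()
    within = distances <= dmin * (1.0 + plateau_tol)
    plateau_idx = int(np.flatnonzero(within)[0])
    plateau_fraction = float(fractions[plateau_idx])
    core_edges = ranked[: int(round(plateau_fraction * len(ranked)))]
    plateau_sc = converted_scs[plateau_idx]

    sim_exp = (
        sc_similarity(nonexpert_sc.weights, expert_sc.weights),
        sc_similarity(plateau_sc.weights, expert_sc.weights),
    )
    sim_non = (
        sc_similarity(nonexpert_sc.weights, nonexpert_sc.weights),
        sc_similarity(plateau_sc.weights, nonexpert_sc.weights),
    )
    return ConversionResult(
        fractions=fractions,
        distances=distances,
        plateau_fraction=plateau_fraction,
        core_edges=core_edges,
        similarity_to_expert=sim_exp,
        similarity_to_nonexpert=sim_non,
    )


def sc_similarity(sc_a, sc_b) -> float:
    """Pearson correlation of vectorized upper-triangle weights."""
    a = sc_a.weights if isinstance(sc_a, StructuralConnectome) else np.asarray(sc_a, float)
    b = sc_b.weights if isinstance(sc_b, StructuralConnectome) else np.asarray(sc_b, float)
    if a.shape != b.shape:
        raise ValueError("SC dimension mismatch")
    iu = np.triu_indices(a.shape[0], 1)
    x, y = a[iu], b[iu]
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero-variance connectome")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Term-map correlation
# ---------------------------------------------------------------------------

def term_map_correlation(
    strength_diff: np.ndarray, term_maps: list[TermMap]
) -> pd.DataFrame:
    """Correlate a nodal-strength difference with cognitive term maps.

    Returns a table (term, r, p, q, n_studies) sorted by r descending, with
    Benjamini-Hochberg q-values across the term family.  Constant maps are
    skipped with a warning.
    """
    diff = np.asarray(strength_diff, float)
    rows = []
    for tm in term_maps:
        v = np.asarray(tm.values, float)
        if v.size != diff.size:
            raise ValueError(f"term map {tm.term!r} length {v.size} != {diff.size}")
        if v.std() == 0.0:
            warnings.warn(f"constant term map {tm.term!r} skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        r, p = pearson_r(diff, v)
        p = max(p, 1e-300)  # |r| = 1 yields p = 0, outside the BH domain
        rows.append({"term": tm.term, "r": r, "p": p, "n_studies": tm.n_studies})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("r", ascending=False).reset_index(drop=True)
    return df
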