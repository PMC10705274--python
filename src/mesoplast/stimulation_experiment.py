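"""In-silico noisy homotopic stimulation protocol.

Pairs of homotopic occipital regions are driven with a sinusoidal forcing
of fixed magnitude F0 = 0.5 at the nodes' own frequency, while the
amplitude noise level sigma is swept from 0 to 2.  One pair is stimulated
at a time and, for each subject and noise level, four functional metrics
are computed from the simulated FC — overall mean FC, parieto-occipital
mean FC, global-efficiency AUC and transitivity AUC — then averaged across
the stimulated pairs (six pairs for the default atlas).  A resting-state
baseline (no forcing) is computed alongside.  Group difference curves over
sigma are tested per metric with independent t tests and BH-FDR across the
tested family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome_core import AtlasTable, GroupDataset, select_mask
from .fc_network_analysis import (
    global_efficiency,
    mean_fc,
    metric_auc,
    transitivity,
)
from .hopf_model import ModelParameters, StimulusSpec, compute_fc, simulate_bold
from .stats import bh_fdr, independent_t_test
from .synthetic_data import derive_seed

__all__ = [
    "METRICS",
    "StimulationSweepResult",
    "occipital_homotopic_pairs",
    "stimulation_sweep",
    "group_difference_curves",
]

METRICS = ("overall_fc", "parieto_occipital_fc", "efficiency_auc", "transitivity_auc")

#: Default sigma sweep: 0 to 2 in steps of 0.2.
DEFAULT_SIGMA_GRID = np.round(np.arange(0.0, 2.0001, 0.2), 10)


@dataclass
class StimulationSweepResult:
    """Metrics per group, noise level, and subject (seed- and pair-averaged)."""

    sigma_grid: np.ndarray
    groups: tuple[str, ...]
    metrics: dict  # metrics[group][metric] -> array (n_sigma, n_subjects)
    baseline: dict  # baseline[group][metric] -> array (n_subjects,)
    stim_pair_fc: dict  # stim_pair_fc[group] -> (n_sigma, n_subjects) mean FC of stimulated pairs
    baseline_pair_fc: dict  # per group -> (n_subjects,)
    pairs: list[tuple[int, int]]

    def difference_curve(self, metric: str) -> np.ndarray:
        """mean(first group) - mean(second group) at each sigma."""
        a, b = self.groups[0], self.groups[1]
        return self.metrics[a][metric].mean(axis=1) - self.metrics[b][metric].mean(axis=1)


def occipital_homotopic_pairs(atlas: AtlasTable) -> list[tuple[int, int]]:
    """The homotopic pairs within the occipital mask (six for AAL90)."""
    occ = select_mask(atlas, {"occipital"})
    return [(i, j) for i, j in atlas.homotopic_pairs() if i in occ and j in occ]


def _metrics_of_fc(fc_values: np.ndarray, po_mask: set[int]) -> dict:
    return {
        "overall_fc": mean_fc(fc_values),
        "parieto_occipital_fc": mean_fc(fc_values, po_mask),
        "efficiency_auc": metric_auc(fc_values, global_efficiency),
        "transitivity_auc": metric_auc(fc_values, transitivity),
    }


def _pair_fc(fc_values: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    return float(np.mean([fc_values[i, j] for i, j in pairs]))


def stimulation_sweep(
    dataset: GroupDataset,
    fitted_g: dict,
    sigma_grid=None,
    f0: float = 0.5,
    pairs: list[tuple[int, int]] | None = None,
    n_seeds: int = 10,
    master_seed: int = 0,
    base_params: ModelParameters | None = None,
) -> StimulationSweepResult:
    """Sweep the forcing-noise level over homotopic stimulation.

    ``fitted_g`` maps subject_id to its fitted coupling.  Each pair is
    stimulated alone (F0 on both members, shared sigma); metrics are
    averaged over seeds and then across pairs.
    """
    atlas = dataset.atlas
    sigma_grid = DEFAULT_SIGMA_GRID if sigma_grid is None else np.asarray(sigma_grid, float)
    if pairs is None:
        pairs = occipital_homotopic_pairs(atlas)
    if not pairs:
        raise ValueError("pairs must be nonempty")
    for i, j in pairs:
        if atlas.partner(i) != j:
            raise ValueError(f"({i}, {j}) is not a homotopic pair")
    po_mask = select_mask(atlas, {"parietal", "occipital"})
    groups = tuple(dataset.group_labels())
    if len(groups) < 2:
        raise ValueError("need two groups")

    def make_params(sc, G, seed):
        if base_params is None:
            return ModelParameters(sc=sc, G=G, seed=seed)
        return ModelParameters(
            sc=sc, G=G, a=base_params.a.copy(), f=base_params.f.copy(),
            beta=base_params.beta, dt=base_params.dt,
            duration=base_params.duration, transient=base_params.transient,
            seed=seed,
        )

    metrics = {g: {m: np.zeros((sigma_grid.size, len(dataset.group(g)))) for m in METRICS}
               for g in groups}
    baseline = {g: {m: np.zeros(len(dataset.group(g))) for m in METRICS} for g in groups}
    stim_pair_fc = {g: np.zeros((sigma_grid.size, len(dataset.group(g)))) for g in groups}
    baseline_pair_fc = {g: np.zeros(len(dataset.group(g))) for g in groups}

    for g in groups:
        for si, subj in enumerate(dataset.group(g)):
            G = float(fitted_g[subj.sc.subject_id])
            # resting-state baseline, seed-averaged
            base_acc = {m: 0.0 for m in METRICS}
            pair_acc = 0.0
            for rep in range(n_seeds):
                seed = derive_seed(master_seed, "rest", subj.sc.subject_id, rep)
                fc = compute_fc(simulate_bold(make_params(subj.sc, G, seed))).values
                vals = _metrics_of_fc(fc, po_mask)
                for m in METRICS:
                    base_acc[m] += vals[m]
                pair_acc += _pair_fc(fc, pairs)
            for m in METRICS:
                baseline[g][m][si] = base_acc[m] / n_seeds
            baseline_pair_fc[g][si] = pair_acc / n_seeds

            for ki, sigma in enumerate(sigma_grid):
                acc = {m: 0.0 for m in METRICS}
                pair_acc = 0.0
                for pi, pair in enumerate(pairs):
                    stim = StimulusSpec(
                        targets=frozenset(pair), f0=f0, sigma=float(sigma)
                    )
                    for rep in range(n_seeds):
                        seed = derive_seed(
                            master_seed, "stim", subj.sc.subject_id, ki, pi, rep
                        )
                        fc = compute_fc(
                            simulate_bold(make_params(subj.sc, G, seed), stim)
                        ).values
                        vals = _metrics_of_fc(fc, po_mask)
                        for m in METRICS:
                            acc[m] += vals[m]
                        pair_acc += fc[pair[0], pair[1]]
                denom = n_seeds * len(pairs)
                for m in METRICS:
                    metrics[g][m][ki, si] = acc[m] / denom
                stim_pair_fc[g][ki, si] = pair_acc / denom

    return StimulationSweepResult(
        sigma_grid=sigma_grid,
        groups=groups,
        metrics=metrics,
        baseline=baseline,
        stim_pair_fc=stim_pair_fc,
        baseline_pair_fc=baseline_pair_fc,
        pairs=list(pairs),
    )


def group_difference_curves(result: StimulationSweepResult) -> pd.DataFrame:
    """Per sigma and metric: group difference, t, p, and BH-FDR q.

    The FDR family is the full (sigma x metric) grid of tests.
    """
    a, b = result.groups[0], result.groups[1]
    rows = []
    for m in METRICS:
        for ki, sigma in enumerate(result.sigma_grid):
            va = result.metrics[a][m][ki]
            vb = result.metrics[b][m][ki]
            if va.size < 2 or vb.size < 2:
                raise ValueError("need at least 2 subjects per group")
            tr = independent_t_test(va, vb)
            rows.append(
                {
                    "metric": m,
                    "sigma": float(sigma),
                    "difference": float(va.mean() - vb.mean()),
                    "t": tr.statistic,
                    "p": tr.p_value,
                    "cohens_d": tr.effect_size,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df
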