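"""Synthetic cohort generator.

The original cohort (expert real-time-strategy players vs non-players, 31
subjects per group, with DTI-derived structural connectomes and a
playing-time covariate) is available only under a data-sharing agreement.
This module generates datasets with the same statistical structure so that
every downstream stage — coupling fitting, graph analysis, network-based
statistics, greedy covariate search, stimulation, connectome conversion —
is fully testable:

* sparse symmetric structural connectomes with heavy-tailed (log-normal)
  weights, max-normalized, emulating streamline-count matrices;
* a planted group effect: expert subjects have the edges of the
  parieto-occipital subnetwork (plus a configurable set of fronto-parietal
  pairs) multiplied by ``effect_size``;
* a playing-time covariate whose natural log correlates with each expert's
  mean planted-edge SC at a configurable level;
* a target functional connectome produced by the model itself at a known
  coupling ``reference_G``, so parameter recovery is checkable.

With ``effect_size = 1`` and no covariate coupling the two groups are
exchangeable, giving exact null datasets for calibration tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .connectome_core import (
    AtlasTable,
    FunctionalConnectome,
    GroupDataset,
    StructuralConnectome,
    Subject,
    default_atlas,
    normalize_sc,
    select_mask,
)
from .hopf_model import ModelParameters, compute_fc, simulate_bold

__all__ = [
    "SyntheticConfig",
    "default_planted_edges",
    "sample_base_sc",
    "generate_group_dataset",
    "make_reference_fc",
    "derive_seed",
]

#: Fronto-parietal homotopic-within-hemisphere pairs planted by default,
#: echoing the frontal/parietal families recurrent in the expert subnetwork.
FRONTO_PARIETAL_PAIRS = (
    ("SFGdor", "IPG"),
    ("MFG", "ANG"),
    ("SMA", "PCUN"),
)


def derive_seed(master: int, *parts) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and labels."""
    text = ":".join([str(master), *map(str, parts)])
    return zlib.crc32(text.encode()) % (2**31)


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror the emulated study: 31 subjects per group, a planted
    strengthening of parieto-occipital plus fronto-parietal structural
    connectivity in the expert group, and experts playing at least 6 h/week.
    """

    n_subjects_per_group: int = 31
    density: float = 0.25
    base_weight_scale: float = 1.0
    weight_sigma: float = 1.2  # log-normal shape; heavy tail as in fiber counts
    planted_edges: tuple[tuple[int, int], ...] | None = None  # None -> default mask
    effect_size: float = 1.5
    subject_noise_sd: float = 0.05
    covariate_r: float = 0.6
    reference_G: float = 1.0
    reference_duration: float = 900.0
    reference_runs: int = 5
    seed: int = 0
    atlas: AtlasTable = field(default_factory=default_atlas)

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1")
        if not (0.0 <= self.covariate_r < 1.0):
            raise ValueError("covariate_r must be in [0, 1)")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")
        if self.reference_G < 0:
            raise ValueError("reference_G must be nonnegative")
        if self.planted_edges is None:
            self.planted_edges = default_planted_edges(self.atlas)
        edges = []
        for i, j in self.planted_edges:
            if i == j:
                raise ValueError("planted edges must be off-diagonal")
            a, b = (i, j) if i < j else (j, i)
            edges.append((int(a), int(b)))
        self.planted_edges = tuple(sorted(set(edges)))

    @property
    def n(self) -> int:
        return self.atlas.n


def default_planted_edges(atlas: AtlasTable) -> tuple[tuple[int, int], ...]:
    """All edges within the parieto-occipital mask plus the listed
    fronto-parietal pairs, both hemispheres."""
    po = sorted(select_mask(atlas, {"parietal", "occipital"}))
    edges = {(po[i], po[j]) for i in range(len(po)) for j in range(i + 1, len(po))}
    for ab_a, ab_b in FRONTO_PARIETAL_PAIRS:
        for hemi in ("L", "R"):
            i = atlas.by_label(f"{ab_a}.{hemi}").index
            j = atlas.by_label(f"{ab_b}.{hemi}").index
            edges.add((min(i, j), max(i, j)))
    return tuple(sorted(edges))


def _planted_mask(config: SyntheticConfig) -> np.ndarray:
    mask = np.zeros((config.n, config.n), dtype=bool)
    for i, j in config.planted_edges:
        mask[i, j] = mask[j, i] = True
    return mask


def sample_base_sc(config: SyntheticConfig, seed: int) -> StructuralConnectome:
    """Sample a sparse heavy-tailed base connectome.

    Exactly ``round(density * n(n-1)/2)`` upper-triangle edges are nonzero
    (positions chosen uniformly) with log-normal weights.  Two stabilizing
    features emulate real streamline-count matrices:

    * weights are scaled by a robust quantile (3x the 99th percentile of
      the nonzero weights) and saturate at that ceiling, and the single
      strongest edge — the dominant "trunk" connection, present in every
      subject — is pinned at the ceiling exactly.  The max-normalized
      matrix therefore has a stable overall coupling scale instead of one
      set by an erratic heavy-tail maximum;
    * planted (association-cortex) edges are capped at 60% of the ceiling:
      the trunk connection is never one of the edges the group manipulation
      strengthens, so the planted effect survives per-subject
      max-normalization intact.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    m = n * (n - 1) // 2
    k = int(round(config.density * m))
    iu = np.triu_indices(n, 1)
    flat = np.zeros(m)
    pos = rng.permutation(m)[:k]
    draws = config.base_weight_scale * rng.lognormal(
        mean=0.0, sigma=config.weight_sigma, size=k
    )
    scale = 3.0 * np.quantile(draws, 0.99)
    flat[pos] = np.minimum(draws / scale, 1.0)
    planted_flat = np.zeros(m, dtype=bool)
    planted_pos = {
        (n * i - i * (i + 1) // 2) + (j - i - 1) for i, j in config.planted_edges
    }
    planted_flat[list(planted_pos)] = True
    eligible = ~planted_flat[pos]
    trunk = pos[eligible][np.argmax(draws[eligible])]
    flat[trunk] = 1.0  # trunk edge at the ceiling, never planted
    flat[planted_flat] = np.minimum(flat[planted_flat], 0.6)
    W = np.zeros((n, n))
    W[iu] = flat
    W = W + W.T
    return normalize_sc(W, subject_id=f"base-{seed}", group="synthetic")


def _subject_sc(
    config: SyntheticConfig, base: np.ndarray, expert: bool, seed: int
) -> np.ndarray:
    """One subject: planted scaling (experts) + symmetric edge noise, renormalized."""
    rng = np.random.default_rng(seed)
    w = base.copy()
    if expert and config.effect_size != 1.0:
        mask = _planted_mask(config)
        w[mask] *= config.effect_size
    if config.subject_noise_sd > 0:
        n = config.n
        iu = np.triu_indices(n, 1)
        noise = rng.normal(0.0, config.subject_noise_sd, size=iu[0].size)
        upper = w[iu]
        upper = np.where(upper > 0, np.maximum(upper + noise * upper, 0.0), 0.0)
        w = np.zeros_like(w)
        w[iu] = upper
        w = w + w.T
    return w


def generate_group_dataset(config: SyntheticConfig) -> GroupDataset:
    """Generate the full two-group cohort with covariate and target FC.

    Expert ("VGP") subjects carry the planted effect and playing times of at
    least 6 h/week whose natural log correlates with their mean
    planted-edge SC at about ``covariate_r``; non-experts ("NVGP") play
    0-2 h/week.
    """
    base = sample_base_sc(config, derive_seed(config.seed, "base")).weights
    n_sub = config.n_subjects_per_group
    mask = _planted_mask(config)

    subjects: list[Subject] = []
    planted_strength = []
    expert_scs = []
    for g, group in enumerate(("VGP", "NVGP")):
        expert = group == "VGP"
        for s in range(n_sub):
            w = _subject_sc(
                config, base, expert, derive_seed(config.seed, "subject", group, s)
            )
            sc = normalize_sc(w, subject_id=f"{group}-{s:02d}", group=group)
            if expert:
                expert_scs.append(sc)
                planted_strength.append(sc.weights[mask].mean())
            subjects.append(Subject(sc=sc, playing_time=0.0))

    # playing time: experts correlated with planted-subnetwork strength
    rng = np.random.default_rng(derive_seed(config.seed, "covariate"))
    strength = np.asarray(planted_strength)
    z = (strength - strength.mean()) / (strength.std() or 1.0)
    eps = rng.standard_normal(n_sub)
    eps = (eps - eps.mean()) / (eps.std() or 1.0)
    r = config.covariate_r
    log_hours = 3.0 + 0.4 * (r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps)
    expert_hours = np.maximum(np.exp(log_hours), 6.0)
    nonexpert_hours = rng.uniform(0.0, 2.0, size=n_sub)

    e = ne = 0
    for s in subjects:
        if s.sc.group == "VGP":
            s.playing_time = float(expert_hours[e])
            e += 1
        else:
            s.playing_time = float(nonexpert_hours[ne])
            ne += 1

    target = make_reference_fc(config)
    return GroupDataset(subjects=subjects, target_fc=target, atlas=config.atlas)


def nonexpert_average_sc(config: SyntheticConfig) -> StructuralConnectome:
    """Group-average non-expert SC (the substrate of the reference FC)."""
    n_sub = config.n_subjects_per_group
    base = sample_base_sc(config, derive_seed(config.seed, "base")).weights
    acc = np.zeros_like(base)
    for s in range(n_sub):
        w = _subject_sc(
            config, base, False, derive_seed(config.seed, "subject", "NVGP", s)
        )
        acc += normalize_sc(w).weights  # per-subject normalization, as in the dataset
    return normalize_sc(acc / n_sub, subject_id="NVGP-mean", group="NVGP")


def make_reference_fc(config: SyntheticConfig) -> FunctionalConnectome:
    """Target FC: seed-averaged model runs on the average non-expert SC.

    The empirical fitting target this stands in for is a grand-average FC
    (many subjects averaged), so the synthetic target averages
    ``reference_runs`` seeded realizations.  Each run uses the same
    duration as the default fitting simulations: FC level depends on the
    correlation window (slow in-band components are partly absorbed into
    the window mean on short windows), so an unmatched window would shift
    the coupling the sweep recovers.
    """
    sc = nonexpert_average_sc(config)
    acc = None
    for run in range(config.reference_runs):
        params = ModelParameters(
            sc=sc,
            G=config.reference_G,
            duration=config.reference_duration,
            seed=derive_seed(config.seed, "reference-fc", run),
        )
        fc = compute_fc(simulate_bold(params)).values
        acc = fc if acc is None else acc + fc
    vals = acc / config.reference_runs
    np.fill_diagonal(vals, 1.0)
    return FunctionalConnectome(values=vals, source="target")
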