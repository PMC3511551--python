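"""Synthetic expression data with known ground truth.

Two generators emulate the statistical structure of RMA-normalized microarray
compendia without reproducing any real data set:

* :func:`simulate_expression` plants pathway blocks of co-regulated genes.
  Genes in a block share a latent factor passed through per-gene monotone
  (optionally nonlinear) links plus noise, so rank methods and Pearson can be
  separated on monotone-nonlinear coupling.  Marginals can be made non-normal
  and outliers injected as +-6 SD spikes.

* :func:`simulate_tf_coordination` plants TF groups that co-drive shared
  target programs, plus a pool of "common" genes weakly tied to every TF
  through a global latent factor.  The commons produce the weak promiscuous
  background of moderate top-list overlaps that real TF coordination
  networks exhibit, which is what makes the mean-plus-SD significance
  threshold of Triple-Link meaningful.  Because each TF's top-100 tail is
  drawn from the same small commons pool, within-group overlaps sit well
  above the threshold and between-group overlaps well below it across a wide
  noise range.

All values are affinely mapped into the log2 range [3, 14] typical of
RMA output; the map is increasing and global, so it changes no pairwise
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["SimulationConfig", "GroundTruth", "simulate_expression", "simulate_tf_coordination"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; identical configs yield identical matrices.

    ``noise_sd`` is the SD of additive per-gene noise relative to the
    unit-variance latent factors; ``outlier_rate`` is the per-entry
    probability of replacement by a +-6 SD spike.
    """

    n_genes: int = 1000
    n_samples: int = 60
    n_pathways: int = 8
    block_size: int = 10
    n_tfs: int = 40
    n_tf_groups: int = 5
    targets_per_group: int = 40
    n_common: int = 60
    dependence_kind: str = "monotone_nonlinear"  # linear | monotone_nonlinear | mixed
    noise_sd: float = 0.5
    outlier_rate: float = 0.0
    marginal: str = "normal"  # normal | lognormal | mixed
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_samples", "n_pathways", "block_size",
                     "n_tfs", "n_tf_groups", "targets_per_group", "n_common"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigurationError("outlier_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.dependence_kind not in ("linear", "monotone_nonlinear", "mixed"):
            raise ConfigurationError(f"unknown dependence_kind {self.dependence_kind!r}")
        if self.marginal not in ("normal", "lognormal", "mixed"):
            raise ConfigurationError(f"unknown marginal {self.marginal!r}")


@dataclass(frozen=True)
class GroundTruth:
    pathway_map: dict = field(default_factory=dict)  # gene -> frozenset of pathway ids
    tf_groups: dict = field(default_factory=dict)  # tf -> group index
    block_of: dict = field(default_factory=dict)  # gene -> block/program index

    def to_dict(self) -> dict:
        return {
            "pathway_map": {g: sorted(v) for g, v in self.pathway_map.items()},
            "tf_groups": dict(self.tf_groups),
            "block_of": dict(self.block_of),
        }


def _monotone_link(rng: np.random.Generator, kind: str):
    """Random strictly monotone link; sign carries co- vs anti-regulation."""
    sign = rng.choice([-1.0, 1.0])
    scale = rng.uniform(0.5, 2.0)
    if kind == "linear":
        return lambda t: sign * scale * t
    choice = rng.integers(3)
    if choice == 0:
        return lambda t: sign * np.exp(0.6 * scale * t)
    if choice == 1:
        return lambda t: sign * (scale * t + (scale * t) ** 3 / 3.0)
    return lambda t: sign * np.sinh(scale * t)


def _pick_link(rng: np.random.Generator, cfg: SimulationConfig):
    kind = cfg.dependence_kind
    if kind == "mixed":
        kind = "linear" if rng.random() < 0.5 else "monotone_nonlinear"
    return _monotone_link(rng, kind)


def _background(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    draws = rng.standard_normal((n, cfg.n_samples))
    if cfg.marginal == "lognormal":
        return np.exp(draws)
    if cfg.marginal == "mixed":
        half = n // 2
        draws[:half] = np.exp(draws[:half])
    return draws


def _inject_outliers(rng: np.random.Generator, values: np.ndarray, rate: float) -> np.ndarray:
    if rate == 0:
        return values
    out = values.copy()
    mask = rng.random(values.shape) < rate
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    spikes = values.mean(axis=1, keepdims=True) + 6.0 * sd * rng.choice(
        [-1.0, 1.0], size=values.shape
    )
    out[mask] = np.broadcast_to(spikes, values.shape)[mask]
    return out


def _to_log2_range(values: np.ndarray, lo: float = 3.0, hi: float = 14.0) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.full_like(values, (lo + hi) / 2.0)
    return lo + (hi - lo) * (values - vmin) / (vmax - vmin)


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression matrix with planted pathway blocks.

    Returns (genes x samples DataFrame, ground truth).  Pathway block ``k``
    holds genes ``P{k}G{j}`` sharing latent factor k; the remaining genes are
    independent background.
    """
    cfg = config
    n_block_genes = cfg.n_pathways * cfg.block_size
    if n_block_genes > cfg.n_genes:
        raise ConfigurationError(
            f"block_size*n_pathways = {n_block_genes} exceeds n_genes = {cfg.n_genes}"
        )
    rng = np.random.default_rng(cfg.seed)
    rows: dict[str, np.ndarray] = {}
    pathway_map: dict[str, frozenset] = {}
    block_of: dict[str, int] = {}
    for k in range(cfg.n_pathways):
        factor = rng.standard_normal(cfg.n_samples)
        for j in range(cfg.block_size):
            name = f"P{k:02d}G{j:03d}"
            link = _pick_link(rng, cfg)
            v = link(factor) + cfg.noise_sd * rng.standard_normal(cfg.n_samples)
            if cfg.marginal == "lognormal":
                v = np.exp((v - v.mean()) / max(v.std(), 1e-12))
            rows[name] = v
            pathway_map[name] = frozenset({f"PWY{k:02d}"})
            block_of[name] = k
    bg = _background(rng, cfg, cfg.n_genes - n_block_genes)
    for i, v in enumerate(bg):
        rows[f"BG{i:04d}"] = v
    names = sorted(rows)
    values = np.array([rows[g] for g in names])
    # per-gene standardization keeps blocks and background on one scale
    values = (values - values.mean(axis=1, keepdims=True)) / np.maximum(
        values.std(axis=1, keepdims=True), 1e-12
    )
    values = _inject_outliers(rng, values, cfg.outlier_rate)
    values = _to_log2_range(values)
    matrix = pd.DataFrame(values, index=names,
                          columns=[f"S{j:03d}" for j in range(cfg.n_samples)])
    return matrix, GroundTruth(pathway_map=pathway_map, block_of=block_of)


def simulate_tf_coordination(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression matrix with planted TF groups sharing target programs.

    Group g holds ``n_tfs / n_tf_groups`` TFs loading on latent factor g plus
    a global factor; its program holds ``targets_per_group`` genes driven by
    factor g alone.  ``n_common`` genes follow the global factor and fill the
    tails of every TF's top list.
    """
    cfg = config
    if cfg.n_tfs % cfg.n_tf_groups:
        raise ConfigurationError("n_tfs must be a multiple of n_tf_groups")
    needed = cfg.n_tfs + cfg.n_tf_groups * cfg.targets_per_group + cfg.n_common
    if needed > cfg.n_genes:
        raise ConfigurationError(
            f"n_genes = {cfg.n_genes} too small for {needed} structured genes"
        )
    rng = np.random.default_rng(cfg.seed)
    per_group = cfg.n_tfs // cfg.n_tf_groups
    factors = rng.standard_normal((cfg.n_tf_groups, cfg.n_samples))
    global_factor = rng.standard_normal(cfg.n_samples)
    rows: dict[str, np.ndarray] = {}
    tf_groups: dict[str, int] = {}
    block_of: dict[str, int] = {}
    for g in range(cfg.n_tf_groups):
        for t in range(per_group):
            name = f"TF{g * per_group + t:03d}"
            lam = rng.uniform(0.5, 0.9)
            rows[name] = (
                factors[g]
                + lam * global_factor
                + cfg.noise_sd * rng.standard_normal(cfg.n_samples)
            )
            tf_groups[name] = g
            block_of[name] = g
        for j in range(cfg.targets_per_group):
            name = f"G{g:02d}T{j:03d}"
            a = rng.uniform(0.8, 2.0)
            rows[name] = a * factors[g] + cfg.noise_sd * rng.standard_normal(cfg.n_samples)
            block_of[name] = g
    for c in range(cfg.n_common):
        a = rng.uniform(0.8, 2.0)
        rows[f"H{c:03d}"] = (
            a * global_factor
            + 0.2 * rng.standard_normal(cfg.n_samples)
            + cfg.noise_sd * rng.standard_normal(cfg.n_samples)
        )
    bg = _background(rng, cfg, cfg.n_genes - needed)
    for i, v in enumerate(bg):
        rows[f"N{i:04d}"] = v
    names = sorted(rows)
    values = np.array([rows[g] for g in names])
    values = _inject_outliers(rng, values, cfg.outlier_rate)
    values = _to_log2_range(values)
    matrix = pd.DataFrame(values, index=names,
                          columns=[f"S{j:03d}" for j in range(cfg.n_samples)])
    return matrix, GroundTruth(tf_groups=tf_groups, block_of=block_of)
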