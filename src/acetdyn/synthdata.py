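"""Synthetic promoter acetylation / expression time courses.

Emulates the structure of a ChIP-chip promoter-tiling study of a
differentiation time course: ~17k genes probed at ~28 positions spaced
~248 bp within ±3.5 kb of the TSS, two ChIP replicates and three expression
replicates measured on days 0, 1, 3 and 5. Each gene carries a contiguous
"acetylation island" — a block of probes with signal above the control-probe
background — whose *location* is fixed over the time course; only signal
levels change:

* ~2.5% of genes are transcriptionally down-regulated and lose acetylation
  broadly (wide islands, full loss by the last day);
* ~2.5% are up-regulated and gain acetylation only within ±1.5 kb of the TSS;
* a small "ESC-like" subset has elevated acetylation across the whole window
  and a strong monotone loss that is only weakly reflected in expression;
* everything else is stable.

Expression change from day 0 is coupled to the standardized true mean
acetylation change with a per-day coupling coefficient that increases over
the time course, so genome-wide acetylation<->expression coordination
strengthens with day — the qualitative behaviour the downstream association
stages are designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ioformats import (
    GeneSetCollection,
    ensure_dir,
    write_expression_table,
    write_gmt,
    write_probe_table,
    write_truth_labels,
)

# Signal-scale constants (units of log-ratio signal; the control-probe null
# is centred at 0 with sd = noise_sd_acet).
ISLAND_HEIGHT = 2.0        # island plateau above background
UP_GAIN_MAX = 0.6          # TSS-proximal gain of up genes; much weaker than loss
UP_GAIN_WINDOW_BP = 1500   # half-width of the gain region
DOWN_ISLAND_FRAC = 0.85    # down genes de-acetylate over nearly the whole window
EFFECT_SCALE_RANGE = (0.4, 1.0)  # per-gene spread of differential effect sizes
ESC_BASELINE_BOOST = 1.0   # window-wide elevation of ESC-like genes
ESC_DECAY_RATE = 1.9       # exp(-rate * t/t_max) retention of ESC signal
ESC_COUPLING_DAMP = 0.25   # ESC de-acetylation is mostly NOT mirrored in expression
EXPR_BASELINE_MEAN = 6.0
EXPR_BASELINE_SD = 1.0


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_genes: int = 17268
    n_control_probes: int = 5000
    probes_per_gene_mean: int = 28
    probe_spacing_bp: float = 248.0
    tss_window_bp: float = 3500.0
    days: tuple[int, ...] = (0, 1, 3, 5)
    chip_replicates: int = 2
    expr_replicates: int = 3
    frac_up: float = 0.025
    frac_down: float = 0.025
    frac_esc: float = 0.02
    coupling_by_day: tuple[float, ...] = (0.0, 0.1, 0.3, 0.35)
    noise_sd_acet: float = 0.5
    noise_sd_expr: float = 0.25
    island_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.days = tuple(self.days)
        self.coupling_by_day = tuple(self.coupling_by_day)
        if min(self.n_genes, self.n_control_probes, self.probes_per_gene_mean,
               self.chip_replicates, self.expr_replicates) <= 0:
            raise ValueError("all counts must be positive")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if len(self.coupling_by_day) != len(self.days):
            raise ValueError("coupling_by_day must align with days")
        if any(abs(c) > 1 for c in self.coupling_by_day):
            raise ValueError("coupling values must lie in [-1, 1]")
        if self.probes_per_gene_mean * self.probe_spacing_bp > 2 * self.tss_window_bp:
            raise ValueError(
                "cannot place probes: probes_per_gene_mean * probe_spacing_bp "
                f"= {self.probes_per_gene_mean * self.probe_spacing_bp:.0f} bp "
                f"exceeds the {2 * self.tss_window_bp:.0f} bp window"
            )
        if not (0 < self.island_frac <= 1):
            raise ValueError("island_frac must be in (0, 1]")


@dataclass
class SimDataset:
    """A generated dataset plus its ground truth."""

    probe_table: pd.DataFrame
    expr_table: pd.DataFrame
    truth: pd.Series                  # gene_id -> {up, down, stable}
    esc_genes: set[str]
    gene_sets: GeneSetCollection
    coupling_by_day: tuple[float, ...]
    island_truth: pd.DataFrame        # gene_id, probe_id, in_island
    config: SimConfig


def _true_mean_signal(cfg: SimConfig, labels: np.ndarray, is_esc: np.ndarray,
                      in_island: np.ndarray, offsets: np.ndarray,
                      effect_scale: np.ndarray) -> np.ndarray:
    """Noise-free mean signal, shape (n_genes, grid, n_days).

    ``effect_scale`` spreads per-gene differential effect sizes so the
    up/down/stable classes overlap realistically instead of being separated
    by a single shared effect magnitude.
    """
    n, m = in_island.shape
    t = np.asarray(cfg.days, dtype=float)
    t_frac = t / max(t[-1], 1.0)                      # 0..1 over the course
    mu = np.empty((n, m, len(t)))
    base = ISLAND_HEIGHT * in_island.astype(float)    # (n, m)
    near_tss = np.abs(offsets) <= UP_GAIN_WINDOW_BP   # (n, m)

    down = labels == "down"
    up = labels == "up"
    for k, f in enumerate(t_frac):
        sig = base.copy()
        # broad loss across the island, (nearly) complete by the last day
        sig[down] *= 1.0 - f * effect_scale[down, None]
        # narrow TSS-proximal gain, much weaker than the down-gene loss
        sig[up] += (UP_GAIN_MAX * f * effect_scale[up, None]) * near_tss[up]
        esc_sig = (base[is_esc] + ESC_BASELINE_BOOST) * np.exp(-ESC_DECAY_RATE * f)
        sig[is_esc] = esc_sig                         # high everywhere, strong loss
        mu[:, :, k] = sig
    return mu


def _esc_gene_sets(rng: np.random.Generator, esc: np.ndarray,
                   others: np.ndarray) -> GeneSetCollection:
    """Five ESC-like gene sets of varying size and specificity, mirroring the
    mix of signatures (large/noisy to small/pure) such studies consume."""
    if len(esc) == 0:
        return GeneSetCollection()

    def mix(frac_esc_members: float, n_extra: int) -> list[str]:
        k = max(1, int(round(frac_esc_members * len(esc))))
        members = list(rng.choice(esc, size=k, replace=False))
        if n_extra > 0 and len(others) > 0:
            n_extra = min(n_extra, len(others))
            members += list(rng.choice(others, size=n_extra, replace=False))
        return sorted(members)

    sets = {
        "pluripotency_signature": mix(0.6, int(0.5 * len(esc))),
        "self_renewal_screen_hits": mix(0.5, int(0.4 * len(esc))),
        "stem_cell_maintenance": mix(0.2, 0),
        "esc_interaction_network": mix(0.4, int(0.15 * len(esc))),
        "core_regulators": list(rng.choice(esc, size=min(15, len(esc)), replace=False)),
    }
    desc = {
        "pluripotency_signature": "large computationally derived stemness signature (noisy)",
        "self_renewal_screen_hits": "hits of a self-renewal perturbation screen",
        "stem_cell_maintenance": "small functional-annotation set",
        "esc_interaction_network": "members of an ESC protein-interaction module",
        "core_regulators": "small set of core transcriptional regulators",
    }
    return GeneSetCollection(sets=sets, descriptions=desc)


def generate(config: SimConfig) -> SimDataset:
    """Generate a full synthetic dataset. Deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.probes_per_gene_mean
    days = np.asarray(cfg.days)
    n_days = len(days)

    genes = np.array([f"g{i:05d}" for i in range(n)])

    # --- truth labels -----------------------------------------------------
    order = rng.permutation(n)
    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    labels = np.full(n, "stable", dtype=object)
    labels[order[:n_up]] = "up"
    labels[order[n_up:n_up + n_down]] = "down"
    stable_idx = order[n_up + n_down:]
    n_esc = int(round(cfg.frac_esc * n))
    esc_idx = rng.choice(stable_idx, size=min(n_esc, len(stable_idx)), replace=False)
    is_esc = np.zeros(n, dtype=bool)
    is_esc[esc_idx] = True

    # --- probe placement: jittered even grid ------------------------------
    span = m * cfg.probe_spacing_bp
    grid = -span / 2 + cfg.probe_spacing_bp * (np.arange(m) + 0.5)
    jitter = rng.uniform(-cfg.probe_spacing_bp / 2, cfg.probe_spacing_bp / 2, size=(n, m))
    offsets = grid[None, :] + jitter
    keep = np.abs(offsets) <= cfg.tss_window_bp     # variable per-gene counts

    # --- fixed island locations -------------------------------------------
    frac = np.where(labels == "down", DOWN_ISLAND_FRAC, cfg.island_frac)
    length = np.maximum(1, np.round(frac * m)).astype(int)
    centre = (m - length) / 2.0
    start = np.clip(
        np.round(centre + rng.uniform(-0.5, 0.5, size=n) * length), 0, m - length
    ).astype(int)
    cols = np.arange(m)
    in_island = (cols[None, :] >= start[:, None]) & (cols[None, :] < (start + length)[:, None])

    effect_scale = rng.uniform(*EFFECT_SCALE_RANGE, size=n)
    mu = _true_mean_signal(cfg, labels, is_esc, in_island, offsets, effect_scale)

    # --- probe table -------------------------------------------------------
    probe_ids = np.char.add(np.repeat(genes, m), np.array([f"_p{j:02d}" for j in range(m)] * n))
    flat_keep = keep.ravel()
    kept_ids = probe_ids[flat_keep]
    kept_genes = np.repeat(genes, m)[flat_keep]
    kept_off = np.round(offsets.ravel()[flat_keep]).astype(int)
    kept_mu = mu.reshape(n * m, n_days)[flat_keep]      # (P, d)
    P = len(kept_ids)

    noise = rng.normal(0.0, cfg.noise_sd_acet, size=(P, n_days, cfg.chip_replicates))
    blocks = []
    for k, day in enumerate(days):
        for r in range(cfg.chip_replicates):
            blocks.append(pd.DataFrame({
                "probe_id": kept_ids,
                "gene_id": kept_genes,
                "offset_bp": kept_off,
                "day": day,
                "replicate": r + 1,
                "signal": kept_mu[:, k] + noise[:, k, r],
            }))
    # control probes: pure null, exchangeable across days
    c_ids = np.array([f"c{i:05d}" for i in range(cfg.n_control_probes)])
    for day in days:
        for r in range(cfg.chip_replicates):
            blocks.append(pd.DataFrame({
                "probe_id": c_ids,
                "gene_id": np.nan,
                "offset_bp": np.nan,
                "day": day,
                "replicate": r + 1,
                "signal": rng.normal(0.0, cfg.noise_sd_acet, size=cfg.n_control_probes),
            }))
    probe_table = pd.concat(blocks, ignore_index=True)

    # --- expression coupled to true acetylation change ---------------------
    # per-gene true mean signal over kept probes, per day
    mu_masked = np.where(keep[:, :, None], mu, np.nan)
    gene_mean = np.nanmean(mu_masked, axis=1)           # (n, d)
    delta = gene_mean - gene_mean[:, [0]]               # change vs day 0
    sd = delta.std(axis=0)
    z = np.where(sd > 0, delta / np.where(sd > 0, sd, 1.0), 0.0)
    z = z - z.mean(axis=0)                              # standardized change

    damp = np.where(is_esc, ESC_COUPLING_DAMP, 1.0)
    coupling = np.asarray(cfg.coupling_by_day)
    change = coupling[None, :] * z * damp[:, None]
    change[:, 1:] += rng.normal(0.0, cfg.noise_sd_expr, size=(n, n_days - 1))
    change[:, 0] = 0.0

    e0 = rng.normal(EXPR_BASELINE_MEAN, EXPR_BASELINE_SD, size=n)
    rep_noise = rng.normal(0.0, cfg.noise_sd_expr, size=(n, n_days, cfg.expr_replicates))
    eblocks = []
    for k, day in enumerate(days):
        for r in range(cfg.expr_replicates):
            eblocks.append(pd.DataFrame({
                "gene_id": genes,
                "day": day,
                "replicate": r + 1,
                "expression": e0 + change[:, k] + rep_noise[:, k, r],
            }))
    expr_table = pd.concat(eblocks, ignore_index=True)

    gene_sets = _esc_gene_sets(rng, genes[is_esc], genes[~is_esc & (labels == "stable")])
    island_truth = pd.DataFrame({
        "gene_id": kept_genes,
        "probe_id": kept_ids,
        "in_island": in_island.ravel()[flat_keep],
    })
    return SimDataset(
        probe_table=probe_table,
        expr_table=expr_table,
        truth=pd.Series(labels, index=genes, name="label").rename_axis("gene_id"),
        esc_genes=set(genes[is_esc]),
        gene_sets=gene_sets,
        coupling_by_day=cfg.coupling_by_day,
        island_truth=island_truth,
        config=cfg,
    )


def write_dataset(ds: SimDataset, outdir) -> dict[str, str]:
    """Write all layers of a dataset to ``outdir``; returns path map."""
    out = ensure_dir(outdir)
    paths = {
        "probe_table": str(out / "probes.tsv"),
        "expr_table": str(out / "expression.tsv"),
        "truth": str(out / "truth.tsv"),
        "gene_sets": str(out / "gene_sets.gmt"),
        "config": str(out / "sim_config.json"),
    }
    write_probe_table(ds.probe_table, paths["probe_table"])
    write_expression_table(ds.expr_table, paths["expr_table"])
    write_truth_labels(ds.truth, paths["truth"])
    if len(ds.gene_sets):
        write_gmt(ds.gene_sets, paths["gene_sets"])
    else:
        paths.pop("gene_sets")
    cfg = asdict(ds.config)
    cfg["esc_genes"] = sorted(ds.esc_genes)
    Path(paths["config"]).write_text(json.dumps(cfg, indent=2, default=list))
    return paths
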