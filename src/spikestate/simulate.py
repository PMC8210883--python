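"""Synthetic data generators for the full analysis pipeline.

Three generators produce every input the downstream stages consume:

* :func:`simulate_single_cell_experiment` — a gene x cell TPM matrix with
  spike-in rows, per-cell endogenous/spike-in read-count pairs, a condition
  annotation table and the planted ground truth.
* :func:`simulate_cell_line_panel` — a log2 expression panel with an
  expressed-call mask, an IC50 vector and a planted co-expression module.
* :func:`simulate_patient_cohort` — an expression matrix plus binary
  responder labels linked to the module latent factor.

The single-cell generator works on absolute molecule amounts: each cell
receives a constant absolute amount of spike-in molecules while its
endogenous content is scaled by its transcriptional state, and TPM is
computed only afterwards.  Spike-in TPM therefore anti-correlates with
cellular mRNA content by construction, which is the physical premise the
normalization stage relies on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

STATES = ("repression", "amplification", "control_like")
CONDITIONS = ("control", "PAC16", "PAC48", "CELE2", "CELE16", "COMBO16")

#: Default cells per condition, mirroring the scale of a ~370-cell experiment.
DEFAULT_CELLS_PER_CONDITION = {
    "control": 57,
    "PAC16": 58,
    "PAC48": 65,
    "CELE2": 66,
    "CELE16": 67,
    "COMBO16": 59,
}

#: Per-condition state composition.  Pure-state conditions anchor the three
#: states; paclitaxel-alone conditions are mixtures.
DEFAULT_CONDITION_STATES: dict[str, dict[str, float]] = {
    "control": {"control_like": 1.0},
    "CELE2": {"control_like": 1.0},
    "CELE16": {"repression": 1.0},
    "COMBO16": {"amplification": 1.0},
    "PAC16": {"repression": 0.55, "amplification": 0.04, "control_like": 0.41},
    "PAC48": {"repression": 0.47, "control_like": 0.53},
}

DEFAULT_STATE_SCALING = {"control_like": 1.0, "repression": 0.45, "amplification": 1.5}

#: Cluster effect spec: number of genes and linear fold applied per state.
DEFAULT_DE_EFFECTS = {
    "I": {"n": 60, "fold": 2.0},
    "II": {"n": 60, "fold": 2.0},
    "III": {"n": 60, "fold": 2.0},
}


@dataclass
class SyntheticConfig:
    """Knobs for all three generators.  Validated on construction."""

    n_genes: int = 2000
    n_spikeins: int = 3
    spikein_design: tuple[float, ...] = (1.0, 0.25, 0.0625)
    cells_per_condition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS_PER_CONDITION)
    )
    condition_states: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITION_STATES.items()}
    )
    state_scaling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_SCALING)
    )
    de_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DE_EFFECTS.items()}
    )
    n_highvar_genes: int = 12
    highvar_factor: float = 12.0
    n_housekeeping: int = 30
    n_lowquality_cells: int = 0
    lowquality_scale: float = 0.0002
    dropout_rate: float = 0.3
    noise_cv: float = 0.3
    content_jitter_cv: float = 0.15
    spike_fraction: float = 0.05
    read_depth: int = 100_000
    # cell-line panel / patient cohort
    n_cell_lines: int = 300
    module_size: int = 20
    n_decoy_genes: int = 20
    n_patients: int = 100
    ic50_link_strength: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_spikeins", "read_depth", "n_cell_lines",
                     "n_patients", "highvar_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be > 0")
        for name in ("n_highvar_genes", "n_housekeeping", "n_lowquality_cells",
                     "n_decoy_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if self.module_size < 2:
            raise ConfigError("module_size", "must be >= 2")
        if len(self.spikein_design) != self.n_spikeins:
            raise ConfigError("spikein_design",
                              f"needs {self.n_spikeins} entries, got {len(self.spikein_design)}")
        if any(c <= 0 for c in self.spikein_design):
            raise ConfigError("spikein_design", "concentrations must be > 0")
        if not self.cells_per_condition:
            raise ConfigError("cells_per_condition", "must name at least one condition")
        for cond, n in self.cells_per_condition.items():
            if n <= 0:
                raise ConfigError("cells_per_condition", f"count for {cond!r} must be > 0")
            if cond not in self.condition_states:
                raise ConfigError("condition_states", f"no state mix for condition {cond!r}")
        for cond, mix in self.condition_states.items():
            if any(p < 0 or p > 1 for p in mix.values()):
                raise ConfigError("condition_states",
                                  f"probabilities for {cond!r} must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError("condition_states",
                                  f"probabilities for {cond!r} must sum to 1")
            if any(s not in STATES for s in mix):
                raise ConfigError("condition_states", f"unknown state in mix for {cond!r}")
        for state, mult in self.state_scaling.items():
            if mult <= 0:
                raise ConfigError("state_scaling", f"multiplier for {state!r} must be > 0")
        for cl, spec in self.de_effects.items():
            if spec["n"] < 0:
                raise ConfigError("de_effects", f"cluster {cl!r} size must be >= 0")
            if spec["fold"] <= 0:
                raise ConfigError("de_effects", f"cluster {cl!r} fold must be > 0")
        for name in ("dropout_rate",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(name, "must lie in [0, 1]")
        for name in ("noise_cv", "content_jitter_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if not 0 < self.spike_fraction < 1:
            raise ConfigError("spike_fraction", "must lie in (0, 1)")
        if not 0 < self.lowquality_scale < 1:
            raise ConfigError("lowquality_scale", "must lie in (0, 1)")
        if not -1.0 <= self.ic50_link_strength <= 1.0:
            raise ConfigError("ic50_link_strength", "must lie in [-1, 1]")
        total_de = sum(spec["n"] for spec in self.de_effects.values())
        if total_de + self.n_highvar_genes + self.n_housekeeping > self.n_genes:
            raise ConfigError("n_genes", "too small for requested DE/high-variance/"
                                          "housekeeping gene counts")

    @classmethod
    def three_state(cls, cells_per_state: int = 50, **kwargs) -> "SyntheticConfig":
        """A minimal design with one pure condition per state."""
        cpc = {"control": cells_per_state, "CELE16": cells_per_state,
               "COMBO16": cells_per_state}
        return cls(cells_per_condition=cpc, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        d = dict(d)
        if "spikein_design" in d:
            d["spikein_design"] = tuple(d["spikein_design"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spikein_design"] = list(d["spikein_design"])
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside each synthetic dataset."""

    true_state: pd.Series | None = None          # per cell
    true_global_scale: pd.Series | None = None   # per cell, includes jitter
    true_cluster: pd.Series | None = None        # per endogenous gene: I/II/III/none
    true_highvar: pd.Series | None = None        # bool per endogenous gene
    true_module_member: pd.Series | None = None  # bool per panel gene
    true_responder: pd.Series | None = None      # bool per patient
    low_quality_cells: list[str] = field(default_factory=list)
    housekeeping_genes: list[str] = field(default_factory=list)
    spikein_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def ser(x):
            if x is None:
                return None
            return {str(k): (bool(v) if isinstance(v, (bool, np.bool_)) else
                             float(v) if isinstance(v, (int, float, np.floating)) else str(v))
                    for k, v in x.items()}
        return json.dumps({
            "true_state": ser(self.true_state),
            "true_global_scale": ser(self.true_global_scale),
            "true_cluster": ser(self.true_cluster),
            "true_highvar": ser(self.true_highvar),
            "true_module_member": ser(self.true_module_member),
            "true_responder": ser(self.true_responder),
            "low_quality_cells": self.low_quality_cells,
            "housekeeping_genes": self.housekeeping_genes,
            "spikein_ids": self.spikein_ids,
        }, indent=1)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_single_cell_experiment(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a spike-in scRNA-seq experiment.

    Returns
    -------
    tpm : DataFrame, genes (endogenous + spike-in rows) x cells; each column
        sums to 1e6.
    reads : DataFrame indexed by cell with columns ``endogenous_reads`` and
        ``spikein_reads``.
    annotation : DataFrame indexed by cell with a ``condition`` column.
    truth : SyntheticTruth

    Mechanics: per-cell endogenous molecule amounts are the state-scaled
    baseline composition (DE-cluster folds renormalized so the planted global
    scale is exact), multiplied by per-gene log-normal noise, then thinned by
    dropout.  Spike-in amounts are constant across cells up to small
    measurement noise.  TPM is computed from the final absolute amounts, so
    every column sums to 1e6 exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ndig = max(4, len(str(cfg.n_genes)))
    genes = [f"G{i:0{ndig}d}" for i in range(cfg.n_genes)]
    spikes = [f"SPIKE{i + 1}" for i in range(cfg.n_spikeins)]

    baseline = rng.lognormal(mean=2.0, sigma=1.2, size=cfg.n_genes)

    # --- gene role assignment (disjoint) ---------------------------------
    perm = rng.permutation(cfg.n_genes)
    cluster = pd.Series("none", index=genes, name="true_cluster")
    pos = 0
    cluster_idx: dict[str, np.ndarray] = {}
    for cl in ("I", "II", "III"):
        n = int(cfg.de_effects.get(cl, {"n": 0})["n"])
        cluster_idx[cl] = perm[pos:pos + n]
        cluster.iloc[perm[pos:pos + n]] = cl
        pos += n
    remaining = perm[pos:]
    # high-variance genes drawn from the top-baseline eighth of the remaining
    # pool: there dropout is negligible, so the planted variance inflation is
    # visible against the bin background (mirrors highly expressed
    # cell-cycle genes)
    rem_sorted = remaining[np.argsort(baseline[remaining])[::-1]]
    top_pool = rem_sorted[: max(cfg.n_highvar_genes, len(rem_sorted) // 8)]
    hv_idx = rng.choice(top_pool, size=cfg.n_highvar_genes, replace=False)
    highvar = pd.Series(False, index=genes, name="true_highvar")
    highvar.iloc[hv_idx] = True
    # housekeeping: highest-baseline stable genes (no cluster, not high-var)
    hk_pool = np.array([i for i in rem_sorted if i not in set(hv_idx)])
    hk_idx = hk_pool[: cfg.n_housekeeping]
    housekeeping = [genes[i] for i in hk_idx]

    # --- per-state compositions ------------------------------------------
    # de_effects folds are TOTAL fold changes vs control at the cluster's
    # defining conditions, so effects divide out the state's global scale:
    # cluster I drops f-fold under repression and rises f-fold under
    # amplification; cluster II/III hold their absolute level ("no dynamic
    # change") in the state where the rules require it.
    fold = {cl: float(cfg.de_effects.get(cl, {"fold": 1.0})["fold"]) for cl in ("I", "II", "III")}
    s_rep = cfg.state_scaling.get("repression", 1.0)
    s_amp = cfg.state_scaling.get("amplification", 1.0)
    effect = {s: np.ones(cfg.n_genes) for s in STATES}
    effect["repression"][cluster_idx["I"]] = (1.0 / fold["I"]) / s_rep
    effect["repression"][cluster_idx["II"]] = (1.0 / fold["II"]) / s_rep
    effect["repression"][cluster_idx["III"]] = 1.0 / s_rep
    effect["amplification"][cluster_idx["I"]] = fold["I"] / s_amp
    effect["amplification"][cluster_idx["II"]] = 1.0 / s_amp
    effect["amplification"][cluster_idx["III"]] = fold["III"] / s_amp
    base_total = baseline.sum()
    # renormalize so the endogenous total equals scale * base_total exactly
    comp = {s: baseline * effect[s] / (baseline * effect[s]).sum() for s in STATES}

    # --- cells ------------------------------------------------------------
    cell_ids, conditions, states = [], [], []
    for cond in cfg.cells_per_condition:
        n = cfg.cells_per_condition[cond]
        mix = cfg.condition_states[cond]
        mix_states = list(mix)
        drawn = rng.choice(mix_states, size=n, p=[mix[s] for s in mix_states])
        for i in range(n):
            cell_ids.append(f"{cond}_c{i:03d}")
            conditions.append(cond)
            states.append(drawn[i])
    n_cells = len(cell_ids)

    jitter_sigma = _lognormal_sigma(cfg.content_jitter_cv)
    jitter = rng.lognormal(mean=-jitter_sigma ** 2 / 2, sigma=jitter_sigma, size=n_cells)
    scale = np.array([cfg.state_scaling[s] for s in states]) * jitter

    lowq = []
    if cfg.n_lowquality_cells:
        if cfg.n_lowquality_cells > n_cells:
            raise ConfigError("n_lowquality_cells", "exceeds total cell count")
        lowq_pos = rng.choice(n_cells, size=cfg.n_lowquality_cells, replace=False)
        lowq = [cell_ids[i] for i in sorted(lowq_pos)]
    lowq_mask = np.isin(np.arange(n_cells), [cell_ids.index(c) for c in lowq])

    # per-gene dropout probability decays with baseline expression; abundant
    # transcripts (> 3x median baseline) are never missed
    b_med = np.median(baseline)
    p_drop = np.where(
        baseline > 3.0 * b_med, 0.0, cfg.dropout_rate * np.exp(-baseline / b_med)
    )

    sigma = _lognormal_sigma(cfg.noise_cv)

    # endogenous absolute amounts: genes x cells
    mean_amt = np.empty((cfg.n_genes, n_cells))
    for k, s in enumerate(states):
        mean_amt[:, k] = comp[s] * scale[k] * base_total
    noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                          size=(cfg.n_genes, n_cells))
    amt = mean_amt * noise
    # high-variance genes toggle between a high and a low expression level
    # (fold ratio highvar_factor, geometric-mean-preserving so their mean
    # E-value stays in place), mimicking phase-specific cell-cycle expression
    if cfg.n_highvar_genes:
        half = np.sqrt(cfg.highvar_factor)
        on = rng.random((cfg.n_highvar_genes, n_cells)) < 0.5
        amt[hv_idx, :] *= np.where(on, half, 1.0 / half)
    keep = rng.random((cfg.n_genes, n_cells)) >= p_drop[:, None]
    amt *= keep
    amt[:, lowq_mask] *= cfg.lowquality_scale

    # spike-ins: constant absolute amount per cell, small measurement noise
    design = np.asarray(cfg.spikein_design, dtype=float)
    spike_base = design / design.max() * (cfg.spike_fraction * base_total / (design / design.max()).sum())
    spike_noise = rng.lognormal(mean=-0.05 ** 2 / 2, sigma=0.05,
                                size=(cfg.n_spikeins, n_cells))
    spike_amt = spike_base[:, None] * spike_noise

    all_amt = np.vstack([amt, spike_amt])
    totals = all_amt.sum(axis=0)
    tpm = pd.DataFrame(all_amt / totals * 1e6, index=genes + spikes, columns=cell_ids)

    endo_frac = amt.sum(axis=0) / totals
    endo_reads = rng.binomial(cfg.read_depth, endo_frac)
    reads = pd.DataFrame(
        {"endogenous_reads": endo_reads,
         "spikein_reads": cfg.read_depth - endo_reads},
        index=pd.Index(cell_ids, name="cell_id"),
    )

    annotation = pd.DataFrame({"condition": conditions},
                              index=pd.Index(cell_ids, name="cell_id"))
    truth = SyntheticTruth(
        true_state=pd.Series(states, index=cell_ids, name="true_state"),
        true_global_scale=pd.Series(scale, index=cell_ids, name="true_global_scale"),
        true_cluster=cluster,
        true_highvar=highvar,
        low_quality_cells=lowq,
        housekeeping_genes=housekeeping,
        spikein_ids=spikes,
    )
    return tpm, reads, annotation, truth


def _panel_latent(cfg: SyntheticConfig, rng: np.random.Generator, n_samples: int):
    """Shared machinery: module/decoy log2 expression driven by one factor."""
    n_genes = cfg.module_size + cfg.n_decoy_genes
    ndig = max(3, len(str(n_genes)))
    genes = [f"MOD{i:0{ndig}d}" for i in range(cfg.module_size)] + \
            [f"DEC{i:0{ndig}d}" for i in range(cfg.n_decoy_genes)]
    z = rng.normal(size=n_samples)
    base = rng.uniform(4.0, 9.0, size=n_genes)
    total_sd = 0.9  # keeps the p90-p10 range comfortably above log2(3)
    loading = np.zeros(n_genes)
    loading[: cfg.module_size] = rng.uniform(0.6, 0.85, size=cfg.module_size) * total_sd
    resid_sd = np.sqrt(np.maximum(total_sd ** 2 - loading ** 2, 1e-6))
    expr = (base[:, None] + loading[:, None] * z[None, :]
            + rng.normal(size=(n_genes, n_samples)) * resid_sd[:, None])
    member = pd.Series([i < cfg.module_size for i in range(n_genes)], index=genes,
                       name="true_module_member")
    return genes, expr, z, member


def simulate_cell_line_panel(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate a cell-line expression panel with a planted coherent module.

    Returns (log2 expression genes x lines, boolean expressed-call mask,
    IC50 vector, truth).  Module genes share one latent factor; decoys are
    independent.  log2(IC50) correlates with the latent factor at
    ``ic50_link_strength``.
    """
    cfg = config
    if cfg.module_size + cfg.n_decoy_genes > cfg.n_genes:
        raise ConfigError("module_size", "module plus decoys exceed n_genes")
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_cell_lines
    genes, expr, z, member = _panel_latent(cfg, rng, n)
    samples = [f"LINE{i:04d}" for i in range(n)]
    values = pd.DataFrame(expr, index=genes, columns=samples)

    # expressed-call mask: mostly present, a few percent absent at random
    mask = pd.DataFrame(rng.random((len(genes), n)) > 0.05, index=genes, columns=samples)

    s = cfg.ic50_link_strength
    log_ic50 = s * z + np.sqrt(max(1 - s * s, 0.0)) * rng.normal(size=n)
    ic50 = pd.Series(np.exp2(log_ic50), index=samples, name="ic50")

    truth = SyntheticTruth(true_module_member=member)
    return values, mask, ic50, truth


def simulate_patient_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a patient expression matrix and binary responder labels.

    Responder probability decreases with the module latent factor:
    ``P(responder) = logistic(-3 * ic50_link_strength * z)``.
    """
    cfg = config
    if cfg.n_patients < 10:
        raise DataError("patient cohort needs >= 10 patients for stable rank tests")
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_patients
    genes, expr, z, _ = _panel_latent(cfg, rng, n)
    samples = [f"PT{i:03d}" for i in range(n)]
    values = pd.DataFrame(expr, index=genes, columns=samples)
    p_resp = 1.0 / (1.0 + np.exp(3.0 * cfg.ic50_link_strength * z))
    responder = pd.Series(rng.random(n) < p_resp, index=samples, name="responder")
    return values, responder
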