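"""Shared fixtures: synthetic datasets and trained models, built once."""

import numpy as np
import pandas as pd
import pytest

import spikestate as ss

ACCEPT_SEED = 20210617


@pytest.fixture(scope="session")
def sc_data():
    """Three-state experiment (50 cells/state) plus QC'd E-values and the
    differential-gene control-normalized matrix."""
    cfg = ss.SyntheticConfig.three_state(50, seed=ACCEPT_SEED)
    tpm, reads, annotation, truth = ss.simulate_single_cell_experiment(cfg)
    spikeins = ss.SpikeInSet(truth.spikein_ids, list(cfg.spikein_design))
    ev, report = ss.run_qc_pipeline(tpm, spikeins, truth.housekeeping_genes,
                                    annotation)
    genes, norm = ss.select_differential_genes(
        ev.E, annotation, fold=1.5, exclude=spikeins.spikein_ids
    )
    return {
        "config": cfg,
        "tpm": tpm,
        "reads": reads,
        "annotation": annotation,
        "truth": truth,
        "spikeins": spikeins,
        "evalues": ev,
        "qc_report": report,
        "de_genes": genes,
        "norm": norm,
        "labels": ss.reference_state_labels(annotation),
    }


@pytest.fixture(scope="session")
def trained(sc_data):
    """State classifier trained on the session dataset (with MDA)."""
    model, aucs = ss.train_state_classifier(
        sc_data["norm"], sc_data["labels"], ntree=200, seed=ACCEPT_SEED
    )
    states = ss.classify_cells(model, sc_data["norm"])
    return {"model": model, "aucs": aucs, "states": states}


@pytest.fixture(scope="session")
def panel_data():
    cfg = ss.SyntheticConfig(seed=0)
    values, mask, ic50, truth = ss.simulate_cell_line_panel(cfg)
    panel = ss.PanelMatrix(values=values, mask=mask, ic50=ic50)
    return {"config": cfg, "panel": panel, "ic50": ic50, "truth": truth}


def derive_pc1_gates(pca: ss.PcaResult, reference: pd.Series) -> dict:
    """Data-driven PC1 gates from state centroids (the constants in
    DEFAULT_GATES presuppose a particular PCA realization)."""
    pc1 = pca.scores["PC1"]
    ref = reference.loc[pc1.index.intersection(reference.index)]
    rep_cells = ref.index[ref == "repression"]
    amp_cells = ref.index[ref == "amplification"]
    # PC signs are arbitrary: orient so repression sits on the positive side,
    # then place thresholds at inner state quantiles, keeping >= 75% of each
    # state's cells in its own pool
    ctl_cells = ref.index[ref == "control_like"]
    sign = 1.0 if pc1[rep_cells].mean() > pc1[amp_cells].mean() else -1.0
    s = pc1 * sign
    hi = float(s[rep_cells].quantile(0.25)) * sign
    lo = float(s[amp_cells].quantile(0.75)) * sign
    # the control gate uses its own inner band, not the leftovers of the
    # other two states, to keep the pool pure
    c_lo = float(s[ctl_cells].quantile(0.05)) * sign
    c_hi = float(s[ctl_cells].quantile(0.95)) * sign
    gt, lt = (">", "<") if sign > 0 else ("<", ">")
    return {
        "repression": [f"PC1 {gt} {hi:.3f}"],
        "amplification": [f"PC1 {lt} {lo:.3f}"],
        "control_like": [f"PC1 {gt} {c_lo:.3f}", f"PC1 {lt} {c_hi:.3f}"],
    }
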