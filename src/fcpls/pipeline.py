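"""End-to-end study pipeline on an in-memory dataset.

Chains the module stages in the order the analysis prescribes: motion QC
-> band-pass filtering -> per-seed Fisher-z connectivity stacks -> site
harmonization (group preserved) -> within-group FWE masks, union mask,
group GLM with age/sex/education, FDR + cluster thresholding -> brain
matrices from the per-seed difference masks (patients only) -> behavioral
PLS with permutation and bootstrap inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import VoxelIndexMap, build_subregion_masks
from .connectivity import (FCMapStack, bandpass, fisher_z, qc_filter,
                           stack_maps, _correlate_with_seed)
from .group_stats import DifferenceMask, difference_features
from .harmonize import harmonize_stack, site_effect_anova
from .pls import (behavior_loadings, bootstrap_reliability, combined_seed_model,
                  permutation_test, pls_fit, residualize)
from .simulate import SimDataset, ground_truth_recovery

__all__ = ["PipelineResult", "compute_fc_stacks", "run_study"]


@dataclass
class PipelineResult:
    qc_report: list
    subject_table: pd.DataFrame
    stacks: dict                 # seed -> harmonized FCMapStack
    raw_stacks: dict
    site_effect: dict            # seed -> (before_fraction, after_fraction)
    difference: dict             # seed -> DifferenceMask
    retained_seeds: list
    model: object = None
    permutation: object = None
    bootstrap: object = None
    loadings: object = None
    feature_maps: dict = field(default_factory=dict)
    recovery: dict | None = None


def compute_fc_stacks(runs, subject_table, seed_masks, gm, *, tr_seconds=None,
                      f_low=0.01, f_high=0.08):
    """Band-pass everything once, then build one Fisher-z stack per seed."""
    index = VoxelIndexMap(gm.mask)
    rows = {name: {} for name in seed_masks.structures}
    for run in runs:
        tr = tr_seconds or run.tr_seconds
        gm_ts = bandpass(index.vectorize(run.data), tr, f_low, f_high)
        for name in seed_masks.structures:
            sv = seed_masks.structure_mask(name)
            if not sv.any():
                raise ValueError(f"seed {name} is empty on this grid")
            seed_ts = bandpass(run.data[sv].mean(axis=0), tr, f_low, f_high)
            rows[name][run.subject_id] = fisher_z(_correlate_with_seed(seed_ts, gm_ts))
    kept_ids = {run.subject_id for run in runs}
    table = subject_table[subject_table["subject_id"].isin(kept_ids)].reset_index(drop=True)
    return {name: stack_maps(rows[name], table, index, seed_name=name)
            for name in seed_masks.structures}, table


def _covariate_matrix(table):
    return np.column_stack([table["age"].to_numpy(float),
                            table["sex"].to_numpy(float),
                            table["education"].to_numpy(float)])


def run_study(dataset: SimDataset, *, n_perm=200, n_boot=200, seed=0,
              fwe_alpha=0.05, q_fdr=0.05, min_cluster=10, connectivity=18,
              bsr_threshold=3.3, mask_threshold=0.10, combined=True,
              residualize_confounds=(), score_recovery=True) -> PipelineResult:
    """Run the full analysis on a synthetic (or loaded) dataset.

    ``residualize_confounds`` names subject-table columns regressed out of
    both the brain matrices and the behavior matrix before PLS (the
    confound-controlled analysis mode); empty means the plain mode.
    """
    kept_runs, qc_report = qc_filter(dataset.runs)
    if not kept_runs:
        raise RuntimeError("every subject was excluded by motion QC")
    seed_masks = build_subregion_masks(dataset.atlas, threshold=mask_threshold)
    raw_stacks, table = compute_fc_stacks(kept_runs, dataset.subject_table,
                                          seed_masks, dataset.gm)

    stacks, site_effect, difference = {}, {}, {}
    covariates = _covariate_matrix(table)
    for name, stack in raw_stacks.items():
        harmonized, _ = harmonize_stack(stack)
        stacks[name] = harmonized
        if len(set(stack.site.tolist())) > 1:
            before = site_effect_anova(stack.values, stack.site).significant_fraction
            after = site_effect_anova(harmonized.values, harmonized.site).significant_fraction
            site_effect[name] = (before, after)
        difference[name] = difference_features(
            harmonized, covariates, contrast_group="PD", fwe_alpha=fwe_alpha,
            q=q_fdr, min_voxels=min_cluster, connectivity=connectivity)
    retained = [name for name, dm in difference.items() if dm.n_voxels > 0]

    result = PipelineResult(qc_report=qc_report, subject_table=table,
                            stacks=stacks, raw_stacks=raw_stacks,
                            site_effect=site_effect, difference=difference,
                            retained_seeds=retained)
    if not retained:
        return result

    patients = table["group"].to_numpy() == "PD"
    behavior_names = dataset.truth.behavior_names
    Y = table.loc[patients, behavior_names].to_numpy(float)
    x_blocks, feature_maps = {}, {}
    for name in retained:
        imap = VoxelIndexMap(difference[name].mask)
        gm_index = stacks[name].index_map
        # difference-mask voxels are a subset of the GM features (row-major both)
        cols = np.searchsorted(gm_index.flat_indices, imap.flat_indices)
        x_blocks[name] = stacks[name].values[np.ix_(patients, cols)]
        feature_maps[name] = imap

    if residualize_confounds:
        conf = table.loc[patients, list(residualize_confounds)].to_numpy(float)
        Y = residualize(Y, conf)
        x_blocks = {k: residualize(v, conf) for k, v in x_blocks.items()}

    if combined or len(retained) > 1:
        model = combined_seed_model(x_blocks, Y, behavior_names=behavior_names)
    else:
        model = pls_fit(x_blocks[retained[0]], Y, behavior_names=behavior_names)
        model.feature_seed = np.asarray([retained[0]] * model.V.shape[0])
    perm = permutation_test(model, n_perm=n_perm, seed=seed)
    boot = bootstrap_reliability(model, n_boot=n_boot, seed=seed + 1)
    loads = behavior_loadings(model, boot, lv=0)

    result.model, result.permutation, result.bootstrap = model, perm, boot
    result.loadings, result.feature_maps = loads, feature_maps
    if score_recovery:
        result.recovery = ground_truth_recovery(
            model, dataset.truth, feature_maps, bsr=boot.bsr,
            bsr_threshold=bsr_threshold, estimated_seeds=retained)
    return result
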