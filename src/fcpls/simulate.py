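"""Synthetic multi-site two-group cohorts with planted ground truth.

The generator emulates the statistical skeleton of a two-cohort
patient/control resting-state study on a small grid: six probabilistic
seed subregions (left/right CMA, BLA, SFA), seed-driven target regions
whose correlation with the seed is reduced in patients at planted
"difference" voxels, scanner/site effects, head-motion traces with a
configurable fraction of high-motion subjects, and clinical scores driven
by a planted latent brain-behavior link.  Each patient carries a latent
severity: it scales their connectivity reduction and, through the true
behavior salience u*, their symptom scores — the rank-1 cross-block
structure that the PLS analysis is meant to recover.

Time series are Gaussian without hemodynamics or autocorrelation; every
downstream statistic is correlation-based, so this preserves the
quantities under test while keeping runs cheap and exactly reproducible
from one master seed.

Matrix-level helpers (`simulate_pls_matrices`, `simulate_site_stack`)
plant the same structures directly in feature space for calibration
studies that do not need the imaging front end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import GreyMatterMask, ProbabilisticAtlas, VoxelIndexMap, save_volume, load_volume
from .connectivity import BoldRun, load_motion_params

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_dataset",
    "simulate_pls_matrices",
    "simulate_site_stack",
    "ground_truth_recovery",
    "write_fixture",
    "read_fixture",
    "DEFAULT_SEEDS",
    "DEFAULT_PLANTED_SEEDS",
    "NMS_BEHAVIORS",
]

DEFAULT_SEEDS = ["CMA-L", "BLA-L", "SFA-L", "CMA-R", "BLA-R", "SFA-R"]
#: the four subregions with planted group differences (left three + right BLA)
DEFAULT_PLANTED_SEEDS = ["CMA-L", "BLA-L", "SFA-L", "BLA-R"]

#: non-motor-symptom inventory used as behavior column labels; simulated
#: marginals (mean, sd) are schematic, not matched to any clinical table
NMS_BEHAVIORS = {
    "UPSIT": (25.0, 6.0),
    "MoCA": (25.0, 3.0),
    "RBDSQ": (4.0, 2.5),
    "ESS": (5.0, 3.0),
    "QUIP": (0.5, 0.8),
    "GDS15": (2.0, 2.0),
    "STAI_state": (32.0, 8.0),
    "STAI_trait": (36.0, 9.0),
    "UPDRS_I_apathy": (0.5, 0.8),
    "UPDRS_I_pain": (0.6, 0.9),
}

# true behavior salience direction over the inventory (unit-normalized at use)
_U_STAR_BASE = np.array([-1.0, -0.8, 0.9, 0.6, 0.5, 0.7, 0.8, 0.6, 0.5, 0.4])


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the target study at desk scale: two groups (PD/HC)
    at two sites, six seeds with differences planted in four, a patient
    connectivity reduction of 0.5 Fisher-z units, and a strong latent
    link from patient severity to the symptom scores.
    """

    grid_shape: tuple = (16, 16, 16)
    n_per_group_per_site: int = 20
    n_sites: int = 2
    tr_seconds: float = 2.0
    n_frames: int = 160
    seeds: tuple = tuple(DEFAULT_SEEDS)
    planted_seeds: tuple = tuple(DEFAULT_PLANTED_SEEDS)
    r_hc: float = 0.5                 # seed-target correlation in controls
    group_effect_z: float = 0.5       # Fisher-z reduction in patients
    effect_heterogeneity: float = 0.4  # severity scaling of the reduction
    site_offset_z: float = 0.2        # global additive site signal amplitude
    site_scale: float = 1.1           # multiplicative site effect on target z
    behavior_link: float = 1.0        # latent-severity amplitude in scores
    behavior_noise_sd: float = 1.0
    seed_noise_sd: float = 0.3        # within-seed voxel noise around the latent
    high_motion_fraction: float = 0.1
    master_seed: int = 0

    def __post_init__(self):
        if self.n_per_group_per_site < 1 or self.n_sites < 1 or self.n_frames < 8:
            raise ValueError("sizes must be positive (and n_frames >= 8)")
        if not 0 <= self.high_motion_fraction <= 1:
            raise ValueError("high_motion_fraction must lie in [0, 1]")
        if abs(self.r_hc) >= 1:
            raise ValueError("|r_hc| must be < 1")
        if not set(self.planted_seeds) <= set(self.seeds):
            raise ValueError("planted seeds must be a subset of the seed list")


@dataclass
class SimTruth:
    """Planted ground truth for recovery scoring."""

    planted_seeds: list
    difference_masks: dict       # seed -> 3D bool volume of true-difference voxels
    target_masks: dict           # seed -> 3D bool volume of seed-driven voxels
    u_star: np.ndarray           # unit-norm true behavior salience
    behavior_names: list
    severity: np.ndarray         # per-subject latent severity (subject-table order)
    group_effect_z: float

    def v_star(self, seed, index_map: VoxelIndexMap):
        """True voxel salience over the features of ``index_map``.

        Patients' connectivity drops with severity at true-difference
        voxels, so the true salience is a uniform negative weight there
        and zero elsewhere; returned unit-normalized (zero vector if the
        features miss the true mask entirely).
        """
        hits = index_map.vectorize(self.difference_masks[seed].astype(np.int8)) > 0
        v = np.where(hits, -1.0, 0.0)
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v


@dataclass
class SimDataset:
    runs: list
    subject_table: pd.DataFrame
    atlas: ProbabilisticAtlas
    gm: GreyMatterMask
    truth: SimTruth
    config: SimConfig


def _seed_geometry(grid_shape, seeds):
    """Deterministic blob layout: seeds in a bottom layer, two 3x3x2
    target blocks per seed in two upper layers."""
    nx, ny, nz = grid_shape
    if (nx, ny, nz) < (16, 16, 16):
        raise ValueError("grid must be at least 16x16x16 for the default layout")
    seed_centers = {}
    xs, ys = [3, 8, 13], [3, 8]
    for k, name in enumerate(seeds):
        seed_centers[name] = (xs[k % 3], ys[k // 3], 3)
    target_blocks = {}
    tx, ty = [2, 7, 12], [2, 7]
    for k, name in enumerate(seeds):
        x0, y0 = tx[k % 3], ty[k // 3]
        target_blocks[name] = [
            (slice(x0, x0 + 3), slice(y0, y0 + 3), slice(8, 10)),
            (slice(x0, x0 + 3), slice(y0, y0 + 3), slice(11, 13)),
        ]
    return seed_centers, target_blocks


def _build_atlas(config):
    """Gaussian probability profile per structure around its center."""
    centers, _ = _seed_geometry(config.grid_shape, config.seeds)
    grid = np.indices(config.grid_shape, dtype=np.float64)
    prob = []
    for name in config.seeds:
        c = np.asarray(centers[name], dtype=np.float64)
        d_sq = ((grid - c[:, None, None, None]) ** 2).sum(axis=0)
        prob.append(0.9 * np.exp(-d_sq / (2 * 1.0**2)))
    return ProbabilisticAtlas(structures=list(config.seeds), prob=np.stack(prob),
                              voxel_size_mm=(3.0, 3.0, 3.0))


def _behavior_table(severity, config, rng):
    u_star = _U_STAR_BASE / np.linalg.norm(_U_STAR_BASE)
    names = list(NMS_BEHAVIORS)
    b = len(names)
    signal = config.behavior_link * np.sqrt(b) * np.outer(severity, u_star)
    noise = rng.normal(0.0, config.behavior_noise_sd, size=signal.shape)
    raw = signal + noise
    cols = {}
    for j, name in enumerate(names):
        mean, sd = NMS_BEHAVIORS[name]
        cols[name] = mean + sd * raw[:, j] / np.sqrt(1 + config.behavior_link**2 * b * u_star[j]**2)
    return pd.DataFrame(cols), u_star, names


def _motion_trace(n_frames, rng, high_motion):
    trans = np.cumsum(rng.normal(0.0, 0.01, size=(n_frames, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 1.5e-4, size=(n_frames, 3)), axis=0)
    if high_motion:
        # sustained large jumps push mean FD well above the 0.3 mm limit
        trans += np.cumsum(rng.choice([-0.25, 0.25], size=(n_frames, 3)), axis=0) * 0.8
    return np.column_stack([trans, rot])


def simulate_dataset(config: SimConfig | None = None, seed=None) -> SimDataset:
    """Generate a full synthetic cohort; reproducible from the master seed."""
    config = config or SimConfig()
    master = config.master_seed if seed is None else seed
    rng = np.random.default_rng(master)

    atlas = _build_atlas(config)
    centers, target_blocks = _seed_geometry(config.grid_shape, config.seeds)
    gm_vol = np.zeros(config.grid_shape, dtype=bool)
    gm_vol[1:-1, 1:-1, 1:-1] = True
    gm = GreyMatterMask(gm_vol)

    # seed voxel sets from the max-probability rule on the generated atlas
    from .atlas import build_subregion_masks

    labels = build_subregion_masks(atlas, threshold=0.10)
    seed_voxels = {name: labels.structure_mask(name) for name in config.seeds}

    target_masks, difference_masks = {}, {}
    for name in config.seeds:
        tmask = np.zeros(config.grid_shape, dtype=bool)
        for block in target_blocks[name]:
            tmask[block] = True
        target_masks[name] = tmask
        difference_masks[name] = tmask.copy() if name in config.planted_seeds \
            else np.zeros(config.grid_shape, dtype=bool)

    # subject roster: sites x groups, interleaved ids
    rows = []
    for site in range(config.n_sites):
        for group in ("PD", "HC"):
            for k in range(config.n_per_group_per_site):
                rows.append({"group": group, "site": f"site{site + 1}"})
    n = len(rows)
    table = pd.DataFrame(rows)
    table.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(n)])
    table["age"] = np.round(rng.normal(60.0, 9.0, n), 1)
    table["sex"] = rng.integers(0, 2, n)
    table["education"] = np.round(np.clip(rng.normal(12.0, 3.0, n), 5, 22), 1)
    n_high = int(round(config.high_motion_fraction * n))
    high_idx = rng.choice(n, size=n_high, replace=False) if n_high else np.array([], int)
    table["planted_high_motion"] = False
    table.loc[high_idx, "planted_high_motion"] = True

    severity = rng.normal(0.0, 1.0, n)
    table["severity"] = severity
    behaviors, u_star, behavior_names = _behavior_table(severity, config, rng)
    table = pd.concat([table, behaviors], axis=1)

    z_hc = np.arctanh(config.r_hc)
    runs = []
    for i, row in table.iterrows():
        latents = rng.normal(0.0, 1.0, size=(len(config.seeds), config.n_frames))
        data = rng.normal(0.0, 1.0, size=config.grid_shape + (config.n_frames,))
        site_idx = int(row["site"][4:]) - 1
        is_pd = row["group"] == "PD"
        delta_i = config.group_effect_z * (1.0 + config.effect_heterogeneity * row["severity"])
        for s_idx, name in enumerate(config.seeds):
            sv = seed_voxels[name]
            data[sv] = latents[s_idx][None, :] + config.seed_noise_sd * rng.normal(
                0.0, 1.0, size=(int(sv.sum()), config.n_frames))
            z = z_hc
            if is_pd and name in config.planted_seeds:
                z = z_hc - delta_i
            if site_idx > 0:
                z = config.site_scale * z
            r = float(np.clip(np.tanh(z), -0.95, 0.95))
            tmask = target_masks[name]
            nt = int(tmask.sum())
            data[tmask] = (r * latents[s_idx][None, :]
                           + np.sqrt(1 - r**2) * rng.normal(0.0, 1.0, size=(nt, config.n_frames)))
        if site_idx > 0 and config.site_offset_z > 0:
            # scanner-like signal shared by every GM voxel (seeds included):
            # shifts this site's seed-to-voxel correlations additively
            site_signal = rng.normal(0.0, 1.0, config.n_frames)
            data[gm_vol] += config.site_offset_z * site_signal
        motion = _motion_trace(config.n_frames, rng, bool(row["planted_high_motion"]))
        runs.append(BoldRun(data=data, tr_seconds=config.tr_seconds,
                            motion_params=motion, subject_id=row["subject_id"],
                            group=row["group"], site=row["site"]))

    truth = SimTruth(planted_seeds=list(config.planted_seeds),
                     difference_masks=difference_masks, target_masks=target_masks,
                     u_star=u_star, behavior_names=behavior_names,
                     severity=severity, group_effect_z=config.group_effect_z)
    return SimDataset(runs=runs, subject_table=table, atlas=atlas, gm=gm,
                      truth=truth, config=config)


def _default_v_star(n_voxels, rng, sparsity=0.2):
    k = max(1, int(round(sparsity * n_voxels)))
    v = np.zeros(n_voxels)
    idx = rng.choice(n_voxels, size=k, replace=False)
    v[idx] = 1.0
    return v / np.linalg.norm(v)


def _default_u_star(n_behaviors):
    u = _U_STAR_BASE[:n_behaviors] if n_behaviors <= _U_STAR_BASE.size else \
        np.resize(_U_STAR_BASE, n_behaviors)
    return u / np.linalg.norm(u)


def simulate_pls_matrices(n_subjects=80, n_voxels=200, n_behaviors=10,
                          link_strength=0.5, v_star=None, u_star=None,
                          rng=None):
    """Plant a rank-1 latent link directly in feature space.

    A subject-level latent ``g ~ N(0,1)`` loads onto brain features
    through v* and onto behaviors through u*, each scaled so the latent
    explains ``link_strength`` of the total variance of its block
    (0 = null: independent Gaussian noise).  Returns ``(X, Y, truth)``.
    """
    if not 0 <= link_strength < 1:
        raise ValueError("link_strength must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    if v_star is None:
        v_star = _default_v_star(n_voxels, rng)
    if u_star is None:
        u_star = _default_u_star(n_behaviors)
    v_star = np.asarray(v_star, float) / np.linalg.norm(v_star)
    u_star = np.asarray(u_star, float) / np.linalg.norm(u_star)
    g = rng.normal(0.0, 1.0, n_subjects)
    X = rng.normal(0.0, 1.0, (n_subjects, n_voxels))
    Y = rng.normal(0.0, 1.0, (n_subjects, n_behaviors))
    if link_strength > 0:
        a_x = np.sqrt(link_strength * n_voxels / (1 - link_strength))
        a_y = np.sqrt(link_strength * n_behaviors / (1 - link_strength))
        X = X + a_x * np.outer(g, v_star)
        Y = Y + a_y * np.outer(g, u_star)
    return X, Y, {"v_star": v_star, "u_star": u_star, "g": g,
                  "link_strength": link_strength}


def simulate_site_stack(n_per_site=30, n_voxels=100, n_sites=2,
                        site_offset_sd=1.0, site_scale=1.0,
                        group_effect=0.4, noise_sd=0.3, rng=None):
    """Plant additive/multiplicative site effects in a subjects x voxels stack.

    Groups are balanced within site; patients carry a uniform reduction of
    ``group_effect`` at every voxel.  ``site_offset_sd`` is the additive
    site shift in units of the between-subject noise SD, applied to every
    site after the first.  Returns ``(values, sites, groups, truth)``.
    """
    rng = np.random.default_rng(rng)
    baseline = rng.normal(0.3, 0.1, n_voxels)
    values, sites, groups = [], [], []
    for s in range(n_sites):
        for k in range(n_per_site):
            group = "PD" if k < n_per_site // 2 else "HC"
            mu = baseline - (group_effect if group == "PD" else 0.0)
            if s > 0:
                mu = site_scale * mu + site_offset_sd * noise_sd
            values.append(mu + rng.normal(0.0, noise_sd, n_voxels))
            sites.append(f"site{s + 1}")
            groups.append(group)
    return (np.vstack(values), np.asarray(sites), np.asarray(groups),
            {"group_effect": group_effect, "site_offset": site_offset_sd * noise_sd})


def ground_truth_recovery(model, truth: SimTruth, feature_maps,
                          bsr=None, bsr_threshold=3.3,
                          estimated_seeds=None):
    """Score a fitted PLS model against the planted ground truth.

    ``feature_maps`` maps each seed in the model to the VoxelIndexMap of
    its brain-feature voxels (the estimated difference mask), aligned
    with the model's feature order.  Reports |cos| between the first
    estimated saliences and the planted ones, BSR-mask sensitivity and
    specificity against the true salient voxel set, and whether the
    planted seed set was recovered.
    """
    if model.feature_seed is None:
        seeds = list(feature_maps)
        if len(seeds) != 1:
            raise ValueError("model lacks feature_seed labels; pass one seed")
        owner = np.asarray([seeds[0]] * model.V.shape[0])
    else:
        owner = model.feature_seed
    v_true = np.zeros(model.V.shape[0])
    truly_salient = np.zeros(model.V.shape[0], dtype=bool)
    for name, imap in feature_maps.items():
        sel = owner == name
        if int(sel.sum()) != imap.n_voxels:
            raise ValueError(f"feature map mismatch for seed {name}")
        block = truth.v_star(name, imap)
        v_true[sel] = block
        truly_salient[sel] = block != 0
    norm = np.linalg.norm(v_true)
    if norm > 0:
        v_true = v_true / norm

    from .pls import cosine_similarity

    report = {
        "cos_v": abs(cosine_similarity(model.V[:, 0], v_true)) if norm > 0 else np.nan,
        "cos_u": abs(cosine_similarity(model.U[:, 0], truth.u_star)),
        "n_features": int(model.V.shape[0]),
        "n_truly_salient": int(truly_salient.sum()),
    }
    if bsr is not None:
        hit = np.abs(np.asarray(bsr)[:, 0]) >= bsr_threshold
        pos, neg = truly_salient, ~truly_salient
        report["bsr_sensitivity"] = float(hit[pos].mean()) if pos.any() else np.nan
        report["bsr_false_positive_rate"] = float(hit[neg].mean()) if neg.any() else np.nan
    if estimated_seeds is not None:
        report["seeds_recovered_exactly"] = set(estimated_seeds) == set(truth.planted_seeds)
    return report


def write_fixture(dataset: SimDataset, directory):
    """Write a dataset as a file tree (NIfTI runs + text tables + truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "atlas").mkdir(exist_ok=True)
    for k, name in enumerate(dataset.atlas.structures):
        save_volume(directory / "atlas" / f"{_safe(name)}_prob.nii.gz",
                    dataset.atlas.prob[k])
    save_volume(directory / "gm_mask.nii.gz", dataset.gm.mask.astype(np.uint8))
    for run in dataset.runs:
        save_volume(directory / f"{run.subject_id}_bold.nii.gz", run.data)
        np.savetxt(directory / f"{run.subject_id}_motion.txt",
                   run.motion_params, fmt="%.17e")
    dataset.subject_table.to_csv(directory / "participants.tsv", sep="\t", index=False)
    truth = dataset.truth
    payload = {
        "planted_seeds": truth.planted_seeds,
        "behavior_names": truth.behavior_names,
        "u_star": truth.u_star.tolist(),
        "severity": truth.severity.tolist(),
        "group_effect_z": truth.group_effect_z,
        "structures": dataset.atlas.structures,
        "tr_seconds": dataset.config.tr_seconds,
        "master_seed": dataset.config.master_seed,
        "difference_masks": {k: np.argwhere(v).tolist()
                             for k, v in truth.difference_masks.items()},
        "target_masks": {k: np.argwhere(v).tolist()
                         for k, v in truth.target_masks.items()},
        "grid_shape": list(dataset.config.grid_shape),
    }
    (directory / "truth.json").write_text(json.dumps(payload))


def read_fixture(directory) -> SimDataset:
    """Read a dataset written by `write_fixture` (config is reconstructed
    only as far as the truth JSON records it)."""
    directory = Path(directory)
    payload = json.loads((directory / "truth.json").read_text())
    shape = tuple(payload["grid_shape"])
    prob = []
    for name in payload["structures"]:
        vol, _, _ = load_volume(directory / "atlas" / f"{_safe(name)}_prob.nii.gz")
        prob.append(vol)
    atlas = ProbabilisticAtlas(structures=payload["structures"], prob=np.stack(prob),
                               voxel_size_mm=(3.0, 3.0, 3.0))
    gm_vol, _, _ = load_volume(directory / "gm_mask.nii.gz")
    gm = GreyMatterMask(gm_vol > 0)
    table = pd.read_csv(directory / "participants.tsv", sep="\t")
    runs = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        bold_path = directory / f"{sid}_bold.nii.gz"
        motion_path = directory / f"{sid}_motion.txt"
        if not motion_path.exists():
            raise FileNotFoundError(f"missing motion file for subject {sid}: {motion_path}")
        data, _, _ = load_volume(bold_path)
        motion = load_motion_params(motion_path, n_frames=data.shape[-1])
        runs.append(BoldRun(data=data, tr_seconds=payload["tr_seconds"],
                            motion_params=motion, subject_id=sid,
                            group=row["group"], site=row["site"]))

    def unpack(coords_by_seed):
        out = {}
        for name, coords in coords_by_seed.items():
            vol = np.zeros(shape, dtype=bool)
            if coords:
                arr = np.asarray(coords)
                vol[arr[:, 0], arr[:, 1], arr[:, 2]] = True
            out[name] = vol
        return out

    truth = SimTruth(planted_seeds=payload["planted_seeds"],
                     difference_masks=unpack(payload["difference_masks"]),
                     target_masks=unpack(payload["target_masks"]),
                     u_star=np.asarray(payload["u_star"]),
                     behavior_names=payload["behavior_names"],
                     severity=np.asarray(payload["severity"]),
                     group_effect_z=payload["group_effect_z"])
    config = SimConfig(grid_shape=shape, tr_seconds=payload["tr_seconds"],
                       n_frames=runs[0].n_frames if runs else 160,
                       master_seed=payload["master_seed"])
    return SimDataset(runs=runs, subject_table=table, atlas=atlas, gm=gm,
                      truth=truth, config=config)


def _safe(name):
    return name.replace("/", "_").replace(" ", "_")
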