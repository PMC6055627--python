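"""Synthetic grey matter volumes, parcellations, and longitudinal cohorts.

Every downstream stage of the pipeline is testable against these generators
because the ground truth is known by construction:

* ``generate_gm_volume`` plants inter-cube similarity through shared latent
  intensity patterns: each *designated* cube pair receives one common
  27-dimensional standard-normal pattern scaled by ``latent_loading`` on top
  of independent voxel noise.  Only designated pairs carry above-chance
  Pearson similarity; all other pairs are chance-level by construction.
* ``generate_atlas`` produces a contiguous integer parcellation standing in
  for a 90-region anatomical atlas.
* ``generate_cohort`` draws longitudinal neuropsychological raw scores from
  a linear mixed model with a known network-measure-by-time interaction,
  a shared random subject intercept, and per-test MCAR missingness.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cognition import DOMAINS, TESTS
from .extract import CUBE_EDGE, CUBE_VOXELS, cube_low_corners
from .volume import AtlasParcellation, GreyMatterVolume

__all__ = [
    "VolumeSpec",
    "CohortSpec",
    "generate_gm_volume",
    "generate_atlas",
    "generate_cohort",
    "save_cohort",
]

# intensity model constants: densities are centred at _BASE with the latent +
# noise signal scaled by _AMP before clipping to [0, 1]
_BASE = 0.55
_AMP = 0.18


@dataclass
class VolumeSpec:
    """Parameters of one synthetic grey matter volume.

    ``n_latents`` designated cube groups (pairs by default) each share a
    latent intensity pattern of magnitude ``latent_loading``; every in-mask
    voxel additionally carries independent noise of SD ``noise_sd``.
    ``gm_fraction`` controls how much of the cube grid lies inside the grey
    matter mask (out-of-mask voxels are exactly 0).  ``cubes_per_latent``
    > 2 makes each latent a clique of similar cubes, which gives the
    extracted network triangles and hence a defined clustering/gamma —
    pairwise latents alone produce only disjoint dyads.
    """

    shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_latents: int = 8
    latent_loading: float = 0.9
    noise_sd: float = 0.1
    gm_fraction: float = 1.0
    cubes_per_latent: int = 2
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 2 * CUBE_EDGE for s in self.shape):
            raise ValueError(f"shape: each dimension must be >= {2 * CUBE_EDGE}, got {self.shape}")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise ValueError(f"latent_loading: must lie in [0, 1], got {self.latent_loading}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd: must be > 0, got {self.noise_sd}")
        if not 0.0 < self.gm_fraction <= 1.0:
            raise ValueError(f"gm_fraction: must lie in (0, 1], got {self.gm_fraction}")
        if self.n_latents < 0:
            raise ValueError(f"n_latents: must be >= 0, got {self.n_latents}")
        if self.cubes_per_latent < 2:
            raise ValueError(f"cubes_per_latent: must be >= 2, got {self.cubes_per_latent}")


def generate_gm_volume(spec: VolumeSpec) -> tuple[GreyMatterVolume, dict]:
    """Generate a density volume with planted inter-cube similarity.

    Returns the volume and a ground-truth dict recording the designated
    cube pairs (as low-corner voxel coordinates) and the generating
    parameters.  Designated pairs are disjoint: no cube belongs to two
    pairs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    corners = cube_low_corners(shape)
    n_cubes = len(corners)
    n_mask = max(1, int(round(spec.gm_fraction * n_cubes)))
    if spec.cubes_per_latent * spec.n_latents > n_mask:
        raise ValueError(
            f"n_latents: {spec.n_latents} groups need "
            f"{spec.cubes_per_latent * spec.n_latents} cubes but the mask holds only {n_mask}"
        )
    mask_idx = np.arange(n_mask)  # first cubes in canonical (z,y,x) order
    k = spec.cubes_per_latent
    chosen = rng.choice(mask_idx, size=k * spec.n_latents, replace=False)
    groups = chosen.reshape(-1, k)
    pairs = np.array(
        [(g[i], g[j]) for g in groups for i in range(k) for j in range(i + 1, k)], dtype=int
    ).reshape(-1, 2)

    signal = rng.normal(0.0, spec.noise_sd, size=(n_mask, CUBE_VOXELS))
    for g in groups:
        latent = rng.normal(0.0, 1.0, size=CUBE_VOXELS)
        signal[g] += spec.latent_loading * latent

    data = np.zeros(shape, dtype=float)
    values = np.clip(_BASE + _AMP * signal, 0.0, 1.0)
    for row, ci in enumerate(mask_idx):
        x, y, z = corners[ci]
        data[x : x + 3, y : y + 3, z : z + 3] = values[row].reshape(3, 3, 3)

    volume = GreyMatterVolume(data=data, voxel_size_mm=spec.voxel_size_mm)
    truth = {
        "designated_pairs": [[corners[a].tolist(), corners[b].tolist()] for a, b in pairs],
        "designated_pair_indices": pairs.tolist(),
        "designated_groups": groups.tolist(),
        "n_cubes_in_mask": int(n_mask),
        "spec": asdict(spec),
    }
    return volume, truth


def generate_atlas(
    shape: tuple[int, int, int],
    n_regions: int,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> AtlasParcellation:
    """Partition the in-mask voxels into contiguous labelled regions.

    Voxels are ordered lexicographically by (z, y, x) and split into
    ``n_regions`` nearly equal contiguous runs, so every region is a
    non-empty spatially contiguous block and labels 1..n_regions partition
    the mask exactly (label 0 = background).
    """
    shape = tuple(int(s) for s in shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match the volume shape")
    n_in = int(mask.sum())
    if not 1 <= n_regions <= n_in:
        raise ValueError(f"n_regions must lie in [1, {n_in}] (mask voxel count), got {n_regions}")

    xs, ys, zs = np.nonzero(mask)
    order = np.lexsort((xs, ys, zs))  # (z, y, x) lexicographic
    labels = np.zeros(shape, dtype=np.int32)
    for lab, chunk in enumerate(np.array_split(order, n_regions), start=1):
        labels[xs[chunk], ys[chunk], zs[chunk]] = lab
    return AtlasParcellation(labels=labels)


def _per_test_rate(spec_rate, test: str) -> float:
    if spec_rate is None:
        return TESTS[test].missing_rate
    if isinstance(spec_rate, dict):
        return float(spec_rate.get(test, 0.0))
    return float(spec_rate)


def _per_domain(value, default: float = 0.0) -> dict[str, float]:
    if isinstance(value, dict):
        return {d: float(value.get(d, default)) for d in DOMAINS}
    return {d: float(value) for d in DOMAINS}


@dataclass
class CohortSpec:
    """Parameters of one synthetic longitudinal cohort.

    Cognitive trajectories follow a linear mixed model per domain:

        score_ij = beta_baseline * x_i + beta_time * t_ij
                   + beta_interaction * x_i * t_ij
                   + covariate effects + u_i + e_ij

    with x_i the subject's (standardized) network measure, u_i a shared
    random subject intercept, and e_ij the within-subject residual.  Raw
    test scores are the domain trajectory mapped onto each test's raw
    mean/SD (timed tests flipped so that higher raw = worse), plus
    independent test-level noise.

    ``beta_time`` / ``beta_interaction`` / ``beta_baseline`` accept a scalar
    (applied to all domains) or a per-domain dict.  Defaults emulate a
    memory-clinic cohort of cognitively intact older adults followed
    approximately annually for 2.8 +/- 1.0 years, with mild language
    decline over time and a network-by-time effect on language.
    """

    n_subjects: int = 231
    followup_years: tuple[float, float] = (2.80, 1.01)
    visit_jitter_sd: float = 0.1
    visits_per_subject: tuple[float, float] | None = None
    beta_time: float | dict = field(
        default_factory=lambda: {"attention": -0.01, "memory": 0.0, "executive": -0.03, "language": -0.14}
    )
    beta_interaction: float | dict = field(
        default_factory=lambda: {"attention": 0.0, "memory": 0.0, "executive": 0.0, "language": 0.10}
    )
    beta_baseline: float | dict = 0.0
    random_intercept_sd: float = 0.70
    residual_sd: float = 0.71
    test_noise_sd: float = 0.30
    missing_rate_per_test: float | dict | None = None
    age_effect: float = -0.01
    sex_effect: float = 0.10
    education_effect: float = 0.05
    gm_volume_effect: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects: must be >= 2, got {self.n_subjects}")
        for name in ("random_intercept_sd", "residual_sd", "test_noise_sd", "visit_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        for test in TESTS:
            r = _per_test_rate(self.missing_rate_per_test, test)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {test} must lie in [0, 1), got {r}")


def generate_cohort(
    spec: CohortSpec, network_values: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Draw a long-format cohort table from the stated mixed model.

    ``network_values`` supplies one network-measure value per subject; it is
    standardized internally so the planted betas are per predictor SD.
    Returns the table and the ground-truth parameter dict.
    """
    spec.validate()
    x_raw = np.asarray(network_values, dtype=float).ravel()
    if len(x_raw) != spec.n_subjects:
        raise ValueError(
            f"network_values has {len(x_raw)} entries but spec.n_subjects = {spec.n_subjects}"
        )
    sd = x_raw.std(ddof=0)
    x = (x_raw - x_raw.mean()) / sd if sd > 0 else np.zeros_like(x_raw)

    rng = np.random.default_rng(spec.seed)
    b_time = _per_domain(spec.beta_time)
    b_int = _per_domain(spec.beta_interaction)
    b_base = _per_domain(spec.beta_baseline)

    # subject-level covariates
    age = rng.normal(62.95, 9.22, spec.n_subjects)
    sex = (rng.random(spec.n_subjects) < 126 / 231).astype(int)  # 1 = male
    education = np.clip(np.round(rng.normal(5.31, 1.36, spec.n_subjects)), 1, 7).astype(int)
    scanner = (rng.random(spec.n_subjects) < 107 / 231).astype(int)  # 1 = 3T
    tgmv = rng.normal(609.50, 85.01, spec.n_subjects)
    hippo = rng.normal(7.14, 0.94, spec.n_subjects)
    u = rng.normal(0.0, spec.random_intercept_sd, spec.n_subjects)
    cov_shift = (
        spec.age_effect * (age - 62.95)
        + spec.sex_effect * (sex - 0.5)
        + spec.education_effect * (education - 5.31)
        + spec.gm_volume_effect * (tgmv - 609.50)
    )

    rows = []
    for i in range(spec.n_subjects):
        if spec.visits_per_subject is not None:
            vm, vs = spec.visits_per_subject
            n_visits = max(2, int(round(rng.normal(vm, vs))))
        else:
            followup = max(1.0, rng.normal(*spec.followup_years))
            n_visits = int(round(followup)) + 1
        times = [0.0] + [
            max(0.1, k + rng.normal(0.0, spec.visit_jitter_sd)) for k in range(1, n_visits)
        ]
        for visit, t in enumerate(times):
            domain_signal = {}
            for d in DOMAINS:
                eps = rng.normal(0.0, spec.residual_sd)
                domain_signal[d] = (
                    b_base[d] * x[i] + b_time[d] * t + b_int[d] * x[i] * t + cov_shift[i] + u[i] + eps
                )
            row = {
                "subject_id": f"S{i + 1:04d}",
                "visit": visit,
                "time_years": round(t, 3),
                "age": round(age[i], 1),
                "sex": sex[i],
                "education": education[i],
                "scanner": scanner[i],
                "total_gm_vol_ml": round(tgmv[i], 1),
                "hippocampus_ml": round(hippo[i], 2),
                "network_value": x_raw[i],
            }
            for test, td in TESTS.items():
                sig = (
                    np.mean(list(domain_signal.values()))
                    if td.domain == "global"
                    else domain_signal[td.domain]
                )
                sig = sig + rng.normal(0.0, spec.test_noise_sd)
                orient = -1.0 if td.inverted else 1.0
                row[test] = td.mean + td.sd * orient * sig
            rows.append(row)

    table = pd.DataFrame(rows)
    # MCAR missingness, per test
    for test in TESTS:
        rate = _per_test_rate(spec.missing_rate_per_test, test)
        if rate > 0:
            drop = rng.random(len(table)) < rate
            table.loc[drop, test] = np.nan

    truth = {
        "beta_time": b_time,
        "beta_interaction": b_int,
        "beta_baseline": b_base,
        "random_intercept_sd": spec.random_intercept_sd,
        "residual_sd": spec.residual_sd,
        "test_noise_sd": spec.test_noise_sd,
        "predictor_standardized": True,
        "spec": {k: v for k, v in asdict(spec).items()},
    }
    return table, truth


def save_cohort(table: pd.DataFrame, truth: dict, csv_path, truth_path=None) -> None:
    """Write the cohort CSV plus a ground-truth JSON sidecar."""
    table.to_csv(csv_path, index=False)
    if truth_path is None:
        truth_path = str(csv_path).rsplit(".", 1)[0] + "_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
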