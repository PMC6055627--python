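"""Repeatable simulation experiments over the pipeline.

These drive the package's own validation studies: threshold calibration on
planted-signal volumes, and parameter recovery of planted longitudinal
effects.  Each function derives all randomness from one integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cognition import compose_domains, z_transform_baseline
from .extract import extract_network
from .longitudinal import ModelSpec, fit_lmm
from .synthetic import CohortSpec, VolumeSpec, generate_cohort, generate_gm_volume

__all__ = ["spurious_connection_fraction", "interaction_recovery"]


def spurious_connection_fraction(
    seed: int,
    n_volumes: int = 50,
    n_permutations: int = 1000,
    latent_loading: float = 0.9,
    noise_sd: float = 0.1,
    spurious_rate: float = 0.05,
) -> pd.DataFrame:
    """Fraction of retained connections that are chance-only, per volume.

    Generates ``n_volumes`` planted-signal volumes, extracts each network
    with the permutation-calibrated threshold, and reports the fraction of
    surviving connections among non-designated (chance-only) cube pairs
    relative to all surviving connections.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_volumes):
        vspec = VolumeSpec(
            latent_loading=latent_loading, noise_sd=noise_sd, seed=int(rng.integers(2**31))
        )
        vol, truth = generate_gm_volume(vspec)
        res = extract_network(
            vol,
            spurious_rate=spurious_rate,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        coord = {tuple(c): i for i, c in enumerate(res.nodes.cube_index_coords)}
        designated = {
            tuple(sorted((coord[tuple(a)], coord[tuple(b)])))
            for a, b in truth["designated_pairs"]
        }
        adj = np.triu(res.network.adjacency)
        kept = {tuple(sorted(map(int, e))) for e in zip(*np.nonzero(adj))}
        n_kept = len(kept)
        n_spurious = len(kept - designated)
        rows.append(
            {
                "n_connections": n_kept,
                "n_spurious": n_spurious,
                "spurious_fraction": n_spurious / n_kept if n_kept else 0.0,
                "n_designated_recovered": len(kept & designated),
                "n_designated": len(designated),
                "flagged_empty": res.threshold.flagged_empty,
            }
        )
    return pd.DataFrame(rows)


def interaction_recovery(
    seed: int,
    n_seeds: int = 50,
    n_subjects: int = 400,
    beta_interaction: float = 0.10,
    outcome: str = "language",
) -> pd.DataFrame:
    """Recover a planted network-by-time interaction from synthetic cohorts.

    For each replicate: draw per-subject network values, generate a complete
    cohort with the planted interaction on ``outcome``, run the z-scoring
    and composite steps, fit the mixed model, and record the interaction
    estimate with its SE and 95% CI coverage of the truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        x = np.random.default_rng(s).normal(0.0, 1.0, n_subjects)
        spec = CohortSpec(
            n_subjects=n_subjects,
            beta_interaction={outcome: beta_interaction},
            missing_rate_per_test=0.0,
            seed=s,
        )
        table, _ = generate_cohort(spec, x)
        data = compose_domains(z_transform_baseline(table))
        fit = fit_lmm(data, ModelSpec(outcome, "network_value"))
        lo = fit.interaction.beta - 1.96 * fit.interaction.se
        hi = fit.interaction.beta + 1.96 * fit.interaction.se
        rows.append(
            {
                "beta_hat": fit.interaction.beta,
                "se": fit.interaction.se,
                "covers_truth": lo <= beta_interaction <= hi,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
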