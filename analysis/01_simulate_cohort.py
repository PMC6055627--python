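#!/usr/bin/env python
"""Define the synthetic imaging cohort.

Creates the per-subject generative parameters for 200 synthetic grey matter
volumes: each subject gets a different number of latent similarity cliques
and a different latent loading, which makes the extracted network topology
(and hence gamma, lambda, clustering, ...) vary across subjects.  Writes
the subject manifest to results/subjects.csv; volumes themselves are
regenerated from these specs downstream (02), so no image files need to be
stored.  One example volume and the atlas are exported as NIfTI under
scratch/ for inspection.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gmnet.synthetic import VolumeSpec, generate_atlas, generate_gm_volume

ROOT = Path(__file__).resolve().parents[1]
N_SUBJECTS = 200
SHAPE = (15, 15, 15)
N_REGIONS = 12
SEED = 20260901


def subject_manifest(seed: int = SEED, n_subjects: int = N_SUBJECTS) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        rows.append(
            {
                "subject_id": f"S{i + 1:04d}",
                "shape_x": SHAPE[0],
                "shape_y": SHAPE[1],
                "shape_z": SHAPE[2],
                "n_latents": int(rng.integers(4, 10)),
                "cubes_per_latent": 5,
                "latent_loading": round(float(rng.uniform(0.55, 0.9)), 4),
                "gm_fraction": round(float(rng.uniform(0.7, 1.0)), 4),
                "noise_sd": 0.1,
                "volume_seed": int(rng.integers(2**31)),
                "extract_seed": int(rng.integers(2**31)),
            }
        )
    return pd.DataFrame(rows)


def spec_from_row(row) -> VolumeSpec:
    return VolumeSpec(
        shape=(int(row.shape_x), int(row.shape_y), int(row.shape_z)),
        n_latents=int(row.n_latents),
        cubes_per_latent=int(row.cubes_per_latent),
        latent_loading=float(row.latent_loading),
        gm_fraction=float(row.gm_fraction),
        noise_sd=float(row.noise_sd),
        seed=int(row.volume_seed),
    )


def main() -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)

    manifest = subject_manifest()
    manifest.to_csv(ROOT / "results" / "subjects.csv", index=False)
    print(f"wrote manifest for {len(manifest)} subjects -> results/subjects.csv")
    print(
        "latent cliques per subject: "
        f"{manifest.n_latents.min()}-{manifest.n_latents.max()}, "
        f"loadings {manifest.latent_loading.min():.2f}-{manifest.latent_loading.max():.2f}"
    )

    vol, _ = generate_gm_volume(spec_from_row(manifest.iloc[0]))
    vol.save(scratch / "example_volume.nii.gz")
    atlas = generate_atlas(SHAPE, n_regions=N_REGIONS, seed=SEED)
    atlas.save(scratch / "atlas.nii.gz")
    print(f"example volume + {N_REGIONS}-region atlas exported under scratch/")


if __name__ == "__main__":
    main()
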