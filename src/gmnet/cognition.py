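"""Neuropsychological score preprocessing: baseline z-scoring, multiple
imputation, and composite cognitive domain scores.

The battery covers four domains plus a global composite:

* attention — digit span forward, TMT-A, Stroop word, Stroop color
* executive — digit span backward, TMT-B, Stroop color-word
* memory — VAT-A, RAVLT total (5 trials), RAVLT delayed recall
* language — category fluency (animals), VAT naming
* global cognition — all twelve tests plus the MMSE

Timed tests (TMT-A/B and the three Stroop cards) are recorded in seconds, so
higher raw scores mean worse performance; after z-transformation their sign
is flipped so that for every score lower always means worse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.imputation import mice

__all__ = [
    "TESTS",
    "DOMAINS",
    "GLOBAL_TESTS",
    "TestDefinition",
    "ImputedEnsemble",
    "z_transform_baseline",
    "impute_multivariate",
    "compose_domains",
]


@dataclass(frozen=True)
class TestDefinition:
    """One neuropsychological test: its domain, a realistic raw-score
    location/scale (population mean and SD in a memory-clinic cohort of
    cognitively intact older adults), whether higher raw = worse (timed
    tests), and a typical longitudinal missingness rate."""

    domain: str
    mean: float
    sd: float
    inverted: bool = False
    missing_rate: float = 0.0


TESTS: dict[str, TestDefinition] = {
    # attention
    "digit_span_forward": TestDefinition("attention", 12.58, 3.17, False, 0.01),
    "tmt_a": TestDefinition("attention", 39.81, 15.66, True, 0.02),
    "stroop_word": TestDefinition("attention", 46.31, 9.29, True, 0.10),
    "stroop_color": TestDefinition("attention", 62.53, 11.97, True, 0.10),
    # executive
    "digit_span_backward": TestDefinition("executive", 9.25, 2.76, False, 0.01),
    "tmt_b": TestDefinition("executive", 95.63, 44.32, True, 0.03),
    "stroop_color_word": TestDefinition("executive", 107.40, 28.14, True, 0.10),
    # memory
    "vat_a": TestDefinition("memory", 11.56, 1.02, False, 0.04),
    "ravlt_total": TestDefinition("memory", 39.59, 8.81, False, 0.06),
    "ravlt_delayed": TestDefinition("memory", 7.92, 3.04, False, 0.06),
    # language
    "fluency_animals": TestDefinition("language", 22.23, 5.84, False, 0.04),
    "vat_naming": TestDefinition("language", 11.94, 0.34, False, 0.04),
    # global screening instrument (enters only the global composite)
    "mmse": TestDefinition("global", 28.35, 1.56, False, 0.01),
}

DOMAINS: dict[str, list[str]] = {
    "attention": ["digit_span_forward", "tmt_a", "stroop_word", "stroop_color"],
    "executive": ["digit_span_backward", "tmt_b", "stroop_color_word"],
    "memory": ["vat_a", "ravlt_total", "ravlt_delayed"],
    "language": ["fluency_animals", "vat_naming"],
}

#: members of the global cognition composite: every domain test plus the MMSE
GLOBAL_TESTS: list[str] = [t for tests in DOMAINS.values() for t in tests] + ["mmse"]

#: default imputation-model predictors besides the test scores themselves
IMPUTATION_COVARIATES = ["age", "sex", "education", "time_years"]


def _test_columns(table: pd.DataFrame) -> list[str]:
    cols = [t for t in TESTS if t in table.columns]
    if not cols:
        raise ValueError("table contains no recognized neuropsychological test columns")
    return cols


def z_transform_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Z-transform every test against its own baseline distribution.

    For each test, z = (raw - baseline mean) / baseline SD, where the
    reference distribution is the scores observed at the baseline visit
    (time_years == 0).  The same transform is applied to every follow-up
    visit.  Timed tests are then sign-inverted so that lower z always
    reflects worse performance.

    Raises
    ------
    ValueError
        If a test has fewer than 2 observed baseline scores or zero
        baseline variance (the offending test is named).
    """
    if "time_years" not in table.columns:
        raise ValueError("table must contain a 'time_years' column")
    out = table.copy()
    baseline = table.loc[table["time_years"] == 0]
    for test in _test_columns(table):
        base = baseline[test].dropna()
        if len(base) < 2:
            raise ValueError(f"test '{test}' has fewer than 2 observed baseline scores")
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"test '{test}' has zero baseline variance")
        z = (table[test] - mu) / sd
        if TESTS[test].inverted:
            z = -z
        out[test] = z
    return out


@dataclass
class ImputedEnsemble:
    """m completed copies of a cohort table from multiple imputation.

    Observed cells are identical across the m tables; only the originally
    missing cells vary between them.
    """

    datasets: list[pd.DataFrame]
    seed: int
    predictors: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("ensemble must contain at least one dataset")


def impute_multivariate(
    table: pd.DataFrame,
    m: int = 15,
    seed: int = 0,
    n_burn: int = 5,
) -> ImputedEnsemble:
    """Multiply impute missing test scores by chained equations.

    The imputation model for each test uses predictive mean matching on
    age, sex, education, time since baseline, and all other test scores
    (statsmodels MICE).  m completed datasets are drawn after ``n_burn``
    burn-in cycles; observed values are never modified.

    statsmodels' MICE engine draws from NumPy's global random state, so the
    state is saved, seeded from ``seed``, and restored to make the ensemble
    reproducible.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    tests = _test_columns(table)
    for test in tests:
        if table[test].isna().all():
            raise ValueError(f"test '{test}' is entirely missing; cannot impute")
        frac = table[test].isna().mean()
        if frac >= 0.5:
            raise ValueError(f"test '{test}' is {frac:.0%} missing (>= 50%); refusing to impute")

    covs = [c for c in IMPUTATION_COVARIATES if c in table.columns]
    model_cols = tests + covs

    if not table[tests].isna().any().any():
        # nothing to impute: m identical copies
        return ImputedEnsemble([table.copy() for _ in range(m)], seed=seed, predictors=model_cols)

    frame = table[model_cols].astype(float).reset_index(drop=True)
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**32))
        imp = mice.MICEData(frame)
        imp.update_all(n_burn)
        datasets = []
        for _ in range(m):
            imp.update_all(1)
            completed = table.copy()
            completed[tests] = imp.data[tests].to_numpy()
            datasets.append(completed)
    finally:
        np.random.set_state(state)
    return ImputedEnsemble(datasets, seed=seed, predictors=model_cols)


def compose_domains(table: pd.DataFrame) -> pd.DataFrame:
    """Append composite domain z-scores to a (completed, z-scored) table.

    Each domain composite is the unweighted mean of its member tests'
    z-scores; global cognition averages all twelve tests plus the MMSE.
    """
    for test in GLOBAL_TESTS:
        if test not in table.columns:
            raise ValueError(f"required test column '{test}' missing from table")
    unknown = [t for t in table.columns if t in TESTS and t not in GLOBAL_TESTS]
    if unknown:  # pragma: no cover - roster is closed
        raise ValueError(f"unknown tests: {unknown}")
    out = table.copy()
    for domain, members in DOMAINS.items():
        out[domain] = table[members].mean(axis=1)
    out["global_cognition"] = table[GLOBAL_TESTS].mean(axis=1)
    if out[list(DOMAINS) + ["global_cognition"]].isna().any().any():
        warnings.warn("composite scores contain missing values; impute before composing")
    return out
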