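"""Published cohort summaries for three GP-database prediction problems.

Three canonical primary-care prediction cohorts: 30-day mortality after a
GP visit in patients over 60, 30-day readmission after hospital discharge
in adults, and 5-year dementia onset from a first GP visit at ages 50-79.
The record-level data are private; what is public are the cohort summary
counts below.  They serve two purposes here: as the arithmetic ground
truth for prevalence computations, and as the density/prevalence regimes
the synthetic generator is parameterized to emulate.
"""

from __future__ import annotations

REFERENCE_COHORTS = {
    "mortality": {
        "observations": 3_836_184,
        "outcomes": 36_952,
        "printed_prevalence_pct": 1.0,
        "printed_decimals": 0,
        "n_features": 2056,
        "matrix_density_pct": 2.3,
        "mean_features_per_observation": 49.5,
    },
    "readmission": {
        "observations": 206_995,
        "outcomes": 20_202,
        "printed_prevalence_pct": 9.8,
        "printed_decimals": 1,
        "n_features": 2303,
        "matrix_density_pct": 1.9,
        "mean_features_per_observation": 45.2,
    },
    "dementia": {
        "observations": 287_208,
        "outcomes": 4_674,
        "printed_prevalence_pct": 1.6,
        "printed_decimals": 1,
        "n_features": 1748,
        "matrix_density_pct": 1.2,
        "mean_features_per_observation": 21.8,
    },
}


def prevalence_pct(cohort_name: str) -> float:
    """Outcome prevalence (percent) recomputed from the published counts."""
    c = REFERENCE_COHORTS[cohort_name]
    return 100.0 * c["outcomes"] / c["observations"]
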