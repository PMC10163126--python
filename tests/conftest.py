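"""Shared fixtures: calibrated study-scale cohort (session-scoped, fixed
seed) and small handmade records."""

from __future__ import annotations

import pytest

from isletquant import (
    DonorRecord,
    Group,
    GroupProfile,
    InsulinStatus,
    IsletRecord,
    default_study_profile,
    generate_cohort,
    summarize_cohort,
)

#: single fixed seed for the shared study-scale cohort
COHORT_SEED = 20231


@pytest.fixture(scope="session")
def study_profile():
    return default_study_profile()


@pytest.fixture(scope="session")
def study_cohort(study_profile):
    """Full study-scale synthetic cohort (15 ND / 8 AAb+ / 10 T1D donors)."""
    return generate_cohort(study_profile, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def study_summaries(study_cohort):
    return summarize_cohort(study_cohort, min_cells=30)


@pytest.fixture(scope="session")
def small_profile():
    """A light, feasible profile for fast generator tests."""
    return GroupProfile(
        n_donors=4,
        islets_per_donor_mean=60.0,
        islet_area_mean_mm2=0.02,
        p_infiltrated=0.3,
        p_high_given_infiltrated=0.1,
        target_pooled_density=40.0,
        cd8pos_fraction=0.7,
        exocrine_density=50.0,
    )


def make_islet(donor="d1", islet="i1", area=0.02, n_cells=100, cd3=0, cd8pos=0,
               status=InsulinStatus.UNKNOWN):
    return IsletRecord(
        donor_id=donor, islet_id=islet, area_mm2=area, n_cells=n_cells,
        insulin_status=status, cd3_count=cd3, cd3cd8pos_count=cd8pos,
        cd3cd8neg_count=cd3 - cd8pos,
    )


@pytest.fixture
def toy_donor():
    """One ND donor with four analysed islets and exocrine measurements."""
    islets = [
        make_islet(islet="i1", cd3=0),
        make_islet(islet="i2", cd3=2, cd8pos=1),
        make_islet(islet="i3", cd3=7, cd8pos=4),
        make_islet(islet="i4", cd3=0),
    ]
    return DonorRecord(
        donor_id="d1", group=Group.ND, islets=islets,
        total_area_mm2=12.0, endocrine_area_mm2=2.0,
        exocrine_cd3=100, exocrine_cd3cd8pos=70, exocrine_cd3cd8neg=30,
    )
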