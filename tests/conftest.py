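"""Shared fixtures: toy references, tiny pedigrees, small cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitoscan.pedigree import FEMALE, MALE, Individual, Pedigree
from mitoscan.reference import ReferenceSequence, toy_reference
from mitoscan.variants import SNV, Haplotype, Variant


@pytest.fixture(scope="session")
def toy_ref() -> ReferenceSequence:
    # fixed 40-base sequence with known bases for hand-computed examples
    return ReferenceSequence(name="toy", bases="ACGTACGTAAGGCCTTACGTACGTACGTAACCGGTTACGT")


@pytest.fixture(scope="session")
def toy_ref_2k() -> ReferenceSequence:
    return toy_reference(length=2000, seed=7)


def snv(pos: int, ref: str, alt: str) -> Variant:
    return Variant(pos, SNV, ref, alt)


@pytest.fixture(scope="session")
def rcrs_like():
    from mitoscan.reference import load_packaged_reference

    return load_packaged_reference()


def make_haplotypes(varsets: dict[str, frozenset], counts: dict[str, int] | None = None):
    """Haplotype list from {id: variant frozenset} (default count 1)."""
    counts = counts or {}
    return [
        Haplotype(hid, frozenset(vs), carrier_count=counts.get(hid, 1))
        for hid, vs in varsets.items()
    ]


def trio_pedigree() -> Pedigree:
    return Pedigree([
        Individual("dad", "f1", MALE, None, None, cohort_member=True),
        Individual("mom", "f1", FEMALE, None, None, cohort_member=True),
        Individual("kid", "f1", MALE, "dad", "mom", cohort_member=True),
    ])


def cousins_pedigree() -> Pedigree:
    """8 members: grandparents, two sibling mothers + husbands, two first cousins."""
    return Pedigree([
        Individual("gf", "f1", MALE, None, None),
        Individual("gm", "f1", FEMALE, None, None),
        Individual("m1", "f1", FEMALE, "gf", "gm"),
        Individual("m2", "f1", FEMALE, "gf", "gm"),
        Individual("h1", "f1", MALE, None, None),
        Individual("h2", "f1", MALE, None, None),
        Individual("c1", "f1", MALE, "h1", "m1", cohort_member=True),
        Individual("c2", "f1", FEMALE, "h2", "m2", cohort_member=True),
    ])


def tiny_subjects(assignments: dict[str, str], phenotypes: dict[str, float],
                  **covariates) -> pd.DataFrame:
    """Subjects frame for treescan tests (no covariates unless given)."""
    ids = sorted(assignments)
    df = pd.DataFrame({
        "subject_id": ids,
        "haplotype": [assignments[s] for s in ids],
        "ad_status": [phenotypes.get(s, np.nan) for s in ids],
    })
    for name, mapping in covariates.items():
        df[name] = [mapping.get(s, np.nan) for s in ids]
    return df
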