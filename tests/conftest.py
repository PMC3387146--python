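"""Shared fixtures: hand-built QC read sets, toy references, small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ampliclass.qc import AmpliconRead, QcPolicy
from ampliclass.synthetic import synthetic_reference

FWD = "CCTACGGGAGGCAGCAG"    # 357F
REV = "CCGTCAATTCMTTTRAGT"   # 926R (M={A,C}, R={A,G})
REV_INSTANCE = "CCGTCAATTCATTTAAGT"  # one concrete expansion of REV

BARCODES = {"AAAA": "S1", "CCCC": "S2"}


def _random_template(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_read(rid: str, template: str, barcode: str = "AAAA",
              rev: str = REV_INSTANCE, qual: int = 30) -> AmpliconRead:
    bases = barcode + FWD + template + rev
    return AmpliconRead(id=rid, bases=bases,
                        qualities=np.full(len(bases), qual, dtype=int))


@pytest.fixture()
def qc_policy() -> QcPolicy:
    return QcPolicy(forward_primer=FWD, reverse_primer=REV,
                    barcode_map=dict(BARCODES))


@pytest.fixture()
def designed_defect_reads() -> tuple[list[AmpliconRead], dict[str, str]]:
    """Ten reads, six violating exactly one QC rule each; four clean passes.

    One passing read carries exactly 4 reverse-primer mismatches (the rule
    rejects only >4).  Returns (reads, expected) where expected maps read id
    to 'pass' or the rejection reason.
    """
    from ampliclass.synthetic import designed_defect_fixture

    reads, _, expected = designed_defect_fixture()
    return reads, expected


@pytest.fixture(scope="session")
def five_genus_reference():
    return synthetic_reference(n_genera=5, seqs_per_genus=3, length=900, seed=7)


@pytest.fixture(scope="session")
def signal_cohort():
    """Planted-signal cohort at the headline conditions (10 taxa, |lfc|=1.5)."""
    from ampliclass import CohortSpec, default_planted, normalize, simulate_cohort

    spec = CohortSpec(n_per_class={"control": 60, "IBD": 60}, n_taxa=200,
                      planted_taxa=default_planted(10, 1.5), seed=1)
    table, labels, truth = simulate_cohort(spec)
    return normalize(table), labels, truth
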