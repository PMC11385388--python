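"""Shared fixtures: one synthetic world, built once per session.

The default cohort (4 genera x 3 species x 4 genomes, 100 kb backbones,
800 database records, seed 1) is the stated world for the end-to-end
checks; cheaper tests build their own miniature inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from strep16s.clustering import run_sweep
from strep16s.genomes import GenomeProfile, apply_genome_filter, extract_16s
from strep16s.sequence_qc import QcConfig, run_qc
from strep16s.simulate import SimConfig, generate_cohort
from strep16s.taxonomy import NomenclatureTable, validate_records

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(SimConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def qc_result(cohort):
    """(survivors, member_map, report) of the default QC run on the cohort."""
    return run_qc(cohort.db_records, QcConfig(), log=None)


@pytest.fixture(scope="session")
def validations(cohort):
    table = NomenclatureTable.from_frame(cohort.lpsn)
    names = dict(zip(cohort.names.name, cohort.names.taxid))
    return validate_records(cohort.db_records, table, names)


@pytest.fixture(scope="session")
def taxid_map(validations):
    return {
        row.id: (None if np.isnan(row.taxid) else int(row.taxid))
        for row in validations.itertuples(index=False)
    }


@pytest.fixture(scope="session")
def sweep(qc_result):
    """Full 98-100% threshold sweep over the QC survivors (slow; shared)."""
    survivors, _, _ = qc_result
    return run_sweep(survivors)


@pytest.fixture(scope="session")
def genome_profiles(cohort):
    """Profiles extracted back out of the in-memory GenBank records."""
    profiles = []
    for rec, g in zip(cohort.to_genbank_records(), cohort.genomes):
        profiles.append(
            GenomeProfile(
                accession=g.accession,
                species_label=g.species_name,
                copies=extract_16s(rec),
            )
        )
    return profiles


@pytest.fixture(scope="session")
def retained_profiles(genome_profiles):
    return apply_genome_filter(list(genome_profiles))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
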