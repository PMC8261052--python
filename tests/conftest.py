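import pandas as pd
import pytest

from merscreen.inventory import GenomeInventory
from merscreen.synthetic_data import SimulationConfig, fixture_tables, simulate_cohort


@pytest.fixture(scope="session")
def fixture_inventories():
    """Inventories reproducing the published marginal tables."""
    inventories, totals = fixture_tables()
    return inventories, totals


@pytest.fixture(scope="session")
def dense_cohort():
    """A marker-dense synthetic cohort exercising every verdict class."""
    config = SimulationConfig(
        seed=11,
        p_merA=0.5,
        p_merB_given_merA=0.4,
        p_merB_given_no_merA=0.2,
        frac_reject=0.05,
        frac_605_variant=0.05,
        frac_99ser=0.05,
        frac_117alt=0.2,
        indel_rate=0.1,
    )
    return simulate_cohort(config)


def cohort_meta(cohort) -> pd.DataFrame:
    """Protein-level metadata plus one row per homolog-free genome."""
    proteins = cohort.protein_meta.merge(cohort.genome_meta, on="genome_id")
    return pd.concat([proteins, cohort.genome_meta], ignore_index=True).fillna("")


def truth_inventories(cohort) -> list[GenomeInventory]:
    """Genome inventories rebuilt directly from the planted truth."""
    by_genome = {
        r["genome_id"]: r for r in cohort.genome_meta.to_dict("records")
    }
    out = []
    for gid, meta in by_genome.items():
        out.append(
            GenomeInventory(
                genome_id=gid,
                domain=meta["domain"],
                phylum=meta["phylum"],
                class_=meta["class"] or None,
                deposit_type=meta["deposit_type"],
                merA_count=cohort.truth.merA_counts[gid],
                merB_count=cohort.truth.merB_counts[gid],
                merB_like_counts=cohort.truth.merB_like_counts[gid],
            )
        )
    return out
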