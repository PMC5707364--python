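import numpy as np
import pandas as pd
import pytest

from tmpop.evidence import EvidenceParams, emit_site_evidence
from tmpop.genome import GeneticMap, build_genome
from tmpop.pedigree import PedigreeConfig, plant_mutations, simulate_pedigree


@pytest.fixture(scope="session")
def small_genome():
    """Two 1-Mb chromosomes with genes, centromeres and TEs."""
    return build_genome([1_000_000, 1_000_000], seed=1)


@pytest.fixture(scope="session")
def small_map(small_genome):
    return GeneticMap.uniform(small_genome.chrom_lengths, 150.0)


@pytest.fixture(scope="session")
def truth6(small_genome, small_map):
    """Six BC2F7 lines with planted mutations (mu = 1e-6), no noise sources."""
    t = simulate_pedigree(small_genome, small_map, PedigreeConfig(seed=3), 6)
    plant_mutations(t, small_genome, 1e-6, seed=4)
    return t


@pytest.fixture(scope="session")
def noiseless_evidence(truth6, small_genome):
    return emit_site_evidence(
        truth6,
        small_genome,
        EvidenceParams(depth_model="fixed", error_rate=0.0, n_background_sites=500),
        seed=6,
    )


def make_evidence_df(sites, lines):
    """Hand-build a SiteEvidenceTable DataFrame.

    ``sites``: list of dicts with chrom,pos,ref,alt,site_mq and per-line
    (gt, ad_ref, ad_alt, hq_ref, hq_alt, mq, pp) tuples under the line id.
    """
    rows = []
    for s in sites:
        row = {k: s[k] for k in ("chrom", "pos", "ref", "alt", "site_mq")}
        for lid in lines:
            gt, ar, aa, hr, ha, mq, pp = s[lid]
            row.update(
                {
                    f"{lid}.gt": gt,
                    f"{lid}.ad_ref": ar,
                    f"{lid}.ad_alt": aa,
                    f"{lid}.hq_ref": hr,
                    f"{lid}.hq_alt": ha,
                    f"{lid}.mq": mq,
                    f"{lid}.pp": pp,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
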