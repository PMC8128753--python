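import numpy as np
import pandas as pd
import pytest

from exonarh import ProbeAnnotation, ProbeMatrix, SimParams, simulate_experiment


def make_annotation(rows):
    """Build a ProbeAnnotation from (probe, gene, exon, chrom, start, end, gc, bg) tuples."""
    return ProbeAnnotation(
        pd.DataFrame(
            rows,
            columns=[
                "probe_id", "gene_id", "exon_id", "chrom",
                "exon_start", "exon_end", "gc_count", "is_background",
            ],
        )
    )


def make_matrix(values, probe_ids, samples, condition_of):
    return ProbeMatrix(
        values=pd.DataFrame(
            np.asarray(values, dtype=float), index=probe_ids, columns=samples
        ),
        condition_of=condition_of,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 200-gene spiked experiment shared across tests."""
    params = SimParams(n_genes=200, frac_de=0.1, frac_as=0.1, seed=11)
    return simulate_experiment(params)


@pytest.fixture
def two_cond_map():
    return {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
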