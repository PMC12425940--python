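import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cubkit.genetic_code import ALL_CODONS, standard_code
from cubkit.seqio import CodonCountTable, count_codons, validate_cds
from cubkit.synthetic_data import SimulationParams, generate_gene_set

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code():
    return standard_code()


def make_count_table(rng, code, mean_per_codon=5.0, gene_id="g"):
    """Random Poisson counts over sense codons, guaranteeing every amino
    acid is observed at least twice (so ENC is defined)."""
    counts = dict.fromkeys(ALL_CODONS, 0)
    for c in code.sense_codons:
        counts[c] = int(rng.poisson(mean_per_codon))
    for fam in code.families.values():
        total = sum(counts[c] for c in fam)
        if total < 2:
            counts[fam[0]] += 2 - total
    return CodonCountTable(
        gene_id=gene_id, counts=counts,
        total_codons=sum(counts[c] for c in code.sense_codons),
    )


@pytest.fixture
def random_tables(code):
    rng = np.random.default_rng(20240915)
    return [make_count_table(rng, code, gene_id=f"g{i}") for i in range(25)]


@pytest.fixture(scope="session")
def mixed_set(code):
    """A small mixed-mode synthetic gene set with its validated counts."""
    params = SimulationParams(n_genes=40, seed=11, min_codons=100,
                              length_log_mean=float(np.log(150.0)),
                              length_log_sigma=0.25)
    records, truth = generate_gene_set(params, code)
    validated = [validate_cds(r, code=code) for r in records]
    tables = {v.gene_id: count_codons(v) for v in validated}
    return {"records": records, "truth": truth, "validated": validated,
            "tables": tables}


def table_to_sequence(table: CodonCountTable) -> str:
    """Deterministic raw CDS string realizing a count table."""
    return "".join(c * n for c, n in sorted(table.counts.items()))
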