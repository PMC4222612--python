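import pytest

from rbpscreen import registry, simulate


@pytest.fixture
def study_scale_domains():
    """143 domain assignments over 16 families: 136 unique proteins, 7 of them
    multi-family; 47 essential / 86 non-essential / 3 unknown."""
    ess = [registry.Essentiality.ESSENTIAL] * 47
    non = [registry.Essentiality.NONESSENTIAL] * 86
    unk = [registry.Essentiality.UNKNOWN] * 3
    statuses = ess + non + unk
    families = [f"fam{i:02d}" for i in range(16)]
    assignments = []
    for i, status in enumerate(statuses):
        pid = f"prot{i:03d}"
        assignments.append(
            registry.DomainAssignment(pid, families[i % 16], f"PF{i:05d}", status)
        )
    # seven proteins carry a second domain from a different family
    for i in range(7):
        pid = f"prot{i:03d}"
        assignments.append(
            registry.DomainAssignment(pid, families[(i + 8) % 16], f"PF9{i:04d}", statuses[i])
        )
    assert len(assignments) == 143
    return assignments


@pytest.fixture
def spike_in_expression():
    """2000-gene table with 50 up-regulated targets (log2 effect 2, sd 0.2, 3 reps)."""
    ids = simulate.gene_ids(2000)
    spec = simulate.RegulonSpec("spike", frozenset(ids[:50]), direction="up")
    table, truth = simulate.gen_expression(spec, n_genes=2000, noise_sd=0.2, seed=101)
    return table, truth


@pytest.fixture
def null_expression():
    spec = simulate.RegulonSpec("null", frozenset(), n_replicates=3)
    table, _ = simulate.gen_expression(spec, n_genes=2000, noise_sd=0.2, seed=55)
    return table
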