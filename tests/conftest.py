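import warnings

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from kleptopop import (
    Dataset,
    IndividualRecord,
    LocusDef,
    MultisetGenotype,
    call_biotypes,
    split_isoloci,
)
from kleptopop.simulator import default_rule_table, preset, simulate


@pytest.fixture
def panel():
    """Small three-locus panel: one J-only, one split, one non-discriminating."""
    return [
        LocusDef("Ja", 4, j_range=(100, 140)),
        LocusDef("Sp", 4, j_range=(133, 193), l_range=(197, 260)),
        LocusDef("Nd", 4, u_range=(80, 120)),
    ]


def make_individual(ind_id, site, cells, panel):
    genotypes = {
        name: MultisetGenotype(name, alleles)
        for name, alleles in cells.items()
        if alleles
    }
    return IndividualRecord(id=ind_id, site=site, genotypes=genotypes)


@pytest.fixture
def make_dataset(panel):
    def _make(rows):
        inds = [make_individual(i, s, cells, panel) for i, s, cells in rows]
        ds = Dataset(individuals=inds, loci=panel)
        split_isoloci(ds)
        call_biotypes(ds)
        return ds

    return _make


def triploid(ind_id, site="S1", l_alleles=(197, 201), j_allele=137):
    """An LLJ individual on the small panel."""
    return (
        ind_id,
        site,
        {"Ja": (104,), "Sp": tuple(sorted((j_allele,) + tuple(l_alleles))), "Nd": (96, 100)},
    )


def diploid(ind_id, site="S1", l_allele=197, j_allele=137):
    return (ind_id, site, {"Ja": (104,), "Sp": (j_allele, l_allele), "Nd": (96,)})


@pytest.fixture(scope="session")
def mixed_run():
    """One mixed-sympatry simulation with the full partition pipeline run."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset, truth = simulate(preset("mixed_sympatry", seed=11))
        split_isoloci(dataset)
        call_biotypes(dataset)
        from kleptopop import assign_groups

        assign_groups(dataset, default_rule_table())
    return dataset, truth


@pytest.fixture(scope="session")
def clonal_run():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset, truth = simulate(preset("clonal_only", seed=11))
        split_isoloci(dataset)
        call_biotypes(dataset)
    return dataset, truth
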