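import pytest

from synorth import fixtures
from synorth.genome_model import GeneRecord, GenomeTable
from synorth.species_tree import SpeciesTree
from synorth.synthetic_evolution import simulate


def build_table(species: str, chrom_specs: dict, coords: bool = False,
                spacing: int = 1_000_000, width: int = 1_000) -> GenomeTable:
    """chrom_specs: {chrom: [gene spec]} where a gene spec is an id string
    or a (id, strand[, biotype[, family]]) tuple."""
    table = GenomeTable(species)
    for chrom, specs in chrom_specs.items():
        for i, spec in enumerate(specs):
            if isinstance(spec, str):
                spec = (spec, "+")
            gid, strand = spec[0], spec[1]
            biotype = spec[2] if len(spec) > 2 else "protein_coding"
            family = spec[3] if len(spec) > 3 else gid
            table.add(GeneRecord(
                gene_id=gid, species=species, chrom=chrom, order_index=i,
                start=i * spacing if coords else None,
                end=i * spacing + width if coords else None,
                strand=strand, family=family, biotype=biotype))
    return table


@pytest.fixture(scope="session")
def vertebrate_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(fixtures.species_tree_newick())


@pytest.fixture(scope="session")
def h1_dataset():
    """The packaged synthetic vertebrate panel (seed fixed for the session)."""
    return simulate(fixtures.sim_config(), seed=1)
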