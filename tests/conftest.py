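import pytest

from duproot import (
    DuplicationEvent,
    GeneTree,
    MappingRule,
    SpeciesTree,
)

RULE = MappingRule.delimiter("_")


@pytest.fixture(scope="session")
def st4():
    """The minimal binary species tree: AB|CD over {A, B, C, D}."""
    return SpeciesTree.from_newick("((A,B),(C,D));")


@pytest.fixture(scope="session")
def st_mammals():
    """Four-taxon tree with elephant+dog sister to bird+fish."""
    return SpeciesTree.from_newick("((elephant,dog),(bird,fish));")


def gene_tree(newick: str, st: SpeciesTree = None, tree_id: str = "gt") -> GeneTree:
    return GeneTree.from_newick(
        newick, RULE, tree_id=tree_id, known_species=st.species if st else None
    )


def event_on(st: SpeciesTree, species, tree_id="t", node_id=0, observed=None) -> DuplicationEvent:
    """Construct a duplication event for the block given by ``species``."""
    block = frozenset(species)
    return DuplicationEvent(
        gene_tree_id=tree_id,
        node_id=node_id,
        branch_id=st.branch_of_block(block),
        dup_block=block,
        species_observed=frozenset(observed) if observed is not None else block,
    )


@pytest.fixture(scope="session")
def mammal_events(st_mammals):
    """One duplication shared by elephant+dog, two by elephant+dog+bird."""
    ed = {"elephant", "dog"}
    edb = {"elephant", "dog", "bird"}
    return [
        event_on(st_mammals, ed, node_id=0),
        event_on(st_mammals, edb, node_id=1),
        event_on(st_mammals, edb, node_id=2),
    ]
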