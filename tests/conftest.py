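"""Shared fixtures: a small synthetic community reused across test modules."""
from __future__ import annotations

from dataclasses import dataclass

import pytest

from uridiv import synthetic
from uridiv.io_formats import FORWARD_PRIMERS, PrimerSpec, TaxonomyTree


@dataclass(frozen=True)
class CommunityKit:
    """A 10-member community plus a 4-member reagent (control) community,
    all templates pairwise >= 5% divergent, with a toy taxonomy."""

    primer: PrimerSpec
    community: synthetic.CommunityModel
    control: synthetic.CommunityModel
    tree: TaxonomyTree
    templates: list[tuple[str, str, str]]


@pytest.fixture(scope="session")
def v1v2_primer() -> PrimerSpec:
    return FORWARD_PRIMERS[0]


@pytest.fixture(scope="session")
def v6_primer() -> PrimerSpec:
    return FORWARD_PRIMERS[1]


@pytest.fixture(scope="session")
def kit(v1v2_primer) -> CommunityKit:
    seqs = synthetic.generate_templates(14, 300, 0.05, seed=11)
    comm_t = tuple((f"t{i}", s, f"t{i}") for i, s in enumerate(seqs[:10]))
    ctrl_t = tuple((f"c{i}", s, f"c{i}") for i, s in enumerate(seqs[10:]))
    tree = synthetic.toy_taxonomy([t[0] for t in comm_t + ctrl_t])
    community = synthetic.CommunityModel(
        comm_t, tuple(synthetic.sample_abundances(10, 0.5)), "V1V2"
    )
    control = synthetic.CommunityModel(
        ctrl_t, tuple(synthetic.sample_abundances(4, 0.5)), "V1V2"
    )
    return CommunityKit(
        primer=v1v2_primer,
        community=community,
        control=control,
        tree=tree,
        templates=list(comm_t + ctrl_t),
    )
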