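"""Shared fixtures: the seeded synthetic world and pipeline products.

Session-scoped so the expensive steps (clustering, recovery, carving,
expansion) run once for the whole suite.
"""

from __future__ import annotations

import random

import pytest

from panflux import pipeline
from panflux.gpr import Gpr
from panflux.model import Metabolite, Model, Reaction, parse_formula
from panflux.synthetic import generate_world


@pytest.fixture(scope="session")
def world():
    return generate_world(seed=42, n_strains=20, n_groups=3)


@pytest.fixture(scope="session")
def recon_result(world):
    return pipeline.recon(
        world.records, world.universe, genomes=world.genomes,
        gffs=world.gffs, completeness=world.completeness,
        reference=world.reference,
        reference_proteome=world.reference_proteome)


@pytest.fixture(scope="session")
def deck(world, recon_result):
    return pipeline.derive_all(recon_result.pan, recon_result.pam,
                               [world.media["M1"]])


def random_gpr(rng: random.Random, genes: list[str], depth: int = 4) -> Gpr:
    """Random GPR tree over the given gene pool."""
    if depth == 0 or rng.random() < 0.35:
        return Gpr.leaf(rng.choice(genes))
    op = rng.choice([Gpr.and_, Gpr.or_])
    children = [random_gpr(rng, genes, depth - 1)
                for _ in range(rng.randint(2, 3))]
    return op(children)


def linear_chain_model() -> Model:
    """EX_A -> A -> B -> DM_B with unit stoichiometry; objective CONV."""
    m = Model("chain")
    m.add_metabolite(Metabolite("A_c", compartment="c"))
    m.add_metabolite(Metabolite("B_c", compartment="c"))
    m.add_reaction(Reaction("EX_A_c", stoichiometry={"A_c": -1},
                            lower_bound=-10, upper_bound=1000))
    m.add_reaction(Reaction("CONV", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0))
    m.add_reaction(Reaction("DM_B_c", stoichiometry={"B_c": -1},
                            lower_bound=0))
    m.objective = "CONV"
    return m


def toy_metabolite(mid: str, formula: str = "", charge: int | None = None
                   ) -> Metabolite:
    comp = mid.rsplit("_", 1)[-1]
    return Metabolite(mid, formula=parse_formula(formula), charge=charge,
                      compartment=comp)
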