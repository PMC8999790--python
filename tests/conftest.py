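"""Shared fixtures: coarse dimer templates, motion fixtures, assay parameters."""

import numpy as np
import pytest

from gce_dynamics.synthetic_data import (
    DomainDefinition,
    MotionSpec,
    build_dimer_template,
    simulate_trajectory,
)

#: Published catalytic parameters of the cyclase variants (Vmax in
#: pmol/(ug*min), EC50 and KM in mM, kcat in 1/s, efficiency in 1e3/(M*s)).
CATALYTIC_TABLE = {
    "WT GC-E + GCAP1": dict(vmax=11.33, ec50=0.37, km=0.34, kcat=0.8, eff_e3=2.35, h=2.07),
    "V902L + GCAP1": dict(vmax=9.0, ec50=0.20, km=0.20, kcat=0.8, eff_e3=4.0, h=1.75),
    "V902L + GCAP2": dict(vmax=7.32, ec50=0.36, km=0.31, kcat=0.7, eff_e3=2.2, h=1.76),
    "V902L no GCAPs": dict(vmax=7.36, ec50=0.37, km=0.34, kcat=0.7, eff_e3=2.1, h=1.58),
}

#: 20 substrate concentrations spanning the assayed 0.05-4 mM range,
#: plus the zero point.
SUBSTRATE_GRID = tuple([0.0] + list(np.geomspace(0.05, 4.0, 20)))


@pytest.fixture(scope="session")
def domains() -> DomainDefinition:
    return DomainDefinition()


@pytest.fixture(scope="session")
def template(domains):
    return build_dimer_template(domains)


@pytest.fixture(scope="session")
def wt_like_trajectory(template, domains):
    """Jitter-only homodimer trajectory (wild-type-like control)."""
    motion = MotionSpec(seed=11, jitter_sd=0.3)
    return simulate_trajectory(template, domains, motion, 30)


@pytest.fixture(scope="session")
def mutant_like_trajectory(template, domains):
    """20-degree catalytic-domain swing plus a displaced Lys1051 (mutant-like)."""
    motion = MotionSpec(
        seed=12,
        jitter_sd=0.3,
        swing_amplitude=20.0,
        displaced_residue=("B", 1051, (6.0, 4.0, 3.0)),
    )
    return simulate_trajectory(template, domains, motion, 30)


@pytest.fixture(scope="session")
def all_residue_pairs(template):
    """(chain, residue) pairs for every residue of the dimer template."""
    return [
        (chain, num)
        for chain in template.chains
        for num in sorted({a.residue_number for a in template.atoms if a.chain_id == chain})
    ]
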