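"""Shared fixtures: small synthetic structures and cross-link tables."""

import numpy as np
import pytest

from igxlink import (
    Chain,
    CrossLink,
    CrossLinkTable,
    SimSpec,
    StructureModel,
    make_multidomain_chain,
    make_ring_oligomer,
    simulate_crosslinks,
)


@pytest.fixture(scope="session")
def small_ring():
    """3-subunit ring, 30 residues per chain: small enough for brute force."""
    spec = SimSpec(seed=7, n_subunits=3, n_residues_per_chain=30,
                   ring_radius=28.0, linkable_fraction=0.4)
    return make_ring_oligomer(spec), spec


@pytest.fixture(scope="session")
def ring7():
    """Mid-size 7-ring with a simulated cross-link table and its truth."""
    spec = SimSpec(seed=3, n_subunits=7, n_residues_per_chain=60,
                   ring_radius=28.0, linkable_fraction=0.3, n_links=40)
    model = make_ring_oligomer(spec)
    table, truth = simulate_crosslinks(model, spec)
    return model, table, truth, spec


@pytest.fixture(scope="session")
def two_domain():
    """Two compact domains on a 28-residue extended linker."""
    model, domains = make_multidomain_chain([60, 60], [28], seed=1,
                                            linkable_fraction=0.4)
    return model, domains


@pytest.fixture()
def toy_dimer():
    """Hand-built homodimer: two 4-residue chains with known coordinates."""
    coords_a = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
    coords_b = coords_a + np.array([0.0, 10.0, 0.0])
    chains = {
        "A": Chain("A", np.arange(1, 5), list("KAKA"), coords_a),
        "B": Chain("B", np.arange(1, 5), list("KAKA"), coords_b),
    }
    return StructureModel("dimer", chains, {"A": "P1", "B": "P1"})


def make_links(rows):
    """Helper: rows of (pa, ia, pb, ib[, csm, rep, cond]) -> table."""
    links = []
    for row in rows:
        pa, ia, pb, ib, *rest = row
        csm = rest[0] if len(rest) > 0 else 1
        rep = rest[1] if len(rest) > 1 else 1
        cond = rest[2] if len(rest) > 2 else ""
        links.append(CrossLink(pa, ia, pb, ib, csm, rep, cond))
    return CrossLinkTable(links=links)
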