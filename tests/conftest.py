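"""Shared fixtures: generated reference panels and simulated libraries."""

import numpy as np
import pytest

import srnapipe as sp


@pytest.fixture(scope="session")
def panel():
    """Mid-size generated reference panel."""
    return sp.build_reference_panel(7, n_mirnas=8, n_families=4, n_hairpins=3)


@pytest.fixture(scope="session")
def truth(panel):
    return sp.build_truth_table(panel, {"Control": 20000, "Test1": 20000}, seed=11)


@pytest.fixture(scope="session")
def profiles(panel, truth):
    """Cleaned, collapsed profiles of two simulated 20k-read libraries."""
    out = {}
    for i, lib in enumerate(("Control", "Test1")):
        recs, _ = sp.simulate_library(panel, truth, lib, 20000, seed=100 + i)
        out[lib] = sp.build_profile(lib, iter(recs), panel.adapter)
    return out


@pytest.fixture(scope="session")
def assignments(panel, profiles):
    return {lib: sp.classify_profile(p, panel) for lib, p in profiles.items()}


@pytest.fixture(scope="session")
def hand_panel():
    """A tiny hand-written panel with known overlaps for annotation tests."""
    let7 = "UGAGGUAGUAGGUUGUGUGGUU"
    mir9 = "UCUUUGGUUAUCUAGCUGUAUGA"
    matures = {"hsa-let-7b-5p": let7, "hsa-miR-9-5p": mir9}
    precursors = {n + "-pre": s for n, s in matures.items()}
    genome = {"segA": "".join(s.replace("U", "T") for s in matures.values()) + "ACGT" * 30}
    rrna = "GGGCGTACGATCGATCGGCTAGCTAGGATCCGATCGTAGCTAGCATCGATT"
    ncrna = {
        "rRNA": {"rRNA_1": rrna},
        # tRNA_1 deliberately contains the let-7 sequence to exercise priority
        "tRNA": {"tRNA_1": "AAAA" + let7.replace("U", "T") + "CCCC"},
        "snRNA": {"snRNA_1": "CATTGCACTCCGGATGTGCTGA"},
        "snoRNA": {"snoRNA_1": "TGATGACTCTAGCAGGGTTCGA"},
        "exon": {"exon_1": "ATGGCGGCGCTGAGCGGTGGCGGTGGTGGCGGCGAGCCGGGCCAGGGG"},
    }
    p = sp.ReferencePanel(genome, matures, {n: n for n in matures}, precursors, ncrna, sp.DEFAULT_ADAPTER)
    p.validate()
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
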