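from __future__ import annotations

import numpy as np
import pytest

from komagen import synth
from komagen.manifest import apply_exclusions, reference_exclusions, reference_manifest


@pytest.fixture(scope="session")
def genome_set() -> synth.SyntheticGenomeSet:
    """The default 18-genome study-shaped synthetic set (fixed seed)."""
    return synth.generate_genome_set(synth.default_config(seed=7))


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    """A light configuration for tests that write files or rerun generation."""
    fams = (
        synth.PlasmidFamilySpec("famA", "backbone", 3, 10_000, mutation_rate=0.005,
                                hosts=None),
        synth.PlasmidFamilySpec("famB", "mosaic", 3, 5_000, module_fraction=0.3,
                                hosts=None),
    )
    return synth.SynthConfig(
        n_genomes=4,
        chromosome_length_bp=900_000,
        plasmid_families=fams,
        bcs_specs=(
            synth.BcsArchSpec(),
            synth.BcsArchSpec(qualifies=False, dispersed=True, bcsA_copies=3),
            synth.BcsArchSpec(ggdef_in_window=False, eal_in_window=False),
            synth.BcsArchSpec(bcsA_copies=3, dispersed=True),
        ),
        is_spec=synth.ISSpec(count_range=(5, 12), length_range=(700, 1500)),
        prophage_spec=synth.ProphageSpec(count_range=(1, 2), length_range=(10_080, 30_000)),
        pangenome_spec=synth.PangenomeSpec(n_core=20, n_accessory=40, singleton_range=(2, 6)),
        seed=11,
    )


@pytest.fixture(scope="session")
def nonredundant_manifest():
    """The bundled curated manifest after clonal exclusions (18 genomes)."""
    return apply_exclusions(reference_manifest(), reference_exclusions())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
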