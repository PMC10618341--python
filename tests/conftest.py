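import numpy as np
import pytest

from gpdva.founders import FounderSpec, get_preset, synth_ancestral
from gpdva.genotypes import GeneticMap


def make_map(chrom_specs):
    """Build a map from {chrom_id: [positions]} with length = max position (min 1 cM)."""
    chromosomes = [(c, max(max(pos), 1.0)) for c, pos in chrom_specs.items()]
    loci = []
    k = 0
    for c, positions in chrom_specs.items():
        for x in positions:
            loci.append((f"m{k}", c, float(x)))
            k += 1
    return GeneticMap.build(chromosomes, loci)


@pytest.fixture(scope="session")
def elite_panel():
    """Default elite-like synthetic ancestral panel, shared across the session."""
    return synth_ancestral(get_preset("elite-like"), np.random.default_rng(2026))


@pytest.fixture(scope="session")
def small_panel():
    """Reduced panel for fast scenario tests: 40 lines, 400 loci, 4 chromosomes."""
    spec = FounderSpec(
        n_lines=40, n_chromosomes=4, total_length_cM=480.0, n_loci=400,
        monomorphic_fraction=0.05, ld_decay_target_cM=20.0,
    )
    panel, _ = synth_ancestral(spec, np.random.default_rng(7))
    return panel
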