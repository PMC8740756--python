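"""Shared fixtures: small synthetic panels and fragment sets.

All fixtures are generated programmatically and deterministically; nothing
is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from sedadna import simulate as sim
from sedadna.profiling import PanelAligner, ReferencePanel
from sedadna.types import AlignedFragment


def make_fragment(
    ref: str,
    read: str,
    fragment_id: str = "f1",
    spot_id: str = "s1",
    reference_id: str = "ref",
    start: int = 0,
    strand: str = "+",
    score: float = 60.0,
) -> AlignedFragment:
    """Hand-built ungapped aligned fragment from two equal-length strings."""
    assert len(ref) == len(read)
    return AlignedFragment(
        fragment_id=fragment_id,
        spot_id=spot_id,
        reference_id=reference_id,
        start=start,
        end=start + len(ref),
        strand=strand,
        pairs=tuple(zip(ref, read)),
        mapping_score=score,
    )


def fragments_with_terminal_ct(
    n_ct: int, n_total: int, length: int = 40
) -> list[AlignedFragment]:
    """Fragments whose position-1 reference base is C at both ends, with
    exactly ``n_ct`` of them showing C→T there (both ends)."""
    out = []
    inner = "A" * (length - 2)
    for i in range(n_total):
        read_end = "T" if i < n_ct else "C"
        ref = "C" + inner + "C"
        read = read_end + inner + read_end
        out.append(make_fragment(ref, read, fragment_id=f"f{i:04d}"))
    return out


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    cfg = sim.default_config(seed=11)
    cfg.mitogenome_length = 3000
    cfg.n_families = 3
    cfg.taxa_layouts = {
        "fam01_sp01": sim.TaxonLayout("clustered", abundance=2.0,
                                      cluster_radius_mm=9.0),
        "fam02_sp01": sim.TaxonLayout("random", abundance=1.5),
        "fam03_sp01": sim.TaxonLayout("uniform", abundance=1.0),
    }
    cfg.fragments_per_mg = 3.0
    return cfg


@pytest.fixture(scope="session")
def small_panel(small_config) -> ReferencePanel:
    return sim.generate_panel(small_config)


@pytest.fixture(scope="session")
def small_aligner(small_panel) -> PanelAligner:
    return PanelAligner(small_panel)


@pytest.fixture(scope="session")
def small_block(small_config, small_panel):
    layout, frags, truth = sim.generate_block(small_config, small_panel)
    return layout, frags, truth


def aligned_from_truth(
    genome: str,
    start: int,
    length: int,
    strand: str,
    read: str,
    fragment_id: str,
    spot_id: str = "s1",
    reference_id: str = "ref",
) -> AlignedFragment:
    """Aligned fragment built from its known (truth) placement.

    ``read`` is the sequenced fragment in read orientation; for minus-strand
    placements the paired reference bases are reverse-complemented to match.
    """
    L = len(genome)
    if start + length <= L:
        ref_slice = genome[start:start + length]
        wraps = False
    else:
        ref_slice = genome[start:] + genome[:start + length - L]
        wraps = True
    if strand == "-":
        ref_slice = sim.revcomp(ref_slice)
    return AlignedFragment(
        fragment_id=fragment_id,
        spot_id=spot_id,
        reference_id=reference_id,
        start=start,
        end=start + length,
        strand=strand,
        pairs=tuple(zip(ref_slice, read)),
        wraps=wraps,
    )


def simulate_deaminated_library(
    genome: str,
    n_fragments: int,
    seed: int,
    p0: float = 0.3,
    lam: float = 0.3,
    error: float = 0.001,
    damaged: bool = True,
    length: int = 45,
) -> list[AlignedFragment]:
    """Fragments with truth placements, damaged per the exponential model."""
    rng = np.random.default_rng(seed)
    out = []
    L = len(genome)
    for i in range(n_fragments):
        start = int(rng.integers(L))
        if start + length <= L:
            raw = genome[start:start + length]
        else:
            raw = genome[start:] + genome[:start + length - L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = sim.revcomp(raw)
        read = sim.apply_damage(raw, rng, p0, lam, error, damaged=damaged)
        out.append(
            aligned_from_truth(genome, start, length, strand, read, f"f{i:05d}")
        )
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
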