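"""Synthetic sediment-block aDNA datasets with a complete truth record.

The generator emulates the data a microstratigraphic sampling campaign
produces: a panel of mammalian mitogenomes with a species→family taxonomy,
a grid of drilled sampling spots on a block face, and per-spot libraries of
short, adapter-merged fragments carrying single-stranded-library damage
(terminal C→T substitutions at both ends, exponentially decaying inward)
plus an undamaged present-day contaminant fraction. Spatial structure per
taxon is one of three canonical patterns: a Thomas-style cluster process,
independent Bernoulli presence, or an alternating sub-grid.

Every fragment's origin (taxon, spot, ancient/contaminant) is recorded in a
:class:`TruthRecord` so downstream estimators can be tested for parameter
recovery rather than against opaque fixtures.

Randomness: one master seed; each spot, taxon layout and auxiliary draw
derives its own `numpy` Generator from ``default_rng([master_seed, tag])``
where ``tag`` is a stable 32-bit hash of a string key. Adding a spot or a
taxon therefore does not perturb the streams of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from sedadna.types import (
    BlockLayout,
    ReferencePanel,
    SamplingSpot,
    write_fragments_fasta,
)

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _stable_u32(key: str) -> int:
    """Stable 32-bit hash of a string key (independent of PYTHONHASHSEED)."""
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big")


def substream(seed: int, key: str) -> np.random.Generator:
    """Deterministic child RNG for one named component of the simulation."""
    return np.random.default_rng([int(seed), _stable_u32(key)])


@dataclass
class TaxonLayout:
    """Spatial pattern settings for one panel taxon.

    pattern 'clustered': spots within ``cluster_radius_mm`` of one of
    ``n_clusters`` centres (centres drawn at spot positions so at least one
    spot is always positive); 'random': i.i.d. Bernoulli(``presence_prob``)
    presence per spot; 'uniform': alternating sub-grid (checkerboard over
    the ranked x/y coordinates). ``abundance`` weights the taxon's share of
    a spot's fragments relative to the other taxa present there.
    """

    pattern: Literal["clustered", "random", "uniform"]
    abundance: float = 1.0
    n_clusters: int = 1
    cluster_radius_mm: float = 10.0
    presence_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.pattern not in ("clustered", "random", "uniform"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset.

    Fragment lengths follow ``min_length - 1 + Geometric(fragment_length_p)``
    (support starts at ``min_length``; mean ``min_length - 1 + 1/p``), so the
    default p=0.1 gives median ≈ 41 bases — short fragments, as expected for
    degraded sedimentary DNA. Damage follows p(d) = p0·exp(−λd) for a
    read-strand C at 0-based distance d from the nearer end, at both ends
    (single-stranded library chemistry).
    """

    seed: int = 0
    n_families: int = 4
    species_per_family: int = 2
    mitogenome_length: int = 16_500
    divergence_within: float = 0.02
    divergence_between: float = 0.10
    min_length: int = 35
    fragment_length_p: float = 0.1
    damage_p0: float = 0.3
    damage_lambda: float = 0.3
    error_rate: float = 0.001
    contaminant_fraction: float = 0.1
    fragments_per_mg: float = 10.0
    spots: list[SamplingSpot] = field(default_factory=list)
    area_cm2: float = 14.0
    taxa_layouts: dict[str, TaxonLayout] = field(default_factory=dict)
    spike_in_copies: int = 10_000
    spike_in_recovery: float = 0.8
    layer_efficiency: dict[str, float] = field(default_factory=dict)
    molecules_per_mg: float = 1.0e6
    quant_noise_sigma: float = 0.3
    sediment_resin_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("damage_p0", "error_rate", "contaminant_fraction",
                     "spike_in_recovery", "divergence_within", "divergence_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.damage_lambda < 0:
            raise ValueError("damage_lambda must be >= 0")
        if self.mitogenome_length <= 0:
            raise ValueError("mitogenome_length must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 < self.fragment_length_p <= 1.0:
            raise ValueError("fragment_length_p must be in (0, 1]")
        if self.n_families < 1 or self.species_per_family < 1:
            raise ValueError("need at least one family and one species per family")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["spots"] = [asdict(s) for s in self.spots]
        d["taxa_layouts"] = {k: asdict(v) for k, v in self.taxa_layouts.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["spots"] = [SamplingSpot(**s) for s in d.get("spots", [])]
        d["taxa_layouts"] = {
            k: TaxonLayout(**v) for k, v in d.get("taxa_layouts", {}).items()
        }
        return cls(**d)


@dataclass
class FragmentOrigin:
    taxon: str
    spot_id: str
    ancient: bool
    start: int
    length: int
    strand: str


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, for parameter-recovery tests."""

    spot_composition: dict[str, dict[str, float]]
    fragment_origin: dict[str, FragmentOrigin]
    damage_p0: float
    damage_lambda: float
    error_rate: float
    taxon_patterns: dict[str, str]
    taxon_presence: dict[str, list[str]]  # taxon -> positive spot ids
    sex_truth: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for spot, comp in self.spot_composition.items():
            if comp and abs(sum(comp.values()) - 1.0) > 1e-9:
                raise AssertionError(f"composition at {spot} does not sum to 1")

    def to_json(self, path: str | Path) -> None:
        d = {
            "spot_composition": self.spot_composition,
            "fragment_origin": {k: asdict(v) for k, v in self.fragment_origin.items()},
            "damage_p0": self.damage_p0,
            "damage_lambda": self.damage_lambda,
            "error_rate": self.error_rate,
            "taxon_patterns": self.taxon_patterns,
            "taxon_presence": self.taxon_presence,
            "sex_truth": self.sex_truth,
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        d["fragment_origin"] = {
            k: FragmentOrigin(**v) for k, v in d["fragment_origin"].items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# panel generation

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability `rate` to a different base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size:
        # shift by 1..3 in base index: always a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def generate_panel(config: SimulationConfig) -> ReferencePanel:
    """Simulate a circular mitogenome panel by mutating a random root.

    Family ancestors diverge from the root by ``divergence_between/2`` each
    (so pairs of families differ by ≈ ``divergence_between``); species
    diverge from their family ancestor by ``divergence_within/2``. Configs
    with within-family divergence ≥ between-family divergence cannot
    satisfy the identity ordering and are rejected.
    """
    if config.species_per_family > 1 and config.n_families > 1 \
            and config.divergence_within >= config.divergence_between:
        raise ValueError(
            "divergence_within must be < divergence_between for the panel "
            "identity ordering to hold"
        )
    rng = substream(config.seed, "panel")
    root = rng.integers(0, 4, size=config.mitogenome_length)
    genomes: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    for i in range(config.n_families):
        family = f"fam{i + 1:02d}"
        ancestor = _mutate(root, config.divergence_between / 2.0, rng)
        for j in range(config.species_per_family):
            sp = f"{family}_sp{j + 1:02d}"
            genome = _mutate(ancestor, config.divergence_within / 2.0, rng)
            genomes[sp] = "".join(BASES[genome])
            taxonomy[sp] = family
    return ReferencePanel(genomes=genomes, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# damage model

def apply_damage(
    sequence: str,
    rng: np.random.Generator,
    p0: float,
    lam: float,
    error_rate: float = 0.0,
    damaged: bool = True,
) -> str:
    """Deaminate a fragment and add sequencing error.

    Each C at 0-based distance d from the nearer end becomes T with
    probability p0·exp(−λd) (both ends: single-stranded prep). Sequencing
    error is applied afterwards to every base at ``error_rate``, replacing
    it with a uniformly chosen different base. With ``damaged=False`` only
    the error step runs (present-day contaminant molecules).
    """
    arr = np.frombuffer(sequence.encode(), dtype="S1").astype("U1")
    n = arr.size
    if damaged and p0 > 0 and n > 0:
        idx = np.arange(n)
        d = np.minimum(idx, n - 1 - idx)
        p = p0 * np.exp(-lam * d)
        hit = (arr == "C") & (rng.random(n) < p)
        arr[hit] = "T"
    if error_rate > 0 and n > 0:
        err = np.flatnonzero(rng.random(n) < error_rate)
        if err.size:
            cur = np.searchsorted(BASES, arr[err])
            arr[err] = BASES[(cur + rng.integers(1, 4, size=err.size)) % 4]
    return "".join(arr)


# ---------------------------------------------------------------------------
# spatial presence patterns

def _grid_ranks(values: np.ndarray) -> np.ndarray:
    """Map coordinates to integer grid ranks (rounded to 0.1 mm)."""
    keys = np.round(values * 10).astype(int)
    uniq = np.unique(keys)
    return np.searchsorted(uniq, keys)


def taxon_presence(
    layout: BlockLayout,
    taxon: str,
    spec: TaxonLayout,
    seed: int,
) -> list[str]:
    """Positive spot ids for one taxon under its spatial pattern."""
    rng = substream(seed, f"layout:{taxon}")
    xs = np.array([s.x_mm for s in layout.spots])
    ys = np.array([s.y_mm for s in layout.spots])
    ids = [s.spot_id for s in layout.spots]
    if spec.pattern == "uniform":
        cols = _grid_ranks(xs)
        rows = _grid_ranks(ys)
        phase = _stable_u32(taxon) % 2
        mask = (cols + rows) % 2 == phase
    elif spec.pattern == "random":
        mask = rng.random(len(ids)) < spec.presence_prob
        if not mask.any():  # a taxon in the layout occurs somewhere
            mask[rng.integers(len(ids))] = True
    else:  # clustered: centres seeded at spot positions (Thomas-style disks)
        centres = rng.choice(len(ids), size=min(spec.n_clusters, len(ids)),
                             replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        for c in centres:
            d = np.hypot(xs - xs[c], ys - ys[c])
            mask |= d <= spec.cluster_radius_mm
    return [i for i, m in zip(ids, mask) if m]


# ---------------------------------------------------------------------------
# block generation

def _draw_fragment_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    return config.min_length - 1 + int(rng.geometric(config.fragment_length_p))


def _draw_fragment(
    genome: str,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> tuple[str, int, int, str]:
    """Slice one fragment from a circular genome: (raw seq, start, length, strand)."""
    L = len(genome)
    length = min(_draw_fragment_length(rng, config), L)
    start = int(rng.integers(L))
    if start + length <= L:
        raw = genome[start:start + length]
    else:
        raw = genome[start:] + genome[: start + length - L]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        raw = revcomp(raw)
    return raw, start, length, strand


def generate_block(
    config: SimulationConfig,
    panel: ReferencePanel | None = None,
) -> tuple[BlockLayout, dict[str, list[tuple[str, str]]], TruthRecord]:
    """Simulate fragment libraries for every sampling spot of a block.

    Returns the layout, per-spot lists of (fragment_id, sequence), and the
    truth record. Fragment counts per spot are Poisson with mean
    ``fragments_per_mg × mass_mg``; each fragment's taxon follows the
    spot's composition (presence pattern × abundance weights), is drawn
    from either strand of the circular genome, and is deaminated unless it
    belongs to the contaminant fraction.
    """
    if not config.spots:
        raise ValueError("config.spots is empty")
    if not config.taxa_layouts:
        raise ValueError("config.taxa_layouts is empty")
    if any(s.mass_mg <= 0 for s in config.spots):
        raise ValueError("spot masses must be positive")
    if panel is None:
        panel = generate_panel(config)
    unknown = set(config.taxa_layouts) - set(panel.genomes)
    if unknown:
        raise ValueError(f"layout taxa not in panel: {sorted(unknown)}")

    layout = BlockLayout(spots=list(config.spots), area_cm2=config.area_cm2)
    presence = {
        taxon: taxon_presence(layout, taxon, spec, config.seed)
        for taxon, spec in sorted(config.taxa_layouts.items())
    }

    spot_fragments: dict[str, list[tuple[str, str]]] = {}
    composition: dict[str, dict[str, float]] = {}
    origins: dict[str, FragmentOrigin] = {}

    for spot in layout.spots:
        rng = substream(config.seed, f"spot:{spot.spot_id}")
        taxa = sorted(t for t, pos in presence.items() if spot.spot_id in pos)
        weights = np.array([config.taxa_layouts[t].abundance for t in taxa])
        frac = weights / weights.sum() if taxa else np.array([])
        composition[spot.spot_id] = dict(zip(taxa, frac.tolist()))
        frags: list[tuple[str, str]] = []
        if taxa:
            n = int(rng.poisson(config.fragments_per_mg * spot.mass_mg))
            choices = rng.choice(len(taxa), size=n, p=frac)
            for i in range(n):
                taxon = taxa[int(choices[i])]
                raw, start, length, strand = _draw_fragment(
                    panel.genomes[taxon], rng, config
                )
                ancient = bool(rng.random() >= config.contaminant_fraction)
                seq = apply_damage(
                    raw, rng, config.damage_p0, config.damage_lambda,
                    config.error_rate, damaged=ancient,
                )
                fid = f"{spot.spot_id}|{i:05d}"
                frags.append((fid, seq))
                origins[fid] = FragmentOrigin(
                    taxon=taxon, spot_id=spot.spot_id, ancient=ancient,
                    start=start, length=length, strand=strand,
                )
        spot_fragments[spot.spot_id] = frags

    truth = TruthRecord(
        spot_composition=composition,
        fragment_origin=origins,
        damage_p0=config.damage_p0,
        damage_lambda=config.damage_lambda,
        error_rate=config.error_rate,
        taxon_patterns={t: s.pattern for t, s in config.taxa_layouts.items()},
        taxon_presence=presence,
    )
    truth.validate()
    return layout, spot_fragments, truth


# ---------------------------------------------------------------------------
# nuclear fragments

def generate_site_panel(n_x: int, n_auto: int, seed: int):
    """Desk-scale stand-in for a genome-wide informative-SNP capture panel."""
    from sedadna.nuclear import NuclearSite, NuclearSitePanel

    rng = substream(seed, "site_panel")
    sites = []
    for i in range(n_x):
        a, b = rng.choice(4, size=2, replace=False)
        sites.append(NuclearSite("X", 1000 + i, str(BASES[a]), str(BASES[b])))
    for i in range(n_auto):
        a, b = rng.choice(4, size=2, replace=False)
        sites.append(NuclearSite("1", 1000 + i, str(BASES[a]), str(BASES[b])))
    return NuclearSitePanel(sites=sites)


def generate_nuclear_fragments(
    site_panel,
    sex: Literal["male", "female"],
    n_fragments: int,
    seed: int,
    mismapping_fraction: float = 0.0,
):
    """Simulate deaminated fragments hitting a nuclear target-site panel.

    A fragment covers an X site with probability Sx·cX/(Sx·cX + 2·Sa) where
    cX is the X copy number (1 male, 2 female) and autosomes contribute two
    copies each. A ``mismapping_fraction`` of fragments carries the faunal
    (non-hominin) allele instead of the hominin one.
    """
    from sedadna.nuclear import NuclearFragment

    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    sx, sa = site_panel.n_x_sites, site_panel.n_auto_sites
    if sx + sa == 0:
        raise ValueError("site panel is empty")
    cx = 1 if sex == "male" else 2
    p_x = sx * cx / (sx * cx + 2 * sa)
    rng = substream(seed, f"nuclear:{sex}")
    x_sites = [s for s in site_panel.sites if s.is_x]
    a_sites = [s for s in site_panel.sites if not s.is_x]
    frags = []
    for i in range(n_fragments):
        if rng.random() < p_x:
            site = x_sites[int(rng.integers(len(x_sites)))]
        else:
            site = a_sites[int(rng.integers(len(a_sites)))]
        faunal = rng.random() < mismapping_fraction
        allele = site.faunal_allele if faunal else site.hominin_allele
        frags.append(
            NuclearFragment(
                fragment_id=f"nuc|{i:05d}",
                chromosome=site.chromosome,
                position=site.position,
                allele=allele,
                deaminated=True,
            )
        )
    truth = {"sex": sex, "mismapping_fraction": mismapping_fraction,
             "p_x_expected": p_x}
    return frags, truth


# ---------------------------------------------------------------------------
# quantification inputs

def simulate_library_quant(layout: BlockLayout, config: SimulationConfig):
    """Draw per-spot qPCR-style molecule counts and spike-in recoveries.

    total_molecules = molecules_per_mg × effective sediment mass × layer
    efficiency × lognormal noise; spike-in recovery is binomial with the
    layer efficiency as success probability, so inhibited layers depress
    both the yield and the spike-in conversion rate.
    """
    import pandas as pd

    rows = []
    for spot in layout.spots:
        rng = substream(config.seed, f"quant:{spot.spot_id}")
        eff = config.layer_efficiency.get(spot.layer, config.spike_in_recovery)
        effective_mg = spot.mass_mg * config.sediment_resin_ratio
        noise = float(np.exp(rng.normal(0.0, config.quant_noise_sigma)))
        total = int(config.molecules_per_mg * effective_mg * eff * noise)
        recovered = int(rng.binomial(config.spike_in_copies, eff))
        rows.append(
            {
                "sample_id": spot.spot_id,
                "total_molecules": total,
                "drilled_mass_mg": spot.mass_mg,
                "sediment_resin_ratio": config.sediment_resin_ratio,
                "spike_in_input": config.spike_in_copies,
                "spike_in_recovered": recovered,
                "layer": spot.layer,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demo configuration and dataset writer

def alternating_grid_spots(
    n_cols: int = 6,
    n_rows: int = 4,
    pitch_mm: float = 8.0,
    regular_mass_mg: float = 30.1,
    micro_mass_mg: float = 3.4,
    layer_boundary_row: int = 2,
) -> list[SamplingSpot]:
    """Alternating regular/micro sampling spots on a rectangular grid.

    Mimics a block face sampled alternately with a standard drill bit and a
    ~1 mm micro bit; rows below ``layer_boundary_row`` belong to the lower
    layer ("11.4"), the rest to the upper ("11.3").
    """
    spots = []
    for r in range(n_rows):
        for c in range(n_cols):
            micro = (r + c) % 2 == 1
            spots.append(
                SamplingSpot(
                    spot_id=f"S{r * n_cols + c + 1:02d}",
                    x_mm=c * pitch_mm,
                    y_mm=r * pitch_mm,
                    mass_mg=micro_mass_mg if micro else regular_mass_mg,
                    category="micro" if micro else "regular",
                    layer="11.4" if r < layer_boundary_row else "11.3",
                )
            )
    return spots


def default_config(seed: int = 0) -> SimulationConfig:
    """The shipped demo: 4 families × 2 species over a 24-spot grid."""
    return SimulationConfig(
        seed=seed,
        spots=alternating_grid_spots(),
        taxa_layouts={
            "fam01_sp01": TaxonLayout("clustered", abundance=2.0,
                                      cluster_radius_mm=9.0),
            "fam02_sp01": TaxonLayout("random", abundance=1.5),
            "fam03_sp01": TaxonLayout("uniform", abundance=1.0),
            "fam04_sp01": TaxonLayout("random", abundance=0.5,
                                      presence_prob=0.3),
        },
        layer_efficiency={"11.3": 0.1, "11.4": 0.8},
        sediment_resin_ratio=0.4,
    )


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write the full synthetic dataset; returns file→sha256."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = generate_panel(config)
    layout, spot_fragments, truth = generate_block(config, panel)

    panel.write(outdir / "panel.fasta", outdir / "taxonomy.tsv")
    layout.to_tsv(outdir / "spots.tsv")
    all_frags = [f for sid in sorted(spot_fragments) for f in spot_fragments[sid]]
    write_fragments_fasta(outdir / "fragments.fasta", all_frags)
    truth.to_json(outdir / "truth.json")
    simulate_library_quant(layout, config).to_csv(
        outdir / "quant.tsv", sep="\t", index=False
    )
    config.to_yaml(outdir / "config.yaml")

    return write_manifest(outdir)


def write_manifest(outdir: str | Path) -> dict[str, str]:
    """(Re)write manifest.json with sha256 of every file in the dataset dir."""
    outdir = Path(outdir)
    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
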